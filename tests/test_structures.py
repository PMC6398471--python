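"""Toy structures, PDB parsing, crosslink distance classification and
linkage maps."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

import kymoxl as kx
from kymoxl.synth import make_toy_structure, simulate_structure_crosslinks

TWO_RESIDUE_PDB = """\
ATOM      1  N   LYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  LYS A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      3  CA  SER A   2       4.000   6.000  12.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA ALYS A   1       0.000   0.000   0.000  0.30  0.00           C
ATOM      2  CA BLYS A   1       9.000   9.000   9.000  0.70  0.00           C
END
"""


class TestToyStructure:
    def test_extended_collinear_spacing(self):
        s = make_toy_structure(12, "extended")
        d = np.linalg.norm(s.coord("A", 1) - s.coord("A", 11))
        assert d == pytest.approx(38.0, abs=1e-9)

    def test_helix_consecutive_residue_distance(self):
        # chord of the ideal alpha-helix: sqrt((2R sin(50 deg))^2 + rise^2)
        expected = math.sqrt((2 * 2.3 * math.sin(math.radians(50))) ** 2 + 1.5**2)
        s = make_toy_structure(20, "helix")
        for i in range(1, 19):
            d = np.linalg.norm(s.coord("A", i) - s.coord("A", i + 1))
            assert d == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.8, abs=0.1)

    def test_two_chains_rigid_offset(self):
        s = make_toy_structure(5, "extended", n_chains=2, chain_offset=100.0)
        span = 4 * 3.8
        for i in range(1, 6):
            for j in range(1, 6):
                d = np.linalg.norm(s.coord("A", i) - s.coord("B", j))
                assert d >= 100.0 - span - 1e-9
                assert d >= 100.0 - 1e-9  # orthogonal offset: never below 100

    def test_determinism_and_minimum_size(self):
        a = make_toy_structure(30, "random", seed=5)
        b = make_toy_structure(30, "random", seed=5)
        pd.testing.assert_frame_equal(a.residues, b.residues)
        with pytest.raises(ValueError):
            make_toy_structure(1)


class TestPDBIO:
    def test_minimal_two_residue_fixture(self):
        s = kx.read_structure(TWO_RESIDUE_PDB)
        assert len(s) == 2
        np.testing.assert_allclose(s.coord("A", 1), [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.coord("A", 2), [4.0, 6.0, 12.0])
        assert s.residues["res_name"].tolist() == ["LYS", "SER"]

    def test_altloc_resolved_by_occupancy(self):
        s = kx.read_structure(ALTLOC_PDB)
        assert len(s) == 1
        np.testing.assert_allclose(s.coord("A", 1), [9.0, 9.0, 9.0])

    def test_round_trip_preserves_coordinates(self):
        s = make_toy_structure(40, "random", n_chains=2, seed=3)
        back = kx.read_structure(kx.to_pdb_string(s))
        np.testing.assert_allclose(
            back.residues[["x", "y", "z"]].to_numpy(),
            s.residues[["x", "y", "z"]].to_numpy(),
            atol=1.5e-3,  # PDB fixed-width: 3 decimals
        )

    def test_no_atom_records_is_error(self):
        with pytest.raises(ValueError):
            kx.read_structure("REMARK nothing here\nEND\n")


class TestDistancesAndClassification:
    def test_self_pair_distance_zero(self):
        s = make_toy_structure(10, "extended")
        links = pd.DataFrame(
            {"protein_a": ["toy"], "res_a": [4], "type_a": ["LYS"],
             "protein_b": ["toy"], "res_b": [4], "type_b": ["LYS"]}
        )
        d = kx.crosslink_distances(links, s, {"toy": ["A"]})
        assert d["intra_distance"].iloc[0] == pytest.approx(0.0)

    def test_extended_chain_collinear_distance(self):
        s = make_toy_structure(15, "extended")
        links = pd.DataFrame(
            {"protein_a": ["toy"], "res_a": [1], "protein_b": ["toy"], "res_b": [11]}
        )
        d = kx.crosslink_distances(links, s, {"toy": ["A"]})
        assert d["intra_distance"].iloc[0] == pytest.approx(38.0)

    def test_distances_match_brute_force_oracle(self):
        s = make_toy_structure(50, "random", n_chains=2, seed=11)
        rng = np.random.default_rng(0)
        res = rng.integers(1, 51, size=(100, 2))
        links = pd.DataFrame(
            {"protein_a": "toy", "res_a": res[:, 0], "protein_b": "toy", "res_b": res[:, 1]}
        )
        d = kx.crosslink_distances(links, s, {"toy": ["A", "B"]})
        coords = {
            (r.chain, r.res_id): np.array([r.x, r.y, r.z])
            for r in s.residues.itertuples()
        }
        for k, (ra, rb) in enumerate(res):
            intra = min(
                np.linalg.norm(coords[(c, ra)] - coords[(c, rb)]) for c in "AB"
            )
            inter = min(
                np.linalg.norm(coords[(ca, ra)] - coords[(cb, rb)])
                for ca in "AB" for cb in "AB" if ca != cb
            )
            assert d["intra_distance"].iloc[k] == pytest.approx(intra, abs=1e-9)
            assert d["inter_distance"].iloc[k] == pytest.approx(inter, abs=1e-9)

    @pytest.mark.parametrize(
        "intra,inter,expected",
        [
            (10.0, 50.0, "intra_satisfied"),
            (30.0, 20.0, "inter_satisfied"),
            (30.0, 40.0, "violated"),
            (26.9, 26.9, "intra_satisfied"),  # intra precedence
        ],
    )
    def test_classification_rules(self, intra, inter, expected):
        df = pd.DataFrame(
            {"intra_distance": [intra], "inter_distance": [inter], "mapped": [True]}
        )
        out = kx.classify_crosslinks(df, d_max=27.0)
        assert out["class"].iloc[0] == expected

    def test_unmapped_residues_flagged_not_error(self):
        s = make_toy_structure(10, "extended")
        links = pd.DataFrame(
            {"protein_a": ["toy"], "res_a": [99], "protein_b": ["toy"], "res_b": [2]}
        )
        out = kx.classify_crosslinks(kx.crosslink_distances(links, s, {"toy": ["A"]}))
        assert out["class"].iloc[0] == "unmapped"

    def test_dmax_must_be_positive(self):
        df = pd.DataFrame({"intra_distance": [5.0], "inter_distance": [np.nan], "mapped": [True]})
        with pytest.raises(ValueError):
            kx.classify_crosslinks(df, d_max=0.0)

    def test_satisfied_set_monotone_in_dmax(self):
        s = make_toy_structure(60, "random", seed=21)
        rng = np.random.default_rng(1)
        res = rng.integers(1, 61, size=(200, 2))
        links = pd.DataFrame(
            {"protein_a": "toy", "res_a": res[:, 0], "protein_b": "toy", "res_b": res[:, 1]}
        )
        d = kx.crosslink_distances(links, s, {"toy": ["A"]})
        sat = lambda dmax: set(
            kx.classify_crosslinks(d, dmax).index[
                kx.classify_crosslinks(d, dmax)["class"].isin(
                    ["intra_satisfied", "inter_satisfied"]
                )
            ]
        )
        assert sat(15.0) <= sat(27.0) <= sat(60.0)

    def test_rigid_motion_invariance(self):
        s = make_toy_structure(40, "extended", n_chains=2, seed=31, chain_offset=100.0)
        theta = 0.7
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = s.transformed(rot, [12.0, -7.0, 3.0])
        links, _ = simulate_structure_crosslinks(s, 8, 4, seed=2)
        groups = {"toy": ["A", "B"]}
        before = kx.classify_crosslinks(kx.crosslink_distances(links, s, groups))
        after = kx.classify_crosslinks(kx.crosslink_distances(links, moved, groups))
        assert (before["class"] == after["class"]).all()
        np.testing.assert_allclose(
            before["intra_distance"], after["intra_distance"], atol=1e-9
        )


class TestSimulatedCrosslinks:
    def test_true_pairs_within_dmax(self):
        s = make_toy_structure(80, "random", seed=41)
        _, truth = simulate_structure_crosslinks(s, 20, 10, d_max=27.0, seed=3)
        assert (truth.loc[truth["is_true"], "min_distance"] <= 27.0).all()
        assert (truth.loc[~truth["is_true"], "min_distance"] > 27.0).all()

    def test_no_decoys_all_satisfied(self):
        s = make_toy_structure(80, "random", seed=41)
        links, _ = simulate_structure_crosslinks(s, 15, 0, seed=4)
        out = kx.classify_crosslinks(
            kx.crosslink_distances(links, s, {"toy": ["A"]}), 27.0
        )
        assert out["class"].isin(["intra_satisfied", "inter_satisfied"]).all()

    def test_seed_determinism(self):
        s = make_toy_structure(60, "random", seed=41)
        a, _ = simulate_structure_crosslinks(s, 10, 5, seed=7)
        b, _ = simulate_structure_crosslinks(s, 10, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_counts_error(self):
        s = make_toy_structure(5, "extended")  # max span 15.2 A: no decoys beyond 27
        with pytest.raises(ValueError):
            simulate_structure_crosslinks(s, 1, 50, d_max=27.0, seed=0)


class TestLinkageMap:
    def test_minimal_one_link_one_domain(self):
        links = pd.DataFrame(
            {"protein_a": ["mcak"], "res_a": [10], "protein_b": ["mcak"], "res_b": [50]}
        )
        arcs, bands = kx.linkage_map(
            links, [("mcak", "motor", 5, 45, "domain")], {"mcak": 100}
        )
        assert len(arcs) == 1 and len(bands) == 1
        assert arcs["x_a"].iloc[0] == 10 and arcs["x_b"].iloc[0] == 50

    def test_inter_protein_links_span_both_axes(self):
        links = pd.DataFrame(
            {"protein_a": ["mcak", "mcak"], "res_a": [10, 20],
             "protein_b": ["tubulin", "mcak"], "res_b": [30, 40]}
        )
        arcs, _ = kx.linkage_map(links, protein_lengths={"mcak": 100, "tubulin": 450})
        inter = arcs[arcs["inter_protein"]]
        assert len(inter) == 1
        assert inter["x_b"].iloc[0] > 100  # lands on the second protein's axis

    def test_empty_links_header_only(self):
        links = pd.DataFrame(columns=["protein_a", "res_a", "protein_b", "res_b"])
        arcs, bands = kx.linkage_map(links)
        assert arcs.empty and list(arcs.columns)

    def test_out_of_range_link_skipped_with_warning(self):
        links = pd.DataFrame(
            {"protein_a": ["p"], "res_a": [500], "protein_b": ["p"], "res_b": [2]}
        )
        with pytest.warns(UserWarning):
            arcs, _ = kx.linkage_map(links, protein_lengths={"p": 100})
        assert arcs.empty

    def test_annotation_outside_sequence_error(self):
        links = pd.DataFrame(
            {"protein_a": ["p"], "res_a": [5], "protein_b": ["p"], "res_b": [20]}
        )
        with pytest.raises(ValueError):
            kx.linkage_map(links, [("p", "bad", 50, 200, "domain")], {"p": 100})
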