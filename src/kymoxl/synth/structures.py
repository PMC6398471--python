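"""Toy structure and structure-derived crosslink generators.

``make_toy_structure`` builds small Cα-only models with analytically known
geometry (ideal α-helix, extended chain, or a random walk), so distance
computations can be checked by hand. ``simulate_structure_crosslinks``
samples residue pairs from such a model that are known to satisfy or
violate a crosslinker's maximum Cα-Cα distance, giving a labelled truth set
for the classification pipeline.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..structures import StructureModel, CROSSLINKABLE_BS3

__all__ = ["make_toy_structure", "simulate_structure_crosslinks"]

# residue-name pool: crosslinkable (K/S/T/Y) kept frequent so small toys
# always have usable sites
_RES_POOL = ["LYS", "SER", "THR", "TYR", "ALA", "LEU", "GLY", "GLU", "ASP", "VAL"]
_RES_P = [0.15, 0.12, 0.10, 0.08, 0.13, 0.12, 0.10, 0.10, 0.05, 0.05]

# ideal α-helix Cα parameters: 1.5 Å rise and 100° turn per residue on a
# 2.3 Å radius, giving consecutive-Cα spacing ≈ 3.8 Å
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
_HELIX_RADIUS = 2.3


def make_toy_structure(
    n_residues: int,
    geometry: str = "helix",
    n_chains: int = 1,
    seed: int = 0,
    spacing: float = 3.8,
    chain_offset: float = 30.0,
) -> StructureModel:
    """Build a deterministic Cα-only structure.

    Parameters
    ----------
    geometry : {'helix', 'extended', 'random'}
        'helix' uses ideal α-helix rise/turn (consecutive Cα ≈ 3.8 Å apart);
        'extended' places residues collinearly at ``spacing`` Å; 'random' is
        a random walk with ``spacing``-Å steps.
    n_chains : int
        Identical copies translated by ``chain_offset`` Å along +y per
        chain; chain ids A, B, C, ...
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if n_chains < 1:
        raise ValueError("need at least 1 chain")
    rng = np.random.default_rng(seed)

    i = np.arange(n_residues)
    if geometry == "extended":
        coords = np.column_stack([i * spacing, np.zeros(n_residues), np.zeros(n_residues)])
    elif geometry == "helix":
        theta = np.deg2rad(_HELIX_TURN_DEG) * i
        coords = np.column_stack(
            [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), _HELIX_RISE * i]
        )
    elif geometry == "random":
        steps = rng.normal(size=(n_residues - 1, 3))
        steps *= spacing / np.linalg.norm(steps, axis=1, keepdims=True)
        coords = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")

    res_names = rng.choice(_RES_POOL, size=n_residues, p=_RES_P)
    rows = []
    for c in range(n_chains):
        chain_id = chr(ord("A") + c)
        offset = np.array([0.0, chain_offset * c, 0.0])
        for k in range(n_residues):
            x, y, z = coords[k] + offset
            rows.append(
                {
                    "chain": chain_id,
                    "res_id": k + 1,
                    "ins_code": "",
                    "res_name": str(res_names[k]),
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    return StructureModel(pd.DataFrame(rows))


def simulate_structure_crosslinks(
    structure: StructureModel,
    n_true: int,
    n_decoy: int,
    d_max: float = 27.0,
    seed: int = 0,
    protein: str = "toy",
    crosslinker: str = "BS3",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample crosslink residue pairs with known distance labels.

    Candidate residues are the crosslinkable set for BS3 chemistry
    (N-terminus, Lys, Ser, Thr, Tyr). A residue-index pair is a *true* link
    if its minimum Cα-Cα distance over all chain assignments is ≤ ``d_max``,
    and a *decoy* if every assignment exceeds ``d_max`` (so no downstream
    chain choice can rescue it).

    Returns ``(links, truth)``: the consumer-facing link table
    (protein/residue columns only, labels withheld) and a truth sidecar with
    ``is_true`` and ``min_distance``.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    rng = np.random.default_rng(seed)

    mask = structure.crosslinkable_mask()
    cand = structure.residues[mask]
    res_ids = np.array(sorted(cand["res_id"].unique()))
    if len(res_ids) < 2:
        raise ValueError("structure has fewer than 2 crosslinkable residues")

    # min distance over all chain assignments, per residue-index pair
    chains = structure.chains
    coords = {}
    names = {}
    for ch in chains:
        sub = structure.chain_residues(ch).set_index("res_id")
        coords[ch] = sub[["x", "y", "z"]]
        names[ch] = sub["res_name"]

    # distinct residue-index pairs only: a self link (i, i) would always
    # classify as satisfied at intra distance 0 downstream
    pairs = []
    for ai in range(len(res_ids)):
        for bi in range(ai + 1, len(res_ids)):
            ra, rb = int(res_ids[ai]), int(res_ids[bi])
            dmin = math.inf
            for ca in chains:
                if ra not in coords[ca].index:
                    continue
                pa = coords[ca].loc[ra].to_numpy(float)
                for cb in chains:
                    if rb not in coords[cb].index:
                        continue
                    pb = coords[cb].loc[rb].to_numpy(float)
                    d = float(np.linalg.norm(pa - pb))
                    dmin = min(dmin, d)
            if math.isfinite(dmin):
                pairs.append((ra, rb, dmin))
    pair_df = pd.DataFrame(pairs, columns=["res_a", "res_b", "min_distance"])

    true_pool = pair_df[pair_df["min_distance"] <= d_max]
    decoy_pool = pair_df[pair_df["min_distance"] > d_max]
    if n_true > len(true_pool):
        raise ValueError(f"only {len(true_pool)} pairs within {d_max} Å; asked for {n_true}")
    if n_decoy > len(decoy_pool):
        raise ValueError(f"only {len(decoy_pool)} pairs beyond {d_max} Å; asked for {n_decoy}")

    chosen_true = true_pool.sample(n=n_true, random_state=rng.integers(2**31)) if n_true else true_pool.iloc[:0]
    chosen_decoy = decoy_pool.sample(n=n_decoy, random_state=rng.integers(2**31)) if n_decoy else decoy_pool.iloc[:0]
    chosen = pd.concat([chosen_true.assign(is_true=True), chosen_decoy.assign(is_true=False)])
    chosen = chosen.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(drop=True)

    first_chain = chains[0]

    def _type(res_id: int) -> str:
        for ch in chains:
            if res_id in names[ch].index:
                return str(names[ch].loc[res_id])
        return "UNK"

    links = pd.DataFrame(
        {
            "protein_a": protein,
            "res_a": chosen["res_a"].astype(int),
            "type_a": chosen["res_a"].map(_type),
            "protein_b": protein,
            "res_b": chosen["res_b"].astype(int),
            "type_b": chosen["res_b"].map(_type),
            "crosslinker": crosslinker,
        }
    )
    truth = chosen[["res_a", "res_b", "is_true", "min_distance"]].copy()
    return links, truth
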