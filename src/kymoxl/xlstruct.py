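"""Crosslink-to-structure distance validation and linkage maps.

A crosslinker of maximum spacer length d_max (27 Å Cα-Cα for BS3) can only
bridge residues whose Cα atoms lie within that distance in some copy of
the protein. Each identified residue pair is therefore checked against the
structure: the minimum Cα-Cα distance placing both residues on one chain
(intra) and on two different chains (inter) are computed over all chain
assignments, and the pair is classed, in order of precedence,
intra_satisfied → inter_satisfied → violated; pairs whose residues are
missing from every mapped chain are 'unmapped'. Intra takes precedence
because XL-MS of a homodimer cannot distinguish intra- from
inter-molecular links.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .structures import StructureModel

__all__ = ["crosslink_distances", "classify_crosslinks", "classification_summary", "linkage_map"]

CLASSES = ("intra_satisfied", "inter_satisfied", "violated", "unmapped")


def crosslink_distances(
    links: pd.DataFrame,
    structure: StructureModel,
    chain_groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Minimum intra- and inter-chain Cα-Cα distances per crosslink.

    Parameters
    ----------
    links : DataFrame
        Columns ``protein_a, res_a, protein_b, res_b`` (extra columns pass
        through untouched).
    chain_groups : dict
        Maps each protein name to the chain ids representing it in the
        structure (e.g. ``{"MCAK": ["A", "B"]}``).

    Returns the link table with ``intra_distance``, ``inter_distance``
    (NaN where no assignment of that kind exists) and ``mapped``.
    """
    for prot in pd.unique(pd.concat([links["protein_a"], links["protein_b"]])):
        if prot not in chain_groups:
            raise ValueError(f"no chain mapping for protein {prot!r}")
        if not chain_groups[prot]:
            raise ValueError(f"empty chain list for protein {prot!r}")

    coords = {
        ch: structure.chain_residues(ch).set_index("res_id")[["x", "y", "z"]]
        for ch in structure.chains
    }

    intra = np.full(len(links), np.nan)
    inter = np.full(len(links), np.nan)
    mapped = np.zeros(len(links), dtype=bool)
    for k, row in enumerate(links.itertuples(index=False)):
        chains_a = [c for c in chain_groups[row.protein_a] if c in coords]
        chains_b = [c for c in chain_groups[row.protein_b] if c in coords]
        best_intra, best_inter = np.inf, np.inf
        for ca in chains_a:
            if row.res_a not in coords[ca].index:
                continue
            pa = coords[ca].loc[row.res_a].to_numpy(float)
            for cb in chains_b:
                if row.res_b not in coords[cb].index:
                    continue
                pb = coords[cb].loc[row.res_b].to_numpy(float)
                d = float(np.linalg.norm(pa - pb))
                if ca == cb:
                    best_intra = min(best_intra, d)
                else:
                    best_inter = min(best_inter, d)
        if np.isfinite(best_intra):
            intra[k] = best_intra
        if np.isfinite(best_inter):
            inter[k] = best_inter
        mapped[k] = np.isfinite(best_intra) or np.isfinite(best_inter)

    out = links.copy()
    out["intra_distance"] = intra
    out["inter_distance"] = inter
    out["mapped"] = mapped
    return out


def classify_crosslinks(distances: pd.DataFrame, d_max: float = 27.0) -> pd.DataFrame:
    """Assign each crosslink a distance class at cutoff ``d_max``.

    Precedence: ``intra_satisfied`` (min intra ≤ d_max), else
    ``inter_satisfied`` (min inter ≤ d_max), else ``violated``; records
    absent from the structure are ``unmapped``.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    out = distances.copy()
    intra_ok = out["intra_distance"] <= d_max
    inter_ok = out["inter_distance"] <= d_max
    cls = np.where(
        ~out["mapped"],
        "unmapped",
        np.where(intra_ok.fillna(False), "intra_satisfied",
                 np.where(inter_ok.fillna(False), "inter_satisfied", "violated")),
    )
    out["class"] = pd.Categorical(cls, categories=list(CLASSES))
    out["d_max"] = d_max
    return out


def classification_summary(classified: pd.DataFrame) -> dict:
    """Counts and fractions per distance class."""
    counts = classified["class"].value_counts().to_dict()
    total = int(len(classified))
    n_sat = counts.get("intra_satisfied", 0) + counts.get("inter_satisfied", 0)
    n_mapped = total - counts.get("unmapped", 0)
    return {
        "total": total,
        "counts": {c: int(counts.get(c, 0)) for c in CLASSES},
        "fraction_satisfied_of_mapped": (n_sat / n_mapped) if n_mapped else float("nan"),
    }


def linkage_map(
    links: pd.DataFrame,
    annotations: list[tuple[str, str, int, int, str]] | None = None,
    protein_lengths: dict[str, int] | None = None,
    gap: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay crosslinks out on concatenated sequence axes for arc plotting.

    Proteins are placed end-to-end (order of first appearance, separated by
    ``gap`` positions); each link becomes one arc row with global source/
    target coordinates, and each annotation ``(protein, name, start, end,
    role)`` becomes one domain band row. Links whose residues fall outside
    the protein length are skipped with a warning. Returns
    ``(arcs, bands)`` ready for any plotting layer.
    """
    proteins = list(dict.fromkeys(pd.concat([links["protein_a"], links["protein_b"]])))
    if protein_lengths is None:
        protein_lengths = {}
        for p in proteins:
            res = pd.concat(
                [links.loc[links["protein_a"] == p, "res_a"],
                 links.loc[links["protein_b"] == p, "res_b"]]
            )
            protein_lengths[p] = int(res.max()) if len(res) else 1
    if annotations:
        for prot, name, start, end, _role in annotations:
            if prot in protein_lengths and not (1 <= start <= end <= protein_lengths[prot]):
                raise ValueError(
                    f"annotation {name!r} [{start}, {end}] outside {prot} "
                    f"(length {protein_lengths[prot]})"
                )
            proteins.append(prot) if prot not in proteins else None

    offsets = {}
    cursor = 0
    for p in proteins:
        offsets[p] = cursor
        cursor += protein_lengths.get(p, 1) + gap

    arc_rows = []
    for row in links.itertuples(index=False):
        ra, rb = int(row.res_a), int(row.res_b)
        ok = (
            1 <= ra <= protein_lengths.get(row.protein_a, ra)
            and 1 <= rb <= protein_lengths.get(row.protein_b, rb)
        )
        if not ok:
            warnings.warn(
                f"link {row.protein_a}:{ra} - {row.protein_b}:{rb} outside sequence; skipped",
                stacklevel=2,
            )
            continue
        arc_rows.append(
            {
                "protein_a": row.protein_a,
                "res_a": ra,
                "x_a": offsets[row.protein_a] + ra,
                "protein_b": row.protein_b,
                "res_b": rb,
                "x_b": offsets[row.protein_b] + rb,
                "inter_protein": row.protein_a != row.protein_b,
            }
        )
    arcs = pd.DataFrame(
        arc_rows,
        columns=["protein_a", "res_a", "x_a", "protein_b", "res_b", "x_b", "inter_protein"],
    )
    band_rows = []
    for prot, name, start, end, role in annotations or []:
        band_rows.append(
            {
                "protein": prot,
                "name": name,
                "start": start,
                "end": end,
                "x_start": offsets.get(prot, 0) + start,
                "x_end": offsets.get(prot, 0) + end,
                "role": role,
            }
        )
    bands = pd.DataFrame(
        band_rows, columns=["protein", "name", "start", "end", "x_start", "x_end", "role"]
    )
    return arcs, bands
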