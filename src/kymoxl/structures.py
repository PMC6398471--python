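"""Atomic structure handling for crosslink validation.

Only Cα positions matter for crosslinker distance checks, so the in-memory
model is a flat per-residue table (chain, author residue number, insertion
code, residue name, Cα coordinate). PDB parsing and writing go through
biotite; altloc conflicts resolve by highest occupancy.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

__all__ = [
    "StructureModel",
    "read_structure",
    "to_pdb_string",
    "CROSSLINKABLE_BS3",
]

# BS3 reacts with primary amines and, at lower efficiency, hydroxyls:
# protein N-terminus plus Lys, Ser, Thr, Tyr side chains.
CROSSLINKABLE_BS3 = frozenset({"LYS", "SER", "THR", "TYR"})


@dataclass
class StructureModel:
    """Per-residue Cα model of one or more chains.

    ``residues`` columns: chain (str), res_id (int, author numbering,
    1-based), ins_code (str, '' if none), res_name (3-letter), x, y, z (Å).
    (chain, res_id, ins_code) keys are unique.
    """

    residues: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chain", "res_id", "ins_code", "res_name", "x", "y", "z"}
        missing = required - set(self.residues.columns)
        if missing:
            raise ValueError(f"residue table missing columns: {sorted(missing)}")
        keys = self.residues[["chain", "res_id", "ins_code"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (chain, res_id, ins_code) keys")
        coords = self.residues[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.residues["chain"]))

    def __len__(self) -> int:
        return len(self.residues)

    def chain_residues(self, chain: str) -> pd.DataFrame:
        return self.residues[self.residues["chain"] == chain]

    def coord(self, chain: str, res_id: int, ins_code: str = "") -> np.ndarray | None:
        """Cα coordinate for a residue, or None if absent."""
        df = self.residues
        hit = df[
            (df["chain"] == chain)
            & (df["res_id"] == res_id)
            & (df["ins_code"] == ins_code)
        ]
        if hit.empty:
            return None
        return hit[["x", "y", "z"]].to_numpy(float)[0]

    def crosslinkable_mask(self, chemistry: frozenset[str] = CROSSLINKABLE_BS3) -> np.ndarray:
        """Boolean mask of residues reactive for the given chemistry,
        always including each chain's first residue (the N-terminus)."""
        by_type = self.residues["res_name"].isin(chemistry).to_numpy()
        n_term = np.zeros(len(self.residues), dtype=bool)
        for chain in self.chains:
            idx = self.residues.index[self.residues["chain"] == chain]
            first = self.residues.loc[idx, "res_id"].idxmin()
            n_term[self.residues.index.get_loc(first)] = True
        return by_type | n_term

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: coords @ rotation.T + translation."""
        out = self.residues.copy()
        coords = out[["x", "y", "z"]].to_numpy(float) @ np.asarray(rotation).T
        coords = coords + np.asarray(translation, float)
        out[["x", "y", "z"]] = coords
        return StructureModel(out)


def read_structure(pdb_text: str) -> StructureModel:
    """Parse PDB ATOM records into a Cα-per-residue model.

    Altloc duplicates resolve by highest occupancy, ties alphabetically by
    altloc id. Residues without a Cα (e.g. heteroatoms, waters, or truncated
    models) are skipped with a warning; insertion codes are preserved in the
    residue key.
    """
    pdb_file = bpdb.PDBFile.read(io.StringIO(pdb_text))
    try:
        atoms = pdb_file.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # no models / malformed
        raise ValueError(f"no parseable ATOM records: {exc}") from None
    if atoms.array_length() == 0:
        raise ValueError("no ATOM records in PDB input")
    atoms = atoms[bst.filter_amino_acids(atoms)]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid ATOM records in PDB input")

    rows = []
    seen_no_ca = []
    # iterate residues in file order
    starts = bst.get_residue_starts(atoms, add_exclusive_stop=True)
    for beg, end in zip(starts[:-1], starts[1:]):
        res = atoms[beg:end]
        ca = res[res.atom_name == "CA"]
        chain = str(res.chain_id[0])
        res_id = int(res.res_id[0])
        ins = str(res.ins_code[0]).strip()
        if ca.array_length() == 0:
            seen_no_ca.append((chain, res_id))
            continue
        xyz = ca.coord[0]
        rows.append(
            {
                "chain": chain,
                "res_id": res_id,
                "ins_code": ins,
                "res_name": str(res.res_name[0]),
                "x": float(xyz[0]),
                "y": float(xyz[1]),
                "z": float(xyz[2]),
            }
        )
    if seen_no_ca:
        warnings.warn(
            f"{len(seen_no_ca)} residue(s) without a CA atom were omitted "
            f"(first: {seen_no_ca[0]})",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no residues with CA atoms found")
    return StructureModel(pd.DataFrame(rows))


def to_pdb_string(model: StructureModel) -> str:
    """Serialize the Cα model as minimal PDB ATOM records (one CA per residue)."""
    n = len(model.residues)
    atoms = bst.AtomArray(n)
    df = model.residues.reset_index(drop=True)
    atoms.chain_id = df["chain"].to_numpy(str)
    atoms.res_id = df["res_id"].to_numpy(int)
    atoms.ins_code = df["ins_code"].to_numpy(str)
    atoms.res_name = df["res_name"].to_numpy(str)
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.coord = df[["x", "y", "z"]].to_numpy(float)
    pdb_file = bpdb.PDBFile()
    pdb_file.set_structure(atoms)
    buf = io.StringIO()
    pdb_file.write(buf)
    return buf.getvalue()
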