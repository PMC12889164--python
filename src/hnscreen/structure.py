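"""Superposition-free structural similarity: Cα lDDT, coverage, hit tables.

The local distance difference test (lDDT) scores how well a model preserves
the reference's interatomic distances: for every mapped reference residue,
all reference Cα–Cα distances below an inclusion radius (15 Å) are checked in
the model, a distance counting as preserved when its change stays below each
tolerance in {0.5, 1, 2, 4} Å; the per-residue score is the preserved fraction
averaged over the four tolerances, and the reported value averages over mapped
residues.  Being distance-based it needs no superposition and is invariant to
rigid motion of either structure.

Only Cα atoms are used — backbone-level similarity is what structure-database
screening compares, and it keeps the score well defined for predicted models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import hit_table as _ht


@dataclass(frozen=True)
class StructureRecord:
    accession: str
    ca_coords: np.ndarray  # (n_residues, 3) in Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"{self.accession}: coordinates must be (n, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{self.accession}: non-finite coordinates")
        object.__setattr__(self, "ca_coords", coords)

    @property
    def length(self) -> int:
        return self.ca_coords.shape[0]


@dataclass(frozen=True)
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        if self.inclusion_radius <= 0:
            raise ValueError("inclusion radius must be positive")
        t = tuple(self.thresholds)
        if not t or any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ValueError("thresholds must be positive and ascending")
        object.__setattr__(self, "thresholds", t)


def validate_mapping(mapping, qlen: int, tlen: int) -> np.ndarray:
    """Check a residue mapping is in-bounds and strictly increasing in both
    components (no crossings); returns it as an (n, 2) int array."""
    pairs = np.asarray(list(mapping), dtype=int)
    if pairs.size == 0:
        raise ValueError("empty residue mapping")
    pairs = pairs.reshape(-1, 2)
    if pairs.min() < 0 or pairs[:, 0].max() >= qlen or pairs[:, 1].max() >= tlen:
        raise IndexError("mapping index out of bounds")
    if np.any(np.diff(pairs[:, 0]) <= 0) or np.any(np.diff(pairs[:, 1]) <= 0):
        raise ValueError("mapping must be strictly increasing in both components")
    return pairs


def average_lddt(
    reference: StructureRecord,
    model: StructureRecord,
    mapping,
    params: LddtParams = LddtParams(),
) -> float:
    """Average Cα lDDT of ``model`` against ``reference`` under ``mapping``.

    ``mapping`` is an iterable of 0-based ``(reference_index, model_index)``
    pairs.  Residues whose reference environment is empty (no other mapped
    residue within the inclusion radius) do not contribute to the average.
    """
    pairs = validate_mapping(mapping, reference.length, model.length)
    if len(pairs) < 2:
        raise ValueError("need at least 2 mapped residues")
    ref = reference.ca_coords[pairs[:, 0]]
    mod = model.ca_coords[pairs[:, 1]]
    d_ref = cdist(ref, ref)
    d_mod = cdist(mod, mod)
    n = len(pairs)
    eligible = (d_ref < params.inclusion_radius) & ~np.eye(n, dtype=bool)
    n_eligible = eligible.sum(axis=1)
    diff = np.abs(d_ref - d_mod)
    per_residue = np.zeros(n)
    for t in params.thresholds:
        preserved = (diff < t) & eligible
        with np.errstate(invalid="ignore"):
            per_residue += np.where(n_eligible > 0, preserved.sum(axis=1) / np.maximum(n_eligible, 1), 0.0)
    per_residue /= len(params.thresholds)
    scored = n_eligible > 0
    if not scored.any():
        raise ValueError("no residue has a neighbour within the inclusion radius")
    return float(per_residue[scored].mean())


def coverage(mapping, qlen: int, tlen: int) -> tuple[float, float]:
    """Fraction of each protein's residues included in the alignment."""
    if qlen < 1 or tlen < 1:
        raise ValueError("protein lengths must be >= 1")
    pairs = validate_mapping(mapping, qlen, tlen)
    return len(pairs) / qlen, len(pairs) / tlen


def read_ca_coords(path) -> StructureRecord:
    """Cα trace from a PDB or mmCIF file: first model, first altloc."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords = []
    model = st[0]
    for chain in model:
        for residue in chain:
            ca = residue.find_atom("CA", "*")
            if ca is not None:
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
    if not coords:
        raise ValueError(f"no Cα atoms in {path}")
    return StructureRecord(accession=st.name or str(path), ca_coords=np.array(coords))


def write_ca_pdb(record: StructureRecord, path, sequence: str | None = None) -> None:
    """Write a Cα-only PDB file (one chain, sequential numbering)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR", "X": "UNK",
    }
    st = gemmi.Structure()
    st.name = record.accession
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, xyz in enumerate(record.ca_coords):
        resname = three[sequence[i]] if sequence else "GLY"
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


# Foldseek-style tabular parsing lives in hit_table; re-export the reader here
# because structural hit tables are this module's external interface.
read_hit_table = _ht.read_hit_table
FOLDSEEK_DEFAULT_COLUMNS = _ht.FOLDSEEK_DEFAULT_COLUMNS
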