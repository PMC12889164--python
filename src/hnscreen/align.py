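"""Pairwise protein alignment with affine gaps, following EMBOSS conventions.

Global mode mirrors EMBOSS Needle defaults (BLOSUM62, gap open 10, gap extend
0.5, end gaps free); local mode mirrors EMBOSS Water.  A gap of length L costs
``gap_open + L * gap_extend`` — EMBOSS assesses the extension penalty on every
gap residue.  Identity% counts identical alignment columns; similarity% counts
columns whose substitution score is positive (or identical), both over the full
alignment length including gap columns.

The dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`;
this module fixes the scoring conventions, the percentage definitions and a
deterministic traceback (the aligner's first optimal path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(f"{self.accession}: residues outside alphabet: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentParams:
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0.0):
            raise ValueError("require gap_open >= gap_extend >= 0")


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    alignment_length: int

    @property
    def is_empty(self) -> bool:
        return self.alignment_length == 0


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62"):
    """Substitution matrix restricted to the 20 amino acids plus X.

    X scores 0 against everything, including itself.
    """
    full = substitution_matrices.load(name)
    mat = substitution_matrices.Array(alphabet=ALPHABET, dims=2)
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            mat[a, b] = full[a, b]
    return mat


def _make_aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(params.substitution_matrix)
    # Biopython scores the first gap position with open_gap_score and the rest
    # with extend_gap_score; EMBOSS charges open + L*extend for a gap of length L.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        # end gaps are free (Needle's -endweight false default)
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _percentages(aligned_a: str, aligned_b: str, matrix) -> tuple[float, float]:
    length = len(aligned_a)
    if length == 0:
        return 0.0, 0.0
    ident = sim = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        same = x == y
        ident += same
        # identical columns count as similar even when the matrix entry is
        # non-positive (X-X scores 0) so identity <= similarity always holds
        sim += same or matrix[x, y] > 0
    return 100.0 * ident / length, 100.0 * sim / length


def _build_result(alignment, matrix) -> PairwiseAlignment:
    aligned_a, aligned_b = alignment[0], alignment[1]
    identity, similarity = _percentages(aligned_a, aligned_b, matrix)
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        identity_pct=identity,
        similarity_pct=similarity,
        alignment_length=len(aligned_a),
    )


def global_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams = AlignmentParams()
) -> PairwiseAlignment:
    """Needleman-Wunsch with affine gaps and free end gaps (Needle defaults)."""
    aligner = _make_aligner(params, "global")
    alignment = next(iter(aligner.align(a.sequence, b.sequence)))
    return _build_result(alignment, aligner.substitution_matrix)


def local_align(
    a: ProteinRecord, b: ProteinRecord, params: AlignmentParams = AlignmentParams()
) -> PairwiseAlignment:
    """Smith-Waterman with affine gaps (Water defaults).

    When no residue pair scores positive the optimal local alignment is empty
    and the score is 0.
    """
    aligner = _make_aligner(params, "local")
    score = aligner.score(a.sequence, b.sequence)
    if score <= 0:
        return PairwiseAlignment("", "", 0.0, 0.0, 0.0, 0)
    alignment = next(iter(aligner.align(a.sequence, b.sequence)))
    return _build_result(alignment, aligner.substitution_matrix)


def read_fasta(path) -> list[ProteinRecord]:
    records = [
        ProteinRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
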