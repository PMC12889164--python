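"""Independent brute-force oracles used by the tests.

These deliberately avoid the library's dynamic programming / vectorized code
paths: alignments are scored by exhaustive enumeration of monotone residue
matchings, and lDDT by a plain double loop over residue pairs.
"""

from __future__ import annotations

import numpy as np


def enumerate_matchings(la: int, lb: int):
    """Yield every strictly increasing set of (i, j) residue pairings."""

    def rec(i0, j0, current):
        yield list(current)
        for i in range(i0, la):
            for j in range(j0, lb):
                current.append((i, j))
                yield from rec(i + 1, j + 1, current)
                current.pop()

    yield from rec(0, 0, [])


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    # EMBOSS charges open + L*extend for a gap of length L
    return gap_open + length * gap_extend if length else 0.0


def _end_cost(rest_a: int, rest_b: int, gap_open: float, gap_extend: float) -> float:
    # At either end of a global alignment only one sequence's unmatched block
    # can occupy the terminal (free) gap; the other block is an internal gap.
    if rest_a == 0 or rest_b == 0:
        return 0.0
    return min(_gap_cost(rest_a, gap_open, gap_extend), _gap_cost(rest_b, gap_open, gap_extend))


def _score_matching(m, a, b, score_of, gap_open, gap_extend, mode) -> float:
    if not m:
        return 0.0
    s = sum(score_of[a[i]][b[j]] for i, j in m)
    for (i1, j1), (i2, j2) in zip(m, m[1:]):
        s -= _gap_cost(i2 - i1 - 1, gap_open, gap_extend)
        s -= _gap_cost(j2 - j1 - 1, gap_open, gap_extend)
    if mode == "global":
        (i1, j1), (ik, jk) = m[0], m[-1]
        s -= _end_cost(i1, j1, gap_open, gap_extend)
        s -= _end_cost(len(a) - 1 - ik, len(b) - 1 - jk, gap_open, gap_extend)
    return s


def matrix_as_dict(matrix) -> dict:
    alphabet = matrix.alphabet
    return {x: {y: float(matrix[x, y]) for y in alphabet} for x in alphabet}


def brute_force_align_score(
    a: str, b: str, score_of: dict, gap_open: float = 10.0, gap_extend: float = 0.5, mode: str = "global"
) -> float:
    """Optimal alignment score by enumerating all monotone matchings.

    Unmatched residues between consecutive matched pairs form gaps, optimally
    one contiguous block per sequence (affine costs are concave in length).
    In global mode end gaps are free (the Needle default) but only one
    sequence's unmatched block fits in each terminal gap; in local mode
    unmatched ends lie outside the alignment entirely, and the optimum is
    never negative because the empty matching scores 0.
    """
    assert mode in ("global", "local")
    best = -np.inf
    for m in enumerate_matchings(len(a), len(b)):
        s = _score_matching(m, a, b, score_of, gap_open, gap_extend, mode)
        best = max(best, s)
    return best


def brute_force_lddt(
    ref: np.ndarray,
    model: np.ndarray,
    radius: float = 15.0,
    thresholds=(0.5, 1.0, 2.0, 4.0),
) -> float:
    """Average lDDT by explicit double loop over mapped residue pairs.

    ``ref`` and ``model`` are already-mapped coordinate arrays of equal
    length (identity mapping).
    """
    n = len(ref)
    per_residue = []
    for i in range(n):
        preserved = []
        for t in thresholds:
            hits = total = 0
            for j in range(n):
                if j == i:
                    continue
                d_ref = float(np.linalg.norm(ref[i] - ref[j]))
                if d_ref >= radius:
                    continue
                d_mod = float(np.linalg.norm(model[i] - model[j]))
                total += 1
                hits += abs(d_ref - d_mod) < t
            if total:
                preserved.append(hits / total)
        if preserved:
            per_residue.append(sum(preserved) / len(thresholds))
    return sum(per_residue) / len(per_residue)


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random rotation matrix and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return rot, rng.normal(scale=50.0, size=3)
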