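"""HN-ratio / HN-score meta-analysis over paired stress/control expression tables.

Each stress experiment is paired with a non-treatment control from the same
study.  For every gene and pair the pseudocounted expression ratio

    HN-ratio = (T_HS + 1) / (T_ctrl + 1)

classifies the observation as upregulated (ratio >= 5), downregulated
(ratio <= 1/5) or unchanged, and the per-gene HN-score is the count of
upregulated pairs minus the count of downregulated pairs.  Genes are ranked by
HN-score and the extreme top/bottom fractions form the up- and downregulated
gene groups carried into the structural screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

LABEL_UP = "upregulated"
LABEL_DOWN = "downregulated"
LABEL_UNCHANGED = "unchanged"


@dataclass(frozen=True)
class ClassificationThresholds:
    """Fold-change thresholds for the three-way call.

    ``up_fold``/``down_fold`` are ratio cutoffs (inclusive on both sides);
    ``pseudocount`` is the additive constant applied to numerator and
    denominator before the ratio is formed.
    """

    up_fold: float = 5.0
    down_fold: float = 1.0 / 5.0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not (self.up_fold > 1.0 > self.down_fold > 0.0):
            raise ValueError(
                f"require up_fold > 1 > down_fold > 0, got {self.up_fold}, {self.down_fold}"
            )
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


DEFAULT_THRESHOLDS = ClassificationThresholds()


def hn_ratio(t_hs, t_ctrl, pseudocount: float = 1.0):
    """Pseudocounted stress/control expression ratio; scalar or array.

    Strictly positive; equals 1 when the two abundances agree (including the
    all-zero case, which the pseudocount keeps well defined).
    """
    t_hs = np.asarray(t_hs, dtype=float)
    t_ctrl = np.asarray(t_ctrl, dtype=float)
    if not (np.all(np.isfinite(t_hs)) and np.all(np.isfinite(t_ctrl))):
        raise ValueError("expression values must be finite")
    if np.any(t_hs < 0) or np.any(t_ctrl < 0):
        raise ValueError("expression values must be non-negative")
    out = (t_hs + pseudocount) / (t_ctrl + pseudocount)
    return float(out) if out.ndim == 0 else out


def classify_ratio(ratio, thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS):
    """Three-way call on an HN-ratio; scalar or array of labels.

    Boundaries are inclusive: a ratio exactly at ``up_fold`` is upregulated
    and one exactly at ``down_fold`` is downregulated.
    """
    r = np.asarray(ratio, dtype=float)
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("HN-ratio must be finite and strictly positive")
    labels = np.select(
        [r >= thresholds.up_fold, r <= thresholds.down_fold],
        [LABEL_UP, LABEL_DOWN],
        default=LABEL_UNCHANGED,
    )
    return str(labels) if labels.ndim == 0 else labels


def hn_scores(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Aggregate three-way calls into per-gene HN-scores.

    Parameters
    ----------
    matrix
        Genes x samples scaled-TPM table, indexed by gene id.
    design
        One row per stress/control pair with columns
        ``pair_id, stress_sample, control_sample``.

    Returns a table with ``gene_id, n_up, n_down, n_unchanged, hn_score``
    sorted by descending HN-score, ties by gene id.
    """
    if matrix.shape[0] == 0 or len(design) == 0:
        raise ValueError("need at least one gene and one pair")
    if matrix.index.duplicated().any():
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in matrix: {dups[:5]}")
    for col in ("stress_sample", "control_sample"):
        missing = set(design[col]) - set(matrix.columns)
        if missing:
            raise KeyError(f"design {col} not in matrix columns: {sorted(missing)[:5]}")

    n_up = np.zeros(len(matrix), dtype=int)
    n_down = np.zeros(len(matrix), dtype=int)
    for _, pair in design.iterrows():
        r = hn_ratio(
            matrix[pair["stress_sample"]].to_numpy(),
            matrix[pair["control_sample"]].to_numpy(),
            thresholds.pseudocount,
        )
        n_up += r >= thresholds.up_fold
        n_down += r <= thresholds.down_fold
    n_pairs = len(design)
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "n_up": n_up,
            "n_down": n_down,
            "n_unchanged": n_pairs - n_up - n_down,
            "hn_score": n_up - n_down,
        }
    )
    return out.sort_values(
        ["hn_score", "gene_id"], ascending=[False, True], ignore_index=True
    )


def select_groups(scores: pd.DataFrame, fraction: float = 0.01):
    """Pick the top/bottom ``fraction`` of genes by HN-score.

    Group size is ``ceil(fraction * N)``; boundary ties are broken by
    lexicographic gene id so the selection is deterministic.  Returns
    ``(up_group, down_group)`` as score-table slices.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError(f"fraction must be in (0, 0.5], got {fraction}")
    if len(scores) == 0:
        raise ValueError("empty score table")
    k = math.ceil(fraction * len(scores))
    by_desc = scores.sort_values(
        ["hn_score", "gene_id"], ascending=[False, True], ignore_index=True
    )
    by_asc = scores.sort_values(
        ["hn_score", "gene_id"], ascending=[True, True], ignore_index=True
    )
    return by_desc.head(k).copy(), by_asc.head(k).copy()
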