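"""Filtering cascade and sequence/structure quadrant classification.

Rice-to-human structural hit pairs are screened in a fixed order:

1. coverage filter — keep pairs with >= 50% alignment coverage on both proteins;
2. within-gene dedupe — one row per (rice gene, human structure), keeping the
   highest-coverage alignment, ties broken by average lDDT;
3. cross-reference filter — keep pairs whose human accession maps unambiguously
   to a single current gene id/symbol, attaching the symbol;
4. percentile thresholds over the retained set — Q2 = median average lDDT,
   Q3 = 75th percentile of global sequence similarity;
5. quadrant classification — LS–HS (similarity <= Q3, lDDT >= Q2),
   HS–HS (similarity > Q3, lDDT >= Q2), other (lDDT < Q2);
6. unique LS–HS — LS–HS pairs whose rice gene has no HS–HS pair anywhere.

Thresholds are computed per gene group (up / down) and per alignment mode,
each on its own retained set.  Hit pairs are finally flagged for concordance
with an alternate alignment mode, for rice proteins matching multiple human
structures, and for membership of the human top/bottom-500 HN-score sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hit_table import validate_hit_table

QUADRANT_LS_HS = "LS_HS"
QUADRANT_HS_HS = "HS_HS"
QUADRANT_OTHER = "other"


@dataclass(frozen=True)
class QuadrantThresholds:
    """Percentile cutoffs computed from one retained hit-pair set."""

    q2_lddt: float
    q3_seqsim: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.q2_lddt) and np.isfinite(self.q3_seqsim)):
            raise ValueError("thresholds must be finite")


def filter_coverage(hits: pd.DataFrame, min_cov: float = 0.5) -> pd.DataFrame:
    """Keep rows with coverage >= ``min_cov`` on both proteins (inclusive)."""
    validate_hit_table(hits)
    keep = (hits["qcov"] >= min_cov) & (hits["tcov"] >= min_cov)
    return hits[keep].reset_index(drop=True)


def dedupe_within_gene(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per (rice gene, human structure).

    Within each group the row maximizing the coverage scalar min(qcov, tcov)
    is kept; ties go to the highest average lDDT, residual ties to the
    lexicographically smallest rice accession.
    """
    validate_hit_table(hits)
    if hits.empty:
        return hits.reset_index(drop=True)
    ranked = hits.assign(_cov=np.minimum(hits["qcov"], hits["tcov"]))
    ranked = ranked.sort_values(
        ["rice_gene_id", "human_accession", "_cov", "avg_lddt", "rice_accession"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    out = ranked.drop_duplicates(["rice_gene_id", "human_accession"], keep="first")
    return out.drop(columns="_cov").reset_index(drop=True)


def filter_xref(hits: pd.DataFrame, xref: pd.DataFrame) -> pd.DataFrame:
    """Keep rows whose human accession maps to exactly one gene id/symbol.

    ``xref`` columns: human_accession, ensembl_gene_id, gene_symbol.
    Ambiguous accessions (several distinct mappings) and accessions absent
    from the table are dropped; the symbol is attached as
    ``human_gene_symbol``.
    """
    need = {"human_accession", "ensembl_gene_id", "gene_symbol"}
    if not need <= set(xref.columns):
        raise KeyError(f"xref table must have columns {sorted(need)}")
    uniq = xref.drop_duplicates(["human_accession", "ensembl_gene_id", "gene_symbol"])
    counts = uniq.groupby("human_accession").size()
    unambiguous = uniq[uniq["human_accession"].map(counts) == 1]
    merged = hits.merge(
        unambiguous[["human_accession", "gene_symbol"]].rename(
            columns={"gene_symbol": "human_gene_symbol"}
        ),
        on="human_accession",
        how="inner",
    )
    return merged.reset_index(drop=True)


def compute_thresholds(hits: pd.DataFrame) -> QuadrantThresholds:
    """Q2 (median avg lDDT) and Q3 (75th-percentile sequence similarity),
    linear-interpolation quantiles over the retained set."""
    if hits.empty:
        raise ValueError("cannot compute thresholds from an empty table")
    if "seq_similarity_pct" not in hits.columns:
        raise KeyError("hit table lacks seq_similarity_pct")
    return QuadrantThresholds(
        q2_lddt=float(np.median(hits["avg_lddt"])),
        q3_seqsim=float(np.percentile(hits["seq_similarity_pct"], 75)),
    )


def classify_quadrant(hits: pd.DataFrame, thr: QuadrantThresholds) -> pd.DataFrame:
    """Attach a ``quadrant`` label: exactly one of LS_HS / HS_HS / other."""
    sim = hits["seq_similarity_pct"].to_numpy(float)
    lddt = hits["avg_lddt"].to_numpy(float)
    label = np.select(
        [(lddt >= thr.q2_lddt) & (sim <= thr.q3_seqsim), lddt >= thr.q2_lddt],
        [QUADRANT_LS_HS, QUADRANT_HS_HS],
        default=QUADRANT_OTHER,
    )
    return hits.assign(quadrant=label)


def unique_ls_hs(classified: pd.DataFrame) -> pd.DataFrame:
    """LS–HS rows whose rice gene owns no HS–HS row anywhere in the table."""
    if classified.empty:
        return classified.assign(unique_ls_hs=pd.Series(dtype=bool))
    hs_genes = set(classified.loc[classified["quadrant"] == QUADRANT_HS_HS, "rice_gene_id"])
    mask = (classified["quadrant"] == QUADRANT_LS_HS) & ~classified["rice_gene_id"].isin(hs_genes)
    return classified[mask].assign(unique_ls_hs=True).reset_index(drop=True)


def concordance_flags(primary_unique: pd.DataFrame, alternate_unique: pd.DataFrame) -> pd.DataFrame:
    """Flag primary unique LS–HS pairs also recovered by the alternate
    alignment mode's cascade (matched on rice gene + human accession)."""
    alt = set(zip(alternate_unique.get("rice_gene_id", []), alternate_unique.get("human_accession", [])))
    keys = list(zip(primary_unique["rice_gene_id"], primary_unique["human_accession"]))
    return primary_unique.assign(concordant=[k in alt for k in keys])


def multiplicity_flags(classified: pd.DataFrame) -> pd.DataFrame:
    """Per rice accession: flag proteins matching multiple human structures
    and mark the top-ranked hit (highest avg lDDT, ties by human accession)."""
    if classified.empty:
        return classified.assign(
            multiple_human_hits=pd.Series(dtype=bool), top_ranked=pd.Series(dtype=bool)
        )
    n_hits = classified.groupby("rice_accession")["human_accession"].transform("nunique")
    ranked = classified.sort_values(
        ["rice_accession", "avg_lddt", "human_accession"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    top_idx = ranked.drop_duplicates("rice_accession", keep="first").index
    return classified.assign(
        multiple_human_hits=(n_hits > 1).to_numpy(),
        top_ranked=classified.index.isin(top_idx),
    )


def human_reference_sets(human_scores: pd.DataFrame, top_n: int = 500):
    """Top/bottom ``top_n`` human gene symbols by human HN-score.

    Rank is by score (descending for the up set, ascending for the down set)
    with lexicographic symbol tie-break at the boundary.  Symbols must be
    unique.  Returns ``(up_set, down_set)``.
    """
    need = {"gene_symbol", "hn_score"}
    if not need <= set(human_scores.columns):
        raise KeyError(f"human score table must have columns {sorted(need)}")
    if human_scores["gene_symbol"].duplicated().any():
        dups = human_scores.loc[human_scores["gene_symbol"].duplicated(), "gene_symbol"]
        raise ValueError(f"duplicate gene symbols in human score table: {dups.tolist()[:5]}")
    up = human_scores.sort_values(
        ["hn_score", "gene_symbol"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    down = human_scores.sort_values(
        ["hn_score", "gene_symbol"], ascending=[True, True], kind="mergesort"
    ).head(top_n)
    return set(up["gene_symbol"]), set(down["gene_symbol"])


def attach_human_scores(
    classified: pd.DataFrame, human_scores: pd.DataFrame, top_n: int = 500
) -> pd.DataFrame:
    """Join human HN-scores by gene symbol and label top/bottom-set membership.

    Adds ``human_hn_score`` (NaN when the symbol is absent from the score
    table) and ``human_group`` in {up500, down500, none}.
    """
    up_set, down_set = human_reference_sets(human_scores, top_n)
    score_of = dict(zip(human_scores["gene_symbol"], human_scores["hn_score"]))
    symbols = classified["human_gene_symbol"]
    group = np.select(
        [symbols.isin(up_set), symbols.isin(down_set)],
        ["up500", "down500"],
        default="none",
    )
    return classified.assign(
        human_hn_score=symbols.map(score_of),
        human_group=group,
    )


@dataclass
class ScreenResult:
    classified: pd.DataFrame
    unique: pd.DataFrame
    thresholds: QuadrantThresholds
    n_input: int
    n_after_coverage: int
    n_after_dedupe: int
    n_after_xref: int


def screen_cascade(
    hits: pd.DataFrame,
    xref: pd.DataFrame,
    human_scores: pd.DataFrame | None = None,
    min_cov: float = 0.5,
    top_n: int = 500,
) -> ScreenResult:
    """Run the full cascade on one hit table and return classified pairs,
    the unique LS–HS subset and the thresholds used."""
    n_input = len(hits)
    covered = filter_coverage(hits, min_cov)
    deduped = dedupe_within_gene(covered)
    retained = filter_xref(deduped, xref)
    thr = compute_thresholds(retained)
    classified = classify_quadrant(retained, thr)
    classified = multiplicity_flags(classified)
    if human_scores is not None:
        classified = attach_human_scores(classified, human_scores, top_n)
    uniq = unique_ls_hs(classified)
    return ScreenResult(
        classified=classified,
        unique=uniq,
        thresholds=thr,
        n_input=n_input,
        n_after_coverage=len(covered),
        n_after_dedupe=len(deduped),
        n_after_xref=len(retained),
    )
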