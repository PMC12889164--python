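"""Filtering cascade, percentile thresholds, quadrant classification, flags."""

import numpy as np
import pandas as pd
import pytest

from hnscreen.screen import (
    QuadrantThresholds,
    attach_human_scores,
    classify_quadrant,
    compute_thresholds,
    concordance_flags,
    dedupe_within_gene,
    filter_coverage,
    filter_xref,
    human_reference_sets,
    multiplicity_flags,
    screen_cascade,
    unique_ls_hs,
)
from hnscreen.synthetic import gen_annotations, gen_hit_table


def _hits(rows):
    defaults = dict(qcov=0.9, tcov=0.9, avg_lddt=0.7, seq_similarity_pct=30.0)
    frame = []
    for i, row in enumerate(rows):
        rec = dict(
            rice_gene_id=f"g{i}", rice_accession=f"r{i}", human_accession=f"h{i}", **defaults
        )
        rec.update(row)
        frame.append(rec)
    return pd.DataFrame(frame)


def test_coverage_filter_is_boundary_inclusive():
    hits = _hits(
        [
            {"qcov": 0.50, "tcov": 0.50},  # exactly at the boundary: retained
            {"qcov": 0.49, "tcov": 0.90},
            {"qcov": 0.90, "tcov": 0.49},
            {"qcov": 0.51, "tcov": 0.51},
        ]
    )
    kept = filter_coverage(hits)
    assert kept["rice_gene_id"].tolist() == ["g0", "g3"]


def test_coverage_filter_hand_enumeration():
    both = [(0.3, 0.3), (0.5, 0.5), (0.5, 0.4), (0.8, 0.8), (1.0, 1.0), (0.51, 0.51)]
    hits = _hits([{"qcov": q, "tcov": t} for q, t in both])
    expected = sum(q >= 0.5 and t >= 0.5 for q, t in both)
    assert len(filter_coverage(hits)) == expected == 4


def test_dedupe_keeps_highest_coverage_then_lddt():
    hits = _hits(
        [
            {"rice_gene_id": "g", "rice_accession": "r1", "human_accession": "h", "qcov": 0.9, "tcov": 0.9},
            {"rice_gene_id": "g", "rice_accession": "r2", "human_accession": "h", "qcov": 0.6, "tcov": 0.95},
        ]
    )
    kept = dedupe_within_gene(hits)
    assert len(kept) == 1 and kept.loc[0, "rice_accession"] == "r1"

    tied = _hits(
        [
            {"rice_gene_id": "g", "rice_accession": "r1", "human_accession": "h", "avg_lddt": 0.7},
            {"rice_gene_id": "g", "rice_accession": "r2", "human_accession": "h", "avg_lddt": 0.8},
        ]
    )
    kept = dedupe_within_gene(tied)
    assert kept.loc[0, "avg_lddt"] == 0.8

    # fully tied -> lexicographically smallest accession; idempotent on singles
    flat = _hits(
        [
            {"rice_gene_id": "g", "rice_accession": "rB", "human_accession": "h"},
            {"rice_gene_id": "g", "rice_accession": "rA", "human_accession": "h"},
        ]
    )
    assert dedupe_within_gene(flat).loc[0, "rice_accession"] == "rA"
    singles = _hits([{}, {}])
    pd.testing.assert_frame_equal(dedupe_within_gene(singles), singles)


def test_xref_filter_keeps_only_unambiguous():
    hits = _hits([{"human_accession": "h0"}, {"human_accession": "h1"}, {"human_accession": "h2"}])
    xref = pd.DataFrame(
        {
            "human_accession": ["h0", "h1", "h1"],
            "ensembl_gene_id": ["E0", "E1", "E1b"],
            "gene_symbol": ["S0", "S1", "S1b"],
        }
    )
    kept = filter_xref(hits, xref)
    assert kept["human_accession"].tolist() == ["h0"]  # h1 ambiguous, h2 absent
    assert kept["human_gene_symbol"].tolist() == ["S0"]
    # duplicate identical rows are not ambiguity
    dup = pd.DataFrame(
        {
            "human_accession": ["h0", "h0"],
            "ensembl_gene_id": ["E0", "E0"],
            "gene_symbol": ["S0", "S0"],
        }
    )
    assert len(filter_xref(hits, dup)) == 1


def test_thresholds_are_hand_computed_quantiles():
    hits = _hits(
        [
            {"avg_lddt": v, "seq_similarity_pct": s}
            for v, s in zip([0.2, 0.4, 0.6, 0.8], [10, 20, 30, 40])
        ]
    )
    thr = compute_thresholds(hits)
    assert thr.q2_lddt == pytest.approx(0.5)
    assert thr.q3_seqsim == pytest.approx(32.5)  # linear interpolation
    single = compute_thresholds(hits.head(1))
    assert (single.q2_lddt, single.q3_seqsim) == (0.2, 10.0)
    with pytest.raises(ValueError):
        compute_thresholds(hits.head(0))


def test_quadrant_boundaries_and_partition():
    thr = QuadrantThresholds(q2_lddt=0.6, q3_seqsim=36.0)
    hits = _hits(
        [
            {"seq_similarity_pct": 36.0, "avg_lddt": 0.6},  # both boundaries -> LS_HS
            {"seq_similarity_pct": 36.01, "avg_lddt": 0.6},  # just over Q3 -> HS_HS
            {"seq_similarity_pct": 10.0, "avg_lddt": 0.599},  # below Q2 -> other
            {"seq_similarity_pct": 90.0, "avg_lddt": 0.2},
        ]
    )
    labeled = classify_quadrant(hits, thr)
    assert labeled["quadrant"].tolist() == ["LS_HS", "HS_HS", "other", "other"]

    rng = np.random.default_rng(12)
    rand = _hits(
        [
            {"seq_similarity_pct": s, "avg_lddt": l}
            for s, l in zip(rng.uniform(0, 100, 200), rng.uniform(0, 1, 200))
        ]
    )
    labeled = classify_quadrant(rand, compute_thresholds(rand))
    counts = labeled["quadrant"].value_counts()
    assert counts.sum() == 200  # exactly one label each
    # quantile guarantees: at least half at/above Q2, at least 3/4 at/below Q3
    assert (labeled["avg_lddt"] >= compute_thresholds(rand).q2_lddt).mean() >= 0.5
    assert (labeled["seq_similarity_pct"] <= compute_thresholds(rand).q3_seqsim).mean() >= 0.75


def test_unique_ls_hs_excludes_genes_with_hs_hs():
    classified = _hits(
        [
            {"rice_gene_id": "gA"},
            {"rice_gene_id": "gA"},
            {"rice_gene_id": "gB"},
            {"rice_gene_id": "gB"},
            {"rice_gene_id": "gC"},
        ]
    ).assign(quadrant=["LS_HS", "LS_HS", "LS_HS", "HS_HS", "other"])
    uniq = unique_ls_hs(classified)
    assert uniq["rice_gene_id"].tolist() == ["gA", "gA"]  # gB owns an HS_HS pair
    assert uniq["unique_ls_hs"].all()
    assert unique_ls_hs(classified.head(0)).empty


def test_concordance_flags():
    primary = _hits([{"rice_gene_id": "gA"}, {"rice_gene_id": "gB", "human_accession": "hX"}])
    alternate = _hits([{"rice_gene_id": "gA"}])
    flagged = concordance_flags(primary, alternate)
    assert flagged["concordant"].tolist() == [True, False]
    none = concordance_flags(primary, alternate.head(0))
    assert not none["concordant"].any()


def test_multiplicity_flags_and_top_rank():
    classified = _hits(
        [
            {"rice_accession": "r1", "human_accession": "h1", "avg_lddt": 0.6},
            {"rice_accession": "r1", "human_accession": "h2", "avg_lddt": 0.9},
            {"rice_accession": "r1", "human_accession": "h3", "avg_lddt": 0.7},
            {"rice_accession": "r2", "human_accession": "h4", "avg_lddt": 0.5},
            {"rice_accession": "r3", "human_accession": "hA", "avg_lddt": 0.5},
            {"rice_accession": "r3", "human_accession": "hB", "avg_lddt": 0.5},
        ]
    )
    flagged = multiplicity_flags(classified)
    by_acc = flagged.set_index("human_accession")
    assert by_acc.loc["h2", "top_ranked"] and by_acc.loc["h1", "multiple_human_hits"]
    assert not by_acc.loc["h4", "multiple_human_hits"] and by_acc.loc["h4", "top_ranked"]
    assert by_acc.loc["hA", "top_ranked"] and not by_acc.loc["hB", "top_ranked"]  # tie: lexicographic


def test_human_reference_sets_rank_and_ties():
    scores = pd.DataFrame(
        {"gene_symbol": [f"S{i:05d}" for i in range(1000)], "hn_score": np.arange(1000) // 2}
    )
    up, down = human_reference_sets(scores, top_n=100)
    assert len(up) == len(down) == 100
    assert max(scores.set_index("gene_symbol").loc[list(down)]["hn_score"]) <= min(
        scores.set_index("gene_symbol").loc[list(up)]["hn_score"]
    )
    with pytest.raises(ValueError, match="duplicate"):
        human_reference_sets(pd.concat([scores, scores.head(1)]), 10)


def test_attach_human_scores_groups():
    scores = pd.DataFrame(
        {"gene_symbol": [f"S{i:04d}" for i in range(10_000)], "hn_score": np.arange(10_000)}
    )
    classified = _hits([{}, {}, {}]).assign(
        human_gene_symbol=["S9999", "S5000", "UNKNOWN"]  # rank 1, mid, unmatched
    )
    out = attach_human_scores(classified, scores, top_n=500)
    assert out["human_group"].tolist() == ["up500", "none", "none"]
    assert out.loc[0, "human_hn_score"] == 9999
    assert pd.isna(out.loc[2, "human_hn_score"])


def test_cascade_recovers_planted_regimes():
    """Thresholds placed between regime means recover >=95% of truth labels."""
    hits = gen_hit_table(250, seed=7)
    thr = QuadrantThresholds(q2_lddt=0.575, q3_seqsim=42.5)  # midpoints of regime means
    labeled = classify_quadrant(hits, thr)
    expected = hits["truth_regime"].map(
        {"LS_HS": "LS_HS", "HS_HS": "HS_HS", "LS_LS": "other", "HS_LS": "other"}
    )
    agreement = (labeled["quadrant"] == expected).mean()
    assert agreement >= 0.95


def test_cascade_is_order_faithful_and_idempotent():
    hits = gen_hit_table(40, seed=9)
    bundle = gen_annotations(hits, seed=9)
    result = screen_cascade(hits.drop(columns=["truth_regime"]), bundle.xref, bundle.human_scores)
    assert result.n_input >= result.n_after_coverage >= result.n_after_dedupe >= result.n_after_xref
    counts = result.classified["quadrant"].value_counts()
    assert counts.sum() == result.n_after_xref
    assert set(result.unique["rice_gene_id"]).isdisjoint(
        result.classified.loc[result.classified["quadrant"] == "HS_HS", "rice_gene_id"]
    )
    # re-running the filters on already-filtered rows changes nothing
    refiltered = dedupe_within_gene(filter_coverage(result.classified[
        ["rice_gene_id", "rice_accession", "human_accession", "qcov", "tcov", "avg_lddt", "seq_similarity_pct"]
    ]))
    assert len(refiltered) == result.n_after_xref
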