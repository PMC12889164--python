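"""Generators: determinism, declared ranges, planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from hnscreen.evidence import AnnotationTables, assign_tiers
from hnscreen.expression import hn_scores
from hnscreen.structure import LddtParams, average_lddt
from hnscreen.synthetic import (
    REGIME_DOWN,
    REGIME_UNCHANGED,
    REGIME_UP,
    gen_annotations,
    gen_expression_study,
    gen_hit_table,
    gen_protein_pair,
)


def test_expression_study_deterministic():
    a_study, a_truth = gen_expression_study(200, 6, seed=1)
    b_study, b_truth = gen_expression_study(200, 6, seed=1)
    pd.testing.assert_frame_equal(a_study.matrix, b_study.matrix)
    pd.testing.assert_frame_equal(a_study.design, b_study.design)
    pd.testing.assert_frame_equal(a_truth, b_truth)
    c_study, _ = gen_expression_study(200, 6, seed=2)
    assert not a_study.matrix.equals(c_study.matrix)


def test_expression_study_shapes_and_ranges():
    study, truth = gen_expression_study(150, 5, frac_up=0.1, frac_down=0.2, seed=3)
    assert study.matrix.shape == (150, 10)
    assert (study.matrix.to_numpy() >= 0).all()
    assert len(study.design) == 5
    counts = truth["regime"].value_counts()
    assert counts[REGIME_UP] == 15 and counts[REGIME_DOWN] == 30
    # truth invariants on the planted effect folds
    assert (truth.loc[truth["regime"] == REGIME_UP, "effect_fold"] > 1).all()
    assert (truth.loc[truth["regime"] == REGIME_DOWN, "effect_fold"] < 1).all()
    assert (truth.loc[truth["regime"] == REGIME_UNCHANGED, "effect_fold"] == 1).all()


def test_zero_noise_study_has_exact_fold_ratios():
    study, truth = gen_expression_study(
        10, 4, frac_up=0.1, frac_down=0.0, effect_fold=8.0, noise_sigma=0.0, seed=0
    )
    up_gene = truth.loc[truth["regime"] == REGIME_UP, "gene_id"].item()
    for _, pair in study.design.iterrows():
        hs = study.matrix.loc[up_gene, pair["stress_sample"]]
        ctrl = study.matrix.loc[up_gene, pair["control_sample"]]
        assert hs == pytest.approx(8.0 * ctrl, rel=1e-12)


def test_zero_noise_planted_scores_are_exact():
    study, truth = gen_expression_study(
        60, 10, frac_up=0.1, frac_down=0.1, effect_fold=8.0, noise_sigma=0.0, seed=4
    )
    scores = hn_scores(study.matrix, study.design).set_index("gene_id")
    regime = truth.set_index("gene_id")["regime"]
    assert (scores.loc[regime == REGIME_UP, "hn_score"] == 10).all()
    assert (scores.loc[regime == REGIME_DOWN, "hn_score"] == -10).all()
    assert (scores.loc[regime == REGIME_UNCHANGED, "hn_score"] == 0).all()


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_genes=0, n_pairs=3),
        dict(n_genes=10, n_pairs=0),
        dict(n_genes=10, n_pairs=3, frac_up=0.7, frac_down=0.5),
        dict(n_genes=10, n_pairs=3, frac_up=-0.1),
        dict(n_genes=10, n_pairs=3, noise_sigma=-1),
    ],
)
def test_expression_study_rejects_bad_params(kwargs):
    with pytest.raises(ValueError):
        gen_expression_study(seed=0, **kwargs)


def test_protein_pair_identical_when_undiverged():
    pair = gen_protein_pair(40, target_identity=1.0, coord_noise_sigma=0.0, seed=7)
    assert pair.rice_seq.sequence == pair.human_seq.sequence
    np.testing.assert_array_equal(pair.rice_struct.ca_coords, pair.human_struct.ca_coords)
    assert average_lddt(pair.rice_struct, pair.human_struct, pair.mapping) == 1.0


def test_protein_pair_achieved_identity():
    pair = gen_protein_pair(200, target_identity=0.3, coord_noise_sigma=0.5, seed=8)
    n_diff = sum(a != b for a, b in zip(pair.rice_seq.sequence, pair.human_seq.sequence))
    assert n_diff == int(np.ceil(0.7 * 200))
    assert 0.25 <= pair.truth.achieved_identity <= 0.35
    assert pair.truth.achieved_identity == pytest.approx(1 - n_diff / 200)


def test_backbone_geometry():
    pair = gen_protein_pair(80, seed=9)
    xyz = pair.rice_struct.ca_coords
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    np.testing.assert_allclose(steps, 3.8, rtol=1e-9)
    d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
    off = ~np.eye(len(xyz), dtype=bool) & ~np.eye(len(xyz), k=1, dtype=bool) & ~np.eye(len(xyz), k=-1, dtype=bool)
    assert d[off].min() >= 3.5


def test_lddt_degrades_with_coordinate_noise():
    """Mean lDDT strictly decreases across sigma in {0, 0.5, 2, 8} Å."""
    means = []
    for sigma in (0.0, 0.5, 2.0, 8.0):
        vals = []
        for seed in range(20):
            pair = gen_protein_pair(50, target_identity=0.5, coord_noise_sigma=sigma, seed=seed)
            vals.append(average_lddt(pair.rice_struct, pair.human_struct, pair.mapping))
        means.append(np.mean(vals))
    assert means[0] == pytest.approx(1.0)
    assert all(a > b for a, b in zip(means, means[1:]))


def test_protein_pair_rejects_bad_params():
    with pytest.raises(ValueError):
        gen_protein_pair(5, seed=0)
    with pytest.raises(ValueError):
        gen_protein_pair(20, target_identity=1.5, seed=0)
    with pytest.raises(ValueError):
        gen_protein_pair(20, coord_noise_sigma=-0.1, seed=0)


def test_hit_table_counts_ranges_and_determinism():
    hits = gen_hit_table(25, seed=7)
    assert len(hits) == 100
    assert hits["truth_regime"].value_counts().eq(25).all()
    assert hits["avg_lddt"].between(0, 1).all()
    assert hits["seq_similarity_pct"].between(0, 100).all()
    assert hits[["qcov", "tcov"]].to_numpy().min() > 0
    assert not hits["rice_gene_id"].duplicated().any()
    pd.testing.assert_frame_equal(hits, gen_hit_table(25, seed=7))


def test_hit_table_empty_and_errors():
    assert gen_hit_table(0, seed=0).empty
    with pytest.raises(ValueError):
        gen_hit_table(5, regime_params={}, seed=0)
    with pytest.raises(KeyError):
        gen_hit_table({"NOPE": 3}, seed=0)


def test_annotations_extreme_probabilities():
    hits = gen_hit_table(10, seed=2)
    certain = gen_annotations(hits, p_shared_domain=1.0, p_ortholog=1.0, seed=2)
    ann = AnnotationTables.from_frames(certain.domains, certain.orthologs)
    xref_symbol = dict(zip(certain.xref["human_accession"], certain.xref["gene_symbol"]))
    evidenced = assign_tiers(
        hits.assign(quadrant="LS_HS", human_gene_symbol=hits["human_accession"].map(xref_symbol)),
        ann,
    )
    assert evidenced["shared_interpro"].all()
    assert evidenced["pan_homology"].all()
    assert (evidenced["tier"] == "both").all()

    nothing = gen_annotations(hits, p_shared_domain=0.0, p_ortholog=0.0, seed=2)
    # background domain IDs are drawn per accession from a large pool; shared
    # IDs only ever come from the injection step
    ann0 = AnnotationTables.from_frames(nothing.domains, nothing.orthologs)
    evidenced0 = assign_tiers(
        hits.assign(quadrant="LS_HS", human_gene_symbol=hits["human_accession"].map(xref_symbol)),
        ann0,
    )
    assert (evidenced0["tier"] == "neither").all()


def test_annotations_shared_fraction_tracks_probability():
    hits = gen_hit_table(250, seed=3)  # 1000 pairs over 4 regimes
    bundle = gen_annotations(hits, p_shared_domain=0.5, p_ortholog=0.0, seed=3)
    ann = AnnotationTables.from_frames(bundle.domains, bundle.orthologs)
    evidenced = assign_tiers(hits.assign(quadrant="LS_HS", human_gene_symbol="x"), ann)
    frac = evidenced["shared_interpro"].mean()
    assert 0.45 <= frac <= 0.55


def test_annotations_xref_is_unambiguous():
    hits = gen_hit_table(8, seed=5)
    bundle = gen_annotations(hits, seed=5)
    assert not bundle.xref["human_accession"].duplicated().any()
    assert not bundle.xref["gene_symbol"].duplicated().any()
    assert not bundle.human_scores["gene_symbol"].duplicated().any()
    assert len(bundle.human_scores) == 10_000
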