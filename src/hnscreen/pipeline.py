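"""End-to-end pipeline: simulate -> HN-scores -> structure metrics -> screen -> evidence.

One YAML/dict config drives every stage; all randomness flows from the single
``seed`` key, and a machine-readable manifest records parameters, stage
outputs and input digests so identical configs regenerate identical results.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import evidence as ev
from . import expression, screen, synthetic
from .align import AlignmentParams, global_align
from .structure import LddtParams, average_lddt, coverage

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "expression": {
        "n_genes": 2000,
        "n_pairs": 20,
        "frac_up": 0.05,
        "frac_down": 0.05,
        "effect_fold": 8.0,
        "noise_sigma": 0.2,
        "baseline_mean": 50.0,
        "up_fold": 5.0,
        "fraction": 0.01,
    },
    "protein_pairs": {
        "n_pairs": 3,
        "length": 80,
        "target_identity": 0.3,
        "coord_noise_sigma": 0.5,
    },
    "hits": {
        "n_per_regime": 60,
        "min_cov": 0.5,
        "top_n": 500,
    },
    "annotations": {
        "p_shared_domain": 0.5,
        "p_ortholog": 0.3,
        "n_human_genes": 10000,
    },
}


def validate_config(config: dict) -> dict:
    """Merge over defaults and reject out-of-range fields before any stage runs."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in (config or {}).items():
        if section == "seed":
            merged["seed"] = int(values)
            continue
        if section not in merged:
            raise ValueError(f"unknown config section: {section!r}")
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        for key, val in values.items():
            if key not in merged[section]:
                raise ValueError(f"unknown config field: {section}.{key}")
            merged[section][key] = val

    exp = merged["expression"]
    if not 0.0 < exp["fraction"] <= 0.5:
        raise ValueError(f"expression.fraction must be in (0, 0.5], got {exp['fraction']}")
    if exp["up_fold"] <= 1.0:
        raise ValueError("expression.up_fold must be > 1")
    if not 0.0 < merged["hits"]["min_cov"] <= 1.0:
        raise ValueError("hits.min_cov must be in (0, 1]")
    if merged["hits"]["top_n"] < 1:
        raise ValueError("hits.top_n must be >= 1")
    return merged


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    manifest: dict
    scores: pd.DataFrame
    up_group: pd.DataFrame
    down_group: pd.DataFrame
    screen_result: screen.ScreenResult
    evidenced: pd.DataFrame
    tally: pd.DataFrame
    set_sizes: dict


def run_pipeline(config: dict, outdir) -> PipelineResult:
    """Run every stage in dependency order and write outputs under ``outdir``.

    Stage outputs: expression matrix/design/truth, HN-score and group tables,
    structure-pair metric table, hit/classified/unique-pair tables, thresholds
    JSON, evidence tables and the UpSet tally, plus ``manifest.json``.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    written: dict[str, str] = {}

    # stage 1: synthetic inputs
    exp_cfg = cfg["expression"]
    study, truth = synthetic.gen_expression_study(
        n_genes=exp_cfg["n_genes"],
        n_pairs=exp_cfg["n_pairs"],
        frac_up=exp_cfg["frac_up"],
        frac_down=exp_cfg["frac_down"],
        effect_fold=exp_cfg["effect_fold"],
        noise_sigma=exp_cfg["noise_sigma"],
        baseline_mean=exp_cfg["baseline_mean"],
        seed=seed,
    )
    written.update(synthetic.write_expression_study(study, truth, outdir, "expression"))

    # stage 2: HN-scores and gene groups
    thresholds = expression.ClassificationThresholds(
        up_fold=exp_cfg["up_fold"], down_fold=1.0 / exp_cfg["up_fold"]
    )
    scores = expression.hn_scores(study.matrix, study.design, thresholds)
    up_group, down_group = expression.select_groups(scores, exp_cfg["fraction"])
    for name, frame in (("hn_scores", scores), ("up_group", up_group), ("down_group", down_group)):
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written[name] = str(path)

    # stage 3: structure pairs — alignment + lDDT on generated pairs
    pp_cfg = cfg["protein_pairs"]
    metric_rows = []
    for i in range(pp_cfg["n_pairs"]):
        pair = synthetic.gen_protein_pair(
            length=pp_cfg["length"],
            target_identity=pp_cfg["target_identity"],
            coord_noise_sigma=pp_cfg["coord_noise_sigma"],
            seed=seed + i,
            pair_id=f"pair{i}",
        )
        aln = global_align(pair.rice_seq, pair.human_seq, AlignmentParams())
        lddt = average_lddt(pair.rice_struct, pair.human_struct, pair.mapping, LddtParams())
        qcov, tcov = coverage(pair.mapping, pair.rice_seq.length, pair.human_seq.length)
        metric_rows.append(
            {
                "pair_id": pair.truth.pair_id,
                "achieved_identity": pair.truth.achieved_identity,
                "identity_pct": aln.identity_pct,
                "similarity_pct": aln.similarity_pct,
                "avg_lddt": lddt,
                "qcov": qcov,
                "tcov": tcov,
            }
        )
    metrics = pd.DataFrame(metric_rows)
    written["pair_metrics"] = str(outdir / "pair_metrics.tsv")
    metrics.to_csv(written["pair_metrics"], sep="\t", index=False)

    # stage 4: screen a synthetic hit table through the cascade
    hit_cfg = cfg["hits"]
    ann_cfg = cfg["annotations"]
    hits = synthetic.gen_hit_table(hit_cfg["n_per_regime"], seed=seed)
    bundle = synthetic.gen_annotations(
        hits,
        p_shared_domain=ann_cfg["p_shared_domain"],
        p_ortholog=ann_cfg["p_ortholog"],
        n_human_genes=ann_cfg["n_human_genes"],
        seed=seed,
    )
    result = screen.screen_cascade(
        hits.drop(columns=["truth_regime"]),
        bundle.xref,
        bundle.human_scores,
        min_cov=hit_cfg["min_cov"],
        top_n=hit_cfg["top_n"],
    )
    for name, frame in (
        ("hit_table", hits),
        ("classified_pairs", result.classified),
        ("unique_ls_hs", result.unique),
    ):
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written[name] = str(path)
    thresholds_path = outdir / "thresholds.json"
    thresholds_path.write_text(
        json.dumps(
            {"q2_lddt": result.thresholds.q2_lddt, "q3_seqsim": result.thresholds.q3_seqsim},
            indent=2,
        )
    )
    written["thresholds"] = str(thresholds_path)

    # stage 5: evidence tiers and intersection tally
    annotations = ev.AnnotationTables.from_frames(bundle.domains, bundle.orthologs)
    uniq_keys = set(zip(result.unique["rice_gene_id"], result.unique["human_accession"]))
    classified = result.classified.assign(
        unique_ls_hs=[
            (g, h) in uniq_keys
            for g, h in zip(
                result.classified["rice_gene_id"], result.classified["human_accession"]
            )
        ]
    )
    evidenced = ev.assign_tiers(classified, annotations)
    tally, set_sizes = ev.intersection_tally(evidenced)
    for name, frame in (("evidenced_pairs", evidenced), ("upset_tally", tally)):
        path = outdir / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written[name] = str(path)

    manifest = {
        "config": cfg,
        "outputs": written,
        "digests": {name: _digest(Path(p)) for name, p in written.items()},
        "counts": {
            "genes": len(scores),
            "up_group": len(up_group),
            "down_group": len(down_group),
            "hits_input": result.n_input,
            "hits_after_coverage": result.n_after_coverage,
            "hits_after_dedupe": result.n_after_dedupe,
            "hits_retained": result.n_after_xref,
            "unique_ls_hs": len(result.unique),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        manifest=manifest,
        scores=scores,
        up_group=up_group,
        down_group=down_group,
        screen_result=result,
        evidenced=evidenced,
        tally=tally,
        set_sizes=set_sizes,
    )
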