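"""Generate every synthetic input for the downstream analyses.

Emulates the study conditions at desk scale: a paired stress/control
expression study (2,000 genes, 20 pairs, 8-fold planted effects under
sigma=0.2 multiplicative noise), a divergence ladder of protein pairs, a
four-regime structural hit table with a second "alternate-mode" table for
concordance flagging, and the annotation tables (domains, orthologs, xref,
human HN-scores).

Writes under results/synthetic/.
"""

from pathlib import Path

from hnscreen.synthetic import (
    gen_annotations,
    gen_expression_study,
    gen_hit_table,
    gen_protein_pair,
    write_expression_study,
    write_protein_pair,
)

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    study, truth = gen_expression_study(
        n_genes=2000, n_pairs=20, frac_up=0.05, frac_down=0.05,
        effect_fold=8.0, noise_sigma=0.2, seed=SEED,
    )
    write_expression_study(study, truth, OUT, "expression")
    print(f"expression study: {study.matrix.shape[0]} genes x {study.matrix.shape[1]} samples, "
          f"{len(study.design)} pairs")

    for i, (identity, sigma) in enumerate([(0.9, 0.2), (0.3, 0.5), (0.3, 4.0)]):
        pair = gen_protein_pair(
            length=120, target_identity=identity, coord_noise_sigma=sigma,
            seed=SEED + i, pair_id=f"pair{i}",
        )
        write_protein_pair(pair, OUT / "structures")
        print(f"pair{i}: identity target {identity:.1f} (achieved "
              f"{pair.truth.achieved_identity:.2f}), coord noise {sigma} A, "
              f"regime {pair.truth.regime_label}")

    hits = gen_hit_table(60, seed=SEED)
    hits.to_csv(OUT / "hits_primary.tsv", sep="\t", index=False)
    alt = gen_hit_table(60, seed=SEED + 1)
    alt.to_csv(OUT / "hits_alternate.tsv", sep="\t", index=False)
    print(f"hit tables: {len(hits)} primary rows, {len(alt)} alternate rows over 4 regimes")

    bundle = gen_annotations(hits, p_shared_domain=0.5, p_ortholog=0.3,
                             n_human_genes=10_000, seed=SEED)
    bundle.domains.to_csv(OUT / "domains.tsv", sep="\t", index=False)
    bundle.orthologs.to_csv(OUT / "orthologs.tsv", sep="\t", index=False)
    bundle.xref.to_csv(OUT / "xref.tsv", sep="\t", index=False)
    bundle.human_scores.to_csv(OUT / "human_scores.tsv", sep="\t", index=False)
    print(f"annotations: {len(bundle.domains)} domain rows, {len(bundle.orthologs)} ortholog "
          f"pairs, {len(bundle.human_scores)} human HN-scores")


if __name__ == "__main__":
    main()
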