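"""Join screened pairs with annotations; tally evidence tiers and intersections.

Flags every classified pair for shared domain IDs and pan-taxonomic ortholog
support, derives the evidence tier (both / domain_only / homology_only /
neither), and computes the five-attribute intersection tally behind an UpSet
plot.

Reads results/synthetic/ and results/screen/, writes results/evidence/.
"""

from pathlib import Path

import pandas as pd

from hnscreen.evidence import AnnotationTables, assign_tiers, intersection_tally

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    classified = pd.read_csv(ROOT / "screen" / "classified_pairs.tsv", sep="\t")
    unique = pd.read_csv(ROOT / "screen" / "unique_ls_hs.tsv", sep="\t")
    annotations = AnnotationTables.from_frames(
        pd.read_csv(ROOT / "synthetic" / "domains.tsv", sep="\t"),
        pd.read_csv(ROOT / "synthetic" / "orthologs.tsv", sep="\t"),
    )

    uniq_keys = set(zip(unique["rice_gene_id"], unique["human_accession"]))
    classified["unique_ls_hs"] = [
        (g, h) in uniq_keys
        for g, h in zip(classified["rice_gene_id"], classified["human_accession"])
    ]
    evidenced = assign_tiers(classified, annotations)
    tally, set_sizes = intersection_tally(evidenced)

    out = ROOT / "evidence"
    out.mkdir(parents=True, exist_ok=True)
    evidenced.to_csv(out / "evidenced_pairs.tsv", sep="\t", index=False)
    tally.to_csv(out / "upset_tally.tsv", sep="\t", index=False)

    print(f"tiers over {len(evidenced)} pairs: {evidenced['tier'].value_counts().to_dict()}")
    print(f"UpSet set sizes: {set_sizes}")
    print(f"{len(tally)} attribute combinations; counts sum to {tally['count'].sum()}")
    uniq_tiers = evidenced.loc[evidenced["unique_ls_hs"], "tier"].value_counts().to_dict()
    print(f"unique LS-HS pairs by tier: {uniq_tiers}")


if __name__ == "__main__":
    main()
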