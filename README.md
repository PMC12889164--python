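# hnscreen

Cross-species discovery of stress-responsive genes that conserve protein
*structure* without conserving protein *sequence*.

Many rice proteins responding to heat stress have human counterparts that
sequence search alone cannot find because the pairs sit in or below the
twilight zone of sequence identity.  `hnscreen` implements the two-stage
screen behind that idea:

1. **HN-score meta-analysis.**  Across many paired stress/control expression
   experiments, each gene × pair observation gets the pseudocounted ratio
   `(T_HS + 1)/(T_ctrl + 1)`, is called upregulated (≥ 5), downregulated
   (≤ 1/5) or unchanged, and the gene's HN-score is
   `#up − #down`.  The top/bottom 1% of genes by HN-score form the up- and
   downregulated groups.
2. **Sequence/structure quadrant screen.**  Structural hit pairs between the
   selected rice genes and human proteins are filtered (≥ 50% alignment
   coverage on both sides, one hit per rice gene × human structure,
   unambiguous gene cross-references), then split by percentile thresholds —
   Q2 = median average Cα lDDT, Q3 = 75th-percentile global sequence
   similarity (EMBOSS Needle conventions) — into **LS–HS** (similarity ≤ Q3,
   lDDT ≥ Q2), **HS–HS** (similarity > Q3, lDDT ≥ Q2) and other.  **Unique
   LS–HS** pairs are LS–HS pairs whose rice gene has no HS–HS pair at all:
   structure-only correspondences.  Pairs are finally annotated with shared
   protein-domain IDs, pan-taxonomic ortholog support, evidence tiers, and
   membership of the human top/bottom-500 HN-score sets.

Because the original inputs are database-scale, the package ships a
first-class synthetic-data module that generates expression studies with
planted effects, protein sequence/structure pairs with tunable divergence,
hit tables with regime labels, and annotation tables — all seeded, all with
ground truth for recovery testing.  See `docs/methods.md` for the model
details and design choices.

## Worked example

```bash
hnscreen run --outdir demo --seed 0
```

runs the full pipeline on synthetic defaults (2,000 genes × 20 pairs,
four-regime hit table) and prints the stage counts:

```json
{
  "genes": 2000,
  "up_group": 20,
  "down_group": 20,
  "hits_input": 240,
  "hits_after_coverage": 240,
  "hits_after_dedupe": 240,
  "hits_retained": 240,
  "unique_ls_hs": 89
}
```

2,000 genes were scored; the top/bottom 1% groups hold 20 genes each; all
240 synthetic hit pairs survive the coverage/dedupe/xref cascade (the
generator plants high coverages and unique accessions), and 89 pairs land in
the low-sequence/high-structure quadrant with no high-sequence match for
their gene — the screen's candidate output.  `demo/` then contains the score
and group tables, classified and unique-pair tables, the thresholds JSON,
evidence tiers, the UpSet tally and a run manifest.

The same stages are available as numbered drivers over a persistent
`results/` tree:

```bash
python analysis/01_simulate_inputs.py   # synthetic study, structures, hits, annotations
python analysis/02_hn_scores.py         # HN-scores + 1% groups (planted genes recovered)
python analysis/03_structure_metrics.py # alignment %, avg lDDT per protein pair
python analysis/04_screen_hits.py       # cascade, Q2/Q3, quadrants, unique LS-HS
python analysis/05_evidence_tiers.py    # tiers + UpSet tally
```

and as library functions (`hnscreen.hn_scores`, `hnscreen.screen_cascade`,
`hnscreen.average_lddt`, `hnscreen.global_align`, ...) plus further CLI
subcommands (`simulate`, `hnscore`, `align`, `lddt`, `screen`, `evidence`).

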