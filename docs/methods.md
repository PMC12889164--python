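# Methods

## The two-part procedure

### Expression meta-analysis (HN-score)

Each stress experiment is paired with a non-treatment control from the same
study.  For gene *g* in pair *p* with scaled-TPM abundances `T_HS` (stress)
and `T_ctrl` (control), the pseudocounted fold change is

    HN-ratio(g, p) = (T_HS + 1) / (T_ctrl + 1)

The +1 pseudocount keeps the ratio defined at zero abundance (ratio 1 when
both sides are zero) and damps ratios for barely-expressed genes.  Each
observation is called **upregulated** when the ratio is ≥ 5, **downregulated**
when ≤ 1/5, and **unchanged** otherwise; both boundaries are inclusive, so a
ratio of exactly 5 is an up call.  The per-gene HN-score is

    HN-score(g) = #upregulated pairs − #downregulated pairs

an integer bounded by ± the number of pairs.  Swapping the stress and control
columns inverts every ratio and, because the thresholds are reciprocal,
negates every HN-score.  Genes with zero expression everywhere are retained
(score 0); no expression floor is applied, so the ranked universe is every
gene in the input matrix.

Group selection takes the top and bottom `ceil(fraction · N)` genes
(default fraction 0.01).  Boundary ties are broken by lexicographic gene id —
an arbitrary but deterministic rule; the score ranges reported by such an
analysis do not pin down a tie rule, and determinism is what reproducibility
needs.

### Structural screen

Cross-species (rice → human) structural hit pairs carry query/target
coverage, an average Cα lDDT, and — after pairwise alignment — a global
sequence similarity.  The cascade runs in a fixed order:

1. **Coverage**: keep pairs with ≥ 50% coverage on *both* proteins
   (inclusive), prioritising global over partial matches.
2. **Within-gene dedupe**: several protein isoform accessions of one rice
   gene may hit the same human structure; keep the alignment with the
   highest coverage, ties broken by highest average lDDT, residual ties by
   accession.  "Coverage" here is the scalar min(qcov, tcov) — the
   conservative reading consistent with the both-sides filter.
3. **Cross-reference**: keep pairs whose human accession maps to exactly one
   current gene id/symbol; ambiguous or missing mappings are dropped.
4. **Thresholds**: over the retained set, Q2 = median average lDDT and
   Q3 = 75th percentile of sequence similarity, with linear-interpolation
   quantiles (the numpy default).  Thresholds are computed per gene group
   (up / down) and per alignment mode, each on its own retained set.
5. **Quadrants**: LS–HS iff similarity ≤ Q3 and lDDT ≥ Q2; HS–HS iff
   similarity > Q3 and lDDT ≥ Q2; everything with lDDT < Q2 is "other".
   The labels partition the retained set.
6. **Unique LS–HS**: LS–HS pairs whose rice gene owns no HS–HS pair anywhere
   in the classified table.  A gene with even one high-sequence-similarity
   structural match is explicable by ordinary homology, so its LS–HS pairs
   are excluded from the "unique" set.

Flags: *concordant* marks unique pairs recovered by the same cascade run on
an alternate alignment mode's hit table (matched on rice gene + human
accession, each mode with its own thresholds); *multiple_human_hits* marks
rice accessions matching more than one human structure, with the highest-lDDT
hit designated top-ranked (ties by accession).  Human heat-response context
joins by gene symbol against a human HN-score table: membership of the
top/bottom 500 symbols by score (rank with lexicographic tie-break at the
boundary) labels each pair up500 / down500 / none.

### Evidence tiers

Per pair: `shared_interpro` is true when the two accessions' domain-ID sets
intersect; `pan_homology` is true when (rice gene, human symbol) appears in
the ortholog table.  The tier is the pure function of those booleans:
both / domain_only / homology_only / neither.  `homology_only` is included
for logical completeness even though screens of this kind rarely surface it
(a reported ortholog with no shared domain signature is usually an
annotation gap).  Missing annotation rows mean empty set / false, never an
error — public annotation coverage is incomplete.  The five-attribute
intersection tally (all pairs, shared domain, HS–HS, pan-homology, unique
LS–HS) is exported as UpSet-plot data; combination counts always sum to the
pair total, and each attribute's set size equals the sum over combinations
containing it.

## Alignment engine

Global mode is Needleman–Wunsch and local mode Smith–Waterman, both with
affine gaps, BLOSUM62, gap open 10 and gap extend 0.5 — the documented EMBOSS
Needle/Water defaults.  Conventions fixed here:

* a gap of length L costs `open + L·extend` (EMBOSS charges extension on
  every gap residue, not only after the first);
* end gaps are free in global mode (Needle's `-endweight false` default);
  note that at each end only one sequence's overhang occupies the free
  terminal gap — the other side's overhang is an internal gap and is charged;
* identity% = identical columns / alignment length; similarity% = columns
  with positive substitution score *or* identical residues, over the same
  denominator, gap columns counting toward it.  The "or identical" clause
  exists because X scores 0 against everything (including itself), and a
  pure score>0 rule would let identity exceed similarity on X–X columns;
* the unknown residue X scores 0 against everything;
* the reported alignment is the dynamic-programming engine's first optimal
  traceback — deterministic, but one of possibly many co-optimal paths, so
  identity/similarity of near-tied alignments can differ between argument
  orders even though the score never does.

The dynamic programming is delegated to biopython's `PairwiseAligner`; tests
verify its scores against exhaustive enumeration of all monotone residue
matchings for short sequences, an oracle that shares no code with the
aligner.

## Cα lDDT

For mapped reference residue *i*, every other mapped residue *j* with
reference distance d_ref(i,j) < 15 Å (strict) defines a local contact; the
contact is preserved at tolerance t ∈ {0.5, 1, 2, 4} Å when
|d_ref − d_model| < t (strict).  The per-residue score averages the
preserved fraction over the four tolerances; the reported score averages
over mapped residues.  Only Cα atoms enter (the full definition uses all
atoms): backbone-level similarity is what database-scale structure screening
ranks by, and the choice is a deliberate simplification.  The rice (query)
structure is the reference side.  Residues with no contact inside the radius
are excluded from the average; a mapping in which *no* residue has a contact
is an error.  The measure uses only internal distances, so it is exactly
invariant under rigid motion of either structure — verified against a plain
double-loop recomputation and random rigid motions.

Foldseek-style tabular hit files are parsed with 1-based inclusive alignment
spans converted to 0-based half-open internally; coverage falls back to
(end − start + 1)/length when not precomputed.

## Synthetic data: what it emulates and what it does not

The generators draw from named, seed-stable substreams (one per generator)
derived from a single integer seed, so outputs are byte-reproducible and
adding a generator never shifts another's stream.

* **Expression** — per-gene baselines are log-normal around a scaled-TPM
  baseline mean of 50 with one natural-log unit of between-gene spread
  (typical of TPM-scale abundance distributions); stress values multiply the
  paired control by the planted effect fold (default 8, comfortably above
  the 5-fold call threshold) and independent log-normal noise (default
  σ = 0.2).  Defaults of 20 pairs and 5% planted genes per direction give a
  study where ranking should separate planted from unchanged genes
  completely; the tests assert exactly that.  What is *not* modelled:
  count-level sampling noise, library-size effects, batch structure between
  studies, correlated co-regulation.  Passing recovery tests therefore shows
  the scoring machinery is correct, not that real curated studies are this
  clean.
* **Protein pairs** — a self-avoiding 3.8 Å fixed-step Cα random walk
  (non-adjacent clash floor 3.5 Å) stands in for a fold; the partner
  substitutes a fixed-size random residue subset (achieving the target
  identity to within 1/length) and perturbs every coordinate with iid
  Gaussian noise.  No secondary structure, no indels (the residue mapping is
  the identity, so coverage is exercised separately through the hit-table
  generator).  This is sufficient to exercise lDDT's monotone degradation
  with noise and the alignment statistics, not to resemble real proteins.
* **Hit tables** — per-regime Gaussian draws (clipped to valid ranges) for
  similarity, lDDT and coverages, with defaults placing LS/HS regime means
  at 15%/70% similarity and 0.30/0.85 lDDT so midpoint thresholds recover
  ≥95% of labels.
* **Annotations** — background domain IDs per accession (0–3 from a large
  pool), shared IDs injected per pair with probability `p_shared_domain`,
  ortholog rows with probability `p_ortholog`, an unambiguous one-to-one
  accession → symbol xref, and an integer human HN-score table over a
  10,000-symbol universe (scores uniform on the integer range a study of
  this design produces).

## Numerical and degenerate-input choices

* Quantiles: linear interpolation between order statistics everywhere.
* Ratio/label boundaries: inclusive at 5, 1/5, 50% coverage, Q2 and Q3
  exactly as the definitions above state.
* Empty local alignment (no positive-scoring residue pair) returns score 0,
  length 0, percentages 0.
* Empty hit tables flow through filters and tallies without error; empty
  retained sets make threshold computation an error (there is nothing to
  take a median of).
* All tie-breaks (group boundary, dedupe, top-ranked hit, human 500
  boundary) are lexicographic and documented at the function level.

## Problem sizes

Default analysis and test sizes — 2,000-gene/20-pair studies, 10,000-gene
selection tables, 240-row hit tables, length ≤ 8 alignment-oracle sequences,
5-residue lDDT toys — were chosen so every oracle comparison is exhaustive
and every planted-truth check is unambiguous at desk scale.

## Known limitations

* lDDT is Cα-only and ignores the stereochemical-plausibility component of
  the full definition.
* The aligner reports one co-optimal traceback; percentage identities near
  score ties are convention-dependent (scores are not).
* The synthetic generators make no attempt at biological realism beyond the
  marginal properties listed above; they define controlled conditions for
  verifying the machinery.
* Per-mode screens are independent; no combined-mode threshold set is
  defined.
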