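# Methods

## The consensus model

The consensome treats each differential-expression contrast as an
independent Bernoulli trial per gene. With `n` the number of contrasts in
which a gene was assayed and `k` the number of those with nominal p
strictly below α = 0.05, the consensus p-value is the upper binomial tail

    CPV(k, n) = P(X ≥ k),  X ~ Binomial(n, p0),  p0 = 0.05.

α (the per-contrast call threshold) and p0 (the null success rate of the
binomial model) are numerically identical by construction but play
different roles, so they are separate configuration parameters. Genes
assayed in zero contrasts are dropped with a log notice, never imputed.
CPVs are adjusted across all retained genes with Benjamini–Hochberg
(`statsmodels` implementation) to give CQVs; the BH family is the full
retained gene list.

Ranking is by CPV ascending, ties broken by |log2 GMFC| descending
(direction-agnostic, since a differentiation signature mixes induced and
repressed genes), final ties by gene id — a total order, so outputs are
reproducible byte-for-byte. The percentile of rank r among m genes is
100·(m − r)/m, kept exact internally and floored to an integer for display.
Significance counting is direction-agnostic: a gene alternating in sign
across contrasts still accumulates k. This matches a consensus notion of
"frequently regulated" rather than "consistently signed"; users who need
sign consistency should filter on GMFC.

Confidence transcripts are the directional tails: CQV < 0.05 and log2 GMFC
> 1 (induced) or < −1 (repressed), i.e. a mean fold change beyond 2× in
either direction. GMFC is reported on the log2 scale (the arithmetic mean
of log2 fold changes, which is the log2 of the geometric mean fold change
with sign carried by the mean).

## HCT designation and the intersection screen

A node's high-confidence transcriptional targets are the genes in the 95th
percentile of its consensome. The cut takes the top ⌈(100 − pct)% · m⌉
ranked genes — a counting rule rather than an interpolated quantile — so
the set is never empty and the 95th-percentile cut of a 12,525-gene
ranking yields exactly 627 genes.

Knockout up/down gene sets use the fold-change/p screen |FC| > 1.5
(linear scale, i.e. |log2 FC| > log2 1.5) and p < 0.05; both thresholds
are exposed because volcano-style selections (e.g. p < 0.01 with no FC
cut) are also in common use.

Each node × direction overlap is scored with the one-sided enrichment
hypergeometric tail P(X ≥ k) over a finite gene universe, plus the
cross-product odds ratio of the 2×2 table (k, |A|−k, |B|−k, N−|A|−|B|+k).
When any cell is zero, 0.5 is added to every cell (Haldane–Anscombe) and
the record is flagged degenerate. The default universe is the genes
jointly observed in the knockout table and the HCT library — published
screens of this kind rarely state a universe, and the jointly-observed
set is the defensible default; it is configurable. BH adjustment is
applied separately within each modality × direction family, because
transcriptomic and ChIP-Seq-derived HCT sets have different size and bias
profiles and are reported as separate panels.

Node-level (second-order) enrichment applies the identical contract to
annotation terms (phenotype-ontology-style term → node maps, curated
interactor lists) against the set of footprinted nodes, relative to the
full node universe.

## ChIP-Seq integration

Peak → gene assignment is an input, not a computation (genomic
nearest-gene logic is upstream of this package). Per-gene strength is the
maximum peak score over the gene's peaks — the best-peak convention, which
is invariant to peak splitting; mean aggregation is available. Genes are
ranked by strength (ties by gene id) and percentilized exactly as in the
consensome; the 50th-percentile cut defines the bound, putative
direct-target set. Enrichment of (up ∩ bound) genes in the induced
confidence set, and mirror-wise for down/repressed, uses the same
hypergeometric contract. Fold-change concordance is a Pearson correlation
over a gene subset (default: confidence-set genes inside the bound set),
reporting r, r², the single-predictor adjusted r² = 1 − (1 − r²)(n−1)/(n−2),
and the two-sided p from the t transform with n − 2 df.

## The synthetic generator

The generator emulates the pipeline's inputs with planted ground truth.
Its central design choice: a planted gene is *detected* in a contrast with
probability `detect_prob`, and detection forces p ~ Uniform(0, 0.05) —
always a nominal call — while non-detections and null genes draw
p ~ Uniform(0, 1]. The per-contrast success probability, the one quantity
the binomial consensus statistic consumes, is therefore an exact, directly
controllable parameter instead of an emergent property of an
effect-size/test model. Planted log2 fold changes are Normal(±effect_mu,
effect_sd) with the sign fixed per gene; nulls are Normal(0, null_sd). The
assay mask is i.i.d. Bernoulli(assay_rate) per gene × contrast, exercising
the varying-n conditioning of the CPV.

Defaults mirror the reference study geometry: 10,000 genes, five
contrasts, 5% planted responders, detect_prob 0.9, effect_mu 2 (4-fold),
effect_sd 0.5, null_sd 0.5, assay_rate 0.9; a 691-node library with
300-gene HCT sets and active-node overlap fraction 0.3; 16-member
annotation terms with enrichment fraction 0.8; 679 peaks. Where the
emulated study does not pin a value (contrast counts per archived series,
numbers of active nodes and enriched terms, peak-strength distribution),
the generator exposes a parameter with a default a practitioner would call
realistic: 10 active nodes, one enriched term (the single-benchmark
geometry), log-normal peak scores.

The knockout table gives planted genes p ~ Uniform(0, 0.01) — "clearly
significant" without modelling a test statistic — and the library's active
nodes draw a fixed fraction of their HCT set from planted knockout-regulated
genes, alternating direction across active nodes. One master seed spawns
fixed named substreams per component (compendium, knockout, library,
annotations, peaks), so any single component can be regenerated
independently and all outputs are byte-identical for a given seed.

What the generator does *not* emulate: count-level noise and
mean–variance structure (inputs are DE summaries by design),
between-contrast correlation (contrasts from one time course share a
baseline; the binomial model assumes independence, and the generator
matches the model rather than breaking it), gene–gene correlation,
annotation-term overlap structure, and realistic peak-to-gene multiplicity
beyond multinomial assignment. Passing calibration and recovery tests
therefore demonstrates the pipeline's statistics are implemented correctly
and behave as designed under the model's own assumptions — not that the
binomial independence assumption holds on archived compendia, where
correlated contrasts make the CPV anti-conservative relative to a
mixed-model alternative.

## Numerical and procedural choices

- Binomial and hypergeometric tails via `scipy.stats` survival functions
  (`sf(k−1)`), accurate in the far tail; k = 0 short-circuits to 1.0.
- p-values are kept in (0, 1]: generator draws use 1 − U[0,1) and a
  tiny-float floor; file readers reject p ≤ 0 or p > 1 on assayed rows.
- Strict inequality at the α threshold: p = 0.05 is not a call.
- Sorting everywhere uses stable mergesort with explicit full tie-break
  chains, and floats are rendered with 6 significant digits, so every
  output file is deterministic across runs and platforms.
- Degenerate cases are surfaced, not hidden: single-gene percentile tables
  (percentile 0), universe-covering annotations (p = 1, degenerate flag),
  zero-variance correlation inputs (error).
- Pipeline stage failures propagate with the stage name and mark the
  summary manifest incomplete; manifests carry no timestamps so output
  trees are reproducible byte-for-byte.
- The demo configuration disables figure output; figure files are
  by-products, never inputs, and the SVG writer strips creation dates when
  figures are enabled.

## Problem sizes in the test and acceptance runs

Calibration and recovery checks run at the reference geometry (10,000
genes × 5 contrasts; 200–691-node libraries; 20 null seeds, 10 power
seeds), which the package's vectorized implementation completes in
seconds. The exact-oracle checks cover the full (k ≤ n ≤ 50) binomial grid
against rational summation and every hypergeometric configuration with
universe N ≤ 12 against exhaustive subset enumeration.

## Known limitations

- Independence of contrasts is assumed, as in the consensus model itself;
  compendia with strongly correlated contrasts will overstate consensus.
- The odds ratio is the unconditional cross-product ratio, not a
  conditional-MLE estimate; with the Haldane correction it is finite but
  biased for sparse tables (the flag marks affected records).
- Percentile cuts use the ceiling counting rule; a rank-interpolated
  quantile would give marginally different set sizes at small m.
- No gene-identifier mapping: all inputs must share one id namespace.
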