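# Methods

This note documents the models, conventions and numerical choices behind
`bivalentscan`, and what the synthetic-study generator does and does not
emulate.

## Coordinates and file conventions

All intervals are 0-based half-open (BED convention) internally; GTF input
(1-based closed) is converted on read. The TSS of a '−'-strand gene is
`end − 1`, the last covered base, so the TSS always lies inside the gene;
for multi-transcript GTF genes the TSS is the 5′-most transcript start on
the gene's strand (the common GREAT-style convention). A narrowPeak summit
offset of −1 (summit not called) falls back to the interval midpoint.
Segmentation gaps are reported as an explicit `Unannotated` state so state
fractions always sum to 1. bedGraph binning is the length-weighted mean over
a fixed `bin_size` denominator, which makes it mass-conserving:
`sum(bins)·bin_size == sum(value·length)`.

## Target calling

High-confidence peaks satisfy p < 1e-8 **and** fold enrichment > 4 with
strict inequalities (boundary values excluded); the p-value is compared in
−log10 space to avoid underflow. Peak→gene assignment is summit-to-TSS with
a closed ±100 kb ball; signed distances are strand-oriented (positive =
downstream). A gene is activated (repressed) iff it has ≥1 assigned
high-confidence peak and a significant log₂FC strictly above 2 (below −2);
the significance flag is consumed from the expression table, not recomputed.
Peaks are labeled activating / repressive / ambiguous / unassigned from the
classes of their assigned target genes; ambiguous peaks are excluded from
metaprofile anchor groups, which keeps the activating and repressive plots
disjoint. The distance histogram uses half-open bins with a closed last bin
at the assignment window.

## Chromatin state

Scalar state fractions use the state at the single anchor base (TSS or
summit), not a windowed majority — unambiguous and exactly testable; the
positional profile (strand-oriented offsets −flank..+flank, default
±2 kb / 50 bp) provides the windowed view. The bivalent/Polycomb group
defaults to {TssBiv, BivFlnk, EnhBiv, ReprPC, ReprPCWk} — weak Polycomb is
included because the biological grouping ("Biv" + "ReprPC") does not
enumerate sub-states — and is configurable. Summit anchors carry no strand
and are profiled unoriented.

## Differential signal

Tracks are scaled to counts-per-million equivalents (`value·1e6/total`)
before the ratio so library size cancels; the ratio is computed as a
difference of logs, `log2(a′+c) − log2(b′+c)`, which makes antisymmetry
bit-exact. **Pseudocount:** the library function defaults to c = 1.0, but
the pipeline configuration defaults to c = 0.25. The reason is scale: after
CPM scaling the *mean* bin value is 1e6/n_bins, which for a 136 Mb genome at
50 bp bins is ≈0.37. A unit pseudocount would then dominate even 12-fold
enriched regions and shrink a planted 1.0 log₂ effect to ≈0.3. With c = 0.25
and ≈12× peak enrichment the residual biases are (i) pseudocount shrinkage
of ≈0.03–0.06 and (ii) library-size renormalization: the planted H3K4me3
gain adds ≈3.5% to the treatment library, so CPM scaling shifts *all* bins
by −log2(1.035) ≈ −0.05 (visible as the small negative offset of repressive
H3K4me3 profiles). Recovered centers are therefore ≈±0.90–0.92 for planted
±1.0 effects; both biases are inherent to CPM-style normalization of
differential ChIP signal, not simulation artifacts.

Loss regions are maximal runs of bins ≤ threshold, merging runs separated by
≤ 2 bins and keeping width ≥ 500 bp. The pipeline default threshold is −0.5
(the library function's default is −1.0): a planted loss of −1.0 means the
per-bin expectation sits *at* −1.0, so a threshold there would call regions
with probability ≈½ per bin; −0.5 sits ≈1.5 enriched-region noise SDs above
the planted mean and ≈1.9 background SDs below zero, giving near-perfect
sensitivity inside planted windows and ≈10⁻⁷ per-bin background run rates.
These parameters have no canonical definition and are explicit config.

## Enrichment statistics

The hypergeometric upper tail P(X ≥ k) is evaluated by a log-gamma
log-space sum (exact to ~1e-12 against rational combinatorics for universes
≤ 20, and against `scipy.stats.hypergeom` elsewhere). Preranked GSEA uses
the classic weighted Kolmogorov–Smirnov statistic with weight exponent 1.0;
the permutation null draws random member sets of equal size (the standard
preranked behavior — only one ranking exists, so phenotype permutation is
unavailable). The null is evaluated by a vectorized closed form: the running
sum is piecewise linear, so its extrema occur only immediately before or
after hit positions, and ES for thousands of permutations reduces to an
(n_perm × set size) array expression (verified against the direct
implementation to 1e-12). The nominal p is
`(1 + #{same-sign |null| ≥ |ES|}) / (1 + #same-sign nulls)` — conditional on
the ES sign, +1-corrected so p > 0; this conditional form is what makes the
p-value calibrated (rejection at α ≈ α for random sets), and its smallest
attainable value is `1/(1 + #same-sign nulls)`, slightly above `1/(1+n_perm)`
whenever some null ES have the opposite sign. NES divides ES by the mean
same-sign |null ES|; the leading edge is the members at or before (after,
for negative ES) the running-sum extremum.

## Survival

"Upper quantile" stratification is read as the upper quartile: Q3 by linear
interpolation, boundary ties assigned to the high stratum; both choices are
documented because other readings (nearest-rank, ties-low) change membership
by at most the tied samples. Kaplan–Meier is the product-limit estimator
(censored-only times shrink the risk set without steps); the log-rank test
accumulates observed−expected and hypergeometric variance at each distinct
event time, handling tied events natively, with p from the χ²(1) upper
tail. TP53 loss-of-function is consumed as an input flag (annotation is an
upstream concern). Both estimators are cross-checked against lifelines in
the test suite.

## The synthetic study

The generator plants effects with protective margins so downstream truth is
exact, then draws everything else from realistic noise laws:

- **Genome/genes** — single-isoform genes on a 260 kb slot grid (TSS
  spacing ≥ 250 kb), so a true peak within ±95 kb of its target's TSS is
  assignable to exactly one gene at the 100 kb window. Requesting more genes
  than the genome holds at that spacing is an error.
- **Peaks** — one true peak per target gene, summit offset ~
  N(0, 30 kb) clipped to ±95 kb; true scores are 8.1+Exp(4) in −log10 p and
  4.1+Exp(6) in fold units (≥0.1 above both thresholds), decoys fail at
  least one threshold by ≥0.1. Expression: activated ~ N(+3, 0.5) resampled
  to stay >2.1, repressed ~ N(−3, 0.5) below −2.1, nulls ~ N(0, 0.7) and
  significant with probability 0.05. Together these margins force target
  recall and precision of exactly 1.0 — the planted *margins*, not the
  caller, are what make the oracle exact.
- **Segmentation** — a ±1 kb state segment at every TSS: bivalent group
  (TssBiv or ReprPC, equal odds) with probability 0.40 for activated
  targets and 0.10 otherwise (echoing the observed ≈38% vs ≈10% contrast);
  ReprPC segments at 30% / 5% of activating / repressive summits away from
  TSS segments; everything else unannotated.
- **Coverage** — 50 bp bins emitted directly as bedGraph (the pipeline
  consumes binned signal; no read-level simulation). Background bins ~
  Gamma(20, 0.5) (mean 10, relative SD 0.22 — binned pooled chromatin has
  modest relative variation); ±500 bp windows around every true summit are
  12-fold enriched with Gamma shape 50 (more signal, lower relative noise,
  as pooled read counts behave); the planted differential effect multiplies
  the overexpression condition by 2^{+1,−1,−1} for H3K4me3/H3K27me3/EZH2 at
  activating summits only. Effects are multiplicative on the background, so
  log-ratio recovery is unbiased by construction up to the normalization
  effects above. The enrichment factor was chosen so enriched bins clear the
  pipeline pseudocount ~17-fold while planted windows remain a small
  fraction of library mass (keeping the renormalization shift ≈0.05).
- **Cohort** — alteration flags for the ten RTK/RAS/BRAF classification
  genes (driver split ~60% KRAS, 20% NF1, rest minor) plus TP53-LOF;
  defaults 45% RAS-driven and 50% TP53-LOF, matching TCGA-LUAD frequencies;
  expression log-normal; survival exponential (median 1000 days) with the
  hazard multiplied by 2.5 **only** for RAS-driven ∧ TP53-LOF ∧
  upper-quartile-expression patients; independent exponential censoring
  calibrated to a 30% rate.

All randomness flows from a single mandatory seed through named substreams
(`SeedSequence([seed, stage])`), so identical configs give byte-identical
files and any stage can be regenerated independently.

**What the generator does not emulate:** read-level noise and mappability,
fragment-size effects, peak-width/shape diversity, copy number, batch
effects, correlated alterations (e.g. KRAS/EGFR mutual exclusivity beyond
one-driver-per-patient), non-exponential survival, and informative
censoring. Passing tests therefore demonstrate the *machinery* is correct
and calibrated under the planted statistical structure, not that real data
meet that structure.

## Problem sizes

Defaults were sized so a full run is desk-scale: a 4×34 Mb genome (the
smallest that holds 520 genes at 260 kb spacing), ≈2.7M coverage bins per
track, 607 peaks, 400 patients; a full pipeline run takes ≈30 s on one CPU.
The power studies use 200–1000 Monte-Carlo replicates; the context-specific
survival contrast uses n = 4000 patients with a 10% RAS-driven fraction —
chosen by a pre-run power analysis so that simultaneously (a) the in-context
test has ≥95% power and (b) the effect is diluted below detectability in an
equal-size unrestricted sample (the contrast requires a small affected
fraction, which at 400 patients would leave the in-context test underpowered).

## Known limitations

- The metaprofile recovers planted effects with the ≈5–10% CPM/pseudocount
  shrinkage described above; an input-subtraction or background-matched
  normalization would remove it but is out of scope.
- `read_bedgraph` sums overlapping intervals (they are treated as additive
  mass); files with intentionally overlapping non-additive intervals are
  not supported.
- The GSEA nominal p is bounded below by `1/(1 + #same-sign nulls)`;
  reporting smaller p-values requires more permutations, not a formula
  change, and the `no_same_sign_nulls` flag marks the degenerate case.
- The log-rank test is the standard unweighted statistic; no Wilcoxon-style
  weighting or trend tests.
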