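# bivalentscan

Integrative analysis of how a transcription factor engages **bivalent and
Polycomb-repressed chromatin**, for regulatory genomicists who have a set of
ChIP-seq binding peaks, two-condition histone-mark coverage, a differential
expression table, a ChromHMM-style chromatin-state segmentation, and a tumor
cohort — and want to connect them. The motivating biology is a factor
(ONECUT2-like) overexpressed in lung adenocarcinoma cells against a
DNA-binding-dead control (ΔDBD): the factor preferentially binds near
promoters carrying both H3K4me3 and H3K27me3 (bivalent) or Polycomb-repressed
(ReprPC) states, activates those genes while gaining H3K4me3 and losing
H3K27me3/EZH2 locally, and its expression is prognostic specifically in
RAS-driven, TP53-mutant tumors.

Because the raw sequencing data behind such a study is not reproducible at
desk scale, the package ships a first-class **synthetic-study generator**
that emits every downstream product (narrowPeak peaks, bedGraph coverage,
GTF genes, BED segmentation, expression/cohort TSVs, GMT gene sets) with
planted, margin-protected effects and a ground-truth manifest, so every
pipeline stage is verifiable exactly.

## What it computes

- **Target calling** — high-confidence peaks (p < 1e-8 *and* fold
  enrichment > 4, both strict), peak→gene assignment by summit-to-TSS
  distance (|summit − TSS| ≤ 100 kb), and target classes: a gene is
  *activated* (*repressed*) iff it has ≥1 assigned high-confidence peak and a
  significant log₂FC > 2 (< −2).
- **Chromatin state** — per-anchor state lookup against a 15-state Roadmap
  segmentation; the bivalent/Polycomb group fraction
  ({TssBiv, BivFlnk, EnhBiv, ReprPC, ReprPCWk}) and positional
  state-composition profiles around TSSs.
- **Differential signal** — CPM-scaled log₂ ratio tracks
  log₂((a′+c)/(b′+c)), metaprofiles and heatmap matrices around anchors, and
  signal-loss regions (gap-merged runs of bins at or below a threshold).
- **Enrichment** — a self-implemented upper-tail hypergeometric overlap test
  P(X ≥ k) with fold enrichment (k/q)/(r/u), and preranked GSEA: the weighted
  Kolmogorov–Smirnov running statistic (hits step by |s|ᵖ/N_R, misses by
  −1/(N−N_h); ES is the signed maximal deviation), with a random-set
  permutation null, NES = ES / mean(same-sign |null ES|), and a +1-corrected
  nominal p conditional on the ES sign.
- **Cohort survival** — RAS-driven (KRAS/NRAS/HRAS/RIT1/NF1) and
  RAS-activated (+EGFR/ERBB2/MET/BRAF/MAP2K1) context classification,
  upper-quartile expression stratification (linear-interpolated Q3, boundary
  ties high), a self-implemented Kaplan–Meier product-limit estimator, and
  the log-rank test with hypergeometric variance at tied event times.

## Worked example

Run the full pipeline on the default synthetic study (a 4×34 Mb genome, 520
genes with 300 activated / 107 repressed planted targets, 607 peaks of which
407 are true, three marks × two conditions of 50-bp coverage, and a
400-patient cohort):

```sh
echo 'seed: 1' > config.yaml
bivalentscan all --config config.yaml --outdir run
```

which prints (about half a minute on one CPU):

```json
{
 "chromstate": {
  "bivalent_fraction_activated_tss": 0.373333,
  "bivalent_fraction_null_tss": 0.035398,
  "bivalent_fraction_activating_summits": 0.29,
  "bivalent_fraction_repressive_summits": 0.056075
 },
 "enrich": {
  "planted_set_es": 1.0,
  "planted_set_nes": 5.763535,
  "planted_set_nominal_p": 0.001049317943336831
 },
 "signal": {
  "h3k4me3_activating_summits_center_log2fc": 0.924955,
  "h3k27me3_activating_summits_center_log2fc": -0.903974,
  "ezh2_activating_summits_center_log2fc": -0.906481,
  "loss_region_jaccard": 0.953175
 },
 "survival": {
  "logrank_p_all": 0.5088439110976103,
  "logrank_p_ras_driven_tp53lof": 0.012672377517032589
 },
 "targets": {
  "n_peaks": 607,
  "n_high_confidence_peaks": 407,
  "n_activated_targets": 300,
  "n_repressed_targets": 107
 }
}
```

(abridged to the headline keys). Reading it: all 407 true peaks pass the
confidence filter and exactly the planted 300/107 targets are recovered;
37.3% of activated-target TSSs sit in bivalent/Polycomb states against a
3.5% draw for null genes (planted probabilities 0.40 vs 0.10); the planted
+1.0/−1.0/−1.0 log₂ effects for H3K4me3/H3K27me3/EZH2 at activating summits
are recovered at +0.92/−0.90/−0.91 (the residual shrinkage is the
pseudocount plus library-size renormalization, see `docs/methods.md`);
H3K27me3- and EZH2-loss regions co-localize with Jaccard 0.95; the planted
activated-target set is maximally significant by preranked GSEA (ES = 1, no
null exceedances at 1000 permutations); and the hazard planted only in
RAS-driven ∧ TP53-LOF ∧ expression-high patients is detected in that context
(p = 0.013) but invisible in the unstratified cohort (p = 0.51).

Every stage is also a standalone subcommand (`simulate`, `targets`,
`chromstate`, `signal`, `enrich`, `survival`) over explicit files, and the
same functionality is importable (`bivalentscan.target_calling`,
`.chromatin_state`, `.differential_signal`, `.enrichment`,
`.cohort_survival`, `.synthetic_data`, `.pipeline`).

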