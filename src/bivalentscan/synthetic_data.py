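"""Synthetic study generator with planted, recoverable effects.

Emulates the downstream products of a transcription-factor overexpression
study — binding peaks with p/fold scores, a chromatin-state segmentation,
binned two-condition coverage for H3K4me3/H3K27me3/EZH2, a differential
expression table and a TCGA-like tumor cohort — never raw reads.  Every
planted effect is recorded in a ground-truth manifest so each pipeline stage
can be scored exactly.

Construction guarantees that make downstream truth exact:

* single-isoform genes whose TSSs are spaced >= 250 kb, so each true peak
  (placed within +/-95 kb of its target's TSS) is assignable to exactly one
  gene at the 100 kb window;
* true peaks clear both high-confidence thresholds with a margin of at least
  0.1 (-log10 p and fold units) and decoys miss at least one by the same
  margin;
* planted expression changes clear the |log2FC| > 2 threshold with a 0.1
  margin, so target recall and precision against the manifest are 1.0.

Coverage is emitted at a fixed bin size directly as bedGraph.  Background
bins draw from a Gamma law; peak windows draw from a higher-mean,
higher-shape Gamma (enriched regions have more signal and lower relative
noise, as pooled read counts do), and the planted differential effect
multiplies the overexpression-condition signal within +/-500 bp of
activating summits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import (
    CoverageTrack,
    GeneSetCollection,
    GeneTable,
    GenomeLayout,
    PeakSet,
    StateSegmentation,
    write_bedgraph,
    write_cohort_table,
    write_expression_table,
    write_gene_annotation_gtf,
    write_gmt,
    write_narrowpeak,
    write_segmentation,
)
from .cohort_survival import RAS_DRIVER_GENES, RAS_ACTIVATED_GENES

__all__ = [
    "SimulationConfig",
    "GroundTruthManifest",
    "MARKS",
    "CONDITIONS",
    "simulate_layout",
    "simulate_genes",
    "simulate_segmentation",
    "simulate_peaks",
    "simulate_expression",
    "simulate_coverage_track",
    "simulate_cohort",
    "simulate_study",
]

MARKS = ("h3k4me3", "h3k27me3", "ezh2")
CONDITIONS = ("onecut2", "ddbd")  # overexpression vs DNA-binding-dead control

_GENE_SLOT = 260_000       # bp per gene slot; keeps TSS spacing >= 250 kb
_TSS_JITTER = 5_000        # bp of uniform jitter inside a slot
_PEAK_MAX_OFFSET = 95_000  # true summits stay this close to their TSS
_SCORE_MARGIN = 0.1        # clearance around the high-confidence thresholds
_LFC_MARGIN = 0.1          # clearance around the |log2FC| = 2 threshold
_EFFECT_HALFWIDTH = 500    # bp around activating summits carrying the effect
_TSS_SEGMENT_HALFWIDTH = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Planted counts and probabilities default to the study conditions the
    analysis is designed around: 300 activated and 107 repressed targets,
    a 0.40 bivalent/Polycomb probability at activated-target TSSs against a
    0.10 background, +1.0/-1.0/-1.0 log2 effects for H3K4me3/H3K27me3/EZH2
    at activating peaks, and a hazard ratio of 2.5 confined to RAS-driven,
    TP53-LOF, high-expression patients.
    """

    seed: int
    n_chroms: int = 4
    chrom_length: int = 34_000_000
    n_genes: int = 520
    n_activated_targets: int = 300
    n_repressed_targets: int = 107
    p_bivalent_given_activated: float = 0.40
    p_bivalent_background: float = 0.10
    peak_window_sd: int = 30_000
    n_decoy_peaks: int = 200
    planted_h3k4me3_log2fc: float = 1.0
    planted_h3k27me3_log2fc: float = -1.0
    planted_ezh2_log2fc: float = -1.0
    background_gamma_shape: float = 20.0
    background_gamma_scale: float = 0.5
    p_reprpc_given_activating_peak: float = 0.30
    p_reprpc_background_peak: float = 0.05
    peak_enrichment: float = 12.0
    peak_gamma_shape: float = 50.0
    bin_size: int = 50
    n_random_gene_sets: int = 5
    random_gene_set_size: int = 50
    # cohort block
    n_patients: int = 400
    frac_ras_driven: float = 0.45
    frac_ras_activated_only: float = 0.15
    frac_tp53_lof: float = 0.50
    hazard_ratio_high_expression: float = 2.5
    censoring_rate: float = 0.30
    median_survival_days: float = 1_000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "p_bivalent_given_activated",
            "p_bivalent_background",
            "p_reprpc_given_activating_peak",
            "p_reprpc_background_peak",
            "frac_ras_driven",
            "frac_ras_activated_only",
            "frac_tp53_lof",
            "censoring_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_ras_driven + self.frac_ras_activated_only > 1.0:
            raise ValueError("subgroup fractions exceed 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_activated_targets + self.n_repressed_targets > self.n_genes:
            raise ValueError("more planted targets than genes")
        if self.chrom_length % self.bin_size != 0:
            raise ValueError("chrom_length must be a multiple of bin_size")
        if self.hazard_ratio_high_expression <= 0:
            raise ValueError("hazard ratio must be positive")


@dataclass
class GroundTruthManifest:
    """Planted truth written alongside every simulation."""

    gene_classes: dict[str, str] = field(default_factory=dict)
    peak_labels: dict[str, str] = field(default_factory=dict)
    tss_states: dict[str, str] = field(default_factory=dict)
    patients: dict[str, dict] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def genes_in_class(self, klass: str) -> tuple[str, ...]:
        return tuple(g for g, c in self.gene_classes.items() if c == klass)

    def peaks_with_label(self, label: str) -> tuple[str, ...]:
        return tuple(p for p, l in self.peak_labels.items() if l == label)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent substream ``stream`` of the study seed."""
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(stream)]))


def simulate_layout(config: SimulationConfig) -> GenomeLayout:
    return GenomeLayout(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )


def simulate_genes(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Place single-isoform genes on a spaced slot grid and assign classes.

    Returns ``(GeneTable, classes)`` where classes maps gene_id to
    activated/repressed/null.  Raises when the genome cannot hold the
    requested gene count at the required spacing.
    """
    rng = rng if rng is not None else _rng(config, 1)
    per_chrom = -(-config.n_genes // config.n_chroms)
    needed = per_chrom * _GENE_SLOT
    if needed > config.chrom_length:
        raise ValueError(
            f"genes too dense: {per_chrom} genes/chromosome need {needed} bp at "
            f">=250 kb spacing but chrom_length is {config.chrom_length}; "
            "use a larger genome or fewer genes"
        )
    rows = []
    gene_idx = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for slot in range(per_chrom):
            if gene_idx >= config.n_genes:
                break
            center = _GENE_SLOT // 2 + slot * _GENE_SLOT
            tss = int(center + rng.integers(-_TSS_JITTER, _TSS_JITTER + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            length = int(rng.integers(2_000, 20_001))
            if strand == "+":
                start, end = tss, tss + length
            else:
                start, end = tss + 1 - length, tss + 1
            rows.append((f"g{gene_idx:05d}", chrom, start, end, strand, tss))
            gene_idx += 1
    genes = GeneTable(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]))

    ids = genes.df["gene_id"].tolist()
    perm = rng.permutation(len(ids))
    classes = {}
    n_act, n_rep = config.n_activated_targets, config.n_repressed_targets
    for rank, gi in enumerate(perm):
        if rank < n_act:
            classes[ids[gi]] = "activated"
        elif rank < n_act + n_rep:
            classes[ids[gi]] = "repressed"
        else:
            classes[ids[gi]] = "null"
    return genes, classes


def simulate_segmentation(
    config: SimulationConfig,
    genes: GeneTable,
    classes: dict[str, str],
    peaks: PeakSet | None = None,
    peak_labels: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
):
    """Plant a chromatin state segment over every TSS (and some summits).

    Activated-target TSSs fall in the bivalent/Polycomb group (TssBiv or
    ReprPC, equal odds) with probability ``p_bivalent_given_activated``;
    other TSSs with ``p_bivalent_background``.  Non-bivalent TSSs get TssA.
    When peaks are supplied, true-peak summits away from any TSS segment
    additionally get a ReprPC segment with probability
    ``p_reprpc_given_activating_peak`` (activating) or
    ``p_reprpc_background_peak`` (repressive), mimicking the Polycomb
    enrichment of activating binding sites.  The rest of the genome stays
    unannotated.
    """
    rng = rng if rng is not None else _rng(config, 2)
    chroms: dict[str, list] = {}
    tss_states: dict[str, str] = {}
    for rec in genes.df.itertuples(index=False):
        p = (
            config.p_bivalent_given_activated
            if classes[rec.gene_id] == "activated"
            else config.p_bivalent_background
        )
        if rng.random() < p:
            state = "TssBiv" if rng.random() < 0.5 else "ReprPC"
        else:
            state = "TssA"
        tss_states[rec.gene_id] = state
        lo = max(0, rec.tss - _TSS_SEGMENT_HALFWIDTH)
        hi = min(config.chrom_length, rec.tss + _TSS_SEGMENT_HALFWIDTH)
        chroms.setdefault(rec.chrom, []).append((lo, hi, state))
    if peaks is not None and peak_labels is not None:
        halfw = _EFFECT_HALFWIDTH
        for rec in peaks.df.itertuples(index=False):
            label = peak_labels[rec.name]
            if label == "decoy":
                continue
            p = (
                config.p_reprpc_given_activating_peak
                if label == "activating"
                else config.p_reprpc_background_peak
            )
            draw = rng.random() < p  # drawn unconditionally: keeps the stream stable
            lo, hi = rec.summit - halfw, rec.summit + halfw
            existing = chroms.get(rec.chrom, [])
            if draw and all(hi <= s or lo >= e for s, e, _ in existing):
                existing.append((lo, hi, "ReprPC"))
    seg = StateSegmentation(
        {
            chrom: (
                np.array([r[0] for r in rows], np.int64),
                np.array([r[1] for r in rows], np.int64),
                np.array([r[2] for r in rows], object),
            )
            for chrom, rows in chroms.items()
        }
    )
    return seg, tss_states


def _true_peak_scores(rng: np.random.Generator, n: int):
    neg_log10_p = 8.0 + _SCORE_MARGIN + rng.exponential(4.0, n)
    fold = 4.0 + _SCORE_MARGIN + rng.exponential(6.0, n)
    return neg_log10_p, fold


def simulate_peaks(
    config: SimulationConfig,
    genes: GeneTable,
    classes: dict[str, str],
    rng: np.random.Generator | None = None,
):
    """True peaks near target TSSs plus decoys failing the confidence filter.

    Returns ``(PeakSet, labels)`` with labels mapping peak name to
    activating/repressive/decoy.  One true peak per target gene, its summit a
    truncated-normal offset (sd ``peak_window_sd``, clipped to +/-95 kb) from
    the TSS.
    """
    rng = rng if rng is not None else _rng(config, 3)
    gdf = genes.df.set_index("gene_id")
    rows = []
    labels: dict[str, str] = {}

    targets = [(g, "activating") for g in genes.df["gene_id"] if classes[g] == "activated"]
    targets += [(g, "repressive") for g in genes.df["gene_id"] if classes[g] == "repressed"]
    n_true = len(targets)
    p_true, f_true = _true_peak_scores(rng, n_true)
    for i, (gene_id, label) in enumerate(targets):
        tss = int(gdf.at[gene_id, "tss"])
        offset = int(np.clip(round(rng.normal(0.0, config.peak_window_sd)),
                             -_PEAK_MAX_OFFSET, _PEAK_MAX_OFFSET))
        summit = tss + offset
        left = int(rng.integers(150, 401))
        right = int(rng.integers(150, 401))
        name = f"peak_{label[:3]}_{gene_id}"
        rows.append(
            (gdf.at[gene_id, "chrom"], summit - left, summit + right, name, 0, ".",
             f_true[i], p_true[i], p_true[i] - 1.0, left)
        )
        labels[name] = label

    for j in range(config.n_decoy_peaks):
        chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
        summit = int(rng.integers(1_000, config.chrom_length - 1_000))
        left = int(rng.integers(150, 401))
        right = int(rng.integers(150, 401))
        mode = int(rng.integers(3))
        p = (rng.uniform(0.0, 8.0 - _SCORE_MARGIN) if mode in (0, 2)
             else 8.0 + _SCORE_MARGIN + rng.exponential(4.0))
        f = (rng.uniform(0.1, 4.0 - _SCORE_MARGIN) if mode in (1, 2)
             else 4.0 + _SCORE_MARGIN + rng.exponential(6.0))
        name = f"peak_dec_{j:05d}"
        rows.append((chrom, summit - left, summit + right, name, 0, ".", f, p, max(p - 1.0, 0.0), left))
        labels[name] = "decoy"

    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "signal_value", "neg_log10_p", "neg_log10_q", "summit_offset"],
    )
    df["score"] = np.minimum(1000, (10 * df["signal_value"]).astype(int))
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return PeakSet(df), labels


def simulate_expression(
    config: SimulationConfig,
    classes: dict[str, str],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """log2 fold changes: activated ~ N(+3, 0.5) (kept > 2.1), repressed
    ~ N(-3, 0.5) (kept < -2.1), nulls ~ N(0, 0.7) and rarely significant."""
    rng = rng if rng is not None else _rng(config, 4)

    def sample_clear(mean: float, sign: float) -> float:
        while True:
            x = rng.normal(mean, 0.5)
            if sign * x > 2.0 + _LFC_MARGIN:
                return x

    rows = []
    for gene_id, klass in sorted(classes.items()):
        if klass == "activated":
            rows.append((gene_id, sample_clear(3.0, +1.0), True))
        elif klass == "repressed":
            rows.append((gene_id, sample_clear(-3.0, -1.0), True))
        else:
            rows.append((gene_id, rng.normal(0.0, 0.7), bool(rng.random() < 0.05)))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "is_significant"])


_PLANTED_EFFECTS = {
    "h3k4me3": "planted_h3k4me3_log2fc",
    "h3k27me3": "planted_h3k27me3_log2fc",
    "ezh2": "planted_ezh2_log2fc",
}


def simulate_coverage_track(
    config: SimulationConfig,
    layout: GenomeLayout,
    peaks: PeakSet,
    peak_labels: dict[str, str],
    mark: str,
    condition: str,
    rng: np.random.Generator | None = None,
) -> CoverageTrack:
    """One mark/condition coverage track with planted differential effects.

    Background bins ~ Gamma(shape, scale); all true-peak windows (activating
    and repressive) are enriched ``peak_enrichment``-fold with shape
    ``peak_gamma_shape``; activating windows in the overexpression condition
    are additionally multiplied by ``2 ** planted_<mark>_log2fc``.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if rng is None:
        stream = 10 + MARKS.index(mark) * len(CONDITIONS) + CONDITIONS.index(condition)
        rng = _rng(config, stream)
    B = config.bin_size
    bg_mean = config.background_gamma_shape * config.background_gamma_scale
    peak_mean = config.peak_enrichment * bg_mean
    peak_scale = peak_mean / config.peak_gamma_shape
    effect = 2.0 ** getattr(config, _PLANTED_EFFECTS[mark])

    data = {}
    pdf = peaks.df
    for chrom in layout.chrom_names:
        n_bins = layout.length(chrom) // B
        vec = rng.gamma(config.background_gamma_shape, config.background_gamma_scale, n_bins)
        sub = pdf.loc[pdf["chrom"] == chrom]
        for rec in sub.itertuples(index=False):
            label = peak_labels[rec.name]
            if label == "decoy":
                continue
            lo = max(0, (int(rec.summit) - _EFFECT_HALFWIDTH) // B)
            hi = min(n_bins, -(-(int(rec.summit) + _EFFECT_HALFWIDTH) // B))
            window = rng.gamma(config.peak_gamma_shape, peak_scale, hi - lo)
            if label == "activating" and condition == "onecut2":
                window = window * effect
            vec[lo:hi] = window
        data[chrom] = vec
    return CoverageTrack(bin_size=B, data=data)


def simulate_gene_sets(
    config: SimulationConfig,
    classes: dict[str, str],
    rng: np.random.Generator | None = None,
) -> GeneSetCollection:
    """GMT collection whose first set is exactly the planted activated targets."""
    rng = rng if rng is not None else _rng(config, 7)
    all_genes = sorted(classes)
    coll = GeneSetCollection()
    coll.add(
        "PLANTED_ACTIVATED_TARGETS",
        "genes planted as activated targets",
        sorted(g for g, c in classes.items() if c == "activated"),
    )
    coll.add(
        "PLANTED_REPRESSED_TARGETS",
        "genes planted as repressed targets",
        sorted(g for g, c in classes.items() if c == "repressed"),
    )
    size = min(config.random_gene_set_size, max(1, len(all_genes) // 2))
    for i in range(config.n_random_gene_sets):
        members = sorted(rng.choice(len(all_genes), size=size, replace=False).tolist())
        coll.add(f"RANDOM_SET_{i:02d}", "random gene set", [all_genes[j] for j in members])
    return coll


def simulate_cohort(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Synthetic tumor cohort with a context-restricted survival effect.

    Patients carry oncogenic-alteration flags for the ten RTK/RAS/BRAF
    classification genes plus a TP53 loss-of-function flag; expression is
    log-normal; survival is exponential, with the hazard multiplied by
    ``hazard_ratio_high_expression`` only for patients who are RAS-driven AND
    TP53-LOF AND at or above the upper quartile of expression.  Censoring is
    an independent exponential clock calibrated to ``censoring_rate``.

    Returns ``(cohort DataFrame, patient truth dict)``.
    """
    if config.n_patients < 8:
        raise ValueError("n_patients must be at least 8 for quartile stratification")
    rng = rng if rng is not None else _rng(config, 6)
    n = config.n_patients

    u = rng.random(n)
    ras_driven = u < config.frac_ras_driven
    ras_act_only = (~ras_driven) & (u < config.frac_ras_driven + config.frac_ras_activated_only)
    tp53 = rng.random(n) < config.frac_tp53_lof
    expression = np.exp(rng.normal(3.0, 0.8, n))

    flags = {g: np.zeros(n, dtype=int) for g in RAS_ACTIVATED_GENES}
    driver_choice = rng.choice(len(RAS_DRIVER_GENES), size=n, p=[0.60, 0.10, 0.05, 0.05, 0.20])
    other = tuple(g for g in RAS_ACTIVATED_GENES if g not in RAS_DRIVER_GENES)
    other_choice = rng.choice(len(other), size=n)
    for i in np.flatnonzero(ras_driven):
        flags[RAS_DRIVER_GENES[driver_choice[i]]][i] = 1
    for i in np.flatnonzero(ras_act_only):
        flags[other[other_choice[i]]][i] = 1

    q3 = float(np.percentile(expression, 75, method="linear"))
    high = expression >= q3
    affected = ras_driven & tp53 & high
    lam0 = np.log(2.0) / config.median_survival_days
    hazard = np.where(affected, lam0 * config.hazard_ratio_high_expression, lam0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        mu = lam0 * config.censoring_rate / (1.0 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / mu, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    cohort = pd.DataFrame(
        {
            "sample_id": [f"P{i:05d}" for i in range(n)],
            "expression": expression,
            **{g: flags[g] for g in RAS_ACTIVATED_GENES},
            "TP53_LOF": tp53.astype(int),
            "time": np.round(time, 2),
            "event": event,
        }
    )
    truth = {
        cohort["sample_id"].iloc[i]: {
            "ras_driven": bool(ras_driven[i]),
            "ras_activated": bool(ras_driven[i] or ras_act_only[i]),
            "tp53_lof": bool(tp53[i]),
            "stratum": "high" if high[i] else "low",
            "affected": bool(affected[i]),
        }
        for i in range(n)
    }
    return cohort, truth


def simulate_study(config: SimulationConfig, outdir) -> GroundTruthManifest:
    """Run the full generator and write every study file plus the manifest.

    Identical config (including seed) yields byte-identical files.  Files:
    ``genes.gtf``, ``segmentation.bed``, ``peaks.narrowPeak``,
    ``<mark>_<condition>.bedGraph`` for all marks/conditions,
    ``expression.tsv``, ``gene_sets.gmt``, ``cohort.tsv``, ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = simulate_layout(config)
    genes, classes = simulate_genes(config)
    peaks, peak_labels = simulate_peaks(config, genes, classes)
    seg, tss_states = simulate_segmentation(config, genes, classes, peaks, peak_labels)
    expression = simulate_expression(config, classes)
    gene_sets = simulate_gene_sets(config, classes)
    cohort, patient_truth = simulate_cohort(config)

    write_gene_annotation_gtf(genes, outdir / "genes.gtf")
    write_segmentation(seg, outdir / "segmentation.bed")
    write_narrowpeak(peaks, outdir / "peaks.narrowPeak")
    write_expression_table(expression, outdir / "expression.tsv")
    write_gmt(gene_sets, outdir / "gene_sets.gmt")
    write_cohort_table(cohort, outdir / "cohort.tsv")
    for mark in MARKS:
        for condition in CONDITIONS:
            track = simulate_coverage_track(config, layout, peaks, peak_labels, mark, condition)
            write_bedgraph(track, outdir / f"{mark}_{condition}.bedGraph")

    manifest = GroundTruthManifest(
        gene_classes=classes,
        peak_labels=peak_labels,
        tss_states=tss_states,
        patients=patient_truth,
        config=dataclasses.asdict(config),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
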