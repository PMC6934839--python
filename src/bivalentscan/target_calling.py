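"""High-confidence peak filtering, peak-to-gene assignment around TSSs, and
activated/repressed target classification.

A gene is an activated (repressed) target when it has at least one
high-confidence binding peak whose summit lies within a window around its TSS
and its expression change is significant with log2FC above (below) a strict
threshold.  All three thresholds — p-value, fold enrichment, |log2FC| — are
strict inequalities, so boundary values are excluded.  The p-value threshold
is compared in -log10 space to avoid underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GeneTable, PeakSet

__all__ = [
    "filter_high_confidence",
    "assign_peaks_to_genes",
    "classify_targets",
    "label_peaks",
    "distance_distribution",
    "DEFAULT_DISTANCE_EDGES",
]

DEFAULT_DISTANCE_EDGES = (0, 5_000, 50_000, 100_000)


def filter_high_confidence(
    peaks: PeakSet, p_threshold: float = 1e-8, fold_threshold: float = 4.0
) -> PeakSet:
    """Keep peaks with p < p_threshold and fold enrichment > fold_threshold.

    Both inequalities are strict; input order is preserved.  Idempotent, and
    the output is always a subset of the input.
    """
    if p_threshold <= 0 or fold_threshold <= 0:
        raise ValueError("thresholds must be positive")
    neg_log10_p_cut = -math.log10(p_threshold)
    df = peaks.df
    keep = (df["neg_log10_p"] > neg_log10_p_cut) & (df["signal_value"] > fold_threshold)
    return PeakSet(df.loc[keep].reset_index(drop=True))


def assign_peaks_to_genes(
    peaks: PeakSet, genes: GeneTable, window: int = 100_000
) -> pd.DataFrame:
    """Emit every (peak, gene) pair with |summit - tss| <= window.

    ``signed_distance`` is strand-oriented: positive means the summit lies
    downstream of the TSS on the gene's strand.  A peak may pair with several
    genes and vice versa.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    cols = ["peak_id", "gene_id", "signed_distance"]
    if len(peaks) == 0 or len(genes) == 0:
        return pd.DataFrame(columns=cols)

    out = []
    gdf = genes.df
    pdf = peaks.df
    for chrom, grp in gdf.groupby("chrom", sort=True):
        psub = pdf.loc[pdf["chrom"] == chrom]
        if psub.empty:
            continue
        tss = grp["tss"].to_numpy(np.int64)
        order = np.argsort(tss, kind="mergesort")
        tss_sorted = tss[order]
        summits = psub["summit"].to_numpy(np.int64)
        lo = np.searchsorted(tss_sorted, summits - window, side="left")
        hi = np.searchsorted(tss_sorted, summits + window, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        peak_idx = np.repeat(np.arange(len(psub)), counts)
        gene_pos = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        gi = order[gene_pos]
        raw = summits[peak_idx] - tss[gi]
        minus = grp["strand"].to_numpy(object)[gi] == "-"
        signed = np.where(minus, -raw, raw)
        out.append(
            pd.DataFrame(
                {
                    "peak_id": psub["name"].to_numpy(object)[peak_idx],
                    "gene_id": grp["gene_id"].to_numpy(object)[gi],
                    "signed_distance": signed,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def classify_targets(
    assignment: pd.DataFrame,
    expression: pd.DataFrame,
    genes: GeneTable,
    up_lfc: float = 2.0,
    down_lfc: float = -2.0,
) -> pd.DataFrame:
    """Classify every gene as activated / repressed / none.

    activated: >=1 assigned high-confidence peak AND significant AND
    log2fc > up_lfc (strict); repressed symmetric with log2fc < down_lfc.
    Genes missing from the expression table are classed ``none``.

    Returns a frame (gene_id, target_class, peak_ids, min_abs_distance) with
    peak_ids a comma-joined sorted list and min_abs_distance NaN when no peak
    is assigned.
    """
    if up_lfc <= down_lfc:
        raise ValueError("up_lfc must exceed down_lfc")
    expr = expression.set_index("gene_id")
    per_gene = (
        assignment.assign(abs_distance=assignment["signed_distance"].abs())
        .groupby("gene_id")
        .agg(
            peak_ids=("peak_id", lambda s: ",".join(sorted(s))),
            min_abs_distance=("abs_distance", "min"),
        )
        if len(assignment)
        else pd.DataFrame(columns=["peak_ids", "min_abs_distance"])
    )
    rows = []
    for gene_id in genes.df["gene_id"]:
        has_peak = gene_id in per_gene.index
        klass = "none"
        if has_peak and gene_id in expr.index:
            lfc = float(expr.at[gene_id, "log2fc"])
            sig = bool(expr.at[gene_id, "is_significant"])
            if sig and lfc > up_lfc:
                klass = "activated"
            elif sig and lfc < down_lfc:
                klass = "repressed"
        rows.append(
            (
                gene_id,
                klass,
                per_gene.at[gene_id, "peak_ids"] if has_peak else "",
                float(per_gene.at[gene_id, "min_abs_distance"]) if has_peak else math.nan,
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "target_class", "peak_ids", "min_abs_distance"])


def label_peaks(assignment: pd.DataFrame, targets: pd.DataFrame, peaks: PeakSet) -> pd.DataFrame:
    """Label each peak by the classes of its assigned target genes.

    activating: all target-classed assigned genes are activated; repressive:
    all repressed; ambiguous: both present; unassigned: none.
    """
    klass = targets.set_index("gene_id")["target_class"]
    merged = assignment.assign(target_class=assignment["gene_id"].map(klass))
    flags = (
        merged.groupby("peak_id")["target_class"]
        .agg(
            has_act=lambda s: bool((s == "activated").any()),
            has_rep=lambda s: bool((s == "repressed").any()),
        )
        if len(merged)
        else pd.DataFrame(columns=["has_act", "has_rep"])
    )
    labels = []
    for peak_id in peaks.df["name"]:
        if peak_id in flags.index:
            a = bool(flags.at[peak_id, "has_act"])
            r = bool(flags.at[peak_id, "has_rep"])
            if a and r:
                lab = "ambiguous"
            elif a:
                lab = "activating"
            elif r:
                lab = "repressive"
            else:
                lab = "unassigned"
        else:
            lab = "unassigned"
        labels.append((peak_id, lab))
    return pd.DataFrame(labels, columns=["peak_id", "label"])


def distance_distribution(
    assignment: pd.DataFrame, bin_edges=DEFAULT_DISTANCE_EDGES
) -> pd.DataFrame:
    """Histogram of |signed_distance| over all (peak, gene) pairs.

    Bins are half-open ``[lo, hi)`` with the last bin closed ``[lo, hi]``.
    """
    edges = np.asarray(bin_edges, dtype=np.int64)
    if edges[0] != 0 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be ascending and start at 0")
    dist = assignment["signed_distance"].abs().to_numpy(np.int64) if len(assignment) else np.array([], np.int64)
    if len(dist) and dist.max() > edges[-1]:
        raise ValueError(f"distance {dist.max()} beyond last bin edge {edges[-1]}")
    # np.histogram uses half-open bins with a closed last bin, as specified
    counts, _ = np.histogram(dist, bins=edges)
    total = counts.sum()
    fractions = counts / total if total else np.zeros(len(counts))
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": counts,
            "fraction": fractions,
        }
    )
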