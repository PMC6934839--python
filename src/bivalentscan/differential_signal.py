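"""Differential histone-signal tracks: log2 ratios between conditions,
metaprofiles and heatmap matrices around anchors, and signal-loss regions.

Tracks are first scaled to counts-per-million equivalents
(``value * 1e6 / total_signal``) so library size cancels, then combined as
``log2((a' + c) / (b' + c))`` with pseudocount ``c``.  The ratio is therefore
antisymmetric in its two arguments and exactly zero where the inputs agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import CoverageTrack

__all__ = [
    "log2_ratio_track",
    "Metaprofile",
    "metaprofile",
    "AnchorMatrix",
    "anchor_matrix",
    "call_loss_regions",
]


@dataclass
class Metaprofile:
    """Mean log2-ratio signal at offsets around an anchor group."""

    offsets: np.ndarray          # bp, bin centers, symmetric around 0
    mean_log2fc: np.ndarray
    n_anchors: int
    anchor_group: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_log2fc": self.mean_log2fc,
             "anchor_group": self.anchor_group}
        )

    def center_mean(self, half_width: int = 500) -> float:
        """Mean profile value over |offset| <= half_width."""
        sel = np.abs(self.offsets) <= half_width
        return float(self.mean_log2fc[sel].mean())


@dataclass
class AnchorMatrix:
    """Per-anchor log2-ratio rows around anchors (heatmap substrate)."""

    offsets: np.ndarray
    values: np.ndarray           # anchors x offset bins
    anchor_ids: tuple[str, ...]

    def column_means(self) -> np.ndarray:
        return self.values.mean(axis=0)


def log2_ratio_track(
    a: CoverageTrack, b: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-bin log2 ratio of two CPM-scaled raw tracks."""
    if a.is_log2_ratio or b.is_log2_ratio:
        raise ValueError("inputs must be raw coverage tracks")
    if not a.compatible_with(b):
        raise ValueError("tracks have mismatched layout or bin size")
    ta, tb = a.total_signal, b.total_signal
    if ta == 0 or tb == 0:
        raise ValueError("zero total signal")
    sa, sb = 1e6 / ta, 1e6 / tb
    # difference of logs (not log of quotient) keeps antisymmetry bit-exact
    data = {
        chrom: np.log2(a.data[chrom] * sa + pseudocount)
        - np.log2(b.data[chrom] * sb + pseudocount)
        for chrom in a.data
    }
    return CoverageTrack(bin_size=a.bin_size, data=data, is_log2_ratio=True)


def _window_slices(track: CoverageTrack, anchors: pd.DataFrame, flank: int, bin: int):
    """Per-anchor windows of ``2*flank/bin`` track bins, strand-oriented.

    The window covers track bins ``[(pos - flank) // B, ...)``; anchors whose
    window leaves the chromosome are dropped.  Returns (ids, matrix, n_dropped).
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    if bin != track.bin_size:
        raise ValueError("bin must equal the track bin size")
    n_cols = 2 * flank // bin
    rows, ids = [], []
    n_dropped = 0
    for rec in anchors.itertuples(index=False):
        vec = track.data.get(rec.chrom)
        if vec is None:
            raise KeyError(f"unknown chromosome {rec.chrom!r}")
        first = (int(rec.pos) - flank) // bin
        if first < 0 or first + n_cols > len(vec):
            n_dropped += 1
            continue
        window = vec[first : first + n_cols]
        if rec.strand == "-":
            window = window[::-1]
        rows.append(window)
        ids.append(str(rec.anchor_id) if hasattr(rec, "anchor_id") else str(len(ids)))
    return ids, rows, n_dropped


def metaprofile(
    track: CoverageTrack,
    anchors: pd.DataFrame,
    flank: int = 5000,
    bin: int = 50,
    anchor_group: str = "",
) -> Metaprofile:
    """Mean track value over anchors at each strand-oriented offset bin."""
    ids, rows, _ = _window_slices(track, anchors, flank, bin)
    if not rows:
        raise ValueError("no anchors left after edge-dropping")
    mat = np.vstack(rows)
    offsets = np.arange(-flank, flank, bin, dtype=np.int64) + bin // 2
    return Metaprofile(
        offsets=offsets,
        mean_log2fc=mat.mean(axis=0),
        n_anchors=len(rows),
        anchor_group=anchor_group,
    )


def anchor_matrix(
    track: CoverageTrack,
    anchors: pd.DataFrame,
    flank: int = 5000,
    bin: int = 50,
    sort_by: str = "none",
) -> AnchorMatrix:
    """Per-anchor signal matrix around anchors; column means reproduce the
    metaprofile.  ``sort_by='mean'`` orders rows by row mean ascending
    (ties broken by anchor id, so the order is input-order independent)."""
    if sort_by not in ("mean", "none"):
        raise ValueError(f"unknown sort_by {sort_by!r}")
    ids, rows, _ = _window_slices(track, anchors, flank, bin)
    if not rows:
        raise ValueError("no anchors left after edge-dropping")
    mat = np.vstack(rows)
    ids = np.asarray(ids, dtype=object)
    if sort_by == "mean":
        order = np.lexsort((ids, mat.mean(axis=1)))
        mat, ids = mat[order], ids[order]
    offsets = np.arange(-flank, flank, bin, dtype=np.int64) + bin // 2
    return AnchorMatrix(offsets=offsets, values=mat, anchor_ids=tuple(ids))


def call_loss_regions(
    track: CoverageTrack,
    threshold: float = -1.0,
    max_gap: int = 2,
    min_width: int = 500,
) -> pd.DataFrame:
    """Maximal runs of bins at or below ``threshold`` in a log2-ratio track.

    Runs separated by at most ``max_gap`` bins are merged; merged runs
    narrower than ``min_width`` bp are discarded.  Returns a BED-like frame
    (chrom, start, end).
    """
    if not track.is_log2_ratio:
        raise ValueError("loss regions are defined on log2-ratio tracks")
    B = track.bin_size
    regions = []
    for chrom in track.data:
        below = track.data[chrom] <= threshold
        if not below.any():
            continue
        idx = np.flatnonzero(below)
        # split where the gap between consecutive below-threshold bins > max_gap
        breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for s, e in zip(starts, ends):
            lo, hi = int(idx[s]) * B, (int(idx[e]) + 1) * B
            if hi - lo >= min_width:
                regions.append((chrom, lo, hi))
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def interval_jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Jaccard index of two BED-like interval sets (bp overlap / bp union)."""
    def to_events(df):
        ev = {}
        for rec in df.itertuples(index=False):
            ev.setdefault(rec.chrom, []).append((rec.start, rec.end))
        return ev

    ea, eb = to_events(a), to_events(b)
    inter = union = 0
    for chrom in set(ea) | set(eb):
        points = sorted(
            [(s, 0, +1) for s, _ in ea.get(chrom, [])]
            + [(e, 0, -1) for _, e in ea.get(chrom, [])]
            + [(s, 1, +1) for s, _ in eb.get(chrom, [])]
            + [(e, 1, -1) for _, e in eb.get(chrom, [])]
        )
        depth = [0, 0]
        prev = None
        for pos, which, delta in points:
            if prev is not None and pos > prev:
                if depth[0] > 0 and depth[1] > 0:
                    inter += pos - prev
                if depth[0] > 0 or depth[1] > 0:
                    union += pos - prev
            depth[which] += delta
            prev = pos
    return inter / union if union else 0.0
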