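"""Chromatin-state annotation of genomic anchors.

Anchors (gene TSSs, peak summits) are annotated with the ChromHMM-style state
covering the anchor base; per-state fractions and a strand-oriented positional
state-composition profile summarize a group of anchors.  The bivalent/Polycomb
summary fraction pools the bivalent (TssBiv, BivFlnk, EnhBiv) and
Polycomb-repressed (ReprPC, ReprPCWk) states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import StateSegmentation, UNANNOTATED_STATE

__all__ = [
    "DEFAULT_BIVALENT_GROUP",
    "StateFractionTable",
    "PositionalStateProfile",
    "state_at",
    "states_at",
    "state_fractions",
    "positional_state_profile",
]

DEFAULT_BIVALENT_GROUP = ("TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk")


@dataclass
class StateFractionTable:
    """Per-state anchor counts/fractions plus the pooled group fraction."""

    counts: dict[str, int]
    fractions: dict[str, float]
    group_fraction: float
    group_states: tuple[str, ...]
    n_anchors: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": list(self.counts),
                "count": list(self.counts.values()),
                "fraction": [self.fractions[s] for s in self.counts],
            }
        )


@dataclass
class PositionalStateProfile:
    """State-composition fractions at strand-oriented offsets around anchors.

    ``matrix[i, j]`` is the fraction of anchors whose state at
    ``anchor + offsets[i]`` (oriented by anchor strand) is ``states[j]``.
    Every row sums to 1.
    """

    offsets: np.ndarray
    states: tuple[str, ...]
    matrix: np.ndarray
    n_anchors: int
    n_dropped: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, off in enumerate(self.offsets):
            for j, st in enumerate(self.states):
                rows.append((int(off), st, self.matrix[i, j]))
        return pd.DataFrame(rows, columns=["offset", "state", "fraction"])


def state_at(seg: StateSegmentation, chrom: str, pos: int) -> str:
    """State of the unique segment covering ``pos``, or ``Unannotated``."""
    if chrom not in seg.chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    starts, ends, states = seg.chroms[chrom]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos < ends[i]:
        return str(states[i])
    return UNANNOTATED_STATE


def states_at(seg: StateSegmentation, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`state_at` for many positions on one chromosome."""
    if chrom not in seg.chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    starts, ends, states = seg.chroms[chrom]
    positions = np.asarray(positions, dtype=np.int64)
    out = np.full(len(positions), UNANNOTATED_STATE, dtype=object)
    if len(starts):
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = idx >= 0
        covered = np.zeros(len(positions), bool)
        covered[valid] = positions[valid] < ends[idx[valid]]
        out[covered] = states[idx[covered]]
    return out


def _anchor_states(anchors: pd.DataFrame, seg: StateSegmentation, offset: int = 0) -> np.ndarray:
    """States at anchor+offset, orienting the offset by anchor strand."""
    out = np.empty(len(anchors), dtype=object)
    pos = anchors["pos"].to_numpy(np.int64)
    oriented = np.where(anchors["strand"].to_numpy(object) == "-", pos - offset, pos + offset)
    for chrom, grp in anchors.groupby("chrom", sort=False):
        loc = anchors.index.get_indexer(grp.index)
        out[loc] = states_at(seg, str(chrom), oriented[loc])
    return out


def state_fractions(
    anchors: pd.DataFrame,
    seg: StateSegmentation,
    bivalent_group: tuple[str, ...] = DEFAULT_BIVALENT_GROUP,
) -> StateFractionTable:
    """Per-state fractions at the anchor bases of an anchor group.

    ``anchors`` is a frame with columns (chrom, pos, strand).  Fractions,
    including ``Unannotated``, sum to 1; ``group_fraction`` is the summed
    fraction over ``bivalent_group``.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor set")
    anchors = anchors.reset_index(drop=True)
    labels = _anchor_states(anchors, seg)
    order = list(seg.alphabet) + [UNANNOTATED_STATE]
    counts = {st: 0 for st in order}
    for st in labels:
        counts[st] += 1
    n = len(anchors)
    fractions = {st: c / n for st, c in counts.items()}
    group_fraction = float(sum(fractions[s] for s in bivalent_group if s in fractions))
    return StateFractionTable(
        counts=counts,
        fractions=fractions,
        group_fraction=group_fraction,
        group_states=tuple(bivalent_group),
        n_anchors=n,
    )


def positional_state_profile(
    anchors: pd.DataFrame,
    seg: StateSegmentation,
    chrom_lengths: dict[str, int],
    flank: int = 2000,
    bin: int = 50,
) -> PositionalStateProfile:
    """State composition at offsets ``-flank .. +flank`` (step ``bin``).

    Offsets are strand-oriented (negative = upstream for '-' anchors too);
    anchors whose full window leaves the chromosome are dropped and counted
    in ``n_dropped``.  The row at offset 0 reproduces :func:`state_fractions`.
    """
    if flank % bin != 0:
        raise ValueError("flank must be a multiple of bin")
    anchors = anchors.reset_index(drop=True)
    pos = anchors["pos"].to_numpy(np.int64)
    lengths = anchors["chrom"].map(chrom_lengths).to_numpy(np.int64)
    keep = (pos - flank >= 0) & (pos + flank < lengths)
    n_dropped = int((~keep).sum())
    kept = anchors.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("all anchors dropped at chromosome edges")
    offsets = np.arange(-flank, flank + 1, bin, dtype=np.int64)
    order = list(seg.alphabet) + [UNANNOTATED_STATE]
    index = {st: j for j, st in enumerate(order)}
    matrix = np.zeros((len(offsets), len(order)))
    for i, off in enumerate(offsets):
        labels = _anchor_states(kept, seg, offset=int(off))
        for st in labels:
            matrix[i, index[st]] += 1
    matrix /= len(kept)
    return PositionalStateProfile(
        offsets=offsets,
        states=tuple(order),
        matrix=matrix,
        n_anchors=len(kept),
        n_dropped=n_dropped,
    )
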