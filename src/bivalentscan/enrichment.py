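"""Set-overlap and preranked gene-set enrichment statistics.

The overlap test is the upper-tail hypergeometric probability of drawing at
least the observed number of reference-set genes in a query set from a finite
universe, evaluated in log space.  Preranked GSEA uses the classic weighted
Kolmogorov-Smirnov running statistic: walking down a fold-change-ranked gene
list, set members increment the running sum by |score|^p normalized over
member scores and non-members decrement it by 1/(N - Nh); the enrichment
score (ES) is the signed maximal deviation.  Significance comes from a
permutation null of random equal-size member sets, with NES defined as
ES / mean(same-sign |null ES|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "hypergeometric_overlap",
    "rank_by_log2fc",
    "RankedList",
    "gsea_es",
    "gsea_permutation",
    "EnrichmentResult",
    "overlap_table",
]


@dataclass
class RankedList:
    """Gene ids ordered by score descending (ties broken lexicographically)."""

    gene_ids: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in ranked list")
        if not np.isfinite(self.scores).all():
            raise ValueError("non-finite score in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nominal_p: float
    n_permutations: int
    seed: int
    leading_edge: tuple[str, ...]
    no_same_sign_nulls: bool = False


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_overlap(query, reference, universe):
    """Upper-tail overlap test of two gene sets within a universe.

    Returns ``(overlap_count, fold_enrichment, p_value)`` where the p-value is
    ``P(X >= k)`` for hypergeometric X with population |universe|, successes
    |reference| and draws |query|, and fold enrichment is the observed overlap
    fraction over its expectation, ``(k/|query|) / (|reference|/|universe|)``.
    """
    query, reference, universe = set(query), set(reference), set(universe)
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query not contained in universe")
    if not reference <= universe:
        raise ValueError("reference not contained in universe")
    u, r, q = len(universe), len(reference), len(query)
    k = len(query & reference)
    fold = (k / q) / (r / u) if r else 0.0
    # P(X >= k) summed in log space; support is max(0, q+r-u) .. min(q, r)
    js = np.arange(k, min(q, r) + 1)
    js = js[js >= max(0, q + r - u)]
    if len(js) == 0:
        p = 0.0 if k > min(q, r) else 1.0
    else:
        logs = _log_comb(r, js) + _log_comb(u - r, q - js) - _log_comb(u, q)
        m = logs.max()
        p = float(np.exp(m) * np.exp(logs - m).sum())
    return k, fold, min(p, 1.0)


def rank_by_log2fc(expression: pd.DataFrame) -> RankedList:
    """Order genes by log2 fold change descending, ties lexicographic."""
    if expression["gene_id"].duplicated().any():
        dup = expression.loc[expression["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    bad = expression.loc[~np.isfinite(expression["log2fc"]), "gene_id"]
    if len(bad):
        raise ValueError(f"non-finite log2fc for gene {bad.iloc[0]!r}")
    ordered = expression.sort_values(
        ["log2fc", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(
        gene_ids=tuple(ordered["gene_id"]),
        scores=ordered["log2fc"].to_numpy(float),
    )


def _member_mask(ranked: RankedList, gene_set) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in ranked.gene_ids), bool, len(ranked))


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight_exponent: float):
    n = len(scores)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("no gene-set members present in the ranked list")
    if nh == n:
        raise ValueError("gene set covers the whole ranked list")
    weights = np.abs(scores[hit]) ** weight_exponent
    total = weights.sum()
    if total == 0:
        # degenerate all-zero hit scores: fall back to uniform hit weights
        weights = np.ones(nh)
        total = float(nh)
    steps = np.full(n, -1.0 / (n - nh))
    steps[hit] = weights / total
    return np.cumsum(steps)


def gsea_es(ranked: RankedList, gene_set, weight_exponent: float = 1.0):
    """Enrichment score and running sum for one gene set.

    The ES is the running-sum value of maximal absolute deviation from zero,
    keeping its sign.  Ties in |deviation| resolve to the earliest position.
    """
    hit = _member_mask(ranked, gene_set)
    running = _running_sum(ranked.scores, hit, weight_exponent)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def leading_edge_genes(ranked: RankedList, gene_set, weight_exponent: float = 1.0):
    """Members at or before (after, for negative ES) the running-sum extremum."""
    hit = _member_mask(ranked, gene_set)
    running = _running_sum(ranked.scores, hit, weight_exponent)
    i = int(np.argmax(np.abs(running)))
    if running[i] >= 0:
        sel = np.zeros(len(ranked), bool)
        sel[: i + 1] = True
    else:
        sel = np.zeros(len(ranked), bool)
        sel[i:] = True
    return tuple(g for g, h, s in zip(ranked.gene_ids, hit, sel) if h and s)


def _null_es(ranked: RankedList, set_size: int, n_perm: int, weight_exponent: float,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random member sets of a given size.

    For hit positions p_1 < ... < p_k the running sum attains its extrema at
    hit points: just after hit i it equals H_i - (p_i + 1 - i) / (N - k) and
    just before hit i it equals H_{i-1} - (p_i - (i - 1)) / (N - k), where H_i
    is the cumulative normalized hit weight.  The signed maximal |deviation|
    over these candidates is the ES.
    """
    n = len(ranked)
    k = set_size
    absw = np.abs(ranked.scores) ** weight_exponent
    positions = np.empty((n_perm, k), dtype=np.int64)
    for b in range(n_perm):
        positions[b] = rng.choice(n, size=k, replace=False)
    positions.sort(axis=1)
    w = absw[positions]
    totals = w.sum(axis=1, keepdims=True)
    uniform = totals == 0
    if uniform.any():
        w[uniform[:, 0]] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    H = np.cumsum(w, axis=1) / totals
    i = np.arange(1, k + 1)
    after = H - (positions + 1 - i) / (n - k)
    before = np.concatenate([np.zeros((n_perm, 1)), H[:, :-1]], axis=1) - (positions - (i - 1)) / (n - k)
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    out = cand[np.arange(n_perm), idx]
    return out


def gsea_permutation(
    ranked: RankedList,
    gene_set,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """Permutation-null significance for one gene set on a preranked list.

    The null draws random member sets of the same size (standard preranked
    behavior).  ``nominal_p = (1 + #{same-sign nulls with |null| >= |ES|}) /
    (1 + #same-sign nulls)`` and ``NES = ES / mean(same-sign |null ES|)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    es, _ = gsea_es(ranked, gene_set, weight_exponent)
    hit = _member_mask(ranked, gene_set)
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    null = _null_es(ranked, int(hit.sum()), n_perm, weight_exponent, rng)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    no_nulls = n_same == 0
    if no_nulls:
        p = 1.0 / (n_perm + 1)
        nes = np.nan
    else:
        exceed = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + exceed) / (1 + n_same)
        nes = es / float(np.abs(null[same_sign]).mean())
    return EnrichmentResult(
        set_name=set_name,
        es=es,
        nes=float(nes),
        nominal_p=float(p),
        n_permutations=n_perm,
        seed=seed,
        leading_edge=leading_edge_genes(ranked, gene_set, weight_exponent),
        no_same_sign_nulls=no_nulls,
    )


def overlap_table(query, collection, universe, top: int = 10) -> pd.DataFrame:
    """Rank a collection's sets against a query set by hypergeometric p.

    Reproduces a "top N overlapping gene sets" table: ascending p, ties broken
    by larger overlap count, then set name.
    """
    rows = []
    for name in collection.names():
        members = set(collection.members(name)) & set(universe)
        if not members:
            continue
        k, fold, p = hypergeometric_overlap(query, members, universe)
        rows.append((name, len(members), k, fold, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "fold_enrichment", "p_value"])
    df = df.sort_values(
        ["p_value", "overlap", "set_name"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(top)
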