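"""Peak filtering, TSS-window assignment and target classification.

Brute-force all-pairs predicates serve as the oracle for the vectorized
implementations; the synthetic manifest supplies exact planted truth.
"""

import numpy as np
import pandas as pd
import pytest

from bivalentscan import target_calling as tc
from bivalentscan.genomic_io import GeneTable, PeakSet
from bivalentscan.synthetic_data import simulate_expression, simulate_genes, simulate_peaks

from conftest import small_sim_config


PEAK_COLS = ["chrom", "start", "end", "name", "score", "strand",
             "signal_value", "neg_log10_p", "neg_log10_q", "summit_offset"]


def make_peaks(rows):
    """rows: (name, chrom, start, end, summit_offset, neg_log10_p, fold)."""
    return PeakSet(
        pd.DataFrame(
            [
                {
                    "chrom": c, "start": s, "end": e, "name": n, "score": 0,
                    "strand": ".", "signal_value": f, "neg_log10_p": p,
                    "neg_log10_q": p, "summit_offset": o,
                }
                for n, c, s, e, o, p, f in rows
            ],
            columns=PEAK_COLS,
        )
    )


def make_genes(rows):
    """rows: (gene_id, chrom, start, end, strand)."""
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return GeneTable(df)


class TestFilter:
    def test_boundary_values_are_excluded(self):
        peaks = make_peaks([("a", "chr1", 0, 100, 50, 8.0, 5.0),
                            ("b", "chr1", 0, 100, 50, 9.0, 4.0),
                            ("c", "chr1", 0, 100, 50, 8.01, 4.01)])
        kept = tc.filter_high_confidence(peaks)
        assert kept.df["name"].tolist() == ["c"]

    def test_empty_input_allowed(self):
        assert len(tc.filter_high_confidence(make_peaks([]))) == 0

    def test_matches_predicate_scan_and_is_idempotent(self, rng):
        rows = [
            (f"p{i}", "chr1", i * 10, i * 10 + 100, 50,
             float(rng.uniform(0, 16)), float(rng.uniform(0, 8)))
            for i in range(200)
        ]
        peaks = make_peaks(rows)
        kept = tc.filter_high_confidence(peaks)
        expected = [n for n, *_rest, p, f in rows if p > 8.0 and f > 4.0]
        assert kept.df["name"].tolist() == expected
        again = tc.filter_high_confidence(kept)
        assert again.df["name"].tolist() == expected  # idempotent subset


class TestAssignment:
    genes = make_genes([("gP", "chr1", 500_000, 510_000, "+"),
                        ("gM", "chr1", 900_000, 910_000, "-")])

    def test_summit_exactly_at_window_included(self):
        peaks = make_peaks([("p", "chr1", 599_900, 600_100, 100, 9, 5)])  # summit 600000
        pairs = tc.assign_peaks_to_genes(peaks, self.genes, window=100_000)
        assert pairs[["peak_id", "gene_id"]].values.tolist() == [["p", "gP"]]
        assert pairs["signed_distance"].iloc[0] == 100_000

    def test_minus_strand_summit_left_of_tss_is_downstream(self):
        # gM tss = 909_999; summit 500 bp to the left
        peaks = make_peaks([("p", "chr1", 909_399, 909_600, 100, 9, 5)])
        pairs = tc.assign_peaks_to_genes(peaks, self.genes, window=100_000)
        assert pairs["signed_distance"].iloc[0] == 500

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            tc.assign_peaks_to_genes(make_peaks([]), self.genes, window=0)

    def test_matches_all_pairs_scan(self, rng):
        genes = make_genes(
            [(f"g{i}", f"chr{1 + i % 2}", int(p), int(p) + 5_000, "+" if i % 3 else "-")
             for i, p in enumerate(rng.integers(0, 2_000_000, 50))]
        )
        peaks = make_peaks(
            [(f"p{i}", f"chr{1 + i % 2}", int(s), int(s) + 200, 100, 9.0, 5.0)
             for i, s in enumerate(rng.integers(0, 2_000_000, 100))]
        )
        got = tc.assign_peaks_to_genes(peaks, genes, 100_000)
        got_set = set(map(tuple, got.values.tolist()))
        expected = set()
        for pk in peaks.df.itertuples(index=False):
            for g in genes.df.itertuples(index=False):
                if pk.chrom == g.chrom and abs(pk.summit - g.tss) <= 100_000:
                    d = pk.summit - g.tss if g.strand == "+" else g.tss - pk.summit
                    expected.add((pk.name, g.gene_id, d))
        assert got_set == expected


class TestClassification:
    def test_boundary_lfc_and_missing_peak_give_none(self):
        genes = make_genes([("gA", "chr1", 1_000, 2_000, "+"),
                            ("gB", "chr1", 600_000, 601_000, "+")])
        peaks = make_peaks([("p", "chr1", 900, 1_100, 100, 9, 5)])
        assignment = tc.assign_peaks_to_genes(peaks, genes, 100_000)
        expr = pd.DataFrame(
            {"gene_id": ["gA", "gB"], "log2fc": [2.0, 3.0], "is_significant": [True, True]}
        )
        calls = tc.classify_targets(assignment, expr, genes).set_index("gene_id")
        assert calls.at["gA", "target_class"] == "none"  # strict >
        assert calls.at["gB", "target_class"] == "none"  # no peak in window

    def test_up_threshold_must_exceed_down(self):
        with pytest.raises(ValueError):
            tc.classify_targets(pd.DataFrame(columns=["peak_id", "gene_id", "signed_distance"]),
                                pd.DataFrame(columns=["gene_id", "log2fc", "is_significant"]),
                                make_genes([]), up_lfc=1.0, down_lfc=1.0)

    def test_recovers_manifest_exactly_on_synthetic_data(self):
        cfg = small_sim_config(seed=5)
        genes, classes = simulate_genes(cfg)
        peaks, labels = simulate_peaks(cfg, genes, classes)
        expr = simulate_expression(cfg, classes)
        hc = tc.filter_high_confidence(peaks)
        assignment = tc.assign_peaks_to_genes(hc, genes)
        calls = tc.classify_targets(assignment, expr, genes)
        got = dict(zip(calls["gene_id"], calls["target_class"]))
        expected = {g: (c if c != "null" else "none") for g, c in classes.items()}
        assert got == expected
        peak_labels = tc.label_peaks(assignment, calls, hc)
        got_labels = dict(zip(peak_labels["peak_id"], peak_labels["label"]))
        for name, truth in labels.items():
            if truth != "decoy":
                assert got_labels[name] == truth


class TestPeakLabels:
    def test_single_class_and_ambiguous(self):
        assignment = pd.DataFrame(
            {"peak_id": ["p1", "p2", "p2"], "gene_id": ["gA", "gA", "gR"],
             "signed_distance": [0, 0, 0]}
        )
        targets = pd.DataFrame(
            {"gene_id": ["gA", "gR"], "target_class": ["activated", "repressed"],
             "peak_ids": ["p1,p2", "p2"], "min_abs_distance": [0.0, 0.0]}
        )
        peaks = make_peaks([("p1", "chr1", 0, 100, 50, 9, 5),
                            ("p2", "chr1", 200, 300, 50, 9, 5),
                            ("p3", "chr1", 400, 500, 50, 9, 5)])
        labels = tc.label_peaks(assignment, targets, peaks).set_index("peak_id")["label"]
        assert labels["p1"] == "activating"
        assert labels["p2"] == "ambiguous"
        assert labels["p3"] == "unassigned"


class TestDistanceDistribution:
    def test_single_pair_at_zero(self):
        pairs = pd.DataFrame({"peak_id": ["p"], "gene_id": ["g"], "signed_distance": [0]})
        hist = tc.distance_distribution(pairs)
        assert hist["count"].tolist() == [1, 0, 0]

    def test_fractions_sum_to_one_and_match_tally(self, rng):
        d = rng.integers(-100_000, 100_001, 500)
        pairs = pd.DataFrame(
            {"peak_id": [f"p{i}" for i in range(500)], "gene_id": "g", "signed_distance": d}
        )
        hist = tc.distance_distribution(pairs)
        assert hist["fraction"].sum() == pytest.approx(1.0)
        edges = [0, 5_000, 50_000, 100_000]
        absd = np.abs(d)
        tally = [
            ((absd >= edges[i]) & ((absd < edges[i + 1]) if i < 2 else (absd <= edges[3]))).sum()
            for i in range(3)
        ]
        assert hist["count"].tolist() == tally

    def test_distance_beyond_last_edge_rejected(self):
        pairs = pd.DataFrame({"peak_id": ["p"], "gene_id": ["g"], "signed_distance": [200_000]})
        with pytest.raises(ValueError):
            tc.distance_distribution(pairs)


def test_coordinate_mirror_invariance(rng):
    """Reflecting all coordinates through the chromosome end and flipping
    strands leaves target classes and |distances| unchanged."""
    L = 2_000_000
    genes = make_genes(
        [(f"g{i}", "chr1", int(p), int(p) + 4_000, "+" if i % 2 else "-")
         for i, p in enumerate(rng.integers(10_000, L - 10_000, 30))]
    )
    peaks = make_peaks(
        [(f"p{i}", "chr1", int(s), int(s) + 200, 100, float(rng.uniform(5, 15)),
          float(rng.uniform(2, 8)))
         for i, s in enumerate(rng.integers(10_000, L - 10_000, 60))]
    )
    expr = pd.DataFrame(
        {"gene_id": [f"g{i}" for i in range(30)],
         "log2fc": rng.normal(0, 2.5, 30), "is_significant": rng.random(30) < 0.8}
    )

    def mirror_genes(gt):
        df = gt.df.copy()
        start = L - df["end"]
        end = L - df["start"]
        strand = df["strand"].map({"+": "-", "-": "+"})
        out = df.assign(start=start, end=end, strand=strand)
        out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"] - 1)
        return GeneTable(out)

    def mirror_peaks(ps):
        df = ps.df.copy()
        start = L - df["end"]
        end = L - df["start"]
        offset = df["end"] - df["start"] - 1 - df["summit_offset"]
        return PeakSet(df.assign(start=start, end=end, summit_offset=offset)
                       .drop(columns="summit"))

    def run(g, p):
        hc = tc.filter_high_confidence(p)
        a = tc.assign_peaks_to_genes(hc, g)
        calls = tc.classify_targets(a, expr, g)
        return (dict(zip(calls["gene_id"], calls["target_class"])),
                sorted(zip(a["peak_id"], a["gene_id"], np.abs(a["signed_distance"]))))

    classes1, dists1 = run(genes, peaks)
    classes2, dists2 = run(mirror_genes(genes), mirror_peaks(peaks))
    assert classes1 == classes2
    assert dists1 == dists2
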