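"""Readers/writers: coordinate conventions, round trips, binning oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bivalentscan import genomic_io as gio


# ---------------------------------------------------------------------- genes


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGeneAnnotation:
    def test_empty_file_gives_empty_table(self, tmp_path):
        p = write(tmp_path, "empty.gtf", "")
        assert len(gio.read_gene_annotation(p)) == 0

    def test_minus_strand_tss_is_last_covered_base(self, tmp_path):
        # gene on [100, 500) in BED coordinates = GTF 101..500
        p = write(tmp_path, "g.gtf", 'chr1\tx\tgene\t101\t500\t.\t-\t.\tgene_id "g1";\n')
        table = gio.read_gene_annotation(p)
        assert table.df.loc[0, ["start", "end", "tss"]].tolist() == [100, 500, 499]

    def test_multi_transcript_tss_is_five_prime_most(self, tmp_path):
        # hand-computed: gA '+': transcripts start at GTF 1001/1201 -> tss 1000
        #                gB '-': transcripts end at 5000/5400      -> tss 5399
        #                gC '+': single transcript at 9001         -> tss 9000
        rows = [
            'chr1\tx\tgene\t1001\t2000\t.\t+\t.\tgene_id "gA";',
            'chr1\tx\ttranscript\t1201\t2000\t.\t+\t.\tgene_id "gA";',
            'chr1\tx\ttranscript\t1001\t1800\t.\t+\t.\tgene_id "gA";',
            'chr1\tx\tgene\t4001\t5400\t.\t-\t.\tgene_id "gB";',
            'chr1\tx\ttranscript\t4001\t5000\t.\t-\t.\tgene_id "gB";',
            'chr1\tx\ttranscript\t4201\t5400\t.\t-\t.\tgene_id "gB";',
            'chr2\tx\tgene\t9001\t9500\t.\t+\t.\tgene_id "gC";',
            'chr2\tx\ttranscript\t9001\t9500\t.\t+\t.\tgene_id "gC";',
        ]
        table = gio.read_gene_annotation(write(tmp_path, "m.gtf", "\n".join(rows) + "\n"))
        tss = table.df.set_index("gene_id")["tss"]
        assert tss["gA"] == 1000
        assert tss["gB"] == 5399
        assert tss["gC"] == 9000

    def test_conflicting_strand_is_hard_error(self, tmp_path):
        rows = [
            'chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "g";',
            'chr1\tx\ttranscript\t1\t100\t.\t-\t.\tgene_id "g";',
        ]
        with pytest.raises(ValueError, match="strand"):
            gio.read_gene_annotation(write(tmp_path, "c.gtf", "\n".join(rows) + "\n"))

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = write(tmp_path, "bad.gtf", 'chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "a";\nchr1\tonly_two\n')
        with pytest.raises(gio.FormatError, match="line 2"):
            gio.read_gene_annotation(p)

    def test_gtf_round_trip_is_byte_identical(self, tmp_path, small_study):
        outdir, _ = small_study
        table = gio.read_gene_annotation(outdir / "genes.gtf")
        again = tmp_path / "again.gtf"
        gio.write_gene_annotation_gtf(table, again)
        assert (outdir / "genes.gtf").read_bytes() == again.read_bytes()

    def test_bed6_reader(self, tmp_path):
        p = write(tmp_path, "g.bed", "chr1\t100\t500\tgM\t0\t-\nchr1\t900\t1200\tgP\t0\t+\n")
        tss = gio.read_gene_annotation(p, format="bed").df.set_index("gene_id")["tss"]
        assert tss["gM"] == 499 and tss["gP"] == 900

    def test_one_based_closed_conversion_is_involutive(self, tmp_path):
        p = write(tmp_path, "g.gtf", 'chr1\tx\tgene\t101\t500\t.\t+\t.\tgene_id "g1";\n')
        rec = gio.read_gene_annotation(p).df.iloc[0]
        # back to 1-based closed and forward again
        assert (rec.start + 1) - 1 == rec.start and rec.end == rec.end


# ----------------------------------------------------------------- narrowPeak


class TestNarrowPeak:
    def test_field_mapping(self, tmp_path):
        p = write(tmp_path, "p.narrowPeak", "chr1\t100\t200\t.\t0\t.\t12.0\t9.5\t8.1\t50\n")
        peak = gio.read_narrowpeak(p).df.iloc[0]
        assert peak.summit == 150
        assert peak.neg_log10_p == 9.5
        assert peak.signal_value == 12.0

    def test_missing_summit_falls_back_to_midpoint(self, tmp_path):
        p = write(tmp_path, "p.narrowPeak", "chr1\t100\t201\tpk\t0\t.\t5\t9\t8\t-1\n")
        assert gio.read_narrowpeak(p).df.loc[0, "summit"] == 100 + 101 // 2

    def test_round_trip_is_byte_identical(self, tmp_path, rng):
        n = 10
        start = rng.integers(0, 10_000, n)
        length = rng.integers(200, 800, n)
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": start,
                "end": start + length,
                "name": [f"pk{i}" for i in range(n)],
                "score": rng.integers(0, 1000, n),
                "strand": ["."] * n,
                "signal_value": np.round(rng.uniform(0, 30, n), 3),
                "neg_log10_p": np.round(rng.uniform(0, 20, n), 3),
                "neg_log10_q": np.round(rng.uniform(0, 20, n), 3),
                "summit_offset": rng.integers(0, 200, n),
            }
        )
        f1 = tmp_path / "a.narrowPeak"
        f2 = tmp_path / "b.narrowPeak"
        gio.write_narrowpeak(gio.PeakSet(df), f1)
        gio.write_narrowpeak(gio.read_narrowpeak(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    @pytest.mark.parametrize(
        "row", ["chr1\t200\t200\tpk\t0\t.\t5\t9\t8\t0", "chr1\t100\t200\tpk\t0\t.\t5\t9\t8\t100"]
    )
    def test_degenerate_interval_or_offset_rejected(self, tmp_path, row):
        with pytest.raises(ValueError):
            gio.read_narrowpeak(write(tmp_path, "bad.narrowPeak", row + "\n"))


# --------------------------------------------------------------- segmentation


class TestSegmentation:
    def test_abutting_segments_accepted_and_sorted(self, tmp_path):
        p = write(tmp_path, "s.bed", "chr1\t100\t200\tReprPC\nchr1\t0\t100\tTssA\n")
        seg = gio.read_segmentation(p)
        starts, ends, states = seg.chroms["chr1"]
        assert starts.tolist() == [0, 100] and states.tolist() == ["TssA", "ReprPC"]

    def test_overlap_rejected(self, tmp_path):
        p = write(tmp_path, "s.bed", "chr1\t0\t100\tTssA\nchr1\t50\t150\tReprPC\n")
        with pytest.raises(ValueError, match="overlap"):
            gio.read_segmentation(p)

    def test_unknown_state_named_in_error(self, tmp_path):
        p = write(tmp_path, "s.bed", "chr1\t0\t100\tNotAState\n")
        with pytest.raises(ValueError, match="NotAState"):
            gio.read_segmentation(p)

    def test_round_trip(self, tmp_path, small_study):
        outdir, _ = small_study
        seg = gio.read_segmentation(outdir / "segmentation.bed")
        again = tmp_path / "seg.bed"
        gio.write_segmentation(seg, again)
        assert (outdir / "segmentation.bed").read_bytes() == again.read_bytes()


# ------------------------------------------------------------------- bedGraph


class TestBedGraph:
    layout = gio.GenomeLayout({"chr1": 1_000, "chr2": 500})

    def test_constant_value_fills_every_bin(self, tmp_path):
        p = write(tmp_path, "c.bedGraph", "chr1\t0\t1000\t3.5\nchr2\t0\t500\t3.5\n")
        track = gio.read_bedgraph(p, self.layout, 50)
        for vec in track.data.values():
            assert np.allclose(vec, 3.5)

    def test_partial_bin_is_length_weighted(self, tmp_path):
        p = write(tmp_path, "p.bedGraph", "chr1\t0\t75\t4\n")
        track = gio.read_bedgraph(p, self.layout, 50)
        assert track.data["chr1"][0] == pytest.approx(4.0)
        assert track.data["chr1"][1] == pytest.approx(2.0)  # (25*4 + 25*0)/50

    def test_random_intervals_match_per_base_expansion(self, tmp_path, rng):
        lines = []
        base = np.zeros(1_000)
        for _ in range(500):
            s = int(rng.integers(0, 990))
            e = int(rng.integers(s + 1, min(s + 120, 1_000) + 1))
            v = float(np.round(rng.uniform(0, 5), 3))
            lines.append(f"chr1\t{s}\t{e}\t{v}")
            base[s:e] += v  # overlapping intervals add, as does binning
        p = write(tmp_path, "r.bedGraph", "\n".join(lines) + "\n")
        track = gio.read_bedgraph(p, self.layout, 50)
        expected = base.reshape(-1, 50).sum(axis=1) / 50
        assert np.allclose(track.data["chr1"], expected, atol=1e-9)

    def test_mass_conservation(self, tmp_path, rng):
        lines, mass = [], 0.0
        for _ in range(200):
            s = int(rng.integers(0, 900))
            e = int(rng.integers(s + 1, 1_000))
            v = float(rng.uniform(0, 2))
            lines.append(f"chr1\t{s}\t{e}\t{v!r}")
            mass += v * (e - s)
        p = write(tmp_path, "m.bedGraph", "\n".join(lines) + "\n")
        track = gio.read_bedgraph(p, self.layout, 50)
        assert track.data["chr1"].sum() * 50 == pytest.approx(mass, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        intervals=st.lists(
            st.tuples(st.integers(0, 990), st.integers(1, 120),
                      st.floats(0, 100, allow_nan=False)),
            min_size=1, max_size=40,
        ),
        bin_size=st.sampled_from([10, 50, 64, 100]),
    )
    def test_mass_conservation_property(self, intervals, bin_size):
        """sum(bins)*bin_size equals sum(value*length) for any interval set."""
        import io as _io

        lines, mass = [], 0.0
        for s, length, v in intervals:
            e = min(s + length, 1_000)
            lines.append(f"chr1\t{s}\t{e}\t{v!r}")
            mass += v * (e - s)
        buf = _io.StringIO("\n".join(lines) + "\n")
        track = gio.read_bedgraph(buf, self.layout, bin_size)
        total = sum(vec.sum() for vec in track.data.values()) * bin_size
        assert total == pytest.approx(mass, rel=1e-9, abs=1e-9)

    def test_interval_beyond_chromosome_rejected(self, tmp_path):
        p = write(tmp_path, "x.bedGraph", "chr2\t400\t600\t1\n")
        with pytest.raises(ValueError, match="beyond"):
            gio.read_bedgraph(p, self.layout, 50)

    def test_write_read_round_trip_values(self, tmp_path, rng):
        track = gio.CoverageTrack(50, {"chr1": np.round(rng.uniform(0, 9, 20), 4),
                                       "chr2": np.round(rng.uniform(0, 9, 10), 4)})
        p = tmp_path / "t.bedGraph"
        gio.write_bedgraph(track, p)
        back = gio.read_bedgraph(p, self.layout, 50)
        assert np.allclose(back.data["chr1"], track.data["chr1"])


# ------------------------------------------------------------------------ GMT


class TestGmt:
    def test_duplicate_members_deduplicated(self, tmp_path):
        coll = gio.read_gmt(write(tmp_path, "s.gmt", "S1\tdesc\tA\tB\tA\n"))
        assert coll.members("S1") == ("A", "B")

    def test_empty_member_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            gio.read_gmt(write(tmp_path, "e.gmt", "S1\tdesc\n"))

    def test_duplicate_set_name_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_gmt(write(tmp_path, "d.gmt", "S1\td\tA\nS1\td\tB\n"))

    def test_five_set_round_trip(self, tmp_path, rng):
        coll = gio.GeneSetCollection()
        for i in range(5):
            coll.add(f"S{i}", f"set {i}", [f"g{j}" for j in rng.integers(0, 99, 10)])
        f1, f2 = tmp_path / "a.gmt", tmp_path / "b.gmt"
        gio.write_gmt(coll, f1)
        gio.write_gmt(gio.read_gmt(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()


# --------------------------------------------------------------------- tables


def test_expression_and_cohort_round_trip(tmp_path, small_study):
    outdir, _ = small_study
    expr = gio.read_expression_table(outdir / "expression.tsv")
    assert expr["gene_id"].is_unique and expr["is_significant"].dtype == bool
    p = tmp_path / "expr.tsv"
    gio.write_expression_table(expr, p)
    pd.testing.assert_frame_equal(gio.read_expression_table(p), expr)

    cohort = gio.read_cohort_table(outdir / "cohort.tsv")
    assert {"sample_id", "expression", "time", "event"} <= set(cohort.columns)
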