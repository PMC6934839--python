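"""Domain types and readers/writers for the genomic file formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) internally.  GTF input
(1-based closed) is converted on read.  The transcription start site (TSS) of a
'-'-strand gene is ``end - 1``, the last covered base, so the TSS always lies
inside the gene interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "GeneTable",
    "PeakSet",
    "StateSegmentation",
    "CoverageTrack",
    "GeneSetCollection",
    "ROADMAP_15_STATES",
    "UNANNOTATED_STATE",
    "read_gene_annotation",
    "write_gene_annotation_gtf",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_segmentation",
    "write_segmentation",
    "read_bedgraph",
    "write_bedgraph",
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "read_cohort_table",
    "write_cohort_table",
]

#: Roadmap Epigenomics 15-state ChromHMM mnemonics (A549 segmentation dialect).
ROADMAP_15_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: Label used for genome positions not covered by any segment.
UNANNOTATED_STATE = "Unannotated"


class FormatError(ValueError):
    """A malformed record in an input file (message carries the line number)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths in base pairs."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("layout needs at least one chromosome")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.length(chrom) // bin_size)


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


@dataclass
class GeneTable:
    """Strand-aware gene records with one derived TSS per gene.

    Backed by a DataFrame with columns ``gene_id, chrom, start, end, strand,
    tss``, sorted by (chrom, start).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in GENE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"GeneTable missing columns: {missing}")
        df = self.df.loc[:, GENE_COLUMNS]
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        if len(df):
            if not (df["start"] < df["end"]).all():
                raise ValueError("gene with start >= end")
            bad = ~df["strand"].isin(["+", "-"])
            if bad.any():
                raise ValueError(f"bad strand {df.loc[bad, 'strand'].iloc[0]!r}")
            plus = df["strand"] == "+"
            expected = np.where(plus, df["start"], df["end"] - 1)
            if not (df["tss"].to_numpy() == expected).all():
                raise ValueError("tss inconsistent with strand convention")
        self.df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def tss_anchors(self) -> pd.DataFrame:
        """Anchor frame (gene_id, chrom, pos, strand) at each TSS."""
        return pd.DataFrame(
            {
                "anchor_id": self.df["gene_id"],
                "chrom": self.df["chrom"],
                "pos": self.df["tss"],
                "strand": self.df["strand"],
            }
        )


NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal_value", "neg_log10_p", "neg_log10_q", "summit_offset",
]


@dataclass
class PeakSet:
    """Scored binding intervals in ENCODE narrowPeak semantics.

    ``summit`` is an absolute coordinate derived from the summit offset;
    an offset of -1 (summit not called) falls back to the interval midpoint.
    ``fold_enrichment`` aliases the narrowPeak signalValue column.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in NARROWPEAK_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"PeakSet missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if len(df):
            if not (df["start"] < df["end"]).all():
                i = int((~(df["start"] < df["end"])).idxmax())
                raise ValueError(f"peak {df['name'].iloc[i]!r}: end <= start")
            if not (df["summit_offset"] < df["end"] - df["start"]).all():
                raise ValueError("summit offset beyond peak interval")
            if (df["summit_offset"] < -1).any():
                raise ValueError("summit offset < -1")
            if (df["neg_log10_p"] < 0).any():
                raise ValueError("negative -log10 p-value")
            if (df["signal_value"] < 0).any():
                raise ValueError("negative fold enrichment")
        fallback = df["start"] + (df["end"] - df["start"]) // 2
        summit = np.where(df["summit_offset"] >= 0, df["start"] + df["summit_offset"], fallback)
        df = df.assign(summit=summit.astype(np.int64) if len(df) else summit)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def fold_enrichment(self) -> pd.Series:
        return self.df["signal_value"]

    def summit_anchors(self) -> pd.DataFrame:
        """Anchor frame at peak summits (summits carry no strand)."""
        return pd.DataFrame(
            {
                "anchor_id": self.df["name"],
                "chrom": self.df["chrom"],
                "pos": self.df["summit"],
                "strand": ".",
            }
        )


@dataclass
class StateSegmentation:
    """Non-overlapping labeled partition of the genome (ChromHMM dialect).

    Per chromosome, sorted parallel arrays of starts, ends and state labels.
    Gaps are permitted and read back as :data:`UNANNOTATED_STATE`.
    """

    chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    alphabet: tuple[str, ...] = ROADMAP_15_STATES

    def __post_init__(self) -> None:
        for chrom, (starts, ends, states) in self.chroms.items():
            if not (len(starts) == len(ends) == len(states)):
                raise ValueError(f"{chrom}: ragged segment arrays")
            if len(starts) == 0:
                continue
            if not (starts < ends).all():
                raise ValueError(f"{chrom}: segment with start >= end")
            order = np.argsort(starts, kind="mergesort")
            starts, ends, states = starts[order], ends[order], states[order]
            if (starts[1:] < ends[:-1]).any():
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValueError(
                    f"{chrom}: overlapping segments at "
                    f"[{starts[i]},{ends[i]}) and [{starts[i + 1]},{ends[i + 1]})"
                )
            unknown = set(states) - set(self.alphabet)
            if unknown:
                raise ValueError(f"unknown state label {sorted(unknown)[0]!r}")
            self.chroms[chrom] = (starts, ends, states)

    def states_present(self) -> set[str]:
        out: set[str] = set()
        for _, _, states in self.chroms.values():
            out.update(states.tolist())
        return out


@dataclass
class CoverageTrack:
    """Fixed-bin per-chromosome signal vectors.

    Raw tracks are non-negative; log2-ratio tracks are flagged with
    ``is_log2_ratio`` and exempt from the non-negativity invariant.
    """

    bin_size: int
    data: dict[str, np.ndarray]
    is_log2_ratio: bool = False

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.is_log2_ratio:
            for chrom, vec in self.data.items():
                if (vec < 0).any():
                    raise ValueError(f"{chrom}: negative signal in raw track")

    @property
    def total_signal(self) -> float:
        return float(sum(vec.sum() for vec in self.data.values()))

    def compatible_with(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.data) == set(other.data)
            and all(len(self.data[c]) == len(other.data[c]) for c in self.data)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def add(self, name: str, description: str, members) -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        deduped = tuple(dict.fromkeys(members))
        if not deduped:
            raise ValueError(f"gene set {name!r} has no members")
        self.sets[name] = (description, deduped)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# gene annotation


def _parse_gtf_attributes(attrs: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise FormatError(f"line {lineno}: malformed GTF attribute {chunk!r}") from None
        out[key] = value.strip().strip('"')
    return out


def read_gene_annotation(path, format: str = "gtf") -> GeneTable:
    """Read a gene annotation as a :class:`GeneTable`.

    GTF (Ensembl dialect, 1-based closed, converted on read): rows with
    feature ``gene`` or ``transcript`` are used; for multi-transcript genes
    the TSS is the 5'-most transcript start on the gene's strand.  BED6:
    one gene per row, name column is the gene_id.
    """
    if format == "bed":
        return _read_genes_bed6(path)
    if format != "gtf":
        raise ValueError(f"unknown annotation format {format!r}")

    # per-gene accumulation: span, strand, candidate 5' transcript boundaries
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"line {lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature not in ("gene", "transcript"):
                continue
            try:
                start = int(start_s) - 1  # 1-based closed -> 0-based half-open
                end = int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"line {lineno}: start >= end after conversion")
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: bad strand {strand!r}")
            gene_id = _parse_gtf_attributes(attrs, lineno).get("gene_id")
            if gene_id is None:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            rec = genes.setdefault(
                gene_id,
                {"chrom": chrom, "strand": strand, "start": start, "end": end, "tx5": []},
            )
            if rec["strand"] != strand:
                raise ValueError(f"gene {gene_id!r}: conflicting strand annotations")
            if rec["chrom"] != chrom:
                raise ValueError(f"gene {gene_id!r}: conflicting chromosomes")
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)
            if feature == "transcript":
                rec["tx5"].append(start if strand == "+" else end - 1)

    rows = []
    for gene_id, rec in genes.items():
        if rec["tx5"]:
            tss = min(rec["tx5"]) if rec["strand"] == "+" else max(rec["tx5"])
        else:
            tss = rec["start"] if rec["strand"] == "+" else rec["end"] - 1
        rows.append((gene_id, rec["chrom"], rec["start"], rec["end"], rec["strand"], tss))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return GeneTable(df)


def _read_genes_bed6(path) -> GeneTable:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str, "gene_id": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    if df["strand"].isna().any():
        raise FormatError("BED6 row with fewer than 6 columns")
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = df.assign(tss=tss)[GENE_COLUMNS] if len(df) else pd.DataFrame(columns=GENE_COLUMNS)
    return GeneTable(out)


def write_gene_annotation_gtf(genes: GeneTable, path) -> None:
    """Write a single-isoform Ensembl-dialect GTF (gene + transcript rows)."""
    with open(path, "w") as fh:
        for rec in genes.df.itertuples(index=False):
            attrs = f'gene_id "{rec.gene_id}"; transcript_id "{rec.gene_id}.t1";'
            for feature in ("gene", "transcript"):
                fh.write(
                    f"{rec.chrom}\tbivalentscan\t{feature}\t{rec.start + 1}\t{rec.end}"
                    f"\t.\t{rec.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# narrowPeak


def _fmt_float(x: float) -> str:
    return format(float(x), "g")


def read_narrowpeak(path) -> PeakSet:
    """Read ENCODE narrowPeak (BED6+4)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=NARROWPEAK_COLUMNS,
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=NARROWPEAK_COLUMNS)
    return PeakSet(df)


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for rec in peaks.df.itertuples(index=False):
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{int(rec.score)}"
                f"\t{rec.strand}\t{_fmt_float(rec.signal_value)}\t{_fmt_float(rec.neg_log10_p)}"
                f"\t{_fmt_float(rec.neg_log10_q)}\t{int(rec.summit_offset)}\n"
            )


# ---------------------------------------------------------------------------
# segmentation (4-column BED)


def read_segmentation(path, alphabet: tuple[str, ...] = ROADMAP_15_STATES) -> StateSegmentation:
    """Read a ChromHMM-style 4-column BED segmentation."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "state"],
            dtype={"chrom": str, "state": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "state"])
    chroms = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        chroms[str(chrom)] = (
            grp["start"].to_numpy(np.int64),
            grp["end"].to_numpy(np.int64),
            grp["state"].to_numpy(object),
        )
    return StateSegmentation(chroms, alphabet=tuple(alphabet))


def write_segmentation(seg: StateSegmentation, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(seg.chroms):
            starts, ends, states = seg.chroms[chrom]
            for s, e, st in zip(starts, ends, states):
                fh.write(f"{chrom}\t{s}\t{e}\t{st}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, layout: GenomeLayout, bin_size: int) -> CoverageTrack:
    """Bin a 4-column bedGraph onto a fixed grid.

    Each output bin is the length-weighted mean of overlapping intervals with
    uncovered bases contributing zero; every bin is averaged over a full
    ``bin_size`` denominator so mass is conserved:
    ``sum(bins) * bin_size == sum(value * length)``.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"], dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    data = {c: np.zeros(layout.n_bins(c, bin_size)) for c in layout.chrom_names}
    for chrom, grp in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in data:
            raise ValueError(f"bedGraph chromosome {chrom!r} not in layout")
        L = layout.length(chrom)
        starts = grp["start"].to_numpy(np.int64)
        ends = grp["end"].to_numpy(np.int64)
        values = grp["value"].to_numpy(float)
        if (starts >= ends).any():
            raise ValueError(f"{chrom}: bedGraph interval with start >= end")
        if (starts < 0).any() or (ends > L).any():
            raise ValueError(f"{chrom}: bedGraph interval beyond chromosome length {L}")
        if (values < 0).any():
            raise ValueError(f"{chrom}: negative value in bedGraph")
        mass = _bin_interval_mass(starts, ends, values, len(data[chrom]), bin_size)
        # the difference-array pass can leave -1e-16-scale residue on exact zeros
        np.clip(mass, 0.0, None, out=mass)
        data[chrom] = mass / bin_size
    return CoverageTrack(bin_size=bin_size, data=data)


def _bin_interval_mass(starts, ends, values, n_bins: int, B: int) -> np.ndarray:
    """Distribute value*length mass of intervals onto bins (vectorized)."""
    mass = np.zeros(n_bins)
    b0 = starts // B
    b1 = (ends - 1) // B
    single = b0 == b1
    np.add.at(mass, b0[single], values[single] * (ends[single] - starts[single]))
    multi = ~single
    if multi.any():
        s, e, v = starts[multi], ends[multi], values[multi]
        mb0, mb1 = b0[multi], b1[multi]
        np.add.at(mass, mb0, v * ((mb0 + 1) * B - s))      # leading partial bin
        np.add.at(mass, mb1, v * (e - mb1 * B))            # trailing partial bin
        # full interior bins via difference-array trick
        diff = np.zeros(n_bins + 1)
        has_mid = mb1 > mb0 + 1
        if has_mid.any():
            np.add.at(diff, mb0[has_mid] + 1, v[has_mid] * B)
            np.add.at(diff, mb1[has_mid], -v[has_mid] * B)
            mass += np.cumsum(diff[:-1])
    return mass


def write_bedgraph(track: CoverageTrack, path, precision: int = 4) -> None:
    """Write one bedGraph line per bin (trailing bins clipped to nothing here:
    tracks are expected to tile chromosomes whose length is a bin multiple)."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        for chrom, vec in track.data.items():
            n = len(vec)
            frame = pd.DataFrame(
                {
                    "chrom": np.repeat(chrom, n),
                    "start": np.arange(n, dtype=np.int64) * track.bin_size,
                    "end": (np.arange(n, dtype=np.int64) + 1) * track.bin_size,
                    "value": vec,
                }
            )
            frame.to_csv(fh, sep="\t", header=False, index=False, float_format=fmt)


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> GeneSetCollection:
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line needs name, description, members")
            coll.add(fields[0], fields[1], fields[2:])
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# expression / cohort tables (TSV with header)


def read_expression_table(path) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2fc, is_significant."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "log2fc", "is_significant"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r} in expression table")
    df["is_significant"] = df["is_significant"].astype(bool)
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["is_significant"] = out["is_significant"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "expression", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
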