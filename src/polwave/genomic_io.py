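"""Genomic coordinate plumbing and file formats shared by every stage.

Conventions used throughout the package:

* all intervals are 0-based, half-open ``[start, end)``;
* bedGraph (4 columns, one file per strand) is the canonical coverage format;
* BED6 for mappability masks, BED12 or refFlat for gene models;
* offsets such as "+1 kb from the TSS" are *transcription-direction*
  coordinates with the TSS at 0, growing toward the polyA site regardless of
  genomic strand.

Coverage is stored as run-length arrays (start, end, value) exactly as it
appears in a bedGraph file, so write-then-read round-trips are lossless and
region sums are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "MappabilityMask",
    "AnnotationError",
    "load_gene_annotation",
    "bin_signal",
    "spike_normalize",
    "read_spike_table",
]


class AnnotationError(ValueError):
    """Raised when an annotation row cannot be turned into a gene model."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with TSS/polyA ends and exon structure.

    ``tss`` equals ``interval.start`` on + and ``interval.end`` on -; exons
    are kept sorted 5'->3' in transcription direction.  Transcription-
    direction offsets are converted with :meth:`tx_to_genomic`.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: gene must be stranded")
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise AnnotationError(
                    f"{self.gene_id}: exon {ex.start}-{ex.end} outside gene bounds"
                )
        # store in transcription direction
        self.exons = sorted(self.exons, key=lambda e: e.start,
                            reverse=self.strand == "-")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def polya_end(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def introns(self) -> list[GenomicInterval]:
        """Introns in transcription order (between consecutive exons)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                lo, hi = a.end, b.start
            else:
                lo, hi = b.end, a.start
            if hi > lo:
                out.append(GenomicInterval(self.chrom, lo, hi, self.strand))
        return out

    @property
    def intron1_length(self) -> int:
        intr = self.introns
        return len(intr[0]) if intr else 0

    # -- transcription-direction coordinates -------------------------------
    def tx_to_genomic(self, offset: float) -> int:
        if self.strand == "+":
            return int(self.tss + offset)
        return int(self.tss - offset)

    def genomic_to_tx(self, pos: float) -> int:
        if self.strand == "+":
            return int(pos - self.tss)
        return int(self.tss - pos)

    def tx_region(self, start_off: int, end_off: int) -> GenomicInterval:
        """Genomic interval for tx-direction offsets [start_off, end_off)."""
        if end_off <= start_off:
            raise ValueError("empty transcription-direction region")
        a = self.tx_to_genomic(start_off)
        b = self.tx_to_genomic(end_off)
        lo, hi = (a, b) if a < b else (b, a)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


class SignalTrack:
    """Strand-specific read counts over one chromosome.

    Counts are stored as non-overlapping sorted runs (bedGraph semantics:
    ``value`` is reads *per bp* times 1, i.e. the per-bp count over the run).
    ``scale`` is the spike-in normalization factor; raw counts stay intact so
    Fisher tests can use them.
    """

    def __init__(self, chrom: str, strand: str, starts=None, ends=None,
                 values=None, scale: float = 1.0):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.chrom = chrom
        self.strand = strand
        self.starts = np.asarray(starts if starts is not None else [], dtype=np.int64)
        self.ends = np.asarray(ends if ends is not None else [], dtype=np.int64)
        self.values = np.asarray(values if values is not None else [], dtype=float)
        self.scale = float(scale)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("run arrays must have equal length")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")
        if len(self.starts) > 1 and np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("runs must be sorted and non-overlapping")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_positions(cls, chrom, strand, positions, counts, width: int = 1,
                       scale: float = 1.0) -> "SignalTrack":
        """Build from per-position counts (each covering ``width`` bp)."""
        positions = np.asarray(positions, dtype=np.int64)
        counts = np.asarray(counts, dtype=float)
        keep = counts != 0
        positions, counts = positions[keep], counts[keep]
        order = np.argsort(positions)
        positions, counts = positions[order], counts[order]
        # per-bp value: counts spread uniformly over the width
        return cls(chrom, strand, positions, positions + width,
                   counts / width, scale=scale)

    @classmethod
    def read_bedgraph(cls, path, chrom: str | None = None, strand: str = "+",
                      scale: float = 1.0) -> "SignalTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        if chrom is None:
            if df.empty:
                raise ValueError(f"{path}: empty bedGraph and no chrom given")
            chrom = df["chrom"].iloc[0]
        df = df[df["chrom"] == chrom].sort_values("start")
        return cls(chrom, strand, df["start"].to_numpy(), df["end"].to_numpy(),
                   df["value"].to_numpy(), scale=scale)

    def write_bedgraph(self, path) -> None:
        keep = self.values != 0
        df = pd.DataFrame({
            "chrom": self.chrom,
            "start": self.starts[keep],
            "end": self.ends[keep],
            "value": self.values[keep],
        })
        df.to_csv(path, sep="\t", header=False, index=False)

    # -- queries ------------------------------------------------------------
    def total(self, scaled: bool = False) -> float:
        tot = float(np.sum(self.values * (self.ends - self.starts)))
        return tot * self.scale if scaled else tot

    def region_sum(self, start: int, end: int, mask: "MappabilityMask | None" = None,
                   scaled: bool = False) -> float:
        """Sum of counts over [start, end), excluding masked bp."""
        if end <= start:
            return 0.0
        lo = np.clip(self.starts, start, end)
        hi = np.clip(self.ends, start, end)
        lengths = (hi - lo).astype(float)
        if mask is not None and len(mask.starts):
            for ms, me in zip(mask.starts, mask.ends):
                mlo = np.clip(self.starts, max(start, ms), min(end, me))
                mhi = np.clip(self.ends, max(start, ms), min(end, me))
                lengths -= (mhi - mlo)
        tot = float(np.dot(self.values, lengths))
        return tot * self.scale if scaled else tot

    def region_density(self, start: int, end: int,
                       mask: "MappabilityMask | None" = None,
                       scaled: bool = False) -> float:
        mappable = (end - start) - (mask.overlap_bp(start, end) if mask else 0)
        if mappable <= 0:
            return float("nan")
        return self.region_sum(start, end, mask, scaled=scaled) / mappable


class MappabilityMask:
    """Disjoint set of unmappable intervals on one chromosome."""

    def __init__(self, intervals=()):
        ivs = sorted((iv.start, iv.end) for iv in intervals)
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)  # merge touching/overlapping
            else:
                starts.append(s)
                ends.append(e)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)

    @classmethod
    def read_bed(cls, path, chrom: str | None = None) -> "MappabilityMask":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return cls(GenomicInterval(r.chrom, r.start, r.end)
                   for r in df.itertuples())

    def overlap_bp(self, start: int, end: int) -> int:
        if not len(self.starts) or end <= start:
            return 0
        lo = np.clip(self.starts, start, end)
        hi = np.clip(self.ends, start, end)
        return int(np.sum(hi - lo))


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _gene_from_bed12(row, idx: int) -> GeneModel:
    try:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name, strand = str(row[3]), row[5]
        n_blocks = int(row[9])
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise AnnotationError(f"row {idx}: unparseable BED12 record ({exc})")
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise AnnotationError(f"row {idx}: blockCount mismatch")
    exons = [GenomicInterval(chrom, start + o, start + o + s, strand)
             for o, s in zip(offsets, sizes)]
    return GeneModel(name, GenomicInterval(chrom, start, end, strand), exons)


def _gene_from_refflat(row, idx: int) -> GeneModel:
    try:
        name, chrom, strand = str(row[0]), row[2], row[3]
        start, end = int(row[4]), int(row[5])
        ex_starts = [int(x) for x in str(row[9]).rstrip(",").split(",")]
        ex_ends = [int(x) for x in str(row[10]).rstrip(",").split(",")]
    except (ValueError, IndexError) as exc:
        raise AnnotationError(f"row {idx}: unparseable refFlat record ({exc})")
    exons = [GenomicInterval(chrom, s, e, strand)
             for s, e in zip(ex_starts, ex_ends)]
    return GeneModel(name, GenomicInterval(chrom, start, end, strand), exons)


def write_bed12(genes: list[GeneModel], path) -> None:
    """Write gene models as BED12 (exons as blocks, genomic order)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(len(e)) for e in exons)
            offs = ",".join(str(e.start - g.interval.start) for e in exons)
            fh.write("\t".join(map(str, [
                g.chrom, g.interval.start, g.interval.end, g.gene_id, 0,
                g.strand, g.interval.start, g.interval.end, "0",
                len(exons), sizes, offs])) + "\n")


def load_gene_annotation(path, fmt: str | None = None) -> list[GeneModel]:
    """Load gene models from a BED12 or refFlat-style table.

    The dialect is auto-detected from the strand column position when ``fmt``
    is None.  Malformed rows raise :class:`AnnotationError` naming the row.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.empty:
        return []
    if fmt is None:
        first = df.iloc[0]
        if len(df.columns) >= 12 and str(first[5]) in "+-":
            fmt = "bed12"
        elif len(df.columns) >= 11 and str(first[3]) in "+-":
            fmt = "refflat"
        else:
            raise AnnotationError("row 0: cannot detect annotation dialect")
    parser = {"bed12": _gene_from_bed12, "refflat": _gene_from_refflat}[fmt]
    genes = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            genes.append(parser(row, idx))
        except AnnotationError:
            raise
        except Exception as exc:  # wrap anything else with the row index
            raise AnnotationError(f"row {idx}: {exc}")
    return genes


# ---------------------------------------------------------------------------
# binning / normalization
# ---------------------------------------------------------------------------

def bin_signal(track: SignalTrack, region: GenomicInterval, bin_size: int,
               mask: MappabilityMask | None = None) -> pd.DataFrame:
    """Bin a track over ``region``, walking in transcription direction.

    Returns a DataFrame with columns start, end, count, mappable_bp, density.
    Fully masked bins report density NaN (the undefined marker) and count 0.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if len(region) == 0:
        raise ValueError("empty region")
    edges = np.arange(region.start, region.end, bin_size, dtype=np.int64)
    rows = []
    for s in edges:
        e = min(int(s) + bin_size, region.end)
        mbp = (e - s) - (mask.overlap_bp(s, e) if mask else 0)
        cnt = track.region_sum(s, e, mask) if mbp > 0 else 0.0
        rows.append((int(s), e, cnt, int(mbp),
                     cnt / mbp if mbp > 0 else np.nan))
    df = pd.DataFrame(rows, columns=["start", "end", "count",
                                     "mappable_bp", "density"])
    if region.strand == "-":
        df = df.iloc[::-1].reset_index(drop=True)
    return df


def spike_normalize(libraries, spike_counts, reference_index: int = 0):
    """Spike-in scale factors: scale_i = spikes[reference] / spikes[i].

    ``libraries`` may be None; if given, each track's ``scale`` is set.
    """
    spikes = np.asarray(spike_counts, dtype=float)
    if np.any(spikes <= 0):
        raise ValueError("spike counts must all be positive")
    scales = spikes[reference_index] / spikes
    if libraries is not None:
        for lib, sc in zip(libraries, scales):
            lib.scale = float(sc)
    return scales


def read_spike_table(path) -> dict[str, int]:
    """TSV with columns (library_id, spike_reads) -> dict."""
    df = pd.read_csv(path, sep="\t")
    if not {"library_id", "spike_reads"}.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["library_id", "spike_reads"])
    return dict(zip(df["library_id"].astype(str), df["spike_reads"].astype(int)))
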