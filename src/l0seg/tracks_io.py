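"""Genome-track I/O: BigWig/BedGraph signals, bismark methylation, BED/GTF.

All coordinates are 0-based half-open throughout.  Segmentation operates on
binned series; :class:`BinGrid` records how bins map back to basepairs so
segment output can be written as BedGraph in genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dp import Segmentation
from .series import DualCountSeries, WeightedSeries

__all__ = [
    "BinGrid",
    "GenomicTrack",
    "IntervalSet",
    "read_bedgraph",
    "read_bigwig_binned",
    "read_bismark",
    "read_paired_bigwig_methylation",
    "write_bedgraph",
    "write_bismark",
    "segmentation_to_intervals",
    "read_bed",
    "read_gene_models",
]


@dataclass
class BinGrid:
    """Fixed-width binning of a genomic region (last bin may be partial)."""

    chrom: str
    start: int
    end: int
    bin_bp: int

    @property
    def n_bins(self) -> int:
        return -(-(self.end - self.start) // self.bin_bp)

    def bin_bounds(self, b: int) -> tuple[int, int]:
        lo = self.start + b * self.bin_bp
        return lo, min(lo + self.bin_bp, self.end)


@dataclass
class GenomicTrack:
    """Signal values on sorted, non-overlapping intervals of one chromosome."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends and values must have equal length")
        if np.any(self.ends <= self.starts):
            raise ValueError("intervals must satisfy end > start")
        if np.any(np.diff(self.starts) < 0) or np.any(self.starts[1:] < self.ends[:-1]):
            raise ValueError("intervals must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class IntervalSet:
    """BED-style intervals with optional name/score/strand."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    name: np.ndarray | None = None
    score: np.ndarray | None = None
    strand: np.ndarray | None = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=int)
        self.end = np.asarray(self.end, dtype=int)
        if np.any(self.end <= self.start):
            raise ValueError("BED intervals must satisfy end > start")

    def __len__(self) -> int:
        return len(self.start)

    def for_chrom(self, chrom: str) -> "IntervalSet":
        m = self.chrom == chrom
        return IntervalSet(
            self.chrom[m],
            self.start[m],
            self.end[m],
            None if self.name is None else self.name[m],
            None if self.score is None else self.score[m],
            None if self.strand is None else self.strand[m],
        )


# --------------------------------------------------------------------- reads


def _is_bigwig(path: str) -> bool:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    return magic in (b"\x26\xfc\x8f\x88", b"\x88\x8f\xfc\x26")


def read_bedgraph(path: str, chrom: str | None = None) -> GenomicTrack:
    """Read a (single-chromosome) BedGraph into a :class:`GenomicTrack`."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    df = df[~df["chrom"].str.startswith("track")]
    if chrom is None:
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError(
                f"BedGraph covers {len(chroms)} chromosomes; pass chrom= explicitly"
            )
        chrom = chroms[0]
    df = df[df["chrom"] == chrom]
    df = df.sort_values("start")
    return GenomicTrack(chrom, df["start"].to_numpy(), df["end"].to_numpy(),
                        df["value"].to_numpy(float))


def _per_base_from_track(track: GenomicTrack, start: int, end: int) -> np.ndarray:
    out = np.zeros(end - start)
    s = np.clip(track.starts, start, end) - start
    e = np.clip(track.ends, start, end) - start
    for si, ei, v in zip(s, e, track.values):
        if ei > si:
            out[si:ei] += v
    return out


def read_bigwig_binned(path: str, chrom: str | None = None, start: int | None = None,
                       end: int | None = None, bin_bp: int = 20,
                       stat: str = "sum") -> tuple[WeightedSeries, BinGrid]:
    """Read a BigWig (or BedGraph) region into fixed-width bins.

    Per-base values are summed into consecutive ``bin_bp``-wide bins (or
    averaged with ``stat="mean"``); missing data count as zero, since for
    sequencing coverage the absence of reads is an observation of zero.  A
    partial last bin keeps its sum but gets weight equal to its covered
    fraction of a full bin.
    """
    if stat not in ("sum", "mean"):
        raise ValueError("stat must be 'sum' or 'mean'")
    if _is_bigwig(path):
        import pyBigWig

        bw = pyBigWig.open(path)
        try:
            chroms = bw.chroms()
            if chrom is None:
                if len(chroms) != 1:
                    raise ValueError("multi-chromosome BigWig; pass chrom= explicitly")
                chrom = next(iter(chroms))
            if chrom not in chroms:
                raise ValueError(f"unknown chromosome {chrom!r}")
            start = 0 if start is None else start
            end = chroms[chrom] if end is None else end
            if not 0 <= start < end <= chroms[chrom]:
                raise ValueError(f"region [{start}, {end}) outside {chrom} bounds")
            per_base = np.nan_to_num(
                np.asarray(bw.values(chrom, start, end), dtype=float), nan=0.0
            )
        finally:
            bw.close()
    else:
        track = read_bedgraph(path, chrom)
        chrom = track.chrom
        start = int(track.starts[0]) if start is None else start
        end = int(track.ends[-1]) if end is None else end
        if start >= end:
            raise ValueError("empty region")
        per_base = _per_base_from_track(track, start, end)

    grid = BinGrid(chrom, start, end, bin_bp)
    n_bins = grid.n_bins
    edges = np.arange(n_bins) * bin_bp
    sums = np.add.reduceat(per_base, edges)
    widths = np.minimum(edges + bin_bp, end - start) - edges
    weights = widths / bin_bp
    if stat == "mean":
        sums = sums / widths
    return WeightedSeries(sums, weights), grid


def read_bismark(path: str, chrom: str | None = None, start: int | None = None,
                 end: int | None = None) -> tuple[DualCountSeries, np.ndarray, str]:
    """Read a bismark coverage file into a :class:`DualCountSeries`.

    Accepts both common 6-column dialects — ``.cov`` exports with 1-based
    positions (``start == end``) and bedGraph-style 0-based half-open rows
    (``end == start + 1``) — auto-detected from the coordinates.  Returns the
    series, the 0-based CpG positions, and the chromosome.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns, got {len(parts)}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             float(parts[4]), float(parts[5])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed record ({exc})") from None
            if rows[-1][3] < 0 or rows[-1][4] < 0:
                raise ValueError(f"{path}:{ln}: negative count")
    if not rows:
        raise ValueError(f"{path}: no records")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "meth", "unmeth"])
    if chrom is None:
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("multi-chromosome file; pass chrom= explicitly")
        chrom = chroms[0]
    df = df[df["chrom"] == chrom]
    if (df["end"] == df["start"]).all():
        pos = df["start"].to_numpy() - 1  # 1-based .cov dialect
    elif (df["end"] == df["start"] + 1).all():
        pos = df["start"].to_numpy()  # 0-based half-open dialect
    else:
        raise ValueError(f"{path}: cannot determine coordinate dialect")
    if np.any(np.diff(pos) <= 0):
        bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 2
        raise ValueError(f"{path}: positions not strictly increasing at record {bad}")
    if start is not None or end is not None:
        lo = -np.inf if start is None else start
        hi = np.inf if end is None else end
        m = (pos >= lo) & (pos < hi)
        df, pos = df[m], pos[m]
    if len(df) == 0:
        return DualCountSeries([0.0], [0.0]), np.array([], dtype=int), chrom
    meth = df["meth"].to_numpy(float)
    total = meth + df["unmeth"].to_numpy(float)
    return DualCountSeries(meth, total), pos.astype(int), chrom


def read_paired_bigwig_methylation(fraction_path: str, coverage_path: str,
                                   chrom: str, start: int | None = None,
                                   end: int | None = None
                                   ) -> tuple[DualCountSeries, np.ndarray, str]:
    """Build dual counts from paired fraction + coverage BigWigs.

    Methylated counts are recovered as ``round(fraction * coverage)``;
    positions with zero coverage are dropped.
    """
    import pyBigWig

    bw_f = pyBigWig.open(fraction_path)
    bw_c = pyBigWig.open(coverage_path)
    try:
        if chrom not in bw_c.chroms():
            raise ValueError(f"unknown chromosome {chrom!r}")
        start = 0 if start is None else start
        end = bw_c.chroms()[chrom] if end is None else end
        frac = np.nan_to_num(np.asarray(bw_f.values(chrom, start, end), float), nan=0.0)
        cov = np.nan_to_num(np.asarray(bw_c.values(chrom, start, end), float), nan=0.0)
    finally:
        bw_f.close()
        bw_c.close()
    keep = cov > 0
    pos = np.flatnonzero(keep) + start
    total = cov[keep]
    meth = np.minimum(np.round(frac[keep] * total), total)
    return DualCountSeries(meth, total), pos, chrom


# -------------------------------------------------------------------- writes


def _format_value(v: float) -> str:
    return f"{v:.6g}"


def write_bedgraph(path: str, chrom: str, starts, ends, values,
                   merge: bool = True) -> None:
    """Write intervals as BedGraph, merging adjacent runs of equal value."""
    starts = np.asarray(starts, dtype=int)
    ends = np.asarray(ends, dtype=int)
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if len(starts) == 0:
            return
        cs, ce, cv = starts[0], ends[0], values[0]
        for s, e, v in zip(starts[1:], ends[1:], values[1:]):
            if merge and s == ce and v == cv:
                ce = e
            else:
                fh.write(f"{chrom}\t{cs}\t{ce}\t{_format_value(cv)}\n")
                cs, ce, cv = s, e, v
        fh.write(f"{chrom}\t{cs}\t{ce}\t{_format_value(cv)}\n")


def write_bismark(path: str, chrom: str, positions, meth, total) -> None:
    """Write a 1-based 6-column bismark ``.cov`` file."""
    positions = np.asarray(positions, dtype=int)
    meth = np.asarray(meth)
    total = np.asarray(total)
    unmeth = total - meth
    with open(path, "w") as fh:
        for p, m, u in zip(positions, meth, unmeth):
            tot = m + u
            pct = 100.0 * m / tot if tot > 0 else 0.0
            fh.write(f"{chrom}\t{p + 1}\t{p + 1}\t{pct:.6g}\t{int(m)}\t{int(u)}\n")


def segmentation_to_intervals(seg: Segmentation, grid: BinGrid
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a binned segmentation back to basepair intervals.

    A segment spanning bins ``[b1, b2]`` becomes the interval
    ``[start + b1*bin_bp, start + (b2+1)*bin_bp)`` clipped to the region end,
    so a partial last bin ends at the region end rather than the bin end.
    """
    if seg.n != grid.n_bins:
        raise ValueError("segmentation length does not match the bin grid")
    starts = grid.start + seg.starts * grid.bin_bp
    ends = np.minimum(grid.start + seg.ends * grid.bin_bp, grid.end)
    return starts, ends, seg.segment_values


def cpg_segmentation_to_intervals(seg: Segmentation, positions: np.ndarray
                                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map a CpG-rank segmentation to the genomic extent of its CpGs."""
    positions = np.asarray(positions, dtype=int)
    if seg.n != positions.size:
        raise ValueError("segmentation length does not match positions")
    starts = positions[seg.starts]
    ends = positions[seg.ends - 1] + 1
    return starts, ends, seg.segment_values


# ----------------------------------------------------------------- BED / GTF


def read_bed(path: str) -> IntervalSet:
    """Read BED3/6/12 (narrowPeak columns beyond 6 are ignored)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype={0: str})
    df = df[~df[0].astype(str).str.startswith("track")]
    if df.shape[1] < 3:
        raise ValueError(f"{path}: fewer than 3 BED columns")
    name = df[3].to_numpy(object) if df.shape[1] > 3 else None
    score = pd.to_numeric(df[4], errors="coerce").to_numpy() if df.shape[1] > 4 else None
    strand = df[5].to_numpy(object) if df.shape[1] > 5 else None
    return IntervalSet(df[0].to_numpy(object), df[1].to_numpy(int),
                       df[2].to_numpy(int), name, score, strand)


def read_gene_models(path: str) -> pd.DataFrame:
    """Read transcripts from BED6/BED12 or GTF and derive strand-aware TSS/TES.

    TES is the transcript end on the + strand and the transcript start on the
    - strand; TSS is the opposite end.  Returns a DataFrame with columns
    ``chrom, start, end, name, strand, tss, tes``.
    """
    if path.endswith((".gtf", ".gff", ".gff3")):
        recs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 8:
                    raise ValueError(f"{path}:{ln}: malformed GTF record")
                if parts[2] != "transcript":
                    continue
                attrs = parts[8] if len(parts) > 8 else ""
                name = ""
                for field in attrs.split(";"):
                    field = field.strip()
                    if field.startswith("transcript_id"):
                        name = field.split(None, 1)[1].strip('"')
                        break
                recs.append((parts[0], int(parts[3]) - 1, int(parts[4]), name, parts[6]))
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name", "strand"])
    else:
        bed = read_bed(path)
        if bed.strand is None:
            raise ValueError("gene models need a strand column (BED6+)")
        df = pd.DataFrame(
            {
                "chrom": bed.chrom,
                "start": bed.start,
                "end": bed.end,
                "name": bed.name if bed.name is not None else "",
                "strand": bed.strand,
            }
        )
    plus = df["strand"] == "+"
    df["tss"] = np.where(plus, df["start"], df["end"])
    df["tes"] = np.where(plus, df["end"], df["start"])
    return df
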