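"""Fragment ingest, quality/size filtering and dyad-midpoint tracks.

Paired-end MNase-seq fragments protect ~147 bp of nucleosomal DNA; the
fragment midpoint estimates the nucleosome dyad.  This module loads aligned
fragments (BAM/SAM via pysam, or BED intervals), applies mapping-quality and
fragment-size filters, removes per-library duplicates, and accumulates
per-base midpoint count tracks.

Coordinates are 0-based half-open throughout (BED convention).  For an
even-length fragment the midpoint is the left of the two central bases,
``start + (length - 1) // 2``, which is deterministic and strand-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FragmentSet",
    "SizeDistribution",
    "MidpointTrack",
    "load_fragments",
    "size_filter",
    "remove_duplicates",
    "compute_midpoints",
]

FRAGMENT_COLUMNS = ["chrom", "start", "end", "library", "strand", "paired"]


@dataclass
class SizeDistribution:
    """Histogram of fragment lengths with central-interval quantile bounds."""

    lengths: np.ndarray  # sorted unique lengths
    counts: np.ndarray

    @classmethod
    def from_lengths(cls, lengths: np.ndarray) -> "SizeDistribution":
        vals, counts = np.unique(np.asarray(lengths, dtype=np.int64), return_counts=True)
        return cls(vals, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def central_interval(self, mass: float) -> tuple[int, int]:
        """Smallest symmetric-in-probability bounds holding the central `mass`.

        Bounds are the (1-mass)/2 and 1-(1-mass)/2 quantiles of the histogram
        (inverse-CDF convention), so they always lie in the observed support.
        """
        if not 0 < mass < 1:
            raise ValueError("mass must be in (0, 1)")
        if self.total == 0:
            raise ValueError("empty size distribution")
        cdf = np.cumsum(self.counts)
        tail = (1.0 - mass) / 2.0
        lo = self.lengths[np.searchsorted(cdf, tail * self.total, side="left")]
        hi = self.lengths[np.searchsorted(cdf, (1.0 - tail) * self.total, side="left")]
        return int(lo), int(hi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.counts / self.total
        return rng.choice(self.lengths, size=n, p=p)


@dataclass
class FragmentSet:
    """A table of mapped fragments plus ingest/filter bookkeeping.

    ``df`` columns: chrom, start, end, library, strand ('+'/'-'/'.'),
    paired (bool).  ``skipped`` tallies records dropped at each step.
    """

    df: pd.DataFrame
    skipped: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def libraries(self) -> set[str]:
        return set(self.df["library"].unique())

    def size_distribution(self) -> SizeDistribution:
        return SizeDistribution.from_lengths(self.lengths)

    @classmethod
    def from_arrays(cls, chrom, start, end, library="lib1", strand=".", paired=True,
                    skipped=None) -> "FragmentSet":
        n = len(start)
        df = pd.DataFrame(
            {
                "chrom": np.broadcast_to(np.asarray(chrom, dtype=object), (n,)).copy()
                if np.ndim(chrom) == 0 else np.asarray(chrom, dtype=object),
                "start": np.asarray(start, dtype=np.int64),
                "end": np.asarray(end, dtype=np.int64),
                "library": np.broadcast_to(np.asarray(library, dtype=object), (n,)).copy()
                if np.ndim(library) == 0 else np.asarray(library, dtype=object),
                "strand": np.broadcast_to(np.asarray(strand, dtype=object), (n,)).copy()
                if np.ndim(strand) == 0 else np.asarray(strand, dtype=object),
                "paired": np.broadcast_to(paired, (n,)).copy()
                if np.ndim(paired) == 0 else np.asarray(paired, dtype=bool),
            }
        )
        return cls(df, dict(skipped or {}))

    def to_bed(self, path) -> None:
        out = self.df[["chrom", "start", "end", "library"]].copy()
        out["score"] = 0
        out["strand"] = self.df["strand"].replace(".", "+")
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class MidpointTrack:
    """Per-chromosome integer counts of inferred dyad midpoints."""

    counts: dict[str, np.ndarray]
    libraries: set[str] = field(default_factory=set)

    @property
    def total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Counts over [start, end), zero-padded beyond the chromosome."""
        arr = self.counts[chrom]
        out = np.zeros(end - start, dtype=arr.dtype)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.counts):
                arr = self.counts[chrom]
                nz = np.flatnonzero(arr)
                if len(nz) == 0:
                    continue
                # merge equal-valued runs of adjacent positions
                breaks = np.flatnonzero((np.diff(nz) != 1) | (np.diff(arr[nz]) != 0))
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks, [len(nz) - 1]])
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{nz[s]}\t{nz[e] + 1}\t{arr[nz[s]]}\n")

    @classmethod
    def from_positions(cls, positions: dict[str, np.ndarray],
                       chrom_sizes: dict[str, int],
                       libraries=()) -> "MidpointTrack":
        counts = {}
        for chrom, size in chrom_sizes.items():
            pos = positions.get(chrom, np.empty(0, dtype=np.int64))
            counts[chrom] = np.bincount(pos, minlength=size).astype(np.int64)
        return cls(counts, set(libraries))


def load_fragments(source, min_mapq: int = 10, library: str | None = None) -> FragmentSet:
    """Load fragments from a BAM/SAM file or a BED interval file.

    For paired alignments one fragment is emitted per proper pair whose two
    mates both pass ``min_mapq`` and map to the same chromosome; pairs with
    mates on different chromosomes are skipped and counted.  Single-end
    records are retained with their strand and flagged ``paired=False`` so
    that :func:`compute_midpoints` can apply the fixed-offset dyad rule.
    """
    src = str(source)
    if src.endswith((".bam", ".sam", ".cram")):
        return _load_alignments(src, min_mapq, library)
    return _load_bed(src, library)


def _load_bed(path: str, library: str | None) -> FragmentSet:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return FragmentSet(pd.DataFrame(columns=FRAGMENT_COLUMNS))
    ncol = df.shape[1]
    out = pd.DataFrame(
        {
            "chrom": df[0].astype(str),
            "start": df[1].astype(np.int64),
            "end": df[2].astype(np.int64),
            "library": df[3].astype(str) if ncol > 3 and library is None
            else (library or "lib1"),
            "strand": df[5].astype(str) if ncol > 5 else ".",
            "paired": True,
        }
    )
    if (out["end"] <= out["start"]).any():
        raise ValueError("BED fragment with end <= start")
    return FragmentSet(out)


def _load_alignments(path: str, min_mapq: int, library: str | None) -> FragmentSet:
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    skipped = {"low_mapq": 0, "mate_other_chrom": 0, "unmapped": 0}
    pending: dict[str, tuple] = {}
    rows = []
    with pysam.AlignmentFile(path, mode) as bam:
        rg = library or (bam.header.get("RG", [{}])[0].get("ID", "lib1")
                         if bam.header.get("RG") else "lib1")
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                skipped["unmapped"] += 1
                continue
            if not read.is_paired:
                if read.mapping_quality < min_mapq:
                    skipped["low_mapq"] += 1
                    continue
                rows.append((read.reference_name, read.reference_start,
                             read.reference_end, rg,
                             "-" if read.is_reverse else "+", False))
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = (read.reference_name, read.reference_start,
                                            read.reference_end, read.mapping_quality)
                continue
            mchrom, mstart, mend, mmapq = mate
            if read.reference_name != mchrom:
                skipped["mate_other_chrom"] += 1
                continue
            if read.mapping_quality < min_mapq or mmapq < min_mapq:
                skipped["low_mapq"] += 1
                continue
            start = min(read.reference_start, mstart)
            end = max(read.reference_end, mend)
            rows.append((mchrom, start, end, rg, ".", True))
    skipped["unpaired_mate"] = len(pending)
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    return FragmentSet(df, skipped)


def size_filter(fragments: FragmentSet, low: int | None = 126, high: int | None = 184,
                mode: str = "explicit", mass: float = 0.95) -> FragmentSet:
    """Keep fragments with ``low <= length <= high``.

    ``mode="central_mass"`` derives the bounds as the central ``mass``
    interval of the input's size distribution instead of using explicit
    bounds; the bounds actually applied are recorded in ``skipped``
    (keys ``size_low``/``size_high``) for reporting.
    """
    if mode == "central_mass":
        low, high = fragments.size_distribution().central_interval(mass)
    elif low is None or high is None or low > high:
        raise ValueError("explicit mode requires low <= high")
    lens = fragments.lengths
    keep = (lens >= low) & (lens <= high)
    out = FragmentSet(fragments.df.loc[keep].reset_index(drop=True),
                      dict(fragments.skipped))
    out.skipped["size_filtered"] = int((~keep).sum())
    out.skipped["size_low"] = int(low)
    out.skipped["size_high"] = int(high)
    if len(out) == 0 and len(fragments) > 0:
        warnings.warn("size_filter removed every fragment")
    return out


def remove_duplicates(fragments: FragmentSet) -> FragmentSet:
    """Drop duplicate fragments within each library.

    A duplicate is an identical (library, chrom, start, end) tuple; identical
    coordinates in different libraries are kept (amplification duplicates are
    a within-library artifact).
    """
    df = fragments.df.drop_duplicates(subset=["library", "chrom", "start", "end"])
    out = FragmentSet(df.reset_index(drop=True), dict(fragments.skipped))
    out.skipped["duplicates"] = len(fragments) - len(out)
    return out


def compute_midpoints(fragments: FragmentSet, chrom_sizes: dict[str, int] | None = None,
                      mode: str = "paired", single_end_offset: int = 75) -> MidpointTrack:
    """Accumulate dyad midpoints into a per-base count track.

    Paired fragments: dyad = start + (length - 1) // 2.  Single-end records
    (``mode="single_end"`` or rows flagged unpaired): dyad = 5' end +
    ``single_end_offset`` on the read's strand; on the minus strand the 5'
    end is the last aligned base (end - 1) and the offset runs leftward.
    Midpoints falling outside the chromosome are dropped and counted.
    """
    df = fragments.df
    if chrom_sizes is None:
        chrom_sizes = {c: int(g["end"].max()) for c, g in df.groupby("chrom")} if len(df) else {}
    single = (df["paired"] == False) | (mode == "single_end")  # noqa: E712
    mid = np.empty(len(df), dtype=np.int64)
    if len(df):
        start = df["start"].to_numpy()
        end = df["end"].to_numpy()
        mid[:] = start + (end - start - 1) // 2
        if single.any():
            s = single.to_numpy()
            minus = (df["strand"].to_numpy() == "-") & s
            plus = s & ~minus
            mid[plus] = start[plus] + single_end_offset
            mid[minus] = end[minus] - 1 - single_end_offset
    positions = {}
    dropped = 0
    for chrom, size in chrom_sizes.items():
        sel = (df["chrom"] == chrom).to_numpy() if len(df) else np.empty(0, dtype=bool)
        m = mid[sel]
        ok = (m >= 0) & (m < size)
        dropped += int((~ok).sum())
        positions[chrom] = m[ok]
    track = MidpointTrack.from_positions(positions, chrom_sizes, fragments.libraries)
    if dropped:
        warnings.warn(f"{dropped} midpoints outside chromosome bounds dropped")
    return track
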