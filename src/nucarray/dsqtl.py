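"""Genotype-stratified aggregation of chromatin tracks at dsQTLs.

A dsQTL is a SNP whose genotype correlates with local DNase I sensitivity.
Each cell line is labeled homozygous-sensitive, heterozygous or
homozygous-insensitive by the genotype of the associated SNP.  The DNase
sensitive region of each dsQTL is localized from the smoothed nick track of
sensitive + heterozygous samples (peak within 200 bp of the dsQTL midpoint,
region = contiguous block above half the peak), dsQTLs with misplaced,
overlapping or genotype-inconsistent regions are filtered, and MNase
midpoints / DNase nicks are aggregated per genotype class on the sensitive
region midpoint, each sample scaled by its sequencing depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered zero-padded sliding mean, computed exactly via cumulative sums.

    Exact summation matters here: the half-peak region boundary compares
    smoothed values against peak/2, and convolution round-off can flip a
    strict inequality on integer count tracks.
    """
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(np.asarray(x, dtype=float))])
    i = np.arange(len(x))
    return (cs[np.minimum(i + half + 1, len(x))]
            - cs[np.maximum(i - half, 0)]) / window

__all__ = [
    "SensitiveRegion",
    "define_sensitive_region",
    "class_means",
    "filter_dsqtls",
    "aggregate_by_genotype",
    "subset_by_effect",
    "GENOTYPE_CLASSES",
]

GENOTYPE_CLASSES = ("sensitive", "heterozygous", "insensitive")


@dataclass
class SensitiveRegion:
    peak: int                 # track-relative position of the smoothed maximum
    start: int                # region [start, end), track-relative
    end: int
    peak_value: float
    valid: bool = True
    mean_by_class: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def define_sensitive_region(nick_track: np.ndarray, dsqtl_mid: int,
                            smooth: int = 101, search: int = 200) -> SensitiveRegion:
    """Locate the DNase-sensitive region around a dsQTL midpoint.

    ``nick_track`` is a per-base nick count vector (sensitive + heterozygous
    samples combined) covering at least ``dsqtl_mid`` +/- (search + smooth);
    positions are track-relative.  The track is smoothed with a centered
    ~101 bp mean; the peak is the maximum within ``search`` bp of the
    midpoint (ties: closest to the midpoint, then leftmost) and the region
    is the maximal contiguous run around the peak where the smoothed value
    exceeds half the peak value.
    """
    x = np.asarray(nick_track, dtype=float)
    if dsqtl_mid - search < 0 or dsqtl_mid + search >= len(x):
        raise ValueError("track does not cover the search window")
    sm = _smooth(x, smooth)
    lo, hi = dsqtl_mid - search, dsqtl_mid + search + 1
    seg = sm[lo:hi]
    best = seg.max()
    if best <= 0:
        return SensitiveRegion(dsqtl_mid, dsqtl_mid, dsqtl_mid, 0.0, valid=False)
    cand = np.flatnonzero(seg == best) + lo
    peak = int(cand[np.argmin(np.abs(cand - dsqtl_mid))])
    above = sm > best / 2.0
    start = peak
    while start > 0 and above[start - 1]:
        start -= 1
    end = peak + 1
    while end < len(sm) and above[end]:
        end += 1
    return SensitiveRegion(peak, start, end, float(best))


def class_means(region: SensitiveRegion, nick_tracks_by_class: dict[str, np.ndarray],
                smooth: int = 101) -> SensitiveRegion:
    """Attach per-genotype-class mean smoothed nick values over the region."""
    for cls, track in nick_tracks_by_class.items():
        sm = _smooth(np.asarray(track, dtype=float), smooth)
        region.mean_by_class[cls] = float(sm[region.start : region.end].mean())
    return region


def filter_dsqtls(dsqtls: pd.DataFrame, regions: list[SensitiveRegion],
                  max_edge_distance: int = 100) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the three dsQTL filters in order; report per-rule discard tallies.

    ``dsqtls`` needs columns chrom and dsqtl_mid (track-relative, matching
    the coordinates in ``regions``).  Rules, applied sequentially:

    1. discard when either sensitive-region edge is more than
       ``max_edge_distance`` bp from the dsQTL midpoint;
    2. discard both members of any pair whose sensitive regions overlap
       (same chromosome);
    3. discard genotype-inconsistent regions: heterozygous mean above the
       homozygous-sensitive mean, or homozygous-insensitive mean above
       either (requires ``mean_by_class`` on each region).
    """
    n = len(dsqtls)
    if n != len(regions):
        raise ValueError("dsqtls and regions must align")
    keep = np.array([r.valid for r in regions])
    tallies = {"invalid_region": int((~keep).sum())}
    # rule 1: edge distance
    drop1 = np.zeros(n, dtype=bool)
    for i, (row, reg) in enumerate(zip(dsqtls.itertuples(), regions)):
        if not keep[i]:
            continue
        mid = row.dsqtl_mid
        if max(abs(reg.start - mid), abs(reg.end - 1 - mid)) > max_edge_distance:
            drop1[i] = True
    keep &= ~drop1
    tallies["edge_distance"] = int(drop1.sum())
    # rule 2: overlapping sensitive regions (both members removed)
    drop2 = np.zeros(n, dtype=bool)
    idx = np.flatnonzero(keep)
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            if dsqtls.iloc[i]["chrom"] != dsqtls.iloc[j]["chrom"]:
                continue
            if regions[i].start < regions[j].end and regions[j].start < regions[i].end:
                drop2[i] = drop2[j] = True
    keep &= ~drop2
    tallies["overlap"] = int(drop2.sum())
    # rule 3: genotype inconsistency
    drop3 = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(keep):
        m = regions[i].mean_by_class
        if not m:
            raise ValueError("regions need class means for the consistency filter")
        if (m["heterozygous"] > m["sensitive"]
                or m["insensitive"] > m["heterozygous"]
                or m["insensitive"] > m["sensitive"]):
            drop3[i] = True
    keep &= ~drop3
    tallies["inconsistent"] = int(drop3.sum())
    tallies["retained"] = int(keep.sum())
    out = dsqtls.loc[keep].reset_index(drop=True)
    out["region_start"] = [regions[i].start for i in np.flatnonzero(keep)]
    out["region_end"] = [regions[i].end for i in np.flatnonzero(keep)]
    out["region_mid"] = [regions[i].midpoint for i in np.flatnonzero(keep)]
    return out, tallies


def aggregate_by_genotype(dsqtls: pd.DataFrame, genotypes: pd.DataFrame,
                          tracks_by_sample: dict[str, dict[str, np.ndarray]],
                          read_totals: dict[str, float],
                          window: int = 800,
                          scale: float = 1e9) -> dict[str, dict[str, np.ndarray]]:
    """Per-genotype-class aggregate tracks centered on sensitive-region midpoints.

    ``dsqtls`` needs columns id, chrom and region_mid; ``genotypes`` is
    indexed by dsQTL id with one column per sample holding a class label
    from :data:`GENOTYPE_CLASSES`.  ``tracks_by_sample`` maps sample ->
    {chrom: per-base array} (call once for midpoints, once for nicks).
    Each sample's contribution is scaled by ``scale / read_totals[sample]``
    (counts per billion by default).  Samples missing a track are excluded
    with a warning.  Returns {class: {"offsets", "aggregate", "n_pairs"}}.
    """
    offsets = np.arange(-window, window + 1)
    agg = {c: np.zeros(len(offsets)) for c in GENOTYPE_CLASSES}
    npairs = {c: 0 for c in GENOTYPE_CLASSES}
    for row in dsqtls.itertuples():
        geno = genotypes.loc[row.id]
        for sample, cls in geno.items():
            if sample not in tracks_by_sample:
                warnings.warn(f"sample {sample!r} has no track; excluded")
                continue
            chrom_tracks = tracks_by_sample[sample]
            if row.chrom not in chrom_tracks:
                continue
            arr = chrom_tracks[row.chrom]
            lo = row.region_mid - window
            hi = row.region_mid + window + 1
            seg = np.zeros(len(offsets))
            a, b = max(lo, 0), min(hi, len(arr))
            if b > a:
                seg[a - lo : b - lo] = arr[a:b]
            agg[cls] += seg * (scale / read_totals[sample])
            npairs[cls] += 1
    return {c: {"offsets": offsets, "aggregate": agg[c], "n_pairs": npairs[c]}
            for c in GENOTYPE_CLASSES}


def subset_by_effect(dsqtls: pd.DataFrame, widths: np.ndarray,
                     effects: np.ndarray) -> pd.DataFrame:
    """Keep dsQTLs with region width strictly below the cohort median and
    |sensitive - insensitive| effect strictly above the cohort median."""
    w = np.asarray(widths, dtype=float)
    e = np.asarray(effects, dtype=float)
    if len(dsqtls) != len(w) or len(dsqtls) != len(e):
        raise ValueError("widths and effects must align with dsqtls")
    if len(dsqtls) < 2:
        warnings.warn("cohort too small for median subsetting; empty subset")
        return dsqtls.iloc[:0]
    keep = (w < np.median(w)) & (e > np.median(e))
    return dsqtls.loc[keep].reset_index(drop=True)
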