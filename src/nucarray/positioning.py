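"""Translational positioning scores, empirical-null FDR, peak calling and NRL.

The positioning score of a genomic site i is the fraction of midpoints in a
201 bp window around i that fall within 15 bp of i:

    S(i) = sum_{|j-i|<=15} x_j / sum_{|j-i|<=100} x_j

where x_j is the midpoint count at site j.  A region's score is the maximum
S(i) over its sites.  Scores are compared against the same statistic on
bias-matched simulated midpoints: the empirical p-value of a region is the
fraction of null scores exceeding its score, the proportion of nulls pi0 is
estimated a la Storey as #{p > lambda} / (m (1 - lambda)), and 1 - pi0
estimates the fraction of regions positioned better than chance.

Nucleosome peaks are contiguous runs of per-bp score above an entry
threshold, kept when the peak score reaches a higher threshold; the
nucleosome repeat length (NRL) is the least-squares slope of aggregate
midpoint-peak offset against peak index around those anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import rng_from_seed, sliding_mean
from .fragments import MidpointTrack

__all__ = [
    "ScoreRecord",
    "NRLEstimate",
    "sample_regions",
    "score_track",
    "positioning_score",
    "null_calibration",
    "classify_scores",
    "call_nucleosome_peaks",
    "estimate_nrl",
]


@dataclass
class ScoreRecord:
    chrom: str
    start: int
    end: int
    score: float
    argmax_site: int
    n_midpoints: int
    valid: bool
    p_value: float | None = None
    q_value: float | None = None


def sample_regions(chrom_sizes: dict[str, int],
                   mappability: dict[str, np.ndarray] | None = None,
                   blacklist: list[tuple[str, int, int]] | None = None,
                   n: int = 1000, length: int = 200, min_mappable: float = 0.8,
                   seed=0) -> pd.DataFrame:
    """Uniformly sample windows meeting a mappable-fraction floor.

    Windows of ``length`` bp are eligible when at least ``min_mappable`` of
    their bases are mappable and they do not intersect any blacklist
    interval.  Sampling is without replacement over eligible window starts;
    if fewer than ``n`` are eligible all are returned with a warning.
    """
    rng = rng_from_seed(seed)
    eligible = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_win = size - length + 1
        if n_win <= 0:
            continue
        ok = np.ones(n_win, dtype=bool)
        if mappability is not None:
            m = mappability[chrom].astype(float)
            cs = np.concatenate([[0.0], np.cumsum(m)])
            frac = (cs[length:] - cs[:-length]) / length
            ok &= frac >= min_mappable
        if blacklist:
            for bc, bs, be in blacklist:
                if bc != chrom:
                    continue
                lo = max(bs - length + 1, 0)
                hi = min(be, n_win)
                if hi > lo:
                    ok[lo:hi] = False
        starts = np.flatnonzero(ok)
        eligible.append((chrom, starts))
    total = sum(len(s) for _, s in eligible)
    if total == 0:
        warnings.warn("no eligible windows")
        return pd.DataFrame(columns=["chrom", "start", "end"])
    k = min(n, total)
    if k < n:
        warnings.warn(f"only {total} eligible windows for {n} requested")
    pick = np.sort(rng.choice(total, size=k, replace=False))
    rows = []
    offset = 0
    for chrom, starts in eligible:
        sel = pick[(pick >= offset) & (pick < offset + len(starts))] - offset
        for s in starts[sel]:
            rows.append((chrom, int(s), int(s) + length))
        offset += len(starts)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def score_track(counts: np.ndarray, window: int = 201, near: int = 15) -> np.ndarray:
    """Per-bp positioning score S(i) over a count vector (0 where empty)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if near >= window // 2:
        raise ValueError("near must be < window/2")
    x = np.asarray(counts, dtype=float)

    def windowed_sum(v: np.ndarray, half: int) -> np.ndarray:
        cs = np.concatenate([[0.0], np.cumsum(v)])
        i = np.arange(len(v))
        return cs[np.minimum(i + half + 1, len(v))] - cs[np.maximum(i - half, 0)]

    num = windowed_sum(x, near)
    den = windowed_sum(x, window // 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return s


def _argmax_tiebreak(values: np.ndarray, center: float) -> int:
    """Index of the maximum; ties go to the index closest to ``center``, then leftmost."""
    best = values.max()
    cand = np.flatnonzero(values == best)
    d = np.abs(cand - center)
    return int(cand[np.argmin(d)])  # argmin is leftmost among distance ties


def positioning_score(track: MidpointTrack, chrom: str, start: int, end: int,
                      window: int = 201, near: int = 15,
                      min_midpoints: int = 50) -> ScoreRecord:
    """Score one region: max S(i) over its sites, with count bookkeeping.

    Windows near the region edges use midpoint data beyond the region
    boundary (zero-padded past the chromosome ends).  ``n_midpoints`` counts
    midpoints inside the region itself; regions under ``min_midpoints`` are
    marked invalid.  Ties in S(i) break toward the site closest to the
    region midpoint, then leftmost.
    """
    half = window // 2
    x = track.window(chrom, start - half, end + half).astype(float)
    s_full = score_track(x, window=window, near=near)
    s = s_full[half : half + (end - start)]
    n_mid = int(x[half : half + (end - start)].sum())
    if n_mid == 0:
        return ScoreRecord(chrom, start, end, 0.0, start, 0, False)
    i = _argmax_tiebreak(s, (end - start) / 2.0)
    return ScoreRecord(chrom, start, end, float(s[i]), start + i, n_mid,
                       n_mid >= min_midpoints)


def score_regions(track: MidpointTrack, regions: pd.DataFrame, window: int = 201,
                  near: int = 15, min_midpoints: int = 50) -> pd.DataFrame:
    """Vectorized convenience: :func:`positioning_score` over a region table."""
    recs = [positioning_score(track, r.chrom, r.start, r.end, window, near, min_midpoints)
            for r in regions.itertuples()]
    return pd.DataFrame([r.__dict__ for r in recs])


def null_calibration(observed_scores: np.ndarray, null_scores: np.ndarray,
                     pi0_lambda: float = 0.5):
    """Empirical p-values against a null score set, Storey pi0 and q-values.

    p = #{null > score} / N, floored at 1/(N+1) so the q-value step never
    sees a zero.  pi0 = #{p > lambda} / (m (1 - lambda)) clamped to [0, 1];
    the fraction positioned better than chance is 1 - pi0.  q-values follow
    the standard monotone step-up over the sorted p-values.

    Returns ``(p_values, q_values, pi0, fraction_positioned)``.
    """
    if not 0 < pi0_lambda < 1:
        raise ValueError("pi0_lambda must be in (0, 1)")
    null = np.sort(np.asarray(null_scores, dtype=float))
    N = len(null)
    if N == 0:
        raise ValueError("empty null score set")
    if N < 100:
        warnings.warn("fewer than 100 null scores; p-value resolution is poor")
    obs = np.asarray(observed_scores, dtype=float)
    exceed = N - np.searchsorted(null, obs, side="right")
    p = np.maximum(exceed / N, 1.0 / (N + 1))
    m = len(p)
    pi0 = min(max(float((p > pi0_lambda).sum()) / (m * (1 - pi0_lambda)), 0.0), 1.0)
    order = np.argsort(p)
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return p, q, pi0, 1.0 - pi0


def classify_scores(scores: np.ndarray,
                    edges: tuple[float, float, float, float] = (0.3, 0.5, 0.7, 1.0)
                    ) -> dict[str, float]:
    """Fractions of scores in the weak/moderate/strong bins (right-closed).

    Defaults: weak (0.3, 0.5], moderate (0.5, 0.7], strong (0.7, 1.0];
    everything at or below the first edge is the remainder.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) == 0:
        return {"below": 0.0, "weak": 0.0, "moderate": 0.0, "strong": 0.0}
    if np.any((s < 0) | (s > 1)):
        raise ValueError("scores must lie in [0, 1]")
    e0, e1, e2, e3 = edges
    n = len(s)
    return {
        "below": float((s <= e0).sum()) / n,
        "weak": float(((s > e0) & (s <= e1)).sum()) / n,
        "moderate": float(((s > e1) & (s <= e2)).sum()) / n,
        "strong": float(((s > e2) & (s <= e3)).sum()) / n,
    }


def call_nucleosome_peaks(scores: np.ndarray, chrom: str = "chr", enter: float = 0.4,
                          keep: float = 0.5) -> pd.DataFrame:
    """One peak per contiguous run of per-bp score > ``enter``.

    The peak is the maximum-score position in the run (ties: closest to the
    run midpoint, then leftmost); peaks whose score is below ``keep`` are
    discarded.  Returns columns chrom, pos, score, region_start, region_end.
    """
    s = np.asarray(scores, dtype=float)
    above = s > enter
    if not above.any():
        return pd.DataFrame(columns=["chrom", "pos", "score", "region_start", "region_end"])
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(s)]])
    rows = []
    for a, b in zip(starts, ends):
        seg = s[a:b]
        i = _argmax_tiebreak(seg, (b - a) / 2.0)
        if seg[i] < keep:
            continue
        rows.append((chrom, int(a + i), float(seg[i]), int(a), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "score", "region_start", "region_end"])


@dataclass
class NRLEstimate:
    repeat_length: float
    intercept: float
    peak_offsets: np.ndarray
    peak_indices: np.ndarray
    residual_sd: float
    aggregate: np.ndarray


def estimate_nrl(track: MidpointTrack, anchors: pd.DataFrame, span: int = 1000,
                 smooth: int = 10, min_separation: int = 30,
                 rel_height: float = 0.25) -> NRLEstimate:
    """Nucleosome repeat length from aggregate midpoints around anchor peaks.

    Midpoint counts are aggregated by offset (-span..span) from every anchor
    position, smoothed with a ~``smooth`` bp sliding mean, and local maxima
    requiring strict dominance over +/- ``min_separation`` bp are located.
    To ignore the 10 bp-lattice shoulders of the major positions, maxima
    must also rise ``rel_height`` of the way from the aggregate's median to
    its maximum.  Peak offsets are regressed on their signed peak index
    (both flanks); the repeat length is the least-squares slope.
    """
    if len(anchors) < 3:
        raise ValueError("need at least 3 anchors")
    agg = np.zeros(2 * span + 1, dtype=float)
    for chrom, g in anchors.groupby("chrom", sort=False):
        if chrom not in track.counts:
            continue
        arr = track.counts[chrom]
        for pos in g["pos"].to_numpy():
            lo, hi = pos - span, pos + span + 1
            a, b = max(lo, 0), min(hi, len(arr))
            if b > a:
                agg[a - lo : b - lo] += arr[a:b]
    sm = sliding_mean(agg, smooth)
    from scipy.signal import find_peaks

    # distance enforces dominance over +/- min_separation; plateaus report
    # their midpoint, so a smoothed noiseless spike maps back to its center
    base = float(np.median(sm))
    floor = max(base + rel_height * (float(sm.max()) - base), np.finfo(float).tiny)
    idx, _ = find_peaks(sm, distance=min_separation, height=floor)
    offsets = idx.astype(float) - span
    if len(offsets) < 3:
        raise ValueError("fewer than 3 aggregate peaks detected")
    diffs = np.diff(np.sort(offsets))
    spacing0 = np.median(diffs)
    center = offsets[np.argmin(np.abs(offsets))]
    indices = np.round((offsets - center) / spacing0) + np.round(center / spacing0)
    X = np.vstack([indices, np.ones_like(indices)]).T
    coef, *_ = np.linalg.lstsq(X, offsets, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = offsets - X @ coef
    sd = float(np.sqrt(np.mean(resid**2)))
    return NRLEstimate(slope, intercept, offsets, indices, sd, sm)
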