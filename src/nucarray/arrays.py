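"""Multinomial nucleosome-array template model.

Midpoint counts x_1..x_k in a k bp window are modeled as multinomial with
per-position probabilities lambda_i.  The null is uniform placement,
lambda_i = 1/k; the alternative is a learned "array" template whose peaks
and troughs describe a phased run of nucleosomes.  The test statistic is

    LLR = sum_i x_i * ln(lambda_i / (1/k))        (natural log, nats)

which is linear in the counts.  The template (default geometry: 879 bp
symmetric, spanning 5 nucleosomes) is learned by iterative alignment of
training windows; regions are tested by sliding the template and taking the
maximum LLR; genome scans stride the template and merge surviving windows;
FDRs come from per-region permutation of the midpoint counts.  Around
protein-binding barriers, two mirror-image 1 kb half-templates separated by
a nucleosome-free region (NFR) of fitted width model the flanking arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_from_seed, sliding_mean

__all__ = [
    "ArrayTemplate",
    "LLRResult",
    "FlankingFit",
    "array_llr",
    "train_template",
    "test_region",
    "scan_genome",
    "permute_region",
    "fdr_curve",
    "permutation_fdr",
    "derive_half_templates",
    "fit_flanking_arrays",
    "stratify_and_aggregate",
]

TEMPLATE_FLOOR = 1e-6


@dataclass
class ArrayTemplate:
    """Probability vector over k template positions (floored, sums to 1)."""

    probs: np.ndarray
    symmetric: bool = False
    floor: float = TEMPLATE_FLOOR
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0):
            raise ValueError("template probabilities must be non-negative")
        p = p / p.sum()          # normalize first so the floor acts on
        p = np.maximum(p, self.floor)  # probabilities, not raw counts
        p = p / p.sum()
        if self.symmetric:
            p = (p + p[::-1]) / 2
        self.probs = p

    @property
    def k(self) -> int:
        return len(self.probs)

    @property
    def log_weights(self) -> np.ndarray:
        """ln(lambda_i * k): per-position LLR contribution per midpoint."""
        return np.log(self.probs * self.k)

    @classmethod
    def gaussian_init(cls, k: int = 879, spacing: float = 186.0, sd: float = 20.0,
                      n_nucleosomes: int = 5, symmetric: bool = True) -> "ArrayTemplate":
        """Default initialization: symmetric sum of Gaussian dyad bumps.

        Used when no externally derived (e.g. CTCF-footprint) pattern is
        supplied; fixes the geometry (k bp, n nucleosomes at the given
        spacing) without committing to a learned shape.
        """
        x = np.arange(k)
        center = (k - 1) / 2.0
        p = np.zeros(k)
        for i in range(n_nucleosomes):
            mu = center + (i - (n_nucleosomes - 1) / 2.0) * spacing
            p += np.exp(-0.5 * ((x - mu) / sd) ** 2)
        return cls(p, symmetric=symmetric)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"position": np.arange(self.k), "probability": self.probs}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, symmetric: bool = False) -> "ArrayTemplate":
        df = pd.read_csv(path, sep="\t")
        return cls(df["probability"].to_numpy(), symmetric=symmetric)


def array_llr(counts: np.ndarray, template: ArrayTemplate) -> float:
    """LLR of counts under the template vs the uniform null (nats)."""
    x = np.asarray(counts, dtype=float)
    if len(x) != template.k:
        raise ValueError("counts length must match template width")
    if np.any(x < 0):
        raise ValueError("negative counts")
    return float(x @ template.log_weights)


def _slide_llr(counts: np.ndarray, template: ArrayTemplate,
               slide: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """LLR vs uniform-over-window at every template-midpoint offset.

    The template is composed with a uniform residual over the rest of the
    window: covered positions get lambda_i, uncovered positions get the
    template's mean density 1/k, and the vector is renormalized.  Template
    positions sliding past the window boundary are truncated (data outside
    the window contribute nothing) with the renormalization adjusted for the
    lost template mass.  Returns (offsets, llrs); offsets are template
    midpoint minus window midpoint.
    """
    x = np.asarray(counts, dtype=float)
    W = len(x)
    k = template.k
    lw = template.log_weights
    tmid = (k - 1) // 2
    wmid = (W - 1) // 2
    offs = np.arange(slide[0], slide[1] + 1)
    ts = wmid + offs - tmid  # template start per offset
    lo_pad = max(0, -ts.min())
    hi_pad = max(0, ts.max() + k - W)
    xp = np.concatenate([np.zeros(lo_pad), x, np.zeros(hi_pad)])
    corr_full = np.correlate(xp, lw, mode="valid")
    corr = corr_full[ts + lo_pad]
    # covered template mass and covered-position count per offset
    cdf = np.concatenate([[0.0], np.cumsum(template.probs)])
    a = np.clip(-ts, 0, k)          # first covered template index
    b = np.clip(W - ts, 0, k)       # one past last covered template index
    S = cdf[np.maximum(b, a)] - cdf[a]
    n_cov = np.maximum(b - a, 0)
    n_tot = x.sum()
    c = 1.0 / (S + (W - n_cov) / k)
    llrs = corr + n_tot * np.log(W * c / k)
    return offs, llrs


@dataclass
class LLRResult:
    chrom: str
    start: int
    end: int
    llr: float
    best_offset: int
    n_midpoints: int
    flagged: bool = False


def test_region(counts: np.ndarray, template: ArrayTemplate,
                slide: tuple[int, int] = (-100, 200), step: int = 1,
                chrom: str = "chr", start: int = 0) -> LLRResult:
    """Maximum sliding-template LLR for a 1 kb window of midpoint counts.

    The template midpoint slides from ``slide[0]`` bp upstream to
    ``slide[1]`` bp downstream of the window midpoint in ``step`` bp
    increments; all counts in the window enter each LLR.  A window with no
    midpoints returns LLR 0, flagged.
    """
    x = np.asarray(counts, dtype=float)
    if x.sum() == 0:
        return LLRResult(chrom, start, start + len(x), 0.0, 0, 0, flagged=True)
    offs, llrs = _slide_llr(x, template, slide)
    if step > 1:
        offs, llrs = offs[::step], llrs[::step]
    i = int(np.argmax(llrs))
    return LLRResult(chrom, start, start + len(x), float(llrs[i]), int(offs[i]),
                     int(x.sum()))


def train_template(training_windows: np.ndarray, init: ArrayTemplate,
                   max_iter: int = 30, tol: float = 1e-4, smooth: int = 5,
                   floor: float = TEMPLATE_FLOOR) -> ArrayTemplate:
    """Iteratively learn the template by aligning training windows.

    Each iteration aligns every window at the full-overlap offset maximizing
    the multinomial likelihood under the current template, accumulates the
    aligned midpoint counts, smooths with a ~``smooth`` bp mean, floors,
    renormalizes and (if the init is symmetric) averages with its mirror
    image.  Stops when the L1 change drops below ``tol``.  Deterministic
    given the input order.
    """
    X = np.asarray(training_windows, dtype=float)
    if X.ndim != 2:
        raise ValueError("training_windows must be 2-D (regions x window)")
    n, W = X.shape
    k = init.k
    if W < k:
        raise ValueError("training windows must be at least as wide as the template")
    tmpl = init
    for it in range(max_iter):
        lw = tmpl.log_weights
        acc = np.zeros(k)
        for row in X:
            corr = np.correlate(row, lw, mode="valid")
            j = int(np.argmax(corr))
            acc += row[j : j + k]
        sm = sliding_mean(acc, smooth)
        new = ArrayTemplate(sm, symmetric=tmpl.symmetric, floor=floor,
                            meta={"iterations": it + 1, "n_regions": n})
        delta = float(np.abs(new.probs - tmpl.probs).sum())
        tmpl = new
        if delta < tol:
            break
    else:
        warnings.warn(f"train_template: no convergence in {max_iter} iterations")
    return tmpl


def scan_genome(track, template: ArrayTemplate, step: int = 5,
                llr_min: float = 50.0, min_midpoints: int | None = None,
                mappability: dict[str, np.ndarray] | None = None,
                min_mappable: float = 0.8) -> pd.DataFrame:
    """Stride the template across each chromosome and merge surviving windows.

    At each start (stride ``step``) the LLR of the k-bp window against the
    uniform null is computed; windows with LLR below ``llr_min``, fewer than
    ``min_midpoints`` midpoints (default: k, i.e. one per position), or a
    mappable fraction below ``min_mappable`` are dropped.  Surviving
    overlapping windows are merged into maximal intervals annotated with
    their maximum LLR.  Output is invariant to chromosome traversal order.
    """
    k = template.k
    if min_midpoints is None:
        min_midpoints = k
    lw = template.log_weights
    rows = []
    for chrom in sorted(track.counts):
        x = track.counts[chrom].astype(float)
        if len(x) < k:
            continue
        corr = np.correlate(x, lw, mode="valid")[::step]
        cs = np.concatenate([[0.0], np.cumsum(x)])
        starts = np.arange(0, len(x) - k + 1, step)
        tot = cs[starts + k] - cs[starts]
        ok = (corr >= llr_min) & (tot >= min_midpoints)
        if mappability is not None:
            m = mappability[chrom].astype(float)
            mcs = np.concatenate([[0.0], np.cumsum(m)])
            frac = (mcs[starts + k] - mcs[starts]) / k
            ok &= frac >= min_mappable
        for s, llr in zip(starts[ok], corr[ok]):
            rows.append((chrom, int(s), int(s) + k, float(llr)))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "max_llr"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "llr"])
    merged = []
    for chrom, g in df.groupby("chrom", sort=True):
        g = g.sort_values("start")
        cur = None
        for r in g.itertuples():
            if cur is None or r.start > cur[2]:
                if cur is not None:
                    merged.append(cur)
                cur = [chrom, r.start, r.end, r.llr]
            else:
                cur[2] = max(cur[2], r.end)
                cur[3] = max(cur[3], r.llr)
        if cur is not None:
            merged.append(cur)
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "max_llr"])


def _single_nucleosome_template(sd: float = 20.0, width: int = 147) -> ArrayTemplate:
    x = np.arange(width)
    p = np.exp(-0.5 * ((x - (width - 1) / 2) / sd) ** 2)
    return ArrayTemplate(p, symmetric=True)


def _best_footprint(counts: np.ndarray, single: ArrayTemplate) -> tuple[int, int]:
    """(start, end) of the 147 bp footprint best matching one nucleosome."""
    corr = np.correlate(counts, single.log_weights, mode="valid")
    j = int(np.argmax(corr))
    return j, j + single.k


def _call_footprints(counts: np.ndarray, single: ArrayTemplate,
                     max_calls: int = 5) -> list[tuple[int, int]]:
    """Greedy non-overlapping single-nucleosome footprint calls."""
    x = counts.astype(float).copy()
    out = []
    for _ in range(max_calls):
        if x.sum() == 0:
            break
        a, b = _best_footprint(x, single)
        out.append((a, b))
        x[a:b] = 0.0
    return out


def permute_region(row: np.ndarray, scheme: str, rng: np.random.Generator,
                   single: ArrayTemplate | None = None) -> np.ndarray:
    """One permuted copy of a region's count vector under the given scheme.

    ``full`` shuffles all positions; ``keep_two`` first calls up to five
    greedy single-nucleosome footprints, randomly keeps two fixed and
    shuffles counts among the remaining positions; ``drop_top`` permutes
    fully (the footprint zeroing happens at LLR time).  Total counts are
    conserved exactly under every scheme.
    """
    if scheme == "keep_two":
        if single is None:
            single = _single_nucleosome_template()
        fps = _call_footprints(row, single)
        chosen = [fps[i] for i in rng.choice(len(fps), size=min(2, len(fps)),
                                             replace=False)] if fps else []
        keep_mask = np.zeros(len(row), dtype=bool)
        for a, b in chosen:
            keep_mask[a:b] = True
        shuffled = row.copy()
        free = np.flatnonzero(~keep_mask)
        shuffled[free] = row[free][rng.permutation(len(free))]
        return shuffled
    return row[rng.permutation(len(row))]


def fdr_curve(observed: np.ndarray, permuted: np.ndarray, n_perm: int = 1,
              levels: tuple[float, ...] = (0.01,)) -> tuple[pd.DataFrame, dict]:
    """FDR(t) = #{perm >= t} / (n_perm * #{obs >= t}) over the observed grid.

    Clamped to [0, 1] and made monotone non-increasing in t by the step-up
    rule (each threshold may inherit a smaller estimate from a less
    stringent one).  Thresholds where no observation survives are NA.
    Returns the table and {level: smallest threshold achieving it}.
    """
    obs = np.asarray(observed, dtype=float)
    perm = np.asarray(permuted, dtype=float)
    thresholds = np.sort(np.unique(obs))
    obs_sorted = np.sort(obs)
    perm_sorted = np.sort(perm)
    n_obs_ge = len(obs) - np.searchsorted(obs_sorted, thresholds, side="left")
    n_perm_ge = len(perm) - np.searchsorted(perm_sorted, thresholds, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_obs_ge > 0, n_perm_ge / (n_perm * n_obs_ge), np.nan)
    fdr = np.minimum(raw, 1.0)
    mono = fdr.copy()
    best = np.inf
    for i in range(len(mono)):
        if np.isnan(mono[i]):
            continue
        best = min(best, mono[i])
        mono[i] = best
    table = pd.DataFrame({"threshold": thresholds, "n_obs_ge": n_obs_ge,
                          "n_perm_ge": n_perm_ge, "fdr": mono})
    out = {}
    for level in levels:
        ok = np.flatnonzero(~np.isnan(mono) & (mono <= level))
        out[level] = float(thresholds[ok[0]]) if len(ok) else float("nan")
    return table, out


def permutation_fdr(regions: np.ndarray, template: ArrayTemplate,
                    scheme: str = "full", n_perm: int = 1, seed=0,
                    slide: tuple[int, int] = (-100, 200), step: int = 1,
                    levels: tuple[float, ...] = (0.01,)) -> dict:
    """Permutation-based FDR-versus-threshold table for region LLRs.

    Schemes: ``full`` shuffles each region's per-position counts; ``drop_top``
    zeroes the best single-nucleosome 147 bp footprint (located independently
    in the observed and the permuted data) before computing the LLR;
    ``keep_two`` excludes two randomly chosen called-nucleosome footprints
    from the shuffle.  FDR(t) = #{perm LLR >= t} / (n_perm * #{obs LLR >= t}),
    clamped to [0, 1] and made monotone non-increasing in t.

    Returns a dict with ``observed_llrs``, ``permuted_llrs``, a ``table``
    DataFrame (threshold, n_obs, n_perm, fdr) over the observed LLR grid, and
    ``thresholds`` mapping each requested FDR level to the smallest observed
    LLR achieving it (NaN when unattainable).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng_from_seed(seed)
    X = np.asarray(regions, dtype=float)
    single = _single_nucleosome_template()

    def region_llr(row: np.ndarray) -> float:
        if scheme == "drop_top":
            row = row.copy()
            a, b = _best_footprint(row, single)
            row[a:b] = 0.0
        return test_region(row, template, slide=slide, step=step).llr

    obs = np.array([region_llr(row) for row in X])
    perm = np.array([region_llr(permute_region(row, scheme, rng, single))
                     for row in X for _ in range(n_perm)])
    table, out_thresholds = fdr_curve(obs, perm, n_perm, levels)
    return {"observed_llrs": obs, "permuted_llrs": perm, "table": table,
            "thresholds": out_thresholds}


def derive_half_templates(template: ArrayTemplate, length: int = 1000,
                          period: float | None = None,
                          inner_offset: int = 74) -> tuple[ArrayTemplate, ArrayTemplate]:
    """Mirror-image 1 kb half-templates for arrays phased against a barrier.

    One repeat period centered on the master template's central peak is
    extracted and tiled across ``length`` bp so that the innermost dyad peak
    sits ``inner_offset`` bp from the template's inner end (the NFR edge) —
    the phased +1 nucleosome's core just touches the barrier.  The upstream
    template ends at the NFR edge; the downstream template is its mirror.
    ``period`` defaults to the template's autocovariance peak lag.
    """
    p = template.probs
    k = len(p)
    if period is None:
        period = estimate_template_period(template)
    per = int(round(period))
    center = int(np.argmax(p[k // 2 - per // 2 : k // 2 + per // 2 + 1])) + k // 2 - per // 2
    lo = center - per // 2
    unit = p[lo : lo + per].copy()
    m = int(np.argmax(unit))  # bump peak index within the unit
    i = np.arange(length)
    up = unit[(m + i - (length - inner_offset)) % per]
    down = up[::-1].copy()
    return (ArrayTemplate(up), ArrayTemplate(down))


def estimate_template_period(template: ArrayTemplate,
                             band: tuple[float, float] = (150.0, 250.0)) -> float:
    """Dominant repeat period of the template via autocovariance peak lag."""
    p = template.probs - template.probs.mean()
    ac = np.correlate(p, p, mode="full")[len(p) - 1 :]
    lo, hi = int(band[0]), int(min(band[1], len(ac) - 1))
    if hi <= lo:
        raise ValueError("template too short for the period band")
    return float(lo + np.argmax(ac[lo : hi + 1]))


@dataclass
class FlankingFit:
    nfr_width: int
    nfr_rate: float
    llr: float
    up_start: int      # window-relative start of the upstream 1 kb template
    down_start: int
    left_edge: int     # window-relative NFR edges (alignment anchors)
    right_edge: int
    flat: bool         # likelihood flat (<1 nat) across widths: unidentifiable


def fit_flanking_arrays(window_counts: np.ndarray, up_template: ArrayTemplate,
                        down_template: ArrayTemplate, max_nfr: int = 200,
                        nfr_step: int = 4,
                        center_slide: tuple[int, int, int] = (-50, 50, 5)) -> FlankingFit:
    """ML fit of [upstream array | uniform NFR | downstream array] to a window.

    For each candidate NFR width (0..max_nfr) and small shift of the
    composite center, the composed probability vector places the two 1 kb
    templates on either side of a uniform NFR whose per-site rate equals the
    window mean; positions outside the composite share the same uniform
    rate, so likelihoods are comparable across widths.  Returns the ML
    width, the total LLR against a fully uniform window, and the NFR edge
    coordinates used for cross-region alignment.  When the likelihood is
    flat within 1 nat across widths the fit is flagged unidentifiable.
    """
    x = np.asarray(window_counts, dtype=float)
    W = len(x)
    L = up_template.k
    if W < 2 * L + max_nfr:
        raise ValueError("window must be at least 2 * template + max_nfr wide")
    n_tot = x.sum()
    # uniform-residual composition: template spans get lambda_i, everything
    # else (NFR + outside) gets 1/W; total mass 2 + (W - 2L)/W, constant.
    c = 1.0 / (2.0 + (W - 2 * L) / W)
    lw_up = np.log(up_template.probs * W)  # ln(lambda W); + ln c added at the end
    lw_down = np.log(down_template.probs * W)
    corr_up = np.correlate(x, lw_up, mode="valid")
    corr_down = np.correlate(x, lw_down, mode="valid")
    base = n_tot * np.log(c)
    center = W // 2
    widths = np.arange(0, max_nfr + 1, nfr_step)
    best = None
    llr_by_width = np.full(len(widths), -np.inf)
    for wi, w in enumerate(widths):
        for shift in range(center_slide[0], center_slide[1] + 1, center_slide[2]):
            cpos = center + shift
            le = cpos - w // 2
            re = cpos + (w - w // 2)
            us = le - L
            ds = re
            if us < 0 or ds + L > W:
                continue
            llr = corr_up[us] + corr_down[ds] + base
            if llr > llr_by_width[wi]:
                llr_by_width[wi] = llr
            if best is None or llr > best[0]:
                best = (llr, int(w), us, ds, le, re)
    llr, w, us, ds, le, re = best
    finite = llr_by_width[np.isfinite(llr_by_width)]
    flat = bool(finite.max() - finite.min() < 1.0) if len(finite) > 1 else True
    return FlankingFit(w, float(n_tot / W), float(llr), us, ds, le, re, flat)


def stratify_and_aggregate(fits: list[FlankingFit], windows: np.ndarray,
                           occupancy: pd.DataFrame, n_bins: int = 5,
                           min_support: float = 0.5,
                           max_nfr: int = 200) -> dict[int, dict]:
    """Occupancy-quintile aggregates of barrier windows aligned on NFR edges.

    ``occupancy`` needs columns ``factor`` and ``value``, one row per peak
    (same order as ``fits``/``windows``).  Peaks are ranked within factor,
    pooled across factors into ``n_bins`` quantile bins (factors with fewer
    than ``n_bins`` peaks are excluded with a warning), and each window is
    re-laid on a common axis centered on its NFR midpoint with the flanks
    aligned on the NFR edges.  Columns supported by fewer than
    ``min_support`` of a bin's peaks are masked to NaN.

    Returns {bin: {"offsets", "aggregate", "support", "n"}} with bin 0 the
    lowest-occupancy quantile.
    """
    X = np.asarray(windows, dtype=float)
    n = len(fits)
    if not (len(X) == n == len(occupancy)):
        raise ValueError("fits, windows and occupancy must align")
    bins = np.full(n, -1)
    for factor, g in occupancy.groupby("factor"):
        if len(g) < n_bins:
            warnings.warn(f"factor {factor!r} has fewer than {n_bins} peaks; excluded")
            continue
        ranks = g["value"].rank(method="first").to_numpy()
        q = np.minimum((ranks - 1) * n_bins // len(g), n_bins - 1).astype(int)
        bins[g.index.to_numpy()] = q
    L = 1000
    half_axis = L + max_nfr // 2
    offsets = np.arange(-half_axis, half_axis + 1)
    out = {}
    for b in range(n_bins):
        idx = np.flatnonzero(bins == b)
        agg = np.zeros(len(offsets))
        support = np.zeros(len(offsets))
        for i in idx:
            fit = fits[i]
            row = X[i]
            w = fit.nfr_width
            # upstream flank: offsets -w/2-L .. -w/2 map to us..left_edge
            up_lo = -(w // 2) - L
            seg = row[fit.up_start : fit.left_edge]
            a = up_lo + half_axis
            agg[a : a + len(seg)] += seg
            support[a : a + len(seg)] += 1
            # NFR interior
            seg = row[fit.left_edge : fit.right_edge]
            a = -(w // 2) + half_axis
            agg[a : a + len(seg)] += seg
            support[a : a + len(seg)] += 1
            # downstream flank
            seg = row[fit.right_edge : fit.down_start + L]
            a = (w - w // 2) + half_axis
            agg[a : a + len(seg)] += seg
            support[a : a + len(seg)] += 1
        vals = agg.copy()
        if len(idx):
            vals[support < min_support * len(idx)] = np.nan
        out[b] = {"offsets": offsets, "aggregate": vals, "support": support,
                  "n": len(idx)}
    return out
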