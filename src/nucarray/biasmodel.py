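"""Sequence-bias models and the bias-matched fragment simulator.

MNase cutting is sequence biased: the 4-mers at the first and last four bases
of a fragment (+1..+4 from each end) carry most of the compositional signal.
We learn the end 4-mer frequencies from real fragments, then draw simulated
fragments uniformly over mappable positions and rejection-sample them so
their end 4-mer frequencies match the learned target.  The simulated
midpoints are the empirical null for every downstream positioning statistic.

DNase I nicking bias is modeled analogously with the 6-mer spanning -3..+3
around each nick; the expected nick rate of a 6-mer is its nick count
divided by its genomic occurrence count.

Orientation conventions: the left-end 4-mer is read on the forward strand
from the fragment start; the right-end 4-mer is the reverse complement of
the last four bases, so both ends describe the cut in the same orientation.
Minus-strand DNase contexts are likewise reverse complemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import Genome, revcomp_table, rng_from_seed
from .fragments import FragmentSet, SizeDistribution

__all__ = [
    "KmerBiasTable",
    "DNaseBiasTable",
    "learn_end_kmer_bias",
    "simulate_fragments",
    "learn_dnase_bias",
    "expected_nick_track",
    "normalize_by_expected",
]

_RC4 = revcomp_table(4)
_RC6 = revcomp_table(6)


@dataclass
class KmerBiasTable:
    """End 4-mer frequency tables (left and right ends), pseudocounted."""

    left: np.ndarray  # (256,) frequencies, sum to 1
    right: np.ndarray
    pseudocount: float = 1.0
    n_skipped: int = 0

    def __post_init__(self):
        for name in ("left", "right"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (256,):
                raise ValueError("4-mer table must have 256 entries")
            setattr(self, name, v / v.sum())

    @classmethod
    def uniform(cls) -> "KmerBiasTable":
        u = np.full(256, 1.0 / 256)
        return cls(u.copy(), u.copy())

    def tv_distance(self, other: "KmerBiasTable") -> float:
        """Mean of the left- and right-end total-variation distances."""
        tl = 0.5 * np.abs(self.left - other.left).sum()
        tr = 0.5 * np.abs(self.right - other.right).sum()
        return float((tl + tr) / 2)

    def to_tsv(self, path) -> None:
        from ._util import codes_to_seq

        kmers = ["".join(codes_to_seq(np.array([(c >> (2 * j)) & 3 for j in (3, 2, 1, 0)],
                                               dtype=np.int8))) for c in range(256)]
        pd.DataFrame({"kmer": kmers, "left": self.left, "right": self.right}).to_csv(
            path, sep="\t", index=False)


def _end_kmer_codes(fragments: FragmentSet, genome: Genome) -> tuple[np.ndarray, np.ndarray]:
    """Left/right end 4-mer codes per fragment (-1 where ambiguous/short)."""
    df = fragments.df
    left = np.full(len(df), -1, dtype=np.int64)
    right = np.full(len(df), -1, dtype=np.int64)
    for chrom, g in df.groupby("chrom", sort=False):
        km = genome.kmers(chrom, 4)
        idx = g.index.to_numpy()
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        ok = (starts >= 0) & (starts < len(km)) & (ends - 4 >= 0) & (ends - 4 < len(km))
        left[idx[ok]] = km[starts[ok]]
        rk = km[ends[ok] - 4]
        right[idx[ok]] = np.where(rk >= 0, _RC4[np.where(rk >= 0, rk, 0)], -1)
        left[idx[ok]] = np.where(left[idx[ok]] >= 0, left[idx[ok]], -1)
    return left, right


def learn_end_kmer_bias(fragments: FragmentSet, genome: Genome,
                        pseudocount: float = 1.0) -> KmerBiasTable:
    """Frequencies of the 4-mer at each fragment end, pseudocounted and normalized.

    Fragments whose end 4-mer overlaps an ambiguous base (or runs off the
    chromosome) are skipped and counted in ``n_skipped``.
    """
    left, right = _end_kmer_codes(fragments, genome)
    bad = (left < 0) | (right < 0)
    lc = np.bincount(left[~bad], minlength=256).astype(float) + pseudocount
    rc = np.bincount(right[~bad], minlength=256).astype(float) + pseudocount
    return KmerBiasTable(lc, rc, pseudocount, n_skipped=int(bad.sum()))


def _proposal_end_tables(genome: Genome, mappable: dict[str, np.ndarray] | None) -> KmerBiasTable:
    """End 4-mer distribution of the uniform proposal sampler.

    Under uniform start positions the left-end 4-mer distribution equals the
    genomic 4-mer frequency over allowed positions; the right end is its
    reverse-complement image.
    """
    counts = np.zeros(256)
    for chrom in genome.chroms:
        km = genome.kmers(chrom, 4)
        ok = km >= 0
        if mappable is not None:
            ok = ok & mappable[chrom][: len(km)]
        counts += np.bincount(km[ok], minlength=256)
    counts += 1.0
    return KmerBiasTable(counts.copy(), counts[_RC4].copy())


def simulate_fragments(genome: Genome, size_dist: SizeDistribution,
                       bias: KmerBiasTable | None, n: int,
                       mappability: dict[str, np.ndarray] | None = None,
                       seed=0, max_attempt_factor: int = 200,
                       library: str = "sim") -> FragmentSet:
    """Draw ``n`` bias-matched fragments by rejection sampling.

    Proposals are uniform over positions where the fragment fits on the
    chromosome and (if a mask is given) both end positions are mappable.
    Each proposal is accepted with probability proportional to
    ``target_L(l) * target_R(r) / (proposal_L(l) * proposal_R(r))``,
    normalized by the analytic maximum weight, so accepted fragments follow
    the target end-composition exactly up to left/right dependence induced
    by the genome.  ``bias=None`` (or a uniform table matching the proposal)
    accepts every proposal.  Reproducible given ``seed``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = rng_from_seed(seed)
    chroms = list(genome.chroms)
    sizes = np.array([genome.chroms[c] for c in chroms], dtype=np.int64)
    weights = sizes / sizes.sum()

    if bias is not None:
        prop = _proposal_end_tables(genome, mappability)
        wl = bias.left / prop.left
        wr = bias.right / prop.right
        wmax = wl.max() * wr.max()
    accepted = {c: [] for c in chroms}
    lengths_out = {c: [] for c in chroms}
    total = 0
    attempts = 0
    max_attempts = max_attempt_factor * n
    batch = max(4096, min(n, 1 << 20))
    while total < n and attempts < max_attempts:
        m = batch
        attempts += m
        ci = rng.choice(len(chroms), size=m, p=weights)
        lens = size_dist.sample(m, rng).astype(np.int64)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if not sel.any():
                continue
            L = lens[sel]
            size = sizes[k]
            starts = rng.integers(0, np.maximum(size - L, 1))
            ok = starts + L <= size
            km = genome.kmers(chrom, 4)
            lk = km[np.clip(starts, 0, len(km) - 1)]
            rk_raw = km[np.clip(starts + L - 4, 0, len(km) - 1)]
            ok &= (lk >= 0) & (rk_raw >= 0)
            if mappability is not None:
                mask = mappability[chrom]
                ok &= mask[np.clip(starts, 0, size - 1)]
                ok &= mask[np.clip(starts + L - 1, 0, size - 1)]
            if bias is not None:
                rk = _RC4[np.where(rk_raw >= 0, rk_raw, 0)]
                w = wl[np.where(lk >= 0, lk, 0)] * wr[rk]
                ok &= rng.random(ok.shape) * wmax < w
            accepted[chrom].append(starts[ok])
            lengths_out[chrom].append(L[ok])
            total += int(ok.sum())
    if total < n:
        warnings.warn(f"simulate_fragments: only {total}/{n} fragments accepted")
    rows = []
    for chrom in chroms:
        if accepted[chrom]:
            s = np.concatenate(accepted[chrom])
            ln = np.concatenate(lengths_out[chrom])
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": s + ln}))
    if rows:
        df = pd.concat(rows, ignore_index=True)
        if len(df) > n:  # trim deterministically to the requested count
            df = df.iloc[:n].reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df["library"] = library
    df["strand"] = "."
    df["paired"] = True
    out = FragmentSet(df[["chrom", "start", "end", "library", "strand", "paired"]])
    out.skipped["acceptance_rate"] = total / max(attempts, 1)
    return out


@dataclass
class DNaseBiasTable:
    """Expected nick rate per 6-mer: nick occurrences / genomic occurrences."""

    rate: np.ndarray  # (4096,), NaN where the 6-mer never occurs in the genome
    genome_count: np.ndarray = field(default=None)
    n_excluded: int = 0

    def to_tsv(self, path) -> None:
        pd.DataFrame({"code": np.arange(4096), "rate": self.rate,
                      "genome_count": self.genome_count}).to_csv(path, sep="\t", index=False)


def _nick_context_codes(nicks: pd.DataFrame, genome: Genome) -> np.ndarray:
    """6-mer code spanning -3..+3 around each nick, in read orientation.

    Plus strand: genomic [pos-3, pos+3).  Minus strand: reverse complement of
    genomic [pos-2, pos+4), i.e. the same window in minus-strand coordinates.
    """
    out = np.full(len(nicks), -1, dtype=np.int64)
    for chrom, g in nicks.groupby("chrom", sort=False):
        km = genome.kmers(chrom, 6)
        idx = g.index.to_numpy()
        pos = g["pos"].to_numpy()
        minus = (g["strand"].to_numpy() == "-")
        start = np.where(minus, pos - 2, pos - 3)
        ok = (start >= 0) & (start < len(km))
        codes = np.where(ok, km[np.clip(start, 0, len(km) - 1)], -1)
        rc = np.where(codes >= 0, _RC6[np.where(codes >= 0, codes, 0)], -1)
        out[idx] = np.where(minus, rc, codes)
    return out


def learn_dnase_bias(nicks: pd.DataFrame, genome: Genome) -> DNaseBiasTable:
    """Per-6-mer expected nick rate.

    ``nicks`` needs columns chrom, pos, strand (one row per nick event; use a
    ``count`` column for pre-aggregated tracks).  Genomic occurrences are
    counted on both strands (a minus-strand occurrence of a 6-mer is a
    forward occurrence of its reverse complement), matching the stranded
    read-out of the nick contexts.  6-mers absent from the genome get NaN
    rate and are reported in ``n_excluded``.
    """
    codes = _nick_context_codes(nicks, genome)
    w = nicks["count"].to_numpy() if "count" in nicks else np.ones(len(nicks))
    ok = codes >= 0
    nick_counts = np.bincount(codes[ok], weights=w[ok], minlength=4096)
    gcount = np.zeros(4096)
    for chrom in genome.chroms:
        km = genome.kmers(chrom, 6)
        gcount += np.bincount(km[km >= 0], minlength=4096)
    gcount = gcount + gcount[_RC6]
    rate = np.full(4096, np.nan)
    nz = gcount > 0
    rate[nz] = nick_counts[nz] / gcount[nz]
    n_excl = int((~nz & (nick_counts > 0)).sum())
    return DNaseBiasTable(rate, gcount, n_excl)


def expected_nick_track(bias: DNaseBiasTable, genome: Genome, chrom: str,
                        strand: str = "+") -> np.ndarray:
    """Per-base expected nick rate on one strand from the 6-mer table."""
    size = genome.chroms[chrom]
    km = genome.kmers(chrom, 6)
    out = np.zeros(size)
    if strand == "+":
        start = np.arange(size) - 3
    else:
        start = np.arange(size) - 2
    ok = (start >= 0) & (start < len(km))
    codes = np.where(ok, km[np.clip(start, 0, len(km) - 1)], -1)
    if strand == "-":
        codes = np.where(codes >= 0, _RC6[np.where(codes >= 0, codes, 0)], -1)
    valid = codes >= 0
    r = bias.rate[np.where(valid, codes, 0)]
    out[valid] = np.nan_to_num(r[valid])
    return out


def normalize_by_expected(observed: np.ndarray, expected: np.ndarray,
                          eps: float = 1e-6) -> np.ndarray:
    """Elementwise log2(observed / expected), both sides floored at ``eps``."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have the same shape")
    return np.log2(np.maximum(obs, eps) / np.maximum(exp, eps))
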