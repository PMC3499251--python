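"""Synthetic genomes, fragment sets, DNase nicks and genotype cohorts.

The generator plants the structures the analysis modules are built to
detect, and emits the ground truth needed for parameter-recovery tests:

* random genomes with optional tandem "container" repeat blocks (GC-rich
  unit bounded by AT-rich spacer, unit length ~188 bp) and unmappable
  blocks;
* nucleosome dyad catalogs: regularly spaced arrays (configurable repeat
  length, default 190 bp) and barrier-phased arrays flanking a
  nucleosome-free region (NFR) around planted protein-binding sites;
* paired-end fragments whose dyads follow a major-position / 10 bp-lattice
  / uniform-fuzz occupancy mixture with tunable positioning strength, and
  whose lengths are truncated-normal (mean 152, SD 11.5, bounds 126-184);
* stranded DNase nick tracks with linker enrichment, ~10.2 bp rotational
  modulation phase-locked to each dyad and a 2.5 bp strand phase shift;
* multi-sample cohorts sharing one truth, with genotype-linked barriers
  whose strength scales with allele dosage (2/1/0), plus dsQTL and
  ChIP-summit tables.

Everything is reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import Genome, rng_from_seed
from .biasmodel import KmerBiasTable
from .fragments import FragmentSet

__all__ = [
    "ArraySpec",
    "BarrierSpec",
    "RepeatSpec",
    "DNaseSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_genome",
    "generate_fragments",
    "generate_cohort_fragments",
    "generate_dnase_and_genotypes",
]

NUC_HALF = 73  # half-width of the 147 bp nucleosome core


@dataclass
class ArraySpec:
    start: int
    end: int
    nrl: int = 190
    strength: float = 0.6       # P(dyad drawn from the 10 bp lattice vs fuzz)
    lattice_decay: float = 0.5  # geometric decay of the +/-10, +/-20 positions


@dataclass
class BarrierSpec:
    pos: int
    nfr_width: int = 140
    strength: float = 1.0       # phasing probability at dosage 2
    nrl: int = 190
    n_flank: int = 4            # phased nucleosomes each side of the NFR
    positioning: float = 0.8    # lattice strength of the phased dyads
    lattice_decay: float = 0.5
    genotype_linked: bool = False


@dataclass
class RepeatSpec:
    start: int
    unit_length: int = 188
    n_copies: int = 20
    spacer: int = 40            # AT-rich tail of each unit
    gc_core: float = 0.7
    gc_spacer: float = 0.2


@dataclass
class DNaseSpec:
    n_nicks: int = 100_000      # per strand
    period: float = 10.2        # rotational modulation period (bp)
    phase_shift: float = 2.5    # minus-strand shift (bp)
    amplitude: float = 0.8      # modulation depth within the core
    linker_enrichment: float = 3.0
    nfr_gain: float = 5.0       # extra sensitivity of an active barrier NFR


@dataclass
class SyntheticConfig:
    seed: int
    genome_length: int = 200_000
    chrom: str = "chrS"
    gc: float = 0.5
    n_fragments: int = 100_000
    background_fraction: float = 0.2
    frag_mean: float = 152.0
    frag_sd: float = 11.5
    frag_min: int = 126
    frag_max: int = 184
    arrays: list[ArraySpec] = field(default_factory=list)
    barriers: list[BarrierSpec] = field(default_factory=list)
    repeats: list[RepeatSpec] = field(default_factory=list)
    unmappable: list[tuple[int, int]] = field(default_factory=list)
    end_bias: KmerBiasTable | None = None
    rotational_sequence_signal: bool = False  # plant AA at 10 bp phase in cores
    dnase: DNaseSpec = field(default_factory=DNaseSpec)
    samples: list[str] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    dyads: pd.DataFrame          # pos, weight, kind, barrier_id
    arrays: list[ArraySpec]
    barriers: list[BarrierSpec]
    genotypes: pd.DataFrame | None = None  # barrier id x sample -> class label
    dosages: pd.DataFrame | None = None    # barrier id x sample -> 0/1/2


def _barrier_dyads(b: BarrierSpec) -> np.ndarray:
    left_edge = b.pos - b.nfr_width // 2
    right_edge = b.pos + (b.nfr_width - b.nfr_width // 2)
    right = right_edge + NUC_HALF + np.arange(b.n_flank) * b.nrl
    left = left_edge - NUC_HALF - np.arange(b.n_flank) * b.nrl
    return np.sort(np.concatenate([left, right]))


def generate_genome(config: SyntheticConfig) -> tuple[Genome, dict[str, np.ndarray], SyntheticTruth]:
    """Random genome + mappability mask + planted-dyad truth skeleton."""
    rng = rng_from_seed(np.random.SeedSequence([config.seed, 0]))
    L = config.genome_length
    gc = config.gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=L, p=p).astype(np.int8)
    for rep in config.repeats:
        core = rep.unit_length - rep.spacer
        if rep.start + rep.n_copies * rep.unit_length > L:
            raise ValueError("repeat block exceeds genome")
        gc_c, gc_s = rep.gc_core, rep.gc_spacer
        unit = np.concatenate([
            rng.choice(4, size=core, p=[(1 - gc_c) / 2, gc_c / 2, gc_c / 2, (1 - gc_c) / 2]),
            rng.choice(4, size=rep.spacer, p=[(1 - gc_s) / 2, gc_s / 2, gc_s / 2, (1 - gc_s) / 2]),
        ]).astype(np.int8)
        block = np.tile(unit, rep.n_copies)
        codes[rep.start : rep.start + len(block)] = block

    rows = []
    for a in config.arrays:
        first = a.start + a.nrl // 2
        dy = np.arange(first, a.end - a.nrl // 2 + 1, a.nrl)
        for d in dy:
            rows.append((int(d), 1.0, "array", -1))
    for bi, b in enumerate(config.barriers):
        for d in _barrier_dyads(b):
            rows.append((int(d), 1.0, "barrier", bi))
    dyads = pd.DataFrame(rows, columns=["pos", "weight", "kind", "barrier_id"])
    if len(dyads):
        dyads = dyads[(dyads["pos"] >= NUC_HALF) & (dyads["pos"] < L - NUC_HALF)]
        dyads = dyads.reset_index(drop=True)

    if config.rotational_sequence_signal:
        for d in dyads["pos"]:
            offs = np.arange(-70, 71, 10)
            pos = d + offs
            codes[pos] = 0       # A
            codes[pos + 1] = 0   # A
            codes[pos + 5] = 2   # G at the opposite rotational phase
            codes[pos + 6] = 1   # C

    mask = np.ones(L, dtype=bool)
    for s, e in config.unmappable:
        mask[s:e] = False

    genotypes = dosages = None
    linked = [i for i, b in enumerate(config.barriers) if b.genotype_linked]
    if linked and config.samples:
        g_rng = rng_from_seed(np.random.SeedSequence([config.seed, 1]))
        classes = np.array(["insensitive", "heterozygous", "sensitive"], dtype=object)
        dos = {}
        for bi in linked:
            n = len(config.samples)
            # guarantee all three classes when the cohort allows it
            base = np.array([2, 1, 0] * (n // 3 + 1))[:n]
            dos[bi] = g_rng.permutation(base)
        dosages = pd.DataFrame(dos, index=config.samples).T
        genotypes = dosages.map(lambda d: classes[d])
    truth = SyntheticTruth(dyads, list(config.arrays), list(config.barriers),
                           genotypes, dosages)
    return Genome({config.chrom: codes}), {config.chrom: mask}, truth


def _truncnorm_lengths(n: int, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(n)
    got = 0
    while got < n:
        draw = rng.normal(config.frag_mean, config.frag_sd, size=2 * (n - got) + 16)
        draw = draw[(draw >= config.frag_min) & (draw <= config.frag_max + 1)]
        take = min(len(draw), n - got)
        out[got : got + take] = draw[:take]
        got += take
    lens = np.floor(out).astype(np.int64)
    return np.clip(lens, config.frag_min, config.frag_max)


def _lattice_offsets(n: int, strength: float, decay: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Dyad offsets: major/lattice mixture with uniform fuzz remainder.

    With probability ``strength`` the offset is drawn from {0, +/-10, +/-20}
    with weights proportional to decay**(|offset|/10); otherwise uniform
    over -73..+73.
    """
    offs = np.array([0, -10, 10, -20, 20])
    w = np.array([1.0, decay, decay, decay**2, decay**2])
    w /= w.sum()
    on_lattice = rng.random(n) < strength
    out = np.empty(n, dtype=np.int64)
    k = int(on_lattice.sum())
    out[on_lattice] = rng.choice(offs, size=k, p=w)
    out[~on_lattice] = rng.integers(-NUC_HALF, NUC_HALF + 1, size=n - k)
    return out


def _fragments_from_dyads(dyads: np.ndarray, config: SyntheticConfig,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    lens = _truncnorm_lengths(len(dyads), config, rng)
    starts = dyads - (lens - 1) // 2
    ends = starts + lens
    ok = (starts >= 0) & (ends <= config.genome_length)
    return starts[ok], ends[ok]


def _apply_end_bias(starts, ends, genome: Genome, chrom: str,
                    bias: KmerBiasTable, rng: np.random.Generator):
    from .biasmodel import _RC4

    km = genome.kmers(chrom, 4)
    lk = km[np.clip(starts, 0, len(km) - 1)]
    rk = km[np.clip(ends - 4, 0, len(km) - 1)]
    rk = np.where(rk >= 0, _RC4[np.where(rk >= 0, rk, 0)], -1)
    w = np.where(lk >= 0, bias.left[np.where(lk >= 0, lk, 0)], 0) * \
        np.where(rk >= 0, bias.right[np.where(rk >= 0, rk, 0)], 0)
    wmax = bias.left.max() * bias.right.max()
    keep = rng.random(len(starts)) * wmax < w
    return starts[keep], ends[keep]


def _sample_dyads(config: SyntheticConfig, truth: SyntheticTruth,
                  rng: np.random.Generator, n: int,
                  dosage_by_barrier: dict[int, int] | None = None,
                  mappability: np.ndarray | None = None) -> np.ndarray:
    """Draw n fragment dyads from the planted mixture for one library.

    Barrier dyads are phased with probability strength * dosage / 2; the
    unphased remainder falls uniformly across the barrier's span (NFR
    included), so a dosage-0 allele leaves no footprint.
    """
    L = config.genome_length
    n_bg = int(round(n * config.background_fraction))
    n_nuc = n - n_bg
    dy = truth.dyads
    parts = []
    if n_nuc > 0 and len(dy):
        w = dy["weight"].to_numpy(dtype=float)
        pick = rng.choice(len(dy), size=n_nuc, p=w / w.sum())
        pos = dy["pos"].to_numpy()[pick]
        kind = dy["kind"].to_numpy()[pick]
        bid = dy["barrier_id"].to_numpy()[pick]
        out = np.empty(n_nuc, dtype=np.int64)
        am = kind == "array"
        if am.any():
            # arrays may differ in strength; map each dyad to its spec
            strength = np.full(n_nuc, 0.6)
            decay = np.full(n_nuc, 0.5)
            for a in truth.arrays:
                inside = am & (pos >= a.start) & (pos < a.end)
                strength[inside] = a.strength
                decay[inside] = a.lattice_decay
            # draw per-spec groups to keep vectorized sampling exact
            for s, d in sorted({(s, d) for s, d in zip(strength[am], decay[am])}):
                sel = am & (strength == s) & (decay == d)
                out[sel] = pos[sel] + _lattice_offsets(int(sel.sum()), s, d, rng)
        bm = kind == "barrier"
        if bm.any():
            for bi, b in enumerate(truth.barriers):
                sel = bm & (bid == bi)
                if not sel.any():
                    continue
                dose = 2 if dosage_by_barrier is None else dosage_by_barrier.get(bi, 2)
                p_phased = b.strength * dose / 2.0
                m = int(sel.sum())
                phased = rng.random(m) < p_phased
                d_off = _lattice_offsets(m, b.positioning, b.lattice_decay, rng)
                span = b.n_flank * b.nrl + b.nfr_width // 2 + NUC_HALF
                uni = rng.integers(b.pos - span, b.pos + span + 1, size=m)
                out[sel] = np.where(phased, pos[sel] + d_off, uni)
        parts.append(out)
    if n_bg > 0:
        if mappability is not None:
            ok = np.flatnonzero(mappability)
            parts.append(rng.choice(ok, size=n_bg))
        else:
            parts.append(rng.integers(NUC_HALF, L - NUC_HALF, size=n_bg))
    dyads = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    return np.clip(dyads, 0, L - 1)


def generate_fragments(config: SyntheticConfig, truth: SyntheticTruth,
                       genome: Genome | None = None,
                       mappability: dict[str, np.ndarray] | None = None,
                       library: str = "lib1", n: int | None = None,
                       dosage_by_barrier: dict[int, int] | None = None,
                       seed_stream: int = 2) -> FragmentSet:
    """One library of paired-end fragments from the planted occupancy model."""
    rng = rng_from_seed(np.random.SeedSequence([config.seed, seed_stream]))
    n = config.n_fragments if n is None else n
    mask = mappability[config.chrom] if mappability else None
    dyads = _sample_dyads(config, truth, rng, n, dosage_by_barrier, mask)
    starts, ends = _fragments_from_dyads(dyads, config, rng)
    if config.end_bias is not None and genome is not None:
        starts, ends = _apply_end_bias(starts, ends, genome, config.chrom,
                                       config.end_bias, rng)
    order = np.argsort(starts, kind="stable")
    return FragmentSet.from_arrays(config.chrom, starts[order], ends[order],
                                   library=library)


def generate_cohort_fragments(config: SyntheticConfig, truth: SyntheticTruth,
                              genome: Genome | None = None,
                              mappability: dict[str, np.ndarray] | None = None,
                              n_per_sample: int | None = None) -> dict[str, FragmentSet]:
    """Per-sample libraries sharing one truth, honoring genotype dosages."""
    out = {}
    for si, sample in enumerate(config.samples):
        dos = None
        if truth.dosages is not None:
            dos = {bi: int(truth.dosages.loc[bi, sample]) for bi in truth.dosages.index}
        out[sample] = generate_fragments(
            config, truth, genome, mappability, library=sample,
            n=n_per_sample, dosage_by_barrier=dos, seed_stream=100 + si)
    return out


def _nick_intensity(config: SyntheticConfig, truth: SyntheticTruth, strand: str,
                    dosage_by_barrier: dict[int, int] | None = None) -> np.ndarray:
    """Per-base nick intensity on one strand for one (virtual) sample."""
    d = config.dnase
    L = config.genome_length
    inten = np.ones(L)
    shift = 0.0 if strand == "+" else d.phase_shift
    x = np.arange(-NUC_HALF, NUC_HALF + 1)
    for row in truth.dyads.itertuples():
        scale = 1.0
        if row.kind == "barrier":
            dose = 2 if dosage_by_barrier is None else dosage_by_barrier.get(row.barrier_id, 2)
            scale = dose / 2.0
        if scale == 0:
            continue
        pos = row.pos + x
        ok = (pos >= 0) & (pos < L)
        core = (1.0 / d.linker_enrichment) * (
            1.0 + d.amplitude * np.cos(2 * np.pi * (x - shift) / d.period))
        # blend toward the linker baseline as the phased fraction drops
        inten[pos[ok]] = scale * core[ok] + (1 - scale) * 1.0
    for bi, b in enumerate(truth.barriers):
        dose = 2 if dosage_by_barrier is None else dosage_by_barrier.get(bi, 2)
        gain = 1.0 + d.nfr_gain * b.strength * dose / 2.0
        le = b.pos - b.nfr_width // 2
        re = b.pos + (b.nfr_width - b.nfr_width // 2)
        inten[max(le, 0) : min(re, L)] *= gain
    return inten


def generate_dnase_and_genotypes(config: SyntheticConfig, truth: SyntheticTruth
                                 ) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Stranded nick tracks (per sample), dsQTL table and ChIP-summit table.

    Returns ``(nicks, dsqtls, summits)`` where ``nicks`` maps sample ->
    strand -> {chrom: per-base count array}.  With no samples configured a
    single pooled pseudo-sample named "pooled" is emitted.
    """
    rng = rng_from_seed(np.random.SeedSequence([config.seed, 3]))
    d = config.dnase
    samples = config.samples or ["pooled"]
    nicks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for sample in samples:
        dos = None
        if truth.dosages is not None and sample in truth.dosages.columns:
            dos = {bi: int(truth.dosages.loc[bi, sample]) for bi in truth.dosages.index}
        per_strand = {}
        for strand in "+-":
            inten = _nick_intensity(config, truth, strand, dos)
            p = inten / inten.sum()
            cdf = np.cumsum(p)
            pos = np.searchsorted(cdf, rng.random(d.n_nicks), side="right")
            per_strand[strand] = {config.chrom: np.bincount(
                np.clip(pos, 0, config.genome_length - 1),
                minlength=config.genome_length).astype(np.int64)}
        nicks[sample] = per_strand
    ds_rows = []
    for bi, b in enumerate(config.barriers):
        if b.genotype_linked:
            ds_rows.append((f"dsqtl_{bi}", config.chrom, int(b.pos), int(b.pos),
                            int(b.nfr_width)))
    dsqtls = pd.DataFrame(ds_rows, columns=["id", "chrom", "dsqtl_mid", "snp_pos",
                                            "true_nfr_width"])
    summit_rows = [(f"summit_{bi}", config.chrom, int(b.pos), float(b.strength),
                    int(b.nfr_width))
                   for bi, b in enumerate(config.barriers)]
    summits = pd.DataFrame(summit_rows, columns=["id", "chrom", "pos", "strength",
                                                 "true_nfr_width"])
    return nicks, dsqtls, summits
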