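# Methods

This note records the models, conventions and numerical choices behind
`nucarray`, and what the synthetic-data tests do and do not establish about
real data.

## Fragment processing and dyad inference

Coordinates are 0-based half-open everywhere; BED on disk, 1-based inputs
converted at the boundary. A paired-end fragment's dyad is
`start + (length - 1) // 2` — for even lengths, the left of the two central
bases, a deterministic and strand-independent convention. Single-end reads
get a dyad a fixed offset downstream of the 5' end (default 75 bp, half the
median paired-end fragment length); on the minus strand the 5' end is the
last aligned base and the offset runs leftward. Duplicates are identical
(library, chrom, start, end) tuples removed within each library only,
because amplification duplicates are a per-library artifact; the same
coordinates observed in two libraries are two real fragments. Default
filters: mapping quality ≥ 10 for both mates, fragment length 126–184 bp
(the central 95 % of a 152 ± 11.5 bp truncated-normal size distribution),
with 142–152 bp used for positioning scores. All are parameters.

## Cutting-bias models and the simulated null

MNase bias is summarized by the 4-mers at the fragment ends (+1..+4 from
each end). The left-end 4-mer is read on the forward strand from the
fragment start; the right-end 4-mer is the reverse complement of the last
four bases, so both ends describe the cut in the same orientation. Tables
carry a pseudocount of 1 per 4-mer.

Simulated fragments — the empirical null for every positioning statistic —
are drawn uniformly over mappable positions with lengths sampled from the
observed size histogram, then rejection-sampled with acceptance weight
proportional to `target_L(l)·target_R(r) / (proposal_L(l)·proposal_R(r))`,
normalized by the analytic maximum weight so acceptance is exact. The two
ends are weighted independently; residual left–right dependence induced by
the genome is the only deviation from the target, and is below total
variation 0.02 at 10^5 fragments in the acceptance checks. Mappability is
enforced by rejecting fragments whose end positions are masked — a shortcut
for re-mapping simulated reads with an aligner, which slightly understates
mappability loss in the fragment interior.

DNase I nick bias uses the 6-mer spanning −3..+3 around each nick; minus
strand contexts are the reverse complement of genomic `[pos-2, pos+4)`.
The expected rate of a 6-mer is its nick count divided by its genomic
occurrence count (both strands), which conserves total nicks by
construction. Log-ratios floor both sides at ε = 10⁻⁶.

## Rotational diagnostics

Profiles are dyad-relative (dyad at offset 0; a 147 bp fragment spans
−73..+73). Dinucleotides are counted on the forward genomic strand without
reverse-complement pooling, so all 16 dinucleotides are reported separately.
Periodicity is quantified by a mean-centered, zero-padded (4096-point) power
spectrum: the dominant period inside a band (default 8–12 bp) and the band's
share of non-DC power. The band-share is scale-invariant; where absolute
amplitudes must be compared across profiles on a common count scale (e.g.
phasing amplitude by genotype class), the square root of absolute band power
is used instead. The strand phase shift is read from the cross-spectral
phase at the band peak, which resolves sub-bp lags. The midpoint-phasing
histogram requires ascertainment and test tracks from disjoint library sets
— a guard against amplification artifacts re-entering as a spurious offset-0
spike.

## Positioning scores, empirical FDR, peaks, NRL

`S(i)` is computed by exact windowed sums (cumulative-sum differences), so
it agrees with the double-loop definition to the last bit. Sites near
region edges use midpoint data beyond the region boundary. Ties in the
region maximum break toward the site closest to the region midpoint, then
leftmost — one rule for region scores and peak calling alike.

Empirical p-values are strict exceedance fractions against the simulated
null, floored at 1/(N+1) so the q-value step never sees zero;
π0 uses fixed λ = 0.5. Because scores are ratios of small counts, they are
discrete: at midpoint depths below ~1/bp, ties between observed and null
scores bias π0 slightly below 1 even on null data. The calibration checks
therefore run at ~1.6 midpoints/bp, the deep-coverage regime the method is
designed for (the motivating datasets reach hundreds of fragments per
nucleosome); at low depth the fraction-positioned estimate should be read
with that caveat.

Nucleosome peaks are contiguous runs of per-bp score > 0.4, kept when the
peak score reaches 0.5, with the same tie-break. The NRL is the
least-squares slope of aggregate-midpoint peak offsets against signed peak
index: counts are aggregated around anchor peaks, smoothed with an ~11 bp
centered mean, and local maxima must dominate ±30 bp and rise a quarter of
the way from the aggregate's median to its maximum — the height floor
rejects the ±10 bp rotational-lattice shoulders that flank each major
position. Peak indices come from rounding offsets by the median inter-peak
spacing, so a missed peak does not corrupt the slope. A noiseless lattice is
recovered to machine precision because smoothing a spike yields a plateau
whose midpoint is the spike.

## The array template model

The LLR uses natural log throughout (values in nats). Templates are floored
at ε = 10⁻⁶ *after* normalization and renormalized, preventing −∞
likelihoods while leaving learned troughs intact. The default
initialization, used when no externally derived pattern is supplied, is a
symmetric sum of five Gaussian bumps (SD 20 bp) at 186 bp spacing over
879 bp — the geometry is fixed, the shape is learned. Training alternates
maximum-likelihood alignment of each window with re-accumulation, a 5 bp
mean smoothing, flooring, renormalization and (for symmetric templates)
mirror-averaging, until the L1 change falls below tolerance.

Testing a 1 kb window slides the template midpoint from 100 bp upstream to
200 bp downstream of the window midpoint (as an option, symmetric ranges).
The composed probability vector places the template over its span and
assigns every other window position the template's mean density 1/k before
renormalizing; with this composition a uniform template gives LLR ≡ 0, and
positions outside the template span contribute exactly nothing, so the
statistic reduces to a cross-correlation with ln(λk) and whole-genome scans
are fast. When the slide pushes template positions past the window
boundary, the template is truncated and the renormalization adjusted for
the lost mass.

Genome scans stride the template 5 bp, drop windows below an LLR threshold
(default 50 nats), a midpoint floor (default one per template position — at
lower sequencing depth this should be reduced proportionally) or a
mappability floor, and merge surviving overlaps. Permutation FDRs shuffle
each region's per-position counts (conserving totals); `drop_top` zeroes
the best single-nucleosome 147 bp footprint (located independently in
observed and permuted data) before the LLR, and `keep_two` excludes two
randomly chosen called footprints from the shuffle. FDR(t) is the permuted
exceedance count over the observed one, clamped to [0,1] and made monotone
non-increasing by the step-up rule. One permutation per region is the
default; the calibration and power checks use four to tighten the threshold
estimate at 2000 regions.

Half-templates for barrier fitting tile one repeat period of the master
template so that the innermost dyad peak sits 74 bp — half a nucleosome
core — from the template's inner end: the phased +1 nucleosome's core just
touches the barrier edge. The NFR fit composes
[upstream 1 kb | uniform NFR | downstream 1 kb] with the NFR and all
positions outside the composite at the window-mean rate, which makes
likelihoods comparable across candidate widths; the composite center also
slides ±50 bp. A fit whose likelihood is flat within 1 nat across widths is
flagged unidentifiable. Occupancy stratification ranks peaks within each
transcription factor, pools ranks into quantile bins, aligns windows on
their fitted NFR edges, and masks columns supported by fewer than half of a
bin's peaks.

## dsQTL aggregation

Sensitive regions use a 101 bp centered sliding *mean* (only relative
comparisons matter; mean keeps values interpretable as rates), computed by
exact cumulative sums because the half-peak boundary is a strict inequality
on integer counts. The three filters run in order — edge distance > 100 bp,
overlapping regions (both members of a pair removed), genotype-inconsistent
class means — and re-running the filter on its own output is a fixed point.
Aggregation scales each sample by counts-per-billion of its post-filter
read total; the narrow/large-effect subset uses strict inequalities against
the cohort medians.

## The synthetic-data generator

The generator realizes the occupancy structure the analyses assume, with
interpretable knobs rather than a biophysical energy model:

* **Dyads.** Each planted nucleosome's fragment dyads follow a mixture:
  with probability `strength` an offset from {0, ±10, ±20} bp with weights
  proportional to `decay^(|offset|/10)` (the rotational lattice); otherwise
  uniform fuzz over ±73 bp. `strength=1, decay=0` collapses to a single
  position.
* **Fragments.** Lengths are truncated-normal (mean 152, SD 11.5, bounds
  126–184 bp); fragments are dyad-centered; optional end 4-mer bias is
  applied by thinning.
* **Arrays and barriers.** Arrays place dyads at the configured repeat
  length (default 190 bp). Barriers place an NFR of configured width with
  phased dyads at `edge ± (74 + i·NRL)`; each barrier fragment is phased
  with probability `strength · dosage/2`, the remainder falling uniformly
  over the barrier span, so a dosage-0 allele leaves no footprint.
* **DNase nicks.** Linker baseline with cores depressed by the linker
  enrichment factor (default 3) and modulated sinusoidally at period
  10.2 bp with a 2.5 bp minus-strand shift, phase-locked to each dyad;
  active-barrier NFRs gain sensitivity with dosage.
* **Cohorts.** Samples share one truth; genotype-linked barriers assign
  dosages 2/1/0 covering all classes when the cohort size allows.

What passing tests show — and don't. Recovery tests demonstrate that the
estimators return the planted parameters under the generator's assumptions:
independent fragments, stationary bias, mixture occupancy, additive nick
intensities. Real chromatin violates several of these (correlated digestion,
heterogeneous cell states, unmodeled mappability structure, container
repeats confounding alignment), so synthetic recovery bounds estimator
correctness, not biological accuracy. One known interaction: when the
repeat length is not a multiple of the rotational period, neighboring cores
shift the apparent DNase period slightly (≈0.2 bp at NRL 190, period 10.2),
within the tolerance used.

Problem sizes in the validation suite — a 5 Mb genome with 5×10⁶ fragments
for FDR calibration, 10⁵ nicks for rotational recovery, 5000 regions for
null calibration — were chosen as the smallest sizes at which the
statistical contracts (3 SE bands, ±2 bp recovery) are meaningfully
testable.

## Known limitations

* The simulator matches end 4-mer marginals, not the joint left×right
  distribution, and abstracts read mappability as a mask instead of
  re-mapping simulated reads with an aligner.
* π0 with fixed λ = 0.5 is biased at low sequencing depth by score
  discreteness (see above).
* The genome scan's uniform null spans all template positions; a
  mappability-aware null is available but not the default.
* Single-end dyad inference assumes a fixed fragment length; its error
  grows with digestion variability and is not modeled by the generator.
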