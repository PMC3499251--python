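# nucarray

Nucleosome positioning and phased-array analysis from paired-end MNase-seq
fragment midpoints.

Micrococcal nuclease (MNase) preferentially digests linker DNA, so the
midpoints of size-selected paired-end MNase-seq fragments estimate nucleosome
dyad positions at base-pair resolution. `nucarray` is a library and command
line tool for asking, from such midpoint data, how consistently nucleosomes
are positioned across cells: it quantifies *translational* positioning with
an empirical score against a bias-matched simulated null, detects regularly
spaced *nucleosome arrays* with a multinomial template likelihood-ratio
model, estimates the *nucleosome repeat length* (NRL), characterizes
*rotational* positioning through ~10 bp periodicities in dinucleotide
content and DNase I nicking, and measures how protein-binding barriers — and
SNPs that disrupt them (dsQTLs) — organize the flanking chromatin. It is
aimed at regulatory-genomics analysts working with deep MNase-seq / DNase-seq
data, and ships a fully tested synthetic-data generator so every statistic
can be validated against planted ground truth.

## The statistics at the core

**Positioning score.** For midpoint counts $x_j$ the score of site $i$ is

$$S(i) = \frac{\sum_{|j-i|\le 15} x_j}{\sum_{|j-i|\le 100} x_j},$$

the fraction of midpoints in a 201 bp window that lie within 15 bp of $i$; a
region's score is $\max_i S(i)$. Scores are compared against midpoints
simulated with matched fragment sizes and matched end 4-mer composition
(MNase cutting bias), via empirical p-values and a Storey-type null
proportion $\pi_0 = \#\{p > \lambda\}/(m(1-\lambda))$; $1-\pi_0$ estimates
the fraction of regions positioned better than chance.

**Array template model.** Midpoint counts in a $k$ bp window are modeled as
multinomial with per-position probabilities $\lambda_i$ (a learned "array"
template, by default 879 bp spanning 5 nucleosomes) against the uniform null
$\lambda_i = 1/k$:

$$\mathrm{LLR} = \sum_i x_i \ln\!\big(\lambda_i k\big)\ \text{(nats)}.$$

Templates are learned by iterative maximum-likelihood alignment of training
windows; false-discovery rates come from per-region permutation of the
counts. Around binding-site summits, two mirror-image 1 kb half-templates
separated by a nucleosome-free region (NFR) of fitted width model
barrier-phased arrays.

## Worked example

Plant a 110 kb phased array (repeat length 190 bp, positioning strength
0.6), then score it and recover the repeat length:

```python
import numpy as np
from nucarray import synthdata as sd
from nucarray.fragments import compute_midpoints
from nucarray.positioning import (score_track, call_nucleosome_peaks,
                                  estimate_nrl, score_regions, sample_regions)

cfg = sd.SyntheticConfig(
    seed=1, genome_length=120_000, n_fragments=50_000,
    arrays=[sd.ArraySpec(start=5_000, end=115_000, nrl=190, strength=0.6)])
genome, mask, truth = sd.generate_genome(cfg)
frags = sd.generate_fragments(cfg, truth, genome, mask)
track = compute_midpoints(frags, {cfg.chrom: cfg.genome_length})

regions = sample_regions({cfg.chrom: cfg.genome_length}, n=500, length=200, seed=2)
scores = score_regions(track, regions, min_midpoints=50)
print(f"mean positioning score: {scores['score'].mean():.3f}")

peaks = call_nucleosome_peaks(score_track(track.counts['chrS']), 'chrS')
est = estimate_nrl(track, peaks, span=800)
print(f"nucleosome peaks called: {len(peaks)}")
print(f"estimated repeat length: {est.repeat_length:.1f} bp "
      f"(residual SD {est.residual_sd:.2f} bp)")
```

prints

```
mean positioning score: 0.532
nucleosome peaks called: 479
estimated repeat length: 190.0 bp (residual SD 0.00 bp)
```

The mean score of 0.53 reflects strong planting (a uniform null scores
~0.28 at this depth); the peak caller finds one peak per planted nucleosome
and the regression over aggregate midpoint peaks returns the planted 190 bp
repeat exactly.

The same pipeline runs from the shell:

```bash
nucarray run --config config.yaml --out results/
```

with stages `synth → fragments → score → scan → nrl`, provenance sidecars
next to every output, and byte-identical reruns for a fixed seed. Individual
stages (`nucarray fragments|simulate|score|scan|nrl|train-template|finescale|flank|dsqtl`)
are also exposed directly.

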