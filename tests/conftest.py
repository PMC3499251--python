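import numpy as np
import pytest

from nucarray import synthdata as sd
from nucarray.fragments import compute_midpoints


@pytest.fixture(scope="session")
def array_cohort():
    """One shared synthetic genome with a long phased-array region.

    120 kb genome fully covered by a repeat-length-190 array at positioning
    strength 0.6, 50k fragments — reused by the NRL, scoring and scan tests.
    """
    cfg = sd.SyntheticConfig(seed=1, genome_length=120_000,
                             arrays=[sd.ArraySpec(5000, 115_000)],
                             n_fragments=50_000)
    genome, mask, truth = sd.generate_genome(cfg)
    fragments = sd.generate_fragments(cfg, truth, genome, mask)
    track = compute_midpoints(fragments, {cfg.chrom: cfg.genome_length})
    return {"config": cfg, "genome": genome, "mask": mask, "truth": truth,
            "fragments": fragments, "track": track}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
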