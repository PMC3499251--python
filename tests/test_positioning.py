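import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucarray.fragments import MidpointTrack
from nucarray.positioning import (call_nucleosome_peaks, classify_scores,
                                  estimate_nrl, null_calibration,
                                  positioning_score, sample_regions, score_track)


def oracle_score_track(counts, window=201, near=15):
    """Literal double-loop definition of S(i) (independent of the fast path)."""
    x = np.asarray(counts, dtype=float)
    half = window // 2
    out = np.zeros(len(x))
    for i in range(len(x)):
        den = num = 0.0
        for j in range(max(0, i - half), min(len(x), i + half + 1)):
            den += x[j]
            if abs(j - i) <= near:
                num += x[j]
        out[i] = num / den if den > 0 else 0.0
    return out


class TestScoreTrack:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            x = rng.poisson(1.0, size=rng.integers(50, 300))
            assert np.array_equal(score_track(x), oracle_score_track(x))

    def test_point_mass_scores_one(self):
        x = np.zeros(500)
        x[250] = 60
        assert score_track(x)[250] == 1.0

    def test_uniform_counts_give_31_over_201(self):
        x = np.ones(601)
        assert score_track(x)[300] == pytest.approx(31 / 201)

    def test_three_spike_example(self):
        """Midpoints {-20: 10, 0: 30, +10: 20} about i give S(i) = 50/60."""
        x = np.zeros(401)
        x[200 - 20] = 10
        x[200] = 30
        x[200 + 10] = 20
        assert score_track(x)[200] == pytest.approx(50 / 60)

    def test_scale_invariance(self, rng):
        x = rng.poisson(2.0, 300)
        assert np.allclose(score_track(x), score_track(5 * x))

    @given(st.lists(st.integers(0, 25), min_size=40, max_size=150))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_oracle_equivalence_property(self, xs):
        x = np.array(xs)
        assert np.array_equal(score_track(x, window=31, near=5),
                              oracle_score_track(x, window=31, near=5))

    def test_adding_near_midpoint_never_decreases_score(self, rng):
        for _ in range(50):
            x = rng.poisson(1.0, 300).astype(float)
            s = score_track(x)
            i = int(np.argmax(s[100:200])) + 100
            x2 = x.copy()
            x2[i + rng.integers(-15, 16)] += 1
            assert score_track(x2)[i] >= s[i] - 1e-12


class TestPositioningScore:
    def _track(self, counts):
        return MidpointTrack({"c": np.asarray(counts, dtype=np.int64)})

    def test_region_max_and_validity(self):
        x = np.zeros(1000, dtype=int)
        x[500] = 60
        rec = positioning_score(self._track(x), "c", 400, 600)
        assert rec.score == 1.0 and rec.argmax_site == 500
        assert rec.valid and rec.n_midpoints == 60

    def test_min_midpoints_marks_invalid(self):
        x = np.zeros(1000, dtype=int)
        x[500] = 10
        rec = positioning_score(self._track(x), "c", 400, 600, min_midpoints=50)
        assert not rec.valid

    def test_tie_breaks_toward_region_midpoint(self):
        x = np.zeros(1000, dtype=int)
        x[450] = 60  # scores 1.0 at many sites within +/-15 of the spike
        rec = positioning_score(self._track(x), "c", 400, 600)
        # sites 435..465 all score 1.0; closest to region midpoint 499.5 is 465
        assert rec.argmax_site == 465

    def test_uses_data_beyond_region_boundary(self):
        x = np.zeros(1000, dtype=int)
        x[350] = 10  # outside the region but inside early sites' windows
        x[405] = 50
        rec = positioning_score(self._track(x), "c", 400, 600)
        assert rec.score == pytest.approx(50 / 60)  # outside midpoint dilutes


class TestSampleRegions:
    def test_blacklist_never_intersected(self, rng):
        blacklist = [("c", 4000, 5000)]
        regs = sample_regions({"c": 10_000}, blacklist=blacklist, n=300,
                              length=200, seed=3)
        assert len(regs) == 300
        for r in regs.itertuples():
            assert r.end <= 4000 or r.start >= 5000

    def test_mappable_fraction_threshold(self):
        mask = {"c": np.tile([True, False], 5000)}  # 50% everywhere
        with pytest.warns(UserWarning):
            regs = sample_regions({"c": 10_000}, mappability=mask, n=10,
                                  length=200, min_mappable=0.8, seed=1)
        assert len(regs) == 0

    def test_fully_eligible_genome(self):
        regs = sample_regions({"c": 5000}, n=100, length=200, seed=2)
        assert len(regs) == 100
        assert regs["start"].min() >= 0 and regs["end"].max() <= 5000

    def test_seed_reproducibility(self):
        a = sample_regions({"c": 5000}, n=50, length=200, seed=9)
        b = sample_regions({"c": 5000}, n=50, length=200, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestNullCalibration:
    def test_strict_exceedance_p_value(self):
        p, _, _, _ = null_calibration(np.array([0.5]),
                                      np.array([0.2, 0.3, 0.6, 0.4]))
        assert p[0] == pytest.approx(0.25)

    def test_pi0_clamped_at_one(self):
        # observed scores chosen so empirical p-values are {0.6, 0.7, 0.2, 0.9}
        null = np.arange(0.05, 1.0, 0.1)
        obs = np.array([0.4, 0.3, 0.78, 0.1])
        p, _, pi0, fpos = null_calibration(obs, null, pi0_lambda=0.5)
        assert np.allclose(np.sort(p), [0.2, 0.6, 0.7, 0.9])
        assert pi0 == 1.0 and fpos == 0.0

    def test_self_null_p_values_uniform(self, rng):
        scores = rng.beta(2, 3, size=4000)
        null = rng.beta(2, 3, size=4000)
        p, _, pi0, fpos = null_calibration(scores, null)
        for alpha in (0.01, 0.05, 0.1):
            se = np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs(np.mean(p <= alpha) - alpha) < 3 * se + 1 / len(null)
        assert fpos == pytest.approx(0.0, abs=0.05)

    def test_qvalues_monotone_in_p(self, rng):
        obs = rng.random(500)
        null = rng.random(1000)
        p, q, _, _ = null_calibration(obs, null)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestClassifyScores:
    def test_quartet_example(self):
        out = classify_scores(np.array([0.35, 0.55, 0.75, 0.25]))
        assert out == {"below": 0.25, "weak": 0.25, "moderate": 0.25,
                       "strong": 0.25}

    def test_right_closed_edges(self):
        out = classify_scores(np.array([0.5, 0.5]))
        assert out["weak"] == 1.0

    def test_uniform_scores_match_binomial_oracle(self, rng):
        s = rng.random(1000)
        out = classify_scores(s)
        for key, p in [("weak", 0.2), ("moderate", 0.2), ("strong", 0.3)]:
            se = np.sqrt(p * (1 - p) / 1000)
            assert abs(out[key] - p) < 3 * se


class TestCallNucleosomePeaks:
    def test_plateau_tie_goes_to_run_midpoint(self):
        s = np.zeros(300)
        s[100:111] = 0.6
        peaks = call_nucleosome_peaks(s, "c")
        assert len(peaks) == 1 and peaks.iloc[0]["pos"] == 105

    def test_sub_keep_threshold_discarded(self):
        s = np.zeros(300)
        s[100:111] = 0.45
        assert len(call_nucleosome_peaks(s, "c")) == 0

    def test_two_disjoint_regions_two_peaks(self):
        s = np.zeros(500)
        s[100] = 0.8
        s[400] = 0.9
        peaks = call_nucleosome_peaks(s, "c")
        assert list(peaks["pos"]) == [100, 400]


class TestEstimateNRL:
    def test_noiseless_lattice_exact(self):
        counts = np.zeros(20_000, dtype=np.int64)
        positions = np.arange(1000, 19_000, 190)
        counts[positions] = 100
        track = MidpointTrack({"c": counts})
        anchors = pd.DataFrame({"chrom": "c", "pos": positions})
        est = estimate_nrl(track, anchors, span=800)
        assert abs(est.repeat_length - 190.0) < 1e-9
        assert est.residual_sd < 1e-9

    def test_matches_closed_form_regression_oracle(self):
        """Aggregate peaks at {0, 188, 377, 564} regress to the same slope as
        an independent closed-form least-squares fit."""
        counts = np.zeros(40_000, dtype=np.int64)
        bases = np.array([5000, 15_000, 25_000])
        offs = np.array([0, 188, 377, 564])
        for b in bases:
            counts[b + offs] = 50
        track = MidpointTrack({"c": counts})
        anchors = pd.DataFrame({"chrom": "c", "pos": bases})
        est = estimate_nrl(track, anchors, span=620)
        idx = np.array([0.0, 1.0, 2.0, 3.0])
        slope_oracle = (np.sum((idx - idx.mean()) * (offs - offs.mean()))
                        / np.sum((idx - idx.mean()) ** 2))
        assert est.repeat_length == pytest.approx(slope_oracle, abs=1e-6)

    def test_too_few_anchors_rejected(self):
        track = MidpointTrack({"c": np.zeros(1000, dtype=np.int64)})
        anchors = pd.DataFrame({"chrom": ["c"], "pos": [500]})
        with pytest.raises(ValueError):
            estimate_nrl(track, anchors)

    def test_parameter_recovery_from_generator(self, array_cohort):
        """Planted repeat length 190 recovered within +/-2 bp from 50k fragments."""
        track = array_cohort["track"]
        s = score_track(track.counts["chrS"])
        peaks = call_nucleosome_peaks(s, "chrS")
        est = estimate_nrl(track, peaks, span=800)
        assert est.repeat_length == pytest.approx(190.0, abs=2.0)
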