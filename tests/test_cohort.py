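"""Generator contracts: group contrasts, subject sampling, signal synthesis."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qeeglda as q
from qeeglda.cohort import PARAM_CLIP_HIGH, PARAM_CLIP_LOW
from qeeglda.montage import CHANNELS, FREQ_GRID, POSTERIOR_IDX


class TestGroupProfiles:
    def test_zero_effect_groups_identical(self):
        profiles = [q.make_group_profile(g, 0.0) for g in ("HC", "AD", "VaD")]
        for p in profiles[1:]:
            np.testing.assert_array_equal(p.params, profiles[0].params)

    def test_ad_posterior_alpha_reduced_and_slowed(self):
        hc = q.make_group_profile("HC", 1.0)
        ad = q.make_group_profile("AD", 1.0)
        o1 = CHANNELS.index("O1")
        assert ad.params[o1, 2] < hc.params[o1, 2]  # alpha amplitude A
        assert ad.params[o1, 3] < hc.params[o1, 3]  # alpha center c

    def test_vad_delta_exceeds_ad_everywhere(self):
        ad = q.make_group_profile("AD", 1.0)
        vad = q.make_group_profile("VaD", 1.0)
        assert np.all(vad.params[:, 0] >= ad.params[:, 0])  # S
        assert np.all(vad.params[:, 2] <= q.make_group_profile("HC", 1.0).params[:, 2])

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            q.make_group_profile("MCI", 1.0)
        with pytest.raises(ValueError):
            q.make_group_profile("AD", -0.5)

    @given(effect=st.floats(0.0, 3.0), group=st.sampled_from(["HC", "AD", "VaD"]))
    def test_profile_respects_parameter_bounds(self, effect, group):
        p = q.make_group_profile(group, effect)
        assert np.all(p.params >= PARAM_CLIP_LOW)
        assert np.all(p.params <= PARAM_CLIP_HIGH)


class TestSampleSubject:
    def test_zero_jitter_reproduces_profile(self):
        p = q.make_group_profile("HC", 1.0, jitter_subject=np.zeros(6),
                                 jitter_channel=np.zeros(6))
        truth = q.sample_subject(p, seed=7)
        np.testing.assert_array_equal(truth.params, p.params)

    def test_deterministic_given_seed(self, hc_profile):
        a = q.sample_subject(hc_profile, seed=11)
        b = q.sample_subject(hc_profile, seed=11)
        np.testing.assert_array_equal(a.params, b.params)
        assert a.subject_id == b.subject_id

    def test_sample_mean_alpha_center_unbiased(self, hc_profile):
        """Monte-Carlo: mean of c over many draws matches the profile."""
        draws = np.array([q.sample_subject(hc_profile, seed=s).params[:, 3]
                          for s in range(1000)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - hc_profile.params[:, 3]) < 3 * se + 1e-12)

    def test_parameters_clipped_to_bounds(self, hc_profile):
        for s in range(50):
            params = q.sample_subject(hc_profile, seed=s).params
            assert np.all(params >= PARAM_CLIP_LOW) and np.all(params <= PARAM_CLIP_HIGH)


class TestSynthesizeTimeseries:
    def test_null_spectrum_gives_zero_signal(self, hc_profile):
        truth = q.sample_subject(hc_profile, 1)
        truth.params[:, [0, 2, 5]] = 0.0  # S = A = b = 0
        sig = q.synthesize_timeseries(truth, 10.0, 256.0, seed=3)
        assert np.allclose(sig.data, 0.0)

    def test_invalid_arguments_raise(self, hc_profile):
        truth = q.sample_subject(hc_profile, 1)
        with pytest.raises(ValueError):
            q.synthesize_timeseries(truth, 10.0, 300.0)
        with pytest.raises(ValueError):
            q.synthesize_timeseries(truth, -1.0, 256.0)
        with pytest.raises(ValueError):
            q.synthesize_timeseries(truth, 10.0, 256.0, artifact_rate=1.5)

    def test_welch_average_matches_model_curve(self, hc_profile):
        """Band-integrated power of the epoch-averaged Welch estimate agrees
        with the analytic target, and the error shrinks with more epochs."""
        truth = q.sample_subject(hc_profile, 5)
        band = (FREQ_GRID >= 1.0) & (FREQ_GRID <= 30.0)

        def band_err(duration):
            sig = q.synthesize_timeseries(truth, duration, 256.0, seed=9)
            powers = q.epoch_spectrum(q.segment_epochs(sig))
            avg = powers.mean(axis=0)
            errs = []
            for ch in range(22):
                target = q.model_curve(truth.params[ch], FREQ_GRID)
                errs.append(abs(avg[ch][band].sum() - target[band].sum())
                            / target[band].sum())
            return np.mean(errs)

        err_334 = band_err(335.0)
        err_3340 = band_err(3341.0)
        assert err_334 < 0.05
        assert err_3340 < err_334

    def test_artifact_count_is_binomial(self, hc_profile):
        truth = q.sample_subject(hc_profile, 2)
        rate, dur = 0.02, 540.0
        counts = [len(q.synthesize_timeseries(truth, dur, 256.0, artifact_rate=rate,
                                              seed=s).artifact_times)
                  for s in range(10)]
        mean, sd = rate * dur, np.sqrt(rate * (1 - rate) * dur)
        assert all(abs(c - mean) < 3 * sd for c in counts)
        # injected transients reach the high-amplitude regime
        sig = q.synthesize_timeseries(truth, dur, 256.0, artifact_rate=rate, seed=0)
        assert np.abs(sig.data).max() >= 500.0

    def test_deterministic_given_seed(self, hc_profile):
        truth = q.sample_subject(hc_profile, 4)
        a = q.synthesize_timeseries(truth, 12.0, 256.0, artifact_rate=0.1, seed=8)
        b = q.synthesize_timeseries(truth, 12.0, 256.0, artifact_rate=0.1, seed=8)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.artifact_times == b.artifact_times


class TestSynthesizeCohort:
    def test_two_group_cohort_has_228_subjects(self):
        cfg = q.CohortConfig(groups=("HC", "AD"), n_per_group=114, mode="spectra")
        cohort = q.synthesize_cohort(cfg, seed=1)
        assert len(cohort.subjects) == 228
        assert len(cohort.manifest) == 228
        assert (cohort.manifest.group.value_counts() == 114).all()

    def test_smallest_valid_cohort_direct_spectra(self):
        cfg = q.CohortConfig(groups=("HC", "AD"), n_per_group=2, mode="spectra")
        cohort = q.synthesize_cohort(cfg, seed=1)
        assert len(cohort.subjects) == 4
        for s in cohort.subjects:
            assert s.spectra is not None and s.spectra.subject_id == s.truth.subject_id

    def test_too_small_cohort_raises(self):
        with pytest.raises(ValueError):
            q.synthesize_cohort(q.CohortConfig(n_per_group=1), seed=1)

    def test_reproducible_from_config_and_seed(self):
        cfg = q.CohortConfig(groups=("HC", "VaD"), n_per_group=2,
                             mode="timeseries", duration_s=4.0)
        a = q.synthesize_cohort(cfg, seed=9)
        b = q.synthesize_cohort(cfg, seed=9)
        assert a.manifest.equals(b.manifest)
        np.testing.assert_array_equal(a.subjects[0].signal.data, b.subjects[0].signal.data)

    def test_zero_effect_cohort_groups_exchangeable_in_truth(self):
        """At effect 0 the group label carries no information about the
        true parameters: group-mean differences stay within sampling noise."""
        cfg = q.CohortConfig(groups=("HC", "AD"), n_per_group=100,
                             effect_scale=0.0, mode="spectra")
        cohort = q.synthesize_cohort(cfg, seed=33)
        truth = np.array([s.truth.params for s in cohort.subjects])
        g = cohort.manifest.group.to_numpy()
        diff = truth[g == "HC"].mean(axis=0) - truth[g == "AD"].mean(axis=0)
        pooled_se = truth.std(axis=(0,), ddof=1) * np.sqrt(2 / 100)
        assert np.all(np.abs(diff) < 4 * pooled_se + 1e-12)
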