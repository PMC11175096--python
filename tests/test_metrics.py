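"""Movement-quality metrics against brute-force and closed-form oracles."""

import dataclasses

import numpy as np
import pytest

from movequal.metrics import (
    MetricError,
    ReconstructionParams,
    average_mutual_information,
    compute_profile,
    dominant_frequency,
    false_nearest_neighbors,
    ldlj_per_trial,
    log_dimensionless_jerk,
    lyapunov_rosenstein,
    rms_variability,
    sample_entropy,
    select_embedding_dim,
    select_time_lag,
    symmetry_autocorrelation,
    tolerance_from_baseline,
)
from movequal.segmentation import segment_trial
from movequal.synthetic import SubjectParams, generate_trial

from oracles import (
    ami_bruteforce,
    autocorr_direct,
    benettin_lyapunov,
    fnn_bruteforce,
    lorenz_series,
    minjerk_ldlj_closed_form,
    sampen_bruteforce,
)


# ---------------------------------------------------------------------------
# spectral analysis and reconstruction


class TestDominantFrequency:
    def test_single_tone(self):
        fs, n = 60.0, 1400
        t = np.arange(n) / fs
        f0 = dominant_frequency(np.sin(2 * np.pi * 0.6 * t), fs)
        assert f0 == pytest.approx(0.6, abs=fs / n)

    def test_dominant_of_two_tones(self):
        fs, n = 60.0, 1400
        t = np.arange(n) / fs
        x = 2 * np.sin(2 * np.pi * 0.6 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        assert dominant_frequency(x, fs) == pytest.approx(0.6, abs=fs / n)

    def test_constant_series_rejected(self):
        with pytest.raises(MetricError, match="dominant frequency"):
            dominant_frequency(np.full(1000, 2.0), 60.0)

    def test_white_noise_triggers_separation_warning(self):
        # the flat-spectrum warning should fire in essentially every draw
        import warnings as w

        rng = np.random.default_rng(2024)
        fired = 0
        for _ in range(100):
            x = rng.standard_normal(1400)
            with w.catch_warnings(record=True) as rec:
                w.simplefilter("always")
                dominant_frequency(x, 60.0)
            fired += any("separated" in str(r.message) for r in rec)
        assert fired >= 95


class TestTimeLag:
    def test_ami_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(300)
        n_bins = 8
        ami = average_mutual_information(x, 5, n_bins=n_bins)
        for lag in range(1, 6):
            assert ami[lag] == pytest.approx(
                ami_bruteforce(x, lag, n_bins), abs=1e-10
            )

    def test_sine_lag_is_about_quarter_period(self):
        t = np.arange(3000)
        x = np.sin(2 * np.pi * t / 100)  # 100 samples per cycle
        lag = select_time_lag(x, max_lag=100)
        assert 20 <= lag <= 30

    def test_white_noise_lag_is_one(self, rng):
        x = rng.standard_normal(2000)
        # oracle: for iid noise the AMI at lag 1 has already collapsed to
        # (far) below 5% of the lag-0 information
        assert ami_bruteforce(x, 1, 13) < 0.05 * ami_bruteforce(x, 0, 13)
        assert select_time_lag(x, max_lag=20) == 1

    def test_constant_series_rejected(self):
        with pytest.raises(MetricError, match="constant"):
            select_time_lag(np.ones(100), max_lag=10)


class TestEmbeddingDim:
    def test_fnn_matches_bruteforce_oracle(self):
        x = np.sin(2 * np.pi * np.arange(300) / 25) + 0.01 * np.sin(
            2 * np.pi * np.arange(300) / 7
        )
        for dim in (2, 3):
            mine = false_nearest_neighbors(x, dim, lag=6)
            assert mine == pytest.approx(fnn_bruteforce(x, dim, 6), abs=1e-12)

    def test_sine_embeds_in_two_or_three(self):
        x = np.sin(2 * np.pi * np.arange(1500) / 100)
        x = x + 1e-9 * np.sin(2 * np.pi * np.arange(1500) / 7)  # break exact ties
        assert select_embedding_dim(x, lag=25) in (2, 3)

    def test_lorenz_embeds_between_three_and_five(self):
        x = lorenz_series(2000)
        lag = select_time_lag(x, max_lag=50)
        assert select_embedding_dim(x, lag) in (3, 4, 5)

    def test_too_short_series_rejected(self):
        with pytest.raises(MetricError, match="too short"):
            false_nearest_neighbors(np.arange(10.0), dim=5, lag=3)


# ---------------------------------------------------------------------------
# (1) local dynamic stability


class TestLyapunov:
    def test_periodic_signal_is_neutral(self):
        rng = np.random.default_rng(5)
        t = np.arange(3000)
        x = np.sin(2 * np.pi * t / 100) + 1e-6 * rng.standard_normal(3000)
        recon = ReconstructionParams(
            dominant_freq_hz=0.6,
            time_lag=25,
            embedding_dim=3,
            theiler_window=100,
            # past the initial noise-equilibration shoulder of the curve
            fit_range=(50, 150),
        )
        lam = lyapunov_rosenstein(x, fs=60.0, recon=recon)
        assert abs(lam) < 0.05

    def test_lorenz_within_20pct_of_benettin_oracle(self):
        x = lorenz_series(8000)
        lam_ref = benettin_lyapunov(30000)
        assert lam_ref == pytest.approx(0.906, abs=0.05)  # literature value
        recon = ReconstructionParams(
            dominant_freq_hz=1.3,  # mean orbital frequency of the attractor
            time_lag=11,
            embedding_dim=3,
            theiler_window=100,
            # the linear scaling region sits past the neighbor-convergence
            # transient, roughly 0.6-1.5 mean orbits
            fit_range=(60, 150),
        )
        lam = lyapunov_rosenstein(x, fs=100.0, recon=recon)
        assert lam == pytest.approx(lam_ref, rel=0.20)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = np.sin(2 * np.pi * np.arange(2000) / 90) + 0.01 * rng.standard_normal(2000)
        recon = ReconstructionParams(
            dominant_freq_hz=0.67,
            time_lag=22,
            embedding_dim=3,
            theiler_window=90,
            fit_range=(0, 45),
        )
        lam1 = lyapunov_rosenstein(x, 60.0, recon)
        lam2 = lyapunov_rosenstein(10.0 * x, 60.0, recon)
        assert lam2 == pytest.approx(lam1, abs=1e-6)

    def test_too_few_neighbors_reported_with_count(self):
        recon = ReconstructionParams(
            dominant_freq_hz=1.0,
            time_lag=1,
            embedding_dim=2,
            theiler_window=3,
            fit_range=(0, 5),
        )
        with pytest.raises(MetricError):
            lyapunov_rosenstein(np.sin(np.arange(30.0)), 60.0, recon)


# ---------------------------------------------------------------------------
# (2) predictability


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(60, 1.7), m=2, r=0.1) == 0.0

    def test_alternating_series_is_zero(self):
        x = np.tile([1.0, 2.0], 25)
        assert sample_entropy(x, m=2, r=0.2) == 0.0

    def test_matches_bruteforce_oracle_exactly(self, rng):
        for n in (100, 300):
            x = rng.uniform(size=n)
            r = 0.2 * np.std(x, ddof=1)
            assert sample_entropy(x, 2, r) == pytest.approx(
                sampen_bruteforce(x, 2, r), abs=1e-12
            )

    def test_matches_oracle_on_long_uniform_noise(self, rng):
        x = rng.uniform(size=1400)
        r = 0.2 * np.std(x, ddof=1)
        assert sample_entropy(x, 2, r) == pytest.approx(
            sampen_bruteforce(x, 2, r), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_non_increasing_in_tolerance_at_study_length(self, seed):
        # with study-scale series (n ~ 1400) template matches are plentiful
        # and the conditional match probability rises with r throughout
        x = np.random.default_rng(seed).standard_normal(1400)
        sd = np.std(x, ddof=1)
        values = [sample_entropy(x, 2, f * sd) for f in (0.1, 0.2, 0.4, 0.8)]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_non_increasing_in_tolerance_on_task_signal(self, noisy_trial):
        # from the study tolerance (0.2 SD) upward; below it, matches on a
        # near-periodic signal are sparse and the ratio estimate fluctuates
        seg = segment_trial(noisy_trial)
        sd = np.std(seg.concat_norm, ddof=1)
        values = [
            sample_entropy(seg.concat_norm, 2, f * sd) for f in (0.2, 0.4, 0.8)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_degenerate_no_extension_matches_is_infinite(self):
        # (0, 0) templates match each other but every continuation differs
        # by more than r, so A = 0 and the entropy is flagged infinite
        x = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 2.0, 0.0, 0.0, 3.0, 0.0, 0.0, 4.0])
        with pytest.warns(UserWarning, match="infinite"):
            v = sample_entropy(x, 2, 0.5)
        assert np.isinf(v)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(MetricError, match="positive"):
            sample_entropy(np.arange(10.0), 2, 0.0)
        with pytest.raises(MetricError, match="exceed"):
            sample_entropy(np.arange(3.0), 2, 0.5)


class TestToleranceFromBaseline:
    def test_definition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.5, 5000)
        assert tolerance_from_baseline(x) == pytest.approx(
            0.2 * np.std(x, ddof=1)
        )

    def test_constant_baseline_rejected(self):
        with pytest.raises(MetricError, match="zero tolerance"):
            tolerance_from_baseline(np.ones(100))

    def test_baseline_tolerance_carried_to_followup(self, clean_config):
        """Follow-up entropy must change when the baseline tolerance
        changes, holding the follow-up signal fixed."""
        trial = generate_trial(clean_config, seed=11, timepoint="followup")
        seg = segment_trial(trial)
        e1 = sample_entropy(seg.concat_norm, 2, r=0.5)
        e2 = sample_entropy(seg.concat_norm, 2, r=1.5)
        assert e1 != e2


# ---------------------------------------------------------------------------
# (3) smoothness


def _minjerk_accel(n=200):
    p = np.linspace(0, 1, n)
    return 60 * p - 180 * p**2 + 120 * p**3


class TestLogDimensionlessJerk:
    def test_matches_symbolic_minimum_jerk_oracle(self):
        ref = minjerk_ldlj_closed_form()
        assert ref == pytest.approx(-np.log(21.6), abs=1e-9)  # 720/(100/3)
        val = log_dimensionless_jerk(_minjerk_accel(400), fs=400.0)
        assert val == pytest.approx(ref, rel=0.01)

    def test_duration_invariance(self):
        a = _minjerk_accel(300)
        v1 = log_dimensionless_jerk(a, fs=300.0)  # 1 s stroke
        v2 = log_dimensionless_jerk(a, fs=150.0)  # same shape, 2x slower
        assert v2 == pytest.approx(v1, abs=1e-9)

    def test_amplitude_invariance(self):
        a = _minjerk_accel(300)
        assert log_dimensionless_jerk(5 * a, 300.0) == pytest.approx(
            log_dimensionless_jerk(a, 300.0), abs=1e-12
        )

    def test_ripple_strictly_lowers_smoothness(self):
        n = 600
        fs = 600.0
        a = _minjerk_accel(n)
        t = np.arange(n) / fs
        rippled = a + 0.1 * np.max(np.abs(a)) * np.sin(2 * np.pi * 6 * t)
        assert log_dimensionless_jerk(rippled, fs) < log_dimensionless_jerk(a, fs)

    def test_degenerate_segments_rejected(self):
        with pytest.raises(MetricError, match="short"):
            log_dimensionless_jerk(np.zeros(4), 60.0)
        with pytest.raises(MetricError, match="zero peak"):
            log_dimensionless_jerk(np.full(100, 2.0), 60.0)

    def test_trial_value_is_mean_over_repetitions(self, clean_trial):
        seg = segment_trial(clean_trial)
        per_rep = [
            log_dimensionless_jerk(rep, clean_trial.sample_rate_hz)
            for rep in seg.iter_segments()
        ]
        assert ldlj_per_trial(seg, clean_trial.sample_rate_hz) == pytest.approx(
            np.mean(per_rep)
        )


# ---------------------------------------------------------------------------
# (4) symmetry


class TestSymmetry:
    def test_perfect_repetition_gives_one(self):
        cycle = np.sin(2 * np.pi * np.arange(100) / 100) + 0.3 * np.sin(
            4 * np.pi * np.arange(100) / 100
        )
        x = np.tile(cycle, 14)
        assert symmetry_autocorrelation(x, fs=60.0, f0=0.6) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_matches_direct_autocorrelation_oracle(self, rng):
        x = rng.standard_normal(300)
        fs, f0 = 60.0, 0.6  # search lags 50..150
        val = symmetry_autocorrelation(x, fs, f0)
        direct = max(autocorr_direct(x, k) for k in range(50, 151))
        assert val == pytest.approx(min(direct, 1.0), abs=1e-12)

    def test_alternating_scaling_breaks_symmetry(self):
        cycle = np.sin(2 * np.pi * np.arange(100) / 100)
        clean = np.tile(cycle, 14)
        scaled = np.concatenate([cycle if k % 2 == 0 else 0.5 * cycle for k in range(14)])
        s_clean = symmetry_autocorrelation(clean, 60.0, 0.6)
        s_alt = symmetry_autocorrelation(scaled, 60.0, 0.6)
        assert s_alt < s_clean
        assert s_alt < 1.0

    def test_white_noise_has_low_symmetry(self, rng):
        x = rng.standard_normal(1400)
        assert abs(symmetry_autocorrelation(x, 60.0, 0.6)) < 0.2

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(400)
        assert symmetry_autocorrelation(7 * x, 60.0, 0.6) == pytest.approx(
            symmetry_autocorrelation(x, 60.0, 0.6), abs=1e-12
        )

    def test_window_beyond_series_rejected(self):
        with pytest.raises(MetricError, match="exceeds"):
            symmetry_autocorrelation(np.sin(np.arange(100.0)), 60.0, 0.6)


# ---------------------------------------------------------------------------
# (5) variability


class TestRmsVariability:
    def test_constant_is_zero(self):
        assert rms_variability(np.full(100, 9.81), window=10) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_sine_full_period_window_is_rms(self):
        n, period = 4000, 200
        x = 2.5 * np.sin(2 * np.pi * np.arange(n) / period)
        assert rms_variability(x, window=period) == pytest.approx(
            2.5 / np.sqrt(2), rel=0.01
        )

    def test_homogeneous_of_degree_one(self, rng):
        x = rng.standard_normal(500)
        assert rms_variability(2 * x, 10) == pytest.approx(
            2 * rms_variability(x, 10), rel=1e-12
        )

    def test_window_larger_than_series_rejected(self):
        with pytest.raises(MetricError, match="window"):
            rms_variability(np.zeros(5), window=10)


# ---------------------------------------------------------------------------
# orchestration and degradation monotonicity


class TestComputeProfile:
    def test_clean_trial_is_symmetric_and_regular(self, noisy_trial):
        seg = segment_trial(noisy_trial)
        prof = compute_profile(seg, noisy_trial.sample_rate_hz)
        assert prof.symmetry == pytest.approx(1.0, abs=0.01)
        assert abs(prof.lyapunov) < 1.5
        assert np.isfinite(prof.sample_entropy)
        assert prof.ldlj < 0
        assert prof.variability_rms > 0
        assert prof.recon is not None and prof.recon.time_lag >= 1
        assert prof.lyapunov_per_cycle == pytest.approx(
            prof.lyapunov / prof.recon.dominant_freq_hz
        )

    def test_metric_failures_are_isolated(self, clean_trial):
        # noise-free trial: identical cycles make nearest-neighbor
        # distances degenerate for the Lyapunov stage; other metrics must
        # still be produced
        seg = segment_trial(clean_trial)
        with pytest.warns(UserWarning):
            prof = compute_profile(seg, clean_trial.sample_rate_hz)
        assert prof.symmetry == pytest.approx(1.0, abs=1e-6)
        assert np.isfinite(prof.ldlj)
        assert np.isfinite(prof.variability_rms)

    def test_repeatability_across_noise_seeds(self, noisy_config):
        values = {name: [] for name in ("sample_entropy", "ldlj", "symmetry",
                                        "variability_rms")}
        for seed in range(10):
            trial = generate_trial(noisy_config, seed=seed)
            seg = segment_trial(trial)
            prof = compute_profile(seg, 60.0)
            for name in values:
                values[name].append(getattr(prof, name))
        for name, v in values.items():
            v = np.asarray(v)
            spread = np.ptp(v) / max(abs(np.mean(v)), 1e-9)
            assert spread < 0.15, f"{name} varies {spread:.2%} across noise seeds"


class TestLdljVariants:
    def test_negation_flag_flips_sign_only(self, noisy_trial):
        seg = segment_trial(noisy_trial)
        base = compute_profile(seg, 60.0)
        neg = compute_profile(seg, 60.0, negate_ldlj=True)
        assert neg.ldlj == pytest.approx(-base.ldlj)
        assert neg.symmetry == base.symmetry

    def test_concatenated_variant_is_the_whole_series_value(self, noisy_trial):
        seg = segment_trial(noisy_trial)
        prof = compute_profile(seg, 60.0, ldlj_on_concatenated=True)
        assert prof.ldlj == pytest.approx(
            log_dimensionless_jerk(seg.concat_norm, 60.0)
        )


class TestDegradationMonotonicity:
    """Each generator knob must move its target metric in the documented
    direction (mean over >= 20 seeds)."""

    N_SEEDS = 20

    def _metric_mean(self, config, params, metric_fn):
        vals = []
        for seed in range(self.N_SEEDS):
            trial = generate_trial(config, params=params, seed=seed)
            seg = segment_trial(trial)
            vals.append(metric_fn(seg))
        return float(np.mean(vals))

    def test_amplitude_jitter_raises_entropy(self, noisy_config):
        f = lambda seg: sample_entropy(seg.concat_norm, 2,
                                       0.2 * np.std(seg.concat_norm, ddof=1))
        clean = self._metric_mean(noisy_config, SubjectParams(), f)
        jit = self._metric_mean(
            noisy_config, SubjectParams(amplitude_jitter=0.2), f
        )
        assert jit > clean

    def test_ripple_lowers_smoothness(self, noisy_config):
        f = lambda seg: ldlj_per_trial(seg, 60.0)
        clean = self._metric_mean(noisy_config, SubjectParams(), f)
        rip = self._metric_mean(noisy_config, SubjectParams(ripple_amp=0.3), f)
        assert rip < clean

    def test_alternation_lowers_symmetry(self, noisy_config):
        f = lambda seg: symmetry_autocorrelation(seg.concat_norm, 60.0, 0.6)
        clean = self._metric_mean(noisy_config, SubjectParams(), f)
        alt = self._metric_mean(
            noisy_config, SubjectParams(alternation_factor=0.5), f
        )
        assert alt < clean

    def test_perturbation_raises_lyapunov(self, noisy_config):
        def f(seg):
            recon = ReconstructionParams(
                dominant_freq_hz=0.6,
                time_lag=6,
                embedding_dim=3,
                theiler_window=100,
                fit_range=(0, 50),
            )
            return lyapunov_rosenstein(seg.concat_norm, 60.0, recon)

        clean = self._metric_mean(noisy_config, SubjectParams(), f)
        pert = self._metric_mean(
            noisy_config, SubjectParams(perturbation_sd=0.3), f
        )
        assert pert > clean

    def test_amplitude_jitter_raises_variability(self, noisy_config):
        f = lambda seg: rms_variability(seg.concat_norm, 10)
        clean = self._metric_mean(noisy_config, SubjectParams(), f)
        jit = self._metric_mean(
            noisy_config, SubjectParams(amplitude_jitter=0.2), f
        )
        assert jit > clean
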