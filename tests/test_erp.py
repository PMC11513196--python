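"""ERP quantification: amplitudes, latency, variability, dependability, exclusions."""

import numpy as np
import pytest

import stabnet as sn
from stabnet.datatypes import EpochSet
from stabnet.erp import (
    EmptyTrialSetError,
    ErpMetrics,
    apply_exclusions,
    compute_metrics,
    dependability,
    fractional_area_latency,
    mean_amplitude,
    trial_amplitudes,
    trial_variability,
)
from stabnet.simulate import EpochSpec


def epochs_from_arrays(arrays, sfreq=1000.0, t0=-100.0):
    n = arrays[0].shape[1]
    times = t0 + np.arange(n) * 1000.0 / sfreq
    return EpochSet(
        subject_ids=[f"s{i}" for i in range(len(arrays))],
        epochs=[np.asarray(a, dtype=float) for a in arrays],
        times=times,
        sampling_rate=sfreq,
    )


class TestMeanAmplitude:
    def test_constant_waveform(self):
        es = epochs_from_arrays([np.full((3, 800), 5.0)])
        assert mean_amplitude(es, (0, 100)).iloc[0] == pytest.approx(5.0)

    def test_rectangular_pulse_covering_half_window(self):
        wave = np.zeros(800)
        t = -100 + np.arange(800)  # 1 kHz
        wave[(t >= 0) & (t <= 50)] = -8.0
        es = epochs_from_arrays([wave[None, :]])
        # pulse covers ~half of the 0-100 ms window -> about -4 uV
        assert mean_amplitude(es, (0, 100)).iloc[0] == pytest.approx(-4.0, abs=0.1)

    def test_matches_loop_oracle_on_synthetic_epochs(self):
        es = sn.make_epochs(EpochSpec(n_subjects=3, trials_per_subject=4,
                                      noise_sd=0.0, amp_sd_within=0.0, seed=1))
        got = mean_amplitude(es, (0.0, 100.0))
        mask = (es.times >= 0.0) & (es.times <= 100.0)
        for k, ep in enumerate(es.epochs):
            acc = []
            for trial in ep:  # independent brute-force loop
                s = 0.0
                c = 0
                for j, keep in enumerate(mask):
                    if keep:
                        s += trial[j]
                        c += 1
                acc.append(s / c)
            assert got.iloc[k] == pytest.approx(np.mean(acc), abs=1e-12)

    def test_empty_trial_set_errors(self):
        es = epochs_from_arrays([np.zeros((0, 800))])
        with pytest.raises(EmptyTrialSetError):
            trial_amplitudes(es, (0, 100))


class TestFractionalAreaLatency:
    def _axis(self):
        return np.linspace(-100, 600, 2801)  # 0.25 ms grid

    def test_symmetric_triangle_centered_at_50(self):
        t = self._axis()
        tri = np.where(np.abs(t - 50) <= 30, -(30 - np.abs(t - 50)), 0.0)
        lat = fractional_area_latency(tri, t, (0, 100))
        assert lat == pytest.approx(50.0, abs=0.25)

    def test_rectangular_pulse_midpoint(self):
        t = self._axis()
        rect = np.where((t >= 20) & (t <= 60), -8.0, 0.0)
        assert fractional_area_latency(rect, t, (0, 100)) == pytest.approx(40.0, abs=0.25)

    def test_asymmetric_waveform_matches_dense_trapezoid_oracle(self):
        t = self._axis()
        wave = np.where((t >= 10) & (t < 30), -2.0, 0.0) + np.where(
            (t >= 30) & (t <= 80), -6.0, 0.0
        )
        lat = fractional_area_latency(wave, t, (0, 100))
        # oracle: dense numerical cumulative integral on a 0.001 ms grid
        tf = np.arange(0, 100, 0.001)
        wf = np.interp(tf, t, -wave)
        cum = np.cumsum((wf[1:] + wf[:-1]) / 2) * 0.001
        oracle = tf[1 + int(np.searchsorted(cum, 0.5 * cum[-1]))]
        assert lat == pytest.approx(oracle, abs=0.25)

    def test_amplitude_scaling_invariance(self):
        t = self._axis()
        wave = -np.exp(-0.5 * ((t - 42) / 15.0) ** 2)
        a = fractional_area_latency(wave, t, (0, 100))
        b = fractional_area_latency(10.0 * wave, t, (0, 100))
        assert a == pytest.approx(b, abs=1e-12)

    def test_polarity_restriction_ignores_overshoot(self):
        t = self._axis()
        wave = np.where((t >= 20) & (t <= 60), -8.0, 0.0) + np.where(
            (t > 60) & (t <= 100), 8.0, 0.0
        )
        assert fractional_area_latency(wave, t, (0, 100)) == pytest.approx(40.0, abs=0.25)

    def test_zero_area_returns_nan(self):
        t = self._axis()
        lat = fractional_area_latency(np.zeros_like(t), t, (0, 100))
        assert np.isnan(lat)

    def test_window_validation(self):
        t = self._axis()
        with pytest.raises(ValueError):
            fractional_area_latency(np.zeros_like(t), t, (0, 700))
        with pytest.raises(ValueError):
            fractional_area_latency(np.zeros_like(t), t, (0, 100), fraction=1.5)


class TestTrialVariability:
    def test_identical_trials_zero_within_sd(self):
        es = epochs_from_arrays([np.tile(np.full(800, -3.0), (5, 1))])
        within, _ = trial_variability(es, (0, 100))
        assert within.iloc[0] == pytest.approx(0.0)

    def test_two_trial_closed_form(self):
        tr0, tr1 = np.zeros(800), np.full(800, 2.0)
        es = epochs_from_arrays([np.vstack([tr0, tr1])])
        within, _ = trial_variability(es, (0, 100))
        assert within.iloc[0] == pytest.approx(np.sqrt(2.0))

    def test_recovers_generating_within_sd(self):
        spec = EpochSpec(n_subjects=20, trials_per_subject=1000, amp_sd_within=8.0,
                         noise_sd=0.0, latency_sd=0.0, seed=2)
        es = sn.make_epochs(spec)
        within, _ = trial_variability(es, (0.0, 100.0))
        mask = (es.times >= 0.0) & (es.times <= 100.0)
        shape_mean = np.exp(-0.5 * ((es.times[mask] - 50.0) / 20.0) ** 2).mean()
        # windowed mean scales the trial amplitude by the mean component shape
        assert within.mean() == pytest.approx(8.0 * shape_mean, rel=0.05)

    def test_single_trial_within_sd_missing(self):
        es = epochs_from_arrays([np.zeros((1, 800)), np.random.default_rng(0).normal(size=(4, 800))])
        within, between = trial_variability(es, (0, 100))
        assert np.isnan(within.iloc[0]) and np.isfinite(within.iloc[1])
        assert np.isfinite(between)


class TestDependability:
    def test_noise_free_subjects_get_one(self):
        arrays = [np.tile(np.full(800, v), (6, 1)) for v in (-1.0, -3.0, -6.0)]
        dep = dependability(epochs_from_arrays(arrays), (0, 100))
        assert np.allclose(dep.to_numpy(), 1.0)

    def test_monotone_in_trial_count(self):
        spec_small = EpochSpec(n_subjects=40, trials_per_subject=5, amp_sd_between=2.0,
                               amp_sd_within=8.0, noise_sd=0.0, latency_sd=0.0, seed=3)
        spec_big = EpochSpec(n_subjects=40, trials_per_subject=200, amp_sd_between=2.0,
                             amp_sd_within=8.0, noise_sd=0.0, latency_sd=0.0, seed=3)
        dep_small = dependability(sn.make_epochs(spec_small), (0.0, 100.0)).mean()
        dep_big = dependability(sn.make_epochs(spec_big), (0.0, 100.0)).mean()
        assert dep_big > dep_small

    def test_matches_generating_variance_plug_in(self):
        spec = EpochSpec(n_subjects=50, trials_per_subject=100, amp_sd_between=2.0,
                         amp_sd_within=8.0, noise_sd=0.0, latency_sd=0.0, seed=4)
        es = sn.make_epochs(spec)
        dep = dependability(es, (0.0, 100.0)).mean()
        mask = (es.times >= 0.0) & (es.times <= 100.0)
        g = np.exp(-0.5 * ((es.times[mask] - 50.0) / 20.0) ** 2).mean()
        s2_b, s2_w = (2.0 * g) ** 2, (8.0 * g) ** 2
        plug_in = s2_b / (s2_b + s2_w / 100)
        assert dep == pytest.approx(plug_in, abs=0.05)

    def test_nonpositive_between_variance_warns_and_zeroes(self):
        # identical subject means with nonzero within-trial spread force a
        # negative between-subject variance estimate
        arrays = [
            np.vstack([np.full(800, -5.0 + d), np.full(800, -5.0 - d)])
            for d in (1.0, 2.0, 3.0)
        ]
        with pytest.warns(UserWarning, match="non-positive"):
            dep = dependability(epochs_from_arrays(arrays), (0, 100))
        assert np.allclose(dep.to_numpy(), 0.0)


class TestExclusions:
    def _metric(self, sid, n_trials=30, dep=0.9):
        return ErpMetrics(subject_id=sid, mean_amplitude=-5.0, latency=50.0,
                          n_trials=n_trials, within_sd=8.0, dependability=dep)

    def test_too_few_trials_excluded(self):
        kept, log = apply_exclusions([self._metric("a", n_trials=4), self._metric("b")])
        assert [m.subject_id for m in kept] == ["b"]
        assert log == [{"subject_id": "a", "rule": "min_trials", "value": 4}]

    def test_dependability_boundary_is_inclusive(self):
        kept, log = apply_exclusions(
            [self._metric("a", dep=0.69), self._metric("b", dep=0.70)]
        )
        assert [m.subject_id for m in kept] == ["b"]  # lower than .70 excluded
        assert log[0]["rule"] == "min_dependability"

    def test_trial_boundary_is_inclusive(self):
        kept, _ = apply_exclusions([self._metric("a", n_trials=5)])
        assert len(kept) == 1  # exactly five trials is kept

    def test_all_pass_returns_input(self):
        metrics = [self._metric(f"s{i}") for i in range(4)]
        kept, log = apply_exclusions(metrics)
        assert kept == metrics and log == []


class TestComputeMetricsRoundTrip:
    def test_metrics_and_io(self, tmp_path):
        es = sn.make_epochs(EpochSpec(n_subjects=5, trials_per_subject=20, seed=6))
        metrics = compute_metrics(es)
        assert len(metrics) == 5
        assert all(0 <= m.dependability <= 1 for m in metrics)
        assert all(0.0 <= m.latency <= 100.0 for m in metrics)
        from stabnet.erp import write_metrics, metrics_frame

        write_metrics(metrics, tmp_path / "metrics.csv", [{"subject_id": "x", "rule": "min_trials", "value": 1}])
        assert (tmp_path / "metrics.csv").exists()
        assert (tmp_path / "metrics.exclusions.jsonl").read_text().strip()

    def test_epochset_io_round_trip(self, tmp_path):
        es = sn.make_epochs(EpochSpec(n_subjects=3, trials_per_subject=4, seed=7))
        es.write(tmp_path / "ep")
        back = EpochSet.read(tmp_path / "ep")
        assert back.subject_ids == es.subject_ids
        for a, b in zip(back.epochs, es.epochs):
            assert np.allclose(a, b, atol=1e-9)
        assert np.allclose(back.truth["amplitude"], es.truth["amplitude"])
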