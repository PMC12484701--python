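"""ERP contrast: baseline handling, paired statistics, duration gating."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

from seegkit import erp
from seegkit.exceptions import ParameterError, StatisticsError
from seegkit.preprocess import EpochSet
from seegkit.synth import EvokedEffect, ScenarioConfig, generate_epochs


def _epochs(data, fs=500.0, t0=-1.0, conditions=None, baseline_n=None):
    n_trials = data.shape[0]
    baseline_n = baseline_n if baseline_n is not None else int(-t0 * fs)
    conditions = (
        conditions
        if conditions is not None
        else np.array(["Neg", "Pos"] * (n_trials // 2 + 1))[:n_trials]
    )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        fs=fs,
        conditions=np.asarray(conditions),
        t0_offset_s=t0,
        baseline_slice=slice(0, baseline_n),
        kept_mask=np.ones(n_trials, dtype=bool),
    )


class TestBaselineAndNormalization:
    def test_constant_trial_becomes_zero(self):
        ep = _epochs(np.full((2, 1, 1500), 5.0))
        out = erp.baseline_correct(ep)
        assert np.all(out.data == 0)

    def test_zero_baseline_leaves_stimulus_untouched(self):
        data = np.zeros((2, 1, 1500))
        data[:, :, 500:] = np.linspace(0, 1, 1000)
        out = erp.baseline_correct(_epochs(data))
        np.testing.assert_array_equal(out.data, data)

    def test_baseline_mean_zero_after_correction(self, rng):
        ep = _epochs(rng.standard_normal((6, 3, 1500)))
        out = erp.baseline_correct(ep)
        b = out.data[:, :, out.baseline_slice]
        assert np.abs(b.mean(axis=2)).max() < 1e-9 * np.abs(out.data).max()

    def test_normalization_divides_by_baseline_sd(self, rng):
        data = rng.standard_normal((4, 1, 1500))
        data[:, :, :500] *= 2.0
        data[0, 0, 900] = 10.0
        ep = erp.baseline_correct(_epochs(data))
        out = erp.normalize_trials(ep)
        sd = ep.data[0, 0, :500].std(ddof=1)
        assert out.data[0, 0, 900] == pytest.approx(ep.data[0, 0, 900] / sd)

    def test_zero_baseline_sd_trial_excluded(self, rng):
        data = rng.standard_normal((4, 1, 1500))
        data[2, 0, :500] = 0.0
        out = erp.normalize_trials(_epochs(data))
        assert out.n_trials == 3
        assert not out.kept_mask[2]

    def test_scale_invariance(self, rng):
        data = rng.standard_normal((4, 2, 1500))
        a = erp.normalize_trials(erp.baseline_correct(_epochs(data)))
        b = erp.normalize_trials(erp.baseline_correct(_epochs(10.0 * data)))
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)


class TestAverage:
    def test_identical_trials_idempotent(self, rng):
        x = rng.standard_normal((1, 2, 1500))
        ep = _epochs(np.repeat(x, 2, axis=0), conditions=["Neg", "Neg"])
        ep.conditions = np.array(["Neg", "Pos"])
        times, means = erp.erp_average(ep)
        np.testing.assert_array_equal(means["Neg"], x[0][:, 500:1500])

    def test_window_sample_count(self, rng):
        ep = _epochs(rng.standard_normal((4, 1, 3500)))
        times, means = erp.erp_average(ep, window_s=(0.0, 2.0))
        assert means["Neg"].shape == (1, 1000)

    def test_average_recovers_clean_signal(self, rng):
        """Monte-Carlo oracle: the mean of signal+noise trials stays within
        3 SEM of the clean signal."""
        n, t = 200, 120
        clean = np.sin(2 * np.pi * np.arange(t) / 60.0)
        noise = rng.standard_normal((n, 1, t + 500))
        data = noise.copy()
        data[:, 0, 500:] += clean
        ep = _epochs(data, t0=-1.0)
        _, means = erp.erp_average(ep, window_s=(0.0, t / 500.0))
        both = np.concatenate(
            [means["Neg"], means["Pos"]], axis=0
        ).mean(axis=0)
        sem = 1.0 / np.sqrt(n)
        assert np.abs(both - clean).max() < 3 * sem


class TestPairedT:
    def test_identical_pairs_null(self, rng):
        x = rng.standard_normal((5, 1, 1500))
        ep = _epochs(
            np.concatenate([x, x]), conditions=["Neg"] * 5 + ["Pos"] * 5
        )
        _, t, p = erp.paired_t_timecourse(ep)
        assert np.all(t == 0)
        assert np.all(p == 1)

    def test_constant_difference_p_floor(self):
        x = np.zeros((3, 1, 1500))
        y = x - 2.0
        ep = _epochs(np.concatenate([x, y]), conditions=["Neg"] * 3 + ["Pos"] * 3)
        _, t, p = erp.paired_t_timecourse(ep)
        assert np.all(np.isinf(t))
        assert np.all(p == 0)

    def test_single_pair_rejected(self, rng):
        ep = _epochs(rng.standard_normal((2, 1, 1500)))
        with pytest.raises(StatisticsError):
            erp.paired_t_timecourse(ep)

    def test_power_at_planted_effect(self, rng):
        """1.5-SD per-sample effect, 12 pairs: per-sample detection power
        exceeds 0.9 inside the effect span (1000 replicate simulation)."""
        reps, n, span = 1000, 12, 41
        diff = rng.standard_normal((reps, n, span)) + 1.5
        t, p = erp.paired_t(diff.transpose(1, 0, 2), axis=0)
        assert (p < 0.05).mean() > 0.9

    def test_label_swap_negates_t(self, rng):
        data = rng.standard_normal((10, 2, 1500))
        data[:5, :, 700:900] += 0.8
        ep = _epochs(data, conditions=["Neg"] * 5 + ["Pos"] * 5)
        swapped = _epochs(data, conditions=["Pos"] * 5 + ["Neg"] * 5)
        _, t1, p1 = erp.paired_t_timecourse(ep)
        _, t2, p2 = erp.paired_t_timecourse(swapped)
        np.testing.assert_array_equal(t1, -t2)
        np.testing.assert_array_equal(p1, p2)


class TestSignificantIntervals:
    fs = 500.0

    def test_all_nonsignificant(self):
        assert erp.significant_intervals(np.ones(100), self.fs) == []

    def test_strict_duration_gate(self):
        """30 ms exactly (15 samples at 500 Hz) is excluded; 32 ms survives."""
        p = np.ones(100)
        p[10:25] = 0.01  # 15 samples
        assert erp.significant_intervals(p, self.fs) == []
        p[10:26] = 0.01  # 16 samples
        out = erp.significant_intervals(p, self.fs)
        assert len(out) == 1
        assert out[0] == pytest.approx((10 / self.fs, 26 / self.fs))

    def test_interrupted_runs_not_merged(self):
        p = np.ones(100)
        p[10:26] = 0.01
        p[26] = 0.5
        p[27:43] = 0.01
        assert len(erp.significant_intervals(p, self.fs)) == 2

    def test_invalid_p_rejected(self):
        with pytest.raises(ParameterError):
            erp.significant_intervals(np.array([0.5, 1.5]), self.fs)

    def test_gate_reduces_null_false_positives(self, rng):
        """Duration gating strictly lowers the per-course false-interval
        rate under the null (smooth-noise simulation)."""
        reps, n, t = 400, 8, 300
        white = rng.standard_normal((reps, n, t + 8))
        smooth = np.cumsum(white, axis=-1)[:, :, 8:] - np.cumsum(white, axis=-1)[:, :, :-8]
        tt, pp = erp.paired_t(smooth, axis=1)
        gated = sum(bool(erp.significant_intervals(pp[r], self.fs)) for r in range(reps))
        ungated = sum(
            bool(erp.significant_intervals(pp[r], self.fs, min_dur_s=0.0))
            for r in range(reps)
        )
        assert gated < ungated


class TestDivergenceLatency:
    def _contrast(self, intervals, direction):
        n_t = 1000
        return erp.ErpContrast(
            time_axis_s=np.arange(n_t) / 500.0,
            mean_neg=np.zeros((1, n_t)),
            mean_pos=np.zeros((1, n_t)),
            t_course=np.zeros((1, n_t)),
            p_course=np.ones((1, n_t)),
            sig_intervals=[intervals],
            onset_latency_s=np.array([np.nan]),
            direction=[direction],
            channel_names=["ch0"],
            alpha=0.05,
            min_dur_s=0.03,
        )

    def test_earliest_interval_start(self):
        c = self._contrast([(0.52, 0.60), (1.1, 1.2)], [1, -1])
        lat, direction = erp.divergence_latency(c)
        assert lat[0] == pytest.approx(0.52)
        assert direction == [1]

    def test_no_intervals_is_nan(self):
        lat, direction = erp.divergence_latency(self._contrast([], []))
        assert np.isnan(lat[0])
        assert direction == [None]

    def test_latency_recovery_from_planted_effect(self):
        """A planted Neg>Pos divergence at 520 ms is recovered within
        [0.50, 0.56] s in >= 90% of simulation replicates."""
        cfg = ScenarioConfig(
            n_channels_per_roi={"Amy": 1},
            n_trials_per_condition=30,
            evoked_effects=(EvokedEffect("Amy", 0.52, 0.40, 3.0, "neg_up"),),
            line_noise=dataclasses.replace(ScenarioConfig().line_noise, amplitude_uv=0.0),
        )
        hits = 0
        reps = 20
        for rep in range(reps):
            cfg = dataclasses.replace(cfg, seed=100 + rep)
            subjects = [
                generate_epochs(cfg, sid, epoch_window=(-1.0, 1.2))[0]
                for sid in range(12)
            ]
            contrast = erp.erp_contrast(subjects, window_s=(0.0, 1.2))
            lat = contrast.onset_latency_s[0]
            if np.isfinite(lat) and 0.50 <= lat <= 0.56:
                hits += 1
        assert hits >= 0.9 * reps


class TestContrastProperties:
    def test_interval_detection_channel_order_invariant(self, rng):
        data = rng.standard_normal((12, 3, 1500))
        data[:6, 1, 800:1000] += 1.2
        ep = _epochs(data, conditions=["Neg"] * 6 + ["Pos"] * 6)
        c1 = erp.erp_contrast(ep)
        perm = [2, 0, 1]
        ep2 = _epochs(data[:, perm], conditions=["Neg"] * 6 + ["Pos"] * 6)
        c2 = erp.erp_contrast(ep2)
        for new_idx, old_idx in enumerate(perm):
            assert c2.sig_intervals[new_idx] == c1.sig_intervals[old_idx]
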