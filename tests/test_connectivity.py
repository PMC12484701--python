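"""Phase-locking value: identities, estimator behaviour, baseline adjustment."""
import numpy as np
import pytest
from scipy import signal

from seegkit import connectivity as conn
from seegkit.exceptions import ParameterError, StatisticsError
from seegkit.io import ChannelInfo
from seegkit.preprocess import EpochSet
from seegkit.spectral import DEFAULT_BANDS, BandDefinition

from conftest import plv_bruteforce

FS = 500.0
DELTA, GAMMA = DEFAULT_BANDS[0], DEFAULT_BANDS[4]


def _epochs(data, shafts=None, rois=None):
    n_trials, n_ch, _ = data.shape
    shafts = shafts or [f"S{i}" for i in range(n_ch)]
    rois = rois or ["Amy"] * n_ch
    return EpochSet(
        data=np.asarray(data, dtype=float),
        fs=FS,
        conditions=np.array(["Neg"] * n_trials),
        t0_offset_s=-1.0,
        baseline_slice=slice(0, int(FS)),
        kept_mask=np.ones(n_trials, dtype=bool),
        channels=[
            ChannelInfo(f"C{i}", shafts[i], 1, roi=rois[i]) for i in range(n_ch)
        ],
    )


def _band_noise(rng, shape, band, fs=FS):
    x = rng.standard_normal(shape)
    sos = signal.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


class TestNarrowbandAndPhase:
    def test_in_band_tone_passes(self):
        t = np.arange(3500) / FS
        ep = _epochs(np.sin(2 * np.pi * 2.0 * t)[None, None, :])
        out = conn.narrowband_filter(ep, DELTA)
        assert np.std(out.data[0, 0, 500:-500]) >= 0.9 * np.std(ep.data[0, 0, 500:-500])

    def test_out_of_band_tone_suppressed(self):
        t = np.arange(3500) / FS
        ep = _epochs(np.sin(2 * np.pi * 2.0 * t)[None, None, :])
        out = conn.narrowband_filter(ep, GAMMA)
        att = 20 * np.log10(np.std(ep.data) / max(np.std(out.data[0, 0, 500:-500]), 1e-300))
        assert att >= 20.0

    def test_zero_in_zero_out(self):
        ep = _epochs(np.zeros((1, 1, 3500)))
        assert np.allclose(conn.narrowband_filter(ep, DELTA).data, 0.0)

    def test_analytic_signal_phase_identities(self):
        t = np.arange(int(FS * 10)) / FS
        k = int(FS * 2)  # interior sample at an integer number of periods
        phase_cos = conn.instantaneous_phase(np.cos(2 * np.pi * 5.0 * t))
        phase_sin = conn.instantaneous_phase(np.sin(2 * np.pi * 5.0 * t))
        assert phase_cos[k] == pytest.approx(0.0, abs=1e-3)
        assert phase_sin[k] == pytest.approx(-np.pi / 2, abs=1e-3)

    def test_phase_slope_matches_frequency(self):
        t = np.arange(int(FS * 6)) / FS
        phase = conn.instantaneous_phase(np.sin(2 * np.pi * 6.0 * t))
        n = phase.size
        interior = slice(int(0.1 * n), int(0.9 * n))
        slope = np.polyfit(t[interior], np.unwrap(phase)[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.01)


class TestPlvIdentities:
    def test_identical_series(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 1000)
        assert conn.plv(phase, phase) == pytest.approx(1.0)

    def test_constant_offset(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 1000)
        assert conn.plv(phase, phase + np.pi / 3) == pytest.approx(1.0)

    def test_symmetry_and_self(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        assert conn.plv(a, b) == conn.plv(b, a)
        assert conn.plv(a, a) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            conn.plv(np.zeros(10), np.zeros(11))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            a = rng.uniform(-np.pi, np.pi, 300)
            b = rng.uniform(-np.pi, np.pi, 300)
            assert conn.plv(a, b) == pytest.approx(plv_bruteforce(a, b), abs=1e-12)

    def test_null_level_matches_rayleigh_oracle(self, rng):
        """Independent uniform phases at N=1e4: mean PLV within 10% of the
        Monte-Carlo null oracle (~sqrt(pi)/2/sqrt(N))."""
        n, reps = 10_000, 400
        vals = [
            conn.plv(rng.uniform(-np.pi, np.pi, n), rng.uniform(-np.pi, np.pi, n))
            for _ in range(reps)
        ]
        # oracle via independent resultant-length simulation
        z = rng.uniform(-np.pi, np.pi, (reps, n))
        oracle = np.hypot(
            np.cos(z).mean(axis=1), np.sin(z).mean(axis=1)
        ).mean()
        assert np.mean(vals) == pytest.approx(oracle, rel=0.10)
        assert oracle == pytest.approx(np.sqrt(np.pi) / 2 / np.sqrt(n), rel=0.10)

    def test_common_offset_and_amplitude_invariance(self, rng):
        a = rng.uniform(-np.pi, np.pi, 800)
        b = rng.uniform(-np.pi, np.pi, 800)
        assert conn.plv(a + 1.3, b + 1.3) == pytest.approx(conn.plv(a, b), abs=1e-12)
        x = _band_noise(rng, (1, 2, 3500), DELTA)
        r1 = conn.trial_plv(_epochs(x), bands=(DELTA,), pairs=[(0, 1)])
        r2 = conn.trial_plv(_epochs(x * 25.0), bands=(DELTA,), pairs=[(0, 1)])
        assert r1.plv_raw[0, 0] == pytest.approx(r2.plv_raw[0, 0], abs=1e-9)


class TestTrialPlv:
    def test_shared_tone_high_plv(self, rng):
        t = np.arange(3500) / FS
        tone = np.sin(2 * np.pi * 6.0 * t)
        data = np.stack(
            [
                np.stack([tone + 0.05 * rng.standard_normal(t.size) for _ in range(2)])
                for _ in range(10)
            ]
        )
        res = conn.trial_plv(_epochs(data), bands=(DEFAULT_BANDS[1],), pairs=[(0, 1)])
        assert res.plv_raw[0, 0] > 0.9

    def test_independent_noise_below_shuffle_null(self, rng):
        """Independent channels score below the 95th percentile of the
        trial-shuffled surrogate distribution."""
        data = _band_noise(rng, (20, 2, 3500), DELTA)
        res = conn.trial_plv(_epochs(data), bands=(DELTA,), pairs=[(0, 1)])
        null = []
        for _ in range(100):
            perm = rng.permutation(20)
            shuffled = np.stack([data[:, 0], data[perm, 1]], axis=1)
            null.append(
                conn.trial_plv(_epochs(shuffled), bands=(DELTA,), pairs=[(0, 1)]).plv_raw[0, 0]
            )
        assert res.plv_raw[0, 0] <= np.quantile(null, 0.95)

    def test_across_trials_needs_eight(self, rng):
        data = rng.standard_normal((1, 2, 3500))
        with pytest.raises(StatisticsError):
            conn.trial_plv(_epochs(data), mode="across_trials")

    def test_cross_shaft_pair_restriction(self, rng):
        data = rng.standard_normal((2, 3, 3500))
        ep = _epochs(data, shafts=["A", "A", "B"])
        res = conn.trial_plv(ep, bands=(DELTA,))
        assert res.pair_index == [(0, 2), (1, 2)]


class TestBaselineAdjust:
    def _result(self, values):
        values = np.asarray(values, dtype=float)
        return conn.PlvResult(
            band_names=("delta",),
            plv_raw=values,
            pair_index=[(0, 1)],
            channels=[
                ChannelInfo("a", "A", 1, roi="Amy"),
                ChannelInfo("b", "B", 1, roi="Hip"),
            ],
            window_s=(0.0, 2.0),
            n_trials=10,
            mode="within_trial",
        )

    def test_identical_windows_zero(self):
        out = conn.baseline_adjust(self._result([[0.5]]), self._result([[0.5]]))
        assert np.all(out.plv_adjusted == 0)

    def test_subtraction(self):
        out = conn.baseline_adjust(self._result([[0.6]]), self._result([[0.2]]))
        assert out.plv_adjusted[0, 0] == pytest.approx(0.4)

    def test_pair_mismatch_rejected(self):
        base = self._result([[0.2]])
        base.pair_index = [(0, 2)]
        with pytest.raises(ParameterError):
            conn.baseline_adjust(self._result([[0.6]]), base)

    def test_surrogate_adjusted_centered_on_zero(self, rng):
        """Stimulus and baseline windows of equal length drawn from the same
        null process: adjusted PLV is centered on 0 (|mean| < 2 SE over 200
        surrogates).  Matched lengths matter: the finite-sample null level of
        PLV depends on the number of effective samples in the window."""
        vals = []
        for _ in range(200):
            data = _band_noise(rng, (6, 2, 3500), DEFAULT_BANDS[1])
            res = conn.condition_plv(
                _epochs(data), bands=(DEFAULT_BANDS[1],),
                stim_window_s=(2.0, 2.8), baseline_window_s=(0.5, 1.3),
                pairs=[(0, 1)],
            )
            vals.append(res.plv_adjusted[0, 0])
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 2 * vals.std(ddof=1) / np.sqrt(vals.size)

    def test_null_plv_decreases_with_window_length(self, rng):
        """Longer windows average more independent phase increments, so the
        finite-sample null PLV of independent 1/f channels shrinks."""
        means = []
        for win in (1.0, 2.0, 4.0, 6.0):
            vals = []
            for _ in range(12):
                n = int((win + 1.4) * FS)
                spec_shape = np.zeros(n // 2 + 1)
                f = np.fft.rfftfreq(n, 1 / FS)
                spec_shape[1:] = f[1:] ** -0.5
                x = np.fft.irfft(
                    (rng.standard_normal((4, 2, f.size))
                     + 1j * rng.standard_normal((4, 2, f.size))) * spec_shape,
                    n=n, axis=-1,
                )
                ep = EpochSet(
                    data=x, fs=FS, conditions=np.array(["Neg"] * 4),
                    t0_offset_s=-0.7, baseline_slice=slice(0, 100),
                    kept_mask=np.ones(4, dtype=bool),
                    channels=[ChannelInfo("a", "A", 1), ChannelInfo("b", "B", 1)],
                )
                res = conn.trial_plv(ep, bands=(DELTA,), window_s=(0.0, win), pairs=[(0, 1)])
                vals.append(res.plv_raw[0, 0])
            means.append(np.mean(vals))
        assert means == sorted(means, reverse=True)


class TestRegionSummary:
    def test_singleton_region_pair(self, rng):
        data = rng.standard_normal((3, 2, 3500))
        ep = _epochs(data, rois=["Amy", "Hip"])
        res = conn.trial_plv(ep, bands=(DELTA,))
        out = conn.region_pair_summary(res)
        row = out[(out.roi_a == "Amy") & (out.roi_b == "Hip")].iloc[0]
        assert row["plv"] == pytest.approx(res.plv_raw[0, 0])
        assert row["n_pairs"] == 1

    def test_unassigned_channels_excluded(self, rng):
        data = rng.standard_normal((3, 3, 3500))
        ep = _epochs(data, rois=["Amy", "unassigned", "Hip"])
        out = conn.region_pair_summary(conn.trial_plv(ep, bands=(DELTA,)))
        assert set(out.roi_a) | set(out.roi_b) == {"Amy", "Hip"}
        assert (out.n_pairs == 1).all()
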