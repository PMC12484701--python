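"""Synthetic two-condition SEEG-like sessions with planted ground truth.

The generator emulates the recording paradigm the analysis chain expects:
multichannel depth-electrode sessions at 2048 Hz, one shaft per region of
interest, 1/f ("pink") background activity with optional 50 Hz line
contamination, and 60 interleaved Neg/Pos picture presentations (1 s rest,
1 s fixation baseline, 6 s picture, cyclic 1-6 s inter-trial gap).

Three planted effect families mirror the statistical structure the pipeline
is meant to recover:

* **Evoked transients** — truncated-Gaussian deflections (SD = duration/4,
  support [latency, latency + duration]) planted with opposite
  half-amplitude in the two conditions (Neg +A/2, Pos -A/2, polarity set by
  the ``neg_up``/``neg_down`` direction).  The symmetric split makes the
  condition *difference* equal to the full amplitude while keeping evoked
  power identical across conditions, so the transients are invisible to the
  band-power contrast — matching the empirical dissociation between
  time-domain and spectral effects.  Amplitude decays as 1/contact along the
  shaft so the deflection survives bipolar referencing.
* **Band power effects** — the band-limited component of the background is
  scaled by sqrt(neg_scale) during Neg stimulation windows (cosine-ramped),
  scaling Neg band power by exactly ``neg_scale``.
* **Phase coupling** — a shared narrowband source is mixed into the
  band-limited component of every coupled region with alternating sign
  across contacts (a local dipole pattern) plus a per-shaft common-mode
  compensator, a construction that preserves band power of both the
  monopolar contacts and their bipolar derivations.  The mixing fraction is
  solved by bisection against a Monte-Carlo estimate of the connectivity
  module's own PLV (fixed inner seed), so the requested PLV target is what
  the pipeline actually measures.

``generate_session`` produces a full continuous recording for the end-to-end
chain; ``generate_epochs`` is a fast path that emits analysis-rate epochs
directly (same effect machinery, per-channel semantics) for calibration
studies that need hundreds of replicates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

from .exceptions import ConfigError
from .io import DEFAULT_ROIS, ChannelInfo, RecordingSession
from .preprocess import EpochSet
from .spectral import DEFAULT_BANDS, BandDefinition

_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}
_RAMP_S = 0.1


@dataclass(frozen=True)
class EvokedEffect:
    roi: str
    latency_s: float
    duration_s: float
    amplitude_z: float
    direction: str  # "neg_up" or "neg_down"


@dataclass(frozen=True)
class BandEffect:
    roi: str
    band: str
    neg_scale: float


@dataclass(frozen=True)
class CouplingEffect:
    roi_a: str
    roi_b: str
    band: str
    plv_target_neg: float
    plv_target_pos: float


@dataclass(frozen=True)
class NoiseSpec:
    pink_exponent: float = 1.0
    rms_uv: float = 20.0


@dataclass(frozen=True)
class LineNoiseSpec:
    freq: float = 50.0
    amplitude_uv: float = 5.0


def _default_channels() -> dict[str, int]:
    return {roi: 2 for roi in DEFAULT_ROIS}


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 12
    n_channels_per_roi: dict[str, int] = field(default_factory=_default_channels)
    fs_raw: float = 2048.0
    n_trials_per_condition: int = 30
    noise: NoiseSpec = NoiseSpec()
    line_noise: LineNoiseSpec = LineNoiseSpec()
    evoked_effects: tuple[EvokedEffect, ...] = ()
    band_effects: tuple[BandEffect, ...] = ()
    coupling_effects: tuple[CouplingEffect, ...] = ()
    artifact_rate: float = 0.0
    artifact_duration_s: float = 0.3
    artifact_z: float = 20.0
    stim_duration_s: float = 6.0
    pre_onset_s: float = 2.0  # 1 s rest + 1 s fixation baseline
    iti_cycle: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.n_subjects < 1 or self.n_trials_per_condition < 1:
            errs.append("subject and trial counts must be positive")
        if self.fs_raw <= 0:
            errs.append("fs_raw must be positive")
        if not self.n_channels_per_roi:
            errs.append("n_channels_per_roi is empty")
        for roi, n in self.n_channels_per_roi.items():
            if n < 1:
                errs.append(f"roi {roi} has {n} channels")
        for e in self.evoked_effects:
            if e.roi not in self.n_channels_per_roi:
                errs.append(f"evoked effect roi {e.roi!r} has no channels")
            if not 0 <= e.latency_s < e.latency_s + e.duration_s <= self.stim_duration_s:
                errs.append(f"evoked effect in {e.roi} outside the stimulation window")
            if e.amplitude_z <= 0:
                errs.append(f"evoked amplitude must be positive ({e.roi})")
            if e.direction not in ("neg_up", "neg_down"):
                errs.append(f"unknown evoked direction {e.direction!r}")
        for b in self.band_effects:
            if b.band not in _BAND_BY_NAME:
                errs.append(f"unknown band {b.band!r}")
            if b.neg_scale <= 0:
                errs.append(f"band scale must be positive ({b.roi}/{b.band})")
            if b.roi not in self.n_channels_per_roi:
                errs.append(f"band effect roi {b.roi!r} has no channels")
        groups: dict[str, list[CouplingEffect]] = {}
        for c in self.coupling_effects:
            if c.band not in _BAND_BY_NAME:
                errs.append(f"unknown band {c.band!r}")
                continue
            for roi in (c.roi_a, c.roi_b):
                if roi not in self.n_channels_per_roi:
                    errs.append(f"coupling roi {roi!r} has no channels")
            for t in (c.plv_target_neg, c.plv_target_pos):
                if not 0 <= t <= 1:
                    errs.append(f"plv target {t} outside [0, 1]")
            groups.setdefault(c.band, []).append(c)
        for band, effs in groups.items():
            tgts = {(e.plv_target_neg, e.plv_target_pos) for e in effs}
            if len(tgts) > 1:
                errs.append(
                    f"coupling effects in band {band!r} share one source and must "
                    f"share PLV targets, got {sorted(tgts)}"
                )
        if not 0 <= self.artifact_rate <= 1:
            errs.append("artifact_rate must be in [0, 1]")
        return errs


@dataclass
class GroundTruth:
    """Realized per-session effect bookkeeping for recovery tests."""

    seed: int
    subject_id: int
    onsets: list[int]
    conditions: list[str]
    evoked: list[tuple[str, float, float, float, str]]  # label, latency, dur, amp_z, dir
    band_scales: dict[tuple[str, str], float]
    coupling: dict[str, dict]
    artifact_trials: list[int]


# ---------------------------------------------------------------------------
# noise and band helpers


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: float, exponent: float, rms: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, float32, exact target RMS per row."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros(freqs.size, dtype=np.float32)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = rng.standard_normal(shape + (2 * freqs.size,), dtype=np.float32).view(
        np.complex64
    )
    spec *= amp
    x = sfft.irfft(spec, n=n, axis=-1)
    x *= (rms / np.sqrt(np.mean(x * x, axis=-1, keepdims=True, dtype=np.float64))).astype(
        np.float32
    )
    return x


def _band_component(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Brick-wall band component via FFT masking along the last axis."""
    n = x.shape[-1]
    spec = sfft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[..., (f < lo) | (f >= hi)] = 0
    return sfft.irfft(spec, n=n, axis=-1)


def _stim_ramp(n_seg: int, i0: int, i1: int, fs: float) -> np.ndarray:
    """0->1->0 raised-cosine activation over segment samples [i0, i1)."""
    r = np.zeros(n_seg, dtype=np.float32)
    i0c, i1c = max(i0, 0), min(i1, n_seg)
    if i1c <= i0c:
        return r
    r[i0c:i1c] = 1.0
    nr = min(int(round(_RAMP_S * fs)), (i1c - i0c) // 2)
    if nr > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * (np.arange(nr) + 0.5) / nr))
        r[i0c : i0c + nr] = ramp
        r[i1c - nr : i1c] = ramp[::-1]
    return r.astype(np.float32)


def _evoked_window(duration_s: float, fs: float) -> np.ndarray:
    """Truncated-Gaussian transient: support [0, duration], SD = duration/4."""
    n = int(round(duration_s * fs))
    t = (np.arange(n) + 0.5) / fs
    sigma = duration_s / 4.0
    return np.exp(-((t - duration_s / 2.0) ** 2) / (2.0 * sigma**2))


# ---------------------------------------------------------------------------
# PLV target calibration

_CALIBRATION_CACHE: dict[tuple, float] = {}
_CALIBRATION_INNER_SEED = 603979776  # fixed; independent of scenario seeds


def _measured_plv(
    fraction: float,
    band: BandDefinition,
    fs: float = 500.0,
    window_s: tuple[float, float] = (0.0, 2.0),
    edge_trim_s: float = 0.2,
    n_trials: int = 40,
) -> float:
    """Monte-Carlo PLV of the connectivity estimator for two channels that
    share ``fraction`` of their band power (common random numbers)."""
    from .connectivity import trial_plv

    rng = np.random.default_rng(_CALIBRATION_INNER_SEED)
    t0 = window_s[0] - edge_trim_s
    T = int(round((window_s[1] - window_s[0] + 2 * edge_trim_s) * fs))
    # 1/f-shaped noise matches the generator's background and shared sources,
    # so the calibrated fraction transfers to the realized sessions
    pink = _pink_noise(rng, (n_trials, 3), T, fs, 1.0, 1.0).astype(np.float64)
    nb = _band_component(pink, fs, band.lo, band.hi)
    nb /= np.sqrt(np.mean(nb**2, axis=-1, keepdims=True))
    a = np.sqrt(1.0 - fraction)
    b = np.sqrt(fraction)
    x = np.stack([a * nb[:, 0] + b * nb[:, 2], a * nb[:, 1] + b * nb[:, 2]], axis=1)
    epochs = EpochSet(
        data=x,
        fs=fs,
        conditions=np.array(["Neg"] * n_trials),
        t0_offset_s=t0,
        baseline_slice=slice(0, 1),
        kept_mask=np.ones(n_trials, dtype=bool),
        channels=[
            ChannelInfo(label="a", shaft_id="a", contact_index=1),
            ChannelInfo(label="b", shaft_id="b", contact_index=1),
        ],
    )
    res = trial_plv(
        epochs, bands=(band,), window_s=window_s, edge_trim_s=edge_trim_s,
        pairs=[(0, 1)],
    )
    return float(res.plv_raw[0, 0])


def plv_target_to_fraction(
    target: float, band: BandDefinition, fs: float = 500.0, tol: float = 1e-3
) -> float:
    """Shared-power fraction whose measured PLV hits ``target``.

    Solved by bisection against the connectivity module's own estimator.
    Raises :class:`ConfigError` with the feasible range when the target lies
    below the finite-window null floor or above the full-sharing ceiling.
    """
    key = (round(target, 6), band.name, fs)
    if key in _CALIBRATION_CACHE:
        return _CALIBRATION_CACHE[key]
    floor = _measured_plv(0.0, band, fs)
    ceiling = _measured_plv(1.0, band, fs)
    if not floor <= target <= ceiling:
        raise ConfigError(
            f"plv target {target} infeasible in band {band.name}: the achievable "
            f"range at this window is [{floor:.3f}, {ceiling:.3f}]"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _measured_plv(mid, band, fs) < target:
            lo = mid
        else:
            hi = mid
    frac = (lo + hi) / 2.0
    _CALIBRATION_CACHE[key] = frac
    return frac


# ---------------------------------------------------------------------------
# session generation


def _event_schedule(cfg: ScenarioConfig, rng: np.random.Generator):
    n_tr = 2 * cfg.n_trials_per_condition
    conds = np.array(
        ["Neg"] * cfg.n_trials_per_condition + ["Pos"] * cfg.n_trials_per_condition
    )
    conds = conds[rng.permutation(n_tr)]
    itis = np.resize(np.asarray(cfg.iti_cycle, dtype=float), n_tr)
    onsets_s = np.empty(n_tr)
    t = cfg.pre_onset_s
    for k in range(n_tr):
        onsets_s[k] = t
        t += cfg.stim_duration_s + itis[k] + cfg.pre_onset_s
    total_s = onsets_s[-1] + cfg.stim_duration_s + 2.0
    return conds, onsets_s, total_s


def _session_channels(cfg: ScenarioConfig) -> list[ChannelInfo]:
    channels = []
    for roi, m in cfg.n_channels_per_roi.items():
        for k in range(1, m + 1):
            channels.append(
                ChannelInfo(label=f"{roi}{k}", shaft_id=roi, contact_index=k, roi=roi)
            )
    return channels


def generate_session(
    cfg: ScenarioConfig, subject_id: int = 0
) -> tuple[RecordingSession, GroundTruth]:
    """Generate one subject's continuous 2048 Hz recording with ground truth.

    Deterministic given ``(cfg.seed, subject_id)``: all randomness flows from
    one seed sequence through per-purpose child streams.
    """
    errs = cfg.validate()
    if errs:
        raise ConfigError("; ".join(errs))
    fs = cfg.fs_raw
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(subject_id,))
    r_events, r_noise, r_sources, r_artifacts = map(np.random.default_rng, ss.spawn(4))

    conds, onsets_s, total_s = _event_schedule(cfg, r_events)
    n_tr = len(conds)
    ns = int(round(total_s * fs))
    onsets = np.round(onsets_s * fs).astype(int)
    channels = _session_channels(cfg)
    nch = len(channels)
    ch_idx = {c.label: i for i, c in enumerate(channels)}
    roi_members = {
        roi: [i for i, c in enumerate(channels) if c.roi == roi]
        for roi in cfg.n_channels_per_roi
    }

    bg = _pink_noise(
        r_noise, (nch,), ns, fs, cfg.noise.pink_exponent, cfg.noise.rms_uv
    )
    data = bg.copy()

    # --- coupling groups: one shared source per band, per-shaft common mode
    groups: dict[str, dict] = {}
    for c in cfg.coupling_effects:
        g = groups.setdefault(
            c.band,
            {"rois": set(), "targets": (c.plv_target_neg, c.plv_target_pos)},
        )
        g["rois"].update((c.roi_a, c.roi_b))
    coupling_truth: dict[str, dict] = {}
    for band_name, g in groups.items():
        band = _BAND_BY_NAME[band_name]
        f_neg = plv_target_to_fraction(g["targets"][0], band)
        f_pos = plv_target_to_fraction(g["targets"][1], band)
        g["fractions"] = {"Neg": f_neg, "Pos": f_pos}
        coupling_truth[band_name] = {
            "rois": sorted(g["rois"]),
            "targets": g["targets"],
            "fraction_neg": f_neg,
            "fraction_pos": f_pos,
        }

    band_mods: dict[str, list] = {}
    for be in cfg.band_effects:
        band_mods.setdefault(be.band, []).append(be)

    # --- per-trial band-limited modifications (scaling and coupling)
    # Wide segments stabilize the band decomposition at the low delta edge;
    # modifications outside the ramped stimulus window are identically zero,
    # so overlapping read margins cannot contaminate neighbouring trials.
    margin = int(round(2.0 * fs))
    stim_n = int(round(cfg.stim_duration_s * fs))
    touched_bands = sorted(set(band_mods) | set(groups))
    for k in range(n_tr):
        seg0 = max(onsets[k] - margin, 0)
        seg1 = min(onsets[k] + stim_n + margin, ns)
        i0, i1 = onsets[k] - seg0, onsets[k] - seg0 + stim_n
        n_seg = seg1 - seg0
        ramp = _stim_ramp(n_seg, i0, i1, fs)
        stim_sl = slice(max(i0, 0), min(i1, n_seg))
        for band_name in touched_bands:
            band = _BAND_BY_NAME[band_name]
            involved: set[int] = set()
            for be in band_mods.get(band_name, ()):
                if conds[k] == "Neg":
                    involved.update(roi_members[be.roi])
            grp = groups.get(band_name)
            if grp is not None:
                for roi in grp["rois"]:
                    involved.update(roi_members[roi])
            if not involved:
                continue
            idx = sorted(involved)
            d = _band_component(bg[idx, seg0:seg1], fs, band.lo, band.hi)
            if grp is not None:
                # per-trial shared source and per-shaft common-mode
                # compensators, 1/f-shaped inside the band like the background
                n_src = 1 + len(grp["rois"])
                srcs = _band_component(
                    _pink_noise(
                        r_sources, (n_src,), n_seg, fs, cfg.noise.pink_exponent, 1.0
                    ).astype(np.float64),
                    fs, band.lo, band.hi,
                )
                srcs /= np.sqrt(np.mean(srcs[:, stim_sl] ** 2, axis=-1, keepdims=True))
                s_seg = srcs[0]
                u_segs = dict(zip(sorted(grp["rois"]), srcs[1:]))
            for pos, ci in enumerate(idx):
                ch = channels[ci]
                gain = np.ones(n_seg, dtype=np.float32)
                for be in band_mods.get(band_name, ()):
                    if conds[k] == "Neg" and ch.roi == be.roi:
                        gain = gain + (np.sqrt(be.neg_scale, dtype=np.float32) - 1.0) * ramp
                delta = (gain - 1.0) * d[pos]
                if grp is not None and ch.roi in grp["rois"]:
                    f = grp["fractions"][conds[k]]
                    P = float(np.mean(d[pos][stim_sl] ** 2))
                    alpha = np.sqrt(1.0 - f * ramp)
                    beta = np.sqrt(0.5 * f * ramp)
                    sign = -1.0 if ch.contact_index % 2 == 0 else 1.0
                    mixed = alpha * gain * d[pos] + np.sqrt(P) * beta * (
                        sign * s_seg + u_segs[ch.roi]
                    )
                    # per-trial power normalization: an amplitude rescale
                    # leaves phases (hence PLV) untouched but pins the
                    # realized band power to the uncoupled value despite
                    # finite-window cross-term fluctuations.  Applied through
                    # the ramp so nothing changes outside the stimulus window.
                    target = float(np.mean((gain[stim_sl] * d[pos][stim_sl]) ** 2))
                    realized = float(np.mean(mixed[stim_sl] ** 2))
                    scale = np.sqrt(target / realized) if realized > 0 else 1.0
                    delta = (1.0 + (scale - 1.0) * ramp) * mixed - d[pos]
                data[ci, seg0:seg1] += delta.astype(np.float32)

    # --- evoked transients (condition difference = amplitude_z * rms)
    evoked_truth = []
    for ev in cfg.evoked_effects:
        w = _evoked_window(ev.duration_s, fs).astype(np.float32)
        base_sign = 1.0 if ev.direction == "neg_up" else -1.0
        start = int(round(ev.latency_s * fs))
        for ci in roi_members[ev.roi]:
            ch = channels[ci]
            amp = 0.5 * ev.amplitude_z * cfg.noise.rms_uv / ch.contact_index
            evoked_truth.append(
                (ch.label, ev.latency_s, ev.duration_s, ev.amplitude_z, ev.direction)
            )
            for k in range(n_tr):
                sgn = base_sign if conds[k] == "Neg" else -base_sign
                j0 = onsets[k] + start
                data[ci, j0 : j0 + w.size] += np.float32(sgn * amp) * w

    # --- line noise
    if cfg.line_noise.amplitude_uv > 0:
        t = np.arange(ns, dtype=np.float64) / fs
        w = 2 * np.pi * cfg.line_noise.freq
        sin_t = np.sin(w * t).astype(np.float32)
        cos_t = np.cos(w * t).astype(np.float32)
        phases = r_noise.uniform(0, 2 * np.pi, nch)
        amp = cfg.line_noise.amplitude_uv
        for ci in range(nch):
            data[ci] += np.float32(amp * np.cos(phases[ci])) * sin_t
            data[ci] += np.float32(amp * np.sin(phases[ci])) * cos_t

    # --- planted paroxysm-like artifacts
    artifact_trials: list[int] = []
    n_art = int(round(cfg.artifact_rate * n_tr))
    if n_art:
        artifact_trials = sorted(
            int(i) for i in r_artifacts.choice(n_tr, size=n_art, replace=False)
        )
        burst_n = int(round(cfg.artifact_duration_s * fs))
        from scipy.signal.windows import tukey

        burst = tukey(burst_n, 0.25).astype(np.float32)
        for k in artifact_trials:
            ci = int(r_artifacts.integers(nch))
            lo = onsets[k] + int(round(0.5 * fs))
            hi = onsets[k] + stim_n - burst_n - int(round(0.5 * fs))
            j0 = int(r_artifacts.integers(lo, max(hi, lo + 1)))
            sgn = 1.0 if r_artifacts.random() < 0.5 else -1.0
            data[ci, j0 : j0 + burst_n] += np.float32(
                sgn * cfg.artifact_z * cfg.noise.rms_uv
            ) * burst

    session = RecordingSession(
        data=data,
        fs=fs,
        channels=channels,
        events=[(int(o), str(c)) for o, c in zip(onsets, conds)],
    )
    truth = GroundTruth(
        seed=cfg.seed,
        subject_id=subject_id,
        onsets=[int(o) for o in onsets],
        conditions=[str(c) for c in conds],
        evoked=evoked_truth,
        band_scales={(b.roi, b.band): b.neg_scale for b in cfg.band_effects},
        coupling=coupling_truth,
        artifact_trials=artifact_trials,
    )
    return session, truth


# ---------------------------------------------------------------------------
# fast path: analysis-rate epochs


def generate_epochs(
    cfg: ScenarioConfig,
    subject_id: int = 0,
    fs: float = 500.0,
    epoch_window: tuple[float, float] = (-1.0, 6.0),
) -> tuple[EpochSet, GroundTruth]:
    """Emit analysis-rate epochs directly (no continuous plumbing).

    Channels are independent analysis leads (one shaft each, no bipolar
    derivation); planted amplitudes and coupling fractions apply per
    channel.  Intended for calibration and recovery studies that need many
    replicates.
    """
    errs = cfg.validate()
    if errs:
        raise ConfigError("; ".join(errs))
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(subject_id, 1))
    r_events, r_noise, r_sources = map(np.random.default_rng, ss.spawn(3))

    n_tr = 2 * cfg.n_trials_per_condition
    conds = np.array(
        ["Neg"] * cfg.n_trials_per_condition + ["Pos"] * cfg.n_trials_per_condition
    )[r_events.permutation(n_tr)]

    channels = []
    for roi, m in cfg.n_channels_per_roi.items():
        for k in range(1, m + 1):
            channels.append(
                ChannelInfo(label=f"{roi}{k}", shaft_id=f"{roi}{k}", contact_index=1, roi=roi)
            )
    nch = len(channels)
    t0, t1 = epoch_window
    T = int(round((t1 - t0) * fs))
    data = _pink_noise(
        r_noise, (n_tr, nch), T, fs, cfg.noise.pink_exponent, cfg.noise.rms_uv
    ).astype(np.float64)

    i_on = int(round(-t0 * fs))
    i_off = min(int(round((cfg.stim_duration_s - t0) * fs)), T)
    ramp = _stim_ramp(T, i_on, i_off, fs)
    stim_sl = slice(i_on, i_off)
    neg = conds == "Neg"

    for be in cfg.band_effects:
        band = _BAND_BY_NAME[be.band]
        idx = [i for i, c in enumerate(channels) if c.roi == be.roi]
        d = _band_component(data[np.ix_(np.flatnonzero(neg), idx)], fs, band.lo, band.hi)
        g = 1.0 + (np.sqrt(be.neg_scale) - 1.0) * ramp
        data[np.ix_(np.flatnonzero(neg), idx)] += (g - 1.0) * d

    groups: dict[str, dict] = {}
    for c in cfg.coupling_effects:
        g = groups.setdefault(
            c.band, {"rois": set(), "targets": (c.plv_target_neg, c.plv_target_pos)}
        )
        g["rois"].update((c.roi_a, c.roi_b))
    coupling_truth = {}
    for band_name, g in groups.items():
        band = _BAND_BY_NAME[band_name]
        f_by_cond = {
            "Neg": plv_target_to_fraction(g["targets"][0], band, fs),
            "Pos": plv_target_to_fraction(g["targets"][1], band, fs),
        }
        src = _band_component(
            _pink_noise(r_sources, (n_tr,), T, fs, cfg.noise.pink_exponent, 1.0).astype(float),
            fs, band.lo, band.hi,
        )
        src /= np.sqrt(np.mean(src[:, stim_sl] ** 2, axis=-1, keepdims=True))
        idx = [i for i, c in enumerate(channels) if c.roi in g["rois"]]
        d = _band_component(data[:, idx], fs, band.lo, band.hi)
        P = np.mean(d[:, :, stim_sl] ** 2, axis=-1, keepdims=True)
        f_tr = np.array([f_by_cond[c] for c in conds])[:, None, None]
        alpha = np.sqrt(1.0 - f_tr * ramp)
        beta = np.sqrt(f_tr * ramp)
        mixed = alpha * d + beta * np.sqrt(P) * src[:, None, :]
        realized = np.mean(mixed[:, :, stim_sl] ** 2, axis=-1, keepdims=True)
        mixed *= np.sqrt(np.where(realized > 0, P / realized, 1.0))
        data[:, idx] += mixed - d
        coupling_truth[band_name] = {
            "rois": sorted(g["rois"]),
            "targets": g["targets"],
            "fraction_neg": f_by_cond["Neg"],
            "fraction_pos": f_by_cond["Pos"],
        }

    evoked_truth = []
    for ev in cfg.evoked_effects:
        w = _evoked_window(ev.duration_s, fs)
        base_sign = 1.0 if ev.direction == "neg_up" else -1.0
        j0 = i_on + int(round(ev.latency_s * fs))
        j1 = min(j0 + w.size, T)
        if j1 <= j0:
            continue
        idx = [i for i, c in enumerate(channels) if c.roi == ev.roi]
        amp = 0.5 * ev.amplitude_z * cfg.noise.rms_uv
        signs = np.where(neg, base_sign, -base_sign)
        for ci in idx:
            data[:, ci, j0:j1] += signs[:, None] * amp * w[: j1 - j0]
            evoked_truth.append(
                (channels[ci].label, ev.latency_s, ev.duration_s, ev.amplitude_z, ev.direction)
            )

    b0 = 0
    b1 = int(round((min(0.0, t1) - t0) * fs))
    epochs = EpochSet(
        data=data,
        fs=fs,
        conditions=conds,
        t0_offset_s=t0,
        baseline_slice=slice(b0, b1),
        kept_mask=np.ones(n_tr, dtype=bool),
        channels=channels,
    )
    truth = GroundTruth(
        seed=cfg.seed,
        subject_id=subject_id,
        onsets=[],
        conditions=[str(c) for c in conds],
        evoked=evoked_truth,
        band_scales={(b.roi, b.band): b.neg_scale for b in cfg.band_effects},
        coupling=coupling_truth,
        artifact_trials=[],
    )
    return epochs, truth


# ---------------------------------------------------------------------------
# canonical scenarios


def headline_scenario() -> ScenarioConfig:
    """The canonical planted-effect cohort.

    Encodes the qualitative findings the pipeline should recover: an evoked
    divergence cascade Amy (0.52 s, Neg up) -> ACC (0.55 s, Neg down) ->
    OFC (1.05 s, Neg down) -> Hip (1.36 s, Neg up); gamma power suppression
    (x0.8) under Neg in Amy/ACC/Hip with OFC spectrally silent; a weaker
    theta suppression (x0.9) in Hip; and delta-band coupling of Amy with
    ACC/Hip/OFC that is stronger under Neg (PLV 0.55 vs 0.40).  Ins, MCC,
    PCC and Pcun carry no effects.
    """
    return ScenarioConfig(
        n_channels_per_roi={
            "Amy": 3, "ACC": 3, "OFC": 3, "Hip": 3,
            "Ins": 2, "MCC": 2, "PCC": 2, "Pcun": 2,
        },
        evoked_effects=(
            EvokedEffect("Amy", 0.52, 0.40, 3.0, "neg_up"),
            EvokedEffect("ACC", 0.55, 0.40, 3.0, "neg_down"),
            EvokedEffect("OFC", 1.05, 0.40, 3.0, "neg_down"),
            EvokedEffect("Hip", 1.36, 0.40, 3.0, "neg_up"),
        ),
        band_effects=(
            BandEffect("Amy", "gamma", 0.8),
            BandEffect("ACC", "gamma", 0.8),
            BandEffect("Hip", "gamma", 0.8),
            BandEffect("Hip", "theta", 0.9),
        ),
        coupling_effects=(
            CouplingEffect("Amy", "ACC", "delta", 0.55, 0.40),
            CouplingEffect("Amy", "Hip", "delta", 0.55, 0.40),
            CouplingEffect("Amy", "OFC", "delta", 0.55, 0.40),
        ),
    )


def null_scenario() -> ScenarioConfig:
    """Same noise structure and paradigm, zero planted effects.

    Used for type-I-error calibration of every analysis stage.
    """
    cfg = headline_scenario()
    cfg.evoked_effects = ()
    cfg.band_effects = ()
    cfg.coupling_effects = ()
    return cfg
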