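"""Event-related potential contrast between the two picture conditions.

Trials are baseline-corrected (baseline-window mean removed) and normalized
to baseline-SD z-units so amplitudes are comparable across leads.  The
contrast is a per-sample paired t-test between Neg and Pos over the 0-2 s
analysis window, and a sample is reported as part of a significant
divergence only when it belongs to a run of sub-alpha samples strictly
longer than 30 ms — the temporal-consistency gate that suppresses isolated
threshold crossings.  The divergence latency of a channel is the start of
its earliest surviving interval.

Pairing units: with several sessions (subjects) the test pairs per-subject
condition means, which is the appropriate group-level statistic; a single
session falls back to pairing trials by presentation index after truncation
to the common trial count.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import ParameterError, StatisticsError
from .io import UNASSIGNED, ChannelInfo
from .preprocess import EpochSet


@dataclass
class ErpContrast:
    """Per-channel ERP contrast results over the analysis window."""

    time_axis_s: np.ndarray
    mean_neg: np.ndarray  # (n_channels, n_times), baseline-z units
    mean_pos: np.ndarray
    t_course: np.ndarray
    p_course: np.ndarray
    sig_intervals: list[list[tuple[float, float]]]
    onset_latency_s: np.ndarray  # NaN where no interval survives
    direction: list[list[int]]  # per interval: +1 where Neg > Pos, else -1
    channel_names: list[str]
    alpha: float
    min_dur_s: float


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the per-trial, per-channel baseline-window mean."""
    b = epochs.baseline_slice
    if b.stop - b.start < 1:
        raise ParameterError("empty baseline window")
    mean = epochs.data[:, :, b].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


def normalize_trials(epochs: EpochSet) -> EpochSet:
    """Divide each trial/channel by its baseline-window standard deviation.

    Trials with a zero baseline SD on any channel carry no usable scale; they
    are flagged and excluded (recorded in ``kept_mask``), not an error.
    """
    b = epochs.baseline_slice
    sd = epochs.data[:, :, b].std(axis=2, ddof=1)
    good = (sd > 0).all(axis=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    data = (epochs.data / sd_safe[:, :, None])[good]
    kept_mask = epochs.kept_mask.copy()
    kept_idx = np.flatnonzero(kept_mask)
    kept_mask[kept_idx[~good]] = False
    return replace(
        epochs, data=data, conditions=epochs.conditions[good], kept_mask=kept_mask
    )


def erp_average(
    epochs: EpochSet, window_s: tuple[float, float] = (0.0, 2.0)
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Arithmetic trial mean per condition, restricted to the analysis window."""
    sl = epochs.window_slice(window_s)
    times = epochs.times()[sl]
    out = {}
    for cond in ("Neg", "Pos"):
        trials = epochs.condition_trials(cond)
        if trials.shape[0] == 0:
            raise StatisticsError(f"no {cond} trials to average")
        out[cond] = trials[:, :, sl].mean(axis=0)
    return times, out


def paired_t(diff: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Paired t statistic and two-sided p from paired differences.

    Degenerate pairs (zero within-pair variance) are documented edge cases:
    a nonzero constant difference gives ``p = 0`` (the |t| -> inf limit); an
    identically zero difference gives ``t = 0, p = 1``.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[axis]
    if n < 2:
        raise StatisticsError(f"paired t needs >= 2 pairs, got {n}")
    md = diff.mean(axis=axis)
    sd = diff.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = md / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t = np.where(zero_sd & (md == 0), 0.0, t)
    t = np.where(zero_sd & (md > 0), np.inf, t)
    t = np.where(zero_sd & (md < 0), -np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def _condition_pairs(epochs: EpochSet) -> np.ndarray:
    """Trial-index pairing within a session: (n_pairs, ch, t) differences."""
    neg = epochs.condition_trials("Neg")
    pos = epochs.condition_trials("Pos")
    n = min(neg.shape[0], pos.shape[0])
    if n < 2:
        raise StatisticsError(f"need >= 2 pairs, got {n}")
    return neg[:n] - pos[:n]


def paired_t_timecourse(
    epochs: EpochSet | list[EpochSet],
    window_s: tuple[float, float] = (0.0, 2.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample paired t/p time-courses over the analysis window.

    A list of epoch sets is treated as subjects: pairs are per-subject
    condition means.  A single epoch set pairs trials by presentation index.
    """
    if isinstance(epochs, EpochSet):
        sl = epochs.window_slice(window_s)
        times = epochs.times()[sl]
        diff = _condition_pairs(epochs)[:, :, sl]
    else:
        if len(epochs) < 2:
            raise StatisticsError("subject-level pairing needs >= 2 subjects")
        diffs = []
        times = None
        for ep in epochs:
            sl = ep.window_slice(window_s)
            times = ep.times()[sl]
            neg = ep.condition_trials("Neg")
            pos = ep.condition_trials("Pos")
            if neg.shape[0] == 0 or pos.shape[0] == 0:
                raise StatisticsError("a subject lacks one condition")
            diffs.append(neg[:, :, sl].mean(axis=0) - pos[:, :, sl].mean(axis=0))
        diff = np.asarray(diffs)
    t, p = paired_t(diff, axis=0)
    return times, t, p


def significant_intervals(
    p_course: np.ndarray,
    fs: float,
    alpha: float = 0.05,
    min_dur_s: float = 0.030,
    t_start: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive sub-alpha samples strictly longer than
    ``min_dur_s``.

    The duration of a k-sample run is ``k / fs``, and the rule is a strict
    inequality: at 500 Hz a 15-sample run (30 ms) is excluded while a
    16-sample run (32 ms) survives.
    """
    p_course = np.asarray(p_course, dtype=float)
    if p_course.ndim != 1:
        raise ParameterError("p_course must be 1-D")
    if np.any((p_course < 0) | (p_course > 1)):
        raise ParameterError("p values must lie in [0, 1]")
    sig = p_course < alpha
    padded = np.concatenate(([False], sig, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    out = []
    for i0, i1 in zip(edges[0::2], edges[1::2]):
        if (i1 - i0) / fs > min_dur_s:
            out.append((t_start + i0 / fs, t_start + i1 / fs))
    return out


def divergence_latency(
    contrast: ErpContrast,
) -> tuple[np.ndarray, list[int | None]]:
    """Earliest interval start per channel and its regulation direction.

    Returns (latencies with NaN where no interval exists, per-channel sign of
    (mean Neg - mean Pos) averaged over the earliest interval: +1 means the
    negative condition is up-regulated).
    """
    lat = np.full(len(contrast.sig_intervals), np.nan)
    direction: list[int | None] = []
    for c, intervals in enumerate(contrast.sig_intervals):
        if not intervals:
            direction.append(None)
            continue
        starts = [iv[0] for iv in intervals]
        k = int(np.argmin(starts))
        lat[c] = intervals[k][0]
        direction.append(contrast.direction[c][k])
    return lat, direction


def _interval_direction(
    times: np.ndarray, diff_mean: np.ndarray, interval: tuple[float, float]
) -> int:
    mask = (times >= interval[0]) & (times < interval[1])
    return 1 if diff_mean[mask].mean() >= 0 else -1


def erp_contrast(
    epochs: EpochSet | list[EpochSet],
    window_s: tuple[float, float] = (0.0, 2.0),
    alpha: float = 0.05,
    min_dur_s: float = 0.030,
    preprocess: bool = True,
) -> ErpContrast:
    """Full ERP contrast: baseline correction, normalization, condition
    means, paired t time-course, duration-gated intervals, latencies.

    ``preprocess=False`` skips baseline correction/normalization for epochs
    that already carry z-units.
    """
    single = isinstance(epochs, EpochSet)
    sets = [epochs] if single else list(epochs)
    if preprocess:
        sets = [normalize_trials(baseline_correct(ep)) for ep in sets]
    ref = sets[0]
    names = [ch.label for ch in ref.channels] or [
        f"ch{i}" for i in range(ref.n_channels)
    ]

    # condition means (grand mean over subjects of per-subject means)
    sl = ref.window_slice(window_s)
    times = ref.times()[sl]
    mean_neg = np.mean(
        [ep.condition_trials("Neg")[:, :, sl].mean(axis=0) for ep in sets], axis=0
    )
    mean_pos = np.mean(
        [ep.condition_trials("Pos")[:, :, sl].mean(axis=0) for ep in sets], axis=0
    )
    _, t, p = paired_t_timecourse(sets[0] if single else sets, window_s)

    fs = ref.fs
    sig, direction = [], []
    dmean = mean_neg - mean_pos
    for c in range(ref.n_channels):
        intervals = significant_intervals(
            p[c], fs, alpha=alpha, min_dur_s=min_dur_s, t_start=times[0]
        )
        sig.append(intervals)
        direction.append([_interval_direction(times, dmean[c], iv) for iv in intervals])
    contrast = ErpContrast(
        time_axis_s=times,
        mean_neg=mean_neg,
        mean_pos=mean_pos,
        t_course=t,
        p_course=p,
        sig_intervals=sig,
        onset_latency_s=np.full(ref.n_channels, np.nan),
        direction=direction,
        channel_names=names,
        alpha=alpha,
        min_dur_s=min_dur_s,
    )
    contrast.onset_latency_s, _ = divergence_latency(contrast)
    return contrast


def pool_rois(epochs: EpochSet, rois: tuple[str, ...] | None = None) -> EpochSet:
    """Average channels within each ROI, yielding one pooled channel per ROI.

    Channels with roi ``"unassigned"`` are dropped.  Useful before
    group-level statistics when contacts within a region are exchangeable.
    """
    present = [ch.roi for ch in epochs.channels]
    if rois is None:
        rois = tuple(dict.fromkeys(r for r in present if r != UNASSIGNED))
    groups = []
    new_channels = []
    for roi in rois:
        idx = [i for i, r in enumerate(present) if r == roi]
        if not idx:
            continue
        groups.append(epochs.data[:, idx].mean(axis=1))
        new_channels.append(
            ChannelInfo(label=roi, shaft_id=roi, contact_index=1, roi=roi)
        )
    if not groups:
        raise ParameterError("no ROI-assigned channels to pool")
    return replace(
        epochs, data=np.stack(groups, axis=1), channels=new_channels
    )
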