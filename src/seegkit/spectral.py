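"""Welch band power and per-band condition contrasts.

Power spectra are estimated per trial and channel with Welch's method (2-s
Hann segments, 50% overlap over the 6-s stimulus window by default, which
resolves the 0.5 Hz delta edge while averaging five segments).  Band power
in the five canonical bands — delta 0.5-4, theta 4-8, alpha 8-13, beta
13-30, gamma 30-100 Hz — is normalized per lead and trial by the total
0.5-100 Hz power, so the five fractions are amplitude-scale free and sum to
one.  Condition contrasts are paired t-tests on the relative powers, paired
per subject (condition means) or per trial index within a session.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import ParameterError, StatisticsError
from .io import UNASSIGNED, ChannelInfo
from .preprocess import EpochSet
from .erp import paired_t


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ParameterError(f"invalid band {self.name}: ({self.lo}, {self.hi})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 100.0),
)


def validate_bands(
    bands: tuple[BandDefinition, ...], fs: float | None = None
) -> list[str]:
    """Bands must be non-overlapping and contiguous, inside (0, fs/2)."""
    errs = []
    for a, b in zip(bands[:-1], bands[1:]):
        if a.hi != b.lo:
            errs.append(f"bands {a.name} and {b.name} are not contiguous ({a.hi} != {b.lo})")
    if fs is not None and bands and bands[-1].hi >= fs / 2:
        errs.append(f"band {bands[-1].name} reaches the Nyquist frequency at fs {fs}")
    return errs


def welch_psd(
    x: np.ndarray,
    fs: float,
    seg_s: float = 2.0,
    overlap: float = 0.5,
    window: str = "hann",
    axis: int = -1,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density (uV^2/Hz) on a uniform frequency grid.

    The integrated PSD of a stationary signal matches its time-domain
    variance (Parseval consistency of the density normalization).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(seg_s * fs))
    if x.shape[axis] < nperseg:
        raise ParameterError(
            f"trial of {x.shape[axis]} samples shorter than one {nperseg}-sample segment"
        )
    if not 0 <= overlap < 1:
        raise ParameterError(f"overlap fraction must be in [0, 1), got {overlap}")
    return signal.welch(
        x, fs=fs, window=window, nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), axis=axis, detrend="constant",
    )


def _band_weights(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoid quadrature weights for the integral of a gridded spectrum
    over [lo, hi], with linear interpolation at the band edges.

    Summing the weight vectors of contiguous bands reproduces the weights of
    the union band exactly, so relative powers sum to one by construction.
    """
    if lo < freqs[0] or hi > freqs[-1]:
        raise ParameterError(f"band ({lo}, {hi}) outside frequency grid")
    w = np.zeros_like(freqs)

    def add_segment(f0: float, f1: float) -> None:
        # contribution of linear segment between grid-interpolated points
        if f1 <= f0:
            return
        i0 = np.searchsorted(freqs, f0, side="right") - 1
        i1 = np.searchsorted(freqs, f1, side="right") - 1
        i1 = min(i1, len(freqs) - 2)
        h = f1 - f0
        # endpoints expressed as linear combinations of neighbouring grid values
        for f, coef in ((f0, h / 2), (f1, h / 2)):
            i = min(np.searchsorted(freqs, f, side="right") - 1, len(freqs) - 2)
            a = (f - freqs[i]) / (freqs[i + 1] - freqs[i])
            w[i] += coef * (1 - a)
            w[i + 1] += coef * a

    # split [lo, hi] at interior grid points so each segment is linear
    interior = freqs[(freqs > lo) & (freqs < hi)]
    nodes = np.concatenate(([lo], interior, [hi]))
    for f0, f1 in zip(nodes[:-1], nodes[1:]):
        add_segment(f0, f1)
    return w


def band_relative_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Per-band power fraction: band integral / total integral over the band
    union (0.5-100 Hz for the defaults).

    Output shape is ``psd.shape[:-1] + (n_bands,)``; rows with zero total
    power are undefined and returned as NaN.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    W = np.stack([_band_weights(freqs, b.lo, b.hi) for b in bands], axis=-1)
    band_power = psd @ W  # (..., n_bands)
    total = band_power.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = band_power / total
    frac[np.broadcast_to(total == 0, frac.shape)] = np.nan
    return frac


@dataclass
class BandPowerTable:
    """Trial x channel x band relative power with condition labels."""

    rel_power: np.ndarray
    condition: np.ndarray
    psd_freqs: np.ndarray
    welch_params: dict
    bands: tuple[BandDefinition, ...]
    channels: list[ChannelInfo]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (trial, channel, roi, condition, band, rel_power)."""
        rows = []
        for t in range(self.rel_power.shape[0]):
            for c, ch in enumerate(self.channels):
                for b, band in enumerate(self.bands):
                    rows.append(
                        (t, ch.label, ch.roi, self.condition[t], band.name,
                         self.rel_power[t, c, b])
                    )
        return pd.DataFrame(
            rows, columns=["trial", "channel", "roi", "condition", "band", "rel_power"]
        )


def band_power_table(
    epochs: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    window_s: tuple[float, float] = (0.0, 6.0),
    seg_s: float = 2.0,
    overlap: float = 0.5,
) -> BandPowerTable:
    """Per-trial normalized band powers over the stimulus window.

    Normalization is per trial (before any averaging), per lead.  Trials with
    zero total power are flagged as NaN and excluded downstream.
    """
    errs = validate_bands(bands, epochs.fs)
    if errs:
        raise ParameterError("; ".join(errs))
    sl = epochs.window_slice(window_s)
    freqs, psd = welch_psd(epochs.data[:, :, sl], epochs.fs, seg_s, overlap)
    rel = band_relative_power(freqs, psd, bands)
    return BandPowerTable(
        rel_power=rel,
        condition=epochs.conditions.copy(),
        psd_freqs=freqs,
        welch_params={"seg_s": seg_s, "overlap": overlap, "window": "hann"},
        bands=bands,
        channels=list(epochs.channels),
    )


def _pool_roi_power(table: BandPowerTable) -> tuple[np.ndarray, list[str]]:
    """Average rel_power across channels within each assigned ROI."""
    rois = list(dict.fromkeys(ch.roi for ch in table.channels if ch.roi != UNASSIGNED))
    if not rois:
        raise ParameterError("no ROI-assigned channels to pool")
    pooled = np.stack(
        [
            table.rel_power[:, [i for i, ch in enumerate(table.channels) if ch.roi == roi]]
            .mean(axis=1)
            for roi in rois
        ],
        axis=1,
    )
    return pooled, rois


def band_contrast(
    tables: BandPowerTable | list[BandPowerTable],
    by_roi: bool = False,
) -> pd.DataFrame:
    """Paired t-test per channel (or ROI) and band on relative power.

    A list of tables is treated as subjects (pairs are per-subject condition
    means); a single table pairs trials by presentation index.  Returns a
    tidy frame with columns unit, band, n_pairs, t, p, diff and direction
    ("Neg<Pos" or "Neg>Pos").
    """
    single = isinstance(tables, BandPowerTable)
    tabs = [tables] if single else list(tables)
    if not tabs:
        raise StatisticsError("no band power tables given")
    bands = tabs[0].bands

    def unit_power(tab: BandPowerTable) -> tuple[np.ndarray, list[str]]:
        if by_roi:
            return _pool_roi_power(tab)
        return tab.rel_power, [ch.label for ch in tab.channels]

    if single:
        power, units = unit_power(tabs[0])
        cond = tabs[0].condition
        neg, pos = power[cond == "Neg"], power[cond == "Pos"]
        n = min(len(neg), len(pos))
        if n < 2:
            raise StatisticsError(f"need >= 2 condition pairs, got {n}")
        diff = neg[:n] - pos[:n]
    else:
        if len(tabs) < 2:
            raise StatisticsError("subject-level pairing needs >= 2 subjects")
        diffs = []
        for tab in tabs:
            power, units = unit_power(tab)
            cond = tab.condition
            m_neg = np.nanmean(power[cond == "Neg"], axis=0)
            m_pos = np.nanmean(power[cond == "Pos"], axis=0)
            diffs.append(m_neg - m_pos)
        diff = np.asarray(diffs)

    t, p = paired_t(diff, axis=0)
    md = diff.mean(axis=0)
    rows = []
    for u, unit in enumerate(units):
        for b, band in enumerate(bands):
            rows.append(
                (
                    unit, band.name, diff.shape[0], t[u, b], p[u, b], md[u, b],
                    "Neg>Pos" if md[u, b] > 0 else "Neg<Pos",
                )
            )
    return pd.DataFrame(
        rows, columns=["unit", "band", "n_pairs", "t", "p", "diff", "direction"]
    )
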