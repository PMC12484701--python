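"""Bipolar montage construction and ROI bookkeeping.

Bipolar referencing subtracts adjacent contacts on the same shaft,
suppressing far-field components shared by neighbouring contacts.  The sign
convention is fixed globally as (lower contact index) minus (higher contact
index); sign conventions cancel in power and phase-locking analyses, but the
ERP contrast needs one consistent choice.
"""
from __future__ import annotations

import logging

import numpy as np

from .exceptions import ParameterError
from .io import UNASSIGNED, ChannelInfo, RecordingSession, RoiAtlas, DEFAULT_ROIS

logger = logging.getLogger(__name__)


def build_bipolar_montage(session: RecordingSession) -> RecordingSession:
    """Re-reference to adjacent-contact bipolar pairs.

    Each shaft with contacts ``c1 < c2 < ... < cm`` yields the ``m - 1``
    difference channels ``c_k - c_(k+1)``, labelled ``"<shaft>k-k+1"``.  The
    ROI of a pair is the parents' shared ROI when they agree, otherwise
    ``"unassigned"``; the MNI coordinate is the parents' midpoint.  Shafts
    with a single contact are skipped with a logged warning.  Applying the
    montage to an already-bipolar session is rejected.
    """
    if session.montage != "monopolar":
        raise ParameterError(
            f"bipolar montage already applied (montage={session.montage!r})"
        )
    by_shaft: dict[str, list[int]] = {}
    for i, ch in enumerate(session.channels):
        by_shaft.setdefault(ch.shaft_id, []).append(i)

    rows, new_channels = [], []
    for shaft, idx in by_shaft.items():
        idx = sorted(idx, key=lambda i: session.channels[i].contact_index)
        if len(idx) < 2:
            logger.warning("shaft %r has a single contact; no bipolar pair formed", shaft)
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            ca, cb = session.channels[a], session.channels[b]
            rows.append(session.data[a] - session.data[b])
            roi = ca.roi if ca.roi == cb.roi else UNASSIGNED
            coord = None
            if ca.mni_coord is not None and cb.mni_coord is not None:
                coord = tuple(
                    (x + y) / 2.0 for x, y in zip(ca.mni_coord, cb.mni_coord)
                )
            new_channels.append(
                ChannelInfo(
                    label=f"{shaft}{ca.contact_index}-{cb.contact_index}",
                    shaft_id=shaft,
                    contact_index=ca.contact_index,
                    mni_coord=coord,
                    roi=roi,
                )
            )
    data = np.asarray(rows) if rows else np.empty((0, session.n_samples))
    return RecordingSession(
        data=data,
        fs=session.fs,
        channels=new_channels,
        events=list(session.events),
        montage="bipolar",
    )


def summarize_atlas(
    sessions: list[RecordingSession], roi_vocabulary: tuple[str, ...] = DEFAULT_ROIS
) -> RoiAtlas:
    """Pool per-ROI contact counts over sessions.

    Counting is done on whatever montage state each session carries.
    """
    if not sessions:
        raise ParameterError("summarize_atlas needs at least one session")
    counts: dict[str, int] = {}
    for s in sessions:
        for ch in s.channels:
            counts[ch.roi] = counts.get(ch.roi, 0) + 1
    names = [r for r in roi_vocabulary if r in counts]
    names += sorted(r for r in counts if r not in roi_vocabulary and r != UNASSIGNED)
    if UNASSIGNED in counts:
        names.append(UNASSIGNED)
    return RoiAtlas(roi_names=tuple(names), contact_counts=counts)
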