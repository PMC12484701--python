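"""Recording containers and file I/O.

A recording session bundles the multichannel signal (microvolts), the sampling
rate, per-channel metadata (shaft, contact index, optional MNI coordinate, ROI
assignment) and the stimulus event table.  Two on-disk representations are
supported:

* a single-file ``.npz`` fixture that round-trips every field bit-exactly,
  used for tests and intermediate pipeline products;
* EDF/EDF+ for interchange with clinical software.  EDF stores samples as
  16-bit integers, so a round trip is exact only up to the per-channel
  quantization step.  Channel metadata and events travel in sidecar TSV files
  (columns ``label  shaft  contact  x  y  z  roi`` for channels,
  ``onset_sample  condition`` for events).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, MetadataError, ParameterError

#: The ROI vocabulary: amygdala, anterior/middle/posterior cingulate,
#: hippocampus, insula, orbitofrontal cortex and precuneus.
DEFAULT_ROIS = ("Amy", "ACC", "MCC", "PCC", "Hip", "Ins", "OFC", "Pcun")
UNASSIGNED = "unassigned"
CONDITIONS = ("Neg", "Pos")


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one recording channel (electrode contact or bipolar pair)."""

    label: str
    shaft_id: str
    contact_index: int
    mni_coord: tuple[float, float, float] | None = None
    roi: str = UNASSIGNED

    def __post_init__(self) -> None:
        if self.contact_index < 1:
            raise ParameterError(
                f"contact_index must be >= 1, got {self.contact_index} for {self.label!r}"
            )


@dataclass
class RecordingSession:
    """A continuous multichannel recording with events.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
        One entry per data row.
    events : list of (int, str)
        Stimulus onsets as 0-based sample indices at ``fs``, with condition
        label ``"Neg"`` or ``"Pos"``.
    montage : str
        ``"monopolar"`` for raw contacts, ``"bipolar"`` after adjacent-contact
        referencing.  Tracked so the bipolar montage cannot be applied twice.
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    events: list[tuple[int, str]]
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ParameterError(f"data must be 2-D, got shape {self.data.shape}")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if len(self.channels) != self.data.shape[0]:
            raise MetadataError(
                f"{len(self.channels)} channel entries for {self.data.shape[0]} data rows"
            )
        seen: dict[tuple[str, int], str] = {}
        for ch in self.channels:
            key = (ch.shaft_id, ch.contact_index)
            if key in seen:
                raise MetadataError(
                    f"duplicate contact {ch.contact_index} on shaft {ch.shaft_id!r} "
                    f"({seen[key]!r} and {ch.label!r})"
                )
            seen[key] = ch.label
        n = self.data.shape[1]
        for onset, cond in self.events:
            if not 0 <= onset < n:
                raise ParameterError(f"event onset {onset} outside [0, {n})")
            if cond not in CONDITIONS:
                raise ParameterError(f"unknown condition {cond!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def labels(self) -> list[str]:
        return [ch.label for ch in self.channels]


@dataclass
class RoiAtlas:
    """Per-ROI contact counts pooled over one or more sessions."""

    roi_names: tuple[str, ...]
    contact_counts: dict[str, int]

    def __post_init__(self) -> None:
        for roi, n in self.contact_counts.items():
            if n < 0:
                raise ParameterError(f"negative count for {roi!r}")
            if roi not in self.roi_names:
                raise ParameterError(f"counted roi {roi!r} missing from roi_names")


# ---------------------------------------------------------------------------
# channel / event tables (TSV)

_TABLE_COLS = ["label", "shaft", "contact", "x", "y", "z", "roi"]


def read_channel_table(path: str | Path) -> list[ChannelInfo]:
    """Read a TSV channel table into ChannelInfo records."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"label": str, "shaft": str, "roi": str})
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise FormatError(f"cannot read channel table {path}: {exc}") from exc
    missing = [c for c in ("label", "shaft", "contact") if c not in df.columns]
    if missing:
        raise FormatError(f"channel table {path} lacks columns {missing}")
    out = []
    for _, row in df.iterrows():
        coord = None
        if all(c in df.columns for c in "xyz"):
            xyz = [row["x"], row["y"], row["z"]]
            if not any(pd.isna(v) for v in xyz):
                coord = tuple(float(v) for v in xyz)
        roi = row.get("roi", UNASSIGNED)
        if pd.isna(roi) or not str(roi).strip():
            roi = UNASSIGNED
        out.append(
            ChannelInfo(
                label=str(row["label"]),
                shaft_id=str(row["shaft"]),
                contact_index=int(row["contact"]),
                mni_coord=coord,
                roi=str(roi),
            )
        )
    return out


def write_channel_table(channels: list[ChannelInfo], path: str | Path) -> None:
    rows = []
    for ch in channels:
        x, y, z = ch.mni_coord if ch.mni_coord is not None else (np.nan,) * 3
        rows.append([ch.label, ch.shaft_id, ch.contact_index, x, y, z, ch.roi])
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep="\t", index=False)


def read_event_table(path: str | Path) -> list[tuple[int, str]]:
    df = pd.read_csv(path, sep="\t")
    if not {"onset_sample", "condition"} <= set(df.columns):
        raise FormatError(f"event table {path} needs onset_sample and condition columns")
    return [(int(r.onset_sample), str(r.condition)) for r in df.itertuples()]


def write_event_table(events: list[tuple[int, str]], path: str | Path) -> None:
    pd.DataFrame(events, columns=["onset_sample", "condition"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# fixture format (.npz)


def save_fixture(session: RecordingSession, path: str | Path) -> None:
    """Write a session to the single-file fixture format (bit-exact)."""
    chans = session.channels
    mni = np.full((len(chans), 3), np.nan)
    for i, ch in enumerate(chans):
        if ch.mni_coord is not None:
            mni[i] = ch.mni_coord
    np.savez(
        path,
        data=session.data,
        fs=np.float64(session.fs),
        montage=np.str_(session.montage),
        onsets=np.array([e[0] for e in session.events], dtype=np.int64),
        conditions=np.array([e[1] for e in session.events], dtype="U8"),
        label=np.array([c.label for c in chans], dtype="U32"),
        shaft=np.array([c.shaft_id for c in chans], dtype="U16"),
        contact=np.array([c.contact_index for c in chans], dtype=np.int64),
        mni=mni,
        roi=np.array([c.roi for c in chans], dtype="U16"),
    )


def load_fixture(path: str | Path) -> RecordingSession:
    try:
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
    except Exception as exc:
        raise FormatError(f"cannot read fixture {path}: {exc}") from exc
    required = {"data", "fs", "onsets", "conditions", "label", "shaft", "contact", "roi"}
    if not required <= set(arrays):
        raise FormatError(f"fixture {path} missing keys {sorted(required - set(arrays))}")
    mni = arrays.get("mni")
    chans = []
    for i in range(len(arrays["label"])):
        coord = None
        if mni is not None and not np.any(np.isnan(mni[i])):
            coord = tuple(float(v) for v in mni[i])
        chans.append(
            ChannelInfo(
                label=str(arrays["label"][i]),
                shaft_id=str(arrays["shaft"][i]),
                contact_index=int(arrays["contact"][i]),
                mni_coord=coord,
                roi=str(arrays["roi"][i]),
            )
        )
    events = [
        (int(o), str(c)) for o, c in zip(arrays["onsets"], arrays["conditions"])
    ]
    montage = str(arrays["montage"]) if "montage" in arrays else "monopolar"
    return RecordingSession(
        data=arrays["data"], fs=float(arrays["fs"]), channels=chans,
        events=events, montage=montage,
    )


# ---------------------------------------------------------------------------
# EDF

_EDF_DIG_MAX = 32767


def write_edf(session: RecordingSession, path: str | Path) -> None:
    """Write the signal to a plain EDF file (16-bit, 1-second data records).

    Requires an integer sampling rate.  Events and channel metadata are not
    representable in plain EDF; write them with :func:`write_event_table` /
    :func:`write_channel_table` alongside.
    """
    spr = int(round(session.fs))
    if abs(session.fs - spr) > 1e-9 or spr <= 0:
        raise ParameterError(f"EDF writer needs an integer sampling rate, got {session.fs}")
    nch, ns = session.data.shape
    n_rec = -(-ns // spr)
    padded = np.zeros((nch, n_rec * spr))
    padded[:, :ns] = session.data

    pmax = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    scale = _EDF_DIG_MAX / pmax
    digital = np.rint(padded * scale[:, None]).astype("<i2")

    def a(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            a("0", 8), a("X X X X", 80), a("Startdate X X X X", 80),
            a("01.01.00", 8), a("00.00.00", 8),
            a(str(256 * (1 + nch)), 8), a("", 44), a(str(n_rec), 8),
            a("1", 8), a(str(nch), 4),
        ]
    )
    fields = [
        ("label", 16, [c.label for c in session.channels]),
        ("transducer", 80, [""] * nch),
        ("dim", 8, ["uV"] * nch),
        ("pmin", 8, [f"{-p:.6g}"[:8] for p in pmax]),
        ("pmax", 8, [f"{p:.6g}"[:8] for p in pmax]),
        ("dmin", 8, [str(-_EDF_DIG_MAX)] * nch),
        ("dmax", 8, [str(_EDF_DIG_MAX)] * nch),
        ("prefilter", 80, [""] * nch),
        ("spr", 8, [str(spr)] * nch),
        ("reserved", 32, [""] * nch),
    ]
    sig_header = b"".join(
        b"".join(a(str(v), width) for v in values) for _, width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: all channels sequentially within each record
        fh.write(
            np.ascontiguousarray(
                digital.reshape(nch, n_rec, spr).transpose(1, 0, 2)
            ).tobytes()
        )


def edf_quantization_step(session: RecordingSession) -> np.ndarray:
    """Per-channel worst-case amplitude error of an EDF round trip (uV)."""
    pmax = np.maximum(np.abs(session.data).max(axis=1), 1e-6)
    return pmax / _EDF_DIG_MAX


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (data_uV, fs, labels)."""
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# loading


def load_recording(
    path: str | Path,
    channel_table: str | Path | None = None,
    events: str | Path | None = None,
) -> RecordingSession:
    """Load a recording from the fixture format or EDF.

    ``channel_table`` (TSV) is required for EDF and optional for fixtures
    (where it overrides embedded metadata).  Channels present in the recording
    but absent from the table raise :class:`MetadataError` naming the
    offenders; table rois outside the declared vocabulary are kept verbatim.
    """
    path = Path(path)
    if path.suffix == ".npz":
        session = load_fixture(path)
        if channel_table is None:
            return session
        data, fs, labels = session.data, session.fs, session.labels()
        event_list = session.events
    elif path.suffix in {".edf", ".EDF"}:
        if channel_table is None:
            raise MetadataError("EDF input requires a channel_table")
        data, fs, labels = read_edf(path)
        event_list = read_event_table(events) if events is not None else []
    else:
        raise FormatError(f"unrecognized recording format: {path}")

    table = {c.label: c for c in read_channel_table(channel_table)}
    missing = [lb for lb in labels if lb not in table]
    if missing:
        raise MetadataError(f"channel table has no entry for: {', '.join(missing)}")
    channels = [table[lb] for lb in labels]
    return RecordingSession(data=data, fs=fs, channels=channels, events=event_list)
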