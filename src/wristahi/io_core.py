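"""Core data model and I/O for overnight wrist-PPG recordings.

Time convention used throughout the package: seconds from recording start,
0-based, with half-open 30-s epoch intervals ``[30k, 30(k+1))``.  Signals are
stored per channel with their own sampling rate (nominally 32 Hz rPPG, 128 Hz
tri-axial accelerometry, 512 Hz ECG).

Recordings travel as EDF files; scored events and hypnograms travel as plain
CSV (``type,onset,duration`` and ``epoch_index,stage``).  The EDF codec here is
deliberately minimal (classic EDF, 1-s records, 16-bit samples) but preserves
per-channel sampling rates on round-trip.
"""

from __future__ import annotations

import datetime as _dt
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("wristahi")

EPOCH_LENGTH = 30.0  # seconds, AASM scoring epoch

#: default regex patterns mapping EDF labels to channel roles
DEFAULT_CHANNEL_PATTERNS = {
    "rppg": r"(?i)ppg|pleth",
    "accel": r"(?i)acc",
    "ecg": r"(?i)ecg|ekg",
}


class EventType(str, Enum):
    OBSTRUCTIVE_APNEA = "obstructive_apnea"
    CENTRAL_APNEA = "central_apnea"
    MIXED_APNEA = "mixed_apnea"
    HYPOPNEA = "hypopnea"
    LIMB_MOVEMENT = "limb_movement"
    AROUSAL = "arousal"


#: event types that count as respiratory events for labelling and the AHI
RESPIRATORY_EVENT_TYPES = frozenset(
    {
        EventType.OBSTRUCTIVE_APNEA,
        EventType.CENTRAL_APNEA,
        EventType.MIXED_APNEA,
        EventType.HYPOPNEA,
    }
)


class SleepStage(str, Enum):
    W = "W"
    N1 = "N1"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"


#: 4-class collapse used by the stage-probability features (N1 and N2 merged)
STAGE_CLASSES = ("W", "N1/N2", "N3", "REM")

_STAGE_TO_CLASS = {
    SleepStage.W: 0,
    SleepStage.N1: 1,
    SleepStage.N2: 1,
    SleepStage.N3: 2,
    SleepStage.REM: 3,
}


def stage_class_index(stage: SleepStage) -> int:
    """Map a 5-level hypnogram stage to the 4-class index (W, N1/N2, N3, REM)."""
    return _STAGE_TO_CLASS[SleepStage(stage)]


@dataclass
class Channel:
    """A uniformly sampled signal: ``samples`` (1-D or n x k) at ``rate`` Hz."""

    samples: np.ndarray
    rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.rate


@dataclass
class Recording:
    """One overnight recording from the wrist device.

    ``rppg`` is mandatory; ``accel`` carries 3 columns (x, y, z) and is needed
    for activity counts and movement-based truncation; ``ecg`` is optional and
    only used for training-set eligibility checks.
    """

    id: str
    rppg: Channel
    accel: Optional[Channel] = None
    ecg: Optional[Channel] = None
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 22, 0, 0)
    )

    def __post_init__(self) -> None:
        durations = [self.rppg.duration]
        if self.accel is not None:
            if self.accel.samples.ndim != 2 or self.accel.samples.shape[1] != 3:
                raise ValueError("accel channel must have 3 columns (x, y, z)")
            durations.append(self.accel.duration)
        if self.ecg is not None:
            durations.append(self.ecg.duration)
        # channel lengths must agree on a common duration within one sample
        tol = max(1.0 / c.rate for c in self.channels())
        if max(durations) - min(durations) > tol + 1e-9:
            raise ValueError("channel durations inconsistent")

    def channels(self) -> list[Channel]:
        out = [self.rppg]
        if self.accel is not None:
            out.append(self.accel)
        if self.ecg is not None:
            out.append(self.ecg)
        return out

    @property
    def duration(self) -> float:
        """Common recording duration in seconds (shortest channel)."""
        return min(c.duration for c in self.channels())


@dataclass(frozen=True)
class ScoredEvent:
    """A manually scored sleep event: type, onset and duration in seconds."""

    type: EventType
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("event onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("event duration must be > 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class AnnotationSet:
    """Scored events plus per-epoch hypnogram and the reference AHI."""

    events: list[ScoredEvent]
    hypnogram: list[SleepStage]
    reference_ahi: Optional[float] = None
    diagnosis: Optional[str] = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset, e.duration))
        self.hypnogram = [SleepStage(s) for s in self.hypnogram]
        if self.reference_ahi is not None and self.reference_ahi < 0:
            raise ValueError("reference AHI must be >= 0")
        for a, b in zip(self.events, self.events[1:]):
            if a.type == b.type and b.onset < a.end and b.end <= a.end and b.onset >= a.onset:
                raise ValueError(f"nested events of type {a.type.value}")

    def respiratory_events(self) -> list[ScoredEvent]:
        return [e for e in self.events if e.type in RESPIRATORY_EVENT_TYPES]


@dataclass(frozen=True)
class EpochGrid:
    """The 30-s epoch grid: epoch k covers [30k, 30(k+1)) seconds."""

    n_epochs: int
    epoch_length: float = EPOCH_LENGTH

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ValueError("grid must contain at least one epoch")

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_length

    def starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_length

    def centers(self) -> np.ndarray:
        return self.starts() + self.epoch_length / 2.0

    def epoch_of(self, t: float) -> int:
        """Epoch index containing time ``t`` (half-open intervals)."""
        k = int(np.floor(t / self.epoch_length))
        if not 0 <= k < self.n_epochs:
            raise ValueError(f"time {t} outside the epoch grid")
        return k


def make_epoch_grid(duration: float, epoch_length: float = EPOCH_LENGTH) -> EpochGrid:
    """Build the epoch grid for a recording, discarding the trailing partial epoch.

    Raises ``ValueError`` for recordings shorter than one epoch (these are
    excluded upstream by the 30-min minimum-sleep rule anyway).
    """
    if duration < epoch_length:
        raise ValueError(
            f"recording of {duration:.0f}s is shorter than one {epoch_length:.0f}s epoch"
        )
    return EpochGrid(n_epochs=int(np.floor(duration / epoch_length)), epoch_length=epoch_length)


# ---------------------------------------------------------------------------
# EDF codec
#
# Classic EDF: 256-byte fixed header, 256 bytes per signal header, then
# fixed-duration data records of little-endian int16 samples.  1-s records are
# used so integer sampling rates map directly to samples-per-record.
# ---------------------------------------------------------------------------


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, recording: Recording) -> None:
    """Write a Recording to a classic EDF file (16-bit, 1-s data records)."""
    path = Path(path)
    signals: list[tuple[str, np.ndarray, int]] = []
    r = recording
    if r.rppg.rate != int(r.rppg.rate):
        raise ValueError("EDF writer requires integer sampling rates")
    signals.append(("PPG wrist", r.rppg.samples, int(r.rppg.rate)))
    if r.accel is not None:
        for i, ax in enumerate("XYZ"):
            signals.append((f"Accel {ax}", r.accel.samples[:, i], int(r.accel.rate)))
    if r.ecg is not None:
        signals.append(("ECG II", r.ecg.samples, int(r.ecg.rate)))

    n_records = min(len(x) // sr for _, x, sr in signals)
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")

    n_sig = len(signals)
    header_bytes = 256 + 256 * n_sig
    st = recording.start_time
    head = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {recording.id}", 80),
            _pad("Startdate X X X X", 80),
            _pad(st.strftime("%d.%m.%y"), 8),
            _pad(st.strftime("%H.%M.%S"), 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )

    phys_min, phys_max, digitised = [], [], []
    for _, x, sr in signals:
        x = np.asarray(x[: n_records * sr], dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            lo, hi = lo - 1.0, hi + 1.0
        scale = (hi - lo) / (32767 - (-32768))
        dig = np.round((x - lo) / scale) + (-32768)
        digitised.append(dig.astype("<i2"))
        phys_min.append(lo)
        phys_max.append(hi)

    def col(vals: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in vals)

    sig_head = b"".join(
        [
            col([lab for lab, _, _ in signals], 16),
            col(["" for _ in signals], 80),
            col(["au" for _ in signals], 8),
            col([f"{v:.8g}"[:8] for v in phys_min], 8),
            col([f"{v:.8g}"[:8] for v in phys_max], 8),
            col(["-32768" for _ in signals], 8),
            col(["32767" for _ in signals], 8),
            col(["" for _ in signals], 80),
            col([str(sr) for _, _, sr in signals], 8),
            col(["" for _ in signals], 32),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(head + sig_head)
        for rec in range(n_records):
            for (_, _, sr), dig in zip(signals, digitised):
                fh.write(dig[rec * sr : (rec + 1) * sr].tobytes())


def _read_edf_raw(path: Path) -> tuple[dict, list[str], list[np.ndarray], list[int]]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("unreadable EDF header (truncated)")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            n_sig = int(head[252:256].decode("ascii").strip())
            date = head[168:176].decode("ascii").strip()
            time = head[176:184].decode("ascii").strip()
        except ValueError as exc:
            raise ValueError("unreadable EDF header") from exc
        sig_head = fh.read(256 * n_sig)
        fields = {}
        off = 0
        for name, width in [
            ("label", 16), ("transducer", 80), ("dim", 8), ("phys_min", 8),
            ("phys_max", 8), ("dig_min", 8), ("dig_max", 8), ("prefilter", 80),
            ("spr", 8), ("reserved", 32),
        ]:
            fields[name] = [
                sig_head[off + i * width : off + (i + 1) * width].decode("ascii").strip()
                for i in range(n_sig)
            ]
            off += width * n_sig
        spr = [int(v) for v in fields["spr"]]
        data = np.frombuffer(fh.read(), dtype="<i2")

    per_rec = sum(spr)
    data = data[: n_records * per_rec].reshape(n_records, per_rec)
    signals = []
    pos = 0
    for i in range(n_sig):
        dig = data[:, pos : pos + spr[i]].reshape(-1).astype(float)
        pos += spr[i]
        pmin, pmax = float(fields["phys_min"][i]), float(fields["phys_max"][i])
        dmin, dmax = float(fields["dig_min"][i]), float(fields["dig_max"][i])
        phys = pmin + (dig - dmin) * (pmax - pmin) / (dmax - dmin)
        signals.append(phys)
    try:
        start = _dt.datetime.strptime(date + " " + time, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = _dt.datetime(2000, 1, 1)
    meta = {"n_records": n_records, "record_duration": record_dur, "start_time": start}
    rates = [s / record_dur for s in spr]
    return meta, fields["label"], signals, rates


def read_recording(
    path: str | Path,
    channel_patterns: dict[str, str] | None = None,
    recording_id: str | None = None,
) -> Recording:
    """Read an EDF file into a Recording, mapping channels by label regex.

    ``channel_patterns`` maps roles (``rppg``, ``accel``, ``ecg``) to regex
    patterns tested against EDF signal labels; EDF label dialects vary, so the
    patterns are configurable.  A missing rPPG channel is fatal.
    """
    path = Path(path)
    pats = dict(DEFAULT_CHANNEL_PATTERNS)
    if channel_patterns:
        pats.update(channel_patterns)
    meta, labels, signals, rates = _read_edf_raw(path)

    def find(role: str) -> list[int]:
        rx = re.compile(pats[role])
        return [i for i, lab in enumerate(labels) if rx.search(lab)]

    ppg_idx = find("rppg")
    if not ppg_idx:
        raise ValueError(f"no rPPG channel in {path} (labels: {labels})")
    rppg = Channel(signals[ppg_idx[0]], rates[ppg_idx[0]], labels[ppg_idx[0]])

    accel = None
    acc_idx = find("accel")
    if len(acc_idx) >= 3:
        acc_idx = acc_idx[:3]
        if len({rates[i] for i in acc_idx}) != 1:
            raise ValueError("accelerometer channels have mismatched rates")
        accel = Channel(
            np.column_stack([signals[i] for i in acc_idx]), rates[acc_idx[0]], "accel"
        )

    ecg = None
    ecg_idx = find("ecg")
    if ecg_idx:
        ecg = Channel(signals[ecg_idx[0]], rates[ecg_idx[0]], labels[ecg_idx[0]])

    return Recording(
        id=recording_id or path.stem,
        rppg=rppg,
        accel=accel,
        ecg=ecg,
        start_time=meta["start_time"],
    )


# ---------------------------------------------------------------------------
# Annotation CSV I/O
# ---------------------------------------------------------------------------


def write_annotations(
    events_path: str | Path,
    hypnogram_path: str | Path,
    annotations: AnnotationSet,
) -> None:
    ev = pd.DataFrame(
        {
            "type": [e.type.value for e in annotations.events],
            "onset": [e.onset for e in annotations.events],
            "duration": [e.duration for e in annotations.events],
        }
    )
    ev.to_csv(events_path, index=False)
    hyp = pd.DataFrame(
        {
            "epoch_index": np.arange(len(annotations.hypnogram)),
            "stage": [s.value for s in annotations.hypnogram],
        }
    )
    hyp.to_csv(hypnogram_path, index=False)


def read_annotations(
    events_path: str | Path,
    hypnogram_path: str | Path | None = None,
    reference_ahi: float | None = None,
    diagnosis: str | None = None,
) -> AnnotationSet:
    """Read scored events (and optionally a hypnogram) from CSV.

    Events CSV columns: ``type,onset,duration``; hypnogram CSV columns:
    ``epoch_index,stage``.  Unknown event types or stage codes are fatal, as is
    a negative duration.
    """
    ev = pd.read_csv(events_path)
    events = []
    for row in ev.itertuples(index=False):
        try:
            etype = EventType(row.type)
        except ValueError as exc:
            raise ValueError(f"unknown event type {row.type!r}") from exc
        events.append(ScoredEvent(etype, float(row.onset), float(row.duration)))

    hypnogram: list[SleepStage] = []
    if hypnogram_path is not None:
        hyp = pd.read_csv(hypnogram_path).sort_values("epoch_index")
        for code in hyp["stage"]:
            try:
                hypnogram.append(SleepStage(str(code)))
            except ValueError as exc:
                raise ValueError(f"unknown sleep stage code {code!r}") from exc

    return AnnotationSet(
        events=events,
        hypnogram=hypnogram,
        reference_ahi=reference_ahi,
        diagnosis=diagnosis,
    )


def load_config(path: str | Path) -> dict:
    """Load a flat key/value configuration file (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a flat key/value mapping")
    return cfg
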