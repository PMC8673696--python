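"""Core domain types and recording-bundle I/O.

A *recording bundle* is a directory holding one session of multichannel
magnetomyography (MMG) + auxiliary (surface EMG, ECG) data:

    <bundle>/
        data.npy      raw samples, float64, shape (n_channels, n_samples)
        meta.json     sampling rate, subject/session labels, per-channel
                      metadata (name, role, position, units)
        events.tsv    exercise-onset annotations, columns
                      onset_s / label / duration_s

The layout is deliberately plain so every part of a session can be inspected
with standard tools.  ``write_recording``/``read_recording`` round-trip all
fields losslessly (the array file is an exact binary image of the float64
matrix).
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ChannelRole",
    "Session",
    "ExerciseLabel",
    "ChannelInfo",
    "Event",
    "EventList",
    "Recording",
    "PipelineConfig",
    "BundleError",
    "write_recording",
    "read_recording",
    "MMG_ROLES",
    "EMG_ROLES",
]


class BundleError(ValueError):
    """Raised when a recording bundle or its metadata violates an invariant."""


class ChannelRole(str, enum.Enum):
    MMG_LOWER = "mmg_lower"
    MMG_OTHER = "mmg_other"
    MMG_EDGE_REFERENCE = "mmg_edge_reference"
    EMG_PERINEUM = "emg_perineum"
    EMG_ABDOMEN = "emg_abdomen"
    EMG_THIGH = "emg_thigh"
    ECG = "ecg"


MMG_ROLES = frozenset(
    {ChannelRole.MMG_LOWER, ChannelRole.MMG_OTHER, ChannelRole.MMG_EDGE_REFERENCE}
)
EMG_ROLES = frozenset(
    {ChannelRole.EMG_PERINEUM, ChannelRole.EMG_ABDOMEN, ChannelRole.EMG_THIGH}
)

#: default units per role: magnetometers report femtotesla, electrodes microvolt
ROLE_UNITS = {role: ("fT" if role in MMG_ROLES else "uV") for role in ChannelRole}


class Session(str, enum.Enum):
    THIRD_TRIMESTER = "third_trimester"
    POSTPARTUM = "postpartum"


class ExerciseLabel(str, enum.Enum):
    """Exercise annotations: graded Kegels plus isolated accessory contractions."""

    SMK = "SmK"  # small Kegel
    MK = "MK"  # moderate Kegel (the analyzed condition)
    STK = "StK"  # strong Kegel
    A = "A"  # isolated abdominal contraction
    T = "T"  # isolated thigh contraction


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one sensor channel.

    Parameters
    ----------
    name:
        Channel identifier, e.g. ``"MMG042"``.
    role:
        Functional role of the channel (lower MMG sensors sit closest to the
        pelvic floor; edge sensors serve as thigh-interference references).
    position:
        3-vector, metres, in the sensor-array frame.
    units:
        Physical units of the samples; defaults to fT for MMG and uV for
        EMG/ECG roles.
    """

    name: str
    role: ChannelRole
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    units: str = ""

    def __post_init__(self) -> None:
        role = ChannelRole(self.role)
        object.__setattr__(self, "role", role)
        pos = tuple(float(p) for p in self.position)
        if len(pos) != 3:
            raise BundleError(f"channel {self.name}: position must be a 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.units:
            object.__setattr__(self, "units", ROLE_UNITS[role])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "role": self.role.value,
            "position": list(self.position),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelInfo":
        return cls(
            name=d["name"],
            role=ChannelRole(d["role"]),
            position=tuple(d.get("position", (0.0, 0.0, 0.0))),
            units=d.get("units", ""),
        )


@dataclass(frozen=True)
class Event:
    """One exercise-onset annotation (onset seconds, label, duration seconds)."""

    onset_s: float
    label: ExerciseLabel
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ExerciseLabel(self.label))
        object.__setattr__(self, "onset_s", float(self.onset_s))
        object.__setattr__(self, "duration_s", float(self.duration_s))


@dataclass
class EventList:
    """Ordered list of exercise-onset annotations for one session."""

    entries: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [e if isinstance(e, Event) else Event(*e) for e in self.entries]
        onsets = [e.onset_s for e in self.entries]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise BundleError("event onsets must be non-decreasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def select(self, labels: Iterable[ExerciseLabel | str]) -> "EventList":
        wanted = {ExerciseLabel(l) for l in labels}
        return EventList([e for e in self.entries if e.label in wanted])

    def validate_against(self, duration_s: float) -> None:
        for e in self.entries:
            if e.onset_s + e.duration_s > duration_s + 1e-9:
                raise BundleError(
                    f"event {e.label.value}@{e.onset_s}s extends past recording "
                    f"end ({duration_s:.3f}s)"
                )


@dataclass
class Recording:
    """One multichannel session: samples matrix plus channel and subject metadata.

    ``data`` has shape ``(n_channels, n_samples)``; row *i* belongs to
    ``channels[i]``.  All samples must be finite.
    """

    data: np.ndarray
    fs: float = 1200.0
    channels: list[ChannelInfo] = field(default_factory=list)
    subject_id: str = "S00"
    session: Session = Session.THIRD_TRIMESTER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise BundleError("data must be a 2-D (channels x samples) array")
        self.session = Session(self.session)
        if self.fs <= 0:
            raise BundleError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise BundleError(
                f"channel metadata count ({len(self.channels)}) does not match "
                f"data rows ({self.data.shape[0]})"
            )
        if not np.all(np.isfinite(self.data)):
            raise BundleError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_indices(self, roles: Iterable[ChannelRole | str]) -> np.ndarray:
        wanted = {ChannelRole(r) for r in roles}
        return np.array(
            [i for i, ch in enumerate(self.channels) if ch.role in wanted], dtype=int
        )

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the samples matrix replaced."""
        return Recording(
            data=np.asarray(data, dtype=np.float64),
            fs=self.fs,
            channels=list(self.channels),
            subject_id=self.subject_id,
            session=self.session,
        )


# --------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """All fixed scalars of the analysis chain, with study defaults.

    Band edges are in Hz, window lengths in seconds unless noted.  The epoch
    window is trigger-locked: 3 s pre-trigger baseline, 10 s contraction.
    """

    low_cut_hz: float = 20.0
    high_cut_hz: float = 200.0
    filter_order: int = 4
    notch_hz: float = 60.0
    notch_q: float = 30.0
    epoch_window_s: tuple[float, float] = (-3.0, 10.0)
    rms_window_s: float = 0.2
    rms_overlap_s: float = 0.199
    smooth_points: int = 100
    welch_window_s: float = 1.0
    welch_overlap: float = 0.5
    band_edges_hz: tuple[float, float, float, float] = (20.0, 80.0, 140.0, 200.0)
    snr_threshold_db: float = 1.0
    alpha: float = 0.05
    ica_enabled: bool = True
    ica_corr_threshold: float = 0.8
    ica_edge_energy_threshold: float = 0.8
    subtr_window_s: float = 1.0
    subtr_loading: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.epoch_window_s = tuple(self.epoch_window_s)  # type: ignore[assignment]
        self.band_edges_hz = tuple(self.band_edges_hz)  # type: ignore[assignment]
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValueError("band edges must satisfy 0 < low < high")
        if list(self.band_edges_hz) != sorted(self.band_edges_hz) or len(
            set(self.band_edges_hz)
        ) != 4:
            raise ValueError("rPSD band edges must be strictly increasing")
        for name in ("rms_window_s", "welch_window_s", "subtr_window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epoch_window_s[0] >= self.epoch_window_s[1]:
            raise ValueError("epoch window must have positive length")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["epoch_window_s"] = list(self.epoch_window_s)
        d["band_edges_hz"] = list(self.band_edges_hz)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


# --------------------------------------------------------------------------
# bundle reader / writer

_META_NAME = "meta.json"
_DATA_NAME = "data.npy"
_EVENTS_NAME = "events.tsv"
_EVENT_COLUMNS = ("onset_s", "label", "duration_s")


def write_recording(
    recording: Recording, events: EventList, path: str | Path
) -> Path:
    """Write a recording bundle (data.npy + meta.json + events.tsv) to *path*.

    Returns the bundle directory.  Raises :class:`BundleError` on inconsistent
    metadata (events past end of recording etc.).
    """
    events.validate_against(recording.duration_s)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / _DATA_NAME, recording.data)
    meta = {
        "fs": recording.fs,
        "subject_id": recording.subject_id,
        "session": recording.session.value,
        "channels": [ch.to_dict() for ch in recording.channels],
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    lines = ["\t".join(_EVENT_COLUMNS)]
    for e in events:
        lines.append(f"{e.onset_s}\t{e.label.value}\t{e.duration_s}")
    (path / _EVENTS_NAME).write_text("\n".join(lines) + "\n")
    return path


def _read_events(path: Path) -> EventList:
    lines = path.read_text().splitlines()
    if not lines or tuple(lines[0].split("\t")) != _EVENT_COLUMNS:
        raise BundleError(f"events file {path} missing header {_EVENT_COLUMNS}")
    entries = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 3:
            raise BundleError(f"malformed events line: {ln!r}")
        onset, label, duration = parts
        try:
            lab = ExerciseLabel(label)
        except ValueError as exc:
            raise BundleError(f"unknown exercise label {label!r}") from exc
        entries.append(Event(float(onset), lab, float(duration)))
    return EventList(entries)


def read_recording(path: str | Path) -> tuple[Recording, EventList]:
    """Read a recording bundle, validating every invariant of the types."""
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise BundleError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    data = np.load(path / _DATA_NAME)
    channels = [ChannelInfo.from_dict(d) for d in meta["channels"]]
    recording = Recording(
        data=data,
        fs=float(meta["fs"]),
        channels=channels,
        subject_id=meta.get("subject_id", "S00"),
        session=Session(meta.get("session", "third_trimester")),
    )
    events = _read_events(path / _EVENTS_NAME)
    events.validate_against(recording.duration_s)
    return recording, events
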