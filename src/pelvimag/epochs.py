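"""Trigger-locked epoching, baseline correction, and SNR-gated quality control.

Epochs span -3 s to +10 s around each exercise-onset trigger: the 3 s
pre-trigger interval is the rest baseline, the 10 s post-trigger interval is
the contraction.  Signal quality per epoch is the squared ratio of
contraction RMS to baseline RMS in dB, pooled over the lower MMG sensors;
epochs below the 1 dB threshold are discarded, and a (subject, session) with
no surviving epochs excludes that subject from downstream paired analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_core import (
    ChannelInfo,
    ChannelRole,
    EventList,
    ExerciseLabel,
    Recording,
    Session,
)

__all__ = [
    "Epoch",
    "EpochSet",
    "QCReport",
    "extract_epochs",
    "baseline_correct",
    "epoch_snr_db",
    "qc_filter",
]

logger = logging.getLogger(__name__)

#: cap used when the baseline interval has exactly zero power
SNR_CAP_DB = 300.0


@dataclass
class Epoch:
    """One trigger-locked segment: 3 s baseline + 10 s contraction by default."""

    data: np.ndarray  # channels x samples
    fs: float
    channels: list[ChannelInfo]
    label: ExerciseLabel
    onset_s: float
    window_s: tuple[float, float] = (-3.0, 10.0)
    subject_id: str = "S00"
    session: Session = Session.THIRD_TRIMESTER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.label = ExerciseLabel(self.label)
        self.session = Session(self.session)
        expected = int(round(self.window_s[1] * self.fs)) - int(
            round(self.window_s[0] * self.fs)
        )
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch has {self.data.shape[1]} samples, expected {expected}"
            )

    @property
    def n_baseline(self) -> int:
        """Samples before the trigger (the trigger sample itself is signal)."""
        return -int(round(self.window_s[0] * self.fs))

    @property
    def baseline(self) -> np.ndarray:
        return self.data[:, : self.n_baseline]

    @property
    def signal(self) -> np.ndarray:
        return self.data[:, self.n_baseline :]

    def channel_indices(self, roles: Iterable[ChannelRole | str]) -> np.ndarray:
        wanted = {ChannelRole(r) for r in roles}
        return np.array(
            [i for i, ch in enumerate(self.channels) if ch.role in wanted], dtype=int
        )


@dataclass
class EpochSet:
    """Epochs sharing a channel set and sampling rate, plus QC bookkeeping."""

    epochs: list[Epoch] = field(default_factory=list)
    n_out_of_bounds: int = 0
    snr_db: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            fs0 = self.epochs[0].fs
            nch0 = self.epochs[0].data.shape[0]
            for e in self.epochs:
                if e.fs != fs0 or e.data.shape[0] != nch0:
                    raise ValueError("all epochs must share fs and channel set")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


@dataclass
class QCReport:
    """Outcome of the SNR gate: per-epoch decisions and subject exclusions."""

    threshold_db: float
    records: list[dict] = field(default_factory=list)
    excluded_subjects: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return sum(1 for r in self.records if r["kept"])

    @property
    def n_discarded(self) -> int:
        return len(self.records) - self.n_kept

    def to_dict(self) -> dict:
        return {
            "threshold_db": self.threshold_db,
            "n_kept": self.n_kept,
            "n_discarded": self.n_discarded,
            "epochs": self.records,
            "excluded_subjects": [
                {"subject": s, "session": sess} for s, sess in self.excluded_subjects
            ],
        }


def extract_epochs(
    recording: Recording,
    events: EventList,
    labels: Iterable[ExerciseLabel | str] | None = None,
    window_s: tuple[float, float] = (-3.0, 10.0),
) -> EpochSet:
    """Cut one epoch per selected event; out-of-bounds windows are dropped.

    An empty selection yields an empty :class:`EpochSet`, not an error.
    Sample indices derive from onset seconds by rounding ``onset * fs``.
    """
    selected = events.select(labels) if labels is not None else events
    off0 = int(round(window_s[0] * recording.fs))
    off1 = int(round(window_s[1] * recording.fs))
    epochs: list[Epoch] = []
    dropped = 0
    for ev in selected:
        trig = int(round(ev.onset_s * recording.fs))
        start, stop = trig + off0, trig + off1
        if start < 0 or stop > recording.n_samples:
            dropped += 1
            logger.warning(
                "dropping %s epoch at %.3fs: window [%d, %d) outside recording",
                ev.label.value,
                ev.onset_s,
                start,
                stop,
            )
            continue
        epochs.append(
            Epoch(
                data=recording.data[:, start:stop].copy(),
                fs=recording.fs,
                channels=list(recording.channels),
                label=ev.label,
                onset_s=ev.onset_s,
                window_s=window_s,
                subject_id=recording.subject_id,
                session=recording.session,
            )
        )
    return EpochSet(epochs=epochs, n_out_of_bounds=dropped)


def baseline_correct(epoch: Epoch) -> Epoch:
    """Subtract each channel's baseline-interval mean from the whole epoch."""
    mu = epoch.baseline.mean(axis=1, keepdims=True)
    return replace(epoch, data=epoch.data - mu, channels=list(epoch.channels))


def _pooled_rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x**2)))


def epoch_snr_db(
    epoch: Epoch,
    channel_roles: Iterable[ChannelRole | str] = (ChannelRole.MMG_LOWER,),
    per_channel_max: bool = False,
) -> float:
    """Signal-to-noise ratio: 10*log10((RMS_signal / RMS_baseline)^2), dB.

    By default RMS pools samples over the lower-sensor subset and the full
    interval; ``per_channel_max=True`` instead returns the best single
    channel's SNR.  Zero baseline RMS is reported as a capped sentinel
    (+300 dB) with a warning.
    """
    idx = epoch.channel_indices(channel_roles)
    if len(idx) == 0:
        raise ValueError("no channels match the requested roles")

    def _one(sig: np.ndarray, base: np.ndarray) -> float:
        rs, rb = _pooled_rms(sig), _pooled_rms(base)
        if rb == 0.0:
            if rs == 0.0:
                return 0.0
            warnings.warn("zero baseline RMS; SNR capped", stacklevel=3)
            return SNR_CAP_DB
        return 20.0 * np.log10(rs / rb)

    if per_channel_max:
        return max(_one(epoch.signal[i], epoch.baseline[i]) for i in idx)
    return _one(epoch.signal[idx], epoch.baseline[idx])


def qc_filter(
    epoch_set: EpochSet,
    threshold_db: float = 1.0,
    channel_roles: Iterable[ChannelRole | str] = (ChannelRole.MMG_LOWER,),
) -> tuple[EpochSet, QCReport]:
    """Discard epochs whose SNR falls below the threshold (strictly < rule).

    An epoch at exactly the threshold is kept — only epochs *below* the
    threshold are excluded.  Any (subject, session) group whose kept-epoch
    count drops to zero is flagged for whole-subject exclusion from the
    paired analysis.
    """
    kept: list[Epoch] = []
    kept_snr: list[float] = []
    report = QCReport(threshold_db=threshold_db)
    group_counts: dict[tuple[str, str], int] = {}
    for i, ep in enumerate(epoch_set):
        snr = epoch_snr_db(ep, channel_roles)
        # strict "below threshold" rule, robust to float round-off at the edge
        keep = not (snr < threshold_db - 1e-9)
        key = (ep.subject_id, ep.session.value)
        group_counts.setdefault(key, 0)
        if keep:
            kept.append(ep)
            kept_snr.append(snr)
            group_counts[key] += 1
        else:
            logger.warning(
                "discarding %s epoch %d of %s/%s: SNR %.2f dB < %.2f dB",
                ep.label.value,
                i,
                *key,
                snr,
                threshold_db,
            )
        report.records.append(
            {
                "index": i,
                "subject": ep.subject_id,
                "session": ep.session.value,
                "label": ep.label.value,
                "snr_db": float(snr),
                "kept": bool(keep),
            }
        )
    report.excluded_subjects = sorted(k for k, n in group_counts.items() if n == 0)
    out = EpochSet(
        epochs=kept, n_out_of_bounds=epoch_set.n_out_of_bounds, snr_db=kept_snr
    )
    return out, report
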