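"""Protocol-faithful synthetic MMG sessions with known ground truth.

The study protocol this emulates: a participant seated over a 151-sensor
SQUID array performs graded voluntary pelvic-floor contractions (small /
moderate / strong Kegels: SmK / MK / StK), then isolated abdominal (A) and
thigh (T) contractions, each 10 s long with intervening 10 s rest, sampled at
1200 Hz.  Simultaneous surface EMG (perineum, abdomen, thigh) and one chest
ECG channel are recorded.

Each contraction burst is band-limited Gaussian noise whose power is split
across the three analysis bands (20-80 / 80-140 / 140-200 Hz) by an exact
spectral-mask decomposition, so the generated band fractions equal the
requested weights by construction.  Bursts are amplitude-modulated by a
raised-cosine on/off envelope and projected onto the array with exponential
spatial falloff from a role-specific target point.  Interference comprises
thigh/abdominal muscle activity concentrated on the array edge, a QRS-like
cardiac template repeated at ~70 bpm with jitter, a 60 Hz line tone, and a
broadband white-noise floor.

A paired-study generator draws per-subject parameters around a base
specification and applies a pregnancy-to-postpartum effect, returning both
the recordings and a ground-truth parameter table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import (
    ChannelInfo,
    ChannelRole,
    Event,
    EventList,
    ExerciseLabel,
    MMG_ROLES,
    Recording,
    Session,
)

__all__ = [
    "BurstSpec",
    "SessionSpec",
    "EffectSpec",
    "make_sensor_array",
    "default_bursts",
    "simulate_session",
    "simulate_paired_study",
    "draw_parameter_study",
    "band_components",
    "burst_envelope",
    "cardiac_template_train",
]

#: analysis band edges (Hz) used for burst band shaping: low / middle / high
BAND_EDGES = (20.0, 80.0, 140.0, 200.0)

_ARRAY_RADIUS_M = 0.13  # curvature radius of the sensor surface
_CAP_HALF_ANGLE = math.radians(60.0)
_FALLOFF_M = 0.045  # spatial decay length of burst projection
_SUPPORT_M = 0.12  # projection support radius: no pickup beyond this distance


@dataclass(frozen=True)
class BurstSpec:
    """Ground truth for one contraction type.

    ``band_profile`` gives the fractions of burst power in the low / middle /
    high analysis bands (must sum to 1); ``spatial_target`` is the channel
    role the burst projects onto most strongly.
    """

    label: ExerciseLabel
    amplitude_fT: float
    band_profile: tuple[float, float, float]
    spatial_target: ChannelRole = ChannelRole.MMG_LOWER

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", ExerciseLabel(self.label))
        object.__setattr__(self, "spatial_target", ChannelRole(self.spatial_target))
        w = np.asarray(self.band_profile, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not np.isfinite(w).all():
            raise ValueError("band_profile must be three non-negative weights")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("band_profile weights must sum to 1")
        if not (np.isfinite(self.amplitude_fT) and self.amplitude_fT > 0):
            raise ValueError("amplitude_fT must be finite and positive")
        object.__setattr__(self, "band_profile", tuple(w))


@dataclass(frozen=True)
class SessionSpec:
    """Session layout and interference levels.

    Durations in seconds; interference levels are RMS amplitudes in the same
    units as the MMG channels (fT).  ``n_kegel_cycles`` repeats the
    SmK -> MK -> StK sequence; A and T contractions follow once each.
    """

    n_kegel_cycles: int = 3
    rest_s: float = 10.0
    contraction_s: float = 10.0
    fs: float = 1200.0
    n_sensors: int = 151
    n_lower: int = 20
    n_edge_ref: int = 12
    thigh_level: float = 40.0
    abdominal_level: float = 20.0
    cardiac_level: float = 15.0
    line_level: float = 10.0
    noise_floor: float = 5.0

    def __post_init__(self) -> None:
        if min(self.rest_s, self.contraction_s) <= 0 or self.fs <= 0:
            raise ValueError("durations and sampling rate must be positive")
        levels = (
            self.thigh_level,
            self.abdominal_level,
            self.cardiac_level,
            self.line_level,
            self.noise_floor,
        )
        if any(l < 0 for l in levels):
            raise ValueError("interference levels must be non-negative")
        if self.n_kegel_cycles < 0:
            raise ValueError("n_kegel_cycles must be non-negative")


@dataclass(frozen=True)
class EffectSpec:
    """Pregnancy -> postpartum shift applied to per-subject ground truth.

    ``rms_ratio`` multiplies burst amplitude postpartum (<1 means the
    postpartum contraction is weaker); ``d_w_low``/``d_w_middle`` shift the
    low/middle band weights additively, with the high band absorbing the
    remainder so the weights renormalize to 1.  ``subject_sd_*`` are
    between-subject standard deviations of the corresponding parameter
    (log-scale for amplitude, absolute for weights).
    """

    rms_ratio: float = 0.8
    d_w_low: float = -0.10
    d_w_middle: float = 0.10
    subject_sd_log_rms: float = 0.15
    subject_sd_band: float = 0.05

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(rms_ratio=1.0, d_w_low=0.0, d_w_middle=0.0)


def default_bursts() -> list[BurstSpec]:
    """Study-condition burst ground truth: graded Kegels plus A/T exercises."""
    kegel_profile = (0.45, 0.35, 0.20)
    return [
        BurstSpec(ExerciseLabel.SMK, 30.0, kegel_profile, ChannelRole.MMG_LOWER),
        BurstSpec(ExerciseLabel.MK, 60.0, kegel_profile, ChannelRole.MMG_LOWER),
        BurstSpec(ExerciseLabel.STK, 120.0, kegel_profile, ChannelRole.MMG_LOWER),
        BurstSpec(ExerciseLabel.A, 80.0, (0.6, 0.3, 0.1), ChannelRole.MMG_OTHER),
        BurstSpec(ExerciseLabel.T, 80.0, (0.6, 0.3, 0.1), ChannelRole.MMG_EDGE_REFERENCE),
    ]


# --------------------------------------------------------------------------
# sensor array


def make_sensor_array(
    n_sensors: int = 151, n_lower: int = 20, n_edge_ref: int = 12
) -> list[ChannelInfo]:
    """Deterministic sensor layout on a spherical-cap grid plus aux channels.

    MMG sensors are placed on a sunflower (Fibonacci) grid over a spherical
    cap; the ``n_edge_ref`` outermost sensors become thigh-interference
    references and, of the rest, the ``n_lower`` sensors lowest on the array
    (closest to the perineum) become the analysis subset.  Six bipolar EMG
    channels (2x perineum, 2x abdomen, 2x thigh) and one ECG channel are
    appended.
    """
    if n_lower + n_edge_ref > n_sensors:
        raise ValueError("n_lower + n_edge_ref must not exceed n_sensors")
    golden = math.pi * (3.0 - math.sqrt(5.0))
    idx = np.arange(n_sensors)
    theta = _CAP_HALF_ANGLE * np.sqrt((idx + 0.5) / n_sensors)  # polar angle
    phi = idx * golden
    x = _ARRAY_RADIUS_M * np.sin(theta) * np.cos(phi)
    y = _ARRAY_RADIUS_M * np.sin(theta) * np.sin(phi)  # y is "up" on the array
    z = _ARRAY_RADIUS_M * np.cos(theta)

    roles: list[ChannelRole] = [ChannelRole.MMG_OTHER] * n_sensors
    # thigh references: lateral (largest |x|) sensors of the outermost ring,
    # excluding the bottom sector that sees the pelvic source most strongly
    outer = np.argsort(theta)[::-1][: min(n_sensors, 3 * n_edge_ref)]
    if len(outer) > n_edge_ref:
        y_cut = np.quantile(y[outer], 0.25)
        cand = outer[y[outer] >= y_cut]
        if len(cand) < n_edge_ref:
            cand = outer
    else:
        cand = outer
    for i in cand[np.argsort(np.abs(x[cand]))[::-1][:n_edge_ref]]:
        roles[i] = ChannelRole.MMG_EDGE_REFERENCE
    rest = np.array([i for i in idx if roles[i] is ChannelRole.MMG_OTHER])
    if n_lower and len(rest):
        for i in rest[np.argsort(y[rest])[:n_lower]]:  # lowest on the array
            roles[i] = ChannelRole.MMG_LOWER

    channels = [
        ChannelInfo(
            name=f"MMG{i:03d}",
            role=roles[i],
            position=(float(x[i]), float(y[i]), float(z[i])),
        )
        for i in range(n_sensors)
    ]
    aux = [
        ChannelInfo("EMGP1", ChannelRole.EMG_PERINEUM, (0.00, -0.16, 0.02)),
        ChannelInfo("EMGP2", ChannelRole.EMG_PERINEUM, (0.02, -0.16, 0.02)),
        ChannelInfo("EMGA1", ChannelRole.EMG_ABDOMEN, (0.00, 0.25, 0.05)),
        ChannelInfo("EMGA2", ChannelRole.EMG_ABDOMEN, (0.03, 0.25, 0.05)),
        ChannelInfo("EMGT1", ChannelRole.EMG_THIGH, (0.15, -0.10, 0.02)),
        ChannelInfo("EMGT2", ChannelRole.EMG_THIGH, (-0.15, -0.10, 0.02)),
        ChannelInfo("ECG1", ChannelRole.ECG, (0.00, 0.45, 0.05)),
    ]
    return channels + aux


# --------------------------------------------------------------------------
# waveform building blocks


def band_components(
    n: int, fs: float, rng: np.random.Generator, edges: Sequence[float] = BAND_EDGES
) -> np.ndarray:
    """Split one white-noise realization into exact spectral-band components.

    Returns an array of shape ``(len(edges)-1, n)``; component *b* contains
    only spectral content in ``[edges[b], edges[b+1])`` (brick-wall mask of
    the rFFT), each normalized to unit RMS.  Components are exactly
    orthogonal because their spectral supports are disjoint.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    comps = np.empty((len(edges) - 1, n))
    for b in range(len(edges) - 1):
        mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
        comp = np.fft.irfft(np.where(mask, spec, 0.0), n=n)
        rms = np.sqrt(np.mean(comp**2))
        comps[b] = comp / rms if rms > 0 else comp
    return comps


def burst_envelope(n: int, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    """Smooth on/off envelope: raised-cosine ramps at contraction on/offset."""
    ramp = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        t = np.arange(ramp) / ramp
        rc = 0.5 * (1.0 - np.cos(np.pi * t))
        env[:ramp] = rc
        env[n - ramp :] = rc[::-1]
    return env


def _shaped_burst(
    n: int, fs: float, profile: Sequence[float], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-envelope burst whose band power fractions equal *profile*."""
    comps = band_components(n, fs, rng)
    w = np.sqrt(np.asarray(profile, dtype=float))
    x = w @ comps  # unit RMS by orthogonality of the components
    return amplitude * burst_envelope(n, fs) * x


def cardiac_template_train(
    n: int, fs: float, rng: np.random.Generator, bpm: float = 70.0, jitter: float = 0.05
) -> np.ndarray:
    """QRS-like artifact: three-Gaussian complex repeated with beat jitter."""
    t_beat = np.arange(int(round(0.12 * fs))) / fs - 0.06
    qrs = (
        -0.25 * np.exp(-((t_beat + 0.025) ** 2) / (2 * 0.008**2))
        + 1.00 * np.exp(-(t_beat**2) / (2 * 0.006**2))
        - 0.35 * np.exp(-((t_beat - 0.025) ** 2) / (2 * 0.008**2))
    )
    out = np.zeros(n)
    period = 60.0 / bpm
    t = 0.2
    while t * fs < n:
        start = int(round(t * fs))
        seg = qrs[: max(0, min(len(qrs), n - start))]
        out[start : start + len(seg)] += seg
        t += period * (1.0 + jitter * rng.uniform(-1.0, 1.0))
    # scale so the train has unit RMS (sparse spikes -> large peak factor)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _projection_gains(
    channels: Sequence[ChannelInfo], target_role: ChannelRole
) -> np.ndarray:
    """Exponential spatial falloff of a source aimed at *target_role* sensors."""
    pos = np.array([ch.position for ch in channels])
    mmg = np.array([ch.role in MMG_ROLES for ch in channels])
    target_pts = pos[[ch.role is target_role for ch in channels]]
    if target_role is ChannelRole.MMG_EDGE_REFERENCE and len(target_pts):
        # thigh activity: one source per side (averaging the two lateral
        # sensor groups would collapse to the array centre)
        centres = []
        for side in (target_pts[:, 0] >= 0, target_pts[:, 0] < 0):
            if side.any():
                centres.append(target_pts[side].mean(axis=0) * np.array([1.2, 1.0, 1.0]))
    else:
        if len(target_pts):
            centre = target_pts.mean(axis=0)
        else:  # degenerate arrays without the role: aim below the array
            centre = np.array([0.0, -_ARRAY_RADIUS_M, _ARRAY_RADIUS_M])
        if target_role is ChannelRole.MMG_LOWER:
            centre = centre + np.array([0.0, -0.05, 0.0])  # source below the array
        centres = [centre]
    dist = np.min(
        [np.linalg.norm(pos - c, axis=1) for c in centres], axis=0
    )
    # exponential falloff with compact support: sensors beyond the cutoff see
    # nothing of the source (keeps distant reference sensors signal-free)
    gains = np.where(mmg & (dist < _SUPPORT_M), np.exp(-dist / _FALLOFF_M), 0.0)
    return gains


def _emg_gains(channels: Sequence[ChannelInfo], role: ChannelRole, gain: float) -> np.ndarray:
    return np.array([gain if ch.role is role else 0.0 for ch in channels])


# --------------------------------------------------------------------------
# session synthesis


def _schedule(spec: SessionSpec, bursts: Sequence[BurstSpec]) -> list[BurstSpec]:
    """Exercise order: n cycles of (SmK, MK, StK), then A, then T (if present)."""
    by_label = {b.label: b for b in bursts}
    out: list[BurstSpec] = []
    kegels = [l for l in (ExerciseLabel.SMK, ExerciseLabel.MK, ExerciseLabel.STK) if l in by_label]
    for _ in range(spec.n_kegel_cycles):
        out.extend(by_label[l] for l in kegels)
    for l in (ExerciseLabel.A, ExerciseLabel.T):
        if l in by_label:
            out.append(by_label[l])
    return out


def simulate_session(
    spec: SessionSpec,
    bursts: Sequence[BurstSpec] | None = None,
    seed: int = 0,
    subject_id: str = "S00",
    session: Session = Session.THIRD_TRIMESTER,
    channels: Sequence[ChannelInfo] | None = None,
) -> tuple[Recording, EventList]:
    """Simulate one full exercise session.

    Deterministic for a fixed seed.  Exercise onsets fall exactly on the
    schedule grid: onset_k = rest_s + k * (contraction_s + rest_s).
    """
    if bursts is None:
        bursts = default_bursts()
    if channels is None:
        channels = make_sensor_array(spec.n_sensors, spec.n_lower, spec.n_edge_ref)
    rng = np.random.default_rng(seed)
    order = _schedule(spec, bursts)
    cycle = spec.contraction_s + spec.rest_s
    total_s = spec.rest_s + len(order) * cycle
    n = int(round(total_s * spec.fs))
    n_ch = len(channels)
    data = np.zeros((n_ch, n))
    events = []

    n_burst = int(round(spec.contraction_s * spec.fs))
    for k, b in enumerate(order):
        onset = spec.rest_s + k * cycle
        start = int(round(onset * spec.fs))
        wave = _shaped_burst(n_burst, spec.fs, b.band_profile, b.amplitude_fT, rng)
        gains = _projection_gains(channels, b.spatial_target)
        # accessory EMG pickup: Kegels on the perineal electrodes, A and T on
        # their own surface electrodes (unit-agnostic gain)
        if b.label in (ExerciseLabel.SMK, ExerciseLabel.MK, ExerciseLabel.STK):
            gains = gains + _emg_gains(channels, ChannelRole.EMG_PERINEUM, 0.5)
        elif b.label is ExerciseLabel.A:
            gains = gains + _emg_gains(channels, ChannelRole.EMG_ABDOMEN, 1.0)
        elif b.label is ExerciseLabel.T:
            gains = gains + _emg_gains(channels, ChannelRole.EMG_THIGH, 1.0)
        data[:, start : start + n_burst] += np.outer(gains, wave)
        events.append(Event(onset, b.label, spec.contraction_s))

    # --- interference ---------------------------------------------------
    roles = np.array([ch.role for ch in channels], dtype=object)
    mmg = np.array([r in MMG_ROLES for r in roles])

    if spec.thigh_level > 0:
        wave = spec.thigh_level * (
            band_components(n, spec.fs, rng)[0] * 0.8
            + band_components(n, spec.fs, rng)[1] * 0.6
        )
        gains = _projection_gains(channels, ChannelRole.MMG_EDGE_REFERENCE)
        gains = gains + _emg_gains(channels, ChannelRole.EMG_THIGH, 0.8)
        data += np.outer(gains, wave)

    if spec.abdominal_level > 0:
        wave = spec.abdominal_level * band_components(n, spec.fs, rng)[0]
        gains = 0.4 * _projection_gains(channels, ChannelRole.MMG_OTHER)
        gains = gains + _emg_gains(channels, ChannelRole.EMG_ABDOMEN, 0.8)
        data += np.outer(gains, wave)

    if spec.cardiac_level > 0:
        heart = cardiac_template_train(n, spec.fs, rng)
        gains = np.where(mmg, spec.cardiac_level, 0.0)
        gains = gains * (0.8 + 0.4 * rng.random(n_ch))  # per-sensor variation
        gains = gains + 10.0 * spec.cardiac_level * np.array(
            [ch.role is ChannelRole.ECG for ch in channels]
        )
        data += np.outer(gains, heart)

    if spec.line_level > 0:
        t = np.arange(n) / spec.fs
        line = math.sqrt(2.0) * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        phase_gain = spec.line_level * (0.7 + 0.6 * rng.random(n_ch))
        data += np.outer(phase_gain, line)

    if spec.noise_floor > 0:
        data += spec.noise_floor * rng.standard_normal((n_ch, n))

    rec = Recording(
        data=data,
        fs=spec.fs,
        channels=list(channels),
        subject_id=subject_id,
        session=session,
    )
    return rec, EventList(events)


# --------------------------------------------------------------------------
# paired study


def _subject_truth(
    base_bursts: Sequence[BurstSpec], effect: EffectSpec, rng: np.random.Generator
) -> dict[ExerciseLabel, tuple[float, tuple[float, float, float]]]:
    """Draw one subject's pregnancy-session parameters around the base."""
    out = {}
    amp_factor = math.exp(effect.subject_sd_log_rms * rng.standard_normal())
    dl = effect.subject_sd_band * rng.standard_normal()
    dm = effect.subject_sd_band * rng.standard_normal()
    for b in base_bursts:
        w = _shift_weights(b.band_profile, dl, dm)
        out[b.label] = (b.amplitude_fT * amp_factor, w)
    return out


def _shift_weights(
    w: Sequence[float], d_low: float, d_middle: float
) -> tuple[float, float, float]:
    wl = w[0] + d_low
    wm = w[1] + d_middle
    wh = 1.0 - wl - wm
    shifted = np.clip([wl, wm, wh], 1e-6, None)
    shifted = shifted / shifted.sum()
    return tuple(float(v) for v in shifted)


def simulate_paired_study(
    n_subjects: int = 9,
    spec: SessionSpec | None = None,
    bursts: Sequence[BurstSpec] | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[dict[str, dict[Session, tuple[Recording, EventList]]], pd.DataFrame]:
    """Paired (third-trimester, postpartum) sessions for *n_subjects* subjects.

    Per-subject parameters are drawn around the base bursts with the
    between-subject SDs of *effect*; postpartum parameters are the pregnancy
    parameters scaled by ``rms_ratio`` and band-shifted by
    ``(d_w_low, d_w_middle)``.  Subject seeds derive as ``seed + index``.

    Returns the study bundle and a ground-truth table with one row per
    (subject, session, exercise) carrying the true amplitude and band weights.
    """
    if n_subjects < 2:
        raise ValueError("a paired study needs at least 2 subjects")
    spec = spec or SessionSpec()
    bursts = list(bursts) if bursts is not None else default_bursts()
    effect = effect or EffectSpec()
    channels = make_sensor_array(spec.n_sensors, spec.n_lower, spec.n_edge_ref)

    bundle: dict[str, dict[Session, tuple[Recording, EventList]]] = {}
    truth_rows = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        rng = np.random.default_rng(seed + s)
        truth = _subject_truth(bursts, effect, rng)
        bundle[subject] = {}
        for sess in (Session.THIRD_TRIMESTER, Session.POSTPARTUM):
            sess_bursts = []
            for b in bursts:
                amp, w = truth[b.label]
                if sess is Session.POSTPARTUM:
                    amp = amp * effect.rms_ratio
                    w = _shift_weights(w, effect.d_w_low, effect.d_w_middle)
                sess_bursts.append(replace(b, amplitude_fT=amp, band_profile=w))
                truth_rows.append(
                    {
                        "subject": subject,
                        "session": sess.value,
                        "label": b.label.value,
                        "amplitude_fT": amp,
                        "w_low": w[0],
                        "w_middle": w[1],
                        "w_high": w[2],
                    }
                )
            sess_seed = seed + s + (100_000 if sess is Session.POSTPARTUM else 0)
            bundle[subject][sess] = simulate_session(
                spec,
                sess_bursts,
                seed=sess_seed,
                subject_id=subject,
                session=sess,
                channels=channels,
            )
    truth = pd.DataFrame(truth_rows)
    return bundle, truth


# --------------------------------------------------------------------------
# parameter-level study sampler (fast path for statistical calibration)


def draw_parameter_study(
    n_subjects: int = 9,
    effect: EffectSpec | None = None,
    n_epochs: int = 3,
    epoch_noise: float = 0.05,
    base_amplitude_fT: float = 60.0,
    base_profile: tuple[float, float, float] = (0.45, 0.35, 0.20),
    seed: int = 0,
) -> pd.DataFrame:
    """Per-epoch feature table drawn directly from the parameter model.

    Bypasses waveform synthesis: each epoch's features are the subject's true
    session parameters plus independent relative measurement noise of size
    *epoch_noise*.  Used for Monte-Carlo calibration of the statistical
    stage, where thousands of replicate studies are needed.

    Returns a feature table with columns subject / session / label / rms_fT /
    total_power / rpsd_low / rpsd_middle / rpsd_high / snr_db.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        amp = base_amplitude_fT * math.exp(
            effect.subject_sd_log_rms * rng.standard_normal()
        )
        dl = effect.subject_sd_band * rng.standard_normal()
        dm = effect.subject_sd_band * rng.standard_normal()
        w_preg = _shift_weights(base_profile, dl, dm)
        for sess in (Session.THIRD_TRIMESTER, Session.POSTPARTUM):
            if sess is Session.POSTPARTUM:
                a = amp * effect.rms_ratio
                w = _shift_weights(w_preg, effect.d_w_low, effect.d_w_middle)
            else:
                a, w = amp, w_preg
            for e in range(n_epochs):
                a_e = a * (1.0 + epoch_noise * rng.standard_normal())
                w_e = np.clip(
                    np.asarray(w) + epoch_noise * rng.standard_normal(3) * 0.5, 1e-6, None
                )
                w_e = w_e / w_e.sum()
                rows.append(
                    {
                        "subject": subject,
                        "session": sess.value,
                        "label": ExerciseLabel.MK.value,
                        "rms_fT": abs(a_e),
                        "total_power": a_e**2,
                        "rpsd_low": w_e[0],
                        "rpsd_middle": w_e[1],
                        "rpsd_high": w_e[2],
                        "snr_db": 20.0,
                    }
                )
    return pd.DataFrame(rows)
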