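"""Signal-cleaning chain: reference subtraction, filtering, ICA denoising.

Stage order for MMG channels follows the acquisition protocol's processing
chain: frequency-dependent reference subtraction (SUBTR) of thigh
interference picked up on the array-edge sensors, a 20-200 Hz 4th-order
Butterworth band-pass plus 60 Hz notch, then ICA-based rejection of residual
cardiac / reference-concentrated components.  EMG channels additionally get
cardiac removal via SUBTR with the chest ECG electrode as the sole reference.

All filters are applied forward-backward (zero phase), so trigger-locked
amplitude analysis downstream suffers no phase distortion; the effective
magnitude response of the band-pass is the squared 4th-order Butterworth.

SUBTR is realized as a per-frequency-bin multichannel least-squares
regression in the STFT domain: for each bin f the complex coefficient matrix
W(f) solves

    W(f) = S_yx(f) [S_xx(f) + lambda I]^{-1}

where S_yx is the cross-spectral matrix between targets and references and
S_xx the reference auto-spectral matrix, with diagonal loading lambda for
stability.  Cleaning subtracts W(f) x_ref(f) per STFT frame and
inverse-transforms with perfect-reconstruction overlap-add.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io_core import (
    ChannelRole,
    EMG_ROLES,
    MMG_ROLES,
    Recording,
)

__all__ = [
    "SubtrFilter",
    "IcaReport",
    "bandpass_notch",
    "fit_subtr",
    "apply_subtr",
    "ica_denoise",
    "remove_cardiac_emg",
]


def bandpass_notch(
    recording: Recording,
    low: float = 20.0,
    high: float = 200.0,
    order: int = 4,
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> Recording:
    """Zero-phase band-pass (Butterworth) + notch filtering of all channels.

    Passband gain is ~1 (squared Butterworth response); DC and content above
    *high* are attenuated; the notch removes the power-line tone by >= 30 dB.
    """
    nyq = recording.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq})")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    out = sps.sosfiltfilt(sos, recording.data, axis=1)
    if notch is not None:
        b, a = sps.iirnotch(notch, notch_q, fs=recording.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return recording.with_data(out)


def bandpass_gain(
    freq_hz: float,
    fs: float,
    low: float = 20.0,
    high: float = 200.0,
    order: int = 4,
    notch: float | None = 60.0,
    notch_q: float = 30.0,
) -> float:
    """Designed amplitude gain of the zero-phase chain at one frequency.

    Forward-backward application squares each filter's magnitude response.
    """
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    gain = float(np.abs(h[0]) ** 2)
    if notch is not None:
        b, a = sps.iirnotch(notch, notch_q, fs=fs)
        _, hn = sps.freqz(b, a, worN=[freq_hz], fs=fs)
        gain *= float(np.abs(hn[0]) ** 2)
    return gain


# --------------------------------------------------------------------------
# SUBTR: frequency-dependent reference subtraction


@dataclass
class SubtrFilter:
    """Per-bin complex regression coefficients mapping references -> targets.

    ``weights`` has shape (n_freqs, n_targets, n_refs); ``target_idx`` and
    ``ref_idx`` are channel indices into the recording the filter was fitted
    on, and must match at application time.
    """

    weights: np.ndarray
    freqs: np.ndarray
    target_idx: np.ndarray
    ref_idx: np.ndarray
    fs: float
    nperseg: int
    hop: int
    n_channels: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights.view(float))):
            raise ValueError("SUBTR weights must be finite")

    def _stft(self):
        win = sps.get_window("hann", self.nperseg)
        return sps.ShortTimeFFT(win, hop=self.hop, fs=self.fs, fft_mode="onesided")


def _resolve_indices(
    recording: Recording,
    roles: Iterable[ChannelRole | str] | None,
    indices: Sequence[int] | None,
) -> np.ndarray:
    if indices is not None:
        return np.asarray(indices, dtype=int)
    return recording.channel_indices(roles or ())


def fit_subtr(
    recording: Recording,
    reference_roles: Iterable[ChannelRole | str] = (ChannelRole.MMG_EDGE_REFERENCE,),
    target_roles: Iterable[ChannelRole | str] | None = None,
    reference_indices: Sequence[int] | None = None,
    target_indices: Sequence[int] | None = None,
    window_s: float = 1.0,
    loading: float = 1e-3,
) -> SubtrFilter:
    """Fit per-bin least-squares subtraction weights from reference channels.

    Defaults regress every non-reference MMG channel on the edge-reference
    sensors.  ``loading`` scales the diagonal stabilization relative to the
    mean reference power per bin.
    """
    ref_idx = _resolve_indices(recording, reference_roles, reference_indices)
    if len(ref_idx) == 0:
        raise ValueError("no reference channels match the requested roles")
    if target_indices is None and target_roles is None:
        ref_set = set(ref_idx.tolist())
        target_idx = np.array(
            [
                i
                for i, ch in enumerate(recording.channels)
                if ch.role in MMG_ROLES and i not in ref_set
            ],
            dtype=int,
        )
    else:
        target_idx = _resolve_indices(recording, target_roles, target_indices)
    if len(target_idx) == 0:
        raise ValueError("no target channels to fit")

    nperseg = int(round(window_s * recording.fs))
    if recording.n_samples < 10 * nperseg:
        raise ValueError("recording too short: need >= 10 STFT windows")
    hop = nperseg // 2
    win = sps.get_window("hann", nperseg)
    sft = sps.ShortTimeFFT(win, hop=hop, fs=recording.fs, fft_mode="onesided")

    X = sft.stft(recording.data[ref_idx], axis=-1)  # (n_ref, n_freq, n_frames)
    Y = sft.stft(recording.data[target_idx], axis=-1)
    n_freq = X.shape[1]
    n_ref = len(ref_idx)
    W = np.zeros((n_freq, len(target_idx), n_ref), dtype=complex)
    for f in range(n_freq):
        Xf = X[:, f, :]  # (n_ref, n_frames)
        Yf = Y[:, f, :]
        Sxx = Xf @ Xf.conj().T / Xf.shape[1]
        Syx = Yf @ Xf.conj().T / Xf.shape[1]
        ref_power = np.real(np.trace(Sxx)) / n_ref
        if ref_power <= 0.0:  # silent references: nothing to subtract
            continue
        lam = loading * ref_power
        W[f] = Syx @ np.linalg.inv(Sxx + lam * np.eye(n_ref))
    return SubtrFilter(
        weights=W,
        freqs=sft.f,
        target_idx=target_idx,
        ref_idx=ref_idx,
        fs=recording.fs,
        nperseg=nperseg,
        hop=hop,
        n_channels=recording.n_channels,
    )


def apply_subtr(recording: Recording, filt: SubtrFilter) -> Recording:
    """Subtract the reference-predicted component from each target channel.

    Reference (and all other non-target) channels pass through unchanged;
    output length equals input length.
    """
    if recording.n_channels != filt.n_channels or recording.fs != filt.fs:
        raise ValueError("recording does not match the fitted filter's channel set")
    sft = filt._stft()
    n = recording.n_samples
    X = sft.stft(recording.data[filt.ref_idx], axis=-1)
    Y = sft.stft(recording.data[filt.target_idx], axis=-1)
    # predicted interference per bin: W(f) @ x_ref(f), per frame
    pred = np.einsum("ftr,rfk->tfk", filt.weights, X)
    cleaned = sft.istft(Y - pred, k1=n)
    out = recording.data.copy()
    out[filt.target_idx] = cleaned[:, :n]
    return recording.with_data(out)


def remove_cardiac_emg(
    recording: Recording, window_s: float = 1.0, loading: float = 1e-3
) -> Recording:
    """Remove the cardiac artifact from EMG channels via ECG-referenced SUBTR."""
    ecg_idx = recording.channel_indices({ChannelRole.ECG})
    if len(ecg_idx) == 0:
        raise ValueError("recording has no ECG channel")
    emg_idx = recording.channel_indices(EMG_ROLES)
    if len(emg_idx) == 0:
        raise ValueError("recording has no EMG channels")
    filt = fit_subtr(
        recording,
        reference_indices=ecg_idx[:1],
        target_indices=emg_idx,
        window_s=window_s,
        loading=loading,
    )
    return apply_subtr(recording, filt)


# --------------------------------------------------------------------------
# ICA denoising


@dataclass
class IcaReport:
    """Decomposition bookkeeping: which components were rejected and why."""

    n_components: int
    rejected: list[tuple[int, str]] = field(default_factory=list)
    variance_removed: float = 0.0
    converged: bool = True

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "rejected": [{"component": int(i), "reason": r} for i, r in self.rejected],
            "variance_removed": float(self.variance_removed),
            "converged": bool(self.converged),
        }


def ica_denoise(
    recording: Recording,
    corr_threshold: float = 0.8,
    edge_energy_threshold: float = 0.8,
    seed: int = 0,
    max_components: int = 40,
    max_iter: int = 500,
    tol: float = 1e-3,
    attempts: int = 3,
    fit_decimation: int = 1,
    on_nonconvergence: str = "fail",
) -> tuple[Recording, IcaReport]:
    """ICA-based rejection of cardiac and reference-concentrated components.

    Decomposes the MMG channels (after whitening, at most *max_components*
    components), rejects components whose source time course correlates with
    the ECG channel above *corr_threshold* (absolute Pearson) or whose mixing
    column concentrates more than *edge_energy_threshold* of its energy on
    the edge-reference sensors, and reconstructs without them.

    Deterministic for a fixed seed.  The unmixing matrix may be fitted on
    every ``fit_decimation``-th sample (the full data is always transformed
    and reconstructed), which bounds cost on long sessions.  On
    non-convergence the decomposition is retried with fresh seeded
    initializations; after *attempts* tries the behaviour follows
    *on_nonconvergence*: ``"fail"`` raises, ``"warn"`` keeps the last
    (unconverged) estimate with a warning.  The fixed-point criterion cannot
    settle when part of the whitened space is near-Gaussian (rotations
    within a Gaussian subspace are unidentifiable), while strongly
    non-Gaussian artifact components are still isolated — the ``"warn"``
    policy exists for that regime.
    """
    if on_nonconvergence not in ("fail", "warn"):
        raise ValueError("on_nonconvergence must be 'fail' or 'warn'")
    mmg_idx = recording.channel_indices(MMG_ROLES)
    if len(mmg_idx) < 2:
        raise ValueError("ICA needs at least 2 MMG channels")
    ecg_idx = recording.channel_indices({ChannelRole.ECG})
    ecg = recording.data[ecg_idx[0]] if len(ecg_idx) else None
    edge_rows = np.isin(
        mmg_idx, recording.channel_indices({ChannelRole.MMG_EDGE_REFERENCE})
    )

    X = recording.data[mmg_idx].T  # samples x channels
    X_fit = X[:: max(1, int(fit_decimation))]
    n_comp = min(len(mmg_idx), max_components)

    fitted = None
    converged = False
    last_exc: Exception | None = None
    for attempt in range(max(1, attempts)):
        ica = FastICA(
            n_components=n_comp,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + attempt,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                ica.fit(X_fit)
            fitted, converged = ica, True
            break
        except ConvergenceWarning as exc:  # retry with new initialization
            last_exc = exc
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica.fit(X_fit)
            fitted = ica
    if not converged:
        if on_nonconvergence == "fail":
            raise RuntimeError(
                f"ICA failed to converge after {attempts} seeded attempts: {last_exc}"
            )
        warnings.warn(
            f"ICA did not converge after {attempts} attempts; "
            "keeping the last estimate",
            stacklevel=2,
        )
    sources = fitted.transform(X)
    mixing = fitted.mixing_  # (n_channels, n_components)
    mean = fitted.mean_

    rejected: list[tuple[int, str]] = []
    for k in range(n_comp):
        if ecg is not None:
            r = _abs_corr(sources[:, k], ecg)
            if r > corr_threshold:
                rejected.append((k, "ecg-correlated"))
                continue
        col = mixing[:, k]
        total = float(np.sum(col**2))
        if total > 0 and edge_rows.any():
            frac = float(np.sum(col[edge_rows] ** 2)) / total
            if frac > edge_energy_threshold:
                rejected.append((k, "reference-concentrated"))

    S_clean = sources.copy()
    comp_var = np.var(sources, axis=0) * np.sum(mixing**2, axis=0)
    removed_var = 0.0
    for k, _ in rejected:
        S_clean[:, k] = 0.0
        removed_var += comp_var[k]
    total_var = float(comp_var.sum())
    X_clean = S_clean @ mixing.T + mean

    out = recording.data.copy()
    out[mmg_idx] = X_clean.T
    report = IcaReport(
        n_components=n_comp,
        rejected=rejected,
        variance_removed=removed_var / total_var if total_var > 0 else 0.0,
        converged=converged,
    )
    return recording.with_data(out), report


def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))
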