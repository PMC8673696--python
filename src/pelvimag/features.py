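"""Amplitude and spectral features of contraction epochs.

Per moderate-Kegel epoch the pipeline computes:

* **RMS amplitude** (fT): sliding-window RMS (200 ms window, 199 ms overlap)
  smoothed with a 100-point moving average, then averaged over the
  contraction interval and the lower MMG sensors.
* **Total power** (fT^2/Hz summed over bins): Welch power spectral density
  (1 s Hann windows, 50% overlap), summed over the 20-200 Hz bins.
* **rPSD** fractions: band power in the low (20-80 Hz), middle (80-140 Hz)
  and high (140-200 Hz) bands, normalized by total power.  Band bins are
  assigned half-open [low, high) for the low and middle bands and closed at
  the top of the high band, so every bin counts exactly once and the three
  fractions sum to 1.

Per-sensor total power over the full MMG array forms a topographic power
map of contraction activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .epochs import Epoch, epoch_snr_db
from .io_core import ChannelRole, MMG_ROLES, PipelineConfig

__all__ = [
    "PSDResult",
    "FeatureRecord",
    "PowerMap",
    "sliding_rms",
    "smooth_ma",
    "welch_psd",
    "total_power",
    "rpsd_bands",
    "epoch_features",
    "power_map",
    "features_table",
]


@dataclass
class PSDResult:
    """One-sided Welch power spectral density per channel."""

    freqs: np.ndarray  # (n_freqs,), Hz, ascending
    density: np.ndarray  # (..., n_freqs), power per Hz
    window_s: float
    overlap: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(self.freqs < 0):
            raise ValueError("frequency grid must be non-negative ascending")
        if np.any(self.density < 0):
            raise ValueError("spectral density must be non-negative")


@dataclass
class FeatureRecord:
    """Per-epoch contraction parameters."""

    subject: str
    session: str
    label: str
    rms_fT: float
    total_power: float
    rpsd_low: float
    rpsd_middle: float
    rpsd_high: float
    snr_db: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PowerMap:
    """Per-sensor total power with sensor positions, for topographic maps."""

    power: np.ndarray  # (n_mmg,)
    positions: np.ndarray  # (n_mmg, 3)
    names: list[str]
    roles: list[ChannelRole]

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("power values must be non-negative")
        if len(self.power) != len(self.positions):
            raise ValueError("one power value per sensor required")


def sliding_rms(
    x: np.ndarray, fs: float, window_s: float = 0.2, overlap_s: float = 0.199
) -> np.ndarray:
    """Sliding-window RMS envelope of a 1-D signal.

    Window length is ``round(window_s * fs)`` samples and the hop is
    ``max(1, round((window_s - overlap_s) * fs))`` samples — at 1200 Hz the
    200 ms / 199 ms parameters give a 240-sample window advancing one sample
    at a time.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    if x.ndim != 1:
        raise ValueError("sliding_rms expects a 1-D signal")
    if len(x) < win:
        raise ValueError(f"signal ({len(x)} samples) shorter than window ({win})")
    hop = max(1, int(round((window_s - overlap_s) * fs)))
    frames = sliding_window_view(x, win)[::hop]
    return np.sqrt(np.mean(frames**2, axis=1))


def smooth_ma(series: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges.

    Index *i* averages ``series[i - n//2 : i + (n - n//2)]`` clipped to the
    array bounds, so the output has the input's length and a constant series
    is unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("smooth_ma expects a non-empty 1-D series")
    n = int(n_points)
    if n <= 1:
        return x.copy()
    half_lo = n // 2
    half_hi = n - half_lo
    csum = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(len(x))
    lo = np.maximum(i - half_lo, 0)
    hi = np.minimum(i + half_hi, len(x))
    return (csum[hi] - csum[lo]) / (hi - lo)


def welch_psd(
    x: np.ndarray, fs: float, window_s: float = 1.0, overlap: float = 0.5
) -> PSDResult:
    """Welch power spectral density (Hann taper, one-sided).

    A 1 s window yields a 1 Hz frequency resolution.  Accepts 1-D signals or
    (channels x samples) matrices (last axis is time).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.shape[-1] < nperseg:
        raise ValueError("signal shorter than one Welch window")
    freqs, density = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=-1,
    )
    return PSDResult(freqs=freqs, density=density, window_s=window_s, overlap=overlap)


def total_power(
    psd: PSDResult, band: tuple[float, float] = (20.0, 200.0)
) -> np.ndarray | float:
    """Sum of spectral-density bins with band[0] <= f <= band[1], per channel."""
    lo, hi = band
    mask = (psd.freqs >= lo) & (psd.freqs <= hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return psd.density[..., mask].sum(axis=-1)


def rpsd_bands(
    psd: PSDResult,
    edges: tuple[float, float, float, float] = (20.0, 80.0, 140.0, 200.0),
) -> tuple[float, float, float]:
    """Band-power fractions (low, middle, high) normalized by total power.

    Bin assignment: [e0, e1) / [e1, e2) / [e2, e3], so the fractions sum to
    1 exactly.  Zero total power yields NaNs with a warning (undefined
    composition).
    """
    d = psd.density
    if d.ndim > 1:
        d = d.mean(axis=tuple(range(d.ndim - 1)))
    e0, e1, e2, e3 = edges
    f = psd.freqs
    sums = np.array(
        [
            d[(f >= e0) & (f < e1)].sum(),
            d[(f >= e1) & (f < e2)].sum(),
            d[(f >= e2) & (f <= e3)].sum(),
        ]
    )
    tot = sums.sum()
    if tot <= 0:
        warnings.warn("zero total power: rPSD undefined", stacklevel=2)
        return (float("nan"),) * 3
    frac = sums / tot
    return tuple(float(v) for v in frac)


def epoch_features(
    epoch: Epoch, config: PipelineConfig | None = None, rms_reduce: str = "mean"
) -> FeatureRecord:
    """Extract the contraction parameters of one baseline-corrected epoch.

    RMS is the reduction (*mean* by default, optionally *max*) of the
    smoothed sliding-RMS series over the contraction interval, averaged over
    lower MMG sensors; total power and rPSD come from the Welch PSD of the
    contraction interval averaged over the same sensors.
    """
    cfg = config or PipelineConfig()
    idx = epoch.channel_indices({ChannelRole.MMG_LOWER})
    if len(idx) == 0:
        raise ValueError("epoch has no lower MMG channels")
    sig = epoch.signal[idx]

    reduce = {"mean": np.mean, "max": np.max}[rms_reduce]
    rms_vals = []
    for row in sig:
        series = sliding_rms(row, epoch.fs, cfg.rms_window_s, cfg.rms_overlap_s)
        rms_vals.append(reduce(smooth_ma(series, cfg.smooth_points)))
    rms = float(np.mean(rms_vals))

    psd = welch_psd(sig, epoch.fs, cfg.welch_window_s, cfg.welch_overlap)
    mean_psd = PSDResult(
        freqs=psd.freqs,
        density=psd.density.mean(axis=0),
        window_s=psd.window_s,
        overlap=psd.overlap,
    )
    band = (cfg.band_edges_hz[0], cfg.band_edges_hz[-1])
    power = float(total_power(mean_psd, band))
    r_low, r_mid, r_high = rpsd_bands(mean_psd, cfg.band_edges_hz)
    return FeatureRecord(
        subject=epoch.subject_id,
        session=epoch.session.value,
        label=epoch.label.value,
        rms_fT=rms,
        total_power=power,
        rpsd_low=r_low,
        rpsd_middle=r_mid,
        rpsd_high=r_high,
        snr_db=float(epoch_snr_db(epoch)),
    )


def features_table(records: list[FeatureRecord]) -> pd.DataFrame:
    """Stack per-epoch records into the pipeline's feature table."""
    return pd.DataFrame([r.to_dict() for r in records])


def power_map(
    epoch: Epoch,
    band: tuple[float, float] = (20.0, 200.0),
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> PowerMap:
    """Per-sensor total power over the contraction interval (all MMG sensors)."""
    idx = epoch.channel_indices(MMG_ROLES)
    if len(idx) == 0:
        raise ValueError("epoch has no MMG channels")
    psd = welch_psd(epoch.signal[idx], epoch.fs, window_s, overlap)
    power = np.atleast_1d(total_power(psd, band))
    chans = [epoch.channels[i] for i in idx]
    return PowerMap(
        power=power,
        positions=np.array([c.position for c in chans]),
        names=[c.name for c in chans],
        roles=[c.role for c in chans],
    )


def plot_power_map(pmap: PowerMap, ax=None):
    """Render a power map as a colored scatter over the flattened array.

    Minimal topographic rendering (x/y sensor coordinates, power as color);
    returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(
        pmap.positions[:, 0], pmap.positions[:, 1], c=pmap.power, cmap="jet", s=40
    )
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label="total power")
    return ax
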