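"""Per-channel electrogram feature extraction.

Local activation is the most negative discrete derivative of the unipolar
electrogram (the intrinsic deflection downstroke); repolarization is the
most positive discrete derivative inside a window placed relative to each
channel's activation (slope-only, T-wave-polarity independent); the
activation recovery interval (ARI) is their difference.

The discrete derivative is the central difference scaled to mV/ms; the
first and last samples are excluded. Ties are broken toward the earliest
sample, so every detector is deterministic and equals an exhaustive scan
of the discrete derivative over its search window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyMapWarning, InvalidParameterError
from .synthetic.geometry import ArrayGeometry
from .synthetic.signals import Recording

log = logging.getLogger(__name__)

#: default post-stimulus blanking (ms) excluded from the activation search
DEFAULT_BLANKING_MS = 5.0
#: default repolarization search window relative to activation (ventricle)
DEFAULT_REPOL_WINDOW_MS = (80.0, 400.0)
#: alternative repolarization window for atrial recordings
ATRIAL_REPOL_WINDOW_MS = (40.0, 250.0)
#: multiplier on the per-channel median absolute derivative (noise floor)
DEFAULT_SLOPE_FACTOR = 5.0
_SLOPE_FLOOR_MV_PER_MS = 1e-6


@dataclass(frozen=True)
class ActivationMap:
    """Per-channel activation times relative to the analyzed stimulus.

    Invalid channels carry NaN times. ``stimulus_time_ms`` anchors the map
    to the recording's absolute time axis.
    """

    channel_id: np.ndarray
    time_ms: np.ndarray
    slope_mv_per_ms: np.ndarray
    valid: np.ndarray
    stimulus_time_ms: float = 0.0

    @classmethod
    def from_times(cls, times_ms: np.ndarray,
                   valid: np.ndarray | None = None,
                   stimulus_time_ms: float = 0.0) -> "ActivationMap":
        """Wrap known activation times (e.g. simulation ground truth)."""
        times = np.asarray(times_ms, dtype=float)
        n = times.size
        if valid is None:
            valid = np.isfinite(times)
        return cls(channel_id=np.arange(n), time_ms=times,
                   slope_mv_per_ms=np.full(n, np.nan),
                   valid=np.asarray(valid, dtype=bool),
                   stimulus_time_ms=float(stimulus_time_ms))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel_id": self.channel_id, "time_ms": self.time_ms,
            "slope": self.slope_mv_per_ms, "valid": self.valid.astype(int),
        })


@dataclass(frozen=True)
class RepolarizationMap:
    channel_id: np.ndarray
    time_ms: np.ndarray
    slope_mv_per_ms: np.ndarray
    valid: np.ndarray
    stimulus_time_ms: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel_id": self.channel_id, "time_ms": self.time_ms,
            "slope": self.slope_mv_per_ms, "valid": self.valid.astype(int),
        })


@dataclass(frozen=True)
class ARIMap:
    """Per-channel activation recovery intervals with an array-level summary."""

    channel_id: np.ndarray
    ari_ms: np.ndarray
    valid: np.ndarray
    mean_ms: float = field(default=float("nan"))
    sd_ms: float = field(default=float("nan"))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel_id": self.channel_id, "time_ms": self.ari_ms,
            "slope": np.nan, "valid": self.valid.astype(int),
        })


def discrete_derivative(signal_mv: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Central-difference derivative in mV/ms; NaN at the endpoints."""
    x = np.asarray(signal_mv, dtype=float)
    d = np.full(x.shape, np.nan)
    dt_ms = 1000.0 / sampling_rate_hz
    d[..., 1:-1] = (x[..., 2:] - x[..., :-2]) / (2.0 * dt_ms)
    return d


def _window_indices(recording: Recording, start_ms: float, end_ms: float) -> tuple[int, int]:
    """Absolute-time window [start, end] -> inclusive sample index range,
    clipped so the central difference is defined."""
    fs_khz = recording.sampling_rate_hz / 1000.0
    i0 = max(int(np.ceil(start_ms * fs_khz)), 1)
    i1 = min(int(np.floor(end_ms * fs_khz)), recording.n_samples - 2)
    return i0, i1


def detect_activation_times(recording: Recording,
                            search_window_ms: tuple[float, float] | None = None,
                            blanking_ms: float = DEFAULT_BLANKING_MS,
                            min_slope_mv_per_ms: float | None = None,
                            stimulus_index: int = 0) -> ActivationMap:
    """Detect per-channel activation as the most negative derivative.

    Parameters
    ----------
    search_window_ms
        (start, end) in ms relative to the analyzed stimulus. Defaults to
        the inter-stimulus interval minus the blanking guard at both ends
        (the artifact of the *next* stimulus extends backwards in time),
        or to the end of the recording for the last stimulus. The first
        ``blanking_ms`` after the stimulus are always excluded.
    min_slope_mv_per_ms
        Absolute validity threshold on the peak negative slope magnitude.
        Default: 5x the channel's median absolute derivative inside the
        window (robust noise floor), floored at a tiny positive value so
        flat channels are invalid.
    stimulus_index
        Which stimulus of the pacing train to analyze.

    Returns times relative to the analyzed stimulus; bad channels and
    channels below the slope threshold are flagged invalid.
    """
    stims = recording.stimulus_times_ms
    if not stims:
        raise InvalidParameterError("recording has no stimulus times")
    if not 0 <= stimulus_index < len(stims):
        raise InvalidParameterError(
            f"stimulus_index {stimulus_index} out of range 0..{len(stims) - 1}")
    stim = stims[stimulus_index]

    if search_window_ms is None:
        end = (stims[stimulus_index + 1] - stim - blanking_ms
               if stimulus_index + 1 < len(stims) else recording.duration_ms - stim)
        search_window_ms = (blanking_ms, end)
    w0 = max(float(search_window_ms[0]), blanking_ms)
    w1 = float(search_window_ms[1])
    if w0 >= w1:
        raise InvalidParameterError(
            f"empty activation search window [{w0}, {w1}] ms after blanking")

    i0, i1 = _window_indices(recording, stim + w0, stim + w1)
    if i0 > i1:
        raise InvalidParameterError("activation search window contains no samples")

    deriv = discrete_derivative(recording.signal_mv, recording.sampling_rate_hz)
    win = deriv[:, i0:i1 + 1]
    idx = np.argmin(win, axis=1)  # first occurrence wins ties
    slopes = win[np.arange(win.shape[0]), idx]
    fs_khz = recording.sampling_rate_hz / 1000.0
    times = (i0 + idx) / fs_khz - stim

    if min_slope_mv_per_ms is None:
        thresh = np.maximum(
            DEFAULT_SLOPE_FACTOR * np.median(np.abs(win), axis=1),
            _SLOPE_FLOOR_MV_PER_MS)
    else:
        thresh = np.full(win.shape[0], float(min_slope_mv_per_ms))

    valid = np.abs(slopes) >= thresh
    if recording.geometry.bad_channels:
        valid[list(recording.geometry.bad_channels)] = False
    times = np.where(valid, times, np.nan)
    slopes = np.where(valid, slopes, np.nan)

    if not valid.any():
        warnings.warn("all channels invalid in activation detection",
                      EmptyMapWarning, stacklevel=2)

    return ActivationMap(channel_id=np.arange(win.shape[0]), time_ms=times,
                         slope_mv_per_ms=slopes, valid=valid,
                         stimulus_time_ms=float(stim))


def detect_repolarization_times(recording: Recording,
                                activation_map: ActivationMap,
                                repol_window_ms: tuple[float, float] = DEFAULT_REPOL_WINDOW_MS,
                                ) -> RepolarizationMap:
    """Detect repolarization as the most positive derivative inside
    [activation + w0, activation + w1] per channel (Wyatt-style: slope
    only, regardless of T-wave polarity)."""
    w0, w1 = float(repol_window_ms[0]), float(repol_window_ms[1])
    if w0 >= w1:
        raise InvalidParameterError(
            f"repolarization window start {w0} must be < end {w1}")

    n = recording.n_channels
    if activation_map.time_ms.size != n:
        raise InvalidParameterError(
            "activation map does not match the recording's channel count")

    deriv = discrete_derivative(recording.signal_mv, recording.sampling_rate_hz)
    fs_khz = recording.sampling_rate_hz / 1000.0
    stim = activation_map.stimulus_time_ms

    times = np.full(n, np.nan)
    slopes = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for ch in range(n):
        if not activation_map.valid[ch]:
            continue
        act_abs = stim + activation_map.time_ms[ch]
        i0, i1 = _window_indices(recording, act_abs + w0, act_abs + w1)
        if i0 > i1:
            continue
        seg = deriv[ch, i0:i1 + 1]
        k = int(np.argmax(seg))
        times[ch] = (i0 + k) / fs_khz - stim
        slopes[ch] = seg[k]
        valid[ch] = True

    if not valid.any():
        warnings.warn("all channels invalid in repolarization detection",
                      EmptyMapWarning, stacklevel=2)

    return RepolarizationMap(channel_id=np.arange(n), time_ms=times,
                             slope_mv_per_ms=slopes, valid=valid,
                             stimulus_time_ms=stim)


def compute_ari(activation_map: ActivationMap,
                repolarization_map: RepolarizationMap) -> ARIMap:
    """ARI_i = t_repol,i - t_act,i over channels valid in both maps.

    Channels with non-positive ARI are flagged invalid and logged. The
    array-level summary is the mean +/- sample SD over valid channels.
    """
    if activation_map.time_ms.size != repolarization_map.time_ms.size:
        raise InvalidParameterError("activation and repolarization maps differ in size")

    ari = repolarization_map.time_ms - activation_map.time_ms
    valid = activation_map.valid & repolarization_map.valid
    nonpos = valid & ~(ari > 0)
    if nonpos.any():
        log.warning("non-positive ARI on channels %s; flagged invalid",
                    np.flatnonzero(nonpos).tolist())
        valid = valid & (ari > 0)
    ari = np.where(valid, ari, np.nan)

    vals = ari[valid]
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else (0.0 if vals.size else float("nan"))
    return ARIMap(channel_id=activation_map.channel_id.copy(), ari_ms=ari,
                  valid=valid, mean_ms=mean, sd_ms=sd)
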