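"""Signal conditioning before event detection.

Baseline wander (movement artifact, electrode drift) and high-frequency
noise are removed here, and unreliable channels are flagged for exclusion.
All filters preserve shape, sampling rate and channel order, pass excluded
channels through untouched, and are zero-phase in effect so activation
times are not shifted.

The recommended default chain for gastric serosal data is moving-median
baseline subtraction (20 s window) followed by Savitzky-Golay smoothing
(1 s window, order 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import median_filter
from scipy.signal import butter, savgol_filter, sosfiltfilt

from .core import CHANNEL_EXCLUDED, CHANNEL_OK, Recording, SlowWaveError

FILTER_KINDS = ("moving_median", "savitzky_golay", "butterworth", "wavelet")


def _odd_samples(window_s: float, fs: float) -> int:
    """Convert a window in seconds to an odd sample count (round up)."""
    n = int(np.ceil(window_s * fs))
    n = max(n, 3)
    return n if n % 2 == 1 else n + 1


@dataclass
class FilterSpec:
    """One filtering operation.

    kind = "moving_median":   window_s
    kind = "savitzky_golay":  window_s, poly_order
    kind = "butterworth":     band in {"low","high","band"}, cutoff_hz
                              (scalar, or (lo, hi) for band), order
    kind = "wavelet":         wavelet_name, decomposition_level,
                              kept_bands (0 = coarsest approximation,
                              1..level = detail bands coarse to fine)
    """

    kind: str
    window_s: float = 1.0
    poly_order: int = 2
    band: str = "low"
    cutoff_hz: float | tuple[float, float] = 1.0
    order: int = 2
    wavelet_name: str = "db4"
    decomposition_level: int = 6
    kept_bands: tuple[int, ...] = (0, 1, 2)

    def validate(self, fs: float, n_samples: int) -> None:
        if self.kind not in FILTER_KINDS:
            raise SlowWaveError(f"unknown filter kind {self.kind!r}")
        if self.kind in ("moving_median", "savitzky_golay"):
            if self.window_s <= 0:
                raise SlowWaveError("filter window must be positive")
            w = _odd_samples(self.window_s, fs)
            if w > n_samples:
                raise SlowWaveError(
                    f"window of {w} samples is longer than the {n_samples}-sample signal"
                )
            if self.kind == "savitzky_golay" and self.poly_order >= w:
                raise SlowWaveError(
                    f"poly_order {self.poly_order} must be < window length {w} samples"
                )
        elif self.kind == "butterworth":
            cuts = np.atleast_1d(np.asarray(self.cutoff_hz, dtype=float))
            if self.band == "band" and len(cuts) != 2:
                raise SlowWaveError("band-pass needs (low, high) cutoffs")
            if np.any(cuts <= 0) or np.any(cuts >= fs / 2):
                raise SlowWaveError(
                    f"Butterworth cutoff {self.cutoff_hz} Hz must lie strictly inside "
                    f"(0, {fs / 2}) Hz"
                )
        elif self.kind == "wavelet":
            if self.decomposition_level < 1:
                raise SlowWaveError("decomposition_level must be >= 1")
            if any(b < 0 or b > self.decomposition_level for b in self.kept_bands):
                raise SlowWaveError("kept_bands indices must be in 0..decomposition_level")


def _filter_1d(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    if spec.kind == "moving_median":
        w = _odd_samples(spec.window_s, fs)
        return median_filter(x, size=w, mode="nearest")
    if spec.kind == "savitzky_golay":
        w = _odd_samples(spec.window_s, fs)
        return savgol_filter(x, w, spec.poly_order, mode="nearest")
    if spec.kind == "butterworth":
        btype = {"low": "lowpass", "high": "highpass", "band": "bandpass"}[spec.band]
        sos = butter(spec.order, spec.cutoff_hz, btype=btype, fs=fs, output="sos")
        return sosfiltfilt(sos, x)
    if spec.kind == "wavelet":
        level = min(spec.decomposition_level, pywt.dwt_max_level(len(x), spec.wavelet_name))
        coeffs = pywt.wavedec(x, spec.wavelet_name, level=level)
        # coeffs[0] is the approximation (band 0); coeffs[i] is detail band i
        for i in range(len(coeffs)):
            if i not in spec.kept_bands:
                coeffs[i] = np.zeros_like(coeffs[i])
        return pywt.waverec(coeffs, spec.wavelet_name)[: len(x)]
    raise SlowWaveError(f"unknown filter kind {spec.kind!r}")


def apply_filter(recording: Recording, spec: FilterSpec) -> Recording:
    """Apply one filter to every non-excluded channel; deterministic."""
    spec.validate(recording.fs, recording.n_samples)
    if not np.isfinite(recording.samples).all():
        raise SlowWaveError("recording contains non-finite samples")
    out = recording.copy()
    for i, status in enumerate(recording.channel_status):
        if status == CHANNEL_EXCLUDED:
            continue
        out.samples[i] = _filter_1d(recording.samples[i], spec, recording.fs)
    return out


def remove_baseline(
    recording: Recording,
    method: str = "moving_median_subtract",
    window_s_or_cutoff: float = 20.0,
    slow_wave_period_s: float | None = None,
) -> Recording:
    """Remove baseline wander.

    ``moving_median_subtract`` returns signal minus its moving median (the
    median tracks the baseline but is blind to brief deflections);
    ``highpass`` applies a zero-phase Butterworth high-pass.  A median
    window of at least 5x the dominant slow-wave period is recommended —
    shorter windows start following the waves themselves.
    """
    if method == "moving_median_subtract":
        if slow_wave_period_s is not None and window_s_or_cutoff < 5 * slow_wave_period_s:
            warnings.warn(
                f"baseline window {window_s_or_cutoff}s is below 5x the slow-wave "
                f"period ({slow_wave_period_s}s); the baseline may track the waves",
                stacklevel=2,
            )
        spec = FilterSpec(kind="moving_median", window_s=window_s_or_cutoff)
        baseline = apply_filter(recording, spec)
        out = recording.copy()
        for i, status in enumerate(recording.channel_status):
            if status != CHANNEL_EXCLUDED:
                out.samples[i] = recording.samples[i] - baseline.samples[i]
        return out
    if method == "highpass":
        spec = FilterSpec(kind="butterworth", band="high", cutoff_hz=window_s_or_cutoff, order=2)
        return apply_filter(recording, spec)
    raise SlowWaveError(f"unknown baseline method {method!r}")


def default_chain(recording: Recording, baseline_window_s: float = 20.0,
                  smooth_window_s: float = 1.0, smooth_poly_order: int = 2) -> Recording:
    """Recommended gastric pre-processing chain.

    Moving-median baseline subtraction followed by Savitzky-Golay smoothing.
    """
    out = remove_baseline(recording, "moving_median_subtract", baseline_window_s)
    return apply_filter(
        out,
        FilterSpec(kind="savitzky_golay", window_s=smooth_window_s, poly_order=smooth_poly_order),
    )


def set_channel_status(recording: Recording, channel_id: str, status: str) -> Recording:
    """Flag a channel ok/excluded; excluded channels are skipped downstream.

    The flag is reversible and the samples are untouched.
    """
    if status not in (CHANNEL_OK, CHANNEL_EXCLUDED):
        raise SlowWaveError(f"status must be ok/excluded, got {status!r}")
    i = recording.channel_index(channel_id)
    out = recording.copy()
    out.channel_status[i] = status
    return out
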