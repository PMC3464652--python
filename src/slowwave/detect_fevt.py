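"""Falling-edge, variable-threshold (FEVT) activation-time detection.

Extracellular slow-wave arrival shows as a sharp negative deflection; the
activation time is conventionally marked at the point of steepest negative
slope.  The detector rectifies the negative part of the signal derivative,
raises it to a power to emphasize high-energy edges, smooths it into a
detection signal D(t), and compares D against a time-varying threshold
built from a running median, so that the threshold adapts to slowly varying
noise levels without being dragged up by the sparse events themselves.

For multiphasic (fractionated) events the mark is placed on the first major
deflection: among descent peaks inside one supra-threshold run, the
earliest whose detection signal reaches a set fraction of the run maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .core import (
    CHANNEL_EXCLUDED,
    ElectrodeLayout,
    EventMarks,
    Mark,
    MARK_AUTO,
    MARK_MANUAL,
    Recording,
    SlowWaveError,
)
from .params import ParameterSet


@dataclass
class DetectionTrace:
    """Detection signal and threshold for one channel, same sampling as the signal."""

    detection: np.ndarray   # D(t) >= 0
    threshold: np.ndarray   # theta(t) > 0


def _centered_derivative(signal: np.ndarray, fs: float, edge_len_s: float) -> np.ndarray:
    """Centred finite difference scaled to units per second.

    ``edge_len_s`` sets the difference span; 0 means one sample each side.
    One-sided differences are used at the array ends.
    """
    k = max(1, int(round(edge_len_s * fs / 2)))
    n = len(signal)
    if n < 2 * k + 1:
        raise SlowWaveError("signal too short for the requested edge length")
    d = np.empty(n)
    d[k:-k] = (signal[2 * k:] - signal[:-2 * k]) * fs / (2 * k)
    for i in range(k):
        d[i] = (signal[i + k] - signal[i]) * fs / k
        d[-(i + 1)] = (signal[-(i + 1)] - signal[-(i + 1 + k)]) * fs / k
    return d


def falling_edge_transform(
    signal: np.ndarray,
    fs: float,
    edge_len_s: float = 0.0,
    power_p: float = 2.0,
    smooth_s: float = 0.25,
) -> np.ndarray:
    """Non-negative detection signal emphasizing downward deflections.

    D(t) = moving average over ``smooth_s`` of [max(0, -s'(t))]^p.  Rising
    edges contribute zero.
    """
    signal = np.asarray(signal, dtype=float)
    if not np.isfinite(signal).all():
        raise SlowWaveError("signal contains non-finite samples")
    d = _centered_derivative(signal, fs, edge_len_s)
    rect = np.maximum(0.0, -d) ** power_p
    if smooth_s > 0:
        w = max(1, int(round(smooth_s * fs)))
        if w % 2 == 0:
            w += 1
        if w > 1:
            rect = uniform_filter1d(rect, size=w, mode="nearest")
    return rect


def variable_threshold(
    detection: np.ndarray,
    fs: float,
    window_s: float = 15.0,
    eta: float = 5.0,
    floor_eps: float | None = None,
) -> np.ndarray:
    """Time-varying threshold: eta times the running median of D.

    The median is robust to sparse events (duty cycle below half the
    window), so the threshold tracks background noise energy only.  A small
    positive floor keeps the threshold defined on silent stretches; by
    default it scales with the data so mark times are invariant under
    amplitude scaling.
    """
    detection = np.asarray(detection, dtype=float)
    if eta <= 0:
        raise SlowWaveError("eta must be positive")
    w = int(round(window_s * fs))
    if w % 2 == 0:
        w += 1
    if w < 3:
        raise SlowWaveError(f"threshold window of {w} samples is too short (< 3)")
    med = median_filter(detection, size=min(w, len(detection) | 1), mode="nearest")
    if floor_eps is None:
        scale = float(np.max(detection)) if detection.size else 0.0
        floor_eps = max(np.finfo(float).tiny, 1e-12 * scale)
    return np.maximum(floor_eps, eta * med)


def channel_trace(signal: np.ndarray, fs: float, params: ParameterSet) -> DetectionTrace:
    d = falling_edge_transform(
        signal, fs, params.fevt_edge_len_s, params.fevt_power, params.fevt_smooth_s
    )
    theta = variable_threshold(
        d, fs, params.fevt_threshold_window_s, params.fevt_eta
    )
    return DetectionTrace(detection=d, threshold=theta)


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [runs[0]]
    for a, b in runs[1:]:
        pa, pb = merged[-1]
        if a - pb < gap:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    return merged


def _mark_index_in_run(
    neg_deriv: np.ndarray,
    detection: np.ndarray,
    a: int,
    b: int,
    fs: float,
    sep_s: float,
    frac: float,
) -> int:
    """Mark placement inside one supra-threshold run.

    Descent peaks (local maxima of the rectified negative derivative)
    separated by more than ``sep_s`` are treated as distinct deflections;
    the first whose detection signal reaches ``frac`` of the run maximum is
    marked at its steepest-descent sample.
    """
    seg = neg_deriv[a:b]
    d_seg = detection[a:b]
    d_max = float(np.max(d_seg))
    peaks = [
        i for i in range(len(seg))
        if seg[i] > 0
        and (i == 0 or seg[i] >= seg[i - 1])
        and (i == len(seg) - 1 or seg[i] > seg[i + 1])
    ]
    if not peaks:
        return a + int(np.argmax(seg))
    # collapse peaks closer than sep_s to the strongest of each cluster
    sep = max(1, int(round(sep_s * fs)))
    clusters: list[int] = []
    for i in peaks:
        if clusters and i - clusters[-1] <= sep:
            if seg[i] > seg[clusters[-1]]:
                clusters[-1] = i
        else:
            clusters.append(i)
    for i in clusters:
        if d_seg[i] >= frac * d_max:
            return a + i
    return a + int(np.argmax(seg))


def fevt_detect(
    recording: Recording,
    layout: ElectrodeLayout | None = None,
    params: ParameterSet | None = None,
) -> EventMarks:
    """Detect activation-time marks on every non-excluded channel.

    Supra-threshold runs of the detection signal are found, runs closer
    than the refractory period are merged, and each surviving run yields a
    single auto mark at the steepest negative slope (first-major-deflection
    rule for multiphasic runs).  The detection score is max(D/theta) over
    the run.  Returns empty marks when nothing crosses the threshold.
    """
    params = params or ParameterSet()
    if recording.n_samples < 3:
        raise SlowWaveError("recording too short for detection")
    fs = recording.fs
    gap = max(1, int(round(params.fevt_refractory_s * fs)))
    by_channel: dict[str, list[Mark]] = {}
    for i, ch in enumerate(recording.channel_ids):
        if recording.channel_status[i] == CHANNEL_EXCLUDED:
            continue
        sig = recording.samples[i]
        trace = channel_trace(sig, fs, params)
        neg_deriv = np.maximum(0.0, -_centered_derivative(sig, fs, params.fevt_edge_len_s))
        runs = _merge_runs(_supra_runs(trace.detection > trace.threshold), gap)
        marks: list[Mark] = []
        for a, b in runs:
            j = _mark_index_in_run(
                neg_deriv, trace.detection, a, b, fs,
                params.fevt_deflection_sep_s, params.fevt_first_deflection_frac,
            )
            score = float(np.max(trace.detection[a:b] / trace.threshold[a:b]))
            marks.append(Mark(time_s=j / fs, source=MARK_AUTO, score=score))
        if marks:
            by_channel[ch] = marks
    out = EventMarks(by_channel)
    out.validate(refractory_s=params.fevt_refractory_s / 2, span_s=recording.duration_s)
    return out


def edit_marks(
    marks: EventMarks,
    action: str,
    channel: str,
    time_s: float,
    recording: Recording | None = None,
    params: ParameterSet | None = None,
    snap: bool = True,
) -> EventMarks:
    """Add or delete a manual mark.

    ``add`` places a manual mark at the steepest-descent sample within the
    snap window of ``time_s`` (needs the recording; with ``snap=False`` the
    exact time is used).  ``delete`` removes the nearest mark within the
    snap window.  Adds violating the refractory spacing raise an error
    naming the conflicting mark.
    """
    params = params or ParameterSet()
    channel = str(channel)
    out = marks.copy()
    existing = out.by_channel.get(channel, [])
    snap_s = params.mark_snap_window_s
    if action == "add":
        t = time_s
        if snap and recording is not None:
            fs = recording.fs
            sig = recording.channel(channel)
            lo = max(0, int(round((time_s - snap_s) * fs)))
            hi = min(len(sig), int(round((time_s + snap_s) * fs)) + 1)
            if hi - lo >= 3:
                d = _centered_derivative(sig, fs, params.fevt_edge_len_s)
                t = (lo + int(np.argmin(d[lo:hi]))) / fs
        for m in existing:
            if abs(m.time_s - t) < params.fevt_refractory_s:
                raise SlowWaveError(
                    f"new mark at {t:.3f}s violates refractory spacing with the "
                    f"existing mark at {m.time_s:.3f}s on channel {channel!r}"
                )
        out.by_channel.setdefault(channel, []).append(Mark(time_s=t, source=MARK_MANUAL))
        out.by_channel[channel].sort(key=lambda m: m.time_s)
        return out
    if action == "delete":
        if not existing:
            raise SlowWaveError(f"no marks on channel {channel!r}")
        nearest = min(existing, key=lambda m: abs(m.time_s - time_s))
        if abs(nearest.time_s - time_s) > snap_s:
            raise SlowWaveError(
                f"no mark within {snap_s}s of {time_s}s on channel {channel!r}"
            )
        out.by_channel[channel] = [m for m in existing if m is not nearest]
        if not out.by_channel[channel]:
            del out.by_channel[channel]
        return out
    raise SlowWaveError(f"unknown edit action {action!r}")
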