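"""Per-cycle spatial products derived from clustered activation marks.

Four grid products are computed per wavefront cycle: activation-time maps
(optionally filled by the two-stage spatial interpolation scheme),
conduction-velocity fields from a smoothed finite-difference gradient,
peak-to-trough amplitude maps, and cycle-to-cycle time-interval (frequency)
maps used to flag brady- and tachygastric regions.

Grid coordinates: x runs along columns, y along rows; distances in mm,
times in seconds, speeds in mm/s, amplitudes in microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .core import CycleAssignment, ElectrodeLayout, EventMarks, Recording, SlowWaveError

# site flags for activation maps
MISSING = 0
MEASURED = 1
INTERPOLATED = 2


@dataclass
class ActivationMap:
    """Grid of activation times (s) for one wavefront cycle."""

    cycle: int                    # 1-based cycle index
    times: np.ndarray             # (rows, cols), NaN where not defined
    flags: np.ndarray             # (rows, cols) in {MISSING, MEASURED, INTERPOLATED}

    def n_measured(self) -> int:
        return int(np.sum(self.flags == MEASURED))

    def n_interpolated(self) -> int:
        return int(np.sum(self.flags == INTERPOLATED))

    def copy(self) -> "ActivationMap":
        return ActivationMap(self.cycle, self.times.copy(), self.flags.copy())


@dataclass
class VelocityField:
    """Conduction-velocity vectors (mm/s) for one cycle."""

    cycle: int
    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    defined: np.ndarray           # bool mask


@dataclass
class AmplitudeMap:
    """Peak-to-trough extracellular amplitudes (uV) for one cycle."""

    cycle: int
    amplitude: np.ndarray         # NaN where no mark
    confidence: np.ndarray        # (rows, cols) of "", "high", "low"


@dataclass
class IntervalMap:
    """Activation-time intervals between one consecutive cycle pair."""

    pair: tuple[int, int]         # (k, k+1), 1-based
    intervals: np.ndarray         # seconds, NaN where undefined
    freq_cpm: np.ndarray          # 60 / interval
    classes: np.ndarray           # "", "brady", "normal", "tachy"
    mean_s: float
    sd_s: float


def build_activation_map(
    assignment: CycleAssignment,
    marks: EventMarks,
    layout: ElectrodeLayout,
    cycle_k: int,
) -> ActivationMap:
    """Place each member mark of 1-based cycle ``cycle_k`` at its grid site."""
    members = assignment.cycle_members(cycle_k)
    rows, cols = layout.grid_shape
    times = np.full((rows, cols), np.nan)
    flags = np.full((rows, cols), MISSING, dtype=int)
    for ch, t in members.items():
        if t not in marks.times(ch):
            raise SlowWaveError(f"cycle {cycle_k} references unknown mark ({ch!r}, {t})")
        r, c = layout.site_of(ch)
        times[r, c] = t
        flags[r, c] = MEASURED
    return ActivationMap(cycle=cycle_k, times=times, flags=flags)


def _neighbor_values(times: np.ndarray, eligible: np.ndarray, r: int, c: int) -> np.ndarray:
    rows, cols = times.shape
    vals = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and eligible[rr, cc]:
                vals.append(times[rr, cc])
    return np.asarray(vals)


def siv_interpolate(amap: ActivationMap, k1: int = 5, k2: int = 3) -> ActivationMap:
    """Two-stage spatial interpolation of blank sites.

    Stage 1 fills every missing site having at least ``k1`` measured
    8-neighbours with the median of those neighbours.  Stage 2 repeats the
    rule with threshold ``k2``, this time counting measured and stage-1
    sites, to fill in the missing borders.  Exactly two stages are run and
    measured values are never altered.
    """
    for k in (k1, k2):
        if not (1 <= k <= 8):
            raise SlowWaveError(f"SIV thresholds must be in 1..8, got {k}")
    out = amap.copy()
    rows, cols = out.times.shape

    measured = out.flags == MEASURED
    stage1: list[tuple[int, int, float]] = []
    for r in range(rows):
        for c in range(cols):
            if out.flags[r, c] != MISSING:
                continue
            vals = _neighbor_values(out.times, measured, r, c)
            if len(vals) >= k1:
                stage1.append((r, c, float(np.median(vals))))
    for r, c, v in stage1:
        out.times[r, c] = v
        out.flags[r, c] = INTERPOLATED

    eligible = out.flags != MISSING   # measured plus stage-1 sites
    stage2: list[tuple[int, int, float]] = []
    for r in range(rows):
        for c in range(cols):
            if out.flags[r, c] != MISSING:
                continue
            vals = _neighbor_values(out.times, eligible, r, c)
            if len(vals) >= k2:
                stage2.append((r, c, float(np.median(vals))))
    for r, c, v in stage2:
        out.times[r, c] = v
        out.flags[r, c] = INTERPOLATED
    return out


def _masked_gaussian_smooth(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing that renormalizes over defined sites only.

    A constant field over any mask is reproduced exactly, which preserves
    the planar-wave closed form for the velocity calculation.
    """
    if sigma <= 0:
        return values.copy()
    radius = int(np.ceil(3 * sigma))
    ax = np.arange(-radius, radius + 1)
    k1d = np.exp(-(ax ** 2) / (2 * sigma ** 2))
    kernel = np.outer(k1d, k1d)

    filled = np.where(mask, values, 0.0)
    rows, cols = values.shape
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    for i, dr in enumerate(range(-radius, radius + 1)):
        for j, dc in enumerate(range(-radius, radius + 1)):
            w = kernel[i, j]
            src_r = slice(max(0, -dr), min(rows, rows - dr))
            src_c = slice(max(0, -dc), min(cols, cols - dc))
            dst_r = slice(max(0, dr), min(rows, rows + dr))
            dst_c = slice(max(0, dc), min(cols, cols + dc))
            num[dst_r, dst_c] += w * filled[src_r, src_c]
            den[dst_r, dst_c] += w * mask[src_r, src_c]
    out = np.full_like(values, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def _grid_gradient(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis finite differences in seconds per electrode unit.

    Central differences where both neighbours are defined, one-sided at
    borders and next to missing sites, NaN where no defined neighbour.
    """
    rows, cols = times.shape
    gx = np.full_like(times, np.nan)
    gy = np.full_like(times, np.nan)
    ok = np.isfinite(times)
    for r in range(rows):
        for c in range(cols):
            if not ok[r, c]:
                continue
            left = times[r, c - 1] if c > 0 and ok[r, c - 1] else None
            right = times[r, c + 1] if c < cols - 1 and ok[r, c + 1] else None
            if left is not None and right is not None:
                gx[r, c] = (right - left) / 2.0
            elif right is not None:
                gx[r, c] = right - times[r, c]
            elif left is not None:
                gx[r, c] = times[r, c] - left
            up = times[r - 1, c] if r > 0 and ok[r - 1, c] else None
            down = times[r + 1, c] if r < rows - 1 and ok[r + 1, c] else None
            if up is not None and down is not None:
                gy[r, c] = (down - up) / 2.0
            elif down is not None:
                gy[r, c] = down - times[r, c]
            elif up is not None:
                gy[r, c] = times[r, c] - up
    return gx, gy


def compute_velocity_field(
    amap: ActivationMap,
    spacing_mm: float,
    sigma_sites: float = 1.0,
    min_grad_s_per_mm: float = 1e-3,
    use_interpolated: bool = True,
) -> VelocityField:
    """Velocity field from the smoothed finite-difference activation gradient.

    The gradient ``g`` of the activation-time surface (s/mm) is estimated by
    finite differences, each component smoothed with a missing-aware Gaussian
    kernel (``sigma_sites`` electrode units, truncated at 3 sigma), and
    inverted via ``v = g / |g|^2`` so that speed is 1/|g| and direction
    follows increasing activation time.  Sites with |g| below
    ``min_grad_s_per_mm`` (near-simultaneous activation) are undefined.
    """
    if spacing_mm <= 0:
        raise SlowWaveError("spacing_mm must be positive")
    times = amap.times.copy()
    if not use_interpolated:
        times[amap.flags == INTERPOLATED] = np.nan
    if not np.isfinite(times).any():
        raise SlowWaveError("activation map has no defined sites")

    gx, gy = _grid_gradient(times)
    mask = np.isfinite(gx) & np.isfinite(gy)
    gx_s = _masked_gaussian_smooth(np.where(mask, gx, 0.0), mask, sigma_sites)
    gy_s = _masked_gaussian_smooth(np.where(mask, gy, 0.0), mask, sigma_sites)

    # seconds per mm
    gx_mm = gx_s / spacing_mm
    gy_mm = gy_s / spacing_mm
    g2 = gx_mm ** 2 + gy_mm ** 2
    defined = mask & np.isfinite(g2) & (np.sqrt(np.where(np.isfinite(g2), g2, 0)) >= min_grad_s_per_mm)

    vx = np.full_like(times, np.nan)
    vy = np.full_like(times, np.nan)
    vx[defined] = gx_mm[defined] / g2[defined]
    vy[defined] = gy_mm[defined] / g2[defined]
    speed = np.sqrt(vx ** 2 + vy ** 2)
    return VelocityField(cycle=amap.cycle, vx=vx, vy=vy, speed=speed, defined=defined)


def _odd_window(seconds: float, fs: float, minimum: int = 5) -> int:
    n = max(minimum, int(np.ceil(seconds * fs)))
    return n + 1 if n % 2 == 0 else n


def estimate_amplitude(
    signal: np.ndarray,
    fs: float,
    t_mark: float,
    window_s: float = 1.5,
    smooth_s: float = 0.25,
) -> tuple[float, str]:
    """Peak-to-trough amplitude around a mark by derivative zero-crossings.

    A window of ``window_s`` centred on the mark is analysed.  The first
    derivative is smoothed (Savitzky-Golay, quadratic), its zero-crossings
    are classified into local maxima/minima by the sign of the second
    derivative, and the amplitude is the highest maximum minus the lowest
    minimum.  If no maximum or no minimum is found the raw max-min of the
    window is returned with low confidence.  Adding a constant offset to the
    signal leaves the estimate unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    idx = int(round(t_mark * fs))
    if not (0 <= idx < n):
        raise SlowWaveError(f"mark at {t_mark}s is outside the recording")
    half = int(round(window_s / 2 * fs))
    lo, hi = idx - half, idx + half + 1
    truncated = lo < 0 or hi > n
    lo, hi = max(0, lo), min(n, hi)
    seg = signal[lo:hi]
    if len(seg) < 5:
        return float(np.max(seg) - np.min(seg)), "low"

    win = min(_odd_window(smooth_s, fs), len(seg) - (1 - len(seg) % 2))
    d1 = savgol_filter(seg, win, 2, deriv=1, delta=1.0 / fs)
    d2 = savgol_filter(seg, win, 2, deriv=2, delta=1.0 / fs)

    maxima: list[float] = []
    minima: list[float] = []
    for i in range(len(seg) - 1):
        if d1[i] == 0 or d1[i] * d1[i + 1] < 0:
            j = i if abs(d1[i]) <= abs(d1[i + 1]) else i + 1
            if d2[j] < 0:
                maxima.append(seg[j])
            elif d2[j] > 0:
                minima.append(seg[j])
    if not maxima or not minima:
        return float(np.max(seg) - np.min(seg)), "low"
    amp = float(max(maxima) - min(minima))
    return amp, ("low" if truncated else "high")


def compute_amplitude_map(
    assignment: CycleAssignment,
    marks: EventMarks,
    layout: ElectrodeLayout,
    recording: Recording,
    cycle_k: int,
    window_s: float = 1.5,
    smooth_s: float = 0.25,
) -> AmplitudeMap:
    """Amplitude at every measured site of one cycle; no interpolation."""
    members = assignment.cycle_members(cycle_k)
    rows, cols = layout.grid_shape
    amp = np.full((rows, cols), np.nan)
    conf = np.full((rows, cols), "", dtype=object)
    for ch, t in members.items():
        r, c = layout.site_of(ch)
        a, cf = estimate_amplitude(recording.channel(ch), recording.fs, t, window_s, smooth_s)
        amp[r, c] = a
        conf[r, c] = cf
    return AmplitudeMap(cycle=cycle_k, amplitude=amp, confidence=conf)


def compute_intervals(
    assignment: CycleAssignment,
    marks: EventMarks,
    layout: ElectrodeLayout,
    bounds_cpm: tuple[float, float] = (2.0, 4.0),
) -> list[IntervalMap]:
    """Per-site intervals between consecutive cycles, with brady/tachy classes.

    Only channels with a measured mark in both cycles of a pair contribute;
    interpolated map values never feed interval statistics.  Frequency is
    60/interval in cycles/min; a site is bradygastric below ``bounds_cpm[0]``
    and tachygastric above ``bounds_cpm[1]``.
    """
    if assignment.n_cycles() < 2:
        raise SlowWaveError("interval maps require at least 2 cycles")
    low, high = bounds_cpm
    rows, cols = layout.grid_shape
    out: list[IntervalMap] = []
    for k in range(1, assignment.n_cycles()):
        a = assignment.cycle_members(k)
        b = assignment.cycle_members(k + 1)
        iv = np.full((rows, cols), np.nan)
        fq = np.full((rows, cols), np.nan)
        cls = np.full((rows, cols), "", dtype=object)
        for ch in set(a) & set(b):
            dt = b[ch] - a[ch]
            if dt <= 0:
                continue
            r, c = layout.site_of(ch)
            iv[r, c] = dt
            f = 60.0 / dt
            fq[r, c] = f
            cls[r, c] = "brady" if f < low else ("tachy" if f > high else "normal")
        defined = np.isfinite(iv)
        mean_s = float(np.mean(iv[defined])) if defined.any() else float("nan")
        sd_s = float(np.std(iv[defined])) if defined.any() else float("nan")
        out.append(IntervalMap(pair=(k, k + 1), intervals=iv, freq_cpm=fq,
                               classes=cls, mean_s=mean_s, sd_s=sd_s))
    return out
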