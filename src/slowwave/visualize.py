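"""Rendering of activation, velocity, amplitude and interval maps, and
propagation animations.

Rendering is a pure function of the analysis products and a style: calling
it twice writes byte-identical files, and no call mutates a product.
Activation maps render as smoothed isochronal contours (red-to-blue: early
sites red, late sites blue) or as patch plots; the electrode grid can be
overlaid as circles, black where an event was measured and white where the
site is missing or interpolated.  Interval maps are always patch plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v2 as imageio
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .core import CycleAssignment, ElectrodeLayout, EventMarks, SlowWaveError  # noqa: E402
from .spatial_metrics import (  # noqa: E402
    INTERPOLATED,
    MEASURED,
    ActivationMap,
    AmplitudeMap,
    IntervalMap,
    VelocityField,
)

#: metadata passed to every PNG save so repeated renders are byte-identical
_PNG_METADATA = {"Software": None}


@dataclass
class MapStyle:
    isochrone_interval_s: float = 2.0
    colormap: str = "RdBu"            # red (early) to blue (late)
    show_grid: bool = True
    interpolate_contours: bool = True
    figsize: tuple[float, float] = (5.0, 4.5)
    dpi: int = 100
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.isochrone_interval_s <= 0:
            raise SlowWaveError("isochrone_interval_s must be positive")


def isochrone_levels(t_min: float, t_max: float, interval_s: float) -> np.ndarray:
    """Contour levels spanning [t_min, t_max] at the isochrone interval.

    The number of isochronal bands is the number of intervals covering the
    span, i.e. ``ceil(span / interval)``.
    """
    if interval_s <= 0:
        raise SlowWaveError("isochrone interval must be positive")
    n_bands = max(1, math.ceil((t_max - t_min) / interval_s - 1e-12))
    return t_min + interval_s * np.arange(n_bands + 1)


def _grid_overlay(ax, amap_flags: np.ndarray) -> None:
    rows, cols = amap_flags.shape
    for r in range(rows):
        for c in range(cols):
            color = "black" if amap_flags[r, c] == MEASURED else "white"
            ax.plot(c, r, "o", markersize=5, markerfacecolor=color,
                    markeredgecolor="black", zorder=5)


def _finish(fig, ax, style: MapStyle, title: str, path: str | Path) -> None:
    ax.set_xlabel("electrode column")
    ax.set_ylabel("electrode row")
    ax.invert_yaxis()               # row 0 displayed at top
    ax.set_title(title if not style.annotation else f"{title} — {style.annotation}")
    fig.savefig(path, dpi=style.dpi, metadata=_PNG_METADATA)
    plt.close(fig)


def render_map(product, layout: ElectrodeLayout, style: MapStyle, path: str | Path) -> None:
    """Render one analysis product to an image file.

    ``product`` is an :class:`ActivationMap`, :class:`VelocityField`,
    :class:`AmplitudeMap` or :class:`IntervalMap`.
    """
    if product is None:
        raise SlowWaveError("no product to render; run the maps stage first")
    fig, ax = plt.subplots(figsize=style.figsize)
    if isinstance(product, ActivationMap):
        defined = np.isfinite(product.times)
        if not defined.any():
            plt.close(fig)
            raise SlowWaveError("activation map has zero defined sites")
        t_min, t_max = float(np.nanmin(product.times)), float(np.nanmax(product.times))
        if style.interpolate_contours and defined.sum() >= 4 and t_max > t_min:
            levels = isochrone_levels(t_min, t_max, style.isochrone_interval_s)
            m = ax.contourf(
                np.ma.masked_invalid(product.times), levels=levels,
                cmap=style.colormap + "_r" if not style.colormap.endswith("_r") else style.colormap,
                extend="both",
            )
        else:
            m = ax.pcolormesh(
                np.ma.masked_invalid(product.times),
                cmap=style.colormap + "_r", shading="nearest",
            )
        fig.colorbar(m, ax=ax, label="activation time (s)")
        if style.show_grid:
            _grid_overlay(ax, product.flags)
        _finish(fig, ax, style, f"activation, cycle {product.cycle}", path)
    elif isinstance(product, VelocityField):
        if not product.defined.any():
            plt.close(fig)
            raise SlowWaveError("velocity field has zero defined sites")
        m = ax.pcolormesh(np.ma.masked_invalid(product.speed), cmap="viridis", shading="nearest")
        fig.colorbar(m, ax=ax, label="speed (mm/s)")
        rr, cc = np.nonzero(product.defined)
        ax.quiver(cc, rr, product.vx[rr, cc], -product.vy[rr, cc], color="white",
                  zorder=4, width=0.004)
        _finish(fig, ax, style, f"velocity, cycle {product.cycle}", path)
    elif isinstance(product, AmplitudeMap):
        if not np.isfinite(product.amplitude).any():
            plt.close(fig)
            raise SlowWaveError("amplitude map has zero defined sites")
        m = ax.pcolormesh(np.ma.masked_invalid(product.amplitude), cmap="magma", shading="nearest")
        fig.colorbar(m, ax=ax, label="amplitude (μV)")
        _finish(fig, ax, style, f"amplitude, cycle {product.cycle}", path)
    elif isinstance(product, IntervalMap):
        if not np.isfinite(product.intervals).any():
            plt.close(fig)
            raise SlowWaveError("interval map has zero defined sites")
        m = ax.pcolormesh(np.ma.masked_invalid(product.intervals), cmap="coolwarm", shading="nearest")
        fig.colorbar(m, ax=ax, label="interval (s)")
        _finish(
            fig, ax, style,
            f"intervals, cycles {product.pair[0]}-{product.pair[1]} "
            f"(mean {product.mean_s:.1f} ± {product.sd_s:.1f} s)", path,
        )
    else:
        plt.close(fig)
        raise SlowWaveError(f"cannot render object of type {type(product).__name__}")


# --------------------------------------------------------------------------
# propagation animation
# --------------------------------------------------------------------------

def site_intensity(t: float, t_activation: float, tail_s: float) -> float:
    """Refractory-tail fade law: 1 at activation, linear to 0 over ``tail_s``."""
    if t < t_activation:
        return 0.0
    if tail_s <= 0:
        return 1.0 if t == t_activation else 0.0
    return max(0.0, 1.0 - (t - t_activation) / tail_s)


def animation_frames(
    assignment: CycleAssignment | None,
    marks: EventMarks,
    layout: ElectrodeLayout,
    fps: float,
    tail_s: float,
    t_start: float,
    t_end: float,
    per_cycle_colors: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw animation data: per-frame site intensities and RGB colors.

    Returns ``(intensity, rgb)`` of shapes ``(n_frames, rows, cols)`` and
    ``(n_frames, rows, cols, 3)``; frame count is ``ceil((t_end - t_start)
    * fps)``.  A site lights at its activation time and fades linearly over
    ``tail_s``.  With clustering, each cycle gets a distinct color;
    otherwise a single color is used.
    """
    if not (t_start < t_end):
        raise SlowWaveError("t_start must be before t_end")
    if fps <= 0:
        raise SlowWaveError("fps must be positive")
    events: list[tuple[tuple[int, int], float, int]] = []   # (site, time, cycle)
    for ch, m in marks.iter_marks():
        if ch not in layout.placement:
            continue
        if not (t_start - tail_s <= m.time_s <= t_end):
            continue
        cyc = 0
        if assignment is not None and per_cycle_colors:
            try:
                cyc = assignment.cycle_of(ch, m.time_s)
            except SlowWaveError:
                cyc = 0
        events.append((layout.site_of(ch), m.time_s, cyc))
    if not any(t_start <= t <= t_end for _, t, _ in events):
        raise SlowWaveError(f"no marks in the window [{t_start}, {t_end}] s")

    n_frames = math.ceil((t_end - t_start) * fps)
    rows, cols = layout.grid_shape
    intensity = np.zeros((n_frames, rows, cols))
    rgb = np.zeros((n_frames, rows, cols, 3))
    cmap = plt.get_cmap("hsv")
    n_cycles = max((cyc for _, _, cyc in events), default=0)

    def color(cyc: int) -> np.ndarray:
        if cyc == 0 or not per_cycle_colors:
            return np.array([1.0, 0.2, 0.1])
        return np.asarray(cmap(((cyc - 1) / max(1, n_cycles)) * 0.85)[:3])

    for f in range(n_frames):
        t = t_start + f / fps
        for site, t_act, cyc in events:
            w = site_intensity(t, t_act, tail_s)
            if w > intensity[f][site]:
                intensity[f][site] = w
                rgb[f][site] = w * color(cyc)
    return intensity, rgb


def render_animation(
    assignment: CycleAssignment | None,
    marks: EventMarks,
    layout: ElectrodeLayout,
    fps: float,
    tail_s: float,
    t_start: float,
    t_end: float,
    path: str | Path,
    per_cycle_colors: bool = True,
    upscale: int = 24,
) -> int:
    """Write a propagation movie; returns the frame count.

    A ``.gif`` path produces an animated GIF; a directory produces numbered
    PNG frames.  Each electrode site is drawn as an ``upscale`` x
    ``upscale`` pixel block.
    """
    _, rgb = animation_frames(
        assignment, marks, layout, fps, tail_s, t_start, t_end, per_cycle_colors
    )
    frames = (np.kron(rgb, np.ones((upscale, upscale, 1))) * 255).astype(np.uint8)
    path = Path(path)
    if path.suffix == "":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            imageio.imwrite(path / f"frame_{i:05d}.png", frame)
    elif path.suffix.lower() == ".gif":
        imageio.mimwrite(path, list(frames), duration=1000.0 / fps, loop=0)
    else:
        imageio.mimwrite(path, list(frames), fps=fps)
    return len(frames)
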