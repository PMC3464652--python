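"""Core data containers shared by every analysis stage.

All internal units are fixed: times in seconds from sample 0, amplitudes in
microvolts, distances in millimetres.  Grid indices are 0-based and
row-major, with row 0 displayed at the top.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

CHANNEL_OK = "ok"
CHANNEL_EXCLUDED = "excluded"


class SlowWaveError(ValueError):
    """Base class for validation and format errors raised by this package."""


@dataclass
class Recording:
    """Multi-channel extracellular recording.

    Parameters
    ----------
    samples
        ``(n_channels, n_samples)`` array of signal values in microvolts.
    fs
        Sampling rate in Hz.  A single rate applies to every channel.
    channel_ids
        Ordered, unique channel labels.
    t0
        Recording start offset in seconds (display only; all analysis times
        are referenced to sample 0).
    channel_status
        Per-channel flag, ``"ok"`` or ``"excluded"``.
    """

    samples: np.ndarray
    fs: float
    channel_ids: list[str]
    t0: float = 0.0
    channel_status: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise SlowWaveError("samples must be a 2-D (channels x samples) array")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise SlowWaveError("recording must have at least one channel and one sample")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise SlowWaveError(f"sampling rate must be finite and positive, got {self.fs}")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise SlowWaveError(
                f"{len(self.channel_ids)} channel ids for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise SlowWaveError("channel ids must be unique")
        if not self.channel_status:
            self.channel_status = [CHANNEL_OK] * self.n_channels
        if len(self.channel_status) != self.n_channels:
            raise SlowWaveError("channel_status length must match channel count")
        for s in self.channel_status:
            if s not in (CHANNEL_OK, CHANNEL_EXCLUDED):
                raise SlowWaveError(f"unknown channel status {s!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds from sample 0."""
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(str(channel_id))
        except ValueError:
            raise SlowWaveError(f"unknown channel {channel_id!r}") from None

    def is_excluded(self, channel_id: str) -> bool:
        return self.channel_status[self.channel_index(channel_id)] == CHANNEL_EXCLUDED

    def channel(self, channel_id: str) -> np.ndarray:
        return self.samples[self.channel_index(channel_id)]

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            fs=self.fs,
            channel_ids=list(self.channel_ids),
            t0=self.t0,
            channel_status=list(self.channel_status),
        )


@dataclass
class ElectrodeLayout:
    """Mapping from channels to sites on a rectangular electrode grid."""

    grid_shape: tuple[int, int]
    placement: dict[str, tuple[int, int]]
    spacing_mm: float
    orientation_deg: float = 0.0  # rendering only, never used in computation

    def __post_init__(self) -> None:
        self.grid_shape = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise SlowWaveError("grid_shape must be at least 1x1")
        if not (self.spacing_mm > 0):
            raise SlowWaveError(f"spacing_mm must be positive, got {self.spacing_mm}")
        seen: dict[tuple[int, int], str] = {}
        clean: dict[str, tuple[int, int]] = {}
        for ch, (r, c) in self.placement.items():
            r, c = int(r), int(c)
            if not (0 <= r < self.grid_shape[0] and 0 <= c < self.grid_shape[1]):
                raise SlowWaveError(f"channel {ch!r} placed at ({r},{c}) outside grid {self.grid_shape}")
            if (r, c) in seen:
                raise SlowWaveError(f"grid site ({r},{c}) holds both {seen[(r, c)]!r} and {ch!r}")
            seen[(r, c)] = str(ch)
            clean[str(ch)] = (r, c)
        self.placement = clean

    @classmethod
    def from_template(
        cls,
        n_rows: int,
        n_cols: int,
        spacing_mm: float,
        order: str = "row-major",
        channel_prefix: str = "",
        start: int = 0,
    ) -> "ElectrodeLayout":
        """Standard template: sequential channel ids filling the grid.

        ``order`` is ``"row-major"`` or ``"col-major"``.
        """
        placement: dict[str, tuple[int, int]] = {}
        k = start
        if order == "row-major":
            sites = [(r, c) for r in range(n_rows) for c in range(n_cols)]
        elif order == "col-major":
            sites = [(r, c) for c in range(n_cols) for r in range(n_rows)]
        else:
            raise SlowWaveError(f"unknown template order {order!r}")
        for r, c in sites:
            placement[f"{channel_prefix}{k}"] = (r, c)
            k += 1
        return cls(grid_shape=(n_rows, n_cols), placement=placement, spacing_mm=spacing_mm)

    def site_of(self, channel_id: str) -> tuple[int, int]:
        try:
            return self.placement[str(channel_id)]
        except KeyError:
            raise SlowWaveError(f"channel {channel_id!r} not in layout") from None

    def channel_at(self, row: int, col: int) -> str | None:
        for ch, (r, c) in self.placement.items():
            if (r, c) == (row, col):
                return ch
        return None

    def site_to_channel(self) -> dict[tuple[int, int], str]:
        return {site: ch for ch, site in self.placement.items()}

    def neighbors8(self, row: int, col: int) -> list[tuple[int, int]]:
        """8-connected grid neighbours of a site, clipped to the grid."""
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r, c = row + dr, col + dc
                if 0 <= r < self.grid_shape[0] and 0 <= c < self.grid_shape[1]:
                    out.append((r, c))
        return out

    def xy_mm(self, channel_id: str) -> tuple[float, float]:
        """Physical (x, y) position in mm: x along columns, y along rows."""
        r, c = self.site_of(channel_id)
        return c * self.spacing_mm, r * self.spacing_mm


MARK_AUTO = "auto"
MARK_MANUAL = "manual"


@dataclass(frozen=True)
class Mark:
    """A single activation-time mark on one channel."""

    time_s: float
    source: str = MARK_AUTO
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.source not in (MARK_AUTO, MARK_MANUAL):
            raise SlowWaveError(f"mark source must be auto/manual, got {self.source!r}")
        if self.score < 0:
            raise SlowWaveError("detection score must be >= 0")


@dataclass
class EventMarks:
    """Per-channel sorted activation-time marks."""

    by_channel: dict[str, list[Mark]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, marks in self.by_channel.items():
            marks.sort(key=lambda m: m.time_s)
            times = [m.time_s for m in marks]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise SlowWaveError(f"marks on channel {ch!r} must be strictly increasing")

    def channels(self) -> list[str]:
        return sorted(self.by_channel)

    def times(self, channel_id: str) -> list[float]:
        return [m.time_s for m in self.by_channel.get(str(channel_id), [])]

    def n_marks(self) -> int:
        return sum(len(v) for v in self.by_channel.values())

    def iter_marks(self) -> Iterator[tuple[str, Mark]]:
        for ch in sorted(self.by_channel):
            for m in self.by_channel[ch]:
                yield ch, m

    def validate(self, refractory_s: float = 0.0, span_s: float | None = None) -> None:
        for ch, marks in self.by_channel.items():
            times = [m.time_s for m in marks]
            for t1, t2 in zip(times, times[1:]):
                if t2 - t1 < refractory_s:
                    raise SlowWaveError(
                        f"marks {t1:.3f}s and {t2:.3f}s on channel {ch!r} violate "
                        f"refractory spacing {refractory_s}s"
                    )
            if span_s is not None and times and (times[0] < 0 or times[-1] > span_s):
                raise SlowWaveError(f"marks on channel {ch!r} fall outside the recording span")

    def copy(self) -> "EventMarks":
        return EventMarks({ch: list(ms) for ch, ms in self.by_channel.items()})


ORPHAN = -1  # internal sentinel for unassigned marks

MarkKey = tuple[str, float]  # (channel_id, time_s) uniquely identifies a mark


@dataclass
class CycleAssignment:
    """Partition of marks into wavefront cycles plus an orphan pool.

    Cycles are stored 0-based internally; user-facing numbering is 1-based
    and strictly ordered by the mean activation time of cycle members.
    """

    cycles: list[dict[str, float]] = field(default_factory=list)
    orphans: set[MarkKey] = field(default_factory=set)

    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle_members(self, k: int) -> dict[str, float]:
        """Members of 1-based cycle ``k`` as ``channel -> time_s``."""
        if not (1 <= k <= len(self.cycles)):
            raise SlowWaveError(f"cycle {k} out of range 1..{len(self.cycles)}")
        return dict(self.cycles[k - 1])

    def cycle_of(self, channel_id: str, time_s: float) -> int:
        """1-based cycle index of a mark, or 0 if orphaned."""
        for i, members in enumerate(self.cycles):
            if members.get(str(channel_id)) == time_s:
                return i + 1
        if (str(channel_id), time_s) in self.orphans:
            return 0
        raise SlowWaveError(f"mark ({channel_id!r}, {time_s}) not in assignment")

    def total_assigned(self) -> int:
        return sum(len(c) for c in self.cycles) + len(self.orphans)

    def renumber(self) -> None:
        """Re-order cycles by mean member activation time (stable)."""
        self.cycles.sort(key=lambda m: (float(np.mean(list(m.values()))), min(m)))

    def check_conservation(self, marks: EventMarks) -> None:
        n = marks.n_marks()
        if self.total_assigned() != n:
            raise SlowWaveError(
                f"assignment covers {self.total_assigned()} marks but {n} exist"
            )
        seen: set[MarkKey] = set()
        for members in self.cycles:
            for ch, t in members.items():
                key = (ch, t)
                if key in seen or key in self.orphans:
                    raise SlowWaveError(f"mark {key} assigned more than once")
                seen.add(key)

    def copy(self) -> "CycleAssignment":
        return CycleAssignment(
            cycles=[dict(c) for c in self.cycles], orphans=set(self.orphans)
        )
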