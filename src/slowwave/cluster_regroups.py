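"""Region-growing cycle clustering with polynomial surface stabilization.

Individual activation marks are grouped into per-cycle wavefronts: starting
from a well-supported seed mark, the wavefront grows across 8-connected
electrode neighbours, accepting on each frontier channel the unassigned
mark closest to a predicted activation time.  While the group is small the
prediction is the mean of already-assigned neighbour times; once at least
six members exist a full second-order surface

    T(x, y) = a0 + a1 x + a2 y + a3 x^2 + a4 x y + a5 y^2

is fit by least squares (x/y in electrode-index units, T in seconds) and
used as the predictor.  The surface is refit on a fixed cadence and members
whose residuals blow out are ejected back into the pool, which stabilizes
growth against wrong early acceptances.  Marks never absorbed into any
cycle end up in the orphan pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    CycleAssignment,
    ElectrodeLayout,
    EventMarks,
    SlowWaveError,
)
from .params import ParameterSet


@dataclass
class PolySurface:
    """Second-order activation-time surface T(x, y)."""

    coeffs: np.ndarray   # (a0..a5)
    residual_rms: float

    def evaluate(self, x: float, y: float) -> float:
        a = self.coeffs
        return float(a[0] + a[1] * x + a[2] * y + a[3] * x * x + a[4] * x * y + a[5] * y * y)


def _design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_activation_surface(points: list[tuple[float, float, float]]) -> PolySurface:
    """Least-squares quadratic surface through (x, y, t) points.

    Requires at least 6 points in a full-rank quadratic configuration;
    degenerate configurations (e.g. collinear sites) raise an error and the
    caller falls back to neighbour-mean prediction.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 6:
        raise SlowWaveError("surface fit needs at least 6 (x, y, t) points")
    A = _design(pts[:, 0], pts[:, 1])
    if np.linalg.matrix_rank(A) < 6:
        raise SlowWaveError("degenerate configuration: quadratic design is rank deficient")
    coeffs, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    resid = A @ coeffs - pts[:, 2]
    return PolySurface(coeffs=coeffs, residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def _chan_sort_key(ch: str):
    try:
        return (0, int(ch), ch)
    except ValueError:
        return (1, 0, ch)


class _Pool:
    """Mutable pool of unassigned marks, per channel, sorted by time."""

    def __init__(self, marks: EventMarks):
        self.by_channel: dict[str, list[float]] = {
            ch: [m.time_s for m in ms] for ch, ms in marks.by_channel.items() if ms
        }

    def channels(self) -> list[str]:
        return sorted(self.by_channel, key=_chan_sort_key)

    def earliest(self, ch: str) -> float:
        return self.by_channel[ch][0]

    def nearest(self, ch: str, t_pred: float, banned: set) -> float | None:
        best, best_d = None, None
        for t in self.by_channel.get(ch, ()):
            if (ch, t) in banned:
                continue
            d = abs(t - t_pred)
            if best_d is None or d < best_d:
                best, best_d = t, d
        return best

    def any_within(self, ch: str, t: float, dt: float) -> bool:
        return any(abs(x - t) <= dt for x in self.by_channel.get(ch, ()))

    def remove(self, ch: str, t: float) -> None:
        self.by_channel[ch].remove(t)
        if not self.by_channel[ch]:
            del self.by_channel[ch]

    def add(self, ch: str, t: float) -> None:
        self.by_channel.setdefault(ch, []).append(t)
        self.by_channel[ch].sort()

    def empty(self) -> bool:
        return not self.by_channel


def _select_seed(pool: _Pool, layout: ElectrodeLayout, dt_seed: float) -> tuple[str, float]:
    """Earliest unassigned mark on the best-supported channel.

    Support is the number of 8-connected neighbour sites whose channel holds
    an unassigned mark within ``dt_seed`` of the candidate's earliest mark.
    Ties go to the smallest channel id.
    """
    site_to_ch = layout.site_to_channel()
    best_ch, best_support = None, -1
    for ch in pool.channels():
        if ch not in layout.placement:
            continue
        t = pool.earliest(ch)
        r, c = layout.site_of(ch)
        support = 0
        for rr, cc in layout.neighbors8(r, c):
            nch = site_to_ch.get((rr, cc))
            if nch is not None and pool.any_within(nch, t, dt_seed):
                support += 1
        if support > best_support:
            best_ch, best_support = ch, support
    if best_ch is None:
        # marks exist only on channels absent from the layout
        ch = pool.channels()[0]
        return ch, pool.earliest(ch)
    return best_ch, pool.earliest(best_ch)


def regroups_cluster(
    marks: EventMarks,
    layout: ElectrodeLayout,
    params: ParameterSet | None = None,
) -> CycleAssignment:
    """Partition marks into wavefront cycles; leftovers become orphans.

    Deterministic; terminates because each mark can enter a given cycle
    attempt at most once.  Cycles are finally renumbered by mean member
    activation time (1-based in user-facing output).
    """
    if marks.n_marks() == 0:
        raise SlowWaveError("no marks to cluster")
    params = params or ParameterSet()
    tau = params.regroups_tau_s
    pool = _Pool(marks)
    site_to_ch = layout.site_to_channel()

    # marks on channels missing from the layout can never be grown over
    off_layout: set[tuple[str, float]] = set()
    for ch in list(pool.by_channel):
        if ch not in layout.placement:
            for t in pool.by_channel[ch]:
                off_layout.add((ch, t))
            del pool.by_channel[ch]

    cycles: list[dict[str, float]] = []
    orphans: set[tuple[str, float]] = set(off_layout)

    while not pool.empty():
        seed_ch, seed_t = _select_seed(pool, layout, params.regroups_seed_window_s)
        pool.remove(seed_ch, seed_t)
        members: dict[str, float] = {seed_ch: seed_t}
        member_sites: dict[tuple[int, int], str] = {layout.site_of(seed_ch): seed_ch}
        banned: set[tuple[str, float]] = set()   # ejected from this cycle attempt
        surface: PolySurface | None = None
        n_since_fit = 0

        def predict(site: tuple[int, int]) -> float | None:
            if surface is not None and len(members) >= 6:
                return surface.evaluate(x=site[1], y=site[0])
            vals = [
                members[member_sites[(rr, cc)]]
                for rr, cc in layout.neighbors8(*site)
                if (rr, cc) in member_sites
            ]
            return float(np.mean(vals)) if vals else None

        def refit() -> None:
            nonlocal surface
            pts = [
                (float(c), float(r), members[ch])
                for ch, (r, c) in ((ch, layout.site_of(ch)) for ch in members)
            ]
            try:
                surface = fit_activation_surface(pts)
            except SlowWaveError:
                surface = None   # degenerate: fall back to neighbour-mean prediction

        while True:
            # frontier: sites 8-adjacent to the group whose channel still has marks
            frontier: set[tuple[int, int]] = set()
            for site in member_sites:
                for nb in layout.neighbors8(*site):
                    if nb in member_sites:
                        continue
                    nch = site_to_ch.get(nb)
                    if nch is not None and nch not in members and nch in pool.by_channel:
                        frontier.add(nb)
            best = None   # (deviation, chan_key, site, ch, t)
            for site in sorted(frontier):
                nch = site_to_ch[site]
                t_pred = predict(site)
                if t_pred is None:
                    continue
                t_cand = pool.nearest(nch, t_pred, banned)
                if t_cand is None:
                    continue
                dev = abs(t_cand - t_pred)
                if dev <= tau:
                    key = (dev, _chan_sort_key(nch), site)
                    if best is None or key < best[0]:
                        best = (key, site, nch, t_cand)
            if best is None:
                break
            _, site, nch, t_cand = best
            pool.remove(nch, t_cand)
            members[nch] = t_cand
            member_sites[site] = nch
            n_since_fit += 1
            if len(members) >= 6 and (surface is None or n_since_fit >= params.regroups_refit_every):
                refit()
                n_since_fit = 0
                if surface is not None:
                    tau_resid = max(tau, params.regroups_resid_mult * surface.residual_rms)
                    ejected = []
                    for ch, t in members.items():
                        if ch == seed_ch:
                            continue
                        r, c = layout.site_of(ch)
                        if abs(surface.evaluate(c, r) - t) > tau_resid:
                            ejected.append((ch, t))
                    for ch, t in ejected:
                        del members[ch]
                        del member_sites[layout.site_of(ch)]
                        banned.add((ch, t))
                        pool.add(ch, t)
                    if ejected and len(members) >= 6:
                        refit()

        if len(members) >= max(1, params.regroups_min_cycle_size):
            cycles.append(members)
        else:
            for ch, t in members.items():
                orphans.add((ch, t))

    assignment = CycleAssignment(cycles=cycles, orphans=orphans)
    assignment.renumber()
    assignment.check_conservation(marks)
    return assignment


def edit_cluster(
    assignment: CycleAssignment,
    mark: tuple[str, float],
    target,
) -> CycleAssignment:
    """Move one mark to a cycle, the orphan pool, or a new cycle.

    ``target`` is a 1-based cycle index, ``"orphan"``, or ``"new_cycle"``.
    Moving onto a channel already occupied in the target cycle raises an
    error naming the displaced mark.  Cycles are renumbered afterwards.
    """
    ch, t = str(mark[0]), float(mark[1])
    out = assignment.copy()
    src = out.cycle_of(ch, t)   # validates existence
    if src == 0:
        out.orphans.discard((ch, t))
    else:
        del out.cycles[src - 1][ch]
    if target == "orphan":
        out.orphans.add((ch, t))
    elif target == "new_cycle":
        out.cycles.append({ch: t})
    else:
        k = int(target)
        if not (1 <= k <= len(out.cycles)):
            raise SlowWaveError(f"target cycle {k} does not exist")
        members = out.cycles[k - 1]
        if ch in members:
            raise SlowWaveError(
                f"channel {ch!r} already holds mark at {members[ch]}s in cycle {k}"
            )
        members[ch] = t
    out.cycles = [c for c in out.cycles if c]
    out.renumber()
    return out
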