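"""Readers, writers and text exports.

Supported on-disk forms:

* BioSemi BDF recordings (see :mod:`slowwave.bdf`), re-exported here.
* Plain delimited text signal matrices (channels as rows or columns).
* Electrode layout files: JSON with an explicit schema version.
* Parameter files: JSON (see :mod:`slowwave.params`).
* Analysis sessions: a single versioned zip archive holding the filtered
  recording plus marks, clustering, layout, parameters and provenance.
* Tab-delimited text exports of marks and map values for statistics; by
  convention interpolated values are excluded from statistical exports.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bdf import read_bdf, write_bdf  # noqa: F401  (re-exported)
from .core import (
    CycleAssignment,
    ElectrodeLayout,
    EventMarks,
    Mark,
    Recording,
    SlowWaveError,
)
from .params import ParameterSet
from .spatial_metrics import (
    INTERPOLATED,
    MEASURED,
    ActivationMap,
    AmplitudeMap,
    IntervalMap,
    VelocityField,
)

LAYOUT_SCHEMA_VERSION = 1
SESSION_SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# delimited text signals
# --------------------------------------------------------------------------

def read_text_signals(
    path: str | Path,
    fs: float,
    delimiter: str | None = None,
    channels_as_rows: bool = True,
    header: bool = False,
) -> Recording:
    """Read a rectangular delimited numeric table as a recording.

    ``delimiter=None`` splits on any whitespace.  With ``header=True`` the
    first line provides channel labels.  Non-numeric cells and ragged rows
    raise errors naming the offending position.
    """
    if fs <= 0:
        raise SlowWaveError(f"sampling rate must be positive, got {fs}")
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise SlowWaveError(f"{path}: empty signal file")
    labels: list[str] | None = None
    if header:
        labels = lines[0].split(delimiter)
        lines = lines[1:]
        if not lines:
            raise SlowWaveError(f"{path}: header but no data rows")
    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        cells = ln.split(delimiter)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise SlowWaveError(
                f"{path}: ragged table — row {i + 1} has {len(cells)} cells, expected {width}"
            )
        row = []
        for j, cell in enumerate(cells):
            try:
                row.append(float(cell))
            except ValueError:
                raise SlowWaveError(
                    f"{path}: non-numeric cell {cell!r} at row {i + 1}, column {j + 1}"
                ) from None
        rows.append(row)
    mat = np.asarray(rows)
    if not channels_as_rows:
        mat = mat.T
    if labels is not None:
        if not channels_as_rows and len(labels) != mat.shape[0]:
            raise SlowWaveError(f"{path}: {len(labels)} header labels for {mat.shape[0]} channels")
        if channels_as_rows:
            # header labels only make sense for channels-as-columns tables
            raise SlowWaveError(f"{path}: header labels require channels_as_columns orientation")
        ids = [str(x) for x in labels]
    else:
        ids = [str(i) for i in range(mat.shape[0])]
    return Recording(samples=mat, fs=fs, channel_ids=ids)


def write_text_signals(recording: Recording, path: str | Path, delimiter: str = "\t") -> None:
    """Write the signal matrix channels-as-rows, full float precision."""
    with open(path, "w") as f:
        for row in recording.samples:
            f.write(delimiter.join(repr(float(v)) for v in row) + "\n")


# --------------------------------------------------------------------------
# electrode layouts
# --------------------------------------------------------------------------

def save_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    d = {
        "schema_version": LAYOUT_SCHEMA_VERSION,
        "grid_shape": list(layout.grid_shape),
        "spacing_mm": layout.spacing_mm,
        "orientation_deg": layout.orientation_deg,
        "placement": {ch: list(site) for ch, site in sorted(layout.placement.items())},
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_layout(path_or_spec) -> ElectrodeLayout:
    """Load a layout file, or build one from a template spec.

    A template spec is a mapping with keys ``n_rows``, ``n_cols``,
    ``spacing_mm`` and optional ``order`` ("row-major"/"col-major"), filling
    the grid with sequential channel ids starting at 0.
    """
    if isinstance(path_or_spec, dict):
        spec = dict(path_or_spec)
        return ElectrodeLayout.from_template(
            n_rows=int(spec.pop("n_rows")),
            n_cols=int(spec.pop("n_cols")),
            spacing_mm=float(spec.pop("spacing_mm")),
            order=spec.pop("order", "row-major"),
            channel_prefix=spec.pop("channel_prefix", ""),
            start=int(spec.pop("start", 0)),
        )
    path = Path(path_or_spec)
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SlowWaveError(f"layout file {path} is not valid JSON: {e}") from None
    if d.get("schema_version") != LAYOUT_SCHEMA_VERSION:
        raise SlowWaveError(
            f"layout file {path}: schema version {d.get('schema_version')} "
            f"!= supported {LAYOUT_SCHEMA_VERSION}"
        )
    return ElectrodeLayout(
        grid_shape=tuple(d["grid_shape"]),
        placement={ch: tuple(site) for ch, site in d["placement"].items()},
        spacing_mm=float(d["spacing_mm"]),
        orientation_deg=float(d.get("orientation_deg", 0.0)),
    )


# --------------------------------------------------------------------------
# analysis sessions
# --------------------------------------------------------------------------

@dataclass
class AnalysisSession:
    """Everything needed to reproduce downstream outputs after reload."""

    recording: Recording                     # filtered signals
    layout: ElectrodeLayout
    params: ParameterSet
    marks: EventMarks | None = None
    assignment: CycleAssignment | None = None
    products: dict = field(default_factory=dict)  # cached maps, not serialized
    provenance: dict = field(default_factory=dict)

    def require(self, what: str):
        stage = {"marks": "detect", "assignment": "cluster"}.get(what, what)
        val = getattr(self, what, None)
        if val is None:
            raise SlowWaveError(f"session has no {what}; run the {stage} stage first")
        return val


def _marks_to_json(marks: EventMarks) -> dict:
    return {
        ch: [{"t": m.time_s, "source": m.source, "score": m.score} for m in ms]
        for ch, ms in sorted(marks.by_channel.items())
    }


def _marks_from_json(d: dict) -> EventMarks:
    return EventMarks({
        ch: [Mark(time_s=m["t"], source=m["source"], score=m["score"]) for m in ms]
        for ch, ms in d.items()
    })


def _assignment_to_json(a: CycleAssignment) -> dict:
    return {
        "cycles": [sorted(((ch, t) for ch, t in c.items())) for c in a.cycles],
        "orphans": sorted([list(k) for k in a.orphans]),
    }


def _assignment_from_json(d: dict) -> CycleAssignment:
    return CycleAssignment(
        cycles=[{ch: t for ch, t in c} for c in d["cycles"]],
        orphans={(ch, t) for ch, t in d["orphans"]},
    )


def save_session(session: AnalysisSession, path: str | Path) -> None:
    """Save a session as a single versioned zip archive."""
    rec = session.recording
    meta = {
        "schema_version": SESSION_SCHEMA_VERSION,
        "tool_version": __version__,
        "provenance": session.provenance,
        "recording": {
            "fs": rec.fs,
            "t0": rec.t0,
            "channel_ids": rec.channel_ids,
            "channel_status": rec.channel_status,
        },
        "layout": {
            "grid_shape": list(session.layout.grid_shape),
            "spacing_mm": session.layout.spacing_mm,
            "orientation_deg": session.layout.orientation_deg,
            "placement": {ch: list(s) for ch, s in sorted(session.layout.placement.items())},
        },
        "params": session.params.to_dict(),
        "marks": _marks_to_json(session.marks) if session.marks is not None else None,
        "assignment": (
            _assignment_to_json(session.assignment) if session.assignment is not None else None
        ),
    }
    buf = io.BytesIO()
    np.save(buf, rec.samples)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as z:
        z.writestr("session.json", json.dumps(meta, indent=2, sort_keys=True))
        z.writestr("samples.npy", buf.getvalue())


def load_session(path: str | Path) -> AnalysisSession:
    try:
        with zipfile.ZipFile(path) as z:
            meta = json.loads(z.read("session.json"))
            samples = np.load(io.BytesIO(z.read("samples.npy")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as e:
        raise SlowWaveError(f"session file {path} is corrupted: {e}") from None
    ver = meta.get("schema_version")
    if ver != SESSION_SCHEMA_VERSION:
        raise SlowWaveError(
            f"session file {path}: schema version {ver} != supported {SESSION_SCHEMA_VERSION}"
        )
    r = meta["recording"]
    recording = Recording(
        samples=samples,
        fs=r["fs"],
        channel_ids=r["channel_ids"],
        t0=r["t0"],
        channel_status=r["channel_status"],
    )
    lay = meta["layout"]
    layout = ElectrodeLayout(
        grid_shape=tuple(lay["grid_shape"]),
        placement={ch: tuple(s) for ch, s in lay["placement"].items()},
        spacing_mm=lay["spacing_mm"],
        orientation_deg=lay["orientation_deg"],
    )
    return AnalysisSession(
        recording=recording,
        layout=layout,
        params=ParameterSet.from_dict(meta["params"]),
        marks=_marks_from_json(meta["marks"]) if meta["marks"] is not None else None,
        assignment=(
            _assignment_from_json(meta["assignment"]) if meta["assignment"] is not None else None
        ),
        provenance=meta.get("provenance", {}),
    )


# --------------------------------------------------------------------------
# text exports
# --------------------------------------------------------------------------

def _site_rows(layout: ElectrodeLayout):
    site_to_ch = layout.site_to_channel()
    rows, cols = layout.grid_shape
    for r in range(rows):
        for c in range(cols):
            yield r, c, site_to_ch.get((r, c), "")


def export_text(
    session: AnalysisSession,
    what: str,
    path: str | Path,
    include_interpolated: bool = False,
) -> None:
    """Tab-delimited export of one analysis product.

    ``what`` is one of ``marks``, ``activation``, ``amplitude``,
    ``velocity``, ``intervals``.  Map products must already be cached in
    ``session.products`` (the pipeline does this); a missing product raises
    an error naming the stage to run.  Interpolated activation values are
    excluded unless ``include_interpolated`` is set, in which case a flag
    column distinguishes them.
    """
    lines: list[str] = []
    if what == "marks":
        marks = session.require("marks")
        assignment = session.assignment
        lines.append("channel_id\trow\tcol\ttime_s\tcycle\tsource")
        for ch, m in marks.iter_marks():
            r, c = session.layout.site_of(ch)
            cyc = ""
            if assignment is not None:
                k = assignment.cycle_of(ch, m.time_s)
                cyc = "orphan" if k == 0 else str(k)
            lines.append(f"{ch}\t{r}\t{c}\t{m.time_s!r}\t{cyc}\t{m.source}")
    elif what == "activation":
        maps: list[ActivationMap] = session.products.get("activation_maps") or _absent("maps")
        header = "cycle\trow\tcol\tchannel_id\ttime_s"
        lines.append(header + "\tflag" if include_interpolated else header)
        for am in maps:
            for r, c, ch in _site_rows(session.layout):
                flag = am.flags[r, c]
                if flag == MEASURED or (include_interpolated and flag == INTERPOLATED):
                    row = f"{am.cycle}\t{r}\t{c}\t{ch}\t{float(am.times[r, c])!r}"
                    if include_interpolated:
                        row += "\t" + ("measured" if flag == MEASURED else "interpolated")
                    lines.append(row)
    elif what == "amplitude":
        maps: list[AmplitudeMap] = session.products.get("amplitude_maps") or _absent("maps")
        lines.append("cycle\trow\tcol\tchannel_id\tamplitude_uv\tconfidence")
        for am in maps:
            for r, c, ch in _site_rows(session.layout):
                if np.isfinite(am.amplitude[r, c]):
                    lines.append(
                        f"{am.cycle}\t{r}\t{c}\t{ch}\t{float(am.amplitude[r, c])!r}\t{am.confidence[r, c]}"
                    )
    elif what == "velocity":
        fields: list[VelocityField] = session.products.get("velocity_fields") or _absent("maps")
        act: list[ActivationMap] = session.products.get("activation_maps") or []
        flags_by_cycle = {a.cycle: a.flags for a in act}
        lines.append("cycle\trow\tcol\tchannel_id\tvx_mm_s\tvy_mm_s\tspeed_mm_s")
        for vf in fields:
            flags = flags_by_cycle.get(vf.cycle)
            for r, c, ch in _site_rows(session.layout):
                if not vf.defined[r, c]:
                    continue
                # statistical exports carry measured sites only
                if flags is not None and flags[r, c] != MEASURED and not include_interpolated:
                    continue
                lines.append(
                    f"{vf.cycle}\t{r}\t{c}\t{ch}\t{float(vf.vx[r, c])!r}\t"
                    f"{float(vf.vy[r, c])!r}\t{float(vf.speed[r, c])!r}"
                )
    elif what == "intervals":
        maps: list[IntervalMap] = session.products.get("interval_maps") or _absent("maps")
        lines.append("cycle_from\tcycle_to\trow\tcol\tchannel_id\tinterval_s\tfreq_cpm\tclass")
        for im in maps:
            for r, c, ch in _site_rows(session.layout):
                if np.isfinite(im.intervals[r, c]):
                    lines.append(
                        f"{im.pair[0]}\t{im.pair[1]}\t{r}\t{c}\t{ch}\t"
                        f"{float(im.intervals[r, c])!r}\t{float(im.freq_cpm[r, c])!r}\t{im.classes[r, c]}"
                    )
    else:
        raise SlowWaveError(f"unknown export product {what!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _absent(stage: str):
    raise SlowWaveError(f"requested product not computed; run the {stage} stage first")


def parse_marks_export(path: str | Path) -> EventMarks:
    """Re-parse a marks export (round-trip of :func:`export_text`)."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("channel_id"):
        raise SlowWaveError(f"{path}: not a marks export")
    by_channel: dict[str, list[Mark]] = {}
    for ln in lines[1:]:
        ch, _r, _c, t, _cyc, source = ln.split("\t")
        by_channel.setdefault(ch, []).append(Mark(time_s=float(t), source=source))
    return EventMarks(by_channel)
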