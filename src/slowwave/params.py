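"""Central parameter registry.

Every tunable in the pipeline lives here with a documented default suited to
typical gastric serosal recordings (slow waves at ~3 cycles/min, biphasic
deflections of a few hundred microvolts).  Unknown keys are rejected on load
so that typos in a parameter file fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

from .core import SlowWaveError

PARAMS_SCHEMA_VERSION = 1


@dataclass
class ParameterSet:
    # --- pre-processing -------------------------------------------------
    #: baseline-removal method: "moving_median_subtract" or "highpass"
    baseline_method: str = "moving_median_subtract"
    #: moving-median baseline window (s); >= 5x the slow-wave period advised
    baseline_window_s: float = 20.0
    #: high-pass cutoff (Hz) when baseline_method == "highpass"
    baseline_cutoff_hz: float = 0.01
    #: smoothing filter applied after baseline removal
    smooth_filter: str = "savitzky_golay"  # or moving_median / butterworth / wavelet / none
    smooth_window_s: float = 1.0
    smooth_poly_order: int = 2

    # --- FEVT event detection ------------------------------------------
    #: span (s) of the centred finite difference in the falling-edge
    #: transform; 0 means a one-sample centred difference
    fevt_edge_len_s: float = 0.0
    #: exponent applied to the rectified negative derivative
    fevt_power: float = 2.0
    #: moving-average smoothing of the detection signal (s); sized to span
    #: the full falling edge of a gastric deflection so the detection
    #: signal integrates the whole edge energy rather than single spikes
    fevt_smooth_s: float = 1.0
    #: threshold multiplier eta on the running median of the detection signal
    fevt_eta: float = 5.0
    #: running-median window (s) for the time-varying threshold
    fevt_threshold_window_s: float = 15.0
    #: refractory period (s): supra-threshold runs closer than this merge
    fevt_refractory_s: float = 2.0
    #: within a multiphasic run, earliest descent peak with detection signal
    #: above this fraction of the run maximum is marked
    fevt_first_deflection_frac: float = 0.5
    #: minimum separation (s) between descent peaks treated as distinct
    fevt_deflection_sep_s: float = 0.5
    #: snap window (s) for manual mark placement
    mark_snap_window_s: float = 0.5

    # --- REGROUPS clustering -------------------------------------------
    #: seed support window (s): neighbour marks within this of a candidate
    #: seed count toward its support
    regroups_seed_window_s: float = 10.0
    #: acceptance tolerance (s) between a mark and its predicted time
    regroups_tau_s: float = 3.0
    #: residual ejection threshold = max(tau, this multiple of the fit RMS)
    regroups_resid_mult: float = 2.0
    #: surface refit cadence (acceptances per refit)
    regroups_refit_every: int = 5
    #: cycles smaller than this are dissolved into orphans
    regroups_min_cycle_size: int = 1

    # --- spatial maps ---------------------------------------------------
    #: SIV stage-1 threshold: measured 8-neighbours needed to interpolate
    siv_k1: int = 5
    #: SIV stage-2 threshold, counting measured plus stage-1 sites
    siv_k2: int = 3
    #: Gaussian smoothing of the activation-time gradient (electrode units)
    velocity_sigma_sites: float = 1.0
    #: gradient magnitudes below this (s/mm) give undefined velocity
    velocity_min_grad_s_per_mm: float = 1e-3
    #: whether velocity is also computed on SIV-interpolated sites
    velocity_on_interpolated: bool = True
    #: signal window for amplitude estimation (s)
    amplitude_window_s: float = 1.5
    #: Savitzky-Golay derivative smoothing inside the amplitude window (s)
    amplitude_smooth_s: float = 0.25
    #: bradygastria / tachygastria frequency bounds (cycles/min)
    interval_bounds_cpm: tuple[float, float] = (2.0, 4.0)

    # --- visualization --------------------------------------------------
    isochrone_interval_s: float = 2.0
    show_grid: bool = True
    interpolate_contours: bool = True
    animation_fps: float = 10.0
    animation_tail_s: float = 2.0

    def to_dict(self) -> dict[str, Any]:
        d = {"schema_version": PARAMS_SCHEMA_VERSION}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = list(v) if isinstance(v, tuple) else v
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ParameterSet":
        d = dict(d)
        d.pop("schema_version", None)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SlowWaveError(f"unknown parameter keys: {sorted(unknown)}")
        if "interval_bounds_cpm" in d:
            d["interval_bounds_cpm"] = tuple(d["interval_bounds_cpm"])
        return cls(**d)

    def replace(self, **kwargs: Any) -> "ParameterSet":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise SlowWaveError(f"unknown parameter keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        try:
            d = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise SlowWaveError(f"parameter file {path} is not valid JSON: {e}") from None
        if not isinstance(d, dict):
            raise SlowWaveError(f"parameter file {path} must hold a JSON object")
        return cls.from_dict(d)
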