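"""Shared fixtures: small synthetic scenarios with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from slowwave.core import ElectrodeLayout
from slowwave.params import ParameterSet
from slowwave.synthgen import Noise, SyntheticScenario, generate_recording


@pytest.fixture(scope="session")
def layout8() -> ElectrodeLayout:
    return ElectrodeLayout.from_template(8, 8, 4.0)


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def clean_planar():
    """Noise-free planar scenario: 8x8 grid, 10 cycles at 3 cycles/min."""
    scn = SyntheticScenario(pattern="planar", duration_s=220.0, seed=0)
    rec, truth = generate_recording(scn)
    return scn, rec, truth


@pytest.fixture(scope="session")
def clean_radial():
    scn = SyntheticScenario(pattern="radial", origin_site=(3, 3), duration_s=220.0, seed=0)
    rec, truth = generate_recording(scn)
    return scn, rec, truth


@pytest.fixture(scope="session")
def clean_retrograde():
    scn = SyntheticScenario(pattern="retrograde", duration_s=220.0, seed=0)
    rec, truth = generate_recording(scn)
    return scn, rec, truth


def marks_from_truth(truth, source="auto"):
    """Build an EventMarks object directly from generator ground truth."""
    from slowwave.core import EventMarks, Mark

    return EventMarks({
        ch: [Mark(time_s=float(t)) for t in times]
        for ch, times in truth.arrivals.items()
        if len(times)
    })
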