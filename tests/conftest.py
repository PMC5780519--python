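import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dsfsim import (
    DyeModel,
    PlateLayout,
    UnfoldingModel,
    WellAssignment,
    build_schedule,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_schedule():
    return build_schedule()


@pytest.fixture
def fine_grid():
    """1 °C pad-scale grid, as on an RT-PCR reference run."""
    return np.arange(25.0, 96.0, 1.0)


def make_layout(conditions, tms, blanks=True, dye=None, rows="ABCDEFGH"):
    """Triplicate layout helper: one plate row per condition (+ col-4 blank)."""
    dye = dye or DyeModel.sypro()
    wells = {}
    for row, cond, tm in zip(rows, conditions, tms):
        model = tm if isinstance(tm, UnfoldingModel) else UnfoldingModel.single(tm)
        for col in (1, 2, 3):
            wells[f"{row}{col}"] = WellAssignment(cond, cond, False, dye, model)
        if blanks:
            wells[f"{row}4"] = WellAssignment(cond, f"{cond} blank", True, dye, None)
    return PlateLayout(wells)


@pytest.fixture
def layout_factory():
    return make_layout
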