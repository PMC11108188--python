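import numpy as np
import pandas as pd
import pytest

from pbranova.io_design import ExperimentDesign, Period, RawSeriesTable
from pbranova.smoothing import CurveSet


@pytest.fixture
def toy_constant_curves() -> CurveSet:
    """Two balanced groups of constant curves {0, 2} and {1, 3}.

    Small enough that every functional ANOVA quantity can be computed by
    hand: mu = 1.5, alpha = (-0.5, +0.5), SSA = 1, SSE = 4, F = 0.5.
    """
    grid = np.array([0.0, 1.0, 2.0])
    values = np.array([[0.0] * 3, [2.0] * 3, [1.0] * 3, [3.0] * 3])
    groups = np.array(["A", "A", "B", "B"])
    return CurveSet(grid=grid, values=values, groups=groups)


@pytest.fixture
def small_table() -> RawSeriesTable:
    """Two groups x two subjects on a 4-point grid."""
    rows = []
    rng = np.random.default_rng(7)
    for gi, g in enumerate(["ctrl", "dose"]):
        for j in range(2):
            for t in range(1, 5):
                rows.append(
                    {"subject": f"{g}{j}", "group": g, "time": float(t),
                     "value": float(10 * gi + j + 0.1 * t + rng.normal(0, 0.01))}
                )
    return RawSeriesTable(pd.DataFrame(rows))


@pytest.fixture
def assay_design() -> ExperimentDesign:
    """The real assay layout: 10-min dark acclimation then L1 D1 L2 D2."""
    return ExperimentDesign(
        domain=(0.0, 50.0),
        acclimation=(0.0, 10.0),
        periods=[
            Period(10, 20, "light"),
            Period(20, 30, "dark"),
            Period(30, 40, "light"),
            Period(40, 50, "dark"),
        ],
    )
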