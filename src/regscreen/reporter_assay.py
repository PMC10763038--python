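"""Catechol 2,3-dioxygenase (XylE) reporter activity from A375 time series.

XylE converts catechol to the yellow 2-hydroxymuconate semialdehyde, which
absorbs at 375 nm; promoter activity is read out as the rate of absorbance
increase per minute, normalized by the protein mass of the cell extract.
Activity is the ordinary-least-squares slope of A375 against time divided
by protein mass, in ΔA375·min⁻¹·mg⁻¹, so it is invariant to any constant
absorbance baseline and scales inversely with the mass loaded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass
class ReporterSeries:
    """One strain's reporter time course."""

    strain: str
    time_min: Sequence[float]
    a375: Sequence[float]
    protein_mg: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.a375, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and absorbance arrays differ in length")
        if len(t) < 3:
            raise ValueError("need at least 3 time points for a rate estimate")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time points must be strictly increasing")
        if self.protein_mg <= 0:
            raise ValueError("protein mass must be positive")


@dataclass(frozen=True)
class ActivityResult:
    strain: str
    activity: float  # ΔA375 · min⁻¹ · mg⁻¹
    fit_r2: float


def xylE_activity(
    series: ReporterSeries, window: tuple[float, float] | None = None
) -> ActivityResult:
    """Enzyme activity as OLS slope of A375 vs time over protein mass.

    ``window=(t0, t1)`` restricts the fit to time points in that closed
    interval (no automatic linear-phase detection is attempted).  A negative
    fitted slope is reported with a warning, not clamped — it signals assay
    failure rather than enzyme activity.
    """
    t = np.asarray(series.time_min, dtype=float)
    y = np.asarray(series.a375, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 3:
            raise ValueError("fit window leaves fewer than 3 points")
        t, y = t[mask], y[mask]
    if np.allclose(y, y[0]):
        # flat trace: slope 0 fits with zero residual
        return ActivityResult(strain=series.strain, activity=0.0, fit_r2=1.0)
    fit = stats.linregress(t, y)
    activity = float(fit.slope) / series.protein_mg
    if activity < 0:
        warnings.warn(
            f"strain {series.strain!r}: negative fitted slope "
            f"({fit.slope:.4g}/min); the assay likely failed"
        )
    return ActivityResult(
        strain=series.strain, activity=activity, fit_r2=float(fit.rvalue**2)
    )


@dataclass(frozen=True)
class ActivityFold:
    """Test-vs-control activity ratio with a direction label."""

    ratio: float  # test / control
    direction: str  # "increase" | "decrease" | "unchanged"

    @property
    def factor(self) -> float:
        """Magnitude of the change (e.g. a 19-fold decrease has factor 19)."""
        return self.ratio if self.ratio >= 1 else 1.0 / self.ratio


def activity_fold(test: ActivityResult, control: ActivityResult) -> ActivityFold:
    """Ratio of test to control activity, labelled increase/decrease."""
    if control.activity == 0:
        raise ZeroDivisionError("control activity is zero; fold change undefined")
    ratio = test.activity / control.activity
    if np.isclose(ratio, 1.0):
        direction = "unchanged"
    elif ratio > 1:
        direction = "increase"
    else:
        direction = "decrease"
    return ActivityFold(ratio=float(ratio), direction=direction)
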