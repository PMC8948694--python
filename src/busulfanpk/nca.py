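"""Non-compartmental AUC per the busulfan SmPC dose-individualization procedure.

The observed concentrations are integrated by the linear-up/log-down
trapezoidal rule after re-referencing the time axis to the *effective*
infusion start (nominal start plus pump lag) and anchoring a zero
concentration there; the area from the last sample to infinity is added as
C_last / lambda_z, with the terminal slope lambda_z obtained by ordinary
least squares of log concentration against time over the last three
sampling times.  Results are classified against the busulfan therapeutic
range of 900-1500 uM*min per q6h dose (both endpoints inclusive).

When the latest sample still lies in the distribution phase of the
two-compartment curve, the three-point slope overestimates the terminal
rate constant and the extrapolated tail — hence the total AUC — is
systematically underestimated; quantifying that error across sampling
schedules is the point of the study module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import ObservationSet, Schedule
from .pk_core import MGHL_TO_UM_MIN

__all__ = [
    "NcaResult",
    "terminal_slope",
    "auc_trapezoid",
    "auc_trap_total",
    "classify_tr",
    "TR_LOWER",
    "TR_UPPER",
]

#: Busulfan therapeutic range per q6h dose, uM*min.
TR_LOWER = 900.0
TR_UPPER = 1500.0


@dataclass
class NcaResult:
    """Trapezoidal AUC decomposition for one patient.

    All areas in uM*min; ``flagged`` results (inestimable or non-positive
    terminal slope) must be excluded from study summaries.
    """

    auc_0_last: float
    auc_extrap: float
    auc_total: float
    lambda_z: float  # 1/h
    n_slope_points: int
    extrap_fraction: float
    flagged: bool = False
    reason: str = ""


def terminal_slope(times, conc, n_last: int = 3) -> tuple[float, int, bool]:
    """Terminal rate constant lambda_z (1/h) from the last ``n_last`` samples.

    Ordinary least squares of ln(conc) on time; non-positive concentrations
    among the slope points are dropped.  Returns ``(lambda_z, n_used,
    flagged)``; the slope is flagged when fewer than two positive points
    remain or when the fitted slope is not strictly negative (e.g. a flat
    profile).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and conc must be 1-D arrays of equal length")
    t, c = t[-n_last:], c[-n_last:]
    pos = c > 0
    t, c = t[pos], c[pos]
    if t.size < 2:
        return math.nan, int(t.size), True
    slope = np.polyfit(t, np.log(c), 1)[0]
    lam = -float(slope)
    if lam <= 1e-10:  # flat or rising terminal data: no estimable decay
        return lam, int(t.size), True
    return lam, int(t.size), False


def _segment_area(t1, t2, c1, c2, log_down: bool) -> float:
    """Area of one trapezoid segment in mg*h/L."""
    dt = t2 - t1
    if log_down and c2 < c1 and c1 > 0 and c2 > 0:
        return dt * (c1 - c2) / math.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def auc_trapezoid(
    times,
    conc,
    t_lag: float = 0.0,
    t_inf: float | None = None,
    method: str = "linear-up-log-down",
) -> float:
    """Partial AUC (uM*min) from the effective infusion start to the last sample.

    Times are shifted by ``t_lag`` (hours) so that zero is the moment drug
    actually starts entering the circulation, and a zero-concentration
    anchor is placed there.  Rising or flat segments use the linear rule;
    strictly falling segments with positive endpoints use the logarithmic
    rule (``method="linear"`` forces the linear rule throughout, for
    sensitivity analysis).  ``t_inf`` is accepted for interface symmetry
    with the infusion context but does not enter the rule.

    Samples at or before the effective start are rejected.
    """
    if method not in ("linear-up-log-down", "linear"):
        raise ValueError(f"unknown trapezoid method: {method!r}")
    t = np.asarray(times, dtype=float) - t_lag
    c = np.asarray(conc, dtype=float)
    if t.size < 1:
        raise ValueError("at least one observation is required")
    if np.any(t <= 0):
        raise ValueError("samples at or before the effective infusion start")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    t = np.concatenate([[0.0], t])
    c = np.concatenate([[0.0], c])
    log_down = method == "linear-up-log-down"
    area = sum(
        _segment_area(t[i], t[i + 1], c[i], c[i + 1], log_down)
        for i in range(t.size - 1)
    )
    return area * MGHL_TO_UM_MIN


def auc_trap_total(
    obs: ObservationSet,
    schedule: Schedule,
    t_lag: float = 0.0,
    n_last: int = 3,
    method: str = "linear-up-log-down",
) -> NcaResult:
    """Total trapezoidal AUC (uM*min): partial area plus C_last/lambda_z tail.

    Uses only the usable (unflagged) observations; ``t_lag`` is the pump
    lag in hours.  The extrapolated tail uses the *observed* last
    concentration.  An inestimable terminal slope flags the whole result.
    """
    mask = obs.usable
    t = obs.times[mask]
    c = obs.conc[mask]
    if t.size < 2:
        return NcaResult(
            math.nan, math.nan, math.nan, math.nan, 0, math.nan, True, "too few samples"
        )
    lam, n_used, flagged = terminal_slope(t, c, n_last=n_last)
    auc_0_last = auc_trapezoid(t, c, t_lag=t_lag, t_inf=schedule.t_inf, method=method)
    if flagged:
        return NcaResult(
            auc_0_last, math.nan, math.nan, lam, n_used, math.nan, True,
            "terminal slope inestimable",
        )
    auc_extrap = float(c[-1]) / lam * MGHL_TO_UM_MIN
    auc_total = auc_0_last + auc_extrap
    return NcaResult(
        auc_0_last=auc_0_last,
        auc_extrap=auc_extrap,
        auc_total=auc_total,
        lambda_z=lam,
        n_slope_points=n_used,
        extrap_fraction=auc_extrap / auc_total,
    )


def classify_tr(auc: float, lower: float = TR_LOWER, upper: float = TR_UPPER) -> str:
    """Classify a per-q6h-dose AUC against the therapeutic range.

    Both endpoints belong to the range.  Once-daily AUCs must be divided by
    the dose multiplier (4) before classification.
    """
    if auc < 0 or math.isnan(auc):
        raise ValueError("AUC must be a non-negative number")
    if auc < lower:
        return "below"
    if auc > upper:
        return "above"
    return "within"
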