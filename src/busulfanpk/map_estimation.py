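"""Empirical-Bayes (MAP) estimation of individual random effects.

Given one patient's observations and the population model, the individual
random effects (eta_CL, eta_V1) are estimated as the mode of their
posterior: the penalized conditional objective

    sum_j [ (y_j - f_j(eta))^2 / (sigma * f_j(eta))^2
            + log((sigma * f_j(eta))^2) ]  +  eta' Omega^-1 eta

is minimized over eta, where f_j is the noise-free model prediction at the
j-th usable observation and Omega the 2x2 inter-individual covariance.  The
residual variance uses the model prediction f (not the observation y), the
standard conditional-likelihood convention for a proportional error model.

The occasion effect kappa_CL is not a free parameter (a single occasion
cannot separate it from eta_CL); the MAP eta_CL therefore absorbs kappa,
which is what makes the resulting empirical-Bayes clearance track the
occasion-specific true clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .cohort import SCHEDULES, ObservationSet, Patient, Schedule, dose_event
from .pk_core import (
    REFERENCE_BW,
    DoseEvent,
    TypicalParams,
    allometric_scale,
    auc_model,
    conc_profile,
)

__all__ = ["MapFit", "EstimationError", "map_objective", "fit_map", "auc_bayes"]

#: Predictions are floored at this value (mg/L) inside the objective so a
#: pathological eta cannot produce log(0) or division by zero.
PREDICTION_FLOOR = 1e-10

#: Deterministic jittered restarts used when the first minimization fails.
_RESTARTS = ((0.3, 0.3), (-0.3, 0.3), (0.3, -0.3), (-0.3, -0.3))


class EstimationError(RuntimeError):
    """Raised when MAP estimation cannot be performed."""


@dataclass
class MapFit:
    """Result of one patient's MAP fit."""

    eta_hat_cl: float
    eta_hat_v1: float
    cl_ebe: float  # L/h
    objective: float  # -2 log-posterior (up to a constant)
    converged: bool
    n_obs_used: int
    grad_norm: float = float("nan")


def _predict(
    eta: np.ndarray,
    typ: TypicalParams,
    bw: float,
    doses: list[DoseEvent],
    times: np.ndarray,
) -> np.ndarray:
    p = allometric_scale(typ, bw, eta_cl=float(eta[0]), eta_v1=float(eta[1]))
    return conc_profile(p, doses, times).conc


def _usable_data(obs: ObservationSet) -> tuple[np.ndarray, np.ndarray]:
    mask = obs.usable
    if not mask.any():
        raise EstimationError("no usable observations for MAP estimation")
    return obs.times[mask], obs.conc[mask]


def _resolve_doses(
    patient: Patient, schedule: Schedule | None, doses: list[DoseEvent] | None
) -> list[DoseEvent]:
    if doses is not None:
        return list(doses)
    if schedule is None:
        schedule = SCHEDULES[patient.schedule]
    return [dose_event(patient, schedule)]


def map_objective(
    eta,
    obs: ObservationSet,
    patient: Patient,
    typ: TypicalParams,
    schedule: Schedule | None = None,
    doses: list[DoseEvent] | None = None,
) -> float:
    """-2 log-posterior (up to a constant) of the random effects.

    ``eta`` is the pair (eta_CL, eta_V1).  Only unflagged observations
    contribute.  The schedule (or an explicit dose-event list) supplies the
    infusion history; by default it is looked up from the patient's
    schedule label.
    """
    # clip to keep exp(eta) finite during optimizer line-search excursions;
    # no plausible random effect approaches this bound
    eta = np.clip(np.asarray(eta, dtype=float), -40.0, 40.0)
    times, y = _usable_data(obs)
    d = _resolve_doses(patient, schedule, doses)
    f = _predict(eta, typ, patient.bw, d, times)
    if np.all(f <= 0):
        raise EstimationError("model predicts zero at every usable observation")
    f = np.maximum(f, PREDICTION_FLOOR)
    var = (max(typ.sigma_prop, 1e-12) * f) ** 2
    data_term = float(np.sum((y - f) ** 2 / var + np.log(var)))
    return data_term + _prior_term(eta, typ)


def _prior_term(eta: np.ndarray, typ: TypicalParams) -> float:
    # Coordinates with zero omega carry no prior term here; fit_map pins
    # them at zero instead (infinite precision limit).
    omega = np.array([typ.omega_cl, typ.omega_v1])
    free = omega > 0
    if not free.any():
        return 0.0
    if free.all():
        prec = np.linalg.inv(typ.iiv_cov())
        return float(eta @ prec @ eta)
    i = int(np.flatnonzero(free)[0])
    return float(eta[i] ** 2 / omega[i] ** 2)


def fit_map(
    obs: ObservationSet,
    patient: Patient,
    typ: TypicalParams,
    schedule: Schedule | None = None,
    doses: list[DoseEvent] | None = None,
    gtol: float = 1e-8,
    maxiter: int = 200,
) -> MapFit:
    """Minimize the MAP objective with BFGS from eta = 0.

    Coordinates whose omega is zero are pinned at zero (the prior is a
    point mass there).  On failure of the initial minimization, four
    deterministic jittered restarts are tried and the best minimum kept;
    a fit that still fails is returned with ``converged=False`` and must be
    excluded by downstream consumers.
    """
    times, y = _usable_data(obs)
    d = _resolve_doses(patient, schedule, doses)
    omega = np.array([typ.omega_cl, typ.omega_v1])
    free = omega > 0

    def objective(eta_free: np.ndarray) -> float:
        eta = np.zeros(2)
        eta[free] = eta_free
        return map_objective(eta, obs, patient, typ, schedule=schedule, doses=d)

    if not free.any():
        eta_hat = np.zeros(2)
        obj = map_objective(eta_hat, obs, patient, typ, schedule=schedule, doses=d)
        converged, grad_norm = True, 0.0
    else:
        starts = [np.zeros(int(free.sum()))]
        starts += [np.asarray(r)[free] for r in _RESTARTS]

        def _ok(res) -> bool:
            # scaled first-order condition; BFGS may report precision loss
            # even at a well-converged optimum of a finite-difference model
            g = np.linalg.norm(res.jac) if res.jac is not None else math.inf
            return bool(res.success) or g < 1e-6 * (1.0 + abs(res.fun))

        best = None
        for x0 in starts:
            res = minimize(
                objective,
                x0,
                method="BFGS",
                jac="3-point",
                options={"gtol": gtol, "maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
            if _ok(res):
                break
        eta_hat = np.zeros(2)
        eta_hat[free] = best.x
        obj = float(best.fun)
        grad_norm = float(np.linalg.norm(best.jac)) if best.jac is not None else math.nan
        converged = _ok(best)

    cl_ebe = typ.cl * (patient.bw / REFERENCE_BW) ** 0.75 * math.exp(eta_hat[0])
    return MapFit(
        eta_hat_cl=float(eta_hat[0]),
        eta_hat_v1=float(eta_hat[1]),
        cl_ebe=cl_ebe,
        objective=obj,
        converged=converged,
        n_obs_used=int(y.size),
        grad_norm=grad_norm,
    )


def auc_bayes(fit: MapFit, dose_per_interval: float) -> float:
    """Model-based AUC (uM*min) from the empirical-Bayes clearance."""
    if not fit.converged:
        raise EstimationError("cannot compute AUC from a non-converged MAP fit")
    return auc_model(dose_per_interval, fit.cl_ebe)
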