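"""Virtual paediatric cohort generation and NONMEM-style dataset exchange.

Builds cohorts matching the study demographics (body weight lognormal with
mean 30.6 kg, SD 21.6 kg, truncated to the observed 7.38-104 kg range),
applies the SmPC weight-band dosing chart and the in-vitro syringe-pump
lag-time table, draws correlated lognormal random effects, and simulates
noisy observations under a chosen sampling schedule.

Datasets are exchanged as NONMEM-style CSV with columns
ID, TIME, AMT, RATE, EVID, MDV, DV, OCC, BW, LAG (times and LAG in hours,
DV in mg/L, missing DV written as '.').
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pk_core import (
    DoseEvent,
    IndividualParams,
    TypicalParams,
    allometric_scale,
    conc_profile,
)

__all__ = [
    "Schedule",
    "SCHEDULES",
    "Patient",
    "ObservationSet",
    "DOSE_BANDS",
    "LAG_BANDS",
    "POSITIVITY_FLOOR",
    "sample_bw",
    "assign_dose",
    "lag_lookup",
    "draw_random_effects",
    "make_patient",
    "dose_event",
    "simulate_observations",
    "cohort_to_frame",
    "write_dataset",
    "read_dataset",
    "frame_to_observations",
]

#: Simulated concentrations at or below this value (mg/L) are flagged and
#: floored; they are excluded from MAP fitting and NCA.
POSITIVITY_FLOOR = 1e-3

DATASET_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV", "OCC", "BW", "LAG"]


@dataclass(frozen=True)
class Schedule:
    """A sampling schedule with its dosing regimen context.

    ``sample_times`` are hours after the *nominal* infusion start.
    ``dose_multiplier`` scales the per-q6h SmPC dose (x4 for the once-daily
    regimen); ``use_lag`` is False for the once-daily regimen, where the
    four-fold infusion volume makes the pump lag negligible.
    """

    label: str
    sample_times: tuple[float, ...]
    t_inf: float
    dose_multiplier: float = 1.0
    interval: float = 6.0
    use_lag: bool = True


#: The three schedules of the simulation study: the original TDM design,
#: a reduced variant, and the once-daily long design.
SCHEDULES: dict[str, Schedule] = {
    "schedule1": Schedule("schedule1", (2.5, 3.0, 4.0, 6.0), t_inf=2.0),
    "schedule2": Schedule("schedule2", (2.5, 4.0, 6.0), t_inf=2.0),
    "schedule3": Schedule(
        "schedule3",
        (3.0, 6.0, 9.0, 12.0),
        t_inf=3.0,
        dose_multiplier=4.0,
        interval=24.0,
        use_lag=False,
    ),
}

# SmPC dosing chart over body weight, as (upper_edge_kg, value, edge_closed)
# triples scanned in order.  Interior edges are half-open (a 16 kg child
# takes the 16-23 band's dose) but 34 kg stays in the 23-34 band because
# the chart's last band is '>34'.
DOSE_BANDS: tuple[tuple[float, float, bool], ...] = (
    (9.0, 1.0, False),
    (16.0, 1.2, False),
    (23.0, 1.1, False),
    (34.0, 0.95, True),
    (math.inf, 0.8, True),
)

# Pump lag-times (min) per band; the chart prints split values 35/25 and
# 10/5 for two bands without defining the sub-band boundary, so the band
# mean is used by default (override via the ``table`` argument).
LAG_BANDS: tuple[tuple[float, float, bool], ...] = (
    (9.0, 40.0, False),
    (16.0, 40.0, False),
    (23.0, 30.0, False),
    (34.0, 20.0, True),
    (math.inf, 7.5, True),
)


def _band_lookup(bw: float, bands) -> float:
    if bw <= 0:
        raise ValueError(f"body weight must be positive, got {bw}")
    for upper, value, closed in bands:
        if bw < upper or (closed and bw == upper):
            return value
    raise AssertionError("bands must cover all positive weights")


def assign_dose(bw: float) -> float:
    """SmPC per-dose amount in mg/kg for the q6h regimen.

    Bands: <9 kg -> 1.0; [9,16) -> 1.2; [16,23) -> 1.1; [23,34] -> 0.95;
    >34 -> 0.8.
    """
    return _band_lookup(bw, DOSE_BANDS)


def lag_lookup(bw: float, table=None) -> float:
    """Syringe-pump lag-time in minutes for a body weight.

    Defaults to the in-vitro lag table (band means where the chart prints a
    split value); pass ``table`` as ``((low, high, minutes), ...)`` to
    override.
    """
    return _band_lookup(bw, LAG_BANDS if table is None else table)


def sample_bw(
    n: int,
    seed=None,
    rng: np.random.Generator | None = None,
    mean: float = 30.6,
    sd: float = 21.6,
    lo: float = 7.38,
    hi: float = 104.0,
) -> np.ndarray:
    """Draw body weights (kg) from a truncated lognormal.

    The lognormal is moment-matched to the cohort mean and SD and then
    truncated (by rejection) to the observed weight range.  With
    ``lo == hi`` the output is constant.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if lo == hi:
        return np.full(n, float(lo))
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    sigma = math.sqrt(sigma2)
    mu = math.log(mean) - sigma2 / 2.0
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def draw_random_effects(
    typ: TypicalParams,
    n: int,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (eta_CL, eta_V1, kappa_CL) for n patients.

    (eta_CL, eta_V1) are jointly normal with zero mean, SDs
    (omega_cl, omega_v1) and correlation corr_cl_v1; kappa_CL is an
    independent normal occasion effect with SD iov_cl.  Built from a
    Cholesky factor so zero omegas give exact zeros.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rho = typ.corr_cl_v1
    z = rng.standard_normal((3, n))
    eta_cl = typ.omega_cl * z[0]
    eta_v1 = typ.omega_v1 * (rho * z[0] + math.sqrt(1.0 - rho * rho) * z[1])
    kappa_cl = typ.iov_cl * z[2]
    return eta_cl, eta_v1, kappa_cl


@dataclass
class Patient:
    """One virtual patient on one occasion."""

    id: int
    bw: float  # kg
    dose_per_kg: float  # mg/kg (per q6h-equivalent dose)
    dose: float  # mg per administered dose (includes schedule multiplier)
    t_lag_min: float  # pump lag, minutes
    schedule: str
    params: IndividualParams

    @property
    def t_lag_h(self) -> float:
        return self.t_lag_min / 60.0


@dataclass
class ObservationSet:
    """Sampled times and observed concentrations for one patient/occasion.

    ``flags`` marks records unusable for estimation: at/below the
    positivity floor, or taken before the effective infusion start.
    """

    patient_id: int
    times: np.ndarray  # h
    conc: np.ndarray  # mg/L
    flags: np.ndarray  # bool, True = excluded from estimation
    schedule: str = ""

    @property
    def usable(self) -> np.ndarray:
        return ~self.flags

    @property
    def n_usable(self) -> int:
        return int(self.usable.sum())


def make_patient(
    typ: TypicalParams,
    bw: float,
    schedule: Schedule,
    eta_cl: float = 0.0,
    eta_v1: float = 0.0,
    kappa_cl: float = 0.0,
    patient_id: int = 0,
    lag_table=None,
) -> Patient:
    """Assemble a patient: chart dose, lag, and realized parameters."""
    dpk = assign_dose(bw)
    dose = dpk * bw * schedule.dose_multiplier
    t_lag_min = lag_lookup(bw, table=lag_table) if schedule.use_lag else 0.0
    params = allometric_scale(typ, bw, eta_cl, eta_v1, kappa_cl)
    return Patient(
        id=patient_id,
        bw=bw,
        dose_per_kg=dpk,
        dose=dose,
        t_lag_min=t_lag_min,
        schedule=schedule.label,
        params=params,
    )


def dose_event(patient: Patient, schedule: Schedule, t_start: float = 0.0) -> DoseEvent:
    """The (single-occasion) infusion event for a patient under a schedule."""
    return DoseEvent(
        amount=patient.dose,
        t_start=t_start,
        t_inf=schedule.t_inf,
        t_lag=patient.t_lag_h,
    )


def simulate_observations(
    patient: Patient,
    schedule: Schedule,
    typ: TypicalParams,
    seed=None,
    rng: np.random.Generator | None = None,
    floor: float = POSITIVITY_FLOOR,
) -> ObservationSet:
    """Simulate noisy observations at the schedule's sampling times.

    Observed concentration is ``c_true * (1 + eps)`` with
    ``eps ~ N(0, sigma_prop^2)`` i.i.d. per sample.  Values at or below the
    positivity floor are set to the floor and flagged; samples before the
    effective infusion start (true concentration 0) are likewise flagged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    times = np.asarray(schedule.sample_times, dtype=float)
    profile = conc_profile(patient.params, [dose_event(patient, schedule)], times)
    c_true = profile.conc
    eps = rng.normal(0.0, typ.sigma_prop, size=times.size)
    c_obs = c_true * (1.0 + eps)
    flags = (c_true <= 0.0) | (c_obs <= floor)
    c_obs = np.where(c_obs <= floor, floor, c_obs)
    return ObservationSet(
        patient_id=patient.id,
        times=times,
        conc=c_obs,
        flags=flags,
        schedule=schedule.label,
    )


# ---------------------------------------------------------------------------
# NONMEM-style dataset exchange


def cohort_to_frame(
    patients: list[Patient],
    observations: list[ObservationSet],
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    """Assemble dosing (EVID=1) and observation (EVID=0) records.

    Flagged observations are written with MDV=1 so a consumer excludes
    them from estimation without losing the record.
    """
    sched = {p.id: SCHEDULES[p.schedule] if schedule is None else schedule for p in patients}
    obs_by_id = {o.patient_id: o for o in observations}
    rows = []
    for p in patients:
        s = sched[p.id]
        rows.append(
            dict(
                ID=p.id,
                TIME=0.0,
                AMT=p.dose,
                RATE=p.dose / s.t_inf,
                EVID=1,
                MDV=1,
                DV=np.nan,
                OCC=1,
                BW=p.bw,
                LAG=p.t_lag_h,
            )
        )
        o = obs_by_id.get(p.id)
        if o is None:
            continue
        for t, c, flagged in zip(o.times, o.conc, o.flags):
            rows.append(
                dict(
                    ID=p.id,
                    TIME=float(t),
                    AMT=0.0,
                    RATE=0.0,
                    EVID=0,
                    MDV=int(flagged),
                    DV=float(c),
                    OCC=1,
                    BW=p.bw,
                    LAG=p.t_lag_h,
                )
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a NONMEM-style CSV (missing DV as '.')."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing mandatory column(s): {missing}")
    df.to_csv(path, index=False, na_rep=".")


def read_dataset(path) -> pd.DataFrame:
    """Read a NONMEM-style CSV, validating mandatory columns."""
    df = pd.read_csv(path, na_values=["."])
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing mandatory column(s): {missing}")
    for col in ("ID", "EVID", "MDV", "OCC"):
        df[col] = df[col].astype(int)
    return df


def frame_to_observations(df: pd.DataFrame) -> list[ObservationSet]:
    """Extract per-patient observation sets (EVID=0 rows) from a dataset."""
    out = []
    for pid, grp in df[df["EVID"] == 0].groupby("ID", sort=True):
        out.append(
            ObservationSet(
                patient_id=int(pid),
                times=grp["TIME"].to_numpy(dtype=float),
                conc=grp["DV"].to_numpy(dtype=float),
                flags=grp["MDV"].to_numpy() == 1,
            )
        )
    return out
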