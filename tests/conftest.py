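import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from busulfanpk import DoseEvent, TypicalParams, allometric_scale

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def typ():
    """Population typical parameters of the final model."""
    return TypicalParams()


@pytest.fixture(scope="session")
def typical_70kg(typ):
    return allometric_scale(typ, 70.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20220315)


def ode_conc_oracle(p, doses, times, rtol=1e-11, atol=1e-13):
    """Independent oracle: integrate the two-compartment infusion ODEs.

    dA1/dt = rate_in(t) - (k10 + k12) A1 + k21 A2
    dA2/dt = k12 A1 - k21 A2,      C1 = A1 / V1

    Integrated piecewise between infusion on/off breakpoints so the
    discontinuous input never degrades the local error control.
    """
    from scipy.integrate import solve_ivp

    from busulfanpk.pk_core import micro_constants

    k10, k12, k21 = micro_constants(p)

    def rate_in(t):
        r = 0.0
        for d in doses:
            if d.effective_start < t <= d.effective_start + d.t_inf:
                r += d.rate
        return r

    breaks = sorted(
        {d.effective_start for d in doses}
        | {d.effective_start + d.t_inf for d in doses}
    )
    times = np.asarray(times, dtype=float)
    t_end = float(times[-1])
    edges = [0.0] + [b for b in breaks if 0.0 < b < t_end] + [t_end]

    def rhs(t, a, rate):
        return [rate - (k10 + k12) * a[0] + k21 * a[1], k12 * a[0] - k21 * a[1]]

    out = np.empty_like(times)
    a = np.array([0.0, 0.0])
    for lo, hi in zip(edges[:-1], edges[1:]):
        rate = rate_in(0.5 * (lo + hi))  # constant within the segment
        t_eval = times[(times > lo) & (times <= hi)]
        sol = solve_ivp(
            rhs,
            (lo, hi),
            a,
            args=(rate,),
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=np.unique(np.concatenate([t_eval, [hi]])),
            max_step=(hi - lo) / 4,
        )
        for t, a1 in zip(sol.t, sol.y[0]):
            hits = np.isclose(times, t, rtol=0, atol=1e-12) & (times > lo)
            out[hits] = a1 / p.v1
        a = sol.y[:, -1]
    out[times <= edges[0]] = 0.0
    first_start = min(d.effective_start for d in doses)
    out[times <= first_start] = 0.0
    return out
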