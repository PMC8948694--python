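"""Closed-form two-compartment kinetics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_

from busulfanpk import (
    MGHL_TO_UM_MIN,
    DoseEvent,
    IndividualParams,
    TypicalParams,
    allometric_scale,
    auc_model,
    conc_profile,
    micro_constants,
    terminal_halflife,
)
from busulfanpk.pk_core import hybrid_constants

from conftest import ode_conc_oracle


class TestAllometry:
    def test_reference_weight_identity(self, typ):
        p = allometric_scale(typ, 70.0)
        assert (p.cl, p.v1, p.q, p.v2) == (typ.cl, typ.v1, typ.q, typ.v2)

    @pytest.mark.parametrize(
        "bw, cl, tol_cl, v1, tol_v1",
        [
            (15.3, 3.4, 0.05, 8.63, 0.01),  # worked comparison weight
            (7.38, 1.98, 0.005, 4.16, 0.005),  # lightest patient
            (104.0, 14.4, 0.05, 58.7, 0.05),  # heaviest patient
        ],
    )
    def test_paper_weights(self, typ, bw, cl, tol_cl, v1, tol_v1):
        """Allometric CL and V1 reproduce the reported values at their printed precision."""
        p = allometric_scale(typ, bw)
        assert p.cl == pytest.approx(cl, abs=tol_cl)
        assert p.v1 == pytest.approx(v1, abs=tol_v1)

    def test_random_effects_compose_lognormally(self, typ):
        p = allometric_scale(typ, 20.0, eta_cl=0.3, eta_v1=-0.2, kappa_cl=0.1)
        base = allometric_scale(typ, 20.0)
        assert p.cl == pytest.approx(base.cl * math.exp(0.4), rel=1e-12)
        assert p.v1 == pytest.approx(base.v1 * math.exp(-0.2), rel=1e-12)
        # Q and V2 carry no random effects
        assert (p.q, p.v2) == (base.q, base.v2)

    def test_nonpositive_weight_rejected(self, typ):
        with pytest.raises(ValueError):
            allometric_scale(typ, 0.0)
        with pytest.raises(ValueError):
            allometric_scale(typ, -5.0)


class TestMicroConstants:
    def test_typical_values(self, typical_70kg):
        k10, k12, k21 = micro_constants(typical_70kg)
        assert k10 == pytest.approx(0.27089, abs=1e-5)
        assert k12 == pytest.approx(0.11848, abs=1e-5)
        assert k21 == pytest.approx(0.26743, abs=1e-5)

    def test_unit_parameters(self):
        p = IndividualParams(cl=1, v1=1, q=1, v2=1, bw=70)
        assert micro_constants(p) == (1.0, 1.0, 1.0)

    def test_10kg_typical(self, typ):
        k10, k12, k21 = micro_constants(allometric_scale(typ, 10.0))
        assert k10 == pytest.approx(0.4406, abs=2e-4)
        assert k12 == pytest.approx(0.1927, abs=2e-4)
        assert k21 == pytest.approx(0.4350, abs=2e-4)


class TestHalflife:
    def test_against_eigendecomposition(self, typ):
        """beta from the stable closed form equals the matrix eigenvalue."""
        for bw in (10.0, 30.6, 70.0):
            p = allometric_scale(typ, bw)
            k10, k12, k21 = micro_constants(p)
            eig = np.linalg.eigvals(np.array([[-(k10 + k12), k21], [k12, -k21]]))
            beta = min(-eig)
            assert terminal_halflife(p) == pytest.approx(
                math.log(2) / beta, rel=1e-10
            )

    @pytest.mark.parametrize("bw, hours", [(10.0, 3), (30.6, 4), (70.0, 5)])
    def test_reported_integer_halflives(self, typ, bw, hours):
        assert round(terminal_halflife(allometric_scale(typ, bw))) == hours

    def test_exact_allometric_scaling_law(self, typ):
        """t1/2(BW) = t1/2(70) * (BW/70)^0.25 since all k scale as (BW/70)^-0.25."""
        t70 = terminal_halflife(allometric_scale(typ, 70.0))
        for bw in (7.38, 10.0, 23.0, 30.6, 50.0, 104.0):
            t = terminal_halflife(allometric_scale(typ, bw))
            assert t == pytest.approx(t70 * (bw / 70.0) ** 0.25, rel=1e-12)

    def test_one_compartment_limit(self):
        """As Q -> 0 the beta phase loses all amplitude and the observable
        decay tends to the one-compartment rate CL/V1 (half-life ln2*V1/CL);
        ln2/beta itself diverges because the decoupled peripheral
        compartment empties arbitrarily slowly."""
        p = IndividualParams(cl=10.7, v1=39.5, q=1e-9, v2=17.5, bw=70)
        alpha, beta, a_coef, b_coef = hybrid_constants(p)
        assert abs(b_coef) < 1e-8  # beta phase invisible in the central curve
        assert math.log(2) / alpha == pytest.approx(
            math.log(2) * 39.5 / 10.7, rel=1e-6
        )
        assert terminal_halflife(p) > 1e6  # formal terminal phase diverges


class TestConcProfile:
    def test_zero_before_effective_start(self, typical_70kg):
        d = DoseEvent(amount=56.0, t_inf=2.0, t_lag=0.5)
        times = np.array([0.0, 0.2, 0.5, 0.6, 3.0])
        c = conc_profile(typical_70kg, [d], times).conc
        assert np.all(c[:3] == 0.0)
        assert np.all(c[3:] > 0.0)

    def test_matches_ode_oracle(self, typ, rng):
        """Closed form vs stiff ODE integration, 10 random parameter sets."""
        grid = np.linspace(0.25, 24.0, 60)
        worst = 0.0
        for _ in range(10):
            bw = rng.uniform(8.0, 100.0)
            p = allometric_scale(
                typ, bw, eta_cl=rng.normal(0, 0.3), eta_v1=rng.normal(0, 0.3)
            )
            d = DoseEvent(
                amount=bw * 1.0,
                t_inf=rng.uniform(1.0, 3.0),
                t_lag=rng.uniform(0.0, 0.7),
            )
            closed = conc_profile(p, [d], grid).conc
            oracle = ode_conc_oracle(p, [d], grid)
            mask = oracle > 0
            worst = max(worst, np.max(np.abs(closed[mask] / oracle[mask] - 1.0)))
        assert worst < 1e-6

    def test_superposition_of_q6h_doses(self, typical_70kg):
        """16 q6h doses equal the sum of 16 independent single-dose profiles."""
        doses = [
            DoseEvent(amount=56.0, t_start=6.0 * k, t_inf=2.0, t_lag=0.25)
            for k in range(16)
        ]
        times = np.linspace(0.0, 102.0, 300)
        combined = conc_profile(typical_70kg, doses, times).conc
        summed = sum(conc_profile(typical_70kg, [d], times).conc for d in doses)
        np.testing.assert_allclose(combined, summed, rtol=1e-12)

    def test_steady_state_trough_geometric_series(self, typical_70kg):
        """q6h trough approaches the geometric-series limit of one dose's exponentials."""
        tau = 6.0
        n_doses = 60  # far past 10 half-lives
        d1 = DoseEvent(amount=56.0, t_inf=2.0)
        doses = [
            DoseEvent(amount=56.0, t_start=tau * k, t_inf=2.0) for k in range(n_doses)
        ]
        trough_t = n_doses * tau
        trough = conc_profile(typical_70kg, doses, np.array([trough_t])).conc[0]
        alpha, beta, a_coef, b_coef = hybrid_constants(typical_70kg)
        scale = d1.rate / typical_70kg.v1
        pred = 0.0
        for lam, coef in ((alpha, a_coef), (beta, b_coef)):
            e_inf = (coef / lam) * (1.0 - math.exp(-lam * d1.t_inf))
            single = e_inf * math.exp(-lam * (tau - d1.t_inf))
            pred += single / (1.0 - math.exp(-lam * tau))
        assert trough == pytest.approx(scale * pred, rel=1e-9)

    def test_unsorted_times_rejected(self, typical_70kg):
        with pytest.raises(ValueError):
            conc_profile(typical_70kg, [DoseEvent(amount=10.0)], [2.0, 1.0])


class TestAucModel:
    def test_unit_conversion(self):
        # 10 mg / 10 L/h = 1 mg*h/L = 60000/246.30 uM*min
        assert auc_model(10.0, 10.0) == pytest.approx(243.6, abs=0.05)

    def test_worked_example_within_tr(self):
        # 15.3 kg x 1.2 mg/kg at the typical 15.3 kg clearance
        assert auc_model(18.36, 3.4) == pytest.approx(1315.0, abs=1.0)

    def test_vanishes_at_infinite_clearance(self):
        assert auc_model(100.0, 1e9) < 1e-4

    def test_noise_free_trapezoid_consistency(self, typ):
        """Dense numerical integration of the profile to 96 h plus an
        analytic tail reproduces dose/CL within 0.5%."""
        p = allometric_scale(typ, 30.0)
        d = DoseEvent(amount=28.5, t_inf=2.0, t_lag=1.0 / 3.0)
        t = np.linspace(d.t_lag + 1e-9, 96.0, 4000)
        c = conc_profile(p, [d], t).conc
        _, beta, _, _ = hybrid_constants(p)
        area = (np.trapezoid(c, t) + c[-1] / beta) * MGHL_TO_UM_MIN
        assert area == pytest.approx(auc_model(28.5, p.cl), rel=5e-3)


@given(bw=st_.floats(min_value=1.0, max_value=200.0))
def test_halflife_scaling_property(bw):
    typ = TypicalParams()
    t70 = terminal_halflife(allometric_scale(typ, 70.0))
    t = terminal_halflife(allometric_scale(typ, bw))
    assert t == pytest.approx(t70 * (bw / 70.0) ** 0.25, rel=1e-11)
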