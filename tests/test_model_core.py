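"""Unit tests for the equation layer: transfer functions, currents, kinetics.

Expected values are either analytic limits, direct high-precision arithmetic
on the model equations, or roots from an independent scalar root-finder.
"""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from serocircuit import (
    InflammationCondition,
    ModelParams,
    SerotoninKineticsParams,
    SystemState,
    gating_derivatives,
    inflammation_factors,
    region_currents,
    serotonergic_current_derivative,
    serotonin_derivative,
    serotonin_fixed_point,
    transfer_rate,
)


class TestTransferRate:
    @pytest.mark.parametrize(
        "I, g, d, I_thr, expected",
        [
            (0.4, 310.0, 0.16, 0.4, 6.25),          # 1/d at threshold
            (0.286, 615.0, 0.087, 0.286, 1 / 0.087),
            (0.42, 310.0, 0.16, 0.4, 9.854319467593546),
        ],
    )
    def test_known_values(self, I, g, d, I_thr, expected):
        assert transfer_rate(I, g, d, I_thr) == pytest.approx(expected, rel=1e-10)

    def test_continuous_at_threshold(self):
        """Left and right limits both converge to the analytic value 1/d,
        and the two branches agree across the series cutoff."""
        g, d, thr = 310.0, 0.16, 0.4
        for eps in (1e-11, 1e-12, 1e-13):
            assert transfer_rate(thr + eps, g, d, thr) == pytest.approx(1 / d, rel=1e-8)
            assert transfer_rate(thr - eps, g, d, thr) == pytest.approx(1 / d, rel=1e-8)
        for eps in (1e-7, 1e-8, 1e-9):  # straddles the branch switch
            lo = transfer_rate(thr - eps, g, d, thr)
            hi = transfer_rate(thr + eps, g, d, thr)
            assert lo <= 1 / d <= hi
            assert hi - lo <= 1.01 * g * eps  # slope-limited gap, no jump

    def test_monotone_increasing_and_nonnegative(self):
        I = np.linspace(-1.0, 2.0, 20001)
        r = transfer_rate(I, 310.0, 0.16, 0.4)
        assert np.all(np.diff(r) > 0)
        assert np.all(r >= 0)

    def test_deep_subthreshold_underflows_to_zero(self):
        assert transfer_rate(-50.0, 310.0, 0.16, 0.4) == 0.0

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            transfer_rate(np.nan, 310.0, 0.16, 0.4)
        with pytest.raises(ValueError):
            transfer_rate(np.inf, 310.0, 0.16, 0.4)


class TestInflammationFactors:
    def setup_method(self):
        self.kin = SerotoninKineticsParams()  # c1=5, m=2, c2=0.019

    def test_control_is_identity(self):
        for B in (1.0, 0.55, 0.1):
            assert inflammation_factors(
                InflammationCondition(degree=1.0, B=B), self.kin) == (1.0, 1.0)
        assert inflammation_factors(
            InflammationCondition(degree=0.5), self.kin) == (1.0, 1.0)

    def test_severe_untreated(self):
        x1, x2 = inflammation_factors(
            InflammationCondition(degree=2.3, B=1.0), self.kin)
        assert x1 == pytest.approx(25 / (25 + 2.3**2), rel=1e-12)
        assert x2 == pytest.approx(1 + 0.019 * 2.3, rel=1e-12)

    def test_severe_with_blocker(self):
        x1, x2 = inflammation_factors(
            InflammationCondition(degree=2.3, B=0.55), self.kin)
        assert x1 == pytest.approx(25 / (25 + 0.55 * 2.3**2), rel=1e-12)
        assert x2 == pytest.approx(1 + 0.019 * 0.55 * 2.3, rel=1e-12)

    def test_monotone_in_degree(self):
        degrees = np.linspace(1.0, 4.0, 50)
        vals = [inflammation_factors(InflammationCondition(degree=d), self.kin)
                for d in degrees]
        x1s, x2s = zip(*vals)
        assert np.all(np.diff(x1s) <= 0)
        assert np.all(np.diff(x2s) >= 0)
        assert all(0 < x1 <= 1 for x1 in x1s)
        assert all(x2 >= 1 for x2 in x2s)

    def test_blocker_moves_factors_toward_identity(self):
        """Finite-difference sign: X1 falls and X2 rises as B increases."""
        eps = 1e-6
        for B in (0.3, 0.55, 0.9):
            lo = inflammation_factors(InflammationCondition(degree=2.3, B=B), self.kin)
            hi = inflammation_factors(
                InflammationCondition(degree=2.3, B=B + eps), self.kin)
            assert hi[0] < lo[0]   # X1 decreasing in B
            assert hi[1] > lo[1]   # X2 increasing in B

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            InflammationCondition(degree=-0.1)
        with pytest.raises(ValueError):
            InflammationCondition(degree=2.3, B=0.0)
        with pytest.raises(ValueError):
            InflammationCondition(degree=2.3, B=1.5)


def _state(s_e, s_i, m, conc=60.0):
    return SystemState(S_E=np.array(s_e, dtype=float),
                       S_I=np.array(s_i, dtype=float),
                       M_5HT=np.array(m, dtype=float),
                       conc_5HT=np.array(conc, dtype=float))


class TestRegionCurrents:
    def test_zero_state_zero_external(self):
        p = dataclasses.replace(ModelParams().pfc, Io=1e-300)
        I_E, I_I = region_currents(_state(0.0, 0.0, 0.0), p, 0.0)
        assert I_E == pytest.approx(0.0, abs=1e-12)
        assert I_I == pytest.approx(0.0, abs=1e-12)

    def test_pfc_assembly(self):
        """Direct arithmetic: serotonergic term adds in PFC."""
        I_E, I_I = region_currents(_state(0.2, 0.1, 0.6), ModelParams().pfc, 0.2)
        expected = (1.4 * 0.15 * 0.2 - 1.135 * 0.1 + 0.48 * 0.6 * 0.6
                    + 1.0 * 0.32 + 0.15 * 0.01 * 0.2)
        assert I_E == pytest.approx(expected, rel=1e-12)
        assert I_E == pytest.approx(0.4216, abs=1e-6)

    def test_scc_assembly_minus_sign(self):
        """Direct arithmetic: serotonergic term subtracts in SCC."""
        I_E, _ = region_currents(_state(0.2, 0.1, 0.6), ModelParams().scc, 0.2)
        expected = (1.4 * 0.33 * 0.2 - 1.135 * 0.1 - 0.19 * 0.6 * 0.6
                    + 1.0 * 0.45 + 0.33 * 0.005 * 0.2)
        assert I_E == pytest.approx(expected, rel=1e-12)
        assert I_E == pytest.approx(0.36083, abs=1e-6)

    def test_linearity_superposition(self):
        p = ModelParams().pfc
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.uniform(0, 1, size=4)
            b = rng.uniform(0, 1, size=4)
            Ia = np.array(region_currents(_state(a[0], a[1], a[2]), p, a[3]))
            Ib = np.array(region_currents(_state(b[0], b[1], b[2]), p, b[3]))
            Iab = np.array(region_currents(
                _state(a[0] + b[0], a[1] + b[1], a[2] + b[2]), p, a[3] + b[3]))
            offset = np.array(region_currents(_state(0, 0, 0), p, 0.0))
            np.testing.assert_allclose(Iab, Ia + Ib - offset, rtol=1e-10)

    def test_serotonergic_sign_asymmetry(self):
        """More serotonergic current excites PFC but inhibits SCC."""
        mp = ModelParams()
        for m_lo, m_hi in [(0.2, 0.4), (0.5, 0.9)]:
            pfc_lo, _ = region_currents(_state(0.2, 0.1, m_lo), mp.pfc, 0.2)
            pfc_hi, _ = region_currents(_state(0.2, 0.1, m_hi), mp.pfc, 0.2)
            scc_lo, _ = region_currents(_state(0.2, 0.1, m_lo), mp.scc, 0.2)
            scc_hi, _ = region_currents(_state(0.2, 0.1, m_hi), mp.scc, 0.2)
            assert pfc_hi > pfc_lo
            assert scc_hi < scc_lo


class TestGatingDerivatives:
    def test_full_gating_decays(self):
        p = ModelParams().pfc
        d_se, _ = gating_derivatives(1.0, 0.1, 123.0, 4.0, p)
        assert d_se == pytest.approx(-1.0 / p.tau_NMDA, rel=1e-12)

    def test_inhibitory_fixed_point(self):
        p = ModelParams().pfc
        _, d_si = gating_derivatives(0.5, p.tau_GABA * 4.0, 1.0, 4.0, p)
        assert d_si == pytest.approx(0.0, abs=1e-12)
        assert p.tau_GABA * 4.0 == pytest.approx(0.04)

    def test_excitatory_fixed_point_closed_form(self):
        """S_E* = gamma tau r / (1 + gamma tau r) zeroes the drift."""
        p = ModelParams().pfc
        r = 4.61
        gtr = p.gamma * p.tau_NMDA * r
        s_star = gtr / (1 + gtr)
        assert s_star == pytest.approx(0.2281, abs=5e-5)
        d_se, _ = gating_derivatives(s_star, 0.0, r, 0.0, p)
        assert d_se == pytest.approx(0.0, abs=1e-12)


class TestSerotonergicCurrent:
    def setup_method(self):
        self.kin = SerotoninKineticsParams()

    def test_equilibrium_sigmoid_values(self):
        # dM/dt = 0 at M = J/(1+exp(-beta(conc+1)))
        for conc, m_star in [(66.35, 1 / (1 + np.exp(-0.5388))),
                             (0.0, 1 / (1 + np.exp(-0.008)))]:
            assert serotonergic_current_derivative(m_star, conc, self.kin) == (
                pytest.approx(0.0, abs=1e-9))
        assert 1 / (1 + np.exp(-0.5388)) == pytest.approx(0.6315, abs=1e-4)
        assert 1 / (1 + np.exp(-0.008)) == pytest.approx(0.5020, abs=1e-4)

    def test_saturation_at_range_limit(self):
        d = serotonergic_current_derivative(self.kin.J_5HT, 1e9, self.kin)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_equilibrium_increases_with_concentration(self):
        concs = np.linspace(0, 200, 50)
        m_star = 1 / (1 + np.exp(-self.kin.beta * (concs + 1)))
        assert np.all(np.diff(m_star) > 0)
        assert np.all((m_star > 0) & (m_star < self.kin.J_5HT))


class TestSerotoninKinetics:
    def setup_method(self):
        self.kin = SerotoninKineticsParams()

    def test_no_reuptake_at_zero_concentration(self):
        d = serotonin_derivative(4.0, 0.0, 1.0, 1.0, self.kin)
        assert d == pytest.approx(self.kin.alpha * self.kin.C_BR * 4.0, rel=1e-12)

    def test_half_maximal_reuptake_at_km(self):
        d = serotonin_derivative(0.0, self.kin.Km, 1.0, 1.0, self.kin)
        assert d == pytest.approx(-self.kin.Vmax / 2, rel=1e-12)
        assert self.kin.Vmax / 2 == 650.0

    def test_closed_form_root_matches_scalar_root_finder(self):
        """conc* = Km u/(1-u) agrees with brentq on the drift to 1e-8 nM."""
        for r_e, x1, x2 in [(4.61, 1.0, 1.0), (4.29, 0.82535, 1.0437),
                            (3.0, 0.9, 1.01)]:
            closed = serotonin_fixed_point(r_e, x1, x2, self.kin)
            numeric = brentq(
                lambda c: serotonin_derivative(r_e, c, x1, x2, self.kin),
                1e-6, 1e4, xtol=1e-12, rtol=1e-14)
            assert abs(closed - numeric) < 1e-8

    def test_control_rate_fixed_point_value(self):
        assert serotonin_fixed_point(4.61, 1.0, 1.0, self.kin) == (
            pytest.approx(61.59, abs=0.01))

    def test_unbounded_synthesis_raises(self):
        with pytest.raises(ValueError):
            serotonin_fixed_point(20.0, 1.0, 1.0, self.kin)
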