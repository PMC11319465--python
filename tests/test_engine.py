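"""Derivation engine: balance, power system, closed-form coefficients."""

import cmath

import numpy as np
import pytest
import sympy as sp

from fanwave.auxiliary import AuxParams, GEECoefficients, gee_from_riccati
from fanwave.engine import (
    BalanceError,
    DegenerateAnsatzError,
    WaveFrame,
    balance_order,
    build_power_system,
    consistent_phi2,
    implied_constraints,
    solve_eta,
)


class Phis:
    def __init__(self, p1, p2, p3=None):
        self.Phi1, self.Phi2, self.Phi3 = p1, p2, p3


class TestBalance:
    @pytest.mark.parametrize("degree,order,expected", [(3, 2, 1), (2, 2, 2), (3, 4, 2)])
    def test_integer_cases(self, degree, order, expected):
        assert balance_order(degree, order) == expected

    def test_non_integer_is_error(self):
        with pytest.raises(BalanceError, match="1/2"):
            balance_order(5, 2)

    def test_preconditions(self):
        with pytest.raises(BalanceError):
            balance_order(1, 2)


@pytest.fixture
def fig2_algebra():
    frame = WaveFrame(xi=1.0, zeta=4.0, Lambda1=1.0)
    coeffs = gee_from_riccati(1.0, 1.0, 0.01)
    return frame, Phis(1.0, 1.0), coeffs


class TestPowerSystem:
    def test_chi3_line_matches_print(self):
        zeta, xi, L1, P1, P2, P3 = sp.symbols("zeta xi Lambda1 Phi1 Phi2 Phi3")
        cs = sp.symbols("c0 c1 c2 c3 c4")
        system = build_power_system(
            WaveFrame(xi, zeta, L1), Phis(P1, P2, P3), GEECoefficients(*cs)
        )
        e0, e1 = system.symbols
        c0, c1, c2, c3, c4 = cs
        printed = {
            system.eq3: 4 * zeta**2 * c4 * e1 - 4 * xi**2 * c4 * e1 * L1**2
            - 2 * e1**3 * P1,
            system.eq2: 3 * zeta**2 * c3 * e1 - 3 * xi**2 * c3 * e1 * L1**2
            - 6 * e0 * e1**2 * P1 - 2 * e1**2 * P2,
            system.eq1: 2 * zeta**2 * c2 * e1 - 2 * xi**2 * c2 * e1 * L1**2
            - 2 * e1 * P3 - 6 * e0**2 * e1 * P1 - 4 * e0 * e1 * P2,
            system.eq0: zeta**2 * c1 * e1 - xi**2 * c1 * e1 * L1**2
            - 2 * e0**3 * P1 - 2 * e0**2 * P2 - 2 * e0 * P3,
        }
        for built, expected in printed.items():
            assert sp.simplify(built - expected) == 0

    def test_render_to_text(self, fig2_algebra):
        system = build_power_system(*fig2_algebra)
        text = system.as_text()
        for power in (3, 2, 1, 0):
            assert f"(chi)^{power}:" in text
        assert text.count("= 0") == 4

    def test_c4_zero_reduces_chi3_line(self):
        frame = WaveFrame(xi=0.0, zeta=1.0, Lambda1=1.0)
        coeffs = GEECoefficients(0, 0, 1.0, 0.5, 0.0)
        system = build_power_system(frame, Phis(2.0, 0.0, 0.0), coeffs)
        e0, e1 = system.symbols
        assert sp.simplify(system.eq3 - (-4 * e1**3)) == 0  # -2*eta1^3*Phi1

    def test_delta_c_side_condition(self):
        with pytest.raises(ValueError, match="nonzero"):
            build_power_system(WaveFrame(1.0, 1.0, 1.0), Phis(1.0, 0.0, 0.0),
                               GEECoefficients(0, 0, 0, 0, 1))


class TestSolveEta:
    def test_trivial_example(self):
        frame = WaveFrame(xi=0.0, zeta=1.0, Lambda1=1.0)
        coeffs = GEECoefficients(0, 0, 0, 0.0, 1.0)
        minus, plus = solve_eta(frame, Phis(2.0, 0.0), coeffs)
        assert minus.eta1 == pytest.approx(-1.0)
        assert plus.eta1 == pytest.approx(+1.0)
        assert minus.eta0 == pytest.approx(0.0)

    def test_figure_caption_arithmetic(self):
        frame = WaveFrame(xi=1.0, zeta=4.0, Lambda1=1.0)
        coeffs = gee_from_riccati(1.0, 1.0, 0.01)  # c3=0.02, c4=1e-4
        minus, plus = solve_eta(frame, Phis(1.0, 1.0), coeffs)
        assert minus.eta1 == pytest.approx(-cmath.sqrt(0.003).real)
        expected_eta0 = (0.9 - 2 * minus.eta1) / (6 * minus.eta1)
        assert minus.eta0 == pytest.approx(expected_eta0)
        assert not minus.is_complex

    def test_branches_are_exact_negatives(self):
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        coeffs = gee_from_riccati(1.0, 3.0, 1.0)
        minus, plus = solve_eta(frame, Phis(1.5, 0.7), coeffs)
        assert minus.eta1 == -plus.eta1

    def test_annihilates_chi3_chi2_numerically(self):
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        rng = np.random.default_rng(3)
        for _ in range(10):
            coeffs = gee_from_riccati(
                float(rng.uniform(0.5, 2)), float(rng.uniform(2.5, 4)), 1.0
            )
            phis = Phis(float(rng.uniform(0.5, 2)), float(rng.uniform(-1, 1)), 0.0)
            system = build_power_system(frame, phis, coeffs)
            for eta in solve_eta(frame, phis, coeffs):
                vals = system.evaluate(eta)
                assert abs(vals[0]) < 1e-10 and abs(vals[1]) < 1e-10

    def test_negative_radicand_flagged_complex(self):
        frame = WaveFrame(xi=1.0, zeta=3.5, Lambda1=5.0)  # delta_c < 0
        coeffs = gee_from_riccati(1.0, 3.5, 0.01)
        minus, _ = solve_eta(frame, Phis(1.0, 1.0), coeffs)
        assert minus.is_complex
        assert abs(minus.eta1.imag) > 0

    def test_c4_zero_degenerate(self):
        frame = WaveFrame(xi=0.0, zeta=1.0, Lambda1=1.0)
        coeffs = GEECoefficients(1.0, 0.0, -1.0, 0.0, 0.0)
        with pytest.raises(DegenerateAnsatzError):
            solve_eta(frame, Phis(1.0, 0.0), coeffs)
        minus, _ = solve_eta(frame, Phis(1.0, 0.0), coeffs, allow_degenerate=True)
        assert minus.eta1 == 0.0


class TestImpliedConstraints:
    def test_zero_cases(self):
        frame = WaveFrame(xi=0.0, zeta=1.0, Lambda1=1.0)
        from fanwave.engine import EtaPair

        eta = EtaPair(0.0, 1.0, -1)
        ic = implied_constraints(eta, frame, Phis(1.0, 0.0),
                                 GEECoefficients(0, 0, 0.0, 0, 1.0))
        assert ic.implied_phi3 == 0.0  # c2 = 0 and eta0 = 0
        ic = implied_constraints(eta, frame, Phis(1.0, 0.5),
                                 GEECoefficients(0, 0.0, 0.7, 0, 1.0))
        assert ic.constant_term_residual == 0.0  # c1 = 0 and eta0 = 0

    def test_phi3_zeroes_chi1_line(self):
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        coeffs = gee_from_riccati(1.0, 3.0, 1.0)
        phis = Phis(1.5, 0.7)
        minus, _ = solve_eta(frame, phis, coeffs)
        ic = implied_constraints(minus, frame, phis, coeffs)
        system = build_power_system(frame, Phis(1.5, 0.7, ic.implied_phi3), coeffs)
        vals = system.evaluate(minus)
        assert abs(vals[2]) < 1e-10  # chi^1 line
        assert abs(vals[3] - ic.constant_term_residual) < 1e-10  # chi^0 line


class TestCalibration:
    def test_root_zeroes_chi0(self):
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        # Case-3-like coefficients where the root is away from zero
        coeffs = GEECoefficients(0.0, 0.0, 1.0, -2.5, 1.2)
        phi1 = 1.5
        phi2 = consistent_phi2(frame, coeffs, phi1)
        phis = Phis(phi1, phi2)
        minus, _ = solve_eta(frame, phis, coeffs)
        ic = implied_constraints(minus, frame, phis, coeffs)
        assert abs(ic.constant_term_residual) < 1e-9

    def test_riccati_root_is_zero(self):
        # for squared-trinomial coefficients the chi^0 equation holds
        # automatically at Phi2 = 0 (2*rho*eta0 = mu*eta1 identity)
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        coeffs = gee_from_riccati(1.2, 3.1, 0.9)
        assert consistent_phi2(frame, coeffs, 2.0) == pytest.approx(0.0, abs=1e-9)

    def test_requires_real_amplitude(self):
        frame = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)
        coeffs = gee_from_riccati(1.0, 3.0, 1.0)
        with pytest.raises(ValueError, match="real amplitude"):
            consistent_phi2(frame, coeffs, -2.0)
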