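"""Derivation engine for the reduced traveling-wave ODE.

The traveling-wave substitution Theta(s,t) = Y(rho), rho = xi*s + zeta*t
turns the cubic field equation into

    (zeta^2 - xi^2*L1^2) Y'' - Phi1 Y^3 - Phi2 Y^2 - Phi3 Y = 0 .

Balancing Y'' against Y^3 gives ansatz order M = 1, so Y = eta0 + eta1*chi
with chi obeying the general elliptic equation.  Substituting and collecting
powers of chi yields four algebraic equations (the chi^3..chi^0 system).  The
published solution fixes (eta0, eta1) from the chi^3 and chi^2 equations
only; the chi^1 equation then determines Phi3 (made explicit here as
``implied_constraints``) and the chi^0 equation is an over-determination
whose residual is an audit quantity, never assumed zero.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass
from typing import Any

import numpy as np
import sympy as sp

from .auxiliary import GEECoefficients

__all__ = [
    "BalanceError",
    "DegenerateAnsatzError",
    "WaveFrame",
    "EtaPair",
    "PowerSystem",
    "ImpliedConstraints",
    "balance_order",
    "build_power_system",
    "solve_eta",
    "implied_constraints",
    "consistent_phi2",
]


class BalanceError(ValueError):
    """Homogeneous balance yields a non-integer ansatz order."""


class DegenerateAnsatzError(ValueError):
    """c4 = 0 forces eta1 = 0: the M = 1 ansatz collapses."""


def _sqrt(x):
    if isinstance(x, sp.Basic):
        return sp.sqrt(x)
    return cmath.sqrt(x)


def _is_symbolic(*vals) -> bool:
    return any(isinstance(v, sp.Basic) for v in vals)


@dataclass(frozen=True)
class WaveFrame:
    """Wave frame rho = xi*s + zeta*t together with the wave speed L1.

    ``delta_c`` = zeta^2 - xi^2*L1^2 multiplies Y'' in the reduced ODE and
    must be nonzero (the printed side condition).
    """

    xi: Any
    zeta: Any
    Lambda1: Any

    @property
    def delta_c(self):
        return self.zeta**2 - self.xi**2 * self.Lambda1**2

    def require_valid(self) -> None:
        dc = self.delta_c
        if not _is_symbolic(dc) and dc == 0:
            raise ValueError("zeta^2 - xi^2*Lambda1^2 must be nonzero")

    def rho(self, s, t):
        return self.xi * np.asarray(s) + self.zeta * np.asarray(t)


@dataclass(frozen=True)
class EtaPair:
    """Series coefficients of the M = 1 ansatz Y = eta0 + eta1*chi.

    ``branch`` is the sign of eta1 relative to the principal square root;
    ``is_complex`` flags a negative radicand (complex amplitude), which is
    legitimate for the complexiton families and propagated, not rejected.
    """

    eta0: complex
    eta1: complex
    branch: int
    is_complex: bool = False


@dataclass(frozen=True)
class ImpliedConstraints:
    implied_phi3: complex
    constant_term_residual: complex


_ETA0, _ETA1 = sp.symbols("eta0 eta1")


@dataclass(frozen=True)
class PowerSystem:
    """The chi^3..chi^0 coefficient system as sympy expressions in eta0, eta1."""

    eq3: sp.Expr
    eq2: sp.Expr
    eq1: sp.Expr
    eq0: sp.Expr

    @property
    def equations(self) -> tuple[sp.Expr, ...]:
        return (self.eq3, self.eq2, self.eq1, self.eq0)

    @property
    def symbols(self) -> tuple[sp.Symbol, sp.Symbol]:
        return (_ETA0, _ETA1)

    def evaluate(self, eta: EtaPair) -> tuple[complex, ...]:
        subs = {_ETA0: sp.sympify(eta.eta0), _ETA1: sp.sympify(eta.eta1)}
        return tuple(complex(sp.N(eq.subs(subs))) for eq in self.equations)

    def as_text(self) -> str:
        lines = []
        for power, eq in zip((3, 2, 1, 0), self.equations):
            lines.append(f"(chi)^{power}: {sp.sstr(sp.expand(eq))} = 0")
        return "\n".join(lines)


def balance_order(nonlinearity_degree: int, derivative_order: int) -> int:
    """Ansatz order from homogeneous balance.

    Matching the chi powers of the highest derivative (M + order) against the
    highest nonlinearity (degree*M) gives degree*M = M + order, i.e.
    M = order/(degree - 1); a non-integer M means the method is inapplicable
    as stated.
    """
    if nonlinearity_degree < 2 or derivative_order < 1:
        raise BalanceError(
            "balance requires nonlinearity degree >= 2 and derivative order >= 1"
        )
    num, den = derivative_order, nonlinearity_degree - 1
    if num % den:
        from math import gcd

        g = gcd(num, den)
        raise BalanceError(
            f"non-integer balance order M = {num // g}/{den // g}; "
            "method inapplicable"
        )
    return num // den


def build_power_system(frame: WaveFrame, phis, coeffs: GEECoefficients) -> PowerSystem:
    """The four chi-power equations of the M = 1 ansatz.

    Constructed term-for-term as published (after multiplying the ODE
    residual by 2); the test suite re-derives the same system independently
    by substituting the ansatz into the ODE with sympy.
    """
    frame.require_valid()
    dc = sp.sympify(frame.delta_c)
    p1, p2 = sp.sympify(phis.Phi1), sp.sympify(phis.Phi2)
    p3 = getattr(phis, "Phi3", None)
    p3 = sp.Symbol("Phi3") if p3 is None else sp.sympify(p3)
    c1, c2, c3, c4 = (sp.sympify(v) for v in (coeffs.c1, coeffs.c2, coeffs.c3, coeffs.c4))
    e0, e1 = _ETA0, _ETA1
    eq3 = 4 * dc * c4 * e1 - 2 * e1**3 * p1
    eq2 = 3 * dc * c3 * e1 - 6 * e0 * e1**2 * p1 - 2 * e1**2 * p2
    eq1 = 2 * dc * c2 * e1 - 2 * e1 * p3 - 6 * e0**2 * e1 * p1 - 4 * e0 * e1 * p2
    eq0 = dc * c1 * e1 - 2 * e0**3 * p1 - 2 * e0**2 * p2 - 2 * e0 * p3
    return PowerSystem(eq3, eq2, eq1, eq0)


def solve_eta(
    frame: WaveFrame,
    phis,
    coeffs: GEECoefficients,
    allow_degenerate: bool = False,
) -> tuple[EtaPair, EtaPair]:
    """Closed-form (eta0, eta1) branches annihilating the chi^3/chi^2 equations.

        eta1 = -/+ sqrt(2*(zeta^2 - xi^2*L1^2)*c4 / Phi1)
        eta0 = (3*(zeta^2 - xi^2*L1^2)*c3 - 2*eta1*Phi2) / (6*eta1*Phi1)

    Returns the (-sqrt, +sqrt) branch pair in the printed -/+ order.  A
    negative radicand yields a complex amplitude, returned flagged.  c4 = 0
    collapses the ansatz (chi^3 equation forces eta1 = 0): error unless
    ``allow_degenerate``, which returns the trivial flagged pair.
    """
    frame.require_valid()
    dc = frame.delta_c
    p1, p2 = phis.Phi1, phis.Phi2
    symbolic = _is_symbolic(dc, p1, p2, coeffs.c3, coeffs.c4)
    if not symbolic and p1 == 0:
        raise ZeroDivisionError("Phi1 = 0: eta1 undefined (flagged upstream)")
    if not symbolic and coeffs.c4 == 0:
        if not allow_degenerate:
            raise DegenerateAnsatzError(
                "c4 = 0 forces eta1 = 0; supply an explicit eta override "
                "to evaluate this formal limit"
            )
        zero = EtaPair(0.0, 0.0, -1, False)
        return zero, EtaPair(0.0, 0.0, +1, False)
    radicand = 2 * dc * coeffs.c4 / p1
    root = _sqrt(radicand)
    pairs = []
    for branch in (-1, +1):
        e1 = branch * root
        e0 = (3 * dc * coeffs.c3 - 2 * e1 * p2) / (6 * e1 * p1)
        if symbolic:
            pairs.append(EtaPair(sp.simplify(e0), sp.simplify(e1), branch, False))
        else:
            is_cx = abs(complex(radicand).imag) > 0 or complex(radicand).real < 0
            pairs.append(EtaPair(complex(e0), complex(e1), branch, is_cx))
    return tuple(pairs)


def implied_constraints(
    eta: EtaPair, frame: WaveFrame, phis, coeffs: GEECoefficients
) -> ImpliedConstraints:
    """What the chi^1 and chi^0 equations say once (eta0, eta1) are fixed.

    The chi^1 equation has the unique solution
    Phi3 = delta_c*c2 - 3*eta0^2*Phi1 - 2*eta0*Phi2; the chi^0 equation is
    then over-determined and its residual is reported, never assumed zero.
    """
    dc = frame.delta_c
    e0, e1 = eta.eta0, eta.eta1
    phi3 = dc * coeffs.c2 - 3 * e0**2 * phis.Phi1 - 2 * e0 * phis.Phi2
    res0 = (
        dc * coeffs.c1 * e1
        - 2 * e0**3 * phis.Phi1
        - 2 * e0**2 * phis.Phi2
        - 2 * e0 * phi3
    )
    if _is_symbolic(phi3, res0):
        return ImpliedConstraints(sp.simplify(phi3), sp.simplify(res0))
    return ImpliedConstraints(complex(phi3), complex(res0))


def _chi0_residual_of_phi2(phi2, frame, coeffs, phi1, branch):
    dc = frame.delta_c
    e1 = branch * cmath.sqrt(2 * dc * coeffs.c4 / phi1)
    e0 = (3 * dc * coeffs.c3 - 2 * e1 * phi2) / (6 * e1 * phi1)
    phi3 = dc * coeffs.c2 - 3 * e0**2 * phi1 - 2 * e0 * phi2
    return dc * coeffs.c1 * e1 - 2 * e0**3 * phi1 - 2 * e0**2 * phi2 - 2 * e0 * phi3


def consistent_phi2(
    frame: WaveFrame, coeffs: GEECoefficients, phi1: float, branch: int = -1
) -> float:
    """The real Phi2 making the chi^0 equation hold exactly.

    With eta1 fixed by the chi^3 equation and eta0, Phi3 by the chi^2/chi^1
    equations, the chi^0 residual is a cubic polynomial in the free model
    parameter Phi2 (Phi2 is proportional to the free transformation slope
    b0).  Its leading coefficient 2/(27*Phi1^2) never vanishes, so a real
    root always exists when the amplitude is real.  Deterministic tie-break:
    the real root of smallest magnitude (then the smaller value).
    """
    rad = 2 * frame.delta_c * coeffs.c4 / phi1
    if complex(rad).real <= 0 or abs(complex(rad).imag) > 1e-12:
        raise ValueError("consistent_phi2 requires a real amplitude (radicand > 0)")
    xs = np.array([0.0, 1.0, 2.0, 3.0])
    ys = np.array(
        [_chi0_residual_of_phi2(x, frame, coeffs, phi1, branch).real for x in xs]
    )
    poly = np.polyfit(xs, ys, 3)  # exact: the residual is a cubic in Phi2
    roots = np.roots(poly)
    real = sorted(
        (r.real for r in roots if abs(r.imag) < 1e-8 * max(1.0, abs(r))),
        key=lambda v: (abs(v), v),
    )
    if not real:  # pragma: no cover - odd-degree real cubic always has one
        raise RuntimeError("no real Phi2 root found")
    return float(real[0])
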