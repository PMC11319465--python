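"""Double-chain DNA lattice model: physical constants to PDE coefficients.

The model treats the two polynucleotide strands as elastic rods coupled by
hydrogen-bond "membranes".  Two fields describe the motion: Theta, the
difference of the longitudinal displacements of the two strands, and Xi, the
difference of their transverse displacements.  The coupled system

    Theta_tt - L1^2 Theta_ss = L2 Theta + L3 Theta Xi + L4 Theta^3 + L5 Theta Xi^2
    Xi_tt    - L6^2 Xi_ss    = L7 Xi + L8 Theta^2 + L9 Theta^2 Xi + L10 Xi^3 + L11

closes under the linear ansatz Xi = b0 Theta + b1 into a single cubic
Klein-Gordon-type equation

    Theta_tt - L1^2 Theta_ss = Phi1 Theta^3 + Phi2 Theta^2 + Phi3 Theta,

valid when b1 = h/sqrt(2) and Z = g.  This module maps the physical constants
(membrane height a0, strand separation h, membrane rigidity omega, thread
stress density g, Young modulus Z, cross-sectional area Gamma, mass density
Delta) to the Lambda and Phi coefficients.

Two corrections to the published coefficient table are applied and reported:
the undeclared symbols delta and y are read as Delta (the only density in the
model) and h (the only choice that closes the Phi3 composition); see
``ReducedCoefficients.diagnostics`` and the audit report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "DomainError",
    "PhysicalParams",
    "ModelCoefficients",
    "ReducedCoefficients",
    "compute_lambda",
    "compute_phi",
    "reduce_model",
    "reconstruct_transverse",
    "read_params",
    "coefficients_report",
]

SQRT2 = math.sqrt(2.0)


class DomainError(ValueError):
    """A physical parameter lies outside the model's domain."""


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants of the double-chain DNA lattice.

    Parameters
    ----------
    a0 : membrane height (length).
    h : separation of the two strands (length).
    omega : elastic membrane rigidity.
    g : stress density per thread.
    Z : Young modulus.
    Gamma : cross-sectional area.
    Delta : mass density.
    b0 : slope of the closing transformation Xi = b0*Theta + b1.
    b1 : intercept of the transformation; defaults to h/sqrt(2), the value
        forced by matching the two reduced equations.
    """

    a0: float
    h: float
    omega: float
    g: float
    Z: float
    Gamma: float
    Delta: float
    b0: float = 1.0
    b1: float | None = None

    def __post_init__(self) -> None:
        for name in ("a0", "h", "Gamma", "Delta"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if self.b1 is None:
            object.__setattr__(self, "b1", self.h / SQRT2)


@dataclass(frozen=True)
class ModelCoefficients:
    """The eleven Lambda coefficients of the coupled system plus kappa."""

    Lambda1: float
    Lambda2: float
    Lambda3: float
    Lambda4: float
    Lambda5: float
    Lambda6: float
    Lambda7: float
    Lambda8: float
    Lambda9: float
    Lambda10: float
    Lambda11: float
    kappa: float

    def as_dict(self) -> dict[str, float]:
        return {f"Lambda{i}": getattr(self, f"Lambda{i}") for i in range(1, 12)} | {
            "kappa": self.kappa
        }


@dataclass
class ReducedCoefficients:
    """Coefficients of the reduced cubic equation for Theta.

    ``diagnostics`` carries the printed closed forms alongside the
    composition-route values; the composition route is authoritative.
    """

    Phi1: float
    Phi2: float
    Phi3: float
    Lambda1: float
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def phi1_is_zero(self) -> bool:
        return self.Phi1 == 0.0


def compute_lambda(
    params: PhysicalParams, sign1: int = +1, sign6: int = +1
) -> ModelCoefficients:
    """Map physical constants to the Lambda coefficients.

    ``sign1`` and ``sign6`` pick the branches of the +/- signs carried by
    Lambda1 and Lambda6.  Lambda1 enters the reduced dynamics only through
    Lambda1**2, so the sign1 branch never changes a solution field.
    """
    if sign1 not in (+1, -1) or sign6 not in (+1, -1):
        raise DomainError("sign1 and sign6 must be +1 or -1")
    p = params
    a0, h, om, Ga, De = p.a0, p.h, p.omega, p.Gamma, p.Delta
    kappa = om * a0 / (De * Ga)
    L1 = sign1 * p.Z / De  # delta read as Delta
    L2 = -2.0 * om * (h - a0) / (De * Ga * h)  # y read as h, delta as Delta
    L3 = 2.0 * SQRT2 * om * a0 / (De * Ga * h**2)
    L4 = -2.0 * om * a0 / (De * Ga * h**2)
    L5 = 4.0 * om * a0 / (De * Ga * h**3)
    L6 = sign6 * p.g / De
    # Lambda7 is never printed; it is fixed by requiring the two reduced
    # equations to share the same linear coefficient: L7 + 3*L10*b1^2 =
    # L2 + b1*L3 + L5*b1^2 at b1 = h/sqrt(2), i.e. L7 = L2 - 2*kappa/h.
    L7 = L2 - 2.0 * kappa / h
    L8 = L3 / 2.0
    L11 = SQRT2 * om * (h - a0) / (De * Ga)
    return ModelCoefficients(L1, L2, L3, L4, L5, L6, L7, L8, L4, L5, L11, kappa)


def compute_phi(
    coeffs: ModelCoefficients, b0: float, h: float, a0: float
) -> ReducedCoefficients:
    """Reduce the coupled Lambda system to (Phi1, Phi2, Phi3).

    The composition route Phi1 = L4 + L5*b0^2, Phi2 = 2*L5*b0*b1 + L3*b0,
    Phi3 = L2 + b1*L3 + L5*b1^2 (with b1 = h/sqrt(2)) is authoritative.  The
    published closed forms are evaluated into ``diagnostics``; the printed
    Phi1 = kappa*(-2+4*b0^2)/h^3 is dimensionally inconsistent with the
    composition and the relative mismatch is reported, never silently used.
    """
    if h <= 0 or a0 <= 0:
        raise DomainError("h and a0 must be positive")
    b1 = h / SQRT2
    k = coeffs.kappa
    phi1 = coeffs.Lambda4 + coeffs.Lambda5 * b0**2
    phi2 = 2.0 * coeffs.Lambda5 * b0 * b1 + coeffs.Lambda3 * b0
    phi3 = coeffs.Lambda2 + b1 * coeffs.Lambda3 + coeffs.Lambda5 * b1**2
    printed = {
        "phi1_printed": k * (-2.0 + 4.0 * b0**2) / h**3,
        "phi2_printed": 6.0 * SQRT2 * b0 * k / h**2,
        "phi3_printed": -2.0 * k / a0 + 6.0 * k / h,
    }
    diag: dict[str, Any] = dict(printed)
    diag["corrections"] = ["delta -> Delta", "y -> h in Lambda2"]
    for name, comp, pr in (
        ("phi1", phi1, printed["phi1_printed"]),
        ("phi2", phi2, printed["phi2_printed"]),
        ("phi3", phi3, printed["phi3_printed"]),
    ):
        scale = max(abs(comp), abs(pr), 1e-300)
        diag[f"{name}_printed_mismatch"] = abs(comp - pr) / scale
    diag["phi1_zero"] = phi1 == 0.0
    return ReducedCoefficients(phi1, phi2, phi3, coeffs.Lambda1, diag)


def reduce_model(
    params: PhysicalParams, sign1: int = +1, sign6: int = +1
) -> ReducedCoefficients:
    """Full physical-parameters -> (Phi1, Phi2, Phi3) pipeline.

    Enforces the closure conditions b1 = h/sqrt(2) and Z = g required for the
    coupled system to collapse to a single equation.
    """
    if not math.isclose(params.Z, params.g, rel_tol=1e-12, abs_tol=1e-300):
        raise DomainError(f"reduction requires Z = g, got Z={params.Z}, g={params.g}")
    if not math.isclose(params.b1, params.h / SQRT2, rel_tol=1e-12):
        raise DomainError(
            f"reduction requires b1 = h/sqrt(2), got b1={params.b1}, h={params.h}"
        )
    lam = compute_lambda(params, sign1=sign1, sign6=sign6)
    return compute_phi(lam, params.b0, params.h, params.a0)


def reconstruct_transverse(theta, b0: float, b1: float, singular_mask=None):
    """Transverse field Xi = b0*Theta + b1, elementwise.

    Preserves any singularity mask: returns (Xi, mask) when a mask is given,
    else Xi alone.
    """
    xi = b0 * np.asarray(theta) + b1
    if singular_mask is not None:
        return xi, np.asarray(singular_mask, dtype=bool)
    return xi


_PARAM_KEYS = ("a0", "h", "omega", "g", "Z", "Gamma", "Delta", "b0", "b1")


def read_params(path) -> PhysicalParams:
    """Read PhysicalParams from a flat ``key = value`` text file.

    Lines starting with '#' and blank lines are ignored; keys must match the
    field names of :class:`PhysicalParams`.
    """
    values: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise DomainError(f"malformed config line: {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in _PARAM_KEYS:
                raise DomainError(f"unknown parameter key: {key!r}")
            values[key] = float(val)
    missing = [k for k in _PARAM_KEYS[:7] if k not in values]
    if missing:
        raise DomainError(f"missing required keys: {missing}")
    return PhysicalParams(**values)


def coefficients_report(
    params: PhysicalParams, sign1: int = +1, sign6: int = +1
) -> dict[str, Any]:
    """JSON-serializable coefficient report for a physical parameter set."""
    lam = compute_lambda(params, sign1=sign1, sign6=sign6)
    red = compute_phi(lam, params.b0, params.h, params.a0)
    return {
        "params": {k: getattr(params, k) for k in _PARAM_KEYS},
        "signs": {"sign1": sign1, "sign6": sign6},
        "lambda": lam.as_dict(),
        "phi": {"Phi1": red.Phi1, "Phi2": red.Phi2, "Phi3": red.Phi3},
        "diagnostics": red.diagnostics,
    }


def write_report(report: dict[str, Any], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
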