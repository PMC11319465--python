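"""Traveling-wave solution families of the double-chain DNA model.

Every family is Theta(s,t) = eta0 + eta1*chi(xi*s + zeta*t) with (eta0, eta1)
fixed by the power-system closed forms and chi one catalogued auxiliary
solution.  Families 1-62 are the Case 1-4 forms; families 63-94 are the
printed q -> 1 (hyperbolic) and q -> 0 (trigonometric) degenerations of the
sixteen Jacobi rows.  The registry records, per family, the auxiliary
selector or degeneration, the printed-typo corrections applied, and whether
the family is a formal limit whose amplitude collapses (c4 = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .auxiliary import (
    AuxParams,
    ChiSelector,
    ConstraintError,
    EvaluationError,
    GEECoefficients,
    eval_chi_grid,
    get_form,
    jef_degenerate,
    validate_aux,
)
from .engine import (
    DegenerateAnsatzError,
    EtaPair,
    ImpliedConstraints,
    WaveFrame,
    implied_constraints,
    solve_eta,
)

__all__ = [
    "FamilyEntry",
    "SolutionSpec",
    "ThetaSolution",
    "SolutionField",
    "FAMILIES",
    "family",
    "make_solution",
    "eval_grid",
    "validate_regime",
]


@dataclass(frozen=True)
class FamilyEntry:
    """One printed Theta family."""

    index: int
    case_id: int
    type_id: int
    chi_index: int
    label: str
    degenerate: bool = False
    limit_q: float | None = None
    parent_index: int | None = None
    notes: tuple[str, ...] = ()

    @property
    def selector(self) -> ChiSelector:
        return ChiSelector(self.case_id, self.type_id, self.chi_index)


def _build_families() -> dict[int, FamilyEntry]:
    fams: dict[int, FamilyEntry] = {}

    def add(entry: FamilyEntry) -> None:
        fams[entry.index] = entry

    # Case 1: indices 1-24 (type 1 hyperbolic, type 2 trigonometric)
    for i in range(1, 25):
        typ = 1 if i <= 12 else 2
        notes = ()
        if i == 1:
            notes = ("theta-1-duplication",)
        add(FamilyEntry(i, 1, typ, i, f"Theta_{{1,{typ},{i}}}", notes=notes))
    # Case 2: indices 25-36
    for i in range(25, 37):
        add(FamilyEntry(i, 2, 1, i - 24, f"Theta_{{2,1,{i}}}"))
    # Case 3: indices 37-46
    c3_types = [1, 2, 3, 4, 5, 5, 6, 6, 7, 7]
    for k, typ in enumerate(c3_types, start=1):
        i = 36 + k
        notes = ("theta-45-squared-factor",) if i == 45 else ()
        add(FamilyEntry(i, 3, typ, k, f"Theta_{{3,{typ},{i}}}", notes=notes))
    # Case 4: indices 47-62
    c4_types = [1, 1, 2, 3, 4, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
    for k, typ in enumerate(c4_types, start=1):
        i = 46 + k
        notes = ("theta-48-cn-over-cd",) if i == 48 else ()
        if i == 62:
            notes = ("table1-row16-function",)
        add(FamilyEntry(i, 4, typ, k, f"Theta_{{4,{typ},{i}}}", notes=notes))
    # Degenerations: 63-78 at q=1, 79-94 at q=0 (parents 47-62 in order)
    special = {
        72: ("degenerate-literal-limits",),
        78: ("degenerate-literal-limits",),
        94: ("degenerate-literal-limits",),
        80: ("degenerate-constant-factors",),
        82: ("degenerate-constant-factors",),
        86: ("degenerate-constant-factors",),
        93: ("minus-branch-identically-zero",),
    }
    for off, qlim in ((16, 1.0), (32, 0.0)):
        for k, typ in enumerate(c4_types, start=1):
            parent = 46 + k
            i = parent + off
            add(
                FamilyEntry(
                    i, 4, typ, k, f"Theta_{{4,{typ},{i}}}",
                    degenerate=True, limit_q=qlim, parent_index=parent,
                    notes=special.get(i, ()),
                )
            )
    return fams


FAMILIES: dict[int, FamilyEntry] = _build_families()


def family(index: int) -> FamilyEntry:
    try:
        return FAMILIES[index]
    except KeyError:
        raise ConstraintError(f"unknown family index {index}") from None


@dataclass(frozen=True)
class SolutionSpec:
    """Everything needed to instantiate one Theta family.

    ``branch`` is the -/+ sign of eta1 (printed upper sign = -1).
    ``eta_override`` supplies (eta0, eta1) explicitly for the formal-limit
    degenerate families whose c4 vanishes.  ``strict`` enforces the printed
    regime constraints; the figure captions violate several of them and are
    evaluated with strict=False in complex arithmetic.
    """

    family_index: int
    aux: AuxParams
    frame: WaveFrame
    phi1: float
    phi2: float
    branch: int = -1
    eta_override: tuple[complex, complex] | None = None
    phi3_override: float | None = None
    strict: bool = True

    @property
    def entry(self) -> FamilyEntry:
        return family(self.family_index)


def _spec_aux(spec: SolutionSpec) -> AuxParams:
    entry = spec.entry
    if entry.degenerate:
        return replace(spec.aux, q=entry.limit_q)
    return spec.aux


def validate_regime(spec: SolutionSpec) -> list[str]:
    """All violated printed constraints for this family (empty iff valid)."""
    entry = spec.entry
    aux = _spec_aux(spec)
    out = validate_aux(entry.selector, aux)
    dc = spec.frame.delta_c
    if dc == 0:
        out.append("zeta^2 - xi^2*Lambda1^2 != 0")
    if spec.phi1 == 0:
        out.append("Phi1 != 0")
    return out


@dataclass
class ThetaSolution:
    """Callable traveling-wave field Theta(s, t) with its derivation record."""

    spec: SolutionSpec
    entry: FamilyEntry
    coeffs: GEECoefficients
    eta: EtaPair
    implied: ImpliedConstraints
    phi3: complex
    chi_profile: Callable  # rho array -> (values, mask)
    regime_violations: list[str] = field(default_factory=list)
    degenerate_amplitude: bool = False

    def profile(self, rho_vals):
        """Y(rho) = eta0 + eta1*chi(rho) along the traveling coordinate."""
        chi, mask = self.chi_profile(np.asarray(rho_vals))
        vals = self.eta.eta0 + self.eta.eta1 * chi
        vals = np.where(mask, 0.0, vals)
        return vals, mask

    def __call__(self, s, t):
        rho = self.spec.frame.rho(s, t)
        return self.profile(rho)

    @property
    def pde_coefficients(self) -> dict[str, complex]:
        return {
            "Lambda1": self.spec.frame.Lambda1,
            "Phi1": self.spec.phi1,
            "Phi2": self.spec.phi2,
            "Phi3": self.phi3,
        }


def make_solution(spec: SolutionSpec) -> ThetaSolution:
    """Instantiate a family: regime check, eta pair, implied Phi3, closure.

    Regime violations surface here (ConstraintError) unless strict=False, in
    which case they are recorded on the returned solution.  Formal-limit
    families with c4 = 0 require ``eta_override``.
    """
    entry = spec.entry
    aux = _spec_aux(spec)
    violations = validate_regime(spec)
    if spec.strict and violations:
        raise ConstraintError(
            f"{entry.label}: violated constraints: {violations}"
        )
    form = get_form(entry.selector)
    coeffs = form.coefficients(aux)
    degenerate_amp = False
    if spec.eta_override is not None:
        eta = EtaPair(complex(spec.eta_override[0]), complex(spec.eta_override[1]),
                      spec.branch, False)
        degenerate_amp = coeffs.c4 == 0
    else:
        pair = solve_eta(spec.frame, _Phis(spec.phi1, spec.phi2), coeffs)
        eta = pair[0] if spec.branch == -1 else pair[1]
    implied = implied_constraints(eta, spec.frame, _Phis(spec.phi1, spec.phi2), coeffs)
    phi3 = spec.phi3_override if spec.phi3_override is not None else implied.implied_phi3

    if entry.degenerate:
        degen = jef_degenerate(entry.selector, replace(aux, q=entry.limit_q))
        chi_profile = degen
    else:
        def chi_profile(rho_vals, _sel=entry.selector, _aux=aux):
            return eval_chi_grid(_sel, _aux, rho_vals, strict=False)

    return ThetaSolution(
        spec, entry, coeffs, eta, implied, phi3, chi_profile,
        regime_violations=violations, degenerate_amplitude=degenerate_amp,
    )


@dataclass(frozen=True)
class _Phis:
    Phi1: float
    Phi2: float


@dataclass
class SolutionField:
    """Dense evaluation of Theta over an (s, t) grid.

    ``values[i, j]`` is Theta(s_axis[j], t_axis[i]); the singular mask marks
    flagged pole cells (values there are zeroed, never NaN).
    """

    s_axis: np.ndarray
    t_axis: np.ndarray
    values: np.ndarray
    singular_mask: np.ndarray
    spec: SolutionSpec

    @property
    def re(self) -> np.ndarray:
        return self.values.real

    @property
    def im(self) -> np.ndarray:
        return self.values.imag

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.values)

    def component(self, name: str) -> np.ndarray:
        try:
            return {"re": self.re, "im": self.im, "abs": self.modulus}[name]
        except KeyError:
            raise ValueError(f"component must be re|im|abs, got {name!r}") from None

    def to_tsv(self, path) -> None:
        """Delimited text export: header s, t, re, im, abs, singular."""
        S, T = np.meshgrid(self.s_axis, self.t_axis)
        cols = np.column_stack(
            [
                S.ravel(), T.ravel(),
                self.re.ravel(), self.im.ravel(), self.modulus.ravel(),
                self.singular_mask.ravel().astype(int),
            ]
        )
        header = "s\tt\tre\tim\tabs\tsingular"
        np.savetxt(path, cols, delimiter="\t", header=header, comments="")

    def spec_sidecar(self) -> dict:
        sp_ = self.spec
        aux = sp_.aux
        return {
            "family_index": sp_.family_index,
            "label": sp_.entry.label,
            "branch": sp_.branch,
            "frame": {"xi": sp_.frame.xi, "zeta": sp_.frame.zeta,
                      "Lambda1": sp_.frame.Lambda1},
            "phi1": sp_.phi1,
            "phi2": sp_.phi2,
            "aux": {
                "sigma": aux.sigma, "mu": aux.mu, "rho": aux.rho,
                "E": aux.E, "F": aux.F,
                "alpha": [aux.alpha1, aux.alpha2, aux.alpha3, aux.alpha4],
                "q": aux.q, "branch_signs": list(aux.branch_signs),
            },
            "strict": sp_.strict,
            "grid": {
                "s": [float(self.s_axis[0]), float(self.s_axis[-1]), len(self.s_axis)],
                "t": [float(self.t_axis[0]), float(self.t_axis[-1]), len(self.t_axis)],
            },
        }

    def to_json_sidecar(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.spec_sidecar(), fh, indent=2, sort_keys=True)


def eval_grid(
    spec: SolutionSpec,
    s_range: tuple[float, float] = (-10.0, 10.0),
    t_range: tuple[float, float] = (0.0, 10.0),
    ns: int = 201,
    nt: int = 101,
) -> SolutionField:
    """Evaluate a family densely on an (s, t) grid with singularity masking."""
    if ns < 2 or nt < 2:
        raise ValueError("ns and nt must be >= 2")
    sol = make_solution(spec)
    s_axis = np.linspace(s_range[0], s_range[1], ns)
    t_axis = np.linspace(t_range[0], t_range[1], nt)
    S, T = np.meshgrid(s_axis, t_axis)
    values, mask = sol(S, T)
    if mask.all():
        raise EvaluationError(f"{sol.entry.label}: grid is fully singular")
    return SolutionField(s_axis, t_axis, values, mask, spec)
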