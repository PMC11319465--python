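"""Audit engine: quantify how well every catalogued family solves the model.

Three layers of checking, symbolic where possible and numeric everywhere:

* auxiliary layer — does each chi satisfy its general elliptic equation
  (chi'^2 = sum c_k chi^k) with the module's own coefficients;
* algebraic layer — the chi^3/chi^2 equations vanish at the closed-form
  (eta0, eta1) (symbolic, once), the chi^1 equation fixes Phi3, and the
  chi^0 residual is recorded per family (the published solution leaves it
  unexamined; a nonzero value is a finding about the source, not a failure
  of this package);
* field layer — the closed-form ODE residual of Y(rho) and the
  finite-difference PDE residual of Theta(s,t), with an observed
  convergence order under grid halving (second-order differencing must
  show order ~2 whenever the family truly solves the ODE).

The audit is deterministic under a fixed seed and serializes to stable JSON
(byte-identical across re-runs) plus a CSV summary table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Any

import numpy as np
import pandas as pd
import sympy as sp
from scipy.ndimage import binary_dilation

from . import figures
from .auxiliary import (
    CORRECTIONS,
    AuxParams,
    EvaluationError,
    aux_ode_residual,
    gee_from_riccati,
    get_form,
    registry_manifest,
    table1_rows,
)
from .engine import (
    WaveFrame,
    build_power_system,
    consistent_phi2,
    implied_constraints,
    solve_eta,
)
from .solutions import FAMILIES, SolutionSpec, ThetaSolution, make_solution

__all__ = [
    "AuditConfig",
    "VerificationReport",
    "ode_residual",
    "pde_residual",
    "audit_catalogue",
    "default_spec",
]

# Tolerances: 1e-8 relative for analytic-route residuals, 1e-10 for pure
# algebraic identities; convergence-order acceptance band [1.7, 2.3]
# (double precision with trig/hyperbolic conditioning).
TOL_ANALYTIC = 1e-8
TOL_ALGEBRAIC = 1e-10
ORDER_BAND = (1.7, 2.3)


def _ser(x) -> Any:
    """JSON-stable serialization of numbers (complex -> [re, im])."""
    if isinstance(x, complex) or isinstance(x, np.complexfloating):
        return [float(np.real(x)), float(np.imag(x))]
    if isinstance(x, (np.floating, np.integer)):
        return float(x)
    return x


def ode_residual(spec_or_sol, points=None) -> dict[str, Any]:
    """Residual of the reduced ODE along rho, via two second-derivative routes.

    Route (a): Y'' = eta1*chi'' with chi'' = (1/2) d/dchi (sum c_k chi^k),
    an algebraic identity given the auxiliary equation.  Route (b): 5-point
    numerical second differencing of the profile.  Both are reported; route
    (a) vanishing (to 1e-10) certifies the family exactly solves the ODE
    with the recorded Phi3.
    """
    sol = spec_or_sol if isinstance(spec_or_sol, ThetaSolution) else make_solution(spec_or_sol)
    if points is None:
        lo, hi = profile_window(sol)
        points = np.linspace(lo, hi, 64)
    pts = np.asarray(points, dtype=float)
    dc = sol.spec.frame.delta_c
    p1, p2, p3 = sol.spec.phi1, sol.spec.phi2, sol.phi3

    chi, mask = sol.chi_profile(pts)
    y = sol.eta.eta0 + sol.eta.eta1 * chi
    nl = p1 * y**3 + p2 * y**2 + p3 * y
    scale = 1.0 + np.abs(nl)
    ypp_closed = sol.eta.eta1 * sol.coeffs.rhs_half_derivative(chi)
    res_closed = np.abs(dc * ypp_closed - nl) / scale

    h = 1e-4 * max(1.0, float(np.ptp(pts)) / 10.0)
    stencil = []
    for k in (-2, -1, 0, 1, 2):
        v, m = sol.profile(pts + k * h)
        mask = mask | m
        stencil.append(v)
    ypp_num = (
        -stencil[0] + 16 * stencil[1] - 30 * stencil[2] + 16 * stencil[3] - stencil[4]
    ) / (12 * h**2)
    res_num = np.abs(dc * ypp_num - nl) / scale

    keep = ~mask & (np.abs(y) < 1e4)
    if not np.any(keep):
        raise EvaluationError(f"{sol.entry.label}: all ODE sample points singular")
    return {
        "closed_max": float(np.max(res_closed[keep])),
        "closed_mean": float(np.mean(res_closed[keep])),
        "numeric_max": float(np.max(res_num[keep])),
        "numeric_mean": float(np.mean(res_num[keep])),
        "n_used": int(keep.sum()),
    }


def profile_window(sol: ThetaSolution, span: float = 12.0, n: int = 3001,
                   cap: float = 50.0) -> tuple[float, float]:
    """Largest pole-free, moderate-magnitude rho interval near the origin.

    Used to place finite-difference grids and morphology checks away from
    the poles of singular families; for pole-free profiles this is simply
    [-span, span] (slightly trimmed).
    """
    rho = np.linspace(-span, span, n)
    vals, mask = sol.profile(rho)
    scale = np.median(np.abs(vals[~mask])) if (~mask).any() else 1.0
    good = ~mask & (np.abs(vals) < max(cap, 10.0 * scale))
    best_len, best_start, cur_start = 0, 0, None
    for i, g in enumerate(np.append(good, False)):
        if g and cur_start is None:
            cur_start = i
        elif not g and cur_start is not None:
            if i - cur_start > best_len:
                best_len, best_start = i - cur_start, cur_start
            cur_start = None
    if best_len < 8:
        raise EvaluationError(f"{sol.entry.label}: no usable pole-free window")
    lo, hi = rho[best_start], rho[best_start + best_len - 1]
    pad = 0.08 * (hi - lo)
    return float(lo + pad), float(hi - pad)


def _grid_residual(sol: ThetaSolution, s_axis, t_axis):
    """Normalized PDE residual field on the grid interior.

    Returns (residual, valid) arrays of shape (nt-2, ns-2); valid excludes a
    2-cell margin around flagged singular cells.
    """
    S, T = np.meshgrid(s_axis, t_axis)
    theta, mask = sol(S, T)
    ds = s_axis[1] - s_axis[0]
    dt = t_axis[1] - t_axis[0]
    c = sol.pde_coefficients
    tt = (theta[2:, 1:-1] - 2 * theta[1:-1, 1:-1] + theta[:-2, 1:-1]) / dt**2
    ss = (theta[1:-1, 2:] - 2 * theta[1:-1, 1:-1] + theta[1:-1, :-2]) / ds**2
    th = theta[1:-1, 1:-1]
    res = tt - c["Lambda1"] ** 2 * ss - (
        c["Phi1"] * th**3 + c["Phi2"] * th**2 + c["Phi3"] * th
    )
    valid = ~binary_dilation(mask, iterations=2)[1:-1, 1:-1]
    if not valid.any():
        raise EvaluationError(f"{sol.entry.label}: PDE grid fully singular")
    return np.abs(res) / (1.0 + np.abs(th)), valid


def _variation_scale(sol: ThetaSolution, lo: float, hi: float):
    """Length scale of the profile's variation and its steepest location."""
    rho = np.linspace(lo, hi, 2001)
    vals, mask = sol.profile(rho)
    good = ~mask
    if good.sum() < 16:
        return None, 0.5 * (lo + hi)
    v, r = vals[good], rho[good]
    dv = np.gradient(v, r)
    m = float(np.max(np.abs(dv)))
    amp = float(np.max(np.abs(v - np.mean(v))))
    if m < 1e-12 or amp < 1e-12:
        return None, 0.5 * (lo + hi)  # effectively constant
    return amp / m, float(r[np.argmax(np.abs(dv))])


def pde_residual(
    spec_or_sol,
    base_ns: int = 129,
    base_nt: int = 13,
    window: tuple[float, float] | None = None,
) -> dict[str, Any]:
    """Finite-difference residual of the full field equation, two resolutions.

    The grid is placed inside a pole-free window of the traveling coordinate
    and sized to the profile's measured variation scale so the coarse grid
    already resolves it with >= 16 points per unit of rho variation.
    Halving the steps must reduce the residual ~4x (observed order ~2) for
    families that exactly solve the reduced ODE; the order is reported only
    when both grids are >= 90% non-singular, and compared at shared nodes.
    """
    sol = spec_or_sol if isinstance(spec_or_sol, ThetaSolution) else make_solution(spec_or_sol)
    fr = sol.spec.frame
    xi, zeta = float(fr.xi), float(fr.zeta)
    if xi == 0:
        raise EvaluationError("PDE grid placement requires xi != 0")
    lo, hi = window if window is not None else profile_window(sol)
    sc, rho_star = _variation_scale(sol, lo, hi)
    if sc is not None:
        half = 4.0 * sc
        glo, ghi = max(lo, rho_star - half), min(hi, rho_star + half)
        if ghi - glo < 4.0 * sc:  # window clipped; recenter as well as possible
            glo, ghi = max(lo, ghi - 2 * half), ghi
        lo, hi = glo, ghi
    L = hi - lo
    t_span = min(0.75 * (sc or L), 0.15 * L) / abs(zeta) if zeta != 0 else 0.15 * L
    s_lo, s_hi = sorted(((lo + 0.02 * L) / xi, (lo + 0.83 * L) / xi))
    out: dict[str, Any] = {"window": [lo, hi]}
    fields = []
    for ref in (1, 2):
        ns = (base_ns - 1) * ref + 1
        nt = (base_nt - 1) * ref + 1
        s_axis = np.linspace(s_lo, s_hi, ns)
        t_axis = np.linspace(0.0, t_span, nt)
        res, valid = _grid_residual(sol, s_axis, t_axis)
        fields.append((res, valid))
        key = "coarse" if ref == 1 else "fine"
        out[key] = {
            "max": float(np.max(res[valid])),
            "mean": float(np.mean(res[valid])),
            "frac_ok": float(valid.mean()),
        }
    # order estimate at shared nodes: the 2x-refined grid contains every
    # coarse node, so the ratio is a clean h^2 comparison point-by-point
    res_c, val_c = fields[0]
    res_f, val_f = fields[1]
    res_f_at_c = res_f[1::2, 1::2]
    val_common = val_c & val_f[1::2, 1::2]
    out["order"] = None
    out["residual_below_roundoff"] = False
    if out["coarse"]["frac_ok"] >= 0.9 and out["fine"]["frac_ok"] >= 0.9:
        rc = float(np.max(res_c[val_common])) if val_common.any() else 0.0
        rf = float(np.max(res_f_at_c[val_common])) if val_common.any() else 0.0
        if rc < 1e-12 and rf < 1e-12:
            # exact (e.g. constant) solution: residual is pure roundoff
            out["residual_below_roundoff"] = True
        elif rf > 0:
            out["order"] = float(np.log2(rc / rf))
    return out


# --------------------------------------------------------------- audit


@dataclass(frozen=True)
class AuditConfig:
    """Parameter draws and grid sizes for the catalogue audit."""

    seed: int = 0
    n_draws: int = 1  # parameter draws per family in the family table
    aux_points: int = 50
    pde_base_ns: int = 81
    pde_base_nt: int = 13
    include_pde: bool = True
    families: tuple[int, ...] | None = None


_DEF_FRAME = WaveFrame(xi=1.0, zeta=2.0, Lambda1=1.0)


def _draw_aux(entry, rng: np.random.Generator) -> AuxParams:
    """One regime-valid auxiliary parameter draw for a family."""
    case = entry.case_id
    if case == 1 and entry.type_id == 1:
        return AuxParams(sigma=1.0, mu=float(rng.uniform(2.2, 3.5)), rho=1.0,
                         E=3.0, F=5.0)
    if case == 1:
        mu = float(rng.uniform(0.3, 1.2)) * (1 if rng.random() < 0.5 else -1)
        return AuxParams(sigma=1.0, mu=mu, rho=1.0, E=5.0, F=3.0)
    if case == 2:
        return AuxParams(sigma=1.0, mu=0.0, rho=-float(rng.uniform(0.5, 2.0)),
                         E=3.0, F=5.0)
    if case == 3:
        for _ in range(64):
            p = AuxParams(
                alpha1=float(rng.uniform(0.8, 1.5)),
                alpha2=float(rng.uniform(0.5, 1.0)),
                alpha3=float(rng.uniform(1.5, 2.5)),
                alpha4=float(rng.uniform(0.3, 0.8)),
            )
            c = get_form(entry.selector).coefficients(p)
            if abs(c.c4) > 1e-3:
                return p
        raise RuntimeError("could not draw valid Case-3 parameters")
    # Case 4 rows (and their degenerations, which override q)
    return AuxParams(q=0.6, branch_signs=(1,))


def default_spec(
    family_index: int, rng: np.random.Generator | None = None,
    calibrated: bool = True, frame: WaveFrame = _DEF_FRAME,
) -> SolutionSpec:
    """Audit parameter set for one family: figure caption if a published one exists
    one, else a seeded regime-valid draw.

    Phi1's sign is chosen so the amplitude radicand 2*delta_c*c4/Phi1 is
    positive (a real amplitude, as in all published figures); with
    ``calibrated`` the free Phi2 is set to the real root that makes the
    chi^0 equation hold exactly (see the methods note).
    """
    entry = FAMILIES[family_index]
    rng = rng or np.random.default_rng(0)
    fig_id = figures.FAMILY_TO_FIGURE.get(family_index)
    if fig_id is not None and not calibrated:
        return figures.figure_config(fig_id).to_spec()
    aux = _draw_aux(entry, rng)
    if entry.degenerate:
        aux = replace(aux, q=entry.limit_q)
    coeffs = get_form(entry.selector).coefficients(aux)
    dc = frame.delta_c
    c4 = complex(coeffs.c4).real
    phi1 = 1.5 if dc * c4 > 0 else -1.5
    if c4 == 0:
        # formal-limit family: amplitude collapses; supply an explicit pair
        return SolutionSpec(family_index, aux, frame, phi1, 0.8,
                            eta_override=(0.1, 0.5), strict=False)
    phi2 = consistent_phi2(frame, coeffs, phi1) if calibrated else 0.8
    return SolutionSpec(family_index, aux, frame, phi1, float(phi2), strict=False)


def _symbolic_block() -> dict[str, Any]:
    """One-off symbolic certificates: printed system re-derived from the ODE,
    and the closed-form eta pair annihilating the chi^3/chi^2 equations."""
    from types import SimpleNamespace

    zeta, xi, L1, P1, P2, P3 = sp.symbols("zeta xi Lambda1 Phi1 Phi2 Phi3", positive=True)
    c1, c2, c3, c4 = sp.symbols("c1 c2 c3 c4")
    frame = WaveFrame(xi, zeta, L1)
    from .auxiliary import GEECoefficients
    from .solutions import _Phis

    coeffs = GEECoefficients(sp.Symbol("c0"), c1, c2, c3, c4)
    system = build_power_system(frame, SimpleNamespace(Phi1=P1, Phi2=P2, Phi3=P3), coeffs)
    e0, e1 = system.symbols
    # independent derivation: substitute the ansatz into the ODE
    chi = sp.Function("chi")
    r = sp.Symbol("varrho")
    quartic = coeffs.c0 + c1 * chi(r) + c2 * chi(r) ** 2 + c3 * chi(r) ** 3 + c4 * chi(r) ** 4
    y = e0 + e1 * chi(r)
    ode = frame.delta_c * sp.diff(y, r, 2) - P1 * y**3 - P2 * y**2 - P3 * y
    chi2nd = sp.Rational(1, 2) * sp.diff(quartic, chi(r))
    ode = ode.subs(sp.Derivative(chi(r), (r, 2)), chi2nd)
    derived = sp.Poly(sp.expand(2 * ode), chi(r)).all_coeffs()[::-1]  # chi^0..chi^3
    match = all(
        sp.simplify(d - printed) == 0
        for d, printed in zip(derived, [system.eq0, system.eq1, system.eq2, system.eq3])
    )
    pair = solve_eta(frame, _Phis(P1, P2), coeffs)
    annihilate = all(
        sp.simplify(eq.subs({e0: p.eta0, e1: p.eta1})) == 0
        for p in pair
        for eq in (system.eq3, system.eq2)
    )
    return {
        "system_matches_derivation": bool(match),
        "eta_annihilates_chi3_chi2": bool(annihilate),
    }


def _family_record(entry, cfg: AuditConfig, rng) -> dict[str, Any]:
    rec: dict[str, Any] = {
        "family": entry.index,
        "label": entry.label,
        "case": entry.case_id,
        "type": entry.type_id,
        "degenerate_form": entry.degenerate,
        "corrections": sorted(
            set(entry.notes) | set(get_form(entry.selector).corrections)
        ),
    }
    spec = default_spec(entry.index, rng, calibrated=True)
    rec["params"] = {
        "sigma": spec.aux.sigma, "mu": spec.aux.mu, "rho": spec.aux.rho,
        "E": spec.aux.E, "F": spec.aux.F,
        "alpha": [spec.aux.alpha1, spec.aux.alpha2, spec.aux.alpha3, spec.aux.alpha4],
        "q": spec.aux.q, "phi1": spec.phi1, "phi2": spec.phi2,
    }
    sol = make_solution(spec)
    rec["regime_violations"] = sol.regime_violations
    rec["degenerate_amplitude"] = sol.degenerate_amplitude or spec.eta_override is not None

    # auxiliary-ODE residual (via the parent row at the limit q for the
    # degenerate forms; the degeneration tests certify pointwise agreement)
    try:
        lo, hi = profile_window(sol)
        pts = np.linspace(lo, hi, cfg.aux_points)
        aux_res = aux_ode_residual(entry.selector, _spec_aux_of(spec), sample_points=pts,
                                   strict=False)
        rec["aux_residual"] = {"max": aux_res.max, "mean": aux_res.mean,
                               "scheme": aux_res.scheme, "n_used": aux_res.n_used}
    except EvaluationError as exc:
        rec["aux_residual"] = {"error": str(exc)}

    rec["eta0"] = _ser(sol.eta.eta0)
    rec["eta1"] = _ser(sol.eta.eta1)
    rec["eta1_complex"] = sol.eta.is_complex
    rec["implied_phi3"] = _ser(sol.implied.implied_phi3)
    chi0 = complex(sol.implied.constant_term_residual)
    dc = spec.frame.delta_c
    chi0_scale = 1.0 + abs(dc) * abs(complex(sol.coeffs.c1)) * abs(complex(sol.eta.eta1))
    rec["chi0_residual"] = _ser(chi0)
    rec["chi0_pass"] = bool(abs(chi0) / chi0_scale < TOL_ALGEBRAIC) and not rec[
        "degenerate_amplitude"
    ]
    try:
        rec["ode"] = ode_residual(sol)
    except EvaluationError as exc:
        rec["ode"] = {"error": str(exc)}
    if cfg.include_pde and rec["chi0_pass"]:
        try:
            rec["pde"] = pde_residual(sol, cfg.pde_base_ns, cfg.pde_base_nt)
        except EvaluationError as exc:
            rec["pde"] = {"error": str(exc)}
    return rec


def _spec_aux_of(spec: SolutionSpec) -> AuxParams:
    entry = spec.entry
    if entry.degenerate:
        return replace(spec.aux, q=entry.limit_q)
    return spec.aux


def _figures_block() -> dict[str, Any]:
    out = {}
    for fig_id in figures.FIGURE_IDS:
        out[str(fig_id)] = figures.check_figure(fig_id)
    return out


def _c0_literal_demo() -> dict[str, Any]:
    """Evaluate the auxiliary residual under both c0 = sigma^2 and the
    printed sigma^3 for a sigma != 1 draw (audit of the misprint)."""
    from .auxiliary import ChiSelector

    sel = ChiSelector(1, 1, 1)
    p = AuxParams(sigma=2.0, mu=4.5, rho=1.0)
    pts = np.linspace(-3, 3, 40)
    corrected = aux_ode_residual(sel, p, sample_points=pts)
    literal = aux_ode_residual(
        sel, p, coeffs=gee_from_riccati(p.sigma, p.mu, p.rho, printed_literal=True),
        sample_points=pts,
    )
    return {
        "sigma": p.sigma,
        "residual_c0_sigma2": corrected.max,
        "residual_c0_sigma3_printed": literal.max,
    }


@dataclass
class VerificationReport:
    """Full audit result; serializes to stable JSON and a CSV summary."""

    payload: dict[str, Any]

    def to_json(self, path=None) -> str:
        text = json.dumps(self.payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "VerificationReport":
        return cls(json.loads(text))

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.payload["families"]:
            aux = rec.get("aux_residual", {})
            ode = rec.get("ode", {})
            pde = rec.get("pde", {})
            rows.append(
                {
                    "family": rec["family"],
                    "label": rec["label"],
                    "case": rec["case"],
                    "degenerate_form": rec["degenerate_form"],
                    "degenerate_amplitude": rec["degenerate_amplitude"],
                    "aux_residual_max": aux.get("max"),
                    "chi0_pass": rec["chi0_pass"],
                    "ode_closed_max": ode.get("closed_max"),
                    "pde_order": pde.get("order"),
                    "corrections": ";".join(rec["corrections"]),
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)


def audit_catalogue(config: AuditConfig | None = None) -> VerificationReport:
    """Run the full catalogue audit (every registry family exactly once)."""
    cfg = config or AuditConfig()
    rng = np.random.default_rng(cfg.seed)
    indices = cfg.families or tuple(sorted(FAMILIES))
    families = [_family_record(FAMILIES[i], cfg, rng) for i in indices]
    payload = {
        "schema_version": 1,
        "seed": cfg.seed,
        "symbolic": _symbolic_block(),
        "families": families,
        "figures": _figures_block(),
        "corrections_applied": CORRECTIONS,
        "c0_sigma_audit": _c0_literal_demo(),
        "table1_rows": table1_rows(),
        "registry": {
            "n_families": len(FAMILIES),
            "n_degenerate": sum(1 for f in FAMILIES.values() if f.degenerate),
            "chi_manifest": registry_manifest()["per_case"],
        },
    }
    return VerificationReport(payload)
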