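# fanwave

Traveling-wave solutions of the double-chain DNA model via the modified
extended Fan sub-equation method — with a verification audit that checks
every catalogued solution against the equations it claims to solve.

## The problem

The double helix can be modeled as two long elastic rods (the
polynucleotide strands) coupled by elastic "membranes" (the hydrogen-bonded
base pairs).  Writing Θ(s,t) for the difference of the strands' longitudinal
displacements and Ξ(s,t) for the difference of their transverse
displacements, the dynamics close into the coupled system

    Θ_tt − Λ₁²Θ_ss = Λ₂Θ + Λ₃ΘΞ + Λ₄Θ³ + Λ₅ΘΞ²
    Ξ_tt − Λ₆²Ξ_ss = Λ₇Ξ + Λ₈Θ² + Λ₉Θ²Ξ + Λ₁₀Ξ³ + Λ₁₁

with Λ's fixed by the lattice constants (membrane height a₀, strand
separation h, rigidity ω, stress density g, Young modulus Z, cross-section
Γ, mass density Δ).  Under the linear ansatz Ξ = b₀Θ + b₁ with b₁ = h/√2 and
Z = g, the system collapses to a single cubic Klein–Gordon-type equation

    Θ_tt − Λ₁²Θ_ss = Φ₁Θ³ + Φ₂Θ² + Φ₃Θ .

The traveling-wave substitution Θ(s,t) = Υ(ϱ), ϱ = ξs + ζt reduces this to
an ODE; homogeneous balance gives ansatz order M = 1, so Υ = η₀ + η₁χ(ϱ)
where χ solves the general elliptic equation χ′² = c₀ + c₁χ + c₂χ² + c₃χ³ +
c₄χ⁴.  Collecting powers of χ yields four algebraic equations; the χ³ and χ²
equations give

    η₁ = ∓√(2(ζ² − ξ²Λ₁²)c₄/Φ₁),   η₀ = (3(ζ² − ξ²Λ₁²)c₃ − 2η₁Φ₂)/(6η₁Φ₁) .

Specializations of (c₀…c₄) — generalized Riccati, cubic–quartic, Jacobi
elliptic, Weierstrass — generate 94 closed-form solution families: kinks,
dark/anti-bell solitons, singular waves, complexitons, and Jacobi-elliptic
waves with their hyperbolic (q→1) and trigonometric (q→0) degenerations.

The package provides, for whoever wants to use or scrutinize these
solutions:

* `fanwave.model` — physical constants → Λ's → (Φ₁, Φ₂, Φ₃), with the
  printed-vs-derived closed forms cross-checked;
* `fanwave.auxiliary` — all 63 auxiliary functions χ with regime guards,
  coefficient maps, singularity masking, and an auxiliary-ODE residual
  checker (known misprints corrected and recorded, never silently);
* `fanwave.engine` — balance order, the χ-power algebraic system, the
  closed-form (η₀, η₁), and the constraints the closed forms leave implicit:
  the χ¹ equation fixes Φ₃, and the χ⁰ equation over-determines the system —
  its residual is an audit quantity;
* `fanwave.solutions` — the 94 Θ families evaluated on (s,t) grids with
  singularity masks and text export;
* `fanwave.verify` — the audit engine (symbolic certificates, closed-form and
  finite-difference residuals, convergence orders, JSON/CSV reports);
* `fanwave.figures` + a `fanwave` CLI — the eight published parameter sets
  and morphology checks (kink monotone front, dark-soliton trough).

## Worked example

```python
from fanwave import (PhysicalParams, compute_lambda, compute_phi, AuxParams,
                     WaveFrame, SolutionSpec, make_solution,
                     ode_residual, pde_residual)

p = PhysicalParams(a0=1.0, h=1.0, omega=1.0, g=1.0, Z=1.0,
                   Gamma=1.0, Delta=1.0, b0=1.0)
lam = compute_lambda(p)
red = compute_phi(lam, p.b0, p.h, p.a0)
print(f"Phi1 = {red.Phi1:.4f}, Phi2 = {red.Phi2:.4f}, Phi3 = {red.Phi3:.4f}")

spec = SolutionSpec(                      # the published kink configuration
    family_index=1,
    aux=AuxParams(sigma=1.0, mu=1.0, rho=0.01),
    frame=WaveFrame(xi=1.0, zeta=4.0, Lambda1=1.0),
    phi1=1.0, phi2=1.0,
)
sol = make_solution(spec)
print(f"eta1 = {sol.eta.eta1.real:+.6f}, eta0 = {sol.eta.eta0.real:+.6f}")
print(f"chi^0 residual = {abs(sol.implied.constant_term_residual):.3e}")
print(f"ODE residual (closed form) = {ode_residual(sol)['closed_max']:.3e}")
```

prints

```
Phi1 = 2.0000, Phi2 = 8.4853, Phi3 = 4.0000
eta1 = -0.054772, eta0 = -3.071946
chi^0 residual = 4.726e+00
ODE residual (closed form) = 2.117e+00
```

Reading the numbers: the unit lattice gives the reduced cubic/quadratic/
linear coefficients (2, 6√2, 4).  The kink configuration's amplitude and
offset follow the closed forms (η₁ = −√0.003), **but** with the published
Φ₂ = 1 the constant-term (χ⁰) equation of the power system is violated by
4.7, and the solution correspondingly fails the reduced ODE with residual
≈ 2 — the published closed forms satisfy only two of the four algebraic
equations.  The χ⁰ equation is a genuine extra constraint; solving it for
the free parameter Φ₂ repairs the family:

```python
from fanwave import consistent_phi2, gee_from_riccati
import dataclasses

phi2 = consistent_phi2(spec.frame, gee_from_riccati(1.0, 1.0, 0.01), phi1=1.0)
sol = make_solution(dataclasses.replace(spec, phi2=phi2))
print(f"consistent Phi2 = {phi2:.6f}")
print(f"ODE residual (closed form) = {ode_residual(sol)['closed_max']:.3e}")
print(f"chi^0 residual = {abs(sol.implied.constant_term_residual):.3e}")
conv = pde_residual(sol)
print(f"PDE residual: coarse {conv['coarse']['max']:.3e}, "
      f"fine {conv['fine']['max']:.3e}, observed order {conv['order']:.3f}")
```

```
consistent Phi2 = 0.000000
ODE residual (closed form) = 2.625e-14
chi^0 residual = 0.000e+00
PDE residual: coarse 6.724e-03, fine 1.683e-03, observed order 1.998
```

For Riccati-type coefficients the consistent Φ₂ is exactly 0 (the identity
2ρη₀ = μη₁ makes the χ⁰ equation collapse); the repaired family then solves
the reduced ODE to machine precision and the full field equation at the
expected second order of the finite-difference check.

## Command line

```
fanwave list                              # 94 families + 32 degenerate forms
fanwave figure --id 2 --out out/          # reproduce a published configuration
fanwave eval --case 1 --type 1 --index 1 --param mu=1 --param rho=0.01 \
        --param zeta=4 --out out/         # evaluate a family on a grid
fanwave verify --suite all --seed 7 --out report/   # full audit
```

## The acceptance script

`scripts/acceptance.py` re-runs the package's whole pipeline from scratch:
the symbolic certificates (the χ-power system re-derived from the ODE, the
closed-form η pair annihilating the χ³/χ² equations), the auxiliary-ODE
residuals of every catalogued χ, the per-family closed-form and
finite-difference residuals with convergence orders, and the eight figure
reproductions.  Run it as

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes the target report to `--out` and the full audit record
(`audit.json`, `audit_summary.csv`) alongside it.

## Fidelity notes

The printed source formulas contain a number of typos (a misprinted
coefficient c₀ = σ³ where the squared-trinomial expansion forces σ²,
sign/argument slips in several χ forms, garbled Jacobi-table rows).  Every
deviation from the printed text is derived from an independent oracle
(symbolic expansion, classical function identities, polynomial fits of
χ′² against χ), applied minimally, and recorded in
`fanwave.auxiliary.CORRECTIONS`, which the audit report embeds verbatim.
The `docs/methods.md` note states the model, the derivation, the numerical
choices and the known limitations.
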