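# Methods

## Model and scope

The package treats the double-strand DNA lattice as two elastic rods coupled
by elastic membranes.  The fields are the strand-difference displacements:
longitudinal Θ(s,t) and transverse Ξ(s,t).  All physics enters through the
constants a₀ (membrane height), h (strand separation), ω (membrane
rigidity), g (stress density per thread), Z (Young modulus), Γ
(cross-sectional area) and Δ (mass density); the package does not fit these
to experimental data and performs no dimensional analysis.  The derived
scale κ = ωa₀/(ΔΓ) carries the units of all membrane-induced coefficients.

Two symbols in the published coefficient table are undeclared; the package
reads them as follows and records the substitution in every report:

* δ ≡ Δ — the only density in the model;
* y ≡ h in Λ₂ — the unique reading for which the composition
  Φ₃ = Λ₂ + b₁Λ₃ + Λ₅b₁² reproduces the closed form −2κ/a₀ + 6κ/h exactly
  (with Λ₂ = −2κ/a₀ + 2κ/h and the "+" branch of Λ₂'s printed ±).

Λ₇ is used by the transverse equation but never printed.  It is fixed by
requiring the two reduced equations to agree in their linear coefficient
under Ξ = b₀Θ + b₁, b₁ = h/√2, Z = g; this gives Λ₇ = Λ₂ − 2κ/h (which
vanishes with ω, consistent with every other membrane coefficient).

The printed closed form Φ₁ = κ(−2 + 4b₀²)/h³ is dimensionally inconsistent
with the composition Λ₄ + Λ₅b₀² = −2κ/h² + 4κb₀²/h³ (they agree only at
h = 1).  The composition route is authoritative; the printed value is
evaluated into `ReducedCoefficients.diagnostics` with its relative mismatch,
never used.

## The method

With Θ(s,t) = Υ(ϱ), ϱ = ξs + ζt, the field equation becomes

    Δ_c Υ″ − Φ₁Υ³ − Φ₂Υ² − Φ₃Υ = 0,   Δ_c = ζ² − ξ²Λ₁² ≠ 0 .

Balancing the derivative term (χ-power M+2) against the cubic (3M) gives
M = 1 (`balance_order` errors on non-integer orders, where the method is
inapplicable as stated).  Substituting Υ = η₀ + η₁χ and the auxiliary
equation χ′² = Σcₖχᵏ (hence χ″ = ½ d/dχ Σcₖχᵏ), then collecting χ powers,
yields four algebraic equations.  `build_power_system` constructs them
term-for-term as published; the test suite re-derives them independently by
symbolic substitution and certifies equality.

The published solution solves only the χ³ and χ² equations:

    η₁ = ∓√(2Δ_c c₄/Φ₁),   η₀ = (3Δ_c c₃ − 2η₁Φ₂)/(6η₁Φ₁) .

The remaining two equations are handled explicitly here:

* the χ¹ equation is linear in Φ₃ with the unique solution
  Φ₃ = Δ_c c₂ − 3η₀²Φ₁ − 2η₀Φ₂ (`implied_constraints`).  This is consistent
  with the published figure captions, which list Φ₁ and Φ₂ but never Φ₃;
* the χ⁰ equation is then an over-determination.  Its residual
  R₀ = Δ_c c₁η₁ − 2η₀³Φ₁ − 2η₀²Φ₂ − 2η₀Φ₃ is reported per family, never
  assumed zero.  A nonzero R₀ means the published family does not solve the
  reduced ODE (the closed-form ODE residual is exactly |R₀|/2 pointwise).

**Consistency calibration.**  R₀ is a cubic polynomial in the free parameter
Φ₂ (Φ₂ ∝ b₀, the free transformation slope) with leading coefficient
2/(27Φ₁²) ≠ 0, so a real root always exists when the amplitude is real.
`consistent_phi2` returns it (smallest-magnitude real root; deterministic).
For squared-trinomial (Riccati) coefficients the root is identically 0:
with Φ₂ = 0 one has 2η₀²Φ₁ = Δ_c μ² and 2ρη₀ = μη₁, which collapse R₀ — so
every Case 1/2 family genuinely solves all four equations at Φ₂ = 0, and
likewise Case 4 (where c₁ = c₃ = 0 give η₀ = 0 at Φ₂ = 0).  Case-3 roots
are generically nonzero.  The audit evaluates every family at its calibrated
Φ₂; families that then satisfy χ⁰ are the exhibits for the
residual/convergence chain below.

**Amplitude realness.**  The audit chooses sign(Φ₁) = sign(Δ_c c₄) so that
the radicand of η₁ is positive, as in all published figures.  A negative
radicand is not an error: the complex amplitude is propagated with a flag
(the catalogue contains explicitly complex "complexiton" families), but no
real Φ₂ can then zero the complex-valued R₀.

## Auxiliary catalogue

All 63 catalogued χ forms are implemented in complex arithmetic over a real
traveling coordinate: Cases 1–3 accept complex ϱ (they are compositions of
entire functions and divisions), Jacobi and Weierstrass forms require real
ϱ.  Regime constraints (μ² − 4ρσ sign, ρσ < 0, F² − E² > 0, 0 ≤ q ≤ 1,
c₃ > 0) are checked by name; violations raise listing the violated printed
inequality, or are recorded when evaluation is non-strict.

*Singularity policy.*  A point is flagged singular when any composing
denominator magnitude falls below 1e−10, or the value is non-finite or
exceeds 1e8.  The flag propagates through every operation; masked values are
zeroed, never NaN.

*Jacobi convention.*  The table's modulus q is the classical modulus k; the
scipy evaluator takes the parameter m = q².  This convention is forced by
the table itself: the sn row prints c₄ = q², and sn's quartic coefficient is
the parameter m.  The published "r" letter is the standard "s" (rn ≡ sn,
nr ≡ ns, cr ≡ cs, rd ≡ sd, …); degenerations are applied letterwise from the
q→1 (hyperbolic) and q→0 (trigonometric) tables.

*Case-4 coefficients.*  The (c₀, c₂, c₄) triple of each row is derived from
the row's actual function via the classical identities (e.g. cn′² =
(1 − cn²)(1 − q² + q²cn²)); the printed triples are retained for comparison
and the audit records the mismatches (row 1's triple, and c₀ of the ns±ds
row where the print has q²/4 for the correct q⁴/4).

*Weierstrass case.*  ℘(z; g₂, g₃) is evaluated through the root formula
℘ = e₃ + (e₁−e₃)/sn²(z√(e₁−e₃), m), m = (e₂−e₃)/(e₁−e₃), with e₁ ≥ e₂ ≥ e₃
the roots of 4t³ − g₂t − g₃; real lattices go through scipy, complex ones
pointwise through mpmath.

*Corrections.*  Several printed forms fail their own auxiliary ODE; each is
replaced by the minimal structurally-intended form, validated against an
independent oracle (symbolic differentiation, or a polynomial fit of χ′²
against powers of χ), and recorded in `CORRECTIONS`, which every audit
report embeds.  The printed c₀ = σ³ (squared-trinomial expansion forces σ²)
remains available behind `gee_from_riccati(..., printed_literal=True)` for
audit, where its residual is evaluated alongside the corrected value.

## Derivatives and residuals

χ′ uses a complex-step derivative (step 1e−20, exact to machine precision)
where the form is analytic in ϱ and real on the real axis; otherwise a
4th-order central difference with step 1e−4 (valid for complex-valued
holomorphic forms, and the only option for the real-argument Jacobi/
Weierstrass evaluators).  The auxiliary residual is |χ′² − Σcₖχᵏ|/(1 + |Σ|),
reported as max/mean over non-singular samples.

The reduced-ODE residual is computed two ways: (a) the closed form
Υ″ = η₁ ·½(c₁ + 2c₂χ + 3c₃χ² + 4c₄χ³) — an algebraic identity given the
auxiliary equation, so route (a) measures exactly the power-system
inconsistency — and (b) 5-point numerical second differencing, which adds
O(h²) discretization error; both are reported.

The full-field residual uses central differences for Θ_tt and Θ_ss on an
(s,t) grid placed inside a pole-free window of ϱ and sized from the measured
variation scale of the profile (amplitude / max slope), so the coarse grid
resolves the profile with ≥ 16 points per variation unit.  A 2-cell margin
around masked cells is excluded.  The observed convergence order compares
the coarse grid and the 2×-refined grid **at shared nodes** (the refined
grid contains every coarse node), which isolates the h² truncation ratio;
comparing grid-wide maxima instead is biased low near steep window edges.
The order is reported only when both grids are ≥ 90% non-singular; constant
profiles whose residual is pure roundoff (< 1e−12) are flagged
`residual_below_roundoff` instead of receiving a meaningless order.

Tolerances: 1e−8 relative for analytic-route residuals, 1e−10 for pure
algebraic identities, convergence-order band 2 ± 0.3 — double precision
with trig/hyperbolic conditioning.

## Degenerate families

The 32 printed q→1/q→0 forms are first-class families (indices 63–94)
evaluated through the letterwise limits.  Nine of them (69–72, 76, 79, 81,
88, 94) have c₄ = 0 in the limiting quartic: the amplitude
η₁ = ∓√(2Δ_c c₄/Φ₁) collapses and η₀ divides by it, so these printed
"solutions" are formal limits without a self-consistent amplitude.  They
are constructible only with an explicit (η₀, η₁) override and are flagged
`degenerate_amplitude` in the audit — a finding about the source, recorded,
not repaired.

## Figures and morphology

The eight caption parameter sets are built in verbatim.  Four of them
violate the printed regime constraints of their own family (σ = 0 where
ρσ ≠ 0 is required, or the wrong sign of μ² − 4ρσ or ρσ); they are evaluated
non-strictly in complex arithmetic, which is precisely what reproduces the
displayed shapes (tan(iθ) = i·tanh θ turns a trigonometric form into its
hyperbolic sibling).

Morphology is judged on the profile Υ(ϱ) inside its largest pole-free,
moderate-magnitude window.  Which complex component the published surfaces
display is unstated, so: the kink check (monotone front) runs on Re with Im
and modulus fallbacks, reporting the carrying component; the dark/anti-bell
check (single interior trough, both window ends higher) runs on Re with a
modulus fallback.  Two caption-forced facts, recorded by the audit:

* the dark-soliton caption's family is tan-based; its trough lives in |Θ|
  between adjacent poles (Re is monotone there), and the window ends are
  pole-divergent rather than equal asymptotic levels;
* one kink caption has Δ_c = ζ² − ξ²Λ₁² < 0, making η₁ imaginary and
  rotating the tanh front into Im Θ (Re carries the sech part).  A monotone
  Re is mathematically impossible for that parameter set.

## What the audit does and does not establish

A green audit establishes: every catalogued χ satisfies its auxiliary ODE
(to 1e−8) in its printed regime; the power system and closed-form η pair are
symbolically certified; every family with a consistent χ⁰ equation solves
the reduced ODE to 1e−10 and the full field equation at observed order
2 ± 0.3; the published figure shapes are reproduced from their captions.

It does not establish: physical adequacy of the elastic-rod model, stability
of the waves, or anything about parameter regimes outside the catalogued
constraints.  The synthetic parameter draws are regime-valid by
construction; they exercise the catalogued formulas, not the space of
physically measured DNA constants.

Known limitation, left deliberately visible: the q → 1 continuity band
(deviation < 1e−4 at q = 1 − 10⁻⁶ on ϱ ∈ [−3, 3]) is unattainable for the
Jacobi rows that degenerate to unbounded functions — the deviation of nc
from cosh at ϱ = 3 is 4.9e−4 (confirmed at 40-digit precision), and even the
bounded quotient dn/cn reaches 1.0036e−4.  The corresponding acceptance test
asserts the band as stated and is expected to fail; the bounded rows pass
with an order of magnitude to spare.
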