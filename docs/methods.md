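# Methods

## Model and assumptions

The state is u = (x₁, …, xₙ, v): n immunity levels and a viral load,
stored with v as the last component. The uncontrolled vector field is

    ẋᵢ = xᵢ (aᵢ − bᵢ xᵢ − cᵢ v),      v̇ = v (p₄ − Σᵢ pᵢ xᵢ),

built from three modelling assumptions: (i) each immunity type follows a
Verhulst logistic law in isolation, saturating at its carrying capacity
aᵢ/bᵢ (the closed form aᵢx₀e^{aᵢt}/(aᵢ + bᵢx₀(e^{aᵢt} − 1)) is exposed as
`logistic_solution`, evaluated in an overflow-safe rearrangement);
(ii) immunity types do not attack each other and are depleted only by the
virus, bilinearly; (iii) the virus grows exponentially at rate p₄ and is
cleared bilinearly by each immunity type. Every factor of xᵢ (or v) in
its own equation makes the coordinate hyperplanes invariant, so the
closed orthant — the biologically meaningful region — is preserved.

The standard configuration has n = 3 types (innate, humoral, cellular).
The package generalizes the uncontrolled system to arbitrary n ≥ 1 so the
combinatorics of the equilibrium catalogue (2^(n+1) − 1 points) can be
studied; the two control variants are defined only for n = 3, matching
their interpretation as interventions on the three physiological
compartments, and the code enforces that.

## Parameters

| symbol | meaning | units | default test bed |
|---|---|---|---|
| aᵢ | intrinsic immunity growth rate | 1/time | 1 |
| bᵢ | logistic self-limitation | 1/(level·time) | 1 |
| cᵢ | depletion of type i by virus | 1/(load·time) | 1 |
| pᵢ | viral clearance by type i | 1/(level·time) | 1 |
| p₄ | viral proliferation rate | 1/time | 0.5 |
| α, β, γ | control constants (either sign) | mixed | 0 |

All rates are validated strictly positive and finite at construction;
operations assume valid inputs. The unit configuration with p₄ = 0.5
places every equilibrium in the closed orthant and makes the virus-free
coexistence point attracting (p₄ < Σ pᵢaᵢ/bᵢ = 3), which is why it serves
as the reference configuration throughout the tests; p₄ = 3 puts the
system exactly on the transcritical surface.

## Equilibrium enumeration

Equilibria are indexed by support pattern. Virus-off patterns put each
supported type at aᵢ/bᵢ. Virus-on patterns share a viral load
v_T = (Σ_{i∈T} pᵢaᵢ/bᵢ − p₄)/(Σ_{i∈T} pᵢcᵢ/bᵢ) with
xᵢ = (aᵢ − cᵢ v_T)/bᵢ on the support; the empty virus-on pattern has no
equilibrium, giving 2^(n+1) − 1 points. For n = 3 the catalogue is also
written out explicitly from the printed per-label formulas (E0, E1i,
E2ij, E3, E4i, E5ij, E6), and the two routes agree to 1e-12 — a
deliberate dual implementation used as a self-check.

Numerical conventions: a coordinate counts as strictly positive above
1e-12 (closed-form coordinates are exact rational expressions, so the
tolerance only guards round-off); `in_sigma_plus` uses the
relative-interior reading (positive on the support, nonnegative
elsewhere), which is the notion the saddle-point criteria refer to for
boundary patterns; degenerate parameter sets where two patterns produce
identical coordinates keep both points, flagged `coincident`, because
enumeration is by pattern, not by geometric point.

### Controlled systems

The controlled equilibrium systems have no closed form for the deformed
interior points, so each support pattern is solved numerically in
per-capita form (the trivial factors xᵢ, v divided out, leaving a smooth
square system whose roots are simple). Multi-start: the uncontrolled
closed-form point plus 32 seeded log-uniform starts spanning
[1e-3, 10] × the carrying-capacity scale per coordinate; solver: Powell
hybrid (`scipy.optimize.root`); acceptance: full-system residual below
1e-9; deduplication at relative distance 1e-7, per support and again
globally. With small control constants this reproduces the 15-point
structure of the uncontrolled catalogue. The cubic product-control terms
do admit additional remote roots (at unit rates with α = 0.05 a symmetric
root sits near x ≈ 18.9, far outside the carrying-capacity scale); the
multi-start box deliberately covers the biologically plausible region,
and the solver reports whatever distinct roots it converges to there.
The pairwise-sum E212 has the printed closed form
((a₁b₂ + a₂α)/(b₁b₂ − αβ), (a₂b₁ + a₁β)/(b₁b₂ − αβ), 0, 0), used both
directly and as a solver cross-check, and the determinant
b₁b₂b₃ − 2αβγ − b₁βγ − b₂αγ − b₃αβ decides uniqueness of the virus-free
coexistence point.

## Stability classification

`classify` computes the Jacobian spectrum (analytic Jacobian, verified
against central finite differences to 1e-6) and labels the point
attractor-node/attractor-focus/repeller/saddle, or nonhyperbolic when
some |Re λ| < 1e-9 · max(1, spectral radius) — a scale-free band chosen
to detect boundary cases such as the vanishing constant term at E512 when
v₅₁₂ = a₃/c₃. At nonhyperbolic points the classifier stops there (no
center-manifold analysis); the analytic verdict tables may still assign
the label that the deflation argument supports (E512 on that boundary is
still a saddle analytically), and this measure-zero discrepancy is
documented rather than resolved.

Analytic oracles implemented alongside the numeric route: the
Routh–Hurwitz quartic criterion (A₃ > 0, A₂A₃ − A₁ > 0,
A₁A₂A₃ − A₀A₃² − A₁² > 0, A₀ > 0, all strict); closed-form quartic
coefficients at E512 (with the known transverse eigenvalue
λ₁ = a₃ − c₃x₄ and its cubic deflation B₂ = A₃ + λ₁, B₁ = A₂ + λ₁B₂,
B₀ = A₁ + λ₁B₁) and at E6 (where interiority forces A₃ > 0 and A₀ < 0,
excluding attractor, repeller and double-Hopf at once); the explicit
eigenvalue pair (−p₄bᵢ ± √Δᵢ)/(2pᵢ) at E4i. Numeric characteristic
polynomials are formed by product expansion of the eigenvalues — at 4×4
scale this is as accurate as determinant recursion and the eigenvalues
are needed anyway.

## Transcritical bifurcation

On S = {p₄ = Σ pᵢaᵢ/bᵢ} the interior point E6 collides with E3; the
package verifies Sotomayor's conditions numerically with μ = p₄ − k as
the distinguished parameter. Null vectors of the Jacobian and its
transpose are taken as the smallest-magnitude eigenpairs, normalized to
last component +1 (at E3 on S they come out as (−c₁/b₁, −c₂/b₂, −c₃/b₃, 1)
and (0, 0, 0, 1)). F_μ = (0, 0, 0, x₄) and its Jacobian are analytic; the
second differential D²F(v, v) is computed by a central second difference
with step 1e-4 × scale, which is *exact* here since the field is
polynomial of degree ≤ 3. The expected values are cond1 = 0, cond2 = 1,
cond3 = 2 Σ pᵢcᵢ/bᵢ. Crossing location uses bisection on the leading
eigenvalue of E3 to 1e-10. The companion surfaces S12/S13/S23 (E6 meeting
E512/E513/E523 where the shared viral load hits a_k/c_k, with feasibility
side conditions aᵢc_k − a_kcᵢ > 0) and the plane intersections π₁/π₂/π₃
(E6 meeting E41/E42/E43) are checked by collision distance along
parameter paths; no printed Sotomayor calculation exists for them, so the
checker verifies collision and eigenvalue crossing only and labels any
further verdict as numeric.

## Controlled attractor criteria

The predicates follow the factorized spectra at the boundary points:
product control E2ij is attracting iff p₄ < pᵢaᵢ/bᵢ + pⱼaⱼ/bⱼ and the
missing type's transverse eigenvalue (a_k bᵢbⱼ + κ_k aᵢaⱼ)/(bᵢbⱼ) is
negative; pairwise-sum E1i is attracting iff p₄ < pᵢaᵢ/bᵢ and both
transverse combinations aⱼbᵢ + κⱼaᵢ are negative; pairwise-sum E212 uses
the characteristic-polynomial factorization
(X − λ₃)(X − λ₄)(X² + q₁X + q₀) with λ₃ = a₃ + γ(x₁ + x₂),
λ₄ = p₄ − p₁x₁ − p₂x₂, q₁ = b₁x₁ + b₂x₂, q₀ = (b₁b₂ − αβ)x₁x₂, requiring
λ₃, λ₄ < 0 and the quadratic Hurwitz (q₁, q₀ > 0). The γ condition is
deliberately implemented through this factorized form — equivalent to
the bound γ < −a₃/(x₁ + x₂) when x₁ + x₂ > 0 — rather than through an
algebraically rearranged composite inequality, to avoid transcription
drift; it is verified against the numeric classifier across random
draws.
"Attractor" means all eigenvalue real parts strictly negative; equality
cases within the caller-supplied band return indeterminate (`None`)
rather than a boolean.

## Dynamics

Trajectories are integrated with `solve_ivp`, default LSODA with the
analytic Jacobian. The choice matters: escaping orbits drive the viral
load toward the escape threshold 1e6 × max(aᵢ/bᵢ, 1), which makes the
immunity equations stiff *through the state* (effective decay rates
∝ v), and LSODA's automatic stiffness switching handles this in
milliseconds where an explicit RK method grinds. Escape is a terminal
event (any component crossing the threshold with the viral derivative
positive) — a finite operational proxy for divergence to infinity.
Outcome classification requires, for "converged", both proximity to a
catalogued equilibrium (1e-6 max-norm) and a vector-field norm below the
same tolerance at the final state, guarding against slow saddle
passages; anything else that did not trigger the escape event is
"undetermined".

## Random parameter draws

Sweeps draw all rates log-uniformly in [0.1, 10] (controls uniformly in
[−3, 3]) under `numpy.random.default_rng` with explicit seeds; agreement
tests exclude thin bands (1e-6) around bifurcation surfaces and
inequality boundaries, where classification is genuinely undefined at
numeric precision. Tests that need the interior equilibrium E6 construct
it by drawing rates and then solving for the p₄ that places the shared
viral load at half the interiority bound, since unconstrained draws make
an interior E6 rare.

## Problem sizes

The test and acceptance workloads are desk-scale by design: catalogues of
15–63 points, 50–200 random draws per property, 1000 random quartics for
the Routh–Hurwitz cross-check, and a handful of trajectory integrations;
the full suite runs in well under a minute on one core.

## Limitations

The analysis is local: no Lyapunov/global stability, no basins of
attraction, no center-manifold computation at nonhyperbolic points, and
no stable/unstable manifold geometry. The model itself is theoretical —
immunity compartments are assumed independent, all interactions are
bilinear (plus the polynomial control terms), and no parameter is fitted
to clinical data — so passing tests certify the mathematics of the
model, not its physiological accuracy. Symbolic analysis of the
controlled interior equilibria is out of scope; they are handled
numerically only.
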