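# immunodyn

Local stability and bifurcation analysis of a deterministic within-host
model of the human immune system fighting a pathogen.

## The model

Three immunity compartments — innate, humoral and cellular immunity, with
levels x₁, x₂, x₃ — each grow logistically toward a carrying capacity
aᵢ/bᵢ and are depleted by a virus whose load v proliferates exponentially
and is cleared by every immunity type:

    ẋᵢ = aᵢ xᵢ − bᵢ xᵢ² − cᵢ xᵢ v        (i = 1, 2, 3)
    v̇  = p₄ v − (p₁x₁ + p₂x₂ + p₃x₃) v

with all rates positive. This is a Lotka–Volterra-type system in which
both combatants are simultaneously predator and prey; the coordinate
hyperplanes are invariant, so the biologically meaningful closed orthant
is preserved by the flow. Two *medically controlled* variants add
intervention terms to the immunity equations — a product control
(+α x₁x₂x₃, +β x₁x₂x₃, +γ x₁x₂x₃) and a pairwise-sum control
(+α x₁(x₂+x₃), +β x₂(x₃+x₁), +γ x₃(x₁+x₂)) — modelling external boosts
such as vaccination or drug administration.

What the package does:

- **Equilibria** — all 15 equilibria of the three-type system in closed
  form, labelled E0 … E6 by support pattern, and the generic
  2^(n+1) − 1 catalogue for any number of immunity types (63 for five
  types); seeded multi-start numeric solving for the controlled systems.
- **Stability** — Jacobian eigenvalue classification
  (attractor/repeller/saddle/nonhyperbolic), the Routh–Hurwitz quartic
  criterion, closed-form characteristic polynomials at E512 and E6,
  explicit eigenvalues at E41, and analytic verdicts for the whole
  catalogue as cross-checks.
- **Bifurcation** — the transcritical surface p₄ = Σ pᵢaᵢ/bᵢ where the
  interior equilibrium E6 exchanges stability with the virus-free
  coexistence point E3, numeric verification of Sotomayor's three
  conditions there, eigenvalue-crossing scans, and a certificate that a
  double-Hopf bifurcation is impossible at E6.
- **Control analysis** — attractor criteria for the controlled boundary
  equilibria: the key qualitative finding is that a sufficiently strong
  intervention can make a *boundary* state (one or two immunity types
  missing) attracting, i.e. the immune system can win even with a
  deficient compartment.
- **Dynamics** — LSODA trajectory integration with orthant-invariance
  auditing and long-run outcome classification (convergence to a named
  equilibrium, viral escape, undetermined).

## Worked example

```python
import numpy as np
import immunodyn as im

params = im.ModelParams.unit()          # a = b = c = p = 1, p4 = 0.5
eqs = im.enumerate_closed_form(params)  # the 15-point catalogue
for eq in eqs[:4] + eqs[-2:]:
    rep = im.classify(params, im.NO_CONTROL, eq)
    print(f"{eq.label:5s} {np.round(eq.coords, 4)} {rep.classification}")

chk = im.sotomayor_at_e3(im.ModelParams.unit(p4=3.0))  # on the surface
print("conds:", chk.cond1, chk.cond2, chk.cond3)

traj = im.simulate(params, im.NO_CONTROL, [0.9, 1.1, 1.0, 0.2], t_end=200)
print(im.classify_outcome(traj, eqs), np.round(traj.final_state, 6))
```

prints

```
E0    [0. 0. 0. 0.] repeller
E11   [1. 0. 0. 0.] saddle
E12   [0. 1. 0. 0.] saddle
E13   [0. 0. 1. 0.] saddle
E523  [0.   0.25 0.25 0.75] saddle
E6    [0.1667 0.1667 0.1667 0.8333] saddle
conds: 0.0 1.0 6.000000000003781
converged-to(E3) [ 1.  1.  1. -0.]
```

Reading: at unit rates with slow viral proliferation (p₄ = 0.5 below the
total clearance at capacity Σ pᵢaᵢ/bᵢ = 3) the origin repels, every
partial-immunity or viral-coexistence state is a saddle, and the
virus-free coexistence point E3 = (1, 1, 1, 0) attracts — the orbit
started near it converges there and the virus is eliminated. On the
collision surface (p₄ = 3) the Sotomayor conditions evaluate to
(0, 1, 2 Σ pᵢcᵢ/bᵢ) = (0, 1, 6), certifying the transcritical exchange
of stability between E3 and E6.

The same analyses are available from the shell:

```sh
immunodyn analyze  --config model.yaml --out-dir out      # equilibria + classification table
immunodyn simulate --config model.yaml --out-dir out      # trajectory + outcome
immunodyn scan     --config model.yaml --out-dir out      # crossing scan + Sotomayor check
immunodyn sample   --n 100 --seed 0    --out-dir out      # seeded parameter draws
```

where `model.yaml` holds the `params:` mapping (and optionally
`control:`, `simulate:`, `scan:` sections); see `immunodyn --help`.

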