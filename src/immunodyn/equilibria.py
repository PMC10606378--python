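"""Equilibrium enumeration for the uncontrolled and controlled systems.

Every equilibrium of the uncontrolled system is determined by its *support
pattern*: the subset of immunity types with positive level, plus a flag for
whether the viral load is positive.  Virus-off supports put each supported
type at its carrying capacity ``a_i/b_i``; virus-on supports share a common
viral load

    v_T = (sum_{i in T} p_i a_i / b_i - p4) / (sum_{i in T} p_i c_i / b_i)

with ``x_i = (a_i - c_i v_T) / b_i`` on the support.  This yields
``2^(n+1) - 1`` equilibria for ``n`` immunity types (the all-zero-immunity
virus-on pattern admits no equilibrium), i.e. 15 for the three-type model
and 63 for five types.

The controlled systems have no closed form for the interior points; they
are solved numerically per support with seeded multi-start root finding.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .model import NO_CONTROL, ControlParams, ModelParams, vector_field

__all__ = [
    "Equilibrium",
    "enumerate_closed_form",
    "enumerate_generic",
    "solve_controlled",
    "solve_controlled_all",
    "e212_closed_form_pairwise",
    "e3_uniqueness_determinant",
    "canonical_label",
]

#: coordinates larger than this count as strictly positive
POSITIVITY_TOL = 1e-12


@dataclass(frozen=True)
class Equilibrium:
    """A labelled equilibrium point.

    ``support`` holds the 0-based indices of immunity types with positive
    level; ``virus_on`` flags a positive viral load.  ``in_sigma_plus`` is
    True when the point is strictly positive on its support (for
    full-support points this is exactly membership in the open orthant
    Sigma+; for boundary patterns it is membership in the relative interior
    of their invariant face, which is what the saddle-point conditions
    refer to).  ``derived`` carries auxiliary closed-form quantities (the
    shared viral load ``v`` and its denominator ``d`` for virus-on points)
    and a ``coincident`` flag when a degenerate parameter set makes two
    support patterns share coordinates.
    """

    label: str
    support: frozenset
    virus_on: bool
    coords: np.ndarray
    in_sigma_plus: bool
    derived: dict = field(default_factory=dict)

    @property
    def in_closed_orthant(self) -> bool:
        return bool(np.all(self.coords >= -POSITIVITY_TOL))

    def residual(self, params: ModelParams,
                 control: ControlParams = NO_CONTROL) -> float:
        return float(np.max(np.abs(vector_field(params, control, self.coords))))

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "support": sorted(i + 1 for i in self.support),
            "virus_on": self.virus_on,
            "coords": self.coords.tolist(),
            "in_sigma_plus": self.in_sigma_plus,
            "derived": {k: v for k, v in self.derived.items()},
        }


def canonical_label(n: int, support: frozenset, virus_on: bool) -> str:
    """Catalogue name of a support pattern.

    For the three-type model the traditional names are used (``E0``,
    ``E11..E13``, ``E212..E223``, ``E3``, ``E41..E43``, ``E512..E523``,
    ``E6``); other dimensions get an explicit support code such as
    ``S10110+v``.
    """
    idx = sorted(i + 1 for i in support)
    if n == 3:
        if not virus_on:
            if len(idx) == 0:
                return "E0"
            if len(idx) == 1:
                return f"E1{idx[0]}"
            if len(idx) == 2:
                return f"E2{idx[0]}{idx[1]}"
            return "E3"
        if len(idx) == 1:
            return f"E4{idx[0]}"
        if len(idx) == 2:
            return f"E5{idx[0]}{idx[1]}"
        return "E6"
    bits = "".join("1" if i in support else "0" for i in range(n))
    return f"S{bits}{'+v' if virus_on else ''}"


def _sigma_plus(coords: np.ndarray, support: frozenset, virus_on: bool) -> bool:
    active = sorted(support) + ([coords.size - 1] if virus_on else [])
    if active and np.min(coords[active]) <= POSITIVITY_TOL:
        return False
    return bool(np.all(coords >= -POSITIVITY_TOL))


def _make_equilibrium(params: ModelParams, support: frozenset, virus_on: bool,
                      coords: np.ndarray, derived: dict | None = None) -> Equilibrium:
    return Equilibrium(
        label=canonical_label(params.n_types, support, virus_on),
        support=support,
        virus_on=virus_on,
        coords=coords,
        in_sigma_plus=_sigma_plus(coords, support, virus_on),
        derived=derived or {},
    )


def _flag_coincident(eqs: list[Equilibrium], tol: float = 1e-12) -> list[Equilibrium]:
    """Mark equilibria whose coordinates collide with another pattern's."""
    for i, e in enumerate(eqs):
        for other in eqs[:i] + eqs[i + 1:]:
            if np.max(np.abs(e.coords - other.coords)) < tol:
                e.derived["coincident"] = True
                break
    return eqs


def _virus_on_point(params: ModelParams, support: frozenset):
    """Shared viral load and coordinates for a virus-on support pattern."""
    idx = sorted(support)
    a, b, c, p = params.a, params.b, params.c, params.p
    d = float(np.sum(p[idx] * c[idx] / b[idx]))
    v = float(np.sum(p[idx] * a[idx] / b[idx]) - params.p4) / d
    coords = np.zeros(params.n_types + 1)
    coords[idx] = (a[idx] - c[idx] * v) / b[idx]
    coords[-1] = v
    return coords, v, d


def enumerate_generic(params: ModelParams) -> list[Equilibrium]:
    """All ``2^(n+1) - 1`` equilibria of the uncontrolled system, by support.

    Works for any number of immunity types; for ``n = 3`` the result matches
    :func:`enumerate_closed_form` coordinate-by-coordinate.
    """
    n = params.n_types
    out: list[Equilibrium] = []
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            support = frozenset(combo)
            coords = np.zeros(n + 1)
            coords[list(combo)] = params.a[list(combo)] / params.b[list(combo)]
            out.append(_make_equilibrium(params, support, False, coords))
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            support = frozenset(combo)
            coords, v, d = _virus_on_point(params, support)
            out.append(_make_equilibrium(params, support, True, coords,
                                         {"v": v, "d": d}))
    return _flag_coincident(out)


def enumerate_closed_form(params: ModelParams) -> list[Equilibrium]:
    """The 15 equilibria of the three-type system, from the printed formulas.

    ``E0`` (extinction of everything), the single-type capacities
    ``E11..E13``, the pairwise capacities ``E212..E223``, the virus-free
    coexistence point ``E3``, the single-type viral coexistence points
    ``E41..E43``, the pairwise ones ``E512..E523`` and the interior point
    ``E6``.  Raises for ``n_types != 3`` (use :func:`enumerate_generic`).
    """
    if params.n_types != 3:
        raise ValueError("closed-form catalogue is defined for 3 immunity "
                         "types; use enumerate_generic for other dimensions")
    a, b, c, p, p4 = params.a, params.b, params.c, params.p, params.p4
    cap = a / b
    out: list[Equilibrium] = []

    out.append(_make_equilibrium(params, frozenset(), False, np.zeros(4)))
    for i in range(3):
        coords = np.zeros(4)
        coords[i] = cap[i]
        out.append(_make_equilibrium(params, frozenset({i}), False, coords))
    for i, j in itertools.combinations(range(3), 2):
        coords = np.zeros(4)
        coords[i], coords[j] = cap[i], cap[j]
        out.append(_make_equilibrium(params, frozenset({i, j}), False, coords))
    out.append(_make_equilibrium(params, frozenset({0, 1, 2}), False,
                                 np.append(cap, 0.0)))

    # E4i: x_i = p4/p_i, v = (a_i - b_i p4/p_i)/c_i
    for i in range(3):
        coords = np.zeros(4)
        coords[i] = p4 / p[i]
        coords[3] = (a[i] - b[i] * p4 / p[i]) / c[i]
        out.append(_make_equilibrium(params, frozenset({i}), True, coords))
    # E5ij: v = (p_i a_i/b_i + p_j a_j/b_j - p4) / (p_i c_i/b_i + p_j c_j/b_j)
    for i, j in itertools.combinations(range(3), 2):
        d = p[i] * c[i] / b[i] + p[j] * c[j] / b[j]
        v = (p[i] * a[i] / b[i] + p[j] * a[j] / b[j] - p4) / d
        coords = np.zeros(4)
        coords[i] = (a[i] - c[i] * v) / b[i]
        coords[j] = (a[j] - c[j] * v) / b[j]
        coords[3] = v
        out.append(_make_equilibrium(params, frozenset({i, j}), True, coords,
                                     {"v": float(v), "d": float(d)}))
    # E6: interior coexistence with the virus
    d6 = float(np.sum(p * c / b))
    t6 = float(np.sum(p * a / b) - p4)
    v6 = t6 / d6
    coords = np.append((a - c * v6) / b, v6)
    out.append(_make_equilibrium(params, frozenset({0, 1, 2}), True, coords,
                                 {"v": v6, "d": d6, "t": t6}))
    return _flag_coincident(out)


def _reduced_system(params: ModelParams, control: ControlParams,
                    support: Sequence[int], virus_on: bool):
    """Residual function on the reduced (support-only) unknowns."""
    idx = list(support)
    n = params.n_types

    def embed(z: np.ndarray) -> np.ndarray:
        u = np.zeros(n + 1)
        u[idx] = z[: len(idx)]
        if virus_on:
            u[n] = z[-1]
        return u

    def fun(z: np.ndarray) -> np.ndarray:
        # per-capita form: the trivial factors x_i (resp. v) are divided
        # out, so roots on the support are simple and the off-support
        # (smaller-support) solutions are excluded
        u = embed(z)
        comps = [_per_capita(params, control, u, i) for i in idx]
        if virus_on:
            comps.append(float(params.p4 - params.p @ u[:n]))
        return np.asarray(comps)

    return fun, embed


def _per_capita(params: ModelParams, control: ControlParams,
                u: np.ndarray, i: int) -> float:
    """Per-capita growth rate of immunity type ``i`` (factor of ``x_i``)."""
    x, v = u[: params.n_types], u[params.n_types]
    base = params.a[i] - params.b[i] * x[i] - params.c[i] * v
    if control.kind == "product":
        others = np.prod([x[m] for m in range(3) if m != i])
        base += control.constants[i] * others
    elif control.kind == "pairwise_sum":
        base += control.constants[i] * (np.sum(x) - x[i])
    return float(base)


def _closed_form_start(params: ModelParams, support: Sequence[int],
                       virus_on: bool) -> np.ndarray | None:
    """Uncontrolled closed-form point for this support, as a solver start."""
    for eq in enumerate_generic(params):
        if eq.support == frozenset(support) and eq.virus_on == virus_on:
            z = eq.coords[list(support)]
            if virus_on:
                z = np.append(z, eq.coords[-1])
            return z
    return None


def solve_controlled(params: ModelParams, control: ControlParams,
                     support: Iterable[int], virus_on: bool,
                     seed: int = 0, n_starts: int = 32,
                     dedup_tol: float = 1e-7,
                     residual_tol: float = 1e-9) -> list[Equilibrium]:
    """Numeric equilibria of a controlled system on one support pattern.

    Off-support coordinates are pinned to zero and the reduced square system
    is solved from ``n_starts`` seeded log-uniform initial guesses (spanning
    ``[1e-3, 10]`` times the carrying-capacity scale) plus the uncontrolled
    closed-form point.  Distinct roots (relative distance above
    ``dedup_tol``) with full-system residual below ``residual_tol`` are
    returned; an empty list means no root was found.
    """
    if control.kind not in ("product", "pairwise_sum"):
        raise ValueError("solve_controlled requires a product or pairwise_sum "
                         "control; use enumerate_closed_form otherwise")
    control.validate_against(params)
    support = sorted(set(support))
    if not support and virus_on:
        return []  # virus cannot be stationary at positive load without immunity
    if not support and not virus_on:
        eq = _make_equilibrium(params, frozenset(), False,
                               np.zeros(params.n_types + 1))
        return [eq]

    fun, embed = _reduced_system(params, control, support, virus_on)
    dim = len(support) + (1 if virus_on else 0)
    rng = np.random.default_rng(seed)
    scale = np.array([params.carrying_capacity[i] for i in support])
    if virus_on:
        scale = np.append(scale, max(np.max(params.a / params.c), params.p4))

    starts = []
    z0 = _closed_form_start(params, support, virus_on)
    if z0 is not None:
        starts.append(z0)
    starts.extend(scale * 10.0 ** rng.uniform(-3, 1, size=(n_starts, dim)))

    roots: list[np.ndarray] = []
    for z in starts:
        sol = optimize.root(fun, z, method="hybr", tol=1e-12)
        if not sol.success:
            continue
        u = embed(sol.x)
        if np.max(np.abs(vector_field(params, control, u))) > residual_tol:
            continue
        ref = np.maximum(np.max(np.abs(u)), 1.0)
        if any(np.max(np.abs(u - r)) < dedup_tol * ref for r in roots):
            continue
        roots.append(u)

    out = []
    for u in roots:
        derived = {"v": float(u[-1])} if virus_on else {}
        out.append(_make_equilibrium(params, frozenset(support), virus_on,
                                     u, derived))
    return out


def solve_controlled_all(params: ModelParams, control: ControlParams,
                         seed: int = 0, **kwargs) -> list[Equilibrium]:
    """Union of :func:`solve_controlled` over every support pattern.

    Roots are deduplicated globally so a solution sitting on a smaller
    support (a coordinate numerically zero) is not double-counted.
    """
    n = params.n_types
    found: list[Equilibrium] = []
    sub = 0
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            for virus_on in (False, True):
                sub += 1
                eqs = solve_controlled(params, control, combo, virus_on,
                                       seed=seed * 1000 + sub, **kwargs)
                for eq in eqs:
                    ref = np.maximum(np.max(np.abs(eq.coords)), 1.0)
                    if any(np.max(np.abs(eq.coords - e.coords)) < 1e-7 * ref
                           for e in found):
                        continue
                    found.append(eq)
    return found


def e212_closed_form_pairwise(params: ModelParams,
                              control: ControlParams) -> np.ndarray:
    """Closed-form ``E212`` of the pairwise-sum controlled system.

    ``x1 = (a1 b2 + a2 alpha) / (b1 b2 - alpha beta)``,
    ``x2 = (a2 b1 + a1 beta) / (b1 b2 - alpha beta)``, ``x3 = v = 0``.
    Raises when the denominator vanishes (nonexistence).
    """
    if control.kind != "pairwise_sum":
        raise ValueError("E212 closed form applies to the pairwise_sum control")
    a, b = params.a, params.b
    den = b[0] * b[1] - control.alpha * control.beta
    if den == 0.0:
        raise ValueError("b1*b2 - alpha*beta = 0: E212 does not exist")
    x1 = (a[0] * b[1] + a[1] * control.alpha) / den
    x2 = (a[1] * b[0] + a[0] * control.beta) / den
    return np.array([x1, x2, 0.0, 0.0])


def e3_uniqueness_determinant(params: ModelParams,
                              control: ControlParams) -> float:
    """Determinant governing uniqueness of the virus-free coexistence point
    under the pairwise-sum control:

    ``b1 b2 b3 - 2 alpha beta gamma - b1 beta gamma - b2 alpha gamma
    - b3 alpha beta``.

    A value near zero signals the degenerate case with either a continuum
    of such equilibria or none.
    """
    if control.kind != "pairwise_sum":
        raise ValueError("uniqueness determinant applies to the pairwise_sum "
                         "control")
    b = params.b
    al, be, ga = control.alpha, control.beta, control.gamma
    return float(b[0] * b[1] * b[2] - 2 * al * be * ga
                 - b[0] * be * ga - b[1] * al * ga - b[2] * al * be)
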