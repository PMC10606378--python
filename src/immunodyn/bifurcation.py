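"""Transcritical-bifurcation surfaces, Sotomayor conditions and scans.

The uncontrolled system undergoes a transcritical bifurcation on the
hyperplane ``S`` in clearance-parameter space where the interior point
``E6`` collides with the virus-free coexistence point ``E3``::

    S :  p1 a1/b1 + p2 a2/b2 + p3 a3/b3 - p4 = 0

Three more transcritical surfaces ``S12, S13, S23`` carry collisions of
``E6`` with the two-type viral points ``E512, E513, E523`` (each with a
pair of side conditions on the ratios ``a_i / c_i`` for feasibility), and
the pairwise intersections ``pi1 = S12 & S13`` etc. carry collisions of
``E6`` with the single-type viral points ``E41, E42, E43``.

Sotomayor's three conditions are verified numerically at ``E3`` with the
viral proliferation rate as the distinguished parameter ``mu = p4 - k``:
the zero-eigenvalue right/left null vectors ``v, w`` of the Jacobian are
computed (last component normalized to 1) and

    cond1 = w . F_mu          (must vanish),
    cond2 = w . (DF_mu) v     (must be nonzero; equals 1 here),
    cond3 = w . D^2F(v, v)    (must be nonzero; equals 2 sum p_i c_i/b_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import NO_CONTROL, ModelParams, jacobian, vector_field
from .equilibria import enumerate_closed_form
from .stability import charpoly_e6, classify_at

__all__ = [
    "SotomayorCheck",
    "surface_residuals",
    "collision_partner",
    "collision_distance",
    "sotomayor_at_e3",
    "crossing_scan",
    "hopf_hopf_exclusion_e6",
]

#: surface label -> label of the equilibrium colliding with E6 there
_PARTNERS = {"S": "E3", "S12": "E512", "S13": "E513", "S23": "E523",
             "pi1": "E41", "pi2": "E42", "pi3": "E43"}


@dataclass(frozen=True)
class SotomayorCheck:
    """The three transcritical-condition values at a candidate point."""

    mu: float
    k: float
    right_eigvec: np.ndarray
    left_eigvec: np.ndarray
    cond1: float
    cond2: float
    cond3: float
    tol: float

    @property
    def verdict(self) -> bool:
        return (abs(self.cond1) <= self.tol and abs(self.cond2) > self.tol
                and abs(self.cond3) > self.tol)


def _pair_surface(params: ModelParams, i: int, j: int, k: int):
    """Residual and feasibility of the surface where E6 meets E5(ij).

    On that surface the third type's level vanishes, i.e. the shared viral
    load equals ``a_k / c_k``; feasibility requires the other two types to
    remain positive there.
    """
    a, b, c, p = params.a, params.b, params.c, params.p
    res = (p[i] * (a[i] - a[k] * c[i] / c[k]) / b[i]
           + p[j] * (a[j] - a[k] * c[j] / c[k]) / b[j] - params.p4)
    feasible = (a[i] * c[k] - a[k] * c[i] > 0) and (a[j] * c[k] - a[k] * c[j] > 0)
    return float(res), bool(feasible)


def surface_residuals(params: ModelParams) -> dict[str, dict]:
    """Defining expressions of all transcritical surfaces at ``params``.

    Each entry maps to ``{"residual", "feasible", "partner"}``; the
    two-plane entries ``pi1..pi3`` report the pair of surface residuals
    whose intersection they are.
    """
    k = params.clearance_at_capacity
    out: dict[str, dict] = {
        "S": {"residual": float(k - params.p4), "feasible": True,
              "partner": _PARTNERS["S"]},
    }
    pairs = {"S12": (0, 1, 2), "S13": (0, 2, 1), "S23": (1, 2, 0)}
    for name, (i, j, kk) in pairs.items():
        res, feas = _pair_surface(params, i, j, kk)
        out[name] = {"residual": res, "feasible": feas,
                     "partner": _PARTNERS[name]}
    for name, (s1, s2) in {"pi1": ("S12", "S13"), "pi2": ("S12", "S23"),
                           "pi3": ("S13", "S23")}.items():
        out[name] = {
            "residual": (out[s1]["residual"], out[s2]["residual"]),
            "feasible": out[s1]["feasible"] and out[s2]["feasible"],
            "partner": _PARTNERS[name],
        }
    return out


def collision_partner(surface: str) -> str:
    return _PARTNERS[surface]


def collision_distance(params: ModelParams, surface: str) -> float:
    """Max-norm distance between ``E6`` and its collision partner."""
    eqs = {e.label: e for e in enumerate_closed_form(params)}
    return float(np.max(np.abs(eqs["E6"].coords
                               - eqs[_PARTNERS[surface]].coords)))


def _null_vectors(J: np.ndarray, tol: float):
    """Right/left null vectors of the near-zero eigenvalue, last comp 1."""
    def smallest(mat):
        lam, vec = np.linalg.eig(mat)
        idx = int(np.argmin(np.abs(lam)))
        return lam[idx], vec[:, idx]

    lam_r, v = smallest(J)
    lam_l, w = smallest(J.T)
    if abs(lam_r) > tol or abs(lam_l) > tol:
        raise ValueError(f"no zero eigenvalue at the candidate point "
                         f"(|lambda| = {abs(lam_r):.3e})")
    v = np.real(v)
    w = np.real(w)
    if abs(v[-1]) < 1e-12 or abs(w[-1]) < 1e-12:
        raise ValueError("null vector has vanishing last component; "
                         "cannot apply the standard normalization")
    return v / v[-1], w / w[-1]


def sotomayor_at_e3(params: ModelParams, tol: float = 1e-6,
                    surface_tol: float = 1e-9) -> SotomayorCheck:
    """Verify the transcritical conditions at ``E3`` on the surface ``S``.

    Requires ``p4`` to sit on the collision value ``k = sum p_i a_i/b_i``
    within ``surface_tol``.  ``F_mu`` is the derivative of the vector field
    in the distinguished parameter, which is ``(0, 0, 0, x4)``; the second
    differential is evaluated by a central second difference along the
    right null vector (exact here, the field being polynomial of degree
    two).
    """
    k = params.clearance_at_capacity
    mu = params.p4 - k
    if abs(mu) > surface_tol * max(1.0, k):
        raise ValueError(f"params are not on S: |p4 - k| = {abs(mu):.3e}")
    u0 = np.append(params.carrying_capacity, 0.0)
    J = jacobian(params, NO_CONTROL, u0)
    scale = max(1.0, float(np.max(np.abs(np.linalg.eigvals(J)))))
    v, w = _null_vectors(J, tol=1e-7 * scale)

    f_mu = np.zeros(params.n_types + 1)
    f_mu[-1] = u0[-1]  # dF/dmu = (0, ..., 0, x4)
    cond1 = float(w @ f_mu)

    df_mu = np.zeros((params.n_types + 1, params.n_types + 1))
    df_mu[-1, -1] = 1.0
    cond2 = float(w @ (df_mu @ v))

    h = 1e-4 * max(1.0, float(np.max(np.abs(u0))))
    d2 = (vector_field(params, NO_CONTROL, u0 + h * v)
          - 2.0 * vector_field(params, NO_CONTROL, u0)
          + vector_field(params, NO_CONTROL, u0 - h * v)) / h ** 2
    cond3 = float(w @ d2)
    return SotomayorCheck(mu=float(mu), k=float(k), right_eigvec=v,
                          left_eigvec=w, cond1=cond1, cond2=cond2,
                          cond3=cond3, tol=tol)


def _with_p4(params: ModelParams, p4: float) -> ModelParams:
    return ModelParams(a=params.a, b=params.b, c=params.c, p=params.p, p4=p4)


def crossing_scan(params: ModelParams, p4_lo: float, p4_hi: float,
                  xtol: float = 1e-10) -> dict:
    """Locate the stability exchange of ``E3`` along a ``p4`` path.

    Bisects the leading eigenvalue ``lambda4(E3) = p4 - k`` over
    ``[p4_lo, p4_hi]``; when the interval brackets the crossing, reports
    its location together with the classification of ``E3`` and the
    orthant status of ``E6`` on both sides, and the ``E6``-``E3`` distance
    at the crossing.
    """

    def lam4(p4: float) -> float:
        pp = _with_p4(params, p4)
        u0 = np.append(pp.carrying_capacity, 0.0)
        return float(np.max(np.linalg.eigvals(
            jacobian(pp, NO_CONTROL, u0)).real))

    f_lo, f_hi = lam4(p4_lo), lam4(p4_hi)
    if f_lo * f_hi > 0:
        return {"crossing_found": False, "interval": (p4_lo, p4_hi),
                "lambda4": (f_lo, f_hi)}
    lo, hi = p4_lo, p4_hi
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if lam4(lo) * lam4(mid) <= 0:
            hi = mid
        else:
            lo = mid
    p4_star = 0.5 * (lo + hi)

    def side_report(p4: float) -> dict:
        pp = _with_p4(params, p4)
        eqs = {e.label: e for e in enumerate_closed_form(pp)}
        rep = classify_at(pp, NO_CONTROL, eqs["E3"].coords)
        return {
            "p4": p4,
            "E3_classification": rep.classification,
            "E6_in_sigma_plus": eqs["E6"].in_sigma_plus,
            "v6": eqs["E6"].derived["v"],
            "E6_classification": classify_at(
                pp, NO_CONTROL, eqs["E6"].coords).classification,
        }

    delta = 0.05 * (p4_hi - p4_lo)
    return {
        "crossing_found": True,
        "p4_star": p4_star,
        "k": params.clearance_at_capacity,
        "below": side_report(p4_star - delta),
        "above": side_report(p4_star + delta),
        "collision_distance_at_crossing": collision_distance(
            _with_p4(params, p4_star), "S"),
    }


def hopf_hopf_exclusion_e6(params: ModelParams) -> tuple[bool, dict]:
    """Certify that a double-Hopf scenario is impossible at interior ``E6``.

    Two pure-imaginary pairs would force trace 0 and positive eigenvalue
    product; the closed-form quartic there has ``A3 > 0`` (nonzero trace)
    and ``A0 < 0`` (negative product), a contradiction.  The eigenvalues
    are also checked directly for a ``(+/- i w1, +/- i w2)`` pattern.
    """
    eqs = {e.label: e for e in enumerate_closed_form(params)}
    e6 = eqs["E6"]
    if not e6.in_sigma_plus:
        raise ValueError("E6 is not interior for these parameters")
    coeffs = charpoly_e6(params)
    lam = np.linalg.eigvals(jacobian(params, NO_CONTROL, e6.coords))
    scale = max(1.0, float(np.max(np.abs(lam))))
    two_imag_pairs = bool(np.all(np.abs(lam.real) < 1e-9 * scale)
                          and np.sum(lam.imag > 1e-9 * scale) == 2)
    excluded = (coeffs.A3 > 0 and coeffs.A0 < 0) and not two_imag_pairs
    return excluded, {"A3": coeffs.A3, "A0": coeffs.A0,
                      "eigenvalues": lam,
                      "two_pure_imaginary_pairs": two_imag_pairs}
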