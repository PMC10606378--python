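"""Eigenvalue classification, Routh-Hurwitz tests and analytic oracles.

An equilibrium is classified from the spectrum of the Jacobian there:
attractor when every eigenvalue has negative real part (node if all are
real, focus otherwise), repeller when every real part is positive, saddle
for mixed signs, and nonhyperbolic when some real part sits within a
scale-free tolerance of zero (linearization is then inconclusive).

The module also carries the closed-form characteristic-polynomial
coefficients at the two-type viral coexistence point ``E512`` and at the
interior point ``E6``, the explicit eigenvalues at ``E41``, and the
analytic saddle/attractor verdicts for the whole uncontrolled catalogue;
these serve as independent oracles for the numeric classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .model import NO_CONTROL, ControlParams, ModelParams, jacobian
from .equilibria import Equilibrium, enumerate_closed_form

__all__ = [
    "StabilityReport",
    "CharPolyCoeffs",
    "classify",
    "classify_at",
    "routh_hurwitz_quartic",
    "charpoly_from_jacobian",
    "charpoly_e512",
    "charpoly_e6",
    "e41_eigenvalues",
    "analytic_verdicts",
]

#: default scale-free real-part tolerance for hyperbolicity detection
HYPERBOLICITY_TOL = 1e-9


@dataclass(frozen=True)
class StabilityReport:
    """Spectrum-based classification of an equilibrium."""

    eigenvalues: np.ndarray
    hyperbolic: bool
    classification: str  # attractor_node | attractor_focus | repeller | saddle | nonhyperbolic
    tol: float

    @property
    def is_attractor(self) -> bool:
        return self.classification.startswith("attractor")


@dataclass(frozen=True)
class CharPolyCoeffs:
    """Monic quartic ``X^4 + A3 X^3 + A2 X^2 + A1 X + A0``.

    ``deflation``, when present, holds ``(lambda1, B2, B1, B0)`` for the
    factorization ``(X - lambda1)(X^3 + B2 X^2 + B1 X + B0)`` by the known
    real root ``lambda1``.
    """

    A3: float
    A2: float
    A1: float
    A0: float
    deflation: tuple | None = None

    def as_array(self) -> np.ndarray:
        return np.array([1.0, self.A3, self.A2, self.A1, self.A0])


def classify_at(params: ModelParams, control: ControlParams, coords,
                tol: float = HYPERBOLICITY_TOL) -> StabilityReport:
    """Classify the equilibrium at ``coords`` from the Jacobian spectrum."""
    J = jacobian(params, control, coords)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite Jacobian entries")
    lam = np.linalg.eigvals(J)
    scale = max(1.0, float(np.max(np.abs(lam))))
    re = lam.real
    if np.any(np.abs(re) < tol * scale):
        cls = "nonhyperbolic"
        hyperbolic = False
    else:
        hyperbolic = True
        if np.all(re < 0):
            focus = np.any(np.abs(lam.imag) > tol * scale)
            cls = "attractor_focus" if focus else "attractor_node"
        elif np.all(re > 0):
            cls = "repeller"
        else:
            cls = "saddle"
    return StabilityReport(eigenvalues=lam, hyperbolic=hyperbolic,
                           classification=cls, tol=tol)


def classify(params: ModelParams, control: ControlParams, eq: Equilibrium,
             tol: float = HYPERBOLICITY_TOL) -> StabilityReport:
    """Classify an :class:`~immunodyn.equilibria.Equilibrium`."""
    return classify_at(params, control, eq.coords, tol=tol)


def routh_hurwitz_quartic(coeffs) -> bool:
    """Routh-Hurwitz stability test for a monic quartic.

    True iff all roots of ``X^4 + A3 X^3 + A2 X^2 + A1 X + A0`` lie in the
    open left half-plane, i.e. all four inequalities hold strictly::

        A3 > 0,  A2 A3 - A1 > 0,  A1 A2 A3 - A0 A3^2 - A1^2 > 0,  A0 > 0
    """
    if isinstance(coeffs, CharPolyCoeffs):
        A3, A2, A1, A0 = coeffs.A3, coeffs.A2, coeffs.A1, coeffs.A0
    else:
        A3, A2, A1, A0 = map(float, coeffs)
    return (A3 > 0 and A2 * A3 - A1 > 0
            and A1 * A2 * A3 - A0 * A3 ** 2 - A1 ** 2 > 0 and A0 > 0)


def charpoly_from_jacobian(J: np.ndarray) -> CharPolyCoeffs:
    """Monic characteristic polynomial via eigenvalue product expansion."""
    lam = np.linalg.eigvals(J)
    c = np.real(np.poly(lam))
    return CharPolyCoeffs(A3=float(c[1]), A2=float(c[2]),
                          A1=float(c[3]), A0=float(c[4]))


def _e512_coords(params: ModelParams) -> np.ndarray:
    for eq in enumerate_closed_form(params):
        if eq.label == "E512":
            return eq.coords
    raise RuntimeError("E512 not found")  # pragma: no cover


def charpoly_e512(params: ModelParams) -> CharPolyCoeffs:
    """Closed-form characteristic polynomial at ``E512``.

    ``E512`` supports immunity types 1 and 2 together with the virus;
    writing ``(x1, x2, 0, x4)`` for its coordinates, the coefficients are
    polynomial in the coordinates and rates.  The known real eigenvalue
    ``lambda1 = a3 - c3 x4`` (the transverse direction of the absent third
    type) gives the attached cubic deflation.
    """
    a, b, c, p = params.a, params.b, params.c, params.p
    x1, x2, _, x4 = _e512_coords(params)
    a3, b3, c3 = a[2], b[2], c[2]
    A3 = b[0] * x1 + b[1] * x2 + c3 * x4 - a3
    A2 = (b[0] * x1 * c3 * x4 + b[1] * x2 * c3 * x4
          - p[0] * x4 * c[0] * x1 - p[1] * x4 * c[1] * x2
          + b[0] * x1 * b[1] * x2 - b[1] * x2 * a3 - b[0] * x1 * a3)
    A1 = (-b[0] * x1 * b[1] * x2 * a3 + b[0] * x1 * b[1] * x2 * c3 * x4
          - b[0] * x1 * p[1] * x4 * c[1] * x2 + p[1] * x4 * c[1] * x2 * a3
          - p[1] * x4 ** 2 * c[1] * x2 * c3
          - p[0] * x4 * c[0] * x1 * b[1] * x2 + p[0] * x4 * c[0] * x1 * a3
          - p[0] * x4 ** 2 * c[0] * x1 * c3)
    A0 = x2 * x1 * x4 * (a3 - c3 * x4) * (b[0] * p[1] * c[1] + p[0] * c[0] * b[1])
    lam1 = a3 - c3 * x4
    B2 = A3 + lam1
    B1 = A2 + lam1 * B2
    B0 = A1 + lam1 * B1
    return CharPolyCoeffs(A3=float(A3), A2=float(A2), A1=float(A1),
                          A0=float(A0),
                          deflation=(float(lam1), float(B2), float(B1),
                                     float(B0)))


def charpoly_e6(params: ModelParams) -> CharPolyCoeffs:
    """Closed-form characteristic polynomial at the interior point ``E6``.

    With coordinates ``(x1, x2, x3, x4)`` all supported, the quartic has
    ``A3 = sum_i b_i x_i > 0`` and
    ``A0 = -x1 x2 x3 x4 * sum over pairings < 0`` whenever ``E6`` is
    interior, which is what rules out both an attractor and a repeller
    there.
    """
    b, c, p = params.b, params.c, params.p
    for eq in enumerate_closed_form(params):
        if eq.label == "E6":
            x = eq.coords[:3]
            x4 = eq.coords[3]
            break
    bx = b * x
    A3 = bx[0] + bx[1] + bx[2]
    A2 = (bx[0] * bx[1] + bx[0] * bx[2] + bx[1] * bx[2]
          - (p[0] * c[0] * x[0] + p[1] * c[1] * x[1] + p[2] * c[2] * x[2]) * x4)
    A1 = (x[0] * x[1] * x[2] * b[0] * b[1] * b[2]
          - x[1] * x[2] * x4 * (p[1] * b[2] * c[1] + p[2] * b[1] * c[2])
          - x[0] * x[1] * x4 * (p[0] * b[1] * c[0] + p[1] * b[0] * c[1])
          - x[0] * x[2] * x4 * (p[2] * b[0] * c[2] + p[0] * b[2] * c[0]))
    A0 = -x[0] * x[1] * x[2] * x4 * (p[2] * b[0] * b[1] * c[2]
                                     + p[0] * b[1] * b[2] * c[0]
                                     + b[0] * p[1] * b[2] * c[1])
    return CharPolyCoeffs(A3=float(A3), A2=float(A2), A1=float(A1),
                          A0=float(A0))


def e41_eigenvalues(params: ModelParams, i: int) -> np.ndarray:
    """Explicit eigenvalues at the single-type viral point ``E4i``.

    Two transverse eigenvalues ``a_j - c_j (p_i a_i - p4 b_i) / (c_i p_i)``
    for the absent types ``j != i``, plus the in-plane pair
    ``(-p4 b_i +/- sqrt(D)) / (2 p_i)`` with discriminant
    ``D = p4^2 b_i^2 + 4 p_i p4 (p_i a_i - p4 b_i)``.  When ``E4i`` is
    interior in its plane (positive viral load), ``sqrt(D) > p4 b_i`` so
    the pair has opposite signs and the point is a saddle.
    """
    a, b, c, p, p4 = params.a, params.b, params.c, params.p, params.p4
    v = (p[i] * a[i] - p4 * b[i]) / (c[i] * p[i])  # viral load at E4i
    if v <= 0:
        raise ValueError(f"E4{i + 1} is not interior: p_i a_i / b_i <= p4")
    disc = p4 ** 2 * b[i] ** 2 + 4 * p[i] * p4 * (p[i] * a[i] - p4 * b[i])
    if disc < 0:
        raise ValueError("negative discriminant inconsistent with an "
                         "interior E4i")
    pair = (-p4 * b[i] + np.array([1.0, -1.0]) * np.sqrt(disc)) / (2 * p[i])
    transverse = [a[j] - c[j] * v for j in range(params.n_types) if j != i]
    return np.array(list(transverse) + list(pair))


def analytic_verdicts(params: ModelParams) -> dict[str, str | None]:
    """Predicted classification of each uncontrolled equilibrium.

    The predictions follow from the closed-form eigenvalues and
    Routh-Hurwitz/deflation arguments: the origin is always a repeller;
    every boundary capacity point (``E1i``, ``E2ij``) is a saddle; the
    virus-free coexistence point ``E3`` is an attractor exactly when
    ``p4 < sum_i p_i a_i / b_i`` and a saddle when the inequality reverses;
    each viral coexistence point (``E4i``, ``E5ij``, ``E6``) is a saddle
    whenever it is interior in the orthant (``None`` otherwise, where the
    argument does not apply).
    """
    k = params.clearance_at_capacity
    out: dict[str, str | None] = {"E0": "repeller"}
    for lbl in ("E11", "E12", "E13", "E212", "E213", "E223"):
        out[lbl] = "saddle"
    if params.p4 < k:
        out["E3"] = "attractor"
    elif params.p4 > k:
        out["E3"] = "saddle"
    else:
        out["E3"] = "nonhyperbolic"
    for eq in enumerate_closed_form(params):
        if eq.label.startswith(("E4", "E5")) or eq.label == "E6":
            out[eq.label] = "saddle" if eq.in_sigma_plus else None
    return out
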