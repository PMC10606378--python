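"""Attractor criteria and closed-form eigenvalues for the controlled models.

The medical controls leave the boundary equilibria largely in place but
reshape their spectra, opening the possibility of *stable* virus-free
states with one or two immunity types missing — the central qualitative
effect of intervention in this model.  This module implements the printed
attractor criteria as predicates and the closed-form boundary eigenvalues
as analytic oracles for the numeric classifier.

All predicates return ``True`` / ``False`` for strict inequalities and
``None`` (indeterminate) when some inequality sits on its boundary within
a tolerance band, where the linearization cannot decide.
"""

from __future__ import annotations

import numpy as np

from .model import ControlParams, ModelParams
from .equilibria import e212_closed_form_pairwise

__all__ = [
    "product_e2_attractor",
    "pairwise_e1_attractor",
    "pairwise_e212_attractor",
    "pairwise_e212_charpoly_factors",
    "controlled_boundary_eigenvalues",
]

_BOUNDARY_BAND = 0.0  # strict by default; predicates take an explicit band


def _strict(conditions, band: float) -> bool | None:
    """All-strict conjunction with an indeterminate band around zero."""
    vals = np.asarray(conditions, dtype=float)
    if np.any(np.abs(vals) <= band):
        return None
    return bool(np.all(vals > 0))


def _require(control: ControlParams, kind: str) -> None:
    if control.kind != kind:
        raise ValueError(f"this predicate applies to the {kind!r} control, "
                         f"got {control.kind!r}")


def product_e2_attractor(params: ModelParams, control: ControlParams,
                         missing: int = 2, band: float = 0.0) -> bool | None:
    """Attractor criterion for a two-type capacity point under the product
    control.

    For ``E212`` (``missing = 2``, i.e. the third type absent) the point is
    an attractor iff ``p4 < p1 a1/b1 + p2 a2/b2`` and
    ``a3 b1 b2 + gamma a1 a2 < 0``: the control constant of the missing
    type must be negative enough to suppress its transverse growth.
    ``missing`` selects the absent type (0-based) for ``E223``/``E213``/
    ``E212`` analogues.
    """
    _require(control, "product")
    a, b, p = params.a, params.b, params.p
    i, j = [m for m in range(3) if m != missing]
    kmiss = control.constants[missing]
    cond_sum = p[i] * a[i] / b[i] + p[j] * a[j] / b[j] - params.p4
    cond_transverse = -(a[missing] * b[i] * b[j] + kmiss * a[i] * a[j])
    return _strict([cond_sum, cond_transverse], band)


def pairwise_e1_attractor(params: ModelParams, control: ControlParams,
                          i: int = 0, band: float = 0.0) -> bool | None:
    """Attractor criterion for a single-type capacity point under the
    pairwise-sum control.

    ``E11`` (``i = 0``) is an attractor iff ``p4 < p1 a1/b1`` and both
    ``a2 b1 + beta a1 < 0`` and ``a3 b1 + gamma a1 < 0``: the controls of
    the two absent types must pull their transverse eigenvalues negative.
    """
    _require(control, "pairwise_sum")
    a, b, p = params.a, params.b, params.p
    conds = [p[i] * a[i] / b[i] - params.p4]
    for j in range(3):
        if j != i:
            conds.append(-(a[j] * b[i] + control.constants[j] * a[i]))
    return _strict(conds, band)


def pairwise_e212_charpoly_factors(params: ModelParams,
                                   control: ControlParams):
    """Factorized characteristic polynomial at pairwise-sum ``E212``.

    Returns ``(lam3, lam4, (q1, q0))`` so that the quartic is
    ``(X - lam3)(X - lam4)(X^2 + q1 X + q0)`` with

    - ``lam3 = a3 + gamma (x1 + x2)`` (transverse to the absent third type),
    - ``lam4 = p4 - p1 x1 - p2 x2`` (viral direction),
    - ``q1 = b1 x1 + b2 x2``, ``q0 = (b1 b2 - alpha beta) x1 x2``
      (the in-plane 2x2 block).
    """
    _require(control, "pairwise_sum")
    a, b, p = params.a, params.b, params.p
    x = e212_closed_form_pairwise(params, control)
    x1, x2 = x[0], x[1]
    lam3 = a[2] + control.gamma * (x1 + x2)
    lam4 = params.p4 - p[0] * x1 - p[1] * x2
    q1 = b[0] * x1 + b[1] * x2
    q0 = (b[0] * b[1] - control.alpha * control.beta) * x1 * x2
    return float(lam3), float(lam4), (float(q1), float(q0))


def pairwise_e212_attractor(params: ModelParams, control: ControlParams,
                            band: float = 0.0):
    """Existence and attractor criterion for pairwise-sum ``E212``.

    Returns ``(exists, verdict)``.  The point exists when
    ``b1 b2 - alpha beta != 0``; it is then an attractor iff all of

    - ``p4 < p1 x1 + p2 x2`` (viral eigenvalue negative),
    - ``a3 + gamma (x1 + x2) < 0`` (transverse eigenvalue negative;
      equivalently the bound ``gamma < -a3 / (x1 + x2)`` when
      ``x1 + x2 > 0``),
    - ``a1 b2 + alpha a2 > 0`` and ``a2 b1 + beta a1 > 0``

    hold strictly, the last pair combining with a positive denominator to
    make the in-plane quadratic factor Hurwitz (``q1 > 0``, ``q0 > 0``).
    """
    _require(control, "pairwise_sum")
    den = params.b[0] * params.b[1] - control.alpha * control.beta
    if den == 0.0:
        return False, None
    lam3, lam4, (q1, q0) = pairwise_e212_charpoly_factors(params, control)
    verdict = _strict([-lam3, -lam4, q1, q0], band)
    return True, verdict


def controlled_boundary_eigenvalues(params: ModelParams,
                                    control: ControlParams,
                                    label: str) -> np.ndarray:
    """Printed closed-form eigenvalues at a boundary equilibrium.

    Supported labels: ``E0``, ``E11``, ``E12``, ``E13`` for both control
    kinds, and ``E212``, ``E213``, ``E223`` for the product control (where
    those points keep their uncontrolled coordinates).
    """
    a, b, p, p4 = params.a, params.b, params.p, params.p4
    kinds = control.constants

    if label == "E0":
        return np.array([a[0], a[1], a[2], p4])

    if label in ("E11", "E12", "E13"):
        i = int(label[2]) - 1
        lam_virus = p4 - p[i] * a[i] / b[i]
        if control.kind == "product":
            # the cubic control vanishes to second order on the axes
            transverse = [a[j] for j in range(3) if j != i]
        elif control.kind == "pairwise_sum":
            transverse = [(a[j] * b[i] + kinds[j] * a[i]) / b[i]
                          for j in range(3) if j != i]
        else:
            raise ValueError("label requires a controlled system")
        return np.array([-a[i]] + transverse + [lam_virus])

    if label in ("E212", "E213", "E223"):
        if control.kind != "product":
            raise ValueError(f"no printed eigenvalues for {label} under the "
                             f"{control.kind!r} control")
        i, j = int(label[2]) - 1, int(label[3]) - 1
        missing = ({0, 1, 2} - {i, j}).pop()
        lam_miss = (a[missing] * b[i] * b[j]
                    + kinds[missing] * a[i] * a[j]) / (b[i] * b[j])
        lam_virus = p4 - p[i] * a[i] / b[i] - p[j] * a[j] / b[j]
        return np.array([-a[i], -a[j], lam_miss, lam_virus])

    raise ValueError(f"unsupported label {label!r}")
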