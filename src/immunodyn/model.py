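"""Core model definitions: parameters, states, vector fields and Jacobians.

The model couples ``n`` immunity compartments ``x_i`` (innate, humoral and
cellular immunity in the standard three-type configuration) with a viral
load ``v``.  Each immunity type grows logistically toward its carrying
capacity ``a_i / b_i`` and is depleted by the virus at rate ``c_i``; the
virus proliferates at rate ``p4`` and is cleared by each immunity type at
rate ``p_i``::

    dx_i/dt = a_i x_i - b_i x_i^2 - c_i x_i v
    dv/dt   = p4 v - sum_i p_i x_i v

Two medically controlled variants are defined for the three-type model,
adding either a product term (``alpha * x1 x2 x3`` etc.) or a pairwise-sum
term (``alpha * x1 (x2 + x3)`` etc.) to the immunity equations; the control
constants ``alpha, beta, gamma`` may take either sign and model external
interventions that boost (or suppress) an immunity compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "ControlParams",
    "State",
    "NO_CONTROL",
    "vector_field",
    "jacobian",
    "logistic_solution",
]

ControlKind = Literal["none", "product", "pairwise_sum"]


def _as_positive_vector(name: str, values: Iterable[float], n: int) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                     dtype=float)
    if arr.ndim != 1 or arr.size != n:
        raise ValueError(f"{name} must be a length-{n} vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
        raise ValueError(f"all entries of {name} must be strictly positive and finite")
    return arr


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the immune-pathogen system.

    Parameters
    ----------
    a : sequence of float
        Intrinsic growth rate of each immunity type (1/time).
    b : sequence of float
        Logistic self-limitation coefficient of each type (1/(level*time));
        ``a_i / b_i`` is the carrying capacity of type ``i``.
    c : sequence of float
        Rate at which the virus depletes each immunity type (1/(load*time)).
    p : sequence of float
        Rate at which each immunity type clears virus (1/(level*time)).
    p4 : float
        Viral proliferation rate (1/time).

    All rates must be strictly positive and finite; ``a``, ``b``, ``c`` and
    ``p`` must share a common length ``n_types >= 1``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    p: np.ndarray
    p4: float

    def __init__(self, a, b, c, p, p4):
        n = len(np.atleast_1d(np.asarray(a, dtype=float)))
        if n < 1:
            raise ValueError("at least one immunity type is required")
        object.__setattr__(self, "a", _as_positive_vector("a", np.atleast_1d(a), n))
        object.__setattr__(self, "b", _as_positive_vector("b", np.atleast_1d(b), n))
        object.__setattr__(self, "c", _as_positive_vector("c", np.atleast_1d(c), n))
        object.__setattr__(self, "p", _as_positive_vector("p", np.atleast_1d(p), n))
        p4 = float(p4)
        if not np.isfinite(p4) or p4 <= 0.0:
            raise ValueError("p4 must be strictly positive and finite")
        object.__setattr__(self, "p4", p4)

    @property
    def n_types(self) -> int:
        return self.a.size

    @property
    def carrying_capacity(self) -> np.ndarray:
        """Virus-free saturation level ``a_i / b_i`` of each immunity type."""
        return self.a / self.b

    @property
    def clearance_at_capacity(self) -> float:
        """Total viral clearance rate ``sum_i p_i a_i / b_i`` at full immunity.

        The virus-free coexistence equilibrium is an attractor exactly when
        ``p4`` is below this threshold.
        """
        return float(np.sum(self.p * self.a / self.b))

    @classmethod
    def unit(cls, n_types: int = 3, p4: float = 0.5) -> "ModelParams":
        """All rates equal to 1 except ``p4`` — the standard test bed."""
        ones = np.ones(n_types)
        return cls(a=ones, b=ones, c=ones, p=ones, p4=p4)

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "p": self.p.tolist(),
            "p4": self.p4,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(a=d["a"], b=d["b"], c=d["c"], p=d["p"], p4=d["p4"])


@dataclass(frozen=True)
class ControlParams:
    """Medical-control configuration for the three-type model.

    ``kind='product'`` adds ``alpha*x1*x2*x3``, ``beta*x1*x2*x3`` and
    ``gamma*x1*x2*x3`` to the three immunity equations; ``'pairwise_sum'``
    adds ``alpha*x1*(x2+x3)``, ``beta*x2*(x3+x1)`` and ``gamma*x3*(x1+x2)``.
    The constants may take either sign.  Controls are only defined for
    ``n_types == 3``.
    """

    kind: ControlKind = "none"
    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "product", "pairwise_sum"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        for name in ("alpha", "beta", "gamma"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)

    @property
    def constants(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def validate_against(self, params: ModelParams) -> None:
        if self.kind != "none" and params.n_types != 3:
            raise ValueError(
                f"control kind {self.kind!r} requires exactly 3 immunity types, "
                f"got {params.n_types}"
            )

    def to_dict(self) -> dict:
        return {"kind": self.kind, "alpha": self.alpha, "beta": self.beta,
                "gamma": self.gamma}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ControlParams":
        return cls(kind=d.get("kind", "none"), alpha=d.get("alpha", 0.0),
                   beta=d.get("beta", 0.0), gamma=d.get("gamma", 0.0))


NO_CONTROL = ControlParams()


@dataclass(frozen=True)
class State:
    """A point of the state space: immunity levels ``x`` and viral load ``v``.

    Internally the viral load is the last component of the packed vector.
    """

    x: np.ndarray
    v: float

    def __init__(self, x, v):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(x)) or not np.isfinite(v):
            raise ValueError("state components must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "v", float(v))

    def to_array(self) -> np.ndarray:
        return np.append(self.x, self.v)

    @classmethod
    def from_array(cls, u: np.ndarray) -> "State":
        u = np.asarray(u, dtype=float)
        return cls(x=u[:-1], v=u[-1])

    @property
    def in_closed_orthant(self) -> bool:
        return bool(np.all(self.to_array() >= 0.0))

    @property
    def in_sigma_plus(self) -> bool:
        return bool(np.all(self.to_array() > 0.0))

    def to_dict(self) -> dict:
        return {"x": self.x.tolist(), "v": self.v}


def _coerce_state(state) -> np.ndarray:
    if isinstance(state, State):
        return state.to_array()
    return np.asarray(state, dtype=float)


def vector_field(params: ModelParams, control: ControlParams, state) -> np.ndarray:
    """Time derivative ``(dx_1, ..., dx_n, dv)`` of the selected system.

    ``state`` may be a :class:`State` or a plain array with the viral load
    last.  The immunity hyperplanes ``{x_i = 0}`` and ``{v = 0}`` are
    invariant: the corresponding component of the returned vector vanishes
    whenever the state component does.
    """
    control.validate_against(params)
    u = _coerce_state(state)
    n = params.n_types
    x, v = u[:n], u[n]
    dx = x * (params.a - params.b * x - params.c * v)
    dv = v * (params.p4 - params.p @ x)
    if control.kind == "product":
        dx = dx + control.constants * (x[0] * x[1] * x[2])
    elif control.kind == "pairwise_sum":
        s = np.sum(x)
        # x_i * (sum of the other two) == x_i * (s - x_i)
        dx = dx + control.constants * x * (s - x)
    return np.append(dx, dv)


def jacobian(params: ModelParams, control: ControlParams, state) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field` at ``state``."""
    control.validate_against(params)
    u = _coerce_state(state)
    n = params.n_types
    x, v = u[:n], u[n]
    J = np.zeros((n + 1, n + 1))
    J[np.arange(n), np.arange(n)] = params.a - 2.0 * params.b * x - params.c * v
    J[:n, n] = -params.c * x
    J[n, :n] = -params.p * v
    J[n, n] = params.p4 - params.p @ x
    if control.kind == "product":
        k = control.constants
        for i in range(3):
            for j in range(3):
                prod_others = np.prod([x[m] for m in range(3) if m != j])
                J[i, j] += k[i] * prod_others
    elif control.kind == "pairwise_sum":
        k = control.constants
        s = np.sum(x)
        for i in range(3):
            J[i, i] += k[i] * (s - x[i])
            for j in range(3):
                if j != i:
                    J[i, j] += k[i] * x[i]
    return J


def logistic_solution(a: float, b: float, x0: float, t) -> np.ndarray | float:
    """Closed-form solution of the logistic law ``dx/dt = a x - b x^2``.

    ``x(t) = a x0 e^{a t} / (a + b x0 (e^{a t} - 1))``, which tends to the
    carrying capacity ``a/b`` as ``t -> inf`` for any ``x0 > 0``.  Evaluated
    in a form stable for large ``a t``.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if x0 < 0:
        raise ValueError("x0 must be nonnegative")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be nonnegative")
    # multiply through by e^{-a t} to avoid overflow for large t
    em = np.exp(-a * t_arr)
    out = a * x0 / (a * em + b * x0 * (1.0 - em))
    if x0 == 0.0:
        out = np.zeros_like(t_arr)
    return out if out.ndim else float(out)
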