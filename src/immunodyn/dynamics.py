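"""Trajectory integration and long-run outcome classification.

The qualitative alternatives of the model are: the viral load converges to
zero with immunity settling at capacity (the immune system wins), the
state converges to some other equilibrium, or the viral load grows without
bound (viral escape — operationalized by a finite threshold event, since
an integrator cannot follow an orbit to infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (NO_CONTROL, ControlParams, ModelParams, State, jacobian,
                    vector_field)
from .equilibria import Equilibrium

__all__ = [
    "Trajectory",
    "Outcome",
    "simulate",
    "classify_outcome",
    "invariance_audit",
    "escape_threshold",
]


@dataclass(frozen=True)
class Trajectory:
    t: np.ndarray
    y: np.ndarray  # shape (n_states, n_times)
    escaped: bool
    params: ModelParams
    control: ControlParams

    @property
    def final_state(self) -> np.ndarray:
        return self.y[:, -1]

    @property
    def viral_load(self) -> np.ndarray:
        return self.y[-1]


@dataclass(frozen=True)
class Outcome:
    kind: str  # "converged" | "escaping" | "undetermined"
    label: str | None = None  # equilibrium label when converged

    def __str__(self) -> str:
        return f"converged-to({self.label})" if self.kind == "converged" \
            else self.kind


def escape_threshold(params: ModelParams) -> float:
    """Finite proxy for 'escape to infinity': any component beyond
    ``1e6 * max(carrying capacity, 1)`` counts as escaped."""
    return 1e6 * max(float(np.max(params.carrying_capacity)), 1.0)


def simulate(params: ModelParams, control: ControlParams = NO_CONTROL,
             state0=None, t_end: float = 100.0, rtol: float = 1e-8,
             atol: float = 1e-10, method: str | None = None,
             max_points: int = 2000) -> Trajectory:
    """Integrate the selected system from ``state0`` up to ``t_end``.

    Integration stops early at the escape event.  The default method is
    LSODA with the analytic Jacobian: escaping orbits make the immunity
    equations arbitrarily stiff (decay rates grow with the viral load), and
    LSODA switches to its implicit mode automatically when that happens.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    u0 = state0.to_array() if isinstance(state0, State) \
        else np.asarray(state0, dtype=float)
    if np.any(u0 < 0):
        raise ValueError("initial state must lie in the closed orthant")
    control.validate_against(params)

    if method is None:
        method = "LSODA"

    thresh = escape_threshold(params)

    def rhs(t, u):
        return vector_field(params, control, u)

    def jac(t, u):
        return jacobian(params, control, u)

    def escape_event(t, u):
        return thresh - np.max(u)

    escape_event.terminal = True
    escape_event.direction = -1

    use_jac = method in ("LSODA", "Radau", "BDF")
    sol = solve_ivp(rhs, (0.0, t_end), u0, method=method, rtol=rtol,
                    atol=atol, events=escape_event, dense_output=False,
                    jac=jac if use_jac else None,
                    t_eval=np.linspace(0.0, t_end, max_points))
    if sol.status == -1:
        raise RuntimeError(f"integration failed: {sol.message}; last state "
                           f"{sol.y[:, -1] if sol.y.size else u0}")
    escaped = sol.status == 1
    t, y = sol.t, sol.y
    if escaped and sol.t_events[0].size:
        t = np.append(t, sol.t_events[0][0])
        y = np.column_stack([y, sol.y_events[0][0]])
    return Trajectory(t=t, y=y, escaped=escaped, params=params,
                      control=control)


def classify_outcome(traj: Trajectory, equilibria: Sequence[Equilibrium],
                     tol: float = 1e-6) -> Outcome:
    """Label the long-run behavior of a trajectory.

    ``converged`` to a listed equilibrium requires the final state within
    ``tol`` (max norm) of its coordinates *and* a vector-field norm below
    ``tol`` there, guarding against slow saddle fly-bys; ``escaping``
    requires the escape event with the viral load still growing;
    anything else is ``undetermined``.
    """
    if traj.t.size == 0:
        return Outcome("undetermined")
    u = traj.final_state
    if traj.escaped:
        dv = vector_field(traj.params, traj.control, u)[-1]
        if dv > 0 or np.max(u[:-1]) >= escape_threshold(traj.params):
            return Outcome("escaping")
        return Outcome("undetermined")
    deriv = float(np.max(np.abs(vector_field(traj.params, traj.control, u))))
    if deriv < tol:
        for eq in equilibria:
            if float(np.max(np.abs(u - eq.coords))) < tol:
                return Outcome("converged", eq.label)
    return Outcome("undetermined")


def invariance_audit(params: ModelParams, control: ControlParams = NO_CONTROL,
                     n_draws: int = 50, seed: int = 0,
                     t_end: float = 50.0) -> float:
    """Worst (most negative) state component seen across seeded runs.

    Integrates random starts in the open orthant and on each boundary
    hyperplane; a correct integration of this model never leaves the
    closed orthant beyond roundoff, so the returned value should exceed
    roughly ``-1e-7``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_types
    cap = params.carrying_capacity
    scale = np.append(cap, max(float(np.max(cap)), params.p4))
    worst = 0.0
    for d in range(n_draws):
        u0 = scale * 10.0 ** rng.uniform(-2, 0.5, size=n + 1)
        if d % 2 == 1:  # pin one coordinate to its invariant hyperplane
            u0[d % (n + 1)] = 0.0
        traj = simulate(params, control, u0, t_end=t_end,
                        rtol=1e-8, atol=1e-10)
        worst = min(worst, float(np.min(traj.y)))
    return worst
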