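import numpy as np
import pytest

from immunodyn import ControlParams, ModelParams, NO_CONTROL


@pytest.fixture
def unit_params():
    """Unit rates with p4 = 0.5: every equilibrium lies in the closed
    orthant and the virus-free coexistence point is an attractor."""
    return ModelParams.unit()


@pytest.fixture
def on_surface_params():
    """Unit rates with p4 = 3 = sum p_i a_i / b_i: on the transcritical
    collision surface where E6 meets E3."""
    return ModelParams.unit(p4=3.0)


def interior_e6_params(n, seed, frac=0.5):
    """Random parameter sets tuned so the interior equilibrium E6 exists.

    Rates are drawn log-uniformly and p4 is then set so the shared viral
    load equals ``frac * min_i a_i/c_i``, which places E6 strictly inside
    the orthant whenever the resulting p4 is positive.
    """
    from immunodyn import sample_params

    out = []
    for params in sample_params(3 * n, seed=seed):
        v_target = frac * float(np.min(params.a / params.c))
        p4 = params.clearance_at_capacity - v_target * float(
            np.sum(params.p * params.c / params.b))
        if p4 <= 1e-6:
            continue
        out.append(ModelParams(a=params.a, b=params.b, c=params.c,
                               p=params.p, p4=p4))
        if len(out) == n:
            break
    return out


def numeric_jacobian(fun, u, h=1e-6):
    """Central finite-difference Jacobian of a vector function."""
    u = np.asarray(u, dtype=float)
    m = fun(u).size
    J = np.zeros((m, u.size))
    for j in range(u.size):
        step = h * max(1.0, abs(u[j]))
        up, um = u.copy(), u.copy()
        up[j] += step
        um[j] -= step
        J[:, j] = (fun(up) - fun(um)) / (2 * step)
    return J
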