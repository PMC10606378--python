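"""Seeded random parameter generation for sweeps and property checks."""

from __future__ import annotations

import numpy as np

from .model import ControlParams, ModelParams

__all__ = ["sample_params", "sample_controls"]


def sample_params(n: int, seed: int, n_types: int = 3,
                  rate_range: tuple[float, float] = (0.1, 10.0),
                  p4_range: tuple[float, float] | None = None) -> list[ModelParams]:
    """Draw ``n`` parameter sets with log-uniform rates.

    All per-type rates and ``p4`` are log-uniform in ``rate_range`` (or in
    ``p4_range`` when given).  Identical seeds reproduce identical draws.
    """
    lo, hi = rate_range
    if lo <= 0 or hi <= lo:
        raise ValueError("rate_range must satisfy 0 < lo < hi")
    p4_lo, p4_hi = p4_range if p4_range is not None else rate_range
    if p4_lo <= 0 or p4_hi <= p4_lo:
        raise ValueError("p4_range must satisfy 0 < lo < hi")
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)

    def draw(a, b, size=n_types):
        return np.exp(rng.uniform(np.log(a), np.log(b), size=size))

    out = []
    for _ in range(n):
        out.append(ModelParams(a=draw(lo, hi), b=draw(lo, hi),
                               c=draw(lo, hi), p=draw(lo, hi),
                               p4=float(draw(p4_lo, p4_hi, size=1)[0])))
    return out


def sample_controls(n: int, seed: int, kind: str,
                    const_range: tuple[float, float] = (-3.0, 3.0)) -> list[ControlParams]:
    """Draw ``n`` control configurations with uniform constants."""
    lo, hi = const_range
    if hi <= lo:
        raise ValueError("const_range must satisfy lo < hi")
    rng = np.random.default_rng(seed)
    return [ControlParams(kind=kind, alpha=rng.uniform(lo, hi),
                          beta=rng.uniform(lo, hi),
                          gamma=rng.uniform(lo, hi))
            for _ in range(n)]
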