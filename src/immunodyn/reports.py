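"""Tabular report builders shared by the CLI and the library API."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import NO_CONTROL, ControlParams, ModelParams
from .equilibria import Equilibrium
from .stability import analytic_verdicts, classify

__all__ = ["equilibrium_table", "write_table", "write_json"]


def equilibrium_table(params: ModelParams, eqs: Sequence[Equilibrium],
                      control: ControlParams = NO_CONTROL,
                      with_stability: bool = True) -> pd.DataFrame:
    """One row per equilibrium: coordinates, orthant status, spectrum.

    For the uncontrolled three-type system a ``predicted`` column carries
    the analytic saddle/attractor verdicts next to the numeric
    classification.
    """
    n = params.n_types
    predicted = (analytic_verdicts(params)
                 if control.kind == "none" and n == 3 else {})
    rows = []
    for eq in eqs:
        row = {"label": eq.label,
               "support": "".join(str(i + 1) for i in sorted(eq.support)),
               "virus_on": eq.virus_on}
        for i in range(n):
            row[f"x{i + 1}"] = eq.coords[i]
        row["v"] = eq.coords[-1]
        row["in_sigma_plus"] = eq.in_sigma_plus
        if with_stability:
            rep = classify(params, control, eq)
            row["eigenvalues"] = ";".join(
                f"{z.real:.12g}{z.imag:+.12g}j" if abs(z.imag) > 0
                else f"{z.real:.12g}" for z in rep.eigenvalues)
            row["classification"] = rep.classification
            if predicted:
                row["predicted"] = predicted.get(eq.label)
        if control.kind != "none":
            row.update(control_kind=control.kind, alpha=control.alpha,
                       beta=control.beta, gamma=control.gamma)
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: Path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        df.to_json(path, orient="records", indent=1)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return [[z.real, z.imag] for z in obj]
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(payload: dict, path: Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(payload), indent=1))
    return path
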