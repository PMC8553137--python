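"""Local (derivative-based) sensitivity of response functionals.

Q_i = (∂y/∂x_i)/(y/x_i) at a reference point x*, computed by a forward
difference with a relative 5% step: Q = (y(x*·(1+h)e_i)/y(x*) − 1)/h.  It is
the elasticity of the functional — the relative output change per relative
parameter change — so entries are unit-free and comparable across rows.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import pandas as pd

from .parameters import ParameterSet

__all__ = ["local_Q", "local_sensitivity_matrix", "local_sensitivity_from_vector_evaluator"]

DEFAULT_REL_STEP = 0.05


def local_Q(
    evaluator: Callable[[ParameterSet], float],
    x_star: ParameterSet,
    name: str,
    rel_step: float = DEFAULT_REL_STEP,
    y_base: float | None = None,
) -> float | None:
    """Elasticity of ``evaluator`` with respect to parameter ``name`` at
    ``x_star``.  Returns None when the base value is zero or either
    evaluation is undefined."""
    if y_base is None:
        y_base = evaluator(x_star)
    if y_base is None or y_base == 0:
        return None
    x_i = getattr(x_star, name)
    y_plus = evaluator(x_star.replace(**{name: x_i * (1.0 + rel_step)}))
    if y_plus is None:
        return None
    return (y_plus / y_base - 1.0) / rel_step


def local_sensitivity_matrix(
    evaluators: Mapping[str, Callable[[ParameterSet], float]],
    x_star: ParameterSet,
    param_names: Sequence[str],
    rel_step: float = DEFAULT_REL_STEP,
) -> pd.DataFrame:
    """Q_i matrix: rows are parameters, columns are functionals.

    The base evaluation of each functional is computed once and shared across
    all rows; solver settings must be deterministic so differences reflect
    the model and not integration noise.
    """
    base = {fn: ev(x_star) for fn, ev in evaluators.items()}
    rows = {}
    for name in param_names:
        rows[name] = {
            fn: local_Q(ev, x_star, name, rel_step, y_base=base[fn])
            for fn, ev in evaluators.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(evaluators))
    df.index.name = "parameter"
    return df.astype(float)


def local_sensitivity_from_vector_evaluator(
    vector_evaluator: Callable[[ParameterSet], Mapping[str, float | None]],
    x_star: ParameterSet,
    param_names: Sequence[str],
    rel_step: float = DEFAULT_REL_STEP,
) -> pd.DataFrame:
    """Q_i matrix from an evaluator returning all functionals of one run.

    One model evaluation per perturbed parameter (plus one base run) instead
    of one per matrix cell; preferred when each evaluation integrates the
    full response.
    """
    base = dict(vector_evaluator(x_star))
    rows = {}
    for name in param_names:
        x_i = getattr(x_star, name)
        plus = dict(vector_evaluator(x_star.replace(**{name: x_i * (1.0 + rel_step)})))
        rows[name] = {
            fn: (
                None
                if base.get(fn) in (None, 0) or plus.get(fn) is None
                else (plus[fn] / base[fn] - 1.0) / rel_step
            )
            for fn in base
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(base))
    df.index.name = "parameter"
    return df.astype(float)
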