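"""Pipelines tying the stages together: global sensitivity runs and the
MCMC reproduction experiment, with manifests for reproducibility.

Two fast evaluation paths serve the Monte Carlo sensitivity designs: the
dark current J_dark through the vectorized dark-state solver (no time
integration needed) and peak E* through the vectorized cascade integrator.
The full nine-functional evaluation integrates the coupled response per
design row and is intended for small N.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cascade import peak_Estar_batch
from .darkstate import solve_dark_state_batch
from .functionals import FUNCTIONAL_NAMES, compute_functionals
from .mcmc_fit import FlashResponseModel, MCMCConfig
from .parameters import ParameterRanges, gsa_ranges, mouse_cone_parameters, parameter_set_from_draw
from .photoresponse import simulate_response
from .sensitivity_sobol import SobolDesign, SobolResult, estimate_indices, sample_design, Target
from .synthetic_data import ExperimentTrace, generate_experiment

__all__ = [
    "evaluate_dark_current",
    "evaluate_peak_Estar",
    "evaluate_functionals_rows",
    "run_sobol",
    "reproduce_gsa",
    "reproduce_fit",
    "write_manifest",
]


def evaluate_dark_current(cols: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """J_dark for each design row via the vectorized dark-state solver."""
    return {"J_dark": solve_dark_state_batch(cols)["J_dark"]}


def evaluate_peak_Estar(cols: dict[str, np.ndarray], phi: float = 940.0) -> dict[str, np.ndarray]:
    """Peak total E* for each design row via the vectorized cascade."""
    return {"E_peak": peak_Estar_batch(cols, phi=phi)}


def evaluate_functionals_rows(
    cols: dict[str, np.ndarray],
    phi: float = 940.0,
    t_end: float = 0.5,
    dt: float = 1e-3,
    rtol: float = 1e-6,
    target: ExperimentTrace | None = None,
    functionals: Sequence[str] = FUNCTIONAL_NAMES,
) -> dict[str, np.ndarray]:
    """All requested functionals per design row, by full response integration.

    Failed integrations or undefined functionals yield NaN for that row, to
    be excluded pairwise by the index estimator.  O(N) ODE solves: meant for
    desk-scale N.
    """
    n = len(next(iter(cols.values())))
    target_t = target.t if target is not None else None
    target_drop = target.drop(int(phi)) if target is not None else None
    out = {fn: np.full(n, np.nan) for fn in functionals}
    for i in range(n):
        draw = {k: float(v[i]) for k, v in cols.items()}
        try:
            p = parameter_set_from_draw(draw)
            tr = simulate_response(p, phi, t_end=t_end, dt=dt, rtol=rtol)
            fv = compute_functionals(tr, target_t=target_t, target_drop=target_drop)
        except (ValueError, RuntimeError):
            continue
        d = fv.as_dict()
        for fn in functionals:
            v = d.get(fn)
            out[fn][i] = np.nan if v is None else v
    return out


def run_sobol(
    targets: Sequence[Target],
    evaluator,
    N: int = 10_000,
    seed: int = 0,
    ranges: ParameterRanges | None = None,
) -> tuple[SobolDesign, SobolResult]:
    """Sample a Saltelli design, evaluate it, and estimate the indices.

    ``evaluator`` maps a name→column dict to a functional-name→values dict;
    it is called on A, B, and each target's swapped matrix.
    """
    if ranges is None:
        ranges = gsa_ranges()
    design = sample_design(ranges, N, seed, targets)
    fA = evaluator(design.as_params(design.A))
    fB = evaluator(design.as_params(design.B))
    fAB = {}
    for t in design.targets:
        key = t if isinstance(t, str) else "(" + ",".join(t) + ")"
        fAB[key] = evaluator(design.as_params(design.AB(t)))
    return design, estimate_indices(design, fA, fB, fAB)


def write_manifest(out_dir: Path, **entries) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"package_version": __version__, **entries}
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def reproduce_gsa(
    out_dir: str | Path,
    N: int = 10_000,
    seed: int = 0,
    phi: float = 940.0,
    top_k: int = 8,
    functionals: Sequence[str] = ("I_act", "E_act", "I_drop", "E_peak", "E_rec", "T_peak", "J_dark", "J_over"),
) -> SobolResult:
    """Full single-parameter Sobol screen of the flash-response functionals.

    Runs the per-row response integration for every sampled parameter as a
    target, writes the long-format table, wide S/S_tot matrices, and ranked
    top-``top_k`` CSVs per functional, plus a manifest.
    """
    out_dir = Path(out_dir)
    ranges = gsa_ranges()
    targets: list[Target] = list(ranges.names)
    _, result = run_sobol(
        targets,
        lambda cols: evaluate_functionals_rows(cols, phi=phi, functionals=functionals),
        N=N, seed=seed, ranges=ranges,
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "sobol_long.csv", index=False)
    for col, name in (("S", "sobol_single_matrix.csv"), ("S_tot", "sobol_total_matrix.csv")):
        wide = result.table.pivot(index="target", columns="functional", values=col)
        wide.to_csv(out_dir / name)
    for fn in functionals:
        sub = result.table[result.table["functional"] == fn]
        sub.sort_values("S_tot", ascending=False).head(top_k).to_csv(
            out_dir / f"ranked_{fn}.csv", index=False
        )
    write_manifest(out_dir, stage="gsa", N=N, seed=seed, phi=phi, functionals=list(functionals))
    return result


def reproduce_fit(
    out_dir: str | Path,
    n_steps: int = 2000,
    seed: int = 0,
    noise_sd: float = 0.3,
    start: dict[str, float] | None = None,
    free_names: Sequence[str] | None = None,
):
    """Fit the model to a synthetic half-maximal-flash target by MCMC.

    Generates the synthetic experiment at the packaged best-fit parameters,
    runs the chain under the hard/soft constraint tables, and writes the
    chain CSV, the best-fit parameter table, and a manifest.
    """
    out_dir = Path(out_dir)
    theta = mouse_cone_parameters()
    target = generate_experiment(theta, noise_sd=noise_sd, seed=seed)
    config = MCMCConfig(n_steps=n_steps, seed=seed)
    kwargs = {} if free_names is None else {"free_names": list(free_names)}
    model = FlashResponseModel(target, config=config, **kwargs)
    if start is None:
        start = {n: getattr(theta, n, None) for n in model.free_names}
        start["alpha_ratio"] = theta.alpha_max / theta.alpha_min
        start = {k: v for k, v in start.items() if v is not None}
    res = model.fit(start=start)
    out_dir.mkdir(parents=True, exist_ok=True)
    res.chain.to_frame().to_csv(out_dir / "chain.csv", index=False)
    best = pd.Series(res.chain.best_draw, name="best_fit")
    best.to_csv(out_dir / "best_fit.csv", header=True)
    (out_dir / "summary.txt").write_text(res.summary())
    write_manifest(out_dir, stage="mcmc", n_steps=n_steps, seed=seed, noise_sd=noise_sd)
    return res
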