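"""Metropolis–Hastings parameter fitting against a recorded flash response.

The stationary density over parameter space x is

    π(x) ∝ (∏_i 2^(−γ·dist(x_i, I_i))) · ‖e(x)‖₂^(−β) · 1_K(x)

where e(x) is the rms error between the model's 940-photoisomerization
current drop and the target trace, I_i are the expected ("soft") intervals
with dist the distance outside the interval normalized by its width, and K
is the hard constraint set — bounds on parameters and on the derived
dark-state quantities ([cG]_dark, [Ca²⁺]_dark, J_dark).  The chain is a
random-walk exploration biased toward low-error regions, not a Bayesian
posterior; the deliverable is the best-fit (lowest-error) sample.

The fitting surface follows the Model → fit() → Results convention:
``FlashResponseModel(target).fit()`` returns a :class:`FlashResponseResults`
carrying the best-fit parameter set, the chain, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .darkstate import solve_dark_state
from .parameters import (
    ParameterRanges,
    ParameterSet,
    mcmc_hard_constraints,
    mcmc_soft_ranges,
    mouse_cone_parameters,
    parameter_set_from_draw,
)
from .photoresponse import simulate_response
from .synthetic_data import ExperimentTrace

__all__ = [
    "MCMCConfig",
    "MCMCChain",
    "rms_error",
    "interval_distance",
    "log_density",
    "metropolis_hastings",
    "run_chain",
    "FlashResponseModel",
    "FlashResponseResults",
    "DEFAULT_FREE_PARAMETERS",
]

#: parameters varied by the search (geometry and D_Ca held fixed); the
#: minimum cyclase rate moves through the alpha_max/alpha_min ratio.
DEFAULT_FREE_PARAMETERS = (
    "k_GE", "nu_RG", "k_R", "k_E", "G_sigma", "PDE_sigma", "beta_dark",
    "B_cG", "kcat_Km", "alpha_max", "alpha_ratio", "m_cyc", "K_cyc",
    "B_Ca", "JcG_max", "m_cG", "K_cG", "f_Ca", "Jex_sat", "K_ex",
)


@dataclass(frozen=True)
class MCMCConfig:
    gamma: float = 5.0  # soft-penalty weight (density factor 2^−γ per interval-width of excursion)
    beta: float = 2.0  # error exponent
    proposal_scale: float = 0.02  # Gaussian step, as a fraction of each interval width
    proposal_scales: dict | None = None  # optional per-parameter overrides (fraction of width)
    n_steps: int = 2000
    seed: int = 0
    phi_fit: float = 940.0  # photoisomerizations of the fitted trace
    t_end: float = 0.5
    dt: float = 1e-3
    rtol: float = 1e-6  # integrator tolerance during the search
    max_start_attempts: int = 20000

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        if self.proposal_scale <= 0:
            raise ValueError("proposal_scale must be positive")


@dataclass
class MCMCChain:
    free_names: list[str]
    samples: np.ndarray  # n_steps × len(free_names), current state each step
    errors: np.ndarray  # rms values e(x), pA
    log_densities: np.ndarray
    accepted: np.ndarray  # bool per proposal
    best_index: int

    @property
    def best_draw(self) -> dict[str, float]:
        return dict(zip(self.free_names, self.samples[self.best_index]))

    @property
    def best_error(self) -> float:
        return float(self.errors[self.best_index])

    @property
    def acceptance_rate(self) -> float:
        return float(np.mean(self.accepted))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.free_names)
        df["rms"] = self.errors
        df["log_density"] = self.log_densities
        df["accepted"] = self.accepted
        return df


def rms_error(
    p: ParameterSet,
    target: ExperimentTrace,
    phi: float = 940.0,
    t_end: float | None = None,
    dt: float = 1e-3,
    rtol: float = 1e-6,
) -> float:
    """rms misfit (pA) between the model drop at ``phi`` and the target drop,
    at the target's sample times.  Infinite when no dark state exists."""
    dark = solve_dark_state(p)
    if not dark.exists:
        return math.inf
    t_target = target.t
    if t_end is None:
        t_end = float(t_target[-1])
    try:
        tr = simulate_response(p, phi, t_end=t_end, dt=dt, rtol=rtol, dark=dark)
    except RuntimeError:
        return math.inf
    model = np.interp(t_target, tr.t, tr.drop)
    return float(np.sqrt(np.mean((model - target.drop(int(phi))) ** 2)))


def interval_distance(x: float, lo: float, hi: float) -> float:
    """Distance of x from [lo, hi], normalized by the interval width
    (0 inside; unit-free so one γ weights heterogeneous parameters)."""
    w = hi - lo
    if w <= 0:
        return 0.0 if x == lo else math.inf
    return max(0.0, lo - x, x - hi) / w


def _satisfies_hard(draw: dict[str, float], p: ParameterSet, hard: ParameterRanges) -> bool:
    dark = solve_dark_state(p)
    if not dark.exists:
        return False
    derived = {
        "cG_dark": dark.cG_dark,
        "Ca_dark": dark.Ca_dark,
        "J_dark": dark.J_dark,
    }
    for r in hard:
        if r.name in draw:
            x = draw[r.name]
        elif r.name in derived:
            x = derived[r.name]
        elif hasattr(p, r.name):
            x = getattr(p, r.name)
        else:
            continue
        if not (r.lo <= x <= r.hi):
            return False
    return True


def log_density(
    p: ParameterSet,
    target: ExperimentTrace | None,
    soft: ParameterRanges,
    config: MCMCConfig,
    hard: ParameterRanges | None = None,
    draw: dict[str, float] | None = None,
    rms: float | None = None,
) -> tuple[float, float]:
    """(log π(x), rms error).  −∞ outside the hard constraint set K.

    K bounds both raw parameters and the dark-state quantities derived from
    them.  With ``target`` None the error factor is dropped (flat-error
    density, useful for sampler diagnostics).
    """
    if draw is None:
        draw = {}
    if hard is not None and not _satisfies_hard(draw, p, hard):
        return -math.inf, math.inf
    penalty = 0.0
    for r in soft:
        if r.name in draw:
            x = draw[r.name]
        elif hasattr(p, r.name):
            x = getattr(p, r.name)
        else:
            continue
        penalty += interval_distance(x, r.lo, r.hi)
    logpi = -config.gamma * math.log(2.0) * penalty
    e = 1.0
    if target is not None:
        if rms is None:
            rms = rms_error(p, target, config.phi_fit, dt=config.dt, rtol=config.rtol)
        e = rms
        if not math.isfinite(e):
            return -math.inf, math.inf
        logpi += -config.beta * math.log(max(e, 1e-300))
    return logpi, e


def metropolis_hastings(
    logpi: Callable[[np.ndarray], tuple[float, float]],
    x0: np.ndarray,
    step_sd: np.ndarray,
    n_steps: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generic symmetric Gaussian random-walk MH kernel.

    ``logpi`` returns (log density, auxiliary error); the auxiliary value of
    the current state is recorded each step.  Returns (states, log
    densities, errors, accepted flags).
    """
    x = np.asarray(x0, dtype=float).copy()
    lp, err = logpi(x)
    if not math.isfinite(lp):
        raise ValueError("start point has zero density")
    d = len(x)
    states = np.empty((n_steps, d))
    lps = np.empty(n_steps)
    errs = np.empty(n_steps)
    acc = np.zeros(n_steps, dtype=bool)
    for k in range(n_steps):
        prop = x + rng.normal(0.0, step_sd, size=d)
        lp_prop, err_prop = logpi(prop)
        if math.isfinite(lp_prop) and math.log(rng.random()) < lp_prop - lp:
            x, lp, err = prop, lp_prop, err_prop
            acc[k] = True
        states[k] = x
        lps[k] = lp
        errs[k] = err
    return states, lps, errs, acc


def run_chain(
    target: ExperimentTrace | None,
    config: MCMCConfig,
    hard: ParameterRanges | None = None,
    soft: ParameterRanges | None = None,
    free_names: Sequence[str] = DEFAULT_FREE_PARAMETERS,
    base: ParameterSet | None = None,
    start: dict[str, float] | None = None,
) -> MCMCChain:
    """Run the Metropolis–Hastings search over the free parameters.

    Proposals are componentwise Gaussian with standard deviation
    ``proposal_scale`` times each soft-interval width.  Without an explicit
    ``start``, a feasible point inside K is sought by rejection sampling of
    the soft boxes (raises after ``max_start_attempts`` failures).
    """
    if hard is None:
        hard = mcmc_hard_constraints()
    if soft is None:
        soft = mcmc_soft_ranges()
    if base is None:
        base = mouse_cone_parameters()
    free_names = list(free_names)
    for n in free_names:
        if n not in soft:
            raise KeyError(f"free parameter {n!r} has no soft range (needed for proposal scale)")
    widths = np.array([soft[n].width() for n in free_names])
    rng = np.random.default_rng(config.seed)

    def make_params(x: np.ndarray) -> tuple[dict[str, float], ParameterSet | None]:
        draw = dict(zip(free_names, x))
        try:
            return draw, parameter_set_from_draw(draw, base=base)
        except ValueError:
            return draw, None

    def logpi(x: np.ndarray) -> tuple[float, float]:
        draw, p = make_params(x)
        if p is None:
            return -math.inf, math.inf
        return log_density(p, target, soft, config, hard=hard, draw=draw)

    if start is not None:
        x0 = np.array([start[n] for n in free_names])
        if not math.isfinite(logpi(x0)[0]):
            raise ValueError("supplied start point lies outside the hard constraint set")
    else:
        los = np.array([soft[n].lo for n in free_names])
        x0 = None
        for _ in range(config.max_start_attempts):
            cand = los + widths * rng.random(len(free_names))
            draw, p = make_params(cand)
            if p is not None and _satisfies_hard(draw, p, hard):
                x0 = cand
                break
        if x0 is None:
            raise RuntimeError(
                f"no feasible start found in {config.max_start_attempts} rejection-sampling attempts"
            )

    scales = np.array(
        [(config.proposal_scales or {}).get(n, config.proposal_scale) for n in free_names]
    )
    states, lps, errs, acc = metropolis_hastings(logpi, x0, scales * widths, config.n_steps, rng)
    finite = np.where(np.isfinite(errs), errs, np.inf)
    return MCMCChain(
        free_names=free_names, samples=states, errors=errs,
        log_densities=lps, accepted=acc, best_index=int(np.argmin(finite)),
    )


class FlashResponseModel:
    """Kinetic flash-response model bound to a target recording.

    Parameters
    ----------
    target : ExperimentTrace
        The flash family to fit; must contain the configured fitting
        intensity (940 photoisomerizations by default).
    free_names : sequence of str
        Parameters the search may move; the rest are taken from ``base``.
    """

    def __init__(
        self,
        target: ExperimentTrace,
        config: MCMCConfig | None = None,
        hard: ParameterRanges | None = None,
        soft: ParameterRanges | None = None,
        free_names: Sequence[str] = DEFAULT_FREE_PARAMETERS,
        base: ParameterSet | None = None,
    ):
        self.target = target
        self.config = config or MCMCConfig()
        if int(self.config.phi_fit) not in target.intensities:
            raise ValueError(
                f"target lacks the fitting intensity {int(self.config.phi_fit)}"
            )
        self.hard = hard or mcmc_hard_constraints()
        self.soft = soft or mcmc_soft_ranges()
        self.free_names = list(free_names)
        self.base = base or mouse_cone_parameters()

    def fit(self, start: dict[str, float] | None = None, seed: int | None = None) -> "FlashResponseResults":
        config = self.config if seed is None else dc_replace(self.config, seed=seed)
        chain = run_chain(
            self.target, config, hard=self.hard, soft=self.soft,
            free_names=self.free_names, base=self.base, start=start,
        )
        params = parameter_set_from_draw(chain.best_draw, base=self.base)
        return FlashResponseResults(model=self, chain=chain, params=params)


@dataclass
class FlashResponseResults:
    """Best-fit parameters and chain diagnostics from an MCMC search."""

    model: FlashResponseModel
    chain: MCMCChain
    params: ParameterSet

    @property
    def rms(self) -> float:
        return self.chain.best_error

    @property
    def dark_state(self):
        return solve_dark_state(self.params)

    def predict(self, phi: float | None = None, **kw):
        """Simulate the fitted model's response (default: at the fitting intensity)."""
        if phi is None:
            phi = self.model.config.phi_fit
        return simulate_response(self.params, phi, **kw)

    def summary(self) -> str:
        soft = self.model.soft
        lines = [
            "Flash-response MCMC fit",
            "=" * 60,
            f"steps: {self.chain.samples.shape[0]}   acceptance: {self.chain.acceptance_rate:.3f}",
            f"best rms error: {self.rms:.4g} pA   (phi = {self.model.config.phi_fit:g})",
            "",
            f"{'parameter':>12} {'best fit':>12} {'expected interval':>22} {'in range':>9}",
        ]
        for name, val in self.chain.best_draw.items():
            if name in soft:
                r = soft[name]
                inside = "yes" if r.contains(val) else "NO"
                lines.append(f"{name:>12} {val:12.5g} {f'[{r.lo:g}, {r.hi:g}]':>22} {inside:>9}")
            else:
                lines.append(f"{name:>12} {val:12.5g} {'-':>22} {'-':>9}")
        ds = self.dark_state
        lines += [
            "",
            f"dark state: cG = {ds.cG_dark:.3g} uM, Ca = {ds.Ca_dark:.3g} uM, "
            f"J_dark = {ds.J_dark:.3g} pA",
        ]
        return "\n".join(lines)
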