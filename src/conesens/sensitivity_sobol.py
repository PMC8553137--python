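"""Variance-based global sensitivity analysis (Sobol indices).

Parameters are drawn independently and uniformly over their uncertainty
intervals in paired Saltelli matrices A and B; for each target (a single
parameter or a pair) a hybrid matrix AB_y replaces the target's columns of A
with B's.  First-order/closed indices use the Saltelli (2010) estimator
S_y = E[f(B)(f(AB_y) − f(A))]/V and total-effect indices the Jansen form
S_y^tot = E[(f(A) − f(AB_y))²]/(2V), with V the pooled sample variance of
f(A) and f(B).  Indices are reported unclamped: small negative estimates are
an expected Monte Carlo artifact and are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterRanges

__all__ = [
    "SobolDesign",
    "SobolResult",
    "sample_design",
    "estimate_indices",
    "confidence_intervals",
    "bootstrap_interval",
]

Target = str | tuple[str, ...]


def _target_key(target: Target) -> str:
    return target if isinstance(target, str) else "(" + ",".join(target) + ")"


@dataclass
class SobolDesign:
    """Paired sample matrices and the column-swap plan for index estimation."""

    A: np.ndarray  # N×d
    B: np.ndarray  # N×d
    names: list[str]
    targets: list[Target]
    seed: int
    ranges: ParameterRanges

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    def columns(self, target: Target) -> list[int]:
        names = [target] if isinstance(target, str) else list(target)
        return [self.names.index(n) for n in names]

    def AB(self, target: Target) -> np.ndarray:
        """A with the target's columns replaced by B's."""
        M = self.A.copy()
        cols = self.columns(target)
        M[:, cols] = self.B[:, cols]
        return M

    def as_params(self, M: np.ndarray) -> dict[str, np.ndarray]:
        """View a design matrix as a name → column mapping."""
        return {n: M[:, j] for j, n in enumerate(self.names)}


def sample_design(
    ranges: ParameterRanges,
    N: int,
    seed: int,
    targets: Sequence[Target],
) -> SobolDesign:
    """Draw the A/B matrices independently and uniformly over ``ranges``.

    Every target must name sampled parameters.  Rows are later converted to
    full parameter sets (the a_min coordinate guaranteeing dark-state
    existence by construction) before evaluation.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    names = ranges.names
    for t in targets:
        for n in [t] if isinstance(t, str) else t:
            if n not in names:
                raise KeyError(f"target parameter {n!r} has no sampled range")
    lo, hi = (np.asarray(b, dtype=float) for b in ranges.bounds())
    rng = np.random.default_rng(seed)
    A = lo + (hi - lo) * rng.random((N, len(names)))
    B = lo + (hi - lo) * rng.random((N, len(names)))
    return SobolDesign(A=A, B=B, names=list(names), targets=list(targets), seed=seed, ranges=ranges)


@dataclass
class SobolResult:
    """Index estimates per (functional, target) with 90% confidence bounds."""

    table: pd.DataFrame  # columns: functional, target, S, S_tot, ci90 bounds, N, n_failed

    def summary(self) -> str:
        with pd.option_context("display.width", 120, "display.float_format", "{:8.4f}".format):
            return self.table.to_string(index=False)

    def lookup(self, functional: str, target: Target) -> pd.Series:
        key = _target_key(target)
        m = (self.table["functional"] == functional) & (self.table["target"] == key)
        if not m.any():
            raise KeyError(f"no entry for ({functional}, {key})")
        return self.table[m].iloc[0]


def confidence_intervals(
    num_samples: np.ndarray,
    den_samples: np.ndarray,
    level_parts: float = 0.95,
) -> tuple[float, float, bool]:
    """90% interval for a ratio of sample means from 95% normal intervals of
    numerator and denominator, using the order-preserving property of
    division.  Returns (lo, hi, bounded); an unbounded interval is flagged
    when the denominator interval straddles zero."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level_parts / 2.0)

    def mean_ci(x: np.ndarray) -> tuple[float, float]:
        m = float(np.mean(x))
        if len(x) < 2:
            return m, m
        se = float(np.std(x, ddof=1)) / np.sqrt(len(x))
        return m - z * se, m + z * se

    nlo, nhi = mean_ci(num_samples)
    dlo, dhi = mean_ci(den_samples)
    if dlo <= 0 <= dhi:
        return -np.inf, np.inf, False
    corners = [nlo / dlo, nlo / dhi, nhi / dlo, nhi / dhi]
    return min(corners), max(corners), True


def bootstrap_interval(
    fA: np.ndarray,
    fB: np.ndarray,
    fAB: np.ndarray,
    statistic: str,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap interval for one index estimate (row resampling)."""
    rng = np.random.default_rng(seed)
    n = len(fA)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        a, bb, ab = fA[idx], fB[idx], fAB[idx]
        V = np.var(np.concatenate([a, bb]), ddof=1)
        if statistic == "S":
            vals[b] = np.mean(bb * (ab - a)) / V
        elif statistic == "S_tot":
            vals[b] = 0.5 * np.mean((a - ab) ** 2) / V
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    q = (1.0 - level) / 2.0
    return float(np.quantile(vals, q)), float(np.quantile(vals, 1.0 - q))


def _den_samples(pooled: np.ndarray) -> np.ndarray:
    # per-sample contributions to the pooled variance, for the denominator CI
    return (pooled - pooled.mean()) ** 2 * (len(pooled) / (len(pooled) - 1.0))


def estimate_indices(
    design: SobolDesign,
    evals_A: Mapping[str, np.ndarray],
    evals_B: Mapping[str, np.ndarray],
    evals_AB: Mapping[str, Mapping[str, np.ndarray]],
) -> SobolResult:
    """Estimate first-order/closed and total indices for every (functional,
    target) pair.

    ``evals_AB`` maps target key → functional name → values.  NaN evaluations
    (integration failures, undefined functionals) are excluded pairwise with
    their design rows; the retained count and failure count are reported.
    """
    rows = []
    for target in design.targets:
        key = _target_key(target)
        per_fn = evals_AB[key]
        for fn in evals_A:
            fA = np.asarray(evals_A[fn], dtype=float)
            fB = np.asarray(evals_B[fn], dtype=float)
            fAB = np.asarray(per_fn[fn], dtype=float)
            mask = np.isfinite(fA) & np.isfinite(fB) & np.isfinite(fAB)
            n_failed = int(len(fA) - mask.sum())
            a, b, ab = fA[mask], fB[mask], fAB[mask]
            pooled = np.concatenate([a, b])
            V = float(np.var(pooled, ddof=1))
            if V == 0.0:
                raise ValueError(f"constant functional {fn!r}: variance is zero")
            num_S = b * (ab - a)
            num_T = 0.5 * (a - ab) ** 2
            den = _den_samples(pooled)
            S = float(np.mean(num_S)) / V
            S_tot = float(np.mean(num_T)) / V
            S_lo, S_hi, S_ok = confidence_intervals(num_S, den)
            T_lo, T_hi, T_ok = confidence_intervals(num_T, den)
            rows.append(
                dict(
                    functional=fn, target=key, S=S, S_tot=S_tot,
                    ci90_S_lo=S_lo, ci90_S_hi=S_hi, ci90_S_tot_lo=T_lo, ci90_S_tot_hi=T_hi,
                    ci_bounded=bool(S_ok and T_ok), N=int(mask.sum()), n_failed=n_failed,
                )
            )
    return SobolResult(pd.DataFrame(rows))
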