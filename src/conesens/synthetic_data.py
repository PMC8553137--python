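"""Synthetic stand-ins for recorded cone flash responses.

The published transducin-knockout (Gnat1⁻/⁻) mouse cone recordings — a flash
family spanning roughly 40–6,000 photoisomerizations with half-maximal
response near 940 — are not deposited as data, so fitting and recovery
experiments run against model-generated traces at a known parameter vector
plus additive Gaussian recording noise.  Also provides closed-form test
functions (additive-linear, Ishigami) with exact Sobol indices for
estimator validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet, mouse_cone_parameters
from .photoresponse import simulate_response
from .darkstate import solve_dark_state

__all__ = [
    "DEFAULT_INTENSITIES",
    "ExperimentTrace",
    "generate_experiment",
    "ishigami",
    "ishigami_exact_indices",
    "additive_linear_exact_indices",
    "make_gsa_smoke_fixture",
]

#: default flash strengths (photoisomerizations); 940 is the half-maximal flash
DEFAULT_INTENSITIES = (40, 235, 940, 6000)


@dataclass(frozen=True)
class ExperimentTrace:
    """A family of (possibly noisy) flash-response drops, one per intensity."""

    t: np.ndarray  # s, uniform grid
    drops: dict[int, np.ndarray]  # intensity → current drop, pA
    intensities: tuple[int, ...]
    noise_sd: float  # pA
    seed: int
    theta_true: ParameterSet  # generating parameters, for recovery tests

    def drop(self, intensity: int) -> np.ndarray:
        return self.drops[intensity]


def generate_experiment(
    theta_true: ParameterSet | None = None,
    intensities=DEFAULT_INTENSITIES,
    t_end: float = 0.5,
    dt: float = 1e-3,
    noise_sd: float = 0.3,
    seed: int = 0,
    rtol: float = 1e-8,
) -> ExperimentTrace:
    """Simulate a flash family at ``theta_true`` and add iid Gaussian noise.

    Defaults emulate the recorded family: intensities 40–6,000
    photoisomerizations, a 0.5 s sweep at 1 ms sampling, and noise of
    0.3 pA — a calibration constant comparable to trace jitter in published
    single-cone recordings.
    """
    if theta_true is None:
        theta_true = mouse_cone_parameters()
    intensities = tuple(sorted(int(i) for i in intensities))
    dark = solve_dark_state(theta_true)
    rng = np.random.default_rng(seed)
    drops: dict[int, np.ndarray] = {}
    t = None
    for phi in intensities:
        tr = simulate_response(theta_true, phi, t_end=t_end, dt=dt, rtol=rtol, dark=dark)
        t = tr.t
        noise = rng.normal(0.0, noise_sd, size=tr.drop.shape) if noise_sd > 0 else 0.0
        drops[phi] = tr.drop + noise
    return ExperimentTrace(
        t=t, drops=drops, intensities=intensities,
        noise_sd=noise_sd, seed=seed, theta_true=theta_true,
    )


# ---------------------------------------------------------------------------
# analytic fixtures for Sobol estimator validation


def ishigami(X: np.ndarray, a: float = 7.0, b: float = 0.1) -> np.ndarray:
    """Ishigami test function on [−π, π]³."""
    X = np.asarray(X, dtype=float)
    return np.sin(X[:, 0]) + a * np.sin(X[:, 1]) ** 2 + b * X[:, 2] ** 4 * np.sin(X[:, 0])


def ishigami_exact_indices(a: float = 7.0, b: float = 0.1) -> dict[str, float]:
    """Closed-form Sobol indices of the Ishigami function.

    With x_i ~ U(−π, π): V1 = ½(1 + bπ⁴/5)², V2 = a²/8, V3 = 0,
    V13 = 8b²π⁸/225, V = V1 + V2 + V13.
    """
    pi = np.pi
    V1 = 0.5 * (1.0 + b * pi**4 / 5.0) ** 2
    V2 = a**2 / 8.0
    V13 = 8.0 * b**2 * pi**8 / 225.0
    V = V1 + V2 + V13
    return {
        "S1": V1 / V, "S2": V2 / V, "S3": 0.0,
        "S_tot1": (V1 + V13) / V, "S_tot2": V2 / V, "S_tot3": V13 / V,
        "V": V,
    }


def additive_linear_exact_indices(
    coeffs: tuple[float, ...], widths: tuple[float, ...]
) -> dict[str, float]:
    """Exact indices of f = Σ c_i x_i with x_i uniform on intervals of the
    given widths: S_i = S_tot,i = c_i²w_i²/12 / Σ c_j²w_j²/12."""
    c = np.asarray(coeffs, dtype=float)
    w = np.asarray(widths, dtype=float)
    v = c**2 * w**2 / 12.0
    V = v.sum()
    return {f"S{i + 1}": float(v[i] / V) for i in range(len(c))} | {"V": float(V)}


def make_gsa_smoke_fixture(seed: int = 0):
    """Bundle the analytic test functions with their exact indices.

    Returns (functions, exact) where functions maps a name to
    (callable on N×d arrays, per-coordinate (lo, hi) bounds) and exact maps
    the same name to its closed-form indices.  The constant function is
    included to exercise the zero-variance error path.
    """
    functions = {
        "ishigami": (ishigami, [(-np.pi, np.pi)] * 3),
        "additive": (lambda X: 3.0 * X[:, 0] + X[:, 1], [(0.0, 1.0), (0.0, 1.0)]),
        "constant": (lambda X: np.ones(X.shape[0]), [(0.0, 1.0), (0.0, 1.0)]),
    }
    exact = {
        "ishigami": ishigami_exact_indices(),
        "additive": additive_linear_exact_indices((3.0, 1.0), (1.0, 1.0)),
        "constant": None,
    }
    return functions, exact
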