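"""Dark-adapted steady state of the cone outer segment.

In darkness, cGMP synthesis by guanylyl cyclase balances hydrolysis by
spontaneously active PDE, and the Ca²⁺ influx through CNG channels balances
extrusion by the Na⁺/Ca²⁺,K⁺ exchanger.  The two balance equations form a
monotone 2×2 system in ([cG]_dark, [Ca²⁺]_dark); the circulating dark current
J_dark is the sum of the CNG and exchanger currents at the solution.
Currents are whole-cell totals in pA, so channel localization drops out of
the well-stirred steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .parameters import DerivedParameters, ParameterSet, resolve_alpha_min

__all__ = [
    "DarkState",
    "cng_current",
    "exchanger_current",
    "cyclase_rate",
    "check_existence",
    "solve_dark_state",
]


@dataclass(frozen=True)
class DarkState:
    cG_dark: float  # μM
    Ca_dark: float  # μM
    J_cG_dark: float  # pA
    J_ex_dark: float  # pA
    J_dark: float  # pA
    alpha_min: float  # μM s⁻¹
    xi: float  # μM s⁻¹
    exists: bool
    residuals: tuple[float, float]  # (cGMP balance μM s⁻¹, current balance pA)


def cng_current(cG, p: ParameterSet):
    """Total CNG channel current (pA): Hill function of [cG], saturating at JcG_max."""
    cG = np.asarray(cG, dtype=float)
    h = cG**p.m_cG
    return p.JcG_max * h / (p.K_cG**p.m_cG + h)


def exchanger_current(Ca, p: ParameterSet):
    """Total exchanger current (pA): Michaelis–Menten in [Ca²⁺]."""
    Ca = np.asarray(Ca, dtype=float)
    return p.Jex_sat * Ca / (p.K_ex + Ca)


def cyclase_rate(Ca, p: ParameterSet, derived: DerivedParameters | None = None):
    """cGMP synthesis rate (μM s⁻¹): falls sigmoidally from α_max toward
    α_min as Ca²⁺ rises past K_cyc."""
    if derived is None:
        derived = resolve_alpha_min(p)
    Ca = np.asarray(Ca, dtype=float)
    K = p.K_cyc_uM
    gate = K**p.m_cyc / (K**p.m_cyc + Ca**p.m_cyc)
    return derived.alpha_min + (p.alpha_max - derived.alpha_min) * gate


def check_existence(p: ParameterSet) -> bool:
    """True iff a dark steady state exists: the minimum cyclase rate must be
    small enough that 1 + (α_min/(β_dark·K_cG))^m_cG stays strictly below
    (1 − 2·Jex_sat/(JcG_max·f_Ca))⁻¹, and the current ratio itself below 1."""
    q = 2.0 * p.Jex_sat / (p.JcG_max * p.f_Ca)
    if q >= 1.0:
        return False
    try:
        derived = resolve_alpha_min(p)
    except ValueError:
        return False
    left = 1.0 + (derived.alpha_min / (p.beta_dark * p.K_cG)) ** p.m_cG
    return left < 1.0 / (1.0 - q)


def _cG_of_Ca(Ca: float, p: ParameterSet, derived: DerivedParameters) -> float:
    # cGMP balance solved for cG: synthesis/β_dark
    return float(cyclase_rate(Ca, p, derived)) / p.beta_dark


def solve_dark_state(
    p: ParameterSet,
    tol: float = 1e-10,
    Ca_bracket: tuple[float, float] = (1e-6, 10.0),
) -> DarkState:
    """Solve the dark steady state by outer bisection on Ca²⁺.

    For each trial Ca the cGMP balance gives cG in closed form; the current
    balance residual f_Ca/2·J_cG(cG(Ca)) − J_ex(Ca) is strictly decreasing in
    Ca (J_ex rises, cG and hence J_cG fall), so a sign change brackets the
    unique root.  Nonexistence is reported with ``exists=False`` rather than
    an exception, so samplers can account for rejections.
    """
    try:
        derived = resolve_alpha_min(p)
    except ValueError:
        return DarkState(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, (np.nan, np.nan))
    if not check_existence(p):
        return DarkState(
            np.nan, np.nan, np.nan, np.nan, np.nan,
            derived.alpha_min, derived.xi, False, (np.nan, np.nan),
        )

    def current_residual(Ca: float) -> float:
        cG = _cG_of_Ca(Ca, p, derived)
        return 0.5 * p.f_Ca * float(cng_current(cG, p)) - float(exchanger_current(Ca, p))

    lo, hi = Ca_bracket
    # expand bracket downward/upward if the residual does not change sign
    while current_residual(lo) < 0 and lo > 1e-15:
        lo *= 0.1
    while current_residual(hi) > 0 and hi < 1e6:
        hi *= 10.0
    Ca = float(brentq(current_residual, lo, hi, rtol=tol, xtol=1e-15))
    cG = _cG_of_Ca(Ca, p, derived)
    J_cG = float(cng_current(cG, p))
    J_ex = float(exchanger_current(Ca, p))
    res_cG = float(cyclase_rate(Ca, p, derived)) - p.beta_dark * cG
    res_J = 0.5 * p.f_Ca * J_cG - J_ex
    return DarkState(
        cG_dark=cG,
        Ca_dark=Ca,
        J_cG_dark=J_cG,
        J_ex_dark=J_ex,
        J_dark=J_cG + J_ex,
        alpha_min=derived.alpha_min,
        xi=derived.xi,
        exists=True,
        residuals=(res_cG, res_J),
    )


def solve_dark_state_batch(params: dict[str, np.ndarray], n_bisect: int = 150) -> dict[str, np.ndarray]:
    """Dark steady state for many parameter draws at once.

    Vectorized bisection on Ca²⁺ with the closed-form cGMP balance inside,
    mirroring :func:`solve_dark_state` row-for-row (validated against it in
    tests).  α_min is resolved from the ``a_min`` coordinate through the
    closed form of the existence root χ, so every row with a_min < 1 admits a
    steady state by construction.  Expects arrays (or scalars) for beta_dark,
    alpha_max, a_min, m_cyc, K_cyc (nM), JcG_max, m_cG, K_cG, f_Ca, Jex_sat,
    K_ex; returns arrays cG_dark, Ca_dark, J_cG_dark, J_ex_dark, J_dark,
    alpha_min, xi.
    """
    n = np.asarray(params["beta_dark"], dtype=float).shape[0]

    def get(name):
        return np.broadcast_to(np.asarray(params[name], dtype=float), (n,))

    beta = get("beta_dark")
    alpha_max = get("alpha_max")
    a_min = get("a_min")
    m_cyc, K_cyc = get("m_cyc"), get("K_cyc") * 1e-3  # nM → μM
    JcG_max, m_cG, K_cG = get("JcG_max"), get("m_cG"), get("K_cG")
    f_Ca, Jex_sat, K_ex = get("f_Ca"), get("Jex_sat"), get("K_ex")

    q = 2.0 * Jex_sat / (JcG_max * f_Ca)
    ok = q < 1.0
    rhs = np.where(ok, 1.0 / (1.0 - np.where(ok, q, 0.0)), np.inf)
    chi = beta * K_cG * np.power(np.maximum(rhs - 1.0, 0.0), 1.0 / m_cG)
    xi = np.minimum(alpha_max, chi)
    alpha_min = a_min * xi

    def cG_of_Ca(Ca):
        gate = K_cyc**m_cyc / (K_cyc**m_cyc + Ca**m_cyc)
        return (alpha_min + (alpha_max - alpha_min) * gate) / beta

    def residual(Ca):
        cG = cG_of_Ca(Ca)
        h = cG**m_cG
        J_cG = JcG_max * h / (K_cG**m_cG + h)
        J_ex = Jex_sat * Ca / (K_ex + Ca)
        return 0.5 * f_Ca * J_cG - J_ex

    # as a_min → 1 the dark Ca²⁺ diverges; the wide upper bracket keeps the
    # current-balance residual below 1e-8 pA even for near-boundary draws
    lo = np.full(n, 1e-9)
    hi = np.full(n, 1e10)
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        pos = residual(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    Ca = 0.5 * (lo + hi)
    cG = cG_of_Ca(Ca)
    h = cG**m_cG
    J_cG = JcG_max * h / (K_cG**m_cG + h)
    J_ex = Jex_sat * Ca / (K_ex + Ca)
    bad = ~ok
    out = {
        "cG_dark": cG, "Ca_dark": Ca, "J_cG_dark": J_cG, "J_ex_dark": J_ex,
        "J_dark": J_cG + J_ex, "alpha_min": alpha_min, "xi": xi,
    }
    for v in out.values():
        v[bad] = np.nan
    return out
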