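"""Disc-surface activation cascade: R* → G* → E*.

A uniform flash of Φ photoisomerizations seeds an initial R* surface density
Φ/S_disc spread over all disc faces.  R* catalytically activates transducin
(G*) at rate ν_RG, drawing on the undepleted pool; free G* complexes with
inactive PDE subunits at coupling coefficient k_GE to form activated
subunits E* (two per holoenzyme, activated independently); R* and E* shut
off with first-order rates k_R and k_E.  One G* is consumed per activated
subunit, so free G* has no independent decay — it decays with the complex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import DomainError, ParameterSet

__all__ = ["Geometry", "CascadeTrace", "derive_geometry", "simulate_cascade", "peak_Estar_batch"]


@dataclass(frozen=True)
class Geometry:
    """Continuum frustum approximation of the outer-segment geometry."""

    S_disc: float  # total disc surface area (both faces of all discs), μm²
    V_cyto: float  # cytosolic (interdiscal) volume, μm³
    Sigma_S: float  # channel-bearing lateral membrane area, μm² (inert here)


@dataclass(frozen=True)
class CascadeTrace:
    t: np.ndarray  # s
    Rstar_sigma: np.ndarray  # μm⁻²
    Gstar_sigma: np.ndarray  # free activated transducin, μm⁻²
    Estar_sigma: np.ndarray  # activated PDE catalytic subunits, μm⁻²
    Estar_total: np.ndarray  # molecules, Estar_sigma · S_disc


def derive_geometry(p: ParameterSet) -> Geometry:
    """Areas and volume of a linearly tapering (frustum) outer segment.

    The mean of R² over the taper is (R_b² + R_b·R_t + R_t²)/3; each of the
    n discs contributes two faces of that mean area.  The cytosol occupies
    the interdiscal fraction ν/(1+ν) of the frustum volume.  Σ_S is the
    open-sliver fraction ω₀/2π of the lateral frustum surface.
    """
    r2 = (p.R_b**2 + p.R_b * p.R_t + p.R_t**2) / 3.0
    S_disc = 2.0 * p.n_discs * np.pi * r2
    V_cyto = (p.nu / (1.0 + p.nu)) * np.pi * p.H * r2
    slant = np.hypot(p.H, p.R_b - p.R_t)
    lateral = np.pi * (p.R_b + p.R_t) * slant
    return Geometry(S_disc=float(S_disc), V_cyto=float(V_cyto),
                    Sigma_S=float(p.omega0 / (2.0 * np.pi) * lateral))


def _cascade_rhs(t, y, p: ParameterSet, E_tot: float):
    R, G, E = y
    act = p.nu_RG * R * max(p.G_sigma - G - E, 0.0) / p.G_sigma
    couple = p.k_GE * (E_tot - E) * G
    return [-p.k_R * R, act - couple, couple - p.k_E * E]


def simulate_cascade(
    p: ParameterSet,
    phi: float,
    t_end: float = 0.5,
    dt: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> CascadeTrace:
    """Integrate the three-species cascade for a flash of ``phi``
    photoisomerizations on a fixed output grid."""
    if phi < 0:
        raise DomainError("phi must be nonnegative")
    geo = derive_geometry(p)
    t = np.arange(int(round(t_end / dt)) + 1) * dt
    E_tot = 2.0 * p.PDE_sigma
    if phi == 0.0:
        z = np.zeros_like(t)
        return CascadeTrace(t, z, z.copy(), z.copy(), z.copy())
    y0 = [phi / geo.S_disc, 0.0, 0.0]
    sol = solve_ivp(
        _cascade_rhs, (0.0, float(t[-1])), y0, t_eval=t, args=(p, E_tot),
        method="LSODA", rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"cascade integration failed: {sol.message}")
    R, G, E = sol.y
    eps = 1e-9 * max(E_tot, p.G_sigma)
    if E.max() > E_tot + eps or (G + E).max() > p.G_sigma + max(eps, 1e-6 * p.G_sigma):
        raise RuntimeError("cascade invariant violated beyond tolerance")
    E = np.clip(E, 0.0, E_tot)
    G = np.maximum(G, 0.0)
    return CascadeTrace(t, np.maximum(R, 0.0), G, E, E * geo.S_disc)


def peak_Estar_batch(
    params: dict[str, np.ndarray],
    phi: float = 940.0,
    t_end: float = 1.5,
    dt: float = 5e-4,
) -> np.ndarray:
    """Peak total activated PDE subunits (molecules) for many parameter draws.

    Vectorized fixed-step RK4 over all rows at once; the cascade subsystem is
    non-stiff across the sampled ranges (all rate×dt products stay well inside
    the explicit stability region).  Used by the Monte Carlo sensitivity
    pipeline, where per-row adaptive integration would dominate the budget.
    Arrays in ``params`` must share one length and provide R_b, R_t, n_discs
    (or scalars), G_sigma, PDE_sigma, nu_RG, k_GE, k_R, k_E.
    """
    nu_RG = np.asarray(params["nu_RG"], dtype=float)
    n = nu_RG.shape[0]

    def get(name, default=None):
        v = params.get(name, default)
        return np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy()

    R_b, R_t = get("R_b", 0.6), get("R_t", 0.4)
    n_discs = get("n_discs", 400.0)
    G_sig, PDE_sig = get("G_sigma"), get("PDE_sigma")
    k_GE, k_R, k_E = get("k_GE"), get("k_R"), get("k_E")

    r2 = (R_b**2 + R_b * R_t + R_t**2) / 3.0
    S_disc = 2.0 * n_discs * np.pi * r2
    E_tot = 2.0 * PDE_sig

    R = phi / S_disc
    G = np.zeros(n)
    E = np.zeros(n)
    peak = np.zeros(n)

    def rhs(R, G, E):
        act = nu_RG * R * np.maximum(G_sig - G - E, 0.0) / G_sig
        couple = k_GE * (E_tot - E) * G
        return -k_R * R, act - couple, couple - k_E * E

    nsteps = int(round(t_end / dt))
    for _ in range(nsteps):
        k1 = rhs(R, G, E)
        k2 = rhs(R + 0.5 * dt * k1[0], G + 0.5 * dt * k1[1], E + 0.5 * dt * k1[2])
        k3 = rhs(R + 0.5 * dt * k2[0], G + 0.5 * dt * k2[1], E + 0.5 * dt * k2[2])
        k4 = rhs(R + dt * k3[0], G + dt * k3[1], E + dt * k3[2])
        R = R + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        G = G + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        E = E + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        E = np.clip(E, 0.0, E_tot)
        np.maximum(peak, E * S_disc, out=peak)
    return peak
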