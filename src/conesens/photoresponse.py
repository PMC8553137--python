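"""Flash response of the cone outer segment: cascade-driven cGMP/Ca²⁺
dynamics and the circulating current J(t).

The well-stirred reduction couples the disc cascade one-way into the
second-messenger balance: activated PDE subunits add a light hydrolysis rate
β_light(E*) on top of the dark turnover β_dark, closing CNG channels; the
falling Ca²⁺ influx then disinhibits guanylyl cyclase, restoring cGMP.  The
response is the current drop r(t) = J_dark − J(t).  Uniform flashes make the
fields spatially uniform, so diffusion coefficients enter no equation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .cascade import derive_geometry
from .darkstate import DarkState, cng_current, cyclase_rate, exchanger_current, solve_dark_state
from .parameters import DerivedParameters, DomainError, ParameterSet, resolve_alpha_min

__all__ = ["PhotoresponseTrace", "current_to_conc_rate", "beta_light", "simulate_response"]


@dataclass(frozen=True)
class PhotoresponseTrace:
    t: np.ndarray  # s
    cG: np.ndarray  # μM
    Ca: np.ndarray  # μM
    J_cG: np.ndarray  # pA
    J_ex: np.ndarray  # pA
    J: np.ndarray  # pA, total circulating current
    drop: np.ndarray  # pA, J_dark − J(t)
    Estar_total: np.ndarray  # molecules
    meta: dict = field(default_factory=dict)

    @property
    def J_dark(self) -> float:
        return float(self.meta["J_dark"])


# Faraday constant used throughout; matches the tabulated model value.
_F = 96500.0


def current_to_conc_rate(J: float, z_charge: float, V: float):
    """Convert a current (pA) carried by ions of charge ``z`` into a rate of
    concentration change (μM s⁻¹) in a compartment of volume ``V`` (μm³)."""
    if V <= 0:
        raise DomainError("volume must be positive")
    if z_charge < 1:
        raise DomainError("ion charge must be >= 1")
    return J * 1e9 / (z_charge * _F * V)


def beta_light(Estar_sigma, p: ParameterSet, derived: DerivedParameters | None = None):
    """Light-induced volumetric cGMP hydrolysis rate (s⁻¹) from the activated
    subunit surface density: k*_σ;hyd·[PDE*]_σ/η with [PDE*] = E*/2, the same
    surface→volume conversion that defines the dark rate."""
    if derived is None:
        derived = resolve_alpha_min(p)
    Estar_sigma = np.asarray(Estar_sigma, dtype=float)
    return derived.k_sigma_hyd_star * (Estar_sigma / 2.0) / (derived.eta * 1e-3)


def simulate_response(
    p: ParameterSet,
    phi: float,
    t_end: float = 0.5,
    dt: float = 1e-4,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    dark: DarkState | None = None,
) -> PhotoresponseTrace:
    """Simulate the flash response for ``phi`` photoisomerizations.

    The full five-state system (R*, G*, E*, [cG], [Ca²⁺]) is integrated
    jointly from the dark steady state with a stiff-capable integrator on a
    fixed output grid.  Raises if no dark steady state exists.
    """
    if dark is None:
        dark = solve_dark_state(p)
    if not dark.exists:
        raise DomainError("no dark steady state exists for these parameters")
    derived = resolve_alpha_min(p)
    geo = derive_geometry(p)
    E_tot = 2.0 * p.PDE_sigma
    c_in = p.f_Ca * 1e9 / (2.0 * _F * geo.V_cyto) / p.B_Ca  # pA → μM/s, CNG influx
    c_out = 1e9 / (1.0 * _F * geo.V_cyto) / p.B_Ca  # pA → μM/s, exchanger efflux
    kstar_over_eta = derived.k_sigma_hyd_star / (2.0 * derived.eta * 1e-3)

    def rhs(t, y):
        R, G, E, cG, Ca = y
        act = p.nu_RG * R * max(p.G_sigma - G - E, 0.0) / p.G_sigma
        couple = p.k_GE * (E_tot - E) * G
        cG_pos = max(cG, 0.0)
        Ca_pos = max(Ca, 0.0)
        J_cG = float(cng_current(cG_pos, p))
        J_ex = float(exchanger_current(Ca_pos, p))
        dcG = float(cyclase_rate(Ca_pos, p, derived)) - (p.beta_dark + kstar_over_eta * E) * cG_pos
        dCa = c_in * J_cG - c_out * J_ex
        return [-p.k_R * R, act - couple, couple - p.k_E * E, dcG, dCa]

    t = np.arange(int(round(t_end / dt)) + 1) * dt
    y0 = [phi / geo.S_disc if phi > 0 else 0.0, 0.0, 0.0, dark.cG_dark, dark.Ca_dark]
    sol = solve_ivp(rhs, (0.0, float(t[-1])), y0, t_eval=t, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"photoresponse integration failed: {sol.message}")
    R, G, E, cG, Ca = sol.y
    if cG.min() < -1e-6 or Ca.min() < -1e-6:
        raise RuntimeError("negative concentration beyond tolerance in photoresponse")
    cG = np.maximum(cG, 0.0)
    Ca = np.maximum(Ca, 0.0)
    J_cG = np.asarray(cng_current(cG, p))
    J_ex = np.asarray(exchanger_current(Ca, p))
    J = J_cG + J_ex
    meta = {
        "phi": phi,
        "J_dark": dark.J_dark,
        "cG_dark": dark.cG_dark,
        "Ca_dark": dark.Ca_dark,
        "rtol": rtol,
        "atol": atol,
        "dt": dt,
    }
    return PhotoresponseTrace(
        t=t, cG=cG, Ca=Ca, J_cG=J_cG, J_ex=J_ex, J=J,
        drop=dark.J_dark - J, Estar_total=np.clip(E, 0.0, E_tot) * geo.S_disc, meta=meta,
    )
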