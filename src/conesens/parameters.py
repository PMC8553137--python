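"""Model parameters for the cone outer-segment phototransduction cascade.

Every symbol of the kinetic model lives here with its units fixed at
construction: concentrations in μM (except the cyclase half-saturation
``K_cyc``, stored in nM as conventionally printed), lengths in μm (disc
thickness ``eps0`` in nm), rates in s⁻¹, currents in pA.  The module also
implements the derived-parameter conversions (volume-to-surface factor η,
surface hydrolysis rates, ν_GE) and the existence-preserving
reparameterization of the minimum cyclase rate α_min → a_min that makes
independent sampling of the dark-steady-state parameters possible.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace, asdict, fields as dc_fields
from importlib import resources
from typing import Iterator, Mapping

from scipy.optimize import brentq

__all__ = [
    "UM_TO_MOLECULES_PER_UM3",
    "DomainError",
    "DarkStateExistenceError",
    "ParameterSet",
    "ParameterRanges",
    "DerivedParameters",
    "eta_factor",
    "surface_density_from_volumic",
    "k_hyd_light",
    "k_hyd_dark",
    "nu_GE_of",
    "beta_dark_from_activity",
    "cyclase_bounds_estimate",
    "chi_existence_root",
    "resolve_alpha_min",
    "mouse_cone_parameters",
    "mouse_cone_printed_dark_values",
    "gsa_ranges",
    "mcmc_hard_constraints",
    "mcmc_soft_ranges",
    "parameter_set_from_draw",
]

#: molecules per μm³ in a 1 μM solution (N_Av · 10⁻²¹); the single constant
#: through which every μM ↔ surface/volumic conversion routes.
UM_TO_MOLECULES_PER_UM3 = 602.214


class DomainError(ValueError):
    """An argument fell outside the physical domain of a conversion."""


class DarkStateExistenceError(ValueError):
    """No dark steady state is possible for the supplied channel currents.

    Raised when 2·Jex_sat ≥ JcG_max·f_Ca, i.e. the saturated exchanger efflux
    cannot be balanced by the calcium fraction of the CNG influx at any cGMP
    level.  Carries the offending current ratio.
    """

    def __init__(self, ratio: float):
        self.ratio = ratio
        super().__init__(
            f"no dark steady state possible: 2*Jex_sat/(JcG_max*f_Ca) = {ratio:.4g} >= 1"
        )


@dataclass(frozen=True)
class ParameterSet:
    """All symbols of the well-stirred cone phototransduction model.

    Exactly one of ``a_min`` (unitless relative position of the minimum
    cyclase rate inside its admissible interval [0, ξ]) or ``alpha_min``
    (μM s⁻¹, the rate itself) must be given; the one supplied is
    authoritative and the other is derived by :func:`resolve_alpha_min`.
    Diffusion coefficients are carried for completeness but are dynamically
    inert in the well-stirred reduction.
    """

    # geometry
    R_b: float  # base radius, μm
    R_t: float  # tip radius, μm
    H: float  # outer-segment length, μm
    eps0: float  # disc thickness, nm
    nu: float  # interdiscal/disc thickness ratio
    sigma: float  # disc/sliver thickness ratio
    omega0: float  # sliver open-margin angle, rad
    n_discs: int  # disc count

    # disc-surface cascade
    R_sigma: float  # rhodopsin surface density, μm⁻²
    G_sigma: float  # transducin surface density, μm⁻²
    PDE_sigma: float  # PDE holoenzyme surface density, μm⁻²
    k_R: float  # R* shutoff rate, s⁻¹
    k_E: float  # activated PDE subunit shutoff rate, s⁻¹
    nu_RG: float  # G* formation rate per R*, s⁻¹
    k_GE: float  # G* → PDE* coupling coefficient, μm² s⁻¹

    # cGMP turnover
    beta_dark: float  # dark cGMP turnover, s⁻¹
    B_cG: float  # cGMP buffering power
    kcat_Km: float  # PDE* dimer hydrolytic efficiency, μM⁻¹ s⁻¹
    alpha_max: float  # maximum cyclase rate, μM s⁻¹
    m_cyc: float  # cyclase Hill coefficient
    K_cyc: float  # cyclase half-saturating Ca²⁺, nM (as printed)

    # channels / Ca²⁺
    B_Ca: float  # Ca²⁺ buffering power
    JcG_max: float  # saturated CNG current, pA
    m_cG: float  # CNG Hill coefficient
    K_cG: float  # half-maximal cGMP for CNG, μM
    f_Ca: float  # fraction of CNG current carried by Ca²⁺
    Jex_sat: float  # saturated exchanger current, pA
    K_ex: float  # half-maximal Ca²⁺ for exchanger, μM

    # diffusion (inert in the reduction)
    D_R: float = 1.71
    D_G: float = 1.42
    D_E: float = 1.47
    D_cG: float = 89.2
    D_Ca: float = 15.0

    # constants
    F: float = 96500.0  # Faraday, C mol⁻¹
    N_Av: float = 6.02e23  # Avogadro, mol⁻¹

    # minimum cyclase rate: exactly one of the two is authoritative
    a_min: float | None = None  # unitless, ∈ [0, 1]
    alpha_min: float | None = None  # μM s⁻¹

    def __post_init__(self) -> None:
        if (self.a_min is None) == (self.alpha_min is None):
            raise DomainError("exactly one of a_min and alpha_min must be set")
        positive = (
            "R_b R_t H eps0 nu sigma omega0 n_discs R_sigma G_sigma PDE_sigma "
            "k_R k_E nu_RG beta_dark B_cG kcat_Km alpha_max m_cyc K_cyc B_Ca "
            "JcG_max m_cG K_cG Jex_sat K_ex F N_Av"
        ).split()
        for name in positive:
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be nonnegative, got {getattr(self, name)}")
        strictly = "R_b R_t H eps0 nu sigma PDE_sigma beta_dark B_cG alpha_max K_cyc JcG_max K_cG K_ex F N_Av".split()
        for name in strictly:
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")
        if self.a_min is not None and not (0.0 <= self.a_min <= 1.0):
            raise DomainError(f"a_min must lie in [0, 1], got {self.a_min}")
        if self.alpha_min is not None and self.alpha_min < 0:
            raise DomainError("alpha_min must be nonnegative")
        if not (0.0 < self.f_Ca < 1.0):
            raise DomainError(f"f_Ca must lie in (0, 1), got {self.f_Ca}")
        if self.m_cG < 1 or self.m_cyc < 1:
            raise DomainError("Hill coefficients must be >= 1")
        if self.R_t > self.R_b:
            raise DomainError("tip radius R_t must not exceed base radius R_b")

    @property
    def a_min_authoritative(self) -> bool:
        return self.a_min is not None

    @property
    def K_cyc_uM(self) -> float:
        """Cyclase half-saturation converted from the printed nM to μM."""
        return self.K_cyc * 1e-3

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with fields replaced (switching between ``a_min`` and
        ``alpha_min`` clears the other)."""
        if "a_min" in updates and "alpha_min" not in updates:
            updates["alpha_min"] = None
        if "alpha_min" in updates and "a_min" not in updates:
            updates["a_min"] = None
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterSet":
        d = dict(d)
        if "alpha_ratio" in d:  # constraint tables express α_min as α_max/α_min
            ratio = d.pop("alpha_ratio")
            if ratio <= 0:
                raise DomainError("alpha_max/alpha_min ratio must be positive")
            d["alpha_min"] = d["alpha_max"] / ratio
            d.setdefault("a_min", None)
        names = {f.name for f in dc_fields(cls)}
        extra = set(d) - names
        if extra:
            raise DomainError(f"unknown parameter names: {sorted(extra)}")
        return cls(**d)  # type: ignore[arg-type]

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ParameterRange:
    name: str
    lo: float
    hi: float
    units: str
    constraint_class: str  # hard | soft | gsa | fixed | derived

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise DomainError(f"range for {self.name} has lo > hi")

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def width(self) -> float:
        return self.hi - self.lo


class ParameterRanges:
    """Ordered collection of per-parameter intervals with constraint classes."""

    def __init__(self, ranges: list[ParameterRange]):
        self._ranges = {r.name: r for r in ranges}
        if len(self._ranges) != len(ranges):
            raise DomainError("duplicate parameter name in ranges")

    def __getitem__(self, name: str) -> ParameterRange:
        return self._ranges[name]

    def __contains__(self, name: str) -> bool:
        return name in self._ranges

    def __iter__(self) -> Iterator[ParameterRange]:
        return iter(self._ranges.values())

    def __len__(self) -> int:
        return len(self._ranges)

    @property
    def names(self) -> list[str]:
        return list(self._ranges)

    def bounds(self) -> tuple[list[float], list[float]]:
        return [r.lo for r in self], [r.hi for r in self]

    @classmethod
    def from_csv(cls, path) -> "ParameterRanges":
        with open(path, newline="") as fh:
            return cls._from_reader(csv.DictReader(fh))

    @classmethod
    def _from_reader(cls, reader) -> "ParameterRanges":
        out = []
        for row in reader:
            lo = float(row["lo"])
            hi = float(row["hi"]) if row.get("hi") else lo
            out.append(
                ParameterRange(row["name"], lo, hi, row.get("units") or "", row["constraint_class"])
            )
        return cls(out)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["name", "lo", "hi", "units", "constraint_class"])
            for r in self:
                w.writerow([r.name, r.lo, r.hi, r.units, r.constraint_class])


@dataclass(frozen=True)
class DerivedParameters:
    """Quantities computed from a :class:`ParameterSet`."""

    eta: float  # volume-to-surface factor, nm
    k_sigma_hyd: float  # dark surface hydrolysis rate, μm³ s⁻¹
    k_sigma_hyd_star: float  # light surface hydrolysis rate, μm³ s⁻¹
    nu_GE: float  # PDE* formation rate per G*, s⁻¹
    xi: float  # upper admissible α_min, μM s⁻¹
    chi: float  # root of the existence equality, μM s⁻¹
    alpha_min: float  # resolved minimum cyclase rate, μM s⁻¹
    a_min: float  # relative position of α_min in [0, ξ]


# ---------------------------------------------------------------------------
# conversions


def eta_factor(nu: float, eps0: float) -> float:
    """Volume-to-surface conversion factor η = ½·ν·ε₀ in nm.

    Converts a volumic concentration in the thin interdiscal space to an
    equivalent surface density on the bounding disc face.
    """
    if nu <= 0 or eps0 <= 0:
        raise DomainError("eta_factor requires nu > 0 and eps0 > 0")
    return 0.5 * nu * eps0


def surface_density_from_volumic(c_vol: float, eta: float) -> float:
    """Surface density (μm⁻²) of a species at volumic concentration ``c_vol``
    (μM) confined to an interdiscal space with conversion factor ``eta`` (nm)."""
    if c_vol < 0 or eta <= 0:
        raise DomainError("surface_density_from_volumic requires c_vol >= 0, eta > 0")
    return c_vol * UM_TO_MOLECULES_PER_UM3 * (eta * 1e-3)


def k_hyd_light(kcat_Km: float, B_cG: float) -> float:
    """Surface hydrolysis rate of cGMP per activated PDE dimer (μm³ s⁻¹):
    the volumetric efficiency k_cat/K_m per molecule, reduced by cGMP buffering."""
    if kcat_Km < 0:
        raise DomainError("kcat_Km must be nonnegative")
    if B_cG <= 0:
        raise DomainError("B_cG must be positive")
    return (kcat_Km / UM_TO_MOLECULES_PER_UM3) / B_cG


def k_hyd_dark(beta_dark: float, eta: float, PDE_sigma: float) -> float:
    """Dark surface hydrolysis rate (μm³ s⁻¹) implied by the volumic dark
    turnover β_dark through the surface/volume balance β_dark = k_σ;hyd·[PDE]_σ/η."""
    if beta_dark < 0 or eta <= 0:
        raise DomainError("k_hyd_dark requires beta_dark >= 0 and eta > 0")
    if PDE_sigma <= 0:
        raise DomainError("PDE_sigma must be positive")
    return beta_dark * (eta * 1e-3) / PDE_sigma


def nu_GE_of(k_GE: float, PDE_sigma: float) -> float:
    """Effective PDE* formation rate per G* (s⁻¹): ν_GE = k_GE·[PDE]_σ."""
    if k_GE < 0 or PDE_sigma < 0:
        raise DomainError("nu_GE_of requires nonnegative inputs")
    return k_GE * PDE_sigma


def beta_dark_from_activity(
    frac_dark: float, max_activity: float, R_vol: float, cG_dark: float
) -> float:
    """Dark cGMP turnover rate (s⁻¹) from the spontaneous PDE activity.

    The dark hydrolysis flux is ``frac_dark`` of the maximal per-R* activity
    times the rhodopsin concentration; dividing by the dark cGMP level turns
    the flux into a first-order rate β_dark.
    """
    if not (0 <= frac_dark < 1):
        raise DomainError("frac_dark must lie in [0, 1)")
    if max_activity < 0 or R_vol < 0:
        raise DomainError("activities must be nonnegative")
    if cG_dark <= 0:
        raise DomainError("cG_dark must be positive")
    return frac_dark * max_activity * R_vol / cG_dark


def cyclase_bounds_estimate(
    GC_free: float, rate_basal: float, GC_GCAP: float, rate_active: float
) -> tuple[float, float, float]:
    """Estimate (α_min, α_max, α_max/α_min) from guanylyl-cyclase pools.

    α_min assumes every cyclase (free plus GCAP-bound pools) runs at the basal
    rate; α_max assumes the GCAP-bound pool runs at its activated rate.
    """
    if min(GC_free, rate_basal, GC_GCAP, rate_active) < 0:
        raise DomainError("cyclase_bounds_estimate requires nonnegative inputs")
    alpha_min_est = (GC_free + GC_GCAP) * rate_basal
    alpha_max_est = GC_free * rate_basal + GC_GCAP * rate_active
    if alpha_min_est == 0:
        raise DomainError("zero total cyclase activity: ratio undefined")
    return alpha_min_est, alpha_max_est, alpha_max_est / alpha_min_est


# ---------------------------------------------------------------------------
# existence of the dark steady state and the a_min reparameterization


def chi_existence_root(
    beta_dark: float,
    K_cG: float,
    m_cG: float,
    Jex_sat: float,
    JcG_max: float,
    f_Ca: float,
    tol: float = 1e-12,
) -> float:
    """Root χ of 1 + (χ/(β_dark·K_cG))^m_cG = (1 − 2·Jex_sat/(JcG_max·f_Ca))⁻¹.

    χ is the largest minimum cyclase rate compatible with a dark steady state
    (before capping by α_max).  Solved by bracketed monotone root finding.
    """
    q = 2.0 * Jex_sat / (JcG_max * f_Ca)
    if q >= 1.0:
        raise DarkStateExistenceError(q)
    if q == 0.0:
        return 0.0
    rhs = 1.0 / (1.0 - q)
    scale = beta_dark * K_cG

    def f(chi: float) -> float:
        return (chi / scale) ** m_cG - (rhs - 1.0)

    hi = scale * (rhs - 1.0) ** (1.0 / m_cG) * 2.0 + scale
    return float(brentq(f, 0.0, hi, rtol=tol, xtol=tol * scale))


def resolve_alpha_min(p: ParameterSet) -> DerivedParameters:
    """Resolve α_min/a_min and all derived parameters for ``p``.

    When ``a_min`` is authoritative, α_min = a_min·ξ with ξ = min(α_max, χ),
    which guarantees the dark-state existence inequality holds for a_min < 1.
    When α_min is given directly, a_min is back-computed as α_min/ξ.
    """
    eta = eta_factor(p.nu, p.eps0)
    chi = chi_existence_root(p.beta_dark, p.K_cG, p.m_cG, p.Jex_sat, p.JcG_max, p.f_Ca)
    xi = min(p.alpha_max, chi)
    if p.a_min is not None:
        alpha_min = p.a_min * xi
        a_min = p.a_min
    else:
        alpha_min = float(p.alpha_min)  # type: ignore[arg-type]
        a_min = alpha_min / xi if xi > 0 else math.inf
    return DerivedParameters(
        eta=eta,
        k_sigma_hyd=k_hyd_dark(p.beta_dark, eta, p.PDE_sigma),
        k_sigma_hyd_star=k_hyd_light(p.kcat_Km, p.B_cG),
        nu_GE=nu_GE_of(p.k_GE, p.PDE_sigma),
        xi=xi,
        chi=chi,
        alpha_min=alpha_min,
        a_min=a_min,
    )


# ---------------------------------------------------------------------------
# packaged fixtures


def _read_packaged(name: str) -> list[dict]:
    text = resources.files("conesens.data").joinpath(name).read_text()
    return list(csv.DictReader(text.splitlines()))


def mouse_cone_parameters() -> ParameterSet:
    """The best-fit mouse-cone parameter set (α_min given via the printed
    α_max/α_min ratio, hence alpha_min-authoritative)."""
    rows = _read_packaged("mouse_cone_fit.csv")
    d = {r["name"]: float(r["lo"]) for r in rows if r["constraint_class"] == "fixed"}
    d["n_discs"] = int(d["n_discs"])
    return ParameterSet.from_dict(d)


def mouse_cone_printed_dark_values() -> dict[str, float]:
    """Printed dark-state quantities (cG_dark, Ca_dark, J_dark) accompanying
    the best-fit set, for cross-checks; not part of the ParameterSet."""
    rows = _read_packaged("mouse_cone_fit.csv")
    return {r["name"]: float(r["lo"]) for r in rows if r["constraint_class"] == "derived"}


def gsa_ranges() -> ParameterRanges:
    """Uncertainty intervals over which global sensitivity analysis samples."""
    return ParameterRanges._from_reader(iter(_read_packaged("gsa_ranges.csv")))


def mcmc_hard_constraints() -> ParameterRanges:
    """Hard constraint set K: bounds on parameters and on derived dark-state
    quantities that every retained MCMC sample must satisfy."""
    return ParameterRanges._from_reader(iter(_read_packaged("mcmc_hard_constraints.csv")))


def mcmc_soft_ranges() -> ParameterRanges:
    """Expected intervals outside which the MCMC stationary density is
    penalized (but not forbidden)."""
    return ParameterRanges._from_reader(iter(_read_packaged("mcmc_soft_ranges.csv")))


def parameter_set_from_draw(
    draw: Mapping[str, float], base: ParameterSet | None = None
) -> ParameterSet:
    """Build a full ParameterSet from a (partial) sampled draw.

    Unsampled fields are taken from ``base`` (default: the packaged mouse-cone
    fit).  A draw containing ``a_min`` is a_min-authoritative; one containing
    ``alpha_min`` or ``alpha_ratio`` is α_min-authoritative.
    """
    if base is None:
        base = mouse_cone_parameters()
    d = base.to_dict()
    draw = dict(draw)
    if "a_min" in draw:
        d["alpha_min"] = None
    elif "alpha_min" in draw or "alpha_ratio" in draw:
        d["a_min"] = None
        d.pop("alpha_min", None)
        if "alpha_ratio" in draw:
            d["alpha_min"] = d.get("alpha_max", base.alpha_max)  # placeholder, fixed below
    for k, v in draw.items():
        if k == "alpha_ratio":
            continue
        d[k] = v
    if "alpha_ratio" in draw:
        d["alpha_min"] = d["alpha_max"] / draw["alpha_ratio"]
    d["n_discs"] = int(d["n_discs"])
    return ParameterSet.from_dict(d)
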