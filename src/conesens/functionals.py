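"""Scalar functionals summarizing one flash response.

Nine numbers characterize a response: early-phase quadratic coefficients of
the current drop (I_act) and of total E* (E_act), the normalized maximum
drop (I_drop), peak and recovery rate of activity (E_peak, E_rec), time to
peak (T_peak), the circulating dark current (J_dark), the normalized
overshoot (J_over, the transient excess of J over J_dark during recovery),
and — when a target recording is supplied — the rms misfit L2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import CascadeTrace
from .photoresponse import PhotoresponseTrace

__all__ = [
    "FunctionalVector",
    "FUNCTIONAL_NAMES",
    "fit_half_quadratic",
    "fit_exp_recovery",
    "compute_functionals",
]

FUNCTIONAL_NAMES = (
    "I_act", "E_act", "I_drop", "E_peak", "E_rec", "T_peak", "J_dark", "J_over", "L2",
)

#: early activation-phase fitting window, s
ACTIVATION_WINDOW = (0.0, 0.010)
#: recovery-phase fitting window, s
RECOVERY_WINDOW = (0.135, 0.5)


@dataclass(frozen=True)
class FunctionalVector:
    I_act: float  # pA s⁻², quadratic rise coefficient of the current drop
    E_act: float  # molecules s⁻², quadratic rise coefficient of total E*
    I_drop: float  # max drop / J_dark, unitless
    E_peak: float  # molecules
    E_rec: float | None  # s⁻¹; None when no positive recovery samples
    T_peak: float  # s
    J_dark: float  # pA
    J_over: float  # max(J − J_dark, 0) / J_dark, unitless
    L2: float | None = None  # pA; None without a target trace

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FUNCTIONAL_NAMES}


def fit_half_quadratic(t: np.ndarray, y: np.ndarray, window=ACTIVATION_WINDOW) -> float:
    """Least-squares coefficient A of y ≈ ½·A·t² on the window.

    The one-parameter problem has the closed form A = Σ y·t² / (½ Σ t⁴).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 3:
        raise ValueError("fit window contains fewer than 3 samples")
    tw, yw = t[m], y[m]
    denom = 0.5 * np.sum(tw**4)
    if denom == 0.0:
        raise ValueError("degenerate fit window (all t = 0)")
    return float(np.sum(yw * tw**2) / denom)


def fit_exp_recovery(t: np.ndarray, y: np.ndarray, window=RECOVERY_WINDOW) -> float | None:
    """Decay rate α of y ≈ c·e^{−αt} on the window, by log-linear regression.

    Nonpositive samples are dropped; with fewer than 3 positive samples the
    functional is undefined and None is returned.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    m = (t >= window[0]) & (t <= window[1]) & (y > 0)
    if m.sum() < 3:
        return None
    slope = np.polyfit(t[m], np.log(y[m]), 1)[0]
    return float(-slope)


def _refine_peak(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Argmax with 3-point parabolic sub-grid refinement."""
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            s = 0.5 * (y0 - y2) / denom
            s = float(np.clip(s, -0.5, 0.5))
            dt = t[i + 1] - t[i]
            return float(t[i] + s * dt), float(y1 - 0.25 * (y0 - y2) * s)
    return float(t[i]), float(y[i])


def compute_functionals(
    trace: PhotoresponseTrace,
    cascade: CascadeTrace | None = None,
    target_t: np.ndarray | None = None,
    target_drop: np.ndarray | None = None,
) -> FunctionalVector:
    """Evaluate all functionals of one flash response.

    ``cascade`` supplies the E* series; when omitted, the E* series carried
    on the photoresponse trace is used (same integration).  L2 is computed
    against ``target_drop`` sampled at ``target_t`` (model drop interpolated
    onto the target grid) and omitted when no target is given.
    """
    t = trace.t
    Estar = cascade.Estar_total if cascade is not None else trace.Estar_total
    if cascade is not None and (len(cascade.t) != len(t) or not np.allclose(cascade.t, t)):
        raise ValueError("photoresponse and cascade traces must share a time grid")
    J_dark = trace.J_dark
    drop = trace.drop

    T_peak, peak_drop = _refine_peak(t, drop)
    L2 = None
    if target_drop is not None:
        tt = target_t if target_t is not None else t
        model = np.interp(tt, t, drop)
        L2 = float(np.sqrt(np.mean((model - np.asarray(target_drop, dtype=float)) ** 2)))
    return FunctionalVector(
        I_act=fit_half_quadratic(t, drop),
        E_act=fit_half_quadratic(t, Estar),
        I_drop=float(max(peak_drop, 0.0) / J_dark),
        E_peak=float(np.max(Estar)),
        E_rec=fit_exp_recovery(t, drop),
        T_peak=T_peak,
        J_dark=float(J_dark),
        J_over=float(max(0.0, -np.min(drop)) / J_dark),
        L2=L2,
    )
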