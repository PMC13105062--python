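"""Torsional-elasticity helical-phasing model for dimeric motif spacing.

Fluorescence of probes carrying two binding motifs oscillates with the
edge-to-edge spacing s because the two sites must present on compatible
rotational faces of the DNA helix. The model places phasing *minima* at
spacings s_min + n*h_r (h_r = helical repeat in bp/turn) and broadens them
with thermal twist fluctuations that grow as sqrt(s):

    F(s) = [ sum_{n=-N}^{N} K_min^{-1} exp( -(s - (s_min + n*h_r))^2
                                             / (2 * sigma_TW(s)^2) ) ]^{-1}

    sigma_TW(s) = sqrt(s) * sigma_bp
    sigma_bp    = (h_r / 2*pi) * sqrt( ell * k_B * T / C_app )

where C_app is the apparent torsional modulus (erg*cm), ell the helical
rise per base pair (cm), k_B Boltzmann's constant (erg/K) and T the
temperature (K). At a minimum F equals K_min, the effective binding
strength at a phasing minimum; between minima all Gaussian terms are small
and F is large. The four free parameters (h_r, C_app, K_min, s_min) are
fit by nonlinear least squares with multi-start initialization over h_r,
because the objective is multimodal in the period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

__all__ = [
    "BOLTZMANN_ERG_PER_K",
    "RISE_PER_BP_CM",
    "PhasingParams",
    "PhasingFit",
    "sigma_bp",
    "sigma_tw",
    "log_predict_F",
    "predict_F",
    "fit_phasing",
    "phase_of",
    "helix_projection",
]

BOLTZMANN_ERG_PER_K = 1.380649e-16  # erg / K
RISE_PER_BP_CM = 3.4e-8  # helical rise per base pair, cm


@dataclass(frozen=True)
class PhasingParams:
    """Model parameters: four fitted quantities plus physical constants."""

    h_r: float = 10.5          # helical repeat, bp per turn
    K_min: float = 1.0         # fluorescence at a phasing minimum
    s_min: float = 1.0         # spacing of the first minimum, bp
    C_app: float = 2.4e-19     # apparent torsional modulus, erg*cm
    ell: float = RISE_PER_BP_CM
    k_B: float = BOLTZMANN_ERG_PER_K
    T: float = 298.0           # K
    N: int = 96                # summation truncation, n = -N..N

    def __post_init__(self):
        if self.h_r <= 0:
            raise ValueError("h_r must be positive")
        if self.K_min <= 0:
            raise ValueError("K_min must be positive")
        if self.C_app <= 0:
            raise ValueError("C_app must be positive")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @classmethod
    def from_sigma_bp(cls, h_r: float, sigma_bp_value: float, **kwargs) -> "PhasingParams":
        """Build params from a per-base twist SD instead of C_app."""
        ell = kwargs.pop("ell", RISE_PER_BP_CM)
        k_B = kwargs.pop("k_B", BOLTZMANN_ERG_PER_K)
        T = kwargs.pop("T", 298.0)
        c_app = ell * k_B * T * (h_r / (2.0 * np.pi * sigma_bp_value)) ** 2
        return cls(h_r=h_r, C_app=c_app, ell=ell, k_B=k_B, T=T, **kwargs)


def sigma_bp(params: PhasingParams) -> float:
    """Per-base-pair twist standard deviation, in bases."""
    if params.C_app <= 0:
        raise ValueError("C_app must be positive")
    return (params.h_r / (2.0 * np.pi)) * np.sqrt(
        params.ell * params.k_B * params.T / params.C_app
    )


def sigma_tw(s, params: PhasingParams):
    """Twist standard deviation at spacing s: sqrt(s) * sigma_bp."""
    s = np.asarray(s, dtype=float)
    if (s < 0).any():
        raise ValueError("spacing must be non-negative")
    return np.sqrt(s) * sigma_bp(params)


def _log_sum_terms(s: np.ndarray, params: PhasingParams) -> np.ndarray:
    """log of sum_n exp(-(s - (s_min + n h_r))^2 / (2 sigma_TW^2)), elementwise.

    Returns -inf where every term underflows and +inf at the sigma_TW = 0
    limit when s sits exactly on a minimum center (delta-like term).
    """
    n = np.arange(-params.N, params.N + 1)
    centers = params.s_min + n * params.h_r
    d2 = (s[:, None] - centers[None, :]) ** 2
    var = sigma_tw(s, params) ** 2  # per-s variance
    out = np.empty(len(s))
    zero = var == 0.0
    if zero.any():
        on_center = (d2[zero] == 0.0).any(axis=1)
        out[zero] = np.where(on_center, 0.0, -np.inf)
    nz = ~zero
    if nz.any():
        out[nz] = logsumexp(-d2[nz] / (2.0 * var[nz, None]), axis=1)
    return out


def log_predict_F(s, params: PhasingParams) -> np.ndarray:
    """Natural log of the predicted fluorescence (numerically stable)."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if (s_arr < 0).any():
        raise ValueError("spacing must be non-negative")
    logF = np.log(params.K_min) - _log_sum_terms(s_arr, params)
    return logF if np.ndim(s) else float(logF[0])


def predict_F(s, params: PhasingParams):
    """Predicted fluorescence at spacing s.

    Where all Gaussian terms underflow to zero (no minimum center within
    numerical reach, e.g. the rigid limit between minima) the prediction is
    +inf and a warning is issued.
    """
    logF = np.atleast_1d(log_predict_F(np.atleast_1d(s), params))
    if (logF > np.log(np.finfo(float).max)).any():
        warnings.warn(
            "predict_F: summation terms underflow at some spacings (no "
            "phasing minimum within numerical reach); returning +inf there",
            stacklevel=2,
        )
    with np.errstate(over="ignore"):
        F = np.exp(logF)
    return F if np.ndim(s) else float(F[0])


@dataclass
class PhasingFit:
    """Result of the four-parameter least-squares phasing fit."""

    params: PhasingParams
    residual_sum: float
    predicted: np.ndarray
    phase: np.ndarray
    converged: bool
    scale: str = "linear"
    message: str = ""
    n_points: int = 0

    def to_dict(self) -> dict:
        p = self.params
        return {
            "h_r": p.h_r,
            "K_min": p.K_min,
            "s_min": p.s_min,
            "C_app": p.C_app,
            "sigma_bp": sigma_bp(p),
            "residual_sum": self.residual_sum,
            "converged": self.converged,
            "scale": self.scale,
            "n_points": self.n_points,
            "message": self.message,
        }


_LN_C_BOUNDS = (np.log(1e-22), np.log(1e-16))


def fit_phasing(
    spacings: Sequence[float],
    intensities: Sequence[float],
    init: PhasingParams | None = None,
    bounds_hr: tuple[float, float] = (2.0, 16.0),
    scale: str = "linear",
    weights: Sequence[float] | None = None,
    multistart_hr: Sequence[float] = (3.5, 5.25, 7.0, 10.5),
    include_zero: bool = False,
    grad_tol: float = 1e-2,
) -> PhasingFit:
    """Fit (h_r, C_app, K_min, s_min) to a fluorescence-versus-spacing series.

    Internally optimizes (h_r, s_min, ln K_min, ln C_app), so the two
    positive parameters stay positive. ``scale='linear'`` minimizes squared
    error on fluorescence; ``scale='log'`` on log fluorescence, appropriate
    when noise is multiplicative. Spacing 0 is excluded by default (the
    torsional broadening vanishes there and the model degenerates to a
    delta comb); non-finite intensities are dropped. Multi-start over h_r
    guards against period-doubled local minima. ``weights`` (e.g. 1/SEM)
    multiply the residuals.
    """
    s = np.asarray(spacings, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if s.shape != y.shape:
        raise ValueError("spacings and intensities must have equal length")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    keep = np.isfinite(y) & (y > 0) & np.isfinite(s)
    if not include_zero:
        keep &= s > 0
    s, y, w = s[keep], y[keep], w[keep]
    if len(s) < 6:
        raise ValueError("need at least 6 usable (spacing, intensity) pairs")
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    log_y = np.log(y)
    degenerate = np.std(log_y) < 1e-12

    def residuals(x: np.ndarray) -> np.ndarray:
        h_r, s_min, ln_k, ln_c = x
        p = PhasingParams(h_r=h_r, K_min=float(np.exp(ln_k)), s_min=s_min,
                          C_app=float(np.exp(ln_c)))
        log_f = log_predict_F(s, p)
        if scale == "log":
            r = log_y - log_f
        else:
            with np.errstate(over="ignore"):
                r = y - np.exp(log_f)
        return w * np.where(np.isfinite(r), r, 1e12)

    lo = [bounds_hr[0], -bounds_hr[1], min(log_y.min(), 0) - 30.0, _LN_C_BOUNDS[0]]
    hi = [bounds_hr[1], 2 * bounds_hr[1], log_y.max() + 30.0, _LN_C_BOUNDS[1]]

    starts = []
    if init is not None:
        starts.append([init.h_r, init.s_min, np.log(init.K_min), np.log(init.C_app)])
    s_at_min = float(s[np.argmin(y)])
    ln_k0 = float(log_y.min())
    for hr0 in multistart_hr:
        if not bounds_hr[0] <= hr0 <= bounds_hr[1]:
            continue
        for sig0 in (0.1, 0.3):
            c0 = PhasingParams.from_sigma_bp(hr0, sig0).C_app
            for smin0 in (s_at_min % hr0, 1.0):
                starts.append([hr0, smin0, ln_k0, float(np.log(c0))])

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                x_scale="jac", max_nfev=2000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("phasing fit failed from every start point")

    h_r, s_min, ln_k, ln_c = best.x
    params = PhasingParams(h_r=float(h_r), K_min=float(np.exp(ln_k)),
                           s_min=float(s_min), C_app=float(np.exp(ln_c)))
    predicted = predict_F(s, params)
    converged = bool(best.status > 0 and best.optimality < grad_tol and not degenerate)
    message = best.message
    if degenerate:
        message = "constant intensities: periodicity unidentifiable; " + message
    return PhasingFit(
        params=params,
        residual_sum=float(2.0 * best.cost),
        predicted=np.asarray(predicted),
        phase=phase_of(s, params),
        converged=converged,
        scale=scale,
        message=message,
        n_points=len(s),
    )


def phase_of(s, fit_or_params) -> np.ndarray:
    """Fractional phase in [0, 1): ((s - s_min) mod h_r) / h_r."""
    params = fit_or_params.params if isinstance(fit_or_params, PhasingFit) else fit_or_params
    if params.h_r <= 0:
        raise ValueError("h_r must be positive")
    s = np.asarray(s, dtype=float)
    r = np.mod(s - params.s_min, params.h_r)
    # snap float-mod residue at ~h_r back to 0 so the phase stays in [0, 1)
    r = np.where(np.isclose(r, params.h_r, rtol=1e-9, atol=1e-9), 0.0, r)
    return r / params.h_r


def helix_projection(s, helical_repeat: float = 10.5):
    """Angle (radians, in [0, 2*pi)) of spacing s around the duplex circumference."""
    s_arr = np.asarray(s, dtype=float)
    if (s_arr < 0).any():
        raise ValueError("spacing must be non-negative")
    ang = np.mod(2.0 * np.pi * s_arr / helical_repeat, 2.0 * np.pi)
    return ang if np.ndim(s) else float(ang)
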