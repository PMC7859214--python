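"""Extended (modified) Tofts tracer-kinetic model.

Tissue concentration under the extended Tofts model is

    Ct(t) = vp * Cp(t) + Cp(t) (*) Ktrans * exp(-kep * t),    kep = Ktrans/ve,

with Ktrans the plasma-to-EES transfer constant (min^-1), ve the fractional
extracellular extravascular volume, and vp the fractional plasma volume.
kep is derived, never fitted independently: the model has three free
parameters.

The convolution with the exponential kernel is evaluated by a recursion
that is exact for piecewise-linear Cp, avoiding FFT wrap-around on the
short uniform grids typical of DCE-MRI (2-s frames).  Times are seconds
externally and converted to minutes internally so rates carry the min^-1
convention used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .aif import AIFCurve, ROIMask
from .exceptions import InvalidParameterError
from .relaxometry import ConcentrationSeries

__all__ = [
    "ToftsParams",
    "ParametricMaps",
    "tofts_forward",
    "exp_kernel_convolve",
    "fit_tofts_curve",
    "fit_map_pixelwise",
    "fit_roi_based",
]

#: fit bounds: Ktrans (min^-1), ve, vp
KTRANS_BOUNDS = (0.0, 10.0)
VE_BOUNDS = (1e-6, 1.0)
VP_BOUNDS = (0.0, 1.0)

#: multi-start initializations (ktrans, ve, vp)
DEFAULT_STARTS = (
    (0.05, 0.3, 0.02),
    (0.2, 0.1, 0.05),
    (0.01, 0.6, 0.01),
)


@dataclass
class ToftsParams:
    """The perfusion parameter quartet with fit diagnostics.

    ``kep`` is derived as ktrans/ve on construction.
    """

    ktrans: float
    ve: float
    vp: float
    kep: float = field(init=False)
    rms_residual: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if self.ktrans < 0:
            raise InvalidParameterError("ktrans must be non-negative")
        if not 0.0 <= self.ve <= 1.0:
            raise InvalidParameterError("ve must be in [0, 1]")
        if not 0.0 <= self.vp <= 1.0:
            raise InvalidParameterError("vp must be in [0, 1]")
        if self.ve == 0.0 and self.ktrans > 0.0:
            raise InvalidParameterError("kep undefined: ve = 0 with ktrans > 0")
        self.kep = self.ktrans / self.ve if self.ve > 0 else 0.0

    def as_dict(self) -> dict:
        return {"ktrans": self.ktrans, "kep": self.kep, "ve": self.ve,
                "vp": self.vp, "rms_residual": self.rms_residual,
                "converged": self.converged}


def exp_kernel_convolve(cp, times_s, ktrans, kep):
    """(Cp (*) Ktrans e^{-kep t})(t) on a uniform grid, in mmol.

    Exact for piecewise-linear Cp.  ``times_s`` in seconds; ``ktrans`` and
    ``kep`` in min^-1.
    """
    cp = np.asarray(cp, dtype=float)
    t = np.asarray(times_s, dtype=float) / 60.0  # minutes
    n = len(cp)
    out = np.zeros(n)
    if n < 2 or ktrans == 0.0:
        return out
    dt = t[1] - t[0]
    a = kep * dt
    if a > 1e-3:
        e = np.exp(-a)
        j0 = -np.expm1(-a) / kep                     # int e^{-kep(dt-s)} ds
        w0 = (1.0 - e * (1.0 + a)) / (kep * a)       # weight of left sample
        w1 = j0 - w0                                 # weight of right sample
    else:
        # series expansions: cancellation-safe for small kep*dt
        e = np.exp(-a)
        w0 = dt * (0.5 - a / 3.0 + a**2 / 8.0)
        w1 = dt * (0.5 - a / 6.0 + a**2 / 24.0)
    # the recursion acc_i = e*acc_{i-1} + increment_i is a first-order IIR filter
    increments = ktrans * (cp[:-1] * w0 + cp[1:] * w1)
    out[1:] = signal.lfilter([1.0], [1.0, -e], increments)
    return out


def tofts_forward(params: ToftsParams, cp, times_s) -> np.ndarray:
    """Forward extended Tofts model: tissue curve from a plasma curve."""
    cp = np.asarray(cp, dtype=float)
    conv = exp_kernel_convolve(cp, times_s, params.ktrans, params.kep)
    return params.vp * cp + conv


def _model(theta, cp, times_s):
    ktrans, ve, vp = theta
    kep = ktrans / ve
    return vp * cp + exp_kernel_convolve(cp, times_s, ktrans, kep)


def fit_tofts_curve(ct, cp, times_s, starts=DEFAULT_STARTS) -> ToftsParams:
    """Bounded nonlinear least-squares fit of (Ktrans, ve, vp) to one curve.

    Multi-start (3 default initializations), best residual kept.  If no
    start converges, the best-effort parameters are returned with
    ``converged=False`` rather than raising, so pixel-wise mapping can
    proceed.
    """
    ct = np.asarray(ct, dtype=float)
    cp = np.asarray(cp, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if ct.shape != cp.shape or ct.shape != times_s.shape:
        raise InvalidParameterError("ct, cp, times must share one time grid")
    lo = np.array([KTRANS_BOUNDS[0], VE_BOUNDS[0], VP_BOUNDS[0]])
    hi = np.array([KTRANS_BOUNDS[1], VE_BOUNDS[1], VP_BOUNDS[1]])

    def resid(theta):
        return _model(theta, cp, times_s) - ct

    best = None
    any_ok = False
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo + 1e-12, hi)
        try:
            res = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         method="trf", max_nfev=2000)
        except Exception:
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        cost = float(res.cost)
        if best is None or cost < best[0]:
            best = (cost, res)
        any_ok = any_ok or bool(res.success)
    if best is None:
        return ToftsParams(0.0, VE_BOUNDS[0], 0.0, rms_residual=np.inf,
                           converged=False)
    res = best[1]
    ktrans, ve, vp = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return ToftsParams(float(ktrans), float(ve), float(vp), rms_residual=rms,
                       converged=any_ok)


@dataclass
class ParametricMaps:
    """Per-parameter 2-D maps over an ROI with a converged-pixel mask.

    ``method`` is "pwm" (pixel-wise) or "rbm" (ROI-based).  Values outside
    the ROI are NaN.  ``roi_summary`` gives mean and SD per parameter over
    converged pixels (the inclusive summary over all fitted pixels is also
    available, since exclusion rules vary between implementations).
    """

    ktrans: np.ndarray
    kep: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    converged: np.ndarray
    roi: ROIMask
    method: str
    n_pixels: int = 0
    n_converged: int = 0

    _PARAMS = ("ktrans", "kep", "ve", "vp")

    def roi_summary(self, converged_only: bool = True) -> dict:
        sel = self.roi.mask & (self.converged if converged_only else True)
        if not np.any(sel):
            raise InvalidParameterError("no pixels to summarize")
        out = {}
        for name in self._PARAMS:
            vals = getattr(self, name)[sel]
            out[name] = (float(np.mean(vals)), float(np.std(vals, ddof=0)))
        return out


def _empty_maps(shape):
    return {name: np.full(shape, np.nan) for name in ParametricMaps._PARAMS}


def fit_map_pixelwise(conc: ConcentrationSeries, roi: ROIMask,
                      aif: AIFCurve) -> ParametricMaps:
    """Pixel-wise method (PWM): fit every ROI pixel, then summarize."""
    shape = roi.mask.shape
    maps = _empty_maps(shape)
    converged = np.zeros(shape, dtype=bool)
    cp = aif.cp
    n_fit = 0
    for r, c in zip(*np.nonzero(roi.mask)):
        curve = conc.conc[:, r, c]
        if not np.all(np.isfinite(curve)):
            continue
        p = fit_tofts_curve(curve, cp, conc.times)
        n_fit += 1
        for name in ParametricMaps._PARAMS:
            maps[name][r, c] = getattr(p, name)
        converged[r, c] = p.converged
    n_conv = int(converged.sum())
    if n_conv == 0:
        raise InvalidParameterError("no converged pixels in ROI")
    return ParametricMaps(**maps, converged=converged, roi=roi, method="pwm",
                          n_pixels=roi.n_pixels, n_converged=n_conv)


def fit_roi_based(conc: ConcentrationSeries, roi: ROIMask,
                  aif: AIFCurve) -> ParametricMaps:
    """ROI-based method (RBM): average the ROI curve first, fit once."""
    shape = roi.mask.shape
    curves = conc.conc[:, roi.mask]
    finite = np.all(np.isfinite(curves), axis=0)
    if not np.any(finite):
        raise InvalidParameterError("no valid pixels in ROI")
    mean_curve = curves[:, finite].mean(axis=1)
    p = fit_tofts_curve(mean_curve, aif.cp, conc.times)
    if not p.converged:
        raise InvalidParameterError("ROI-based fit did not converge")
    maps = _empty_maps(shape)
    for name in ParametricMaps._PARAMS:
        maps[name][roi.mask] = getattr(p, name)
    converged = roi.mask.copy()
    return ParametricMaps(**maps, converged=converged, roi=roi, method="rbm",
                          n_pixels=roi.n_pixels, n_converged=roi.n_pixels)
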