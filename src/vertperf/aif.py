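"""Arterial input function (AIF) construction.

Three AIF variants are supported, mirroring how they are measured in axial
lumbar DCE-MRI:

* aortic (``AIF_A``): mean concentration curve of a manually placed aortic
  ROI;
* segmental-arterial (``AIF_SA``): the single ROI pixel whose
  baseline-subtracted time curve has the largest peak — segmental arteries
  are only 1-2 pixels wide, so a single bright pixel minimizes partial
  volume;
* population-normalized (``AIF_PA``): the aortic curve rescaled so its
  blood peak equals a population value (Parker-style, 6 mmol by default).

The first pass of the bolus is modelled as a Gaussian plus an exponential
washout gated by a sigmoid,

    Cb(t) = A/(sigma*sqrt(2*pi)) * exp(-(t-T)^2/(2*sigma^2))
          + alpha * exp(-beta*t) / (1 + exp(-s*(t-tau))),

fitted only over a first-pass window (baseline, upslope, peak, and a few
post-peak points) so that recirculation does not contaminate the fit.  The
curve handed to kinetic modelling is the fitted model evaluated on the full
time grid, which extrapolates the first pass past the second-pass arrival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import expit

from .exceptions import FitError, InvalidParameterError, NoBolusError
from .relaxometry import ConcentrationSeries, DynamicSeries

__all__ = [
    "FirstPassFit",
    "AIFCurve",
    "ROIMask",
    "first_pass_model",
    "subtract_baseline_series",
    "select_sa_pixel",
    "extract_roi_curve",
    "first_pass_window",
    "fit_first_pass",
    "blood_to_plasma",
    "normalize_population",
    "aif_snr",
    "build_aif",
]

DEFAULT_HCT = 0.42
DEFAULT_TARGET_PEAK = 6.0  # mmol, population blood peak
PEAK_GATE_SD = 5.0         # bolus detection: peak must exceed baseline by k SDs
SECOND_PASS_RISE_SD = 2.0  # recirculation detection: rise after a local minimum
ARRIVAL_FRACTION = 0.10    # arrival = first frame above this fraction of peak


def first_pass_model(t, a_gauss, t_center, sigma, alpha_exp, beta_exp, s_sig, tau_sig):
    """Gaussian bolus plus sigmoid-gated exponential washout (blood curve)."""
    t = np.asarray(t, dtype=float)
    gauss = a_gauss / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(
        -((t - t_center) ** 2) / (2.0 * sigma**2)
    )
    washout = alpha_exp * np.exp(-beta_exp * t) * expit(s_sig * (t - tau_sig))
    return gauss + washout


@dataclass
class FirstPassFit:
    """Fitted first-pass model parameters.

    ``a_gauss``/``t_center``/``sigma``: Gaussian scale, center (s), width (s);
    ``alpha_exp``/``beta_exp``: washout amplitude (mmol) and decay (s^-1);
    ``s_sig``/``tau_sig``: sigmoid width (s^-1) and center (s).
    (The washout amplitude is called alpha in the source model; renamed here
    to avoid colliding with the flip angle.)
    """

    a_gauss: float
    t_center: float
    sigma: float
    alpha_exp: float
    beta_exp: float
    s_sig: float
    tau_sig: float
    rms_residual: float = np.nan

    def __post_init__(self):
        if self.sigma <= 0 or self.s_sig <= 0:
            raise InvalidParameterError("sigma and s_sig must be positive")

    def __call__(self, t):
        return first_pass_model(
            t, self.a_gauss, self.t_center, self.sigma,
            self.alpha_exp, self.beta_exp, self.s_sig, self.tau_sig,
        )

    def as_dict(self) -> dict:
        return {
            "a_gauss": self.a_gauss, "t_center": self.t_center,
            "sigma": self.sigma, "alpha_exp": self.alpha_exp,
            "beta_exp": self.beta_exp, "s_sig": self.s_sig,
            "tau_sig": self.tau_sig, "rms_residual": self.rms_residual,
        }


@dataclass
class ROIMask:
    """A boolean pixel mask with a free-text label."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise InvalidParameterError("ROI mask has no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class AIFCurve:
    """A blood concentration time curve with its first-pass fit.

    ``cb`` is the blood curve handed to kinetic modelling (by default the
    fitted first-pass model on the full grid); ``cp = cb/(1-hct)`` is the
    plasma curve; ``raw`` keeps the measured curve the fit came from.
    """

    cb: np.ndarray
    times: np.ndarray
    hct: float = DEFAULT_HCT
    fit: FirstPassFit | None = None
    window: np.ndarray | None = None
    snr: float = np.nan
    arrival_index: int | None = None
    kind: str = "aortic"
    raw: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.hct < 1.0:
            raise InvalidParameterError("hct must be in [0, 1)")
        self.cb = np.asarray(self.cb, dtype=float)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def cp(self) -> np.ndarray:
        return blood_to_plasma(self.cb, self.hct)

    @property
    def peak(self) -> float:
        return float(self.cb.max())

    @property
    def arrival_time(self) -> float:
        if self.arrival_index is None:
            return np.nan
        return float(self.times[self.arrival_index])


def subtract_baseline_series(series: DynamicSeries) -> DynamicSeries:
    """Subtract the pre-bolus mean image from every frame.

    Static tissue cancels, leaving enhancing structures (arteries) bright —
    the standard trick for finding thin segmental arteries.
    """
    if series.n_frames < series.n_baseline:
        raise InvalidParameterError("fewer frames than baseline length")
    out = series.signal - series.baseline_mean()
    return DynamicSeries(signal=out, times=series.times.copy(),
                         n_baseline=series.n_baseline)


def select_sa_pixel(subtracted, roi: ROIMask) -> tuple:
    """Pick the ROI pixel whose subtracted time curve peaks highest.

    Ties break toward the lowest row-major index.  Returns (row, col).
    """
    sig = subtracted.signal if isinstance(subtracted, DynamicSeries) else np.asarray(subtracted)
    peaks = sig.max(axis=0)
    masked = np.where(roi.mask, peaks, -np.inf)
    idx = int(np.argmax(masked))  # argmax returns the first (row-major) max
    return np.unravel_index(idx, roi.mask.shape)


def extract_roi_curve(conc, roi: ROIMask) -> np.ndarray:
    """Per-frame mean concentration over the ROI pixels."""
    arr = conc.conc if isinstance(conc, ConcentrationSeries) else np.asarray(conc)
    return arr[:, roi.mask].mean(axis=1)


def first_pass_window(curve, n_baseline: int, n_post: int = 3,
                      k: float = PEAK_GATE_SD) -> np.ndarray:
    """Frame indices of the first pass: baseline, upslope, peak, + n_post.

    The peak must exceed the baseline mean by ``k`` baseline SDs to count as
    a bolus.  The window never extends past a detected second-pass arrival,
    taken as the first post-peak local minimum followed by a rise of at
    least 2 baseline SDs.
    """
    curve = np.asarray(curve, dtype=float)
    n = len(curve)
    base = curve[:n_baseline]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    peak_idx = int(np.argmax(curve))
    peak = curve[peak_idx]
    if not (peak > mu + k * sd and peak > mu):
        raise NoBolusError(
            f"no detectable bolus: peak {peak:.4g} at frame {peak_idx} vs "
            f"baseline {mu:.4g} +/- {sd:.4g} (gate {k} SD)"
        )
    end = min(peak_idx + n_post, n - 1)
    rise = max(SECOND_PASS_RISE_SD * sd, 1e-12)
    for i in range(peak_idx + 1, n - 1):
        if curve[i] <= curve[i - 1] and curve[i] <= curve[i + 1]:
            if curve[i + 1:].max() >= curve[i] + rise:
                end = min(end, i)
                break
    return np.arange(0, end + 1)


def _window_times(times, window):
    return np.asarray(times, dtype=float)[np.asarray(window, dtype=int)]


def fit_first_pass(curve, window, times) -> FirstPassFit:
    """Least-squares fit of the first-pass model over the window frames.

    Initialization from curve moments: center at the argmax time, Gaussian
    area from the peak height, width from the upslope half-height distance.
    All widths are bounded positive.  Frames outside the window never enter
    the fit.
    """
    curve = np.asarray(curve, dtype=float)
    window = np.asarray(window, dtype=int)
    t = _window_times(times, window)
    y = curve[window]
    dt = np.median(np.diff(np.asarray(times, dtype=float)))
    span = t[-1] - t[0] + dt

    i_pk = int(np.argmax(y))
    peak, t_pk = float(y[i_pk]), float(t[i_pk])
    half = peak / 2.0
    above = np.flatnonzero(y[: i_pk + 1] >= half)
    sigma0 = max(t_pk - t[above[0]], dt) if len(above) else 2.0 * dt
    a0 = peak * sigma0 * np.sqrt(2.0 * np.pi)
    tail = max(float(y[-1]), 1e-3 * peak)
    lo = np.array([0.0, t[0], 1e-3, 0.0, 0.0, 1e-3, t[0] - span])
    hi = np.array([np.inf, t[-1] + span, span, np.inf, 1.0, 10.0, t[-1] + span])
    # the washout/sigmoid corner of the model is weakly constrained by a
    # short window and prone to local minima: multi-start and keep the best
    starts = [
        (tail, 0.0, 0.5, t_pk - 2.0 * sigma0),
        (tail, 0.003, 1.0, t_pk - sigma0),
        (tail, 0.01, 0.5, t_pk),
        (0.1 * peak, 0.0, 1.0, t_pk + sigma0),
    ]

    def resid(p):
        return first_pass_model(t, *p) - y

    best = None
    for alpha0, beta0, s0, tau0 in starts:
        x0 = np.clip(np.array([a0, t_pk, sigma0, alpha0, beta0, s0, tau0]),
                     lo + 1e-9, np.where(np.isfinite(hi), hi - 1e-9, np.inf))
        try:
            res = optimize.least_squares(resid, x0, bounds=(lo, hi),
                                         method="trf", x_scale="jac",
                                         ftol=1e-12, xtol=1e-12, gtol=1e-12,
                                         max_nfev=3000)
        except Exception:
            continue
        if (res.success and np.all(np.isfinite(res.x))
                and (best is None or res.cost < best.cost)):
            best = res
    if best is None:
        raise FitError("first-pass AIF fit did not converge", result=best)
    rms = float(np.sqrt(np.mean(best.fun**2)))
    return FirstPassFit(*best.x, rms_residual=rms)


def blood_to_plasma(cb, hct: float = DEFAULT_HCT) -> np.ndarray:
    """Plasma concentration Cp = Cb / (1 - Hct)."""
    if not 0.0 <= hct < 1.0:
        raise InvalidParameterError(f"hct must be in [0, 1), got {hct}")
    return np.asarray(cb, dtype=float) / (1.0 - hct)


def aif_snr(curve, n_baseline: int) -> float:
    """Temporal SNR of an AIF: max(curve) / SD(baseline frames).

    A constant baseline gives infinite SNR, flagged with a warning.
    """
    curve = np.asarray(curve, dtype=float)
    if n_baseline < 2:
        raise InvalidParameterError("aif_snr needs at least 2 baseline frames")
    sd = float(curve[:n_baseline].std(ddof=0))
    if sd == 0.0:
        warnings.warn("zero baseline SD: AIF SNR reported as infinite",
                      RuntimeWarning, stacklevel=2)
        return np.inf
    return float(curve.max()) / sd


def normalize_population(aif: AIFCurve,
                         target_peak: float = DEFAULT_TARGET_PEAK) -> AIFCurve:
    """Rescale a blood curve so its peak equals a population value.

    Returns a population-kind AIF; amplitudes of the first-pass fit scale
    with the curve, times and SNR (a ratio) are unchanged.  Idempotent at a
    fixed target.
    """
    peak = aif.peak
    if peak <= 0:
        raise InvalidParameterError("cannot normalize an AIF with non-positive peak")
    scale = target_peak / peak
    fit = None
    if aif.fit is not None:
        fit = replace(aif.fit, a_gauss=aif.fit.a_gauss * scale,
                      alpha_exp=aif.fit.alpha_exp * scale,
                      rms_residual=aif.fit.rms_residual * scale)
    return AIFCurve(
        cb=aif.cb * scale, times=aif.times.copy(), hct=aif.hct, fit=fit,
        window=None if aif.window is None else aif.window.copy(),
        snr=aif.snr, arrival_index=aif.arrival_index, kind="population",
        raw=None if aif.raw is None else aif.raw * scale,
    )


def build_aif(curve, times, n_baseline: int = 5, kind: str = "aortic",
              hct: float = DEFAULT_HCT, n_post: int = 3,
              use_fitted: bool = True) -> AIFCurve:
    """Assemble an AIFCurve from a measured blood concentration curve.

    Windows the first pass, fits the first-pass model, and (by default)
    uses the fitted model evaluated on the full grid as the downstream
    curve, suppressing recirculation.  SNR is computed on the raw curve.
    Errors if the bolus arrives inside the baseline window.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    window = first_pass_window(curve, n_baseline, n_post=n_post)
    fit = fit_first_pass(curve, window, times)
    cb = fit(times) if use_fitted else curve.copy()
    peak = cb.max()
    above = np.flatnonzero(cb > ARRIVAL_FRACTION * peak)
    arrival = int(above[0]) if len(above) else 0
    if arrival <= n_baseline - 1:
        raise NoBolusError(
            f"bolus arrival (frame {arrival}) inside the {n_baseline}-frame baseline"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        snr = aif_snr(curve, n_baseline)
    return AIFCurve(cb=cb, times=times.copy(), hct=hct, fit=fit, window=window,
                    snr=snr, arrival_index=arrival, kind=kind, raw=curve.copy())
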