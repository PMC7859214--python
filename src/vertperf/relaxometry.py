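"""Spoiled gradient-echo (SPGR/FLASH) relaxometry.

Forward steady-state signal model, variable-flip-angle (VFA) T1 estimation,
and conversion between dynamic signal and gadolinium concentration.

The steady-state SPGR signal is

    S = M0_eff * sin(a) * (1 - E) / (1 - cos(a) * E),   E = exp(-TR/T1),

where ``M0_eff`` absorbs the equilibrium magnetization and the (flip-angle
independent) TE/T2* decay factor.  Concentration follows from the change in
longitudinal relaxation rate,

    C(t) = (1/r1) * (1/T1(t) - 1/T10),

with r1 the contrast-agent relaxivity (default 3.6 s^-1 mmol^-1 for Gd-DOTA
at 1.5 T).  T1 values are carried in milliseconds (MR convention) and
converted to seconds only where they meet r1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .exceptions import InvalidParameterError

__all__ = [
    "SPGRProtocol",
    "T1Map",
    "DynamicSeries",
    "ConcentrationSeries",
    "spgr_signal",
    "fit_t1_vfa",
    "vfa_linearized",
    "concentration_from_signal",
    "concentration_to_signal",
    "signal_ratio_to_t1",
    "frame_acquisition_time",
]

#: bounds (ms) for the nonlinear T10 refinement
T1_BOUNDS_MS = (50.0, 5000.0)

#: clamp width for the signal-ratio inversion
E1_EPS = 1e-6


@dataclass(frozen=True)
class SPGRProtocol:
    """Acquisition constants shared by the forward model and its inversions.

    Parameters
    ----------
    tr : repetition time, ms
    te : echo time, ms (kept for provenance; absorbed into ``m0_eff``)
    flip_angles : VFA excitation angles, degrees
    frame_interval : dynamic frame spacing, s
    r1 : contrast relaxivity, s^-1 mmol^-1
    """

    tr: float = 19.0
    te: float = 4.0
    flip_angles: tuple = (5.0, 10.0, 20.0, 40.0, 60.0, 80.0)
    frame_interval: float = 2.0
    r1: float = 3.6

    def __post_init__(self):
        object.__setattr__(self, "flip_angles", tuple(float(a) for a in self.flip_angles))
        if self.tr <= 0:
            raise InvalidParameterError(f"tr must be positive, got {self.tr}")
        if self.te < 0:
            raise InvalidParameterError(f"te must be non-negative, got {self.te}")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be positive")
        if self.r1 <= 0:
            raise InvalidParameterError("r1 must be positive")
        for a in self.flip_angles:
            if not 0.0 < a <= 90.0:
                raise InvalidParameterError(f"flip angle {a} outside (0, 90] degrees")


@dataclass
class T1Map:
    """Per-voxel pre-contrast T1 (ms) and effective amplitude from a VFA fit.

    ``converged`` flags voxels where the fit succeeded; non-converged voxels
    keep their (unreliable) best-effort values rather than being zeroed.
    """

    t10: np.ndarray
    m0_eff: np.ndarray
    fit_residual: np.ndarray
    converged: np.ndarray


@dataclass
class DynamicSeries:
    """A 2-D + time dynamic signal series.

    ``signal`` is indexed (frame, row, col); ``times`` are frame midpoints in
    seconds on a uniform grid; ``n_baseline`` counts pre-bolus frames.
    """

    signal: np.ndarray
    times: np.ndarray
    n_baseline: int = 5

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.signal.shape[0] != self.times.shape[0]:
            raise InvalidParameterError("signal and times disagree on frame count")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise InvalidParameterError("times must be strictly increasing and uniform")
        if not 1 <= self.n_baseline < self.signal.shape[0]:
            raise InvalidParameterError(
                f"n_baseline={self.n_baseline} must be in [1, n_frames)"
            )

    @property
    def n_frames(self) -> int:
        return self.signal.shape[0]

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def baseline_mean(self) -> np.ndarray:
        """Pre-bolus signal S0: mean over the first ``n_baseline`` frames."""
        return self.signal[: self.n_baseline].mean(axis=0)


@dataclass
class ConcentrationSeries:
    """Contrast-agent concentration (mmol), indexed (frame, row, col).

    ``clamped`` marks voxel-frames whose signal ratio left the physically
    invertible range and was clamped.  The unit label "mmol" follows the
    source convention for this analysis; mmol/L (mM) is the usual reading.
    """

    conc: np.ndarray
    times: np.ndarray
    clamped: np.ndarray | None = None
    n_baseline: int = 5


def spgr_signal(m0_eff, t1, flip_angle, tr):
    """Steady-state spoiled gradient-echo signal.

    Parameters are broadcast; ``t1`` and ``tr`` in ms, ``flip_angle`` in
    degrees.  The TE/T2* factor is treated as absorbed into ``m0_eff``.
    """
    t1 = np.asarray(t1, dtype=float)
    if np.any(t1 <= 0):
        raise InvalidParameterError("t1 must be positive")
    if np.any(np.asarray(tr, dtype=float) <= 0):
        raise InvalidParameterError("tr must be positive")
    a = np.deg2rad(flip_angle)
    e = np.exp(-np.asarray(tr, dtype=float) / t1)
    return np.asarray(m0_eff) * np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e)


def frame_acquisition_time(tr_ms, n_phase_encodes, partial_fourier=1.0, acceleration=1):
    """Time (s) to acquire one dynamic frame.

    TR times the number of phase-encoding lines, reduced by the partial
    Fourier fraction and the parallel-imaging acceleration factor.
    """
    if tr_ms <= 0 or n_phase_encodes <= 0:
        raise InvalidParameterError("tr and phase-encode count must be positive")
    return tr_ms * 1e-3 * n_phase_encodes * partial_fourier / acceleration


def vfa_linearized(signals, flip_angles_deg, tr):
    """Closed-form DESPOT1 estimate of (t10, m0_eff) per voxel.

    Regresses S/sin(a) on S/tan(a): the slope is E = exp(-TR/T10) and the
    intercept is m0_eff*(1-E).  ``signals`` has shape (n_angles, ...).
    """
    sig = np.asarray(signals, dtype=float)
    a = np.deg2rad(np.asarray(flip_angles_deg, dtype=float))
    shape = sig.shape[1:]
    flat = sig.reshape(len(a), -1)
    y = flat / np.sin(a)[:, None]
    x = flat / np.tan(a)[:, None]
    n = len(a)
    sx, sy = x.sum(0), y.sum(0)
    sxx, sxy = (x * x).sum(0), (x * y).sum(0)
    denom = sxx - sx * sx / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sxy - sx * sy / n) / denom
        intercept = (sy - slope * sx) / n
    slope = np.clip(np.nan_to_num(slope, nan=0.5), 1e-6, 1.0 - 1e-9)
    t10 = -tr / np.log(slope)
    m0 = intercept / (1.0 - slope)
    t10 = np.clip(t10, *T1_BOUNDS_MS)
    m0 = np.where(m0 > 0, m0, np.abs(flat).max(axis=0) + 1e-12)
    return t10.reshape(shape), m0.reshape(shape)


def _vfa_residual_jac(params, sig, sin_a, cos_a, tr):
    m0, t1 = params
    e = np.exp(-tr / t1)
    denom = 1.0 - cos_a * e
    model = m0 * sin_a * (1.0 - e) / denom
    resid = model - sig
    d_e = m0 * sin_a * (cos_a - 1.0) / denom**2
    de_dt1 = e * tr / t1**2
    jac = np.stack([model / m0 if m0 != 0 else sin_a * (1 - e) / denom,
                    d_e * de_dt1], axis=1)
    return resid, jac


def fit_t1_vfa(signals_by_angle, protocol: SPGRProtocol, mask=None) -> T1Map:
    """Per-voxel VFA T1 fit: linearized initialization, nonlinear refinement.

    Parameters
    ----------
    signals_by_angle : array (n_angles, ...) of SPGR signals, one image per
        flip angle in ``protocol.flip_angles``.
    mask : optional boolean array over the spatial shape restricting which
        voxels are fitted; others are flagged non-converged.

    Degenerate voxels (all-zero signal) are flagged non-converged, never
    silently zeroed.
    """
    sig = np.asarray(signals_by_angle, dtype=float)
    angles = protocol.flip_angles
    if len(angles) < 3:
        raise InvalidParameterError("VFA fitting requires at least 3 flip angles")
    if sig.shape[0] != len(angles):
        raise InvalidParameterError(
            f"got {sig.shape[0]} images for {len(angles)} flip angles"
        )
    shape = sig.shape[1:]
    flat = sig.reshape(len(angles), -1)
    n_vox = flat.shape[1]

    t10_init, m0_init = vfa_linearized(sig, angles, protocol.tr)
    t10_init = t10_init.ravel()
    m0_init = m0_init.ravel()

    if mask is None:
        fit_sel = np.ones(n_vox, dtype=bool)
    else:
        fit_sel = np.asarray(mask, dtype=bool).ravel()
    nonzero = np.abs(flat).max(axis=0) > 0
    fit_sel = fit_sel & nonzero

    a = np.deg2rad(np.asarray(angles, dtype=float))
    sin_a, cos_a = np.sin(a), np.cos(a)

    t10 = np.full(n_vox, np.nan)
    m0 = np.full(n_vox, np.nan)
    resid = np.full(n_vox, np.nan)
    conv = np.zeros(n_vox, dtype=bool)

    lo = np.array([0.0, T1_BOUNDS_MS[0]])
    hi = np.array([np.inf, T1_BOUNDS_MS[1]])
    for i in np.flatnonzero(fit_sel):
        y = flat[:, i]
        x0 = np.clip(
            np.array([max(m0_init[i], 1e-9), t10_init[i]]),
            lo + 1e-12,
            [np.inf, hi[1]],
        )
        try:
            res = optimize.least_squares(
                lambda p: _vfa_residual_jac(p, y, sin_a, cos_a, protocol.tr)[0],
                x0,
                jac=lambda p: _vfa_residual_jac(p, y, sin_a, cos_a, protocol.tr)[1],
                bounds=(lo, hi),
                method="trf",
            )
        except Exception:
            continue
        if res.success and np.all(np.isfinite(res.x)):
            m0[i], t10[i] = res.x
            resid[i] = np.sqrt(np.mean(res.fun**2))
            conv[i] = True

    return T1Map(
        t10=t10.reshape(shape),
        m0_eff=m0.reshape(shape),
        fit_residual=resid.reshape(shape),
        converged=conv.reshape(shape),
    )


def signal_ratio_to_t1(ratio, t10_ms, flip_angle, tr, eps=E1_EPS):
    """Invert the SPGR signal ratio S(t)/S0 to T1(t) in closed form.

    Returns (t1_ms, clamped) where ``clamped`` marks entries whose implied
    E1 = exp(-TR/T1) fell outside (0, 1) — noise can push ratios past the
    model range — and was clamped to (eps, 1-eps).
    """
    ratio = np.asarray(ratio, dtype=float)
    t10_ms = np.asarray(t10_ms, dtype=float)
    a = np.deg2rad(flip_angle)
    cos_a = np.cos(a)
    e10 = np.exp(-tr / t10_ms)
    b = ratio * (1.0 - e10) / (1.0 - cos_a * e10)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (1.0 - b) / (1.0 - b * cos_a)
    clamped = ~((e1 > eps) & (e1 < 1.0 - eps)) | ~np.isfinite(e1)
    e1 = np.clip(np.nan_to_num(e1, nan=eps), eps, 1.0 - eps)
    t1 = -tr / np.log(e1)
    return t1, clamped


def concentration_from_signal(
    series: DynamicSeries,
    t1map: T1Map | np.ndarray | float,
    protocol: SPGRProtocol,
    flip_angle: float,
) -> ConcentrationSeries:
    """Convert a dynamic SPGR series to contrast concentration (mmol).

    Per voxel and frame: ratio = S(t)/S0 (S0 the pre-bolus mean), T1(t) from
    the closed-form ratio inversion, then C(t) = (1/r1)(1/T1(t) - 1/T10)
    with T1 in seconds.  Voxels without a valid T10 (non-converged fits)
    come out NaN; out-of-range ratios are clamped and flagged.
    """
    if isinstance(t1map, T1Map):
        t10 = np.where(t1map.converged, t1map.t10, np.nan)
    else:
        t10 = np.asarray(t1map, dtype=float)
    s0 = series.baseline_mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.signal / s0
    ratio = np.where(s0 > 0, ratio, np.nan)
    t1t, clamped = signal_ratio_to_t1(ratio, t10, flip_angle, protocol.tr)
    conc = (1.0 / protocol.r1) * (1000.0 / t1t - 1000.0 / t10)  # T1 ms -> s
    return ConcentrationSeries(
        conc=conc, times=series.times.copy(), clamped=clamped,
        n_baseline=series.n_baseline,
    )


def concentration_to_signal(conc, t10_ms, m0_eff, protocol: SPGRProtocol, flip_angle):
    """Forward-encode a concentration curve as SPGR signal.

    1/T1(t) = 1/T10 + r1*C(t) (rates in s^-1), then the SPGR equation at the
    dynamic flip angle.  Used by the phantom generator and round-trip tests.
    """
    conc = np.asarray(conc, dtype=float)
    r1_rate = 1000.0 / np.asarray(t10_ms, dtype=float) + protocol.r1 * conc  # s^-1
    if np.any(r1_rate <= 0):
        raise InvalidParameterError("implied relaxation rate non-positive")
    t1_ms = 1000.0 / r1_rate
    return spgr_signal(m0_eff, t1_ms, flip_angle, protocol.tr)
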