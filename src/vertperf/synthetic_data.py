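"""Digital phantom emulating an axial lumbar DCE-MRI acquisition.

The phantom stands in for patient scans: a 2-D slice containing an aorta,
a pair of bright segmental-artery pixels inside a larger search ROI, a
vertebral body, and static background tissue.  Region kinetics:

* aorta: first-pass bolus (Gaussian + sigmoid-gated exponential washout)
  with a dispersed recirculation bump; blood peak ~5.04 mmol;
* segmental artery: the same shape scaled to ~1.81 mmol and delayed by one
  frame (arrival ~2 s later, the aorta-to-segmental delay measured in
  vivo), with its own recirculation bump;
* vertebra: extended Tofts response to the first-pass aortic plasma curve
  (the recirculation-free input, matching what the analysis assumes);
* background: no enhancement.

Every region's concentration curve is encoded as SPGR signal at the
region's T10, VFA images are generated from the same T10 map, and Gaussian
noise is added in signal space: an i.i.d. per-pixel component plus a
shared per-frame component per vessel region (physiological fluctuation
that ROI averaging cannot remove — it is what limits the temporal SNR of a
measured AIF).  Regeneration with the same spec is bit-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .aif import FirstPassFit, ROIMask, first_pass_model
from .exceptions import InvalidParameterError
from .relaxometry import (
    DynamicSeries,
    SPGRProtocol,
    concentration_to_signal,
    spgr_signal,
)
from .tofts import ToftsParams, tofts_forward

__all__ = ["PhantomSpec", "PhantomBundle", "generate_phantom"]

REGIONS = ("aorta", "segmental", "vertebra", "background")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of the digital phantom.

    Bolus shape parameters are shared between aorta and segmental artery;
    amplitudes are solved so the blood peaks hit ``aorta_peak`` and
    ``sa_peak``.  T1 values in ms, times in s, rates in the units of the
    model they feed.
    """

    shape: tuple = (64, 64)
    n_frames: int = 220
    frame_interval: float = 2.0
    n_baseline: int = 5
    # first-pass bolus shape
    aorta_peak: float = 5.04          # mmol, blood
    sa_peak: float = 1.81             # mmol, blood
    sa_delay_frames: int = 1
    bolus_center: float = 33.0        # s
    bolus_sigma: float = 4.0          # s
    washout_amplitude: float = 1.0    # relative to Gaussian peak of 5
    washout_decay: float = 0.0        # s^-1 (plateau; see module docstring)
    sigmoid_width: float = 1.2        # s^-1
    sigmoid_center: float = 27.0      # s
    # recirculation (second pass)
    recirc_fraction: float = 0.3      # of first-pass peak
    recirc_lag: float = 36.0          # s after the bolus center
    recirc_dispersion: float = 1.5    # width multiplier
    # tissue kinetics
    vertebra_ktrans: float = 0.05     # min^-1
    vertebra_ve: float = 0.30
    vertebra_vp: float = 0.025
    hct: float = 0.42
    # relaxometry
    t10_ms: tuple = (("aorta", 1400.0), ("segmental", 1400.0),
                     ("vertebra", 700.0), ("background", 900.0))
    m0_eff: float = 1000.0
    dynamic_flip: float = 40.0
    # signal-space noise: per-pixel i.i.d. SD and per-region shared SD
    # vertebra SD chosen so the tissue-curve temporal SNR (peak/SD) is ~20
    noise_sd: tuple = (("aorta", 2.0), ("segmental", 5.0),
                       ("vertebra", 2.5), ("background", 3.0))
    noise_shared_sd: tuple = (("aorta", 0.5), ("segmental", 0.5),
                              ("vertebra", 0.0), ("background", 0.0))
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        for name in ("t10_ms", "noise_sd", "noise_shared_sd"):
            value = getattr(self, name)
            pairs = value.items() if isinstance(value, dict) else value
            object.__setattr__(self, name,
                               tuple((str(k), float(v)) for k, v in pairs))
        if self.aorta_peak <= 0 or self.sa_peak <= 0:
            raise InvalidParameterError("AIF peaks must be positive")
        if self.n_frames * self.frame_interval < self.bolus_center + 4 * self.bolus_sigma:
            raise InvalidParameterError("scan too short for the bolus")

    @property
    def t10(self) -> dict:
        return dict(self.t10_ms)

    @property
    def noise(self) -> dict:
        return dict(self.noise_sd)

    @property
    def noise_shared(self) -> dict:
        return dict(self.noise_shared_sd)

    @property
    def protocol(self) -> SPGRProtocol:
        return SPGRProtocol(frame_interval=self.frame_interval)

    @property
    def vertebra_params(self) -> ToftsParams:
        return ToftsParams(self.vertebra_ktrans, self.vertebra_ve,
                           self.vertebra_vp)

    def noiseless(self) -> "PhantomSpec":
        zero = tuple((k, 0.0) for k, _ in self.noise_sd)
        return dataclasses.replace(self, noise_sd=zero, noise_shared_sd=zero)


@dataclass
class PhantomBundle:
    """Generated phantom data with complete ground truth."""

    vfa: np.ndarray                    # (n_angles, rows, cols)
    dynamic: DynamicSeries
    masks: dict                        # name -> ROIMask
    t10_truth: np.ndarray
    truth_curves: dict                 # name -> concentration curve (mmol)
    truth_params: ToftsParams
    aorta_fit_truth: FirstPassFit
    sa_fit_truth: FirstPassFit
    manifest: dict
    spec: PhantomSpec


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _geometry(shape):
    """Region masks: aorta disk, segmental ROI box with a 2-pixel artery,
    vertebral disk.  Laid out on a 64x64 reference grid and scaled."""
    r, c = shape
    if min(r, c) < 32:
        raise InvalidParameterError("phantom grid must be at least 32x32")

    def sr(v):  # scale a reference row coordinate
        return int(round(v * r / 64))

    def sc(v):
        return int(round(v * c / 64))

    radius_scale = min(r, c) / 64.0
    aorta = _disk(shape, (sr(20), sc(22)), 4.5 * radius_scale)
    sa_roi = np.zeros(shape, dtype=bool)
    sa_roi[sr(18): sr(25), sc(34): sc(41)] = True
    sa_pixels = np.zeros(shape, dtype=bool)
    sa_pixels[sr(21), sc(37)] = True
    sa_pixels[sr(21), sc(37) + 1] = True
    vertebra = _disk(shape, (sr(42), sc(32)), 8.0 * radius_scale)
    if (aorta & sa_roi).any() or (aorta & vertebra).any() or (sa_roi & vertebra).any():
        raise InvalidParameterError("phantom regions overlap")
    return aorta, sa_roi, sa_pixels, vertebra


def _first_pass_params(spec: PhantomSpec, target_peak: float,
                       times: np.ndarray) -> FirstPassFit:
    """Solve the amplitude pair so the first-pass blood peak hits target."""
    a0 = 5.0 * spec.bolus_sigma * np.sqrt(2.0 * np.pi)
    alpha0 = spec.washout_amplitude
    base = FirstPassFit(a0, spec.bolus_center, spec.bolus_sigma, alpha0,
                        spec.washout_decay, spec.sigmoid_width,
                        spec.sigmoid_center)
    scale = target_peak / base(times).max()  # peak on the frame grid
    return FirstPassFit(a0 * scale, spec.bolus_center, spec.bolus_sigma,
                        alpha0 * scale, spec.washout_decay,
                        spec.sigmoid_width, spec.sigmoid_center)


def _recirc(spec: PhantomSpec, fit: FirstPassFit, t):
    """Dispersed second-pass bump added on top of the first pass."""
    peak = fit.a_gauss / (fit.sigma * np.sqrt(2.0 * np.pi))
    width = fit.sigma * spec.recirc_dispersion
    center = fit.t_center + spec.recirc_lag
    return spec.recirc_fraction * peak * np.exp(
        -((t - center) ** 2) / (2.0 * width**2)
    )


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Build the phantom: curves, signal encoding, noise, masks, manifest."""
    protocol = spec.protocol
    times = (np.arange(spec.n_frames) + 0.5) * spec.frame_interval
    aorta_m, sa_roi_m, sa_px_m, vert_m = _geometry(spec.shape)
    background_m = ~(aorta_m | sa_roi_m | vert_m)
    # segmental-artery pixels sit inside the search ROI; the rest of that
    # box behaves like background tissue
    sa_rest_m = sa_roi_m & ~sa_px_m

    aorta_fit = _first_pass_params(spec, spec.aorta_peak, times)
    sa_fit_undelayed = _first_pass_params(spec, spec.sa_peak, times)
    delay_s = spec.sa_delay_frames * spec.frame_interval
    sa_fit = dataclasses.replace(
        sa_fit_undelayed,
        t_center=sa_fit_undelayed.t_center + delay_s,
        tau_sig=sa_fit_undelayed.tau_sig + delay_s,
    )

    nb = spec.n_baseline
    aorta_fp = aorta_fit(times)
    aorta_fp[:nb] = 0.0  # bolus support begins after the baseline window
    aorta_cb = aorta_fp + _recirc(spec, aorta_fit, times)
    sa_cb = sa_fit(times) + _recirc(spec, sa_fit, times)
    sa_cb[:nb] = 0.0
    # tissue responds to the recirculation-free first-pass input, the same
    # input the downstream fitted AIF represents
    aorta_cp_fp = aorta_fp / (1.0 - spec.hct)
    vert_ct = tofts_forward(spec.vertebra_params, aorta_cp_fp, times)

    t10 = spec.t10
    t10_map = np.full(spec.shape, t10["background"])
    t10_map[vert_m] = t10["vertebra"]
    t10_map[aorta_m] = t10["aorta"]
    t10_map[sa_roi_m] = t10["background"]
    t10_map[sa_px_m] = t10["segmental"]

    region_curves = {
        "aorta": (aorta_m, aorta_cb, t10["aorta"]),
        "segmental": (sa_px_m, sa_cb, t10["segmental"]),
        "vertebra": (vert_m, vert_ct, t10["vertebra"]),
        "sa_background": (sa_rest_m, np.zeros_like(times), t10["background"]),
        "background": (background_m, np.zeros_like(times), t10["background"]),
    }

    rng = np.random.default_rng(spec.seed)
    noise = spec.noise
    shared = spec.noise_shared
    dyn = np.zeros((spec.n_frames,) + spec.shape)
    for name, (mask, curve, t10_r) in region_curves.items():
        key = "background" if name == "sa_background" else name
        sig = concentration_to_signal(curve, t10_r, spec.m0_eff, protocol,
                                      spec.dynamic_flip)
        n_px = int(mask.sum())
        block = np.tile(sig[:, None], (1, n_px))
        if noise[key] > 0:
            block = block + rng.normal(0.0, noise[key], block.shape)
        if shared[key] > 0:
            block = block + rng.normal(0.0, shared[key], (spec.n_frames, 1))
        dyn[:, mask] = block

    n_angles = len(protocol.flip_angles)
    vfa = np.zeros((n_angles,) + spec.shape)
    for j, angle in enumerate(protocol.flip_angles):
        img = spgr_signal(spec.m0_eff, t10_map, angle, protocol.tr)
        for name, (mask, _, _) in region_curves.items():
            key = "background" if name == "sa_background" else name
            if noise[key] > 0:
                img = np.where(
                    mask, img + rng.normal(0.0, noise[key], spec.shape), img
                )
        vfa[j] = img

    masks = {
        "aorta": ROIMask(aorta_m, "aorta"),
        "sa_roi": ROIMask(sa_roi_m, "segmental artery search ROI"),
        "sa_pixels": ROIMask(sa_px_m, "segmental artery pixels"),
        "vertebra": ROIMask(vert_m, "vertebral body"),
    }
    manifest = {
        "spec": dataclasses.asdict(spec),
        "aorta_fit": aorta_fit.as_dict(),
        "sa_fit": sa_fit.as_dict(),
        "regions": {k: int(v.mask.sum()) for k, v in masks.items()},
    }
    return PhantomBundle(
        vfa=vfa,
        dynamic=DynamicSeries(signal=dyn, times=times,
                              n_baseline=spec.n_baseline),
        masks=masks,
        t10_truth=t10_map,
        truth_curves={
            "aorta_cb": aorta_cb,
            "aorta_first_pass": aorta_fp,
            "sa_cb": sa_cb,
            "vertebra_ct": vert_ct,
        },
        truth_params=spec.vertebra_params,
        aorta_fit_truth=aorta_fit,
        sa_fit_truth=sa_fit,
        manifest=manifest,
        spec=spec,
    )
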