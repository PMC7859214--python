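"""End-to-end analysis convenience layer.

Chains the stages the way they run on a patient (or phantom) dataset:
VFA T1 map over the analysis regions, signal-to-concentration conversion,
AIF construction (aortic ROI mean, segmental max-peak pixel, population
normalization), and vertebral Tofts fitting by both the pixel-wise and
ROI-based methods against each AIF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aif import (
    AIFCurve,
    ROIMask,
    build_aif,
    extract_roi_curve,
    normalize_population,
    select_sa_pixel,
    subtract_baseline_series,
)
from .relaxometry import (
    ConcentrationSeries,
    DynamicSeries,
    SPGRProtocol,
    T1Map,
    concentration_from_signal,
    fit_t1_vfa,
)
from .tofts import ParametricMaps, fit_map_pixelwise, fit_roi_based

__all__ = ["PerfusionAnalysis", "analyze"]


@dataclass
class PerfusionAnalysis:
    """All intermediate and final products of one dataset's analysis."""

    t1map: T1Map
    conc: ConcentrationSeries
    aifs: dict          # kind -> AIFCurve ("aortic", "segmental", "population")
    sa_pixel: tuple
    fits: dict          # (aif_kind, method) -> ParametricMaps


def analyze(
    vfa: np.ndarray,
    dynamic: DynamicSeries,
    masks: dict,
    protocol: SPGRProtocol,
    dynamic_flip: float = 40.0,
    hct: float = 0.42,
    n_post: int = 3,
    target_peak: float = 6.0,
    methods: tuple = ("pwm", "rbm"),
    aif_kinds: tuple = ("aortic", "segmental", "population"),
) -> PerfusionAnalysis:
    """Run the full perfusion analysis.

    ``masks`` must provide "aorta", "sa_roi" and "vertebra" ROIMasks.  The
    T1 map is fitted only over the union of the masks (the voxels whose
    concentration is needed downstream).
    """
    union = masks["aorta"].mask | masks["sa_roi"].mask | masks["vertebra"].mask
    t1map = fit_t1_vfa(vfa, protocol, mask=union)
    conc = concentration_from_signal(dynamic, t1map, protocol, dynamic_flip)
    n_base = dynamic.n_baseline

    aifs: dict = {}
    # aortic: ROI-mean concentration curve
    aorta_curve = extract_roi_curve(conc, masks["aorta"])
    aifs["aortic"] = build_aif(aorta_curve, conc.times, n_baseline=n_base,
                               kind="aortic", hct=hct, n_post=n_post)
    # segmental: max-peak pixel on the baseline-subtracted series
    subtracted = subtract_baseline_series(dynamic)
    sa_pixel = select_sa_pixel(subtracted, masks["sa_roi"])
    sa_curve = conc.conc[:, sa_pixel[0], sa_pixel[1]]
    aifs["segmental"] = build_aif(sa_curve, conc.times, n_baseline=n_base,
                                  kind="segmental", hct=hct, n_post=n_post)
    # population: aortic curve normalized to the population blood peak
    aifs["population"] = normalize_population(aifs["aortic"], target_peak)

    fits = {}
    vert = masks["vertebra"]
    for kind in aif_kinds:
        if "rbm" in methods:
            fits[(kind, "rbm")] = fit_roi_based(conc, vert, aifs[kind])
        if "pwm" in methods:
            fits[(kind, "pwm")] = fit_map_pixelwise(conc, vert, aifs[kind])
    return PerfusionAnalysis(t1map=t1map, conc=conc, aifs=aifs,
                             sa_pixel=sa_pixel, fits=fits)
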