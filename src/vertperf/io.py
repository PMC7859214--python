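"""Readers and writers for the formats the pipeline touches.

NIfTI volumes (via nibabel) for images, maps and byte masks; JSON
run-length masks; CSV curves; JSON first-pass fits and ROI summaries;
YAML/JSON acquisition configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .aif import AIFCurve, FirstPassFit, ROIMask
from .exceptions import InvalidParameterError
from .relaxometry import DynamicSeries, SPGRProtocol, T1Map

__all__ = [
    "load_volume", "save_volume", "load_dynamic", "load_mask", "save_mask",
    "load_protocol", "save_curve", "load_curve", "save_first_pass_fit",
    "load_first_pass_fit", "save_aif_curve", "save_roi_summary",
    "save_t1map", "load_t1map",
]


def load_volume(path) -> np.ndarray:
    """Load a NIfTI volume as a float array, singleton axes squeezed."""
    img = nib.load(str(path))
    return np.squeeze(np.asarray(img.get_fdata(), dtype=float))


def save_volume(arr, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)),
             str(path))


def load_dynamic(path, frame_interval: float, n_baseline: int = 5) -> DynamicSeries:
    """Load a dynamic series; the last NIfTI axis is time, moved first."""
    arr = load_volume(path)
    if arr.ndim != 3:
        raise InvalidParameterError(f"expected 2-D + time data, got shape {arr.shape}")
    sig = np.moveaxis(arr, -1, 0)
    times = (np.arange(sig.shape[0]) + 0.5) * frame_interval
    return DynamicSeries(signal=sig, times=times, n_baseline=n_baseline)


def load_mask(path, label: str = "") -> ROIMask:
    """Load an ROI mask from a NIfTI byte mask or run-length JSON.

    Run-length JSON: ``{"shape": [rows, cols], "runs": [[start, length], ...]}``
    with row-major flat offsets.
    """
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        flat = np.zeros(int(np.prod(payload["shape"])), dtype=bool)
        for start, length in payload["runs"]:
            flat[start: start + length] = True
        return ROIMask(flat.reshape(payload["shape"]), label or payload.get("label", ""))
    return ROIMask(load_volume(path) > 0, label)


def save_mask(roi: ROIMask, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        flat = roi.mask.ravel()
        runs = []
        i = 0
        while i < len(flat):
            if flat[i]:
                j = i
                while j < len(flat) and flat[j]:
                    j += 1
                runs.append([int(i), int(j - i)])
                i = j
            else:
                i += 1
        path.write_text(json.dumps(
            {"shape": list(roi.mask.shape), "runs": runs, "label": roi.label}))
    else:
        save_volume(roi.mask.astype(np.uint8), path)


def load_protocol(path) -> SPGRProtocol:
    """Read acquisition constants from a YAML or JSON config."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    fields = {k: cfg[k] for k in
              ("tr", "te", "flip_angles", "frame_interval", "r1") if k in cfg}
    return SPGRProtocol(**fields)


def save_curve(times, values, path, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": times, value_name: values}).to_csv(path, index=False)


def load_curve(path):
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(), df[df.columns[1]].to_numpy()


def save_first_pass_fit(fit: FirstPassFit, path) -> None:
    Path(path).write_text(json.dumps(fit.as_dict(), indent=2))


def load_first_pass_fit(path) -> FirstPassFit:
    return FirstPassFit(**json.loads(Path(path).read_text()))


def save_aif_curve(aif: AIFCurve, path) -> None:
    """Write an AIF as CSV: time_s, cb_mmol, cp_mmol."""
    pd.DataFrame({"time_s": aif.times, "cb_mmol": aif.cb,
                  "cp_mmol": aif.cp}).to_csv(path, index=False)


def save_roi_summary(maps, path) -> None:
    """Write a ParametricMaps ROI summary as JSON."""
    summary = maps.roi_summary()
    payload = {
        "method": maps.method,
        "n_pixels": maps.n_pixels,
        "n_converged": maps.n_converged,
    }
    for name, (mean, sd) in summary.items():
        unit = "_min^-1" if name in ("ktrans", "kep") else ""
        payload[f"{name}{unit}_mean"] = mean
        payload[f"{name}{unit}_sd"] = sd
    Path(path).write_text(json.dumps(payload, indent=2))


def save_t1map(t1map: T1Map, prefix) -> None:
    prefix = str(prefix)
    save_volume(np.where(t1map.converged, t1map.t10, np.nan), prefix + "_t10.nii.gz")
    save_volume(np.where(t1map.converged, t1map.m0_eff, np.nan), prefix + "_m0.nii.gz")


def load_t1map(prefix) -> T1Map:
    t10 = load_volume(str(prefix) + "_t10.nii.gz")
    m0 = load_volume(str(prefix) + "_m0.nii.gz")
    conv = np.isfinite(t10)
    return T1Map(t10=t10, m0_eff=m0,
                 fit_residual=np.full(t10.shape, np.nan), converged=conv)
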