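"""File formats: NIfTI image stacks with JSON sidecars, CSV tables.

Conventions
-----------
* Signal stacks are 4-D NIfTI volumes (rows x cols x 1 x acquisition
  points); the acquisition grid (TI/TSL/TE values, TR, contrast) lives in a
  JSON sidecar next to the image (same stem, ``.json``).
* Masks and zonal label maps are integer NIfTI volumes.
* Parameter maps are written as NIfTI (relaxation time in ms) plus a
  per-pixel diagnostics CSV (amplitude, residual norm, convergence flag).
* Stress-strain curves are CSV with columns ``strain, stress_MPa``; Pauli
  score tables are CSV with one row per sample.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relaxometry import ParameterMap, SignalStack
from .zones import ZonalPartition

__all__ = [
    "save_stack", "load_stack", "save_mask", "load_mask",
    "save_parameter_map", "load_parameter_map",
    "save_partition", "load_partition",
    "save_curve", "load_curve", "save_scores", "load_scores",
]


def _affine(pixel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_size
    return aff


def save_stack(stack: SignalStack, path: str | Path, pixel_size: float = 1.0) -> Path:
    """Write a signal stack as 4-D NIfTI plus a JSON acquisition sidecar."""
    path = Path(path)
    data = stack.data[:, :, None, :].astype(np.float32)
    nib.save(nib.Nifti1Image(data, _affine(pixel_size)), path)
    sidecar = {
        "contrast": stack.contrast,
        "acquisition_variable": stack.acquisition_variable,
        "times_ms": list(map(float, stack.times)),
        "tr_ms": stack.tr,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_stack(path: str | Path) -> SignalStack:
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return SignalStack(
        data=data,
        times=np.asarray(meta["times_ms"], dtype=float),
        contrast=meta["contrast"],
        tr=meta.get("tr_ms"),
    )


def save_mask(mask: np.ndarray, path: str | Path, pixel_size: float = 1.0) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(pixel_size)), path)
    return path


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0


def save_parameter_map(pmap: ParameterMap, path: str | Path, pixel_size: float = 1.0) -> Path:
    """NIfTI of the relaxation-time map + diagnostics CSV alongside."""
    path = Path(path)
    nib.save(
        nib.Nifti1Image(pmap.relaxation_time.astype(np.float32), _affine(pixel_size)),
        path,
    )
    rows, cols = np.nonzero(pmap.mask)
    diag = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "relaxation_time_ms": pmap.relaxation_time[rows, cols],
            "amplitude": pmap.amplitude[rows, cols],
            "residual_norm": pmap.residual_norm[rows, cols],
            "converged": pmap.converged[rows, cols],
        }
    )
    diag.to_csv(path.with_suffix("").with_suffix(".diagnostics.csv"), index=False)
    meta = {"contrast": pmap.contrast, "bounds_ms": list(pmap.bounds)}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    values = np.asarray(nib.load(path).dataobj, dtype=float)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    diag = pd.read_csv(path.with_suffix("").with_suffix(".diagnostics.csv"))
    amplitude = np.full(values.shape, np.nan)
    residual = np.full(values.shape, np.nan)
    converged = np.zeros(values.shape, dtype=bool)
    r, c = diag["row"].to_numpy(), diag["col"].to_numpy()
    amplitude[r, c] = diag["amplitude"]
    residual[r, c] = diag["residual_norm"]
    converged[r, c] = diag["converged"]
    return ParameterMap(
        relaxation_time=values,
        amplitude=amplitude,
        converged=converged,
        residual_norm=residual,
        contrast=meta["contrast"],
        bounds=tuple(meta["bounds_ms"]),
    )


def save_partition(partition: ZonalPartition, path: str | Path, pixel_size: float = 1.0) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(partition.labels.astype(np.uint8), _affine(pixel_size)), path)
    meta = {
        "division_x": list(partition.division_x),
        "apex_side": partition.apex_side,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_partition(path: str | Path) -> ZonalPartition:
    path = Path(path)
    labels = np.asarray(nib.load(path).dataobj, dtype=np.int8)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return ZonalPartition(
        labels=labels,
        division_x=tuple(meta["division_x"]),
        apex_side=meta["apex_side"],
    )


def save_curve(curve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"strain": curve.strain, "stress_MPa": curve.stress}).to_csv(
        path, index=False
    )
    return path


def load_curve(path: str | Path, sample_id: str | None = None):
    from .biomechanics import StressStrainCurve

    df = pd.read_csv(path)
    return StressStrainCurve.from_dataframe(df, sample_id=sample_id)


def save_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    scores.to_csv(path, index=False)
    return path


def load_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
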