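"""ROI summaries and response-to-loading statistics for serial qMRI maps.

Samples are imaged at three loading positions: delta0 (unloaded, 0 bar),
delta1 (2 bar, compressive force 37.1 N) and delta2 (4 bar, 69.1 N).  Each
position's parameter maps are summarised per region of interest (the entire
sample and the apex/intermediate/base zones) as median (IQR) over unflagged
pixels; per-load maps are summarised independently, with no inter-load
registration, matching per-position re-segmentation.

The response to loading is the per-sample relative change of an ROI median
at a loaded position versus the unloaded reference:

    Delta_i = (value(delta_i) / value(delta0) - 1) * 100   [%]

so decreases are negative.  Cohort-level Delta statistics are means +/- SD
over these per-sample values (never ratios of cohort medians).

IQR convention: linear-interpolation quartiles (numpy's default percentile
rule), frozen here for reproducibility.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relaxometry import ParameterMap
from .zones import ZonalPartition

__all__ = [
    "LoadingState",
    "ROISummary",
    "LOAD_LABELS",
    "LOAD_PRESSURES_BAR",
    "LOAD_FORCES_N",
    "summarize_roi",
    "summarize_maps",
    "relative_change",
    "pressure_from_force",
    "pixel_count_series",
    "delta_table",
]

log = logging.getLogger(__name__)

LOAD_LABELS = ("delta0", "delta1", "delta2")
LOAD_PRESSURES_BAR = {"delta0": 0.0, "delta1": 2.0, "delta2": 4.0}
LOAD_FORCES_N = {"delta0": 0.0, "delta1": 37.1, "delta2": 69.1}
ROIS = ("entire", "I", "II", "III")


@dataclass
class LoadingState:
    """One loading position: set pressure, force, maps and zonal partition."""

    label: str
    maps: dict[str, ParameterMap]
    partition: ZonalPartition
    set_pressure_bar: float | None = None
    compressive_force_n: float | None = None

    def __post_init__(self) -> None:
        if self.label not in LOAD_LABELS:
            raise ValueError(f"loading label must be one of {LOAD_LABELS}")
        if self.set_pressure_bar is None:
            self.set_pressure_bar = LOAD_PRESSURES_BAR[self.label]
        if self.compressive_force_n is None:
            self.compressive_force_n = LOAD_FORCES_N[self.label]
        if self.label == "delta0" and self.compressive_force_n != 0.0:
            raise ValueError("the unloaded position delta0 must have zero force")


@dataclass
class ROISummary:
    """Median (IQR) of one contrast in one ROI at one loading position."""

    sample_id: str
    roi: str
    load: str
    contrast: str
    median: float
    q1: float
    q3: float
    pixel_count: int

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def summarize_roi(
    pmap: ParameterMap,
    partition: ZonalPartition,
    roi: str,
    sample_id: str = "",
    load: str = "delta0",
) -> ROISummary:
    """Median/IQR of a parameter map over the unflagged pixels of one ROI.

    An empty ROI yields a missing-value entry (NaN median, count 0) and is
    logged rather than raised.
    """
    if roi not in ROIS:
        raise ValueError(f"roi must be one of {ROIS}, got {roi!r}")
    if pmap.relaxation_time.shape != partition.labels.shape:
        raise ValueError("parameter map and partition do not share a grid")
    sel = partition.zone_mask(roi) & pmap.valid_mask()
    values = pmap.relaxation_time[sel]
    if values.size == 0:
        log.warning(
            "empty ROI %s for sample %s (%s, %s): missing-value entry",
            roi, sample_id, load, pmap.contrast,
        )
        return ROISummary(sample_id, roi, load, pmap.contrast, np.nan, np.nan, np.nan, 0)
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return ROISummary(
        sample_id, roi, load, pmap.contrast,
        float(med), float(q1), float(q3), int(values.size),
    )


def summarize_maps(
    states: list[LoadingState], sample_id: str, grade_group: str | None = None
) -> pd.DataFrame:
    """Long-format summary table over states x contrasts x ROIs.

    Columns: sample, grade_group, roi, load, contrast, median, q1, q3, iqr,
    pixel_count.
    """
    rows = []
    for state in states:
        for contrast, pmap in state.maps.items():
            for roi in ROIS:
                s = summarize_roi(pmap, state.partition, roi, sample_id, state.label)
                rows.append(
                    {
                        "sample": sample_id,
                        "grade_group": grade_group,
                        "roi": roi,
                        "load": state.label,
                        "contrast": contrast,
                        "median": s.median,
                        "q1": s.q1,
                        "q3": s.q3,
                        "iqr": s.iqr,
                        "pixel_count": s.pixel_count,
                    }
                )
    return pd.DataFrame(rows)


def relative_change(value_loaded: float, value_ref: float) -> float:
    """Relative response-to-loading change in percent.

    ``Delta = ((loaded / reference) - 1) * 100``; decreases are negative.
    A non-positive or non-finite reference yields NaN (missing value).
    """
    if not np.isfinite(value_ref) or value_ref <= 0 or not np.isfinite(value_loaded):
        return float("nan")
    return (value_loaded / value_ref - 1.0) * 100.0


def delta_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Delta1/Delta2 from a long-format ROI summary table.

    Returns columns: sample, grade_group, roi, contrast, delta1, delta2.
    Deltas are computed from per-sample ROI medians; entries missing either
    state are NaN.
    """
    wide = summary.pivot_table(
        index=["sample", "grade_group", "roi", "contrast"],
        columns="load",
        values="median",
        aggfunc="first",
        dropna=False,
    )
    rows = []
    for key, row in wide.iterrows():
        sample, grade, roi, contrast = key
        ref = row.get("delta0", np.nan)
        rows.append(
            {
                "sample": sample,
                "grade_group": grade,
                "roi": roi,
                "contrast": contrast,
                "delta1": relative_change(row.get("delta1", np.nan), ref),
                "delta2": relative_change(row.get("delta2", np.nan), ref),
            }
        )
    return pd.DataFrame(rows)


def pressure_from_force(
    force_n: float, length_mm: float, width_mm: float, ndigits: int | None = 2
) -> float:
    """Mean contact pressure in MPa: force / (length * width).

    With N and mm, force/area is directly MPa.  Reported to 2 decimals by
    default (pass ``ndigits=None`` for full precision).
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("sample dimensions must be positive")
    if force_n < 0:
        raise ValueError("force must be non-negative")
    p = force_n / (length_mm * width_mm)
    return round(p, ndigits) if ndigits is not None else p


def pixel_count_series(masks: dict[str, np.ndarray] | list[np.ndarray]) -> pd.DataFrame:
    """Per-load mask pixel counts plus a monotone-decrease flag.

    Accepts a mapping load-label -> mask or an ordered list of masks.
    """
    if isinstance(masks, dict):
        items = list(masks.items())
    else:
        items = list(zip(LOAD_LABELS, masks))
    if len(items) < 2:
        raise ValueError("need at least two loading states")
    counts = [int(np.asarray(m, dtype=bool).sum()) for _, m in items]
    monotone = all(b < a for a, b in zip(counts, counts[1:]))
    return pd.DataFrame(
        {
            "load": [label for label, _ in items],
            "pixel_count": counts,
            "monotone_decrease": monotone,
        }
    )
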