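"""Zonal partitioning of segmented meniscus cross-sections.

A segmented meniscus body cross-section is wedge shaped, running from the
inner apex to the peripheral base.  After excluding boundary pixels (one
morphological erosion, to suppress partial-volume contamination), the mask
is split into three zones of equal mediolateral extent: apex (I),
intermediate (II) and base (III).  The split is computed by projecting the
mask onto the horizontal axis, dividing the spanned interval into thirds,
and classifying every pixel by the third its column falls into.

Which image side is the apex is acquisition metadata and must be supplied
explicitly; it is never inferred from image content.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["ZonalPartition", "exclude_boundary", "partition_thirds", "ZONE_CODES"]

#: integer label codes used in the partition label image
ZONE_CODES = {"background": 0, "I": 1, "II": 2, "III": 3}
ZONE_NAMES = {v: k for k, v in ZONE_CODES.items()}


@dataclass(frozen=True)
class ZonalPartition:
    """Mask split into apex (I) / intermediate (II) / base (III) labels.

    Attributes
    ----------
    labels : ndarray of int
        Same shape as the mask; 0 background, 1 apex, 2 intermediate, 3 base.
    division_x : tuple of float
        The two mediolateral cut positions in (continuous, 0-based) pixel
        coordinates.
    apex_side : str
        ``"left"`` or ``"right"``.
    """

    labels: np.ndarray
    division_x: tuple[float, float]
    apex_side: str

    def zone_mask(self, zone: str) -> np.ndarray:
        """Boolean mask of one zone (``"I" | "II" | "III"``) or ``"entire"``."""
        if zone == "entire":
            return self.labels > 0
        return self.labels == ZONE_CODES[zone]

    def zone_counts(self) -> dict[str, int]:
        return {z: int(self.zone_mask(z).sum()) for z in ("I", "II", "III")}


def exclude_boundary(mask: np.ndarray, *, sample_id: str | None = None) -> np.ndarray:
    """Remove boundary pixels from a binary mask (one 8-connectivity erosion).

    Every mask pixel with at least one background 8-neighbour (image borders
    count as background) is dropped, eliminating partial-volume pixels at the
    segmented outline.

    Raises
    ------
    ValueError
        If the mask is empty or erosion empties it (e.g. a one-pixel-wide
        structure); the message names ``sample_id`` when given.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    tag = f" (sample {sample_id})" if sample_id else ""
    if not mask.any():
        raise ValueError(f"mask is empty{tag}")
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    if not eroded.any():
        raise ValueError(f"mask is empty after boundary-pixel exclusion{tag}")
    return eroded


def partition_thirds(mask: np.ndarray, apex_side: str = "left") -> ZonalPartition:
    """Partition a mask into mediolateral thirds: apex (I) to base (III).

    The mask's maximum mediolateral diameter is the column interval
    ``[x_min, x_max + 1)`` spanned by its most peripheral pixels.  That
    interval is divided into three equal thirds and every pixel is labelled
    by the third containing its column *centre* (``x + 0.5``).  Pixel
    centres can never coincide with a cut (centres have half-integer
    coordinates while cuts are multiples of w/3), so the rule is tie-free,
    conservation-exact, translation invariant and mirror symmetric.

    Parameters
    ----------
    mask : 2-D bool array
        Segmentation mask, normally already boundary-excluded.
    apex_side : {"left", "right"}
        Which image side the meniscus apex (inner tip) faces.
    """
    if apex_side not in ("left", "right"):
        raise ValueError(f"apex_side must be 'left' or 'right', got {apex_side!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {mask.shape}")
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise ValueError("mask is empty")
    x_min, x_max = int(cols[0]), int(cols[-1])
    width = x_max - x_min + 1
    if width < 3:
        raise ValueError(
            f"mask spans only {width} column(s); at least 3 are needed to "
            "partition into thirds"
        )

    col_idx = np.arange(mask.shape[1])
    centre = col_idx + 0.5 - x_min
    bucket = np.clip(np.floor(3.0 * centre / width).astype(int), 0, 2)
    if apex_side == "right":
        bucket = 2 - bucket
    zone_of_col = bucket + 1  # 1..3, I on the apex side

    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[mask] = zone_of_col[np.nonzero(mask)[1]]

    cut1 = x_min + width / 3.0
    cut2 = x_min + 2.0 * width / 3.0
    return ZonalPartition(labels=labels, division_x=(cut1, cut2), apex_side=apex_side)
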