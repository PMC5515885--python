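"""Label conventions and boundary-band geometry shared across modules.

Masks use 0-based pixel indices, row-major order.  Label images encode
background=0, cytoplasm=1, nucleus=2, rim=3.  The rim is always a band
of configured width straddling a region boundary; interphase rims, the
chromosome-surface band in mitosis, and phantom ground truth all share
this one convention.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CYTOPLASM",
    "LABEL_NUCLEUS",
    "LABEL_RIM",
    "boundary_band",
    "disk_band",
    "masks_from_labels",
]

LABEL_BACKGROUND = 0
LABEL_CYTOPLASM = 1
LABEL_NUCLEUS = 2
LABEL_RIM = 3


def boundary_band(mask: np.ndarray, width: float) -> np.ndarray:
    """Band of ``width`` pixels straddling the boundary of a binary mask.

    A pixel belongs to the band when its Euclidean distance to the
    inside/outside interface is at most ``width/2``.  Pixel centers sit
    half a pixel from the interface, hence the 0.5 offsets; the outer
    comparison is strict so a symmetric band of odd integer width
    contains exactly ``width`` pixel layers across a straight edge.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("boundary_band: mask is empty")
    if mask.all():
        raise ValueError("boundary_band: mask covers the whole frame")
    half = width / 2.0
    dist_in = ndi.distance_transform_edt(mask)
    dist_out = ndi.distance_transform_edt(~mask)
    inner = mask & (dist_in - 0.5 <= half)
    outer = (~mask) & (dist_out - 0.5 < half)
    return inner | outer


def disk_band(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    width: float,
) -> np.ndarray:
    """Annulus ``|r(x) - radius| <= width/2`` from a continuous distance map.

    Used both by the phantom generator (exact ground truth) and by the
    subpixel radial refinement of rim segmentation, so that the two
    agree by construction for circular nuclei.
    """
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return np.abs(d - radius) <= width / 2.0


def masks_from_labels(labels: np.ndarray) -> dict[str, np.ndarray]:
    """Split a label image into named boolean masks."""
    return {
        "background": labels == LABEL_BACKGROUND,
        "cytoplasm": labels == LABEL_CYTOPLASM,
        "nucleus": labels == LABEL_NUCLEUS,
        "rim": labels == LABEL_RIM,
    }
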