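"""Chromosome-rim localization and crowding through anaphase -> G1.

Works on 3-channel time-lapse stacks (donor, acceptor, chromosome
marker).  Anaphase onset — time zero — is the first frame at which the
thresholded chromosome mask splits into two well-separated masses and
stays split.  Per frame, the chromosome-surface rim band carries two
readouts:

* the relative nuclear localization (RNL) of the donor signal,
  ``(rim mean - bg) / (cytoplasm mean - bg) - 1``, a dimensionless
  excess over the cytoplasm that rises as the subunit assembles;
* the probe signal ``probe_NE / probe_Cyto`` normalized to its value at
  onset, which falls as crowding builds.

Half-times are extracted as the earliest linear-interpolated crossing of
the midpoint between the trace extremes over the post-onset window, with
the plateau taken as the mean of the last three frames to resist noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .config import PipelineConfig, SegmentationParams
from .interphase import probe_signal
from .regions import boundary_band

__all__ = [
    "OnsetNotFoundError",
    "HalfTimeResult",
    "TimelapseTrace",
    "chromosome_mask",
    "detect_anaphase_onset",
    "chromosome_rim_mask",
    "localization_signal",
    "probe_timecourse",
    "extract_half_time",
    "chromosome_area_timecourse",
    "analyze_timelapse",
]


class OnsetNotFoundError(RuntimeError):
    """No persistent chromosome separation event found in the stack."""


@dataclass
class HalfTimeResult:
    """Half-maximum (rise) or half-minimum (fall) crossing time."""

    time: Optional[float]  # min after anaphase onset; None if unrecoverable
    recovered: bool
    direction: str  # 'rise-to-max' | 'fall-to-min'
    level: Optional[float] = None  # the half level that was crossed
    method: str = "midpoint of (max+min)/2, plateau = mean of last 3 frames, earliest linear-interpolated crossing"


@dataclass
class TimelapseTrace:
    """Per-frame readouts of one cell's reassembly time course."""

    times: np.ndarray  # min after anaphase onset (negative pre-onset)
    localization: np.ndarray
    probe: np.ndarray
    area: np.ndarray  # chromosome mask area relative to onset
    anaphase_onset_frame: int
    half_max_localization: Optional[HalfTimeResult] = None
    half_min_probe: Optional[HalfTimeResult] = None
    qc_flags: list[str] = field(default_factory=list)


def chromosome_mask(
    frame: np.ndarray, threshold: Optional[float] = None, min_area: int = 20
) -> np.ndarray:
    """Thresholded chromosome-marker mask with small components removed."""
    frame = np.asarray(frame, dtype=float)
    thr = threshold_otsu(frame) if threshold is None else threshold
    mask = frame > thr
    lab = cc_label(mask)
    if lab.max() == 0:
        return np.zeros_like(mask)
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_area)
    keep = keep[keep != 0]
    return np.isin(lab, keep)


def _split_distance(mask: np.ndarray) -> Optional[float]:
    """Centroid distance of the two largest components, or None if < 2."""
    lab = cc_label(mask)
    props = sorted(regionprops(lab), key=lambda p: p.area, reverse=True)
    if len(props) < 2:
        return None
    (y1, x1), (y2, x2) = props[0].centroid, props[1].centroid
    return float(np.hypot(y1 - y2, x1 - x2))


def detect_anaphase_onset(
    chrom_stack: np.ndarray,
    min_distance: float = 10.0,
    persistence: int = 2,
    threshold: Optional[float] = None,
) -> int:
    """First frame of persistent chromosome separation (anaphase onset).

    Onset is the first frame whose thresholded chromosome mask splits
    into >= 2 connected components with centroid distance above
    ``min_distance`` px, and stays split for ``persistence`` consecutive
    frames (spurious one-frame splits are ignored).  Raises
    :class:`OnsetNotFoundError` if no such frame exists; callers may
    supply the onset manually instead.
    """
    n = chrom_stack.shape[0]
    split = np.zeros(n, dtype=bool)
    for f in range(n):
        d = _split_distance(chromosome_mask(chrom_stack[f], threshold))
        split[f] = d is not None and d >= min_distance
    for f in range(n - persistence + 1):
        if split[f : f + persistence].all():
            return f
    raise OnsetNotFoundError(
        f"no chromosome separation with centroid distance >= {min_distance} px "
        f"persisting {persistence} frames in {n}-frame stack"
    )


def chromosome_rim_mask(
    frame_or_mask: np.ndarray,
    rim_width: float = 3.0,
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Boundary band of ``rim_width`` around the chromosome mass(es).

    Accepts either a boolean chromosome mask or a raw marker frame
    (thresholded first).  Separated masses get one band each; the band
    convention matches the interphase NE rim.
    """
    arr = np.asarray(frame_or_mask)
    mask = arr if arr.dtype == bool else chromosome_mask(arr, threshold)
    if not mask.any():
        raise ValueError("chromosome_rim_mask: empty chromosome mask")
    return boundary_band(mask, rim_width)


def localization_signal(
    donor: np.ndarray,
    rim_mask: np.ndarray,
    cyto_mask: np.ndarray,
    background: float = 0.0,
) -> float:
    """Relative nuclear localization: rim excess over cytoplasm.

    ``(rim mean - bg) / (cyto mean - bg) - 1``, clipped at zero.  Zero
    when the rim is indistinguishable from cytoplasm, 1.0 when the
    background-subtracted rim is twice the cytoplasm.
    """
    if not rim_mask.any() or not cyto_mask.any():
        raise ValueError("localization_signal: empty mask")
    donor = np.asarray(donor, dtype=float)
    cyto = float(donor[cyto_mask].mean()) - background
    if cyto <= 0:
        raise ValueError("cytoplasm mean at or below background; RNL undefined")
    rim = float(donor[rim_mask].mean()) - background
    return max(rim / cyto - 1.0, 0.0)


def probe_timecourse(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    rim_masks: Sequence[np.ndarray],
    cyto_masks: Sequence[np.ndarray],
    onset_frame: int,
    background: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Rim-over-cytoplasm probe signal per frame, relative to onset.

    Per frame: ``probe_signal`` on the chromosome rim divided by
    ``probe_signal`` on the cytoplasm; the series is then divided by its
    value at the onset frame, so it equals 1 at time zero by
    construction.
    """
    n = donor_stack.shape[0]
    series = np.empty(n)
    for f in range(n):
        rim = probe_signal(acceptor_stack[f], donor_stack[f], rim_masks[f], background)
        cyto = probe_signal(acceptor_stack[f], donor_stack[f], cyto_masks[f], background)
        series[f] = rim / cyto
    anchor = series[onset_frame]
    if not np.isfinite(anchor) or anchor <= 0:
        raise ValueError("probe signal undefined at the onset frame")
    return series / anchor


def extract_half_time(
    series: np.ndarray,
    times: np.ndarray,
    direction: str,
) -> HalfTimeResult:
    """Earliest crossing of the midpoint between the trace extremes.

    ``direction='rise-to-max'`` (localization): levels are the series
    minimum and the plateau (mean of the last 3 frames); the first
    upward crossing is returned.  ``direction='fall-to-min'`` (probe):
    levels are the series maximum and the final plateau; the first
    downward crossing is returned.  Crossings are linearly interpolated
    between adjacent frames.  A flat series (or one that never crosses)
    yields ``recovered=False`` rather than an error, mirroring traces
    where the probe signal does not significantly change.
    """
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    if series.size < 3:
        raise ValueError("need at least 3 frames to extract a half-time")
    if direction not in ("rise-to-max", "fall-to-min"):
        raise ValueError(f"unknown direction {direction!r}")

    plateau = float(series[-3:].mean())
    if direction == "rise-to-max":
        lo, hi = float(series.min()), plateau
    else:
        lo, hi = plateau, float(series.max())
    if hi <= lo:
        return HalfTimeResult(time=None, recovered=False, direction=direction)
    half = 0.5 * (lo + hi)

    rising = direction == "rise-to-max"
    for i in range(1, series.size):
        a, b = series[i - 1], series[i]
        crossed = (a < half <= b) if rising else (a > half >= b)
        if crossed:
            frac = (half - a) / (b - a)
            t = times[i - 1] + frac * (times[i] - times[i - 1])
            return HalfTimeResult(
                time=float(t), recovered=True, direction=direction, level=half
            )
    return HalfTimeResult(time=None, recovered=False, direction=direction, level=half)


def chromosome_area_timecourse(
    chrom_stack: np.ndarray,
    onset_frame: int,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, list[str]]:
    """Chromosome mask area per frame, relative to the onset frame.

    Frames with no chromosome signal become NaN gaps with a QC flag,
    never a hard error.
    """
    n = chrom_stack.shape[0]
    areas = np.empty(n)
    flags: list[str] = []
    for f in range(n):
        mask = chromosome_mask(chrom_stack[f], threshold)
        a = float(mask.sum())
        if a == 0:
            areas[f] = np.nan
            flags.append(f"empty_chromosome_mask:frame{f}")
        else:
            areas[f] = a
    anchor = areas[onset_frame]
    if not np.isfinite(anchor) or anchor == 0:
        raise ValueError("chromosome area undefined at the onset frame")
    return areas / anchor, flags


def _frame_regions(
    donor: np.ndarray,
    chrom: np.ndarray,
    rim_width: float,
    margin: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame rim and cytoplasm masks (per-frame re-segmentation)."""
    rim = boundary_band(chrom, rim_width)
    fg = donor > threshold_otsu(donor)
    fg = ndi.binary_fill_holes(fg)
    excl = ndi.binary_dilation(chrom | rim, iterations=margin)
    cyto = fg & ~excl & ndi.binary_erosion(fg, iterations=margin)
    if not cyto.any():
        cyto = fg & ~excl
    return rim, cyto


def analyze_timelapse(
    stack: np.ndarray,
    frame_interval: float = 2.0,
    config: Optional[PipelineConfig] = None,
    onset_frame: Optional[int] = None,
    times: Optional[np.ndarray] = None,
) -> TimelapseTrace:
    """Full per-cell time-lapse analysis of a (T, 3, H, W) stack.

    Channels are (donor, acceptor, chromosome marker).  Detects anaphase
    onset (unless supplied), re-segments the chromosome rim and
    cytoplasm per frame, computes the localization and probe series,
    and extracts both half-times over the post-onset window.  Frame
    times come from ``times`` metadata when given, else
    ``index * frame_interval``.
    """
    if config is None:
        config = PipelineConfig()
    seg = config.segmentation
    donor_stack, acceptor_stack, chrom_stack = stack[:, 0], stack[:, 1], stack[:, 2]
    n = stack.shape[0]

    if onset_frame is None:
        onset_frame = detect_anaphase_onset(
            chrom_stack,
            min_distance=config.min_separation_px,
            persistence=config.onset_persistence,
        )
    if times is None:
        times = (np.arange(n) - onset_frame) * frame_interval
    times = np.asarray(times, dtype=float)

    rim_masks, cyto_masks, bg_masks = [], [], []
    qc: list[str] = []
    loc = np.empty(n)
    for f in range(n):
        chrom = chromosome_mask(chrom_stack[f])
        rim, cyto = _frame_regions(donor_stack[f], chrom, seg.rim_width)
        rim_masks.append(rim)
        cyto_masks.append(cyto)
        fg = ndi.binary_dilation(
            donor_stack[f] > threshold_otsu(donor_stack[f]),
            iterations=seg.background_margin,
        )
        bg = ~fg
        bg_d = float(np.median(donor_stack[f][bg])) if bg.any() else 0.0
        bg_masks.append(bg_d)
        loc[f] = localization_signal(donor_stack[f], rim, cyto, bg_d)

    bg_d = float(np.median(bg_masks))
    # acceptor background from the same off-cell region of the last frame
    fg = ndi.binary_dilation(
        donor_stack[-1] > threshold_otsu(donor_stack[-1]),
        iterations=seg.background_margin,
    )
    bg_a = float(np.median(acceptor_stack[-1][~fg])) if (~fg).any() else 0.0

    probe = probe_timecourse(
        donor_stack, acceptor_stack, rim_masks, cyto_masks, onset_frame, (bg_d, bg_a)
    )
    area, area_flags = chromosome_area_timecourse(chrom_stack, onset_frame)
    qc.extend(area_flags)

    post = times >= 0
    half_loc = extract_half_time(loc[post], times[post], "rise-to-max")
    half_probe = extract_half_time(probe[post], times[post], "fall-to-min")

    return TimelapseTrace(
        times=times,
        localization=loc,
        probe=probe,
        area=area,
        anaphase_onset_frame=int(onset_frame),
        half_max_localization=half_loc,
        half_min_probe=half_probe,
        qc_flags=qc,
    )
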