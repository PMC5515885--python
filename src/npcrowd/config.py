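"""Validated configuration models and named presets.

All generator and analysis parameters live in pydantic models so every
run can serialize its full configuration for provenance.  Named presets
(``peripheral``, ``central_cavity``, ``scaffold``,
``digitonin_immunostain``, ``early_assembler``, ``early_assembler_decay``,
``pom121_like``, ``late_assembler``) resolve to fully populated configs
from the packaged ``presets.yaml``.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .spectra import DEFAULT_QUENCH_FLOOR, DEFAULT_QUENCH_SLOPE

__all__ = [
    "QuenchModelParams",
    "CellPhantomConfig",
    "TimelapsePhantomConfig",
    "SegmentationParams",
    "PipelineConfig",
    "available_presets",
    "load_preset",
]


class QuenchModelParams(BaseModel):
    """Parameters of the linear-with-floor acceptor quench model."""

    slope: float = Field(default=DEFAULT_QUENCH_SLOPE, ge=0.0)
    floor: float = Field(default=DEFAULT_QUENCH_FLOOR, gt=0.0, le=1.0)


class CellPhantomConfig(BaseModel):
    """Geometry, optics and noise of a synthetic interphase cell image.

    One cell per frame: a disk-shaped cell containing a circular nucleus
    whose boundary carries a bright rim band of nuclear-pore-embedded
    probe.  Crowder concentrations are in mg/mL; probe densities in
    relative expression units; intensities in detector counts.
    """

    image_size: tuple[int, int] = (256, 256)
    cell_radius: float = Field(default=110.0, gt=0)
    nucleus_radius_range: tuple[float, float] = (34.0, 44.0)
    rim_width: float = Field(default=3.0, ge=1.0)
    center_jitter: float = Field(default=6.0, ge=0.0)

    concentration_cyto: float = Field(default=100.0, ge=0)
    concentration_rim: float = Field(default=200.0, ge=0)
    concentration_nucleus: float = Field(default=100.0, ge=0)

    probe_density_cyto: float = Field(default=1.0, ge=0)
    probe_density_rim: float = Field(default=3.0, ge=0)
    probe_density_nucleus: float = Field(default=1.0, ge=0)

    psf_sigma: float = Field(default=1.5, ge=0)
    background: float = Field(default=100.0, ge=0)
    photon_scale: float = Field(default=500.0, gt=0)
    baseline_ad: float = Field(default=1.2, gt=0)
    quench: QuenchModelParams = QuenchModelParams()
    noise: Literal["poisson", "none"] = "poisson"
    seed: int = 0
    preset: str = ""

    @model_validator(mode="after")
    def _check_geometry(self) -> "CellPhantomConfig":
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ValueError("nucleus_radius_range must satisfy 0 < lo <= hi")
        if hi + self.rim_width >= self.cell_radius:
            raise ValueError("nucleus (plus rim) must fit inside the cell")
        half_frame = min(self.image_size) / 2
        if self.cell_radius + self.center_jitter >= half_frame:
            raise ValueError("cell must fit inside the frame")
        return self


class TimelapsePhantomConfig(BaseModel):
    """A mitotic anaphase-to-G1 time-lapse phantom.

    Two elliptical chromosome masses overlap before ``anaphase_onset_frame``
    and separate afterwards at ``separation_velocity``.  Probe density on
    the chromosome-surface rim follows first-order assembly kinetics

        L(t) = plateau_density * (1 - exp(-k (t - t0)))   for t >= t0

    (t in minutes after anaphase onset), optionally multiplied by
    ``exp(-telophase_decay_rate * (t - telophase_time))`` after telophase
    for early-assembling classes.  The rim crowder concentration ramps
    from ``c_start`` to ``c_plateau`` proportionally to the running
    maximum of L(t)/plateau_density, so crowding follows assembly but
    does not reverse when early subunits dissociate.
    """

    image_size: tuple[int, int] = (256, 256)
    frame_interval: float = Field(default=2.0, gt=0)  # min
    duration: float = Field(default=30.0, gt=0)  # min after onset
    anaphase_onset_frame: int = Field(default=3, ge=0)
    separation_velocity: float = Field(default=5.0, gt=0)  # px/frame
    chromosome_semiaxes: tuple[float, float] = (16.0, 12.0)
    area_growth: float = Field(default=1.0, ge=1.0)  # final/initial mask area

    t0: float = Field(default=1.0, ge=0)  # min after anaphase onset
    k: float = Field(default=math.log(2) / 3.0, gt=0)  # 1/min
    plateau_density: float = Field(default=2.0, gt=0)
    telophase_decay_rate: Optional[float] = Field(default=None, gt=0)
    telophase_time: float = Field(default=10.0, ge=0)  # min after onset

    c_start: float = Field(default=100.0, ge=0)
    c_plateau: float = Field(default=180.0, ge=0)
    concentration_cyto: float = Field(default=100.0, ge=0)

    cell_radius: float = Field(default=118.0, gt=0)
    rim_width: float = Field(default=3.0, ge=1.0)
    probe_density_cyto: float = Field(default=1.0, ge=0)
    probe_density_chromosome: float = Field(default=0.3, ge=0)
    chromosome_marker_density: float = Field(default=3.0, gt=0)

    psf_sigma: float = Field(default=1.5, ge=0)
    background: float = Field(default=100.0, ge=0)
    photon_scale: float = Field(default=500.0, gt=0)
    baseline_ad: float = Field(default=1.2, gt=0)
    quench: QuenchModelParams = QuenchModelParams()
    noise: Literal["poisson", "none"] = "poisson"
    seed: int = 0
    preset: str = ""

    @property
    def n_frames(self) -> int:
        return self.anaphase_onset_frame + int(round(self.duration / self.frame_interval)) + 1

    @property
    def half_max_time(self) -> float:
        """Analytic half-maximum time of L(t): t0 + ln(2)/k, minutes."""
        return self.t0 + math.log(2) / self.k


class SegmentationParams(BaseModel):
    """Parameters of nuclear-envelope rim segmentation."""

    rim_width: float = Field(default=3.0, ge=1.0)
    threshold_method: Literal["otsu"] = "otsu"
    min_region_px: int = Field(default=50, ge=1)
    min_cell_px: int = Field(default=500, ge=1)
    background_margin: int = Field(default=5, ge=0)
    circularity_for_radial_fit: float = Field(default=0.85, ge=0, le=1.0)


class PipelineConfig(BaseModel):
    """Top-level analysis configuration serialized with every output."""

    segmentation: SegmentationParams = SegmentationParams()
    quench: QuenchModelParams = QuenchModelParams()
    donor_band: tuple[float, float] = (460.0, 500.0)
    acceptor_band: tuple[float, float] = (520.0, 570.0)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    min_separation_px: float = Field(default=10.0, gt=0)
    onset_persistence: int = Field(default=2, ge=1)
    seed: int = 0


def _presets_dict() -> dict:
    text = resources.files("npcrowd").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def available_presets() -> dict[str, str]:
    """Map preset name -> kind ('interphase', 'immunostain', 'timelapse')."""
    raw = _presets_dict()
    return {name: entry["kind"] for name, entry in raw.items()}


def load_preset(name: str, **overrides):
    """Resolve a named preset to a fully validated config.

    Returns a :class:`CellPhantomConfig` for interphase/immunostain
    presets or a :class:`TimelapsePhantomConfig` for time-lapse presets.
    Keyword overrides replace preset fields (e.g. ``seed=7``,
    ``noise="none"``).  Immunostain presets carry their retention
    fraction in the ``retention`` key of the returned tuple's second
    element.
    """
    raw = _presets_dict()
    if name not in raw:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(raw)}"
        )
    entry = dict(raw[name])
    kind = entry.pop("kind")
    params = dict(entry.pop("params", {}))
    params.update(overrides)
    params.setdefault("preset", name)
    if kind == "timelapse":
        return TimelapsePhantomConfig(**params)
    if kind == "immunostain":
        retention = params.pop("retention", 0.70)
        return CellPhantomConfig(**params), float(retention)
    return CellPhantomConfig(**params)
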