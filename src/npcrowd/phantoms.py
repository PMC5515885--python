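"""Synthetic spectra, interphase cells, and mitotic time-lapse phantoms.

Every generated dataset comes with a :class:`PhantomManifest` carrying
exact ground-truth masks, concentration maps, kinetic parameters and the
analytically expected readouts, so the analysis modules can be tested as
parameter-recovery experiments.

Image formation model (per pixel x, per channel, in detector counts)::

    donor(x)    = background + photon_scale * rho(x)
    acceptor(x) = background + photon_scale * rho(x) * baseline_ad * f(C(x))

where ``rho`` is the probe density field blurred by a Gaussian PSF,
``C`` the (unblurred) crowder concentration map, and ``f`` the
linear-with-floor quench factor from :mod:`npcrowd.spectra`.  Quenching
is a pixelwise property of local concentration and is applied after the
PSF: the blur mixes probe molecules, not the crowding they report.
Optional noise is independent per-channel Poisson on the expected
counts.  Identical seed + config give bit-identical output.

The crowder concentration field defaults to the cytoplasmic value
everywhere (with nucleus/rim overrides) rather than zero outside the
cell: concentration only matters where probe density is nonzero, and
this convention keeps the cell edge free of partial-volume ratio
artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .config import CellPhantomConfig, TimelapsePhantomConfig
from .regions import (
    LABEL_BACKGROUND,
    LABEL_CYTOPLASM,
    LABEL_NUCLEUS,
    LABEL_RIM,
    boundary_band,
    disk_band,
)
from .spectra import EmissionSpectrum, ad_ratio, quench_factor

__all__ = [
    "PROBE_GIMRET",
    "PROBE_CONTROL",
    "PhantomManifest",
    "make_spectrum",
    "make_interphase_image",
    "make_immunostain_pair",
    "make_timelapse",
    "localization_kinetics",
]

PROBE_GIMRET = "GimRET"
PROBE_CONTROL = "CFP-wtYFP"

_GRID = np.arange(450.0, 601.0, 1.0)
#: Spectral crossover (nm): donor emission is truncated above, acceptor
#: below.  An idealization (like a perfect dichroic split) that makes the
#: band integrals isolate each fluorophore exactly, so the quench factor
#: propagates to the A/D ratio without cross-bleed terms.
_CROSSOVER_NM = 515.0


def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def _component_shapes(baseline_ad: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit donor and acceptor emission components on the default grid.

    Donor: CFP-like double hump (475/501 nm); acceptor: YFP-like single
    peak (527 nm).  The acceptor amplitude is set so the unquenched A/D
    ratio equals ``baseline_ad`` exactly.
    """
    wl = _GRID
    donor = (_gauss(wl, 475.0, 15.0) + 0.6 * _gauss(wl, 501.0, 15.0)) * (
        wl < _CROSSOVER_NM
    )
    acceptor_unit = _gauss(wl, 527.0, 12.0) * (wl >= _CROSSOVER_NM)
    donor_band = donor[(wl >= 460) & (wl <= 500)].sum()
    acceptor_band = acceptor_unit[(wl >= 520) & (wl <= 570)].sum()
    acceptor = acceptor_unit * (baseline_ad * donor_band / acceptor_band)
    return donor, acceptor


def make_spectrum(
    probe: str,
    c: float,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    baseline_ad: float = 1.2,
    slope: float = 1.0 / 500.0,
    floor: float = 0.2,
    amplitude: float = 1000.0,
) -> EmissionSpectrum:
    """Synthetic emission spectrum of a crowding probe at concentration ``c``.

    For the crowding-sensitive probe (``"GimRET"``) the acceptor
    component is scaled by the quench factor f(c); for the
    crowding-insensitive control pair (``"CFP-wtYFP"``) it is left
    unchanged.  The donor component never depends on ``c``.  Optional
    additive Gaussian noise (sd in the same arbitrary units as the
    intensities) is clipped at zero to preserve non-negativity.
    """
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if probe == PROBE_GIMRET:
        q = quench_factor(c, slope=slope, floor=floor)
    elif probe == PROBE_CONTROL:
        q = 1.0
    else:
        raise ValueError(
            f"unknown probe {probe!r}; expected {PROBE_GIMRET!r} or {PROBE_CONTROL!r}"
        )
    donor, acceptor = _component_shapes(baseline_ad)
    intensities = amplitude * (donor + q * acceptor)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = np.clip(
            intensities + rng.normal(0.0, noise_sd, intensities.shape), 0.0, None
        )
    return EmissionSpectrum(
        _GRID.copy(),
        intensities,
        excitation_nm=433.0,
        label=f"{probe} at {c:g} mg/mL",
    )


@dataclass
class PhantomManifest:
    """Ground truth emitted with every synthetic dataset."""

    kind: str  # 'interphase' | 'immunostain' | 'timelapse'
    preset: str
    seed: int
    config: dict
    # interphase / immunostain
    labels: Optional[np.ndarray] = None
    concentration_map: Optional[np.ndarray] = None
    expected_relative_probe: Optional[float] = None
    expected_rim_ad: Optional[float] = None
    expected_cyto_ad: Optional[float] = None
    retention: Optional[float] = None
    nucleus_center: Optional[tuple[float, float]] = None
    nucleus_radius: Optional[float] = None
    # timelapse
    chromosome_masks: Optional[np.ndarray] = None  # (T, H, W) bool
    rim_masks: Optional[np.ndarray] = None  # (T, H, W) bool
    times_min: Optional[np.ndarray] = None
    localization_truth: Optional[np.ndarray] = None
    rim_concentration: Optional[np.ndarray] = None
    chromosome_area_px: Optional[np.ndarray] = None
    anaphase_onset_frame: Optional[int] = None
    half_max_time: Optional[float] = None
    half_time_recoverable: Optional[bool] = None
    expected_plateau_probe_drop: Optional[float] = None
    notes: list[str] = field(default_factory=list)

    def summary_dict(self) -> dict:
        """JSON-serializable summary (arrays reduced to shapes/values)."""
        out = {
            "kind": self.kind,
            "preset": self.preset,
            "seed": self.seed,
            "config": self.config,
            "notes": self.notes,
        }
        for key in (
            "expected_relative_probe",
            "expected_rim_ad",
            "expected_cyto_ad",
            "retention",
            "nucleus_radius",
            "anaphase_onset_frame",
            "half_max_time",
            "half_time_recoverable",
            "expected_plateau_probe_drop",
        ):
            val = getattr(self, key)
            if val is not None:
                out[key] = val
        if self.times_min is not None:
            out["times_min"] = list(map(float, self.times_min))
            out["localization_truth"] = list(map(float, self.localization_truth))
            out["rim_concentration"] = list(map(float, self.rim_concentration))
        return out


def _interphase_geometry(config: CellPhantomConfig, rng: np.random.Generator):
    h, w = config.image_size
    cy = h / 2.0 + rng.uniform(-config.center_jitter, config.center_jitter)
    cx = w / 2.0 + rng.uniform(-config.center_jitter, config.center_jitter)
    r_lo, r_hi = config.nucleus_radius_range
    radius = rng.uniform(r_lo, r_hi)
    max_off = max(
        config.cell_radius - radius - config.rim_width - 4.0, 0.0
    )
    off = rng.uniform(-min(max_off, 10.0), min(max_off, 10.0), size=2)
    ncy, ncx = cy + off[0], cx + off[1]

    rr, cc = np.mgrid[0:h, 0:w]
    cell = np.hypot(rr - cy, cc - cx) <= config.cell_radius
    d_nuc = np.hypot(rr - ncy, cc - ncx)
    rim = np.abs(d_nuc - radius) <= config.rim_width / 2.0
    nucleus = d_nuc < radius - config.rim_width / 2.0
    labels = np.full((h, w), LABEL_BACKGROUND, dtype=np.uint8)
    labels[cell] = LABEL_CYTOPLASM
    labels[nucleus] = LABEL_NUCLEUS
    labels[rim] = LABEL_RIM
    return labels, (ncy, ncx), radius


def _render_two_channel(
    density: np.ndarray,
    conc: np.ndarray,
    config,
    rng: Optional[np.random.Generator],
):
    """Apply PSF, quench, background and optional Poisson noise."""
    rho = ndi.gaussian_filter(density, config.psf_sigma) if config.psf_sigma > 0 else density
    q = quench_factor(conc, slope=config.quench.slope, floor=config.quench.floor)
    donor = config.background + config.photon_scale * rho
    acceptor = config.background + config.photon_scale * rho * config.baseline_ad * q
    if config.noise == "poisson":
        assert rng is not None
        donor = rng.poisson(donor).astype(float)
        acceptor = rng.poisson(acceptor).astype(float)
    return donor, acceptor


def make_interphase_image(
    config: CellPhantomConfig,
) -> tuple[np.ndarray, np.ndarray, PhantomManifest]:
    """Render a two-channel (donor, acceptor) interphase cell image.

    The manifest carries the exact label image, the concentration map,
    and the expected relative probe signal f(C_rim)/f(C_cyto), which the
    analysis pipeline should recover up to noise and segmentation error.
    """
    rng = np.random.default_rng(config.seed)
    labels, ncenter, nradius = _interphase_geometry(config, rng)

    density = np.zeros(config.image_size, dtype=float)
    density[labels == LABEL_CYTOPLASM] = config.probe_density_cyto
    density[labels == LABEL_NUCLEUS] = config.probe_density_nucleus
    density[labels == LABEL_RIM] = config.probe_density_rim

    conc = np.full(config.image_size, config.concentration_cyto, dtype=float)
    conc[labels == LABEL_NUCLEUS] = config.concentration_nucleus
    conc[labels == LABEL_RIM] = config.concentration_rim

    donor, acceptor = _render_two_channel(density, conc, config, rng)

    q_rim = quench_factor(
        config.concentration_rim, config.quench.slope, config.quench.floor
    )
    q_cyto = quench_factor(
        config.concentration_cyto, config.quench.slope, config.quench.floor
    )
    manifest = PhantomManifest(
        kind="interphase",
        preset=config.preset,
        seed=config.seed,
        config=config.model_dump(),
        labels=labels,
        concentration_map=conc,
        expected_relative_probe=q_rim / q_cyto,
        expected_rim_ad=config.baseline_ad * q_rim,
        expected_cyto_ad=config.baseline_ad * q_cyto,
        nucleus_center=ncenter,
        nucleus_radius=nradius,
    )
    return donor, acceptor, manifest


def make_immunostain_pair(
    retention: float,
    config: CellPhantomConfig,
) -> tuple[np.ndarray, np.ndarray, PhantomManifest]:
    """Render an intact/treated single-channel immunostain image pair.

    Emulates a detergent-extraction control: the treated image shares
    the intact image's geometry exactly, with rim stain density scaled
    by ``retention`` (0.70 models a 30% removal of a transport receptor
    from the nuclear envelope).
    """
    if not (0.0 <= retention <= 1.0):
        raise ValueError("retention must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    labels, ncenter, nradius = _interphase_geometry(config, rng)

    def render(rim_density: float, noise_rng):
        density = np.zeros(config.image_size, dtype=float)
        density[labels == LABEL_CYTOPLASM] = config.probe_density_cyto
        density[labels == LABEL_NUCLEUS] = config.probe_density_nucleus
        density[labels == LABEL_RIM] = rim_density
        rho = (
            ndi.gaussian_filter(density, config.psf_sigma)
            if config.psf_sigma > 0
            else density
        )
        img = config.background + config.photon_scale * rho
        if config.noise == "poisson":
            img = noise_rng.poisson(img).astype(float)
        return img

    intact = render(config.probe_density_rim, rng)
    treated = render(retention * config.probe_density_rim, rng)
    manifest = PhantomManifest(
        kind="immunostain",
        preset=config.preset,
        seed=config.seed,
        config=config.model_dump(),
        labels=labels,
        retention=retention,
        nucleus_center=ncenter,
        nucleus_radius=nradius,
    )
    return intact, treated, manifest


def localization_kinetics(
    t: np.ndarray, config: TimelapsePhantomConfig
) -> np.ndarray:
    """Rim probe density L(t) for times t (min after anaphase onset).

    First-order assembly ``plateau * (1 - exp(-k (t - t0)))`` for
    t >= t0, zero before, optionally multiplied by an exponential decay
    after telophase (early-assembling classes).
    """
    t = np.asarray(t, dtype=float)
    rise = np.where(
        t >= config.t0,
        config.plateau_density * (1.0 - np.exp(-config.k * (t - config.t0))),
        0.0,
    )
    if config.telophase_decay_rate is not None:
        decay = np.where(
            t > config.telophase_time,
            np.exp(-config.telophase_decay_rate * (t - config.telophase_time)),
            1.0,
        )
        rise = rise * decay
    return rise


def _chromosome_masks(config: TimelapsePhantomConfig):
    """Per-frame chromosome masks: two ellipses, merged before onset.

    Center-to-center separation jumps from overlap (2a - 8 px) to a
    2-px gap at the onset frame and then grows by ``separation_velocity``
    per frame, so the thresholded mask first splits exactly at
    ``anaphase_onset_frame``.  ``area_growth`` scales both semi-axes by
    sqrt(g(t)) with g ramping linearly to its final value, emulating
    chromatin decondensation.
    """
    h, w = config.image_size
    a0, b0 = config.chromosome_semiaxes
    cy, cx = h / 2.0, w / 2.0
    rr, cc = np.mgrid[0:h, 0:w]
    n = config.n_frames
    onset = config.anaphase_onset_frame
    masks = np.zeros((n, h, w), dtype=bool)
    for f in range(n):
        if f >= onset and n - 1 > onset:
            g = 1.0 + (config.area_growth - 1.0) * (f - onset) / (n - 1 - onset)
        else:
            g = 1.0
        a, b = a0 * math.sqrt(g), b0 * math.sqrt(g)
        if f < onset:
            sep = 2 * a - 8.0
        else:
            sep = 2 * a + 2.0 + config.separation_velocity * (f - onset)
        for sgn in (-1.0, 1.0):
            ex = cx + sgn * sep / 2.0
            masks[f] |= ((rr - cy) / b) ** 2 + ((cc - ex) / a) ** 2 <= 1.0
    return masks


def make_timelapse(
    config: TimelapsePhantomConfig,
) -> tuple[np.ndarray, PhantomManifest]:
    """Render a 3-channel (donor, acceptor, chromosome marker) stack.

    Returns ``(stack, manifest)`` with stack shape (T, 3, H, W).  The
    chromosome-surface rim accumulates probe density following
    :func:`localization_kinetics`; the rim crowder concentration ramps
    from ``c_start`` to ``c_plateau`` with the *running maximum* of
    L(t)/plateau, so crowding tracks assembly but persists through the
    post-telophase dissociation of early subunits.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size
    n = config.n_frames
    onset = config.anaphase_onset_frame
    times = (np.arange(n) - onset) * config.frame_interval

    chrom_masks = _chromosome_masks(config)
    rim_masks = np.zeros_like(chrom_masks)
    loc = localization_kinetics(times, config)
    frac = np.maximum.accumulate(loc) / config.plateau_density
    c_rim = config.c_start + (config.c_plateau - config.c_start) * frac

    rr, cc = np.mgrid[0:h, 0:w]
    cell = np.hypot(rr - h / 2.0, cc - w / 2.0) <= config.cell_radius

    stack = np.zeros((n, 3, h, w), dtype=float)
    areas = chrom_masks.reshape(n, -1).sum(axis=1).astype(float)
    for f in range(n):
        chrom = chrom_masks[f]
        rim = boundary_band(chrom, config.rim_width)
        rim_masks[f] = rim

        density = np.where(cell, config.probe_density_cyto, 0.0)
        density[chrom] = config.probe_density_chromosome
        density[rim] = config.probe_density_cyto + loc[f]
        conc = np.full((h, w), config.concentration_cyto, dtype=float)
        conc[rim] = c_rim[f]
        donor, acceptor = _render_two_channel(density, conc, config, rng)

        marker_density = np.where(chrom, config.chromosome_marker_density, 0.0)
        marker_rho = (
            ndi.gaussian_filter(marker_density, config.psf_sigma)
            if config.psf_sigma > 0
            else marker_density
        )
        marker = config.background + config.photon_scale * marker_rho
        if config.noise == "poisson":
            marker = rng.poisson(marker).astype(float)
        stack[f, 0], stack[f, 1], stack[f, 2] = donor, acceptor, marker

    q = lambda c: quench_factor(c, config.quench.slope, config.quench.floor)
    expected_drop = 1.0 - q(config.c_plateau) / q(config.concentration_cyto)
    half_time = config.half_max_time
    recoverable = half_time <= config.duration
    notes = []
    if not recoverable:
        notes.append(
            f"analytic half-max time {half_time:.2f} min exceeds duration "
            f"{config.duration:g} min; unrecoverable from this stack"
        )
    manifest = PhantomManifest(
        kind="timelapse",
        preset=config.preset,
        seed=config.seed,
        config=config.model_dump(),
        chromosome_masks=chrom_masks,
        rim_masks=rim_masks,
        times_min=times,
        localization_truth=loc,
        rim_concentration=c_rim,
        chromosome_area_px=areas,
        anaphase_onset_frame=onset,
        half_max_time=half_time,
        half_time_recoverable=recoverable,
        expected_plateau_probe_drop=expected_drop,
        notes=notes,
    )
    return stack, manifest
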