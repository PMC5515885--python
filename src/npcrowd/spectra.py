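"""Emission spectra, band-integrated A/D ratios, and crowding calibration.

The crowding probe is a FRET pair of CFP (donor) and a glycine-inserted
YFP (acceptor, "YFP1G") whose acceptor fluorescence is quenched by
macromolecular crowding while the donor is insensitive.  The probe
readout is the acceptor/donor (A/D) ratio: the sum of fluorescence
intensities over the acceptor band (520-570 nm) divided by the sum over
the donor band (460-500 nm), both bands inclusive on the sample grid.
A lower A/D ratio means higher crowding.

Band statistics are plain grid-point sums rather than trapezoid
integrals; the contract is the *ratio*, which is invariant to the
(uniform) grid step and to any positive rescaling of the intensities.

The concentration dependence of the acceptor quench is modelled as
linear with a floor::

    f(C) = max(1 - slope * C, floor),      f(0) = 1

with default ``slope = 1/500`` per mg/mL and ``floor = 0.2``, giving a
usable dynamic range beyond 200 mg/mL.  The measured ratio at crowder
concentration C is then ``ratio_at_zero * f(C)``, where ``ratio_at_zero``
is instrument-dependent and always fitted, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DONOR_BAND",
    "ACCEPTOR_BAND",
    "DEFAULT_QUENCH_SLOPE",
    "DEFAULT_QUENCH_FLOOR",
    "BandRangeError",
    "UndefinedRatioError",
    "SaturationError",
    "EmissionSpectrum",
    "BandDefinition",
    "CalibrationCurve",
    "integrate_band",
    "ad_ratio",
    "quench_factor",
    "fit_calibration",
    "invert_calibration",
]

#: Donor (CFP) emission band, nm, endpoints inclusive.
DONOR_BAND: tuple[float, float] = (460.0, 500.0)
#: Acceptor (YFP1G) emission band, nm, endpoints inclusive.
ACCEPTOR_BAND: tuple[float, float] = (520.0, 570.0)

#: Default acceptor quench slope, per (mg/mL).
DEFAULT_QUENCH_SLOPE: float = 1.0 / 500.0
#: Default minimum quench factor (saturation floor).
DEFAULT_QUENCH_FLOOR: float = 0.2


class BandRangeError(ValueError):
    """Requested wavelength band contains no grid point of the spectrum."""


class UndefinedRatioError(ValueError):
    """Donor band integral is zero or below epsilon; A/D ratio undefined."""


class SaturationError(ValueError):
    """Ratio lies outside the invertible range of a calibration curve.

    Attributes
    ----------
    boundary_concentration : float
        The concentration at the nearest boundary of the invertible
        range (0 for ratios above ``ratio_at_zero``, the floor-onset
        concentration for ratios at or below the floor).
    """

    def __init__(self, message: str, boundary_concentration: float):
        super().__init__(message)
        self.boundary_concentration = float(boundary_concentration)


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum on a uniform wavelength grid.

    Parameters
    ----------
    wavelengths : array-like
        Strictly increasing, uniformly spaced wavelengths in nm
        (conventionally a 1-nm grid over 450-600 nm).
    intensities : array-like
        Non-negative fluorescence intensities, arbitrary units, one per
        wavelength.
    excitation_nm : float
        Excitation wavelength (433 nm for the CFP/YFP1G pair).
    label : str
        Free-text description (probe, crowder, concentration).
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    excitation_nm: float = 433.0
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1:
            raise ValueError("wavelengths and intensities must be 1-D")
        if wl.size != it.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths, {it.size} intensities"
            )
        if wl.size < 2:
            raise ValueError("spectrum needs at least two grid points")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > 1e-9 * max(abs(step), 1.0)):
            raise ValueError("wavelength grid must be uniform")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    @property
    def grid_step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    def scaled(self, factor: float) -> "EmissionSpectrum":
        """Return a copy with intensities multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return EmissionSpectrum(
            self.wavelengths,
            self.intensities * factor,
            excitation_nm=self.excitation_nm,
            label=self.label,
        )


@dataclass(frozen=True)
class BandDefinition:
    """Donor and acceptor integration bands (nm, endpoints inclusive)."""

    donor_lo: float = DONOR_BAND[0]
    donor_hi: float = DONOR_BAND[1]
    acceptor_lo: float = ACCEPTOR_BAND[0]
    acceptor_hi: float = ACCEPTOR_BAND[1]

    def __post_init__(self) -> None:
        if not (self.donor_lo < self.donor_hi):
            raise ValueError("donor band requires lo < hi")
        if not (self.acceptor_lo < self.acceptor_hi):
            raise ValueError("acceptor band requires lo < hi")
        overlap = max(self.donor_lo, self.acceptor_lo) <= min(
            self.donor_hi, self.acceptor_hi
        )
        if overlap:
            raise ValueError("donor and acceptor bands must not overlap")


def integrate_band(spectrum: EmissionSpectrum, lo: float, hi: float) -> float:
    """Sum intensities at grid points with ``lo <= wavelength <= hi``.

    Both endpoints are inclusive.  Raises :class:`BandRangeError` if the
    band contains no grid point (never silently returns 0 in that case).
    """
    if lo > hi:
        raise ValueError(f"band lo ({lo}) must not exceed hi ({hi})")
    sel = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not np.any(sel):
        raise BandRangeError(
            f"band [{lo}, {hi}] nm contains no grid point of the spectrum "
            f"({spectrum.wavelengths[0]}-{spectrum.wavelengths[-1]} nm)"
        )
    return float(spectrum.intensities[sel].sum())


def ad_ratio(
    spectrum: EmissionSpectrum,
    bands: BandDefinition | None = None,
    donor_epsilon: float = 1e-12,
) -> float:
    """Acceptor/donor ratio: acceptor band sum over donor band sum.

    Scale-invariant: multiplying all intensities by k > 0 leaves the
    ratio unchanged.  Raises :class:`UndefinedRatioError` when the donor
    band integral is at or below ``donor_epsilon``.
    """
    if bands is None:
        bands = BandDefinition()
    donor = integrate_band(spectrum, bands.donor_lo, bands.donor_hi)
    acceptor = integrate_band(spectrum, bands.acceptor_lo, bands.acceptor_hi)
    if donor <= donor_epsilon:
        raise UndefinedRatioError(
            f"donor band integral {donor} <= epsilon {donor_epsilon}"
        )
    return acceptor / donor


def quench_factor(
    c,
    slope: float = DEFAULT_QUENCH_SLOPE,
    floor: float = DEFAULT_QUENCH_FLOOR,
):
    """Acceptor quench factor f(C) = max(1 - slope*C, floor), in (0, 1].

    ``c`` may be a scalar (mg/mL) or an array; the return type matches.
    Raises on negative concentrations.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    if not (0 < floor <= 1):
        raise ValueError("floor must lie in (0, 1]")
    if slope < 0:
        raise ValueError("slope must be non-negative")
    f = np.maximum(1.0 - slope * c_arr, floor)
    if np.isscalar(c) or c_arr.ndim == 0:
        return float(f)
    return f


@dataclass
class CalibrationCurve:
    """Fitted monotone map between crowder concentration and A/D ratio.

    Model: ``ratio(C) = ratio_at_zero * max(1 - slope*C, floor)``.
    """

    slope: float
    floor: float
    ratio_at_zero: float
    fitted_on: list[tuple[float, float]] = field(default_factory=list)
    residual_rms: float = 0.0
    monotone_warning: bool = False
    model: str = "linear-with-floor"

    def __post_init__(self) -> None:
        if self.ratio_at_zero <= 0:
            raise ValueError("ratio_at_zero must be positive")
        if not (0 < self.floor <= 1):
            raise ValueError("floor must lie in (0, 1]")
        if self.slope < 0:
            raise ValueError(
                "slope must be non-negative (monotone non-increasing ratio)"
            )

    @property
    def floor_onset(self) -> float:
        """Concentration at which the linear segment reaches the floor."""
        if self.slope == 0:
            return np.inf
        return (1.0 - self.floor) / self.slope

    def predict(self, c) -> float:
        """Predicted A/D ratio at concentration ``c`` (mg/mL)."""
        return self.ratio_at_zero * quench_factor(c, self.slope, self.floor)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "slope_per_mg_per_ml": self.slope,
            "floor": self.floor,
            "ratio_at_zero": self.ratio_at_zero,
            "residual_rms": self.residual_rms,
            "monotone_warning": self.monotone_warning,
            "fitted_on": [[c, r] for c, r in self.fitted_on],
        }


def fit_calibration(
    pairs: Sequence[tuple[float, float]],
    floor: float = DEFAULT_QUENCH_FLOOR,
    residual_warn_fraction: float = 0.05,
) -> CalibrationCurve:
    """Least-squares fit of ``A/D(C) = ratio_at_zero * max(1 - slope*C, floor)``.

    Parameters
    ----------
    pairs
        (concentration mg/mL, measured A/D) tuples; at least three
        distinct concentrations are required.
    floor
        Saturation floor, held fixed (it is unidentifiable from data
        confined to the linear segment).
    residual_warn_fraction
        The ``monotone_warning`` flag is set when the fit residual RMS
        exceeds this fraction of the fitted ``ratio_at_zero``, or when
        the unconstrained slope comes out negative (ratio increasing
        with concentration).  A warning, never a hard error.
    """
    pairs = [(float(c), float(r)) for c, r in pairs]
    if any(c < 0 for c, _ in pairs):
        raise ValueError("concentrations must be non-negative")
    concs = np.array([c for c, _ in pairs])
    ratios = np.array([r for _, r in pairs])
    if np.unique(concs).size < 3:
        raise ValueError("need at least 3 distinct concentrations to fit")

    r0_guess = float(ratios[np.argmin(concs)])
    if r0_guess <= 0:
        r0_guess = max(float(np.max(ratios)), 1e-6)

    def resid(params, clip_slope: bool):
        r0, slope = params
        s = max(slope, 0.0) if clip_slope else slope
        return r0 * np.maximum(1.0 - s * concs, floor) - ratios

    # Unconstrained slope first: a negative optimum signals data whose
    # ratio *increases* with concentration.
    free = least_squares(resid, x0=[r0_guess, 1e-3], args=(False,))
    monotone_warning = free.x[1] < 0
    if monotone_warning:
        bounded = least_squares(
            resid,
            x0=[r0_guess, 0.0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            args=(False,),
        )
        r0, slope = bounded.x
        res = bounded.fun
    else:
        r0, slope = free.x
        res = free.fun

    residual_rms = float(np.sqrt(np.mean(res**2)))
    if residual_rms > residual_warn_fraction * r0:
        monotone_warning = True
    return CalibrationCurve(
        slope=float(max(slope, 0.0)),
        floor=floor,
        ratio_at_zero=float(r0),
        fitted_on=pairs,
        residual_rms=residual_rms,
        monotone_warning=bool(monotone_warning),
    )


def invert_calibration(ratio: float, curve: CalibrationCurve) -> float:
    """Unique concentration whose predicted A/D equals ``ratio``.

    Valid only on the linear segment, i.e. for ratios in
    ``(ratio_at_zero * floor, ratio_at_zero]``.  Outside that range a
    :class:`SaturationError` is raised carrying the boundary
    concentration (0 above, the floor-onset concentration below).
    """
    r0 = curve.ratio_at_zero
    if ratio > r0:
        raise SaturationError(
            f"ratio {ratio} exceeds ratio_at_zero {r0}; concentration "
            "saturates at 0",
            boundary_concentration=0.0,
        )
    if ratio <= r0 * curve.floor:
        raise SaturationError(
            f"ratio {ratio} at or below the floor segment "
            f"({r0 * curve.floor}); concentration saturates at the "
            f"floor onset {curve.floor_onset} mg/mL",
            boundary_concentration=curve.floor_onset,
        )
    if curve.slope == 0:
        raise SaturationError(
            "curve has zero slope; inverse undefined", boundary_concentration=0.0
        )
    return (1.0 - ratio / r0) / curve.slope
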