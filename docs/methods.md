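# Methods

## Sensor model

The crowding sensor pairs a CFP donor with a glycine-inserted YFP
acceptor whose brightness falls as macromolecular crowding rises; the
donor is insensitive. The readout is the acceptor/donor (A/D) ratio of
band-integrated emission: acceptor 520–570 nm over donor 460–500 nm,
both bands inclusive on the wavelength grid, under 433-nm excitation.
Band statistics are plain grid-point sums, not trapezoid integrals —
the quantity of record is the *ratio*, which is invariant to the grid
step (a uniform grid is enforced) and to any positive rescaling of the
intensities. No spectral unmixing or bleed-through correction is
applied; the ratio is raw band counts.

Concentration dependence is a linear quench with a floor:

    f(C) = max(1 - slope * C, floor),  slope = 1/500 per mg/mL, floor = 0.2
    A/D(C) = ratio_at_zero * f(C)

The linear-with-floor form is the simplest monotone model with a
saturation plateau and a usable dynamic range beyond 200 mg/mL.
`ratio_at_zero` is instrument-dependent and always fitted, never
assumed to be 1. Calibration fits hold the floor fixed (it is
unidentifiable from data confined to the linear segment) and solve for
`ratio_at_zero` and the slope by least squares; data whose ratio
increases with concentration, or whose residual RMS exceeds 5% of
`ratio_at_zero`, set a non-monotone warning flag rather than erroring.
Inversion is defined only on the linear segment; ratios outside
`(ratio_at_zero * floor, ratio_at_zero]` raise a saturation error
carrying the boundary concentration.

## Synthetic spectra

Phantom spectra use a CFP-like double-hump donor (475/501 nm, sigma
15 nm) and a YFP-like acceptor (527 nm, sigma 12 nm) on a 1-nm grid
over 450–600 nm, with the acceptor amplitude set so the unquenched A/D
is exactly 1.2. The two components are hard-windowed at a 515-nm
crossover (donor zero above, acceptor zero below) — an idealization
equivalent to a perfect dichroic split — so each integration band sees
exactly one fluorophore and the quench factor propagates to the A/D
ratio without cross-bleed terms. Real CFP/YFP spectra overlap; only
ratios, never absolute shapes, are meaningful downstream, so this
idealization costs nothing the pipeline relies on. The
crowding-insensitive control pair (`CFP-wtYFP`) uses the same shapes
with the quench factor pinned at 1.

## Image phantoms

Per pixel and channel, in detector counts:

    donor    = background + photon_scale * rho
    acceptor = background + photon_scale * rho * baseline_ad * f(C)

`rho` is the probe density field blurred by a Gaussian PSF (sigma
1.5 px); `C` is the unblurred crowder concentration map. The PSF is
applied to density *before* quench scaling: blur mixes probe molecules,
while the crowding each molecule reports is a pixelwise property of its
location. Noise, when enabled, is independent per-channel Poisson on
the expected counts; read noise is omitted as negligible at the
simulated count levels. Identical seed + config give bit-identical
output.

Interphase geometry: one disk cell (radius 110 px in a 256x256 frame,
jittered center), a circular nucleus (radius 34–44 px), and an NE rim
band of width 3 px straddling the nuclear boundary with probe density
3x the cytoplasm (NPC-embedded sensor accumulates at the rim). Default
counts — background 100, photon_scale 500 — put the cytoplasm at ~600
and the rim at ~1600 counts, a realistic confocal regime where Poisson
noise is a few percent per pixel. The concentration field defaults to
the cytoplasmic value *everywhere* (with nucleus/rim overrides) rather
than zero outside the cell: concentration only matters where probe
density is nonzero, and the convention keeps the cell edge free of
partial-volume ratio artifacts. Preset concentrations (rim 200, 140,
180 mg/mL against cytoplasm 100) are chosen so the quench model yields
NE/cytoplasm probe ratios of 0.75, 0.90 and 0.80 — the ~25%/~10%/~20%
reductions characteristic of peripheral, central-cavity and scaffold
nucleoporin environments. Cytoplasm at 100 mg/mL sits in the
commonly cited 50–200 mg/mL range for cellular interiors.

Immunostain pairs share one geometry per seed; the treated image scales
the rim stain density by the retention factor (0.70 models a 30%
removal of a transport receptor by detergent extraction), with a faint
cytoplasmic stain (0.2) providing realistic PSF bleed.

Time-lapse phantoms: two elliptical chromosome masses (semi-axes
16x12 px) overlap before the anaphase-onset frame and separate at
5 px/frame from a 2-px gap, so the thresholded mask first splits
exactly at the onset frame. Frames are 2 min apart over 30 min after
onset (plus 3 pre-onset frames). The chromosome-surface rim band
accumulates probe density by first-order kinetics

    L(t) = plateau * (1 - exp(-k (t - t0))),  k = ln(2)/3 per min,

with class presets differing in onset t0 (1, 3, 10 min), giving
analytic half-max times t0 + 3 min — the ~4/~6/~13-min assembly
ordering of scaffold, membrane-spanning and cytoplasmic subunits. An
optional post-telophase exponential decay (preset
`early_assembler_decay`, 0.08/min from 10 min) emulates the partial
dissociation of early-assembling subunits. The rim concentration ramps
from 100 to 180 mg/mL proportionally to the *running maximum* of
L(t)/plateau: crowding follows assembly but does not reverse when early
subunits dissociate, reproducing the observed dissociation signature
(localization falls after its peak while the probe signal holds its
plateau). A plain proportional tie would force the probe signal to
recover alongside the localization decay, which is not what such data
show. Chromatin decondensation is modelled as an optional linear ramp
of mask area (axes scaled by sqrt of the growth factor).

## Segmentation and measurement

Segmentation runs on the donor channel only (the acceptor is
crowding-attenuated at the rim; the donor is not). A 3-class multi-Otsu
split yields the cell (low threshold) and the bright NE ring (high
threshold) — a single Otsu can lock onto the tiny bright class and
swallow the cytoplasm into "background", corrupting background
estimates. The ring is hole-filled to find the enclosed nucleus. When
the filled region is near-circular (circularity >= 0.85), the nucleus
boundary is refined by a weighted algebraic (Kasa) circle fit to the
ring pixels, weighted by contrast over the cytoplasmic level; this is
subpixel-accurate (center/radius errors < 0.05 px on phantoms), whereas
discrete morphology alone carries half-pixel biases that are material
for a 3-px band. Non-circular nuclei fall back to a purely
morphological boundary band. The rim is the band of configured width
(default 3 px, fixed in pixels, not inferred per cell) straddling the
nucleus boundary; one band convention is shared by interphase rims,
chromosome-surface bands and phantom ground truth.

Region probe signals are ratios of background-subtracted region
*means* (never means of pixel ratios — robust to low-intensity pixels,
and exactly invariant to a constant offset supplied as the background
estimate). Backgrounds are estimated per channel as the mode of the
integer-binned histogram over the background mask; phantoms also allow
supplying the true level for noise-free tests. Regions below 50 px are
QC-flagged but still measured. A frame is assumed to hold one dominant
cell (the phantom contract); otherwise the largest connected component
is taken.

Mitotic analysis re-segments per frame: chromosome masks by Otsu on the
marker channel (components < 20 px discarded), rim as the boundary
band, cytoplasm as the cell foreground minus a 3-px-dilated exclusion
zone around chromosomes and rim. Anaphase onset is the first frame
whose chromosome mask splits into >= 2 components with centroid
distance >= 10 px, persisting >= 2 consecutive frames (one-frame
spurious splits are ignored); a manual onset override is a first-class
input because real data may lack a clean split. The relative nuclear
localization is the rim/cytoplasm excess ratio
`(rim - bg)/(cyto - bg) - 1`, clipped at 0 — a simple monotone
localization index; all half-time results are insensitive to affine
rescaling of the trace. The probe series is rim-over-cytoplasm A/D per
frame, divided by its value at the onset frame (exactly 1 at time 0 by
construction). Frame times come from metadata when supplied, else
index x frame_interval.

## Half-time extraction

Target level is the midpoint (max + min)/2 over the post-onset window,
with the plateau estimated as the mean of the last three frames to
resist noise spikes; the reported time is the earliest crossing,
linearly interpolated between adjacent frames; direction selects the
rising (localization) or falling (probe) crossing. A flat or
non-crossing series returns an explicit unrecoverable flag, never a
fabricated time. For a step series the convention yields the midpoint
of the bracketing interval. These conventions are recorded in every
half-time output.

## Statistics

Group summaries report mean, SD (n-1 denominator), median, type-7
(linear-interpolation) quartiles and 1.5*IQR outliers, matching the
boxplot presentation standard in cell-biology figures. Treatment
comparisons divide treated values by the reference-group mean for
presentation, and test the unnormalized values with a two-tailed Welch
t-test (Welch–Satterthwaite degrees of freedom, Student-t survival
function). The expression-independence check reports the OLS slope and
Pearson correlation of relative probe signal against rim localization
intensity, with no built-in decision rule.

## What the phantoms do and do not show

The generator reproduces the *statistical structure* the pipeline must
handle — three-population intensity histograms, PSF blur, Poisson
noise, rim geometry, assembly kinetics with decoupled crowding — with
known ground truth, so passing tests demonstrate correct recovery of
generating parameters under those conditions. Phantoms are 2-D, single
cell per frame, circular nuclei, stationary cells, no photobleaching,
no intensity gradients, and their crowding is linked to concentration
by the very quench model the analysis assumes. Agreement on phantoms
therefore validates the measurement chain, not the photophysics of any
real sensor; applying concentration estimates to real images requires
a user-supplied spectroscopic calibration, and segmentation of
irregular real nuclei will be less accurate than the subpixel circular
case.

## Problem sizes and tolerances

Headline quantities are recomputed at desk scale: 20 noisy 256x256
interphase phantoms per condition (one cell each, matching the "more
than 20 cells" convention for such measurements), 20 immunostain
pairs, one 19-frame time-lapse, and noise-free 16-point kinetic traces
for the timing presets — sizes at which the stochastic quantities are
stable to well under a percentage point across seeds while the full
recomputation stays in seconds. Noise-free pipeline checks use a 0.01
absolute tolerance on relative probe values (residual segmentation
discretization); noisy batch means are checked at +/-2 percentage
points; half-times at +/-0.5 min against the closed form; the Welch
implementation is checked against an independent oracle at 1e-10 and
its null rejection rate over 2000 replicates must lie in [0.035,
0.065] at alpha = 0.05.
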