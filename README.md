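# npcrowd

Ratiometric analysis of macromolecular crowding in the nuclear pore
complex (NPC), measured with a genetically encoded FRET crowding sensor
(GimRET: a CFP donor fused to a glycine-inserted YFP acceptor whose
fluorescence is quenched by crowding while the donor is insensitive).

The package is for cell biologists and imaging scientists who want to
turn two-channel fluorescence data of sensor-fused nucleoporins into
quantitative crowding readouts: how much more crowded the nuclear
envelope (NE) is than the cytoplasm in interphase, and how crowding
builds on the chromosome surface as the NPC reassembles after mitosis.
A synthetic phantom generator with exact ground truth makes every step
testable as a parameter-recovery experiment.

## The statistic

The sensor readout is the band-integrated acceptor/donor ratio

    A/D = sum I(lambda), 520-570 nm  /  sum I(lambda), 460-500 nm

(433-nm excitation; lower A/D = higher crowding). Its concentration
dependence is modelled as a linear quench with a floor,

    A/D(C) = R0 * f(C),   f(C) = max(1 - C/500, 0.2)   [C in mg/mL],

with the instrument-dependent `R0` always fitted. In images, the
per-cell crowding statistic is the ratio of background-subtracted
region A/D values,

    relative probe = [probe]_NE / [probe]_Cyto = f(C_NE) / f(C_Cyto),

which cancels expression level, optics and background by construction.
In mitotic time-lapse data, the chromosome-surface rim carries two
co-plotted traces against time after anaphase onset: the relative
nuclear localization of the donor signal (assembly) and the probe
signal normalized to its value at onset (crowding); assembly timing is
summarized by the half-maximum crossing time t0 + ln(2)/k.

## Worked example

```python
from npcrowd import (load_preset, make_interphase_image, quantify_image,
                     make_spectrum, ad_ratio, fit_calibration,
                     invert_calibration)

# one synthetic interphase cell: NE at 200 mg/mL, cytoplasm at 100 mg/mL
cfg = load_preset("peripheral", seed=1)
donor, acceptor, manifest = make_interphase_image(cfg)
m = quantify_image(donor, acceptor)
print(f"probe_NE   = {m.probe_ne:.4f}")
print(f"probe_Cyto = {m.probe_cyto:.4f}")
print(f"relative   = {m.relative_probe:.4f}")

# calibrate A/D against crowder concentration from noisy spectra
pairs = [(c, ad_ratio(make_spectrum("GimRET", c, noise_sd=5.0, seed=i)))
         for i, c in enumerate([0, 50, 100, 150, 200])]
curve = fit_calibration(pairs)
print(f"ratio_at_zero = {curve.ratio_at_zero:.4f}, "
      f"slope = {curve.slope:.6f} per mg/mL")
print(f"inferred C at A/D 0.96: {invert_calibration(0.96, curve):.1f} mg/mL")
```

prints

```
probe_NE   = 0.7213
probe_Cyto = 0.9576
relative   = 0.7532
ratio_at_zero = 1.1999, slope = 0.001998 per mg/mL
inferred C at A/D 0.96: 100.1 mg/mL
```

The NE probe signal is ~25% below the cytoplasm — the rim is markedly
more crowded — and the fitted calibration recovers the generating
quench model (R0 = 1.2, slope 1/500 per mg/mL), so an A/D of 0.96 maps
back to ~100 mg/mL.

The same workflow is available from the shell:

```sh
npcrowd simulate cells --preset peripheral --n 20 --seed 1 --out data/
npcrowd quantify interphase data/cell_*[0-9].tif --out results/
npcrowd simulate timelapse --preset early_assembler --out tl/
npcrowd quantify timelapse tl/timelapse.tif --out results_tl/
```

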