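# Named phantom presets, version 1.
#
# Interphase presets differ only in the rim crowder concentration; the
# expected relative probe signal is quench(rim)/quench(cyto) under the
# default linear-with-floor model f(C) = max(1 - C/500, 0.2):
#   peripheral      200 vs 100 mg/mL -> 0.60/0.80 = 0.75  (~25% reduction)
#   central_cavity  140 vs 100 mg/mL -> 0.72/0.80 = 0.90  (~10% reduction)
#   scaffold        180 vs 100 mg/mL -> 0.64/0.80 = 0.80  (~20% reduction)
# Time-lapse presets share k = ln(2)/3 per min and a 100 -> 180 mg/mL rim
# concentration ramp; they differ in assembly onset t0 (min after
# anaphase onset), giving analytic half-max times t0 + ln(2)/k = t0 + 3.

peripheral:
  kind: interphase
  params:
    concentration_rim: 200.0
    concentration_cyto: 100.0

central_cavity:
  kind: interphase
  params:
    concentration_rim: 140.0
    concentration_cyto: 100.0

scaffold:
  kind: interphase
  params:
    concentration_rim: 180.0
    concentration_cyto: 100.0

digitonin_immunostain:
  kind: immunostain
  params:
    retention: 0.70
    probe_density_rim: 3.0
    probe_density_cyto: 0.2
    probe_density_nucleus: 0.2

early_assembler:
  kind: timelapse
  params:
    t0: 1.0

early_assembler_decay:
  kind: timelapse
  params:
    t0: 1.0
    telophase_decay_rate: 0.08
    telophase_time: 10.0

pom121_like:
  kind: timelapse
  params:
    t0: 3.0

late_assembler:
  kind: timelapse
  params:
    t0: 10.0
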