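{
  "reference_conductance.csv": "Published water-displacement reference conductance of PEEK tubing (kg s^-1 kPa^-1), aggregated by colour and laboratory (DRF, UQAM): determination count, mean, min-max and CV%.",
  "interlab_overlap.csv": "Published inter-laboratory overlap of the reference ranges per colour: shared [min, max] range and the number of reference values falling inside it.",
  "validation_counts.json": "Published QC outcome of the validation campaign: 37 of 1198 measurements rejected, with per-laboratory totals and rejection-cause counts.",
  "color_thresholds.json": "Colour-specific upper conductance plausibility bounds (kg s^-1 kPa^-1) used for raw-data filtering; the orange bound is laboratory-specific."
}
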