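# Methods

## The measurement model

A gravity-fed pressure-drop flow meter infers the hydraulic conductance of a
sample from two pressure sensors placed on either side of a PEEK capillary of
known resistance. The hydraulic circuit is two resistors in series: an
upstream reservoir at water-column height *h* drives flow *Q* through the
meter's internal tubing (resistance *R*<sub>tubing</sub>, kPa s kg⁻¹) and
then through the sample (*R*<sub>sample</sub>) into a downstream reservoir
whose immersion depth contributes a static backpressure *P*<sub>b</sub>. At
steady state the flows are equal, so

&nbsp;&nbsp;*K*′ = *Q* / Δ*P*<sub>sample</sub> =
Δ*P*<sub>tubing</sub> / (*R*<sub>tubing</sub> · Δ*P*<sub>sample</sub>)

with Δ*P*<sub>tubing</sub> = *P*<sub>up</sub> − *P*<sub>down</sub> and
Δ*P*<sub>sample</sub> = *P*<sub>down</sub> − *P*<sub>b</sub>. The
backpressure is read by the same downstream sensor with the sample isolated
by stopcocks, which is what lets a constant downstream-sensor offset cancel
out of Δ*P*<sub>sample</sub>.

The head is converted with *P* = ρ(*T*)·g·*h* using the Kell density
polynomial; 1 cm of water at 25 °C is 0.0978 kPa, the field's
"0.001 bar per cm" rule. Conductance is normalized to 25 °C with
*K*′₂₅ = *K*′<sub>T</sub> · μ(*T*)/μ(25 °C), where μ is a Vogel-type
three-parameter viscosity fit valid over 0–50 °C.

One subtlety: the conductance relation must use the tubing resistance *at
the stream temperature*, i.e. *R*<sub>tubing,ref</sub> · μ(*T*)/μ(25),
because the PEEK tubing's resistance carries the same viscosity factor as
the sample's. Using the 25 °C reference value directly makes the two factors
cancel inside the ratio and the final normalization then overcorrects by
μ(*T*)/μ(25). With the scaled form the closed loop (simulate at *T*, measure,
normalize) recovers the true 25 °C conductance exactly.

## Quality control

A determination is accepted only if all of the following hold, mirroring
established operating practice for this instrument class:

- **Operating window** — mean *P*<sub>down</sub>/*P*<sub>up</sub> in
  [0.2, 0.8]; the optimum is 0.5, reached when tubing and sample resistances
  match.
- **Steady state** — CV of the instantaneous per-sample conductance < 0.05
  over the final 300 s, which is also the minimum recording length. The CV is
  computed on conductance rather than on raw pressures because conductance is
  the quantity whose stability matters; the choice is configurable through
  `detect_steady_state`.
- **Colour plausibility** — *K*′₂₅ below an upper bound per tubing colour
  (yellow 0.1, blue 0.15, orange 1.5/1.65 kg s⁻¹ kPa⁻¹ for DRF/UQAM). The
  bounds are upper bounds because the characteristic failure modes (leaks,
  stopcock errors) all *overestimate* conductance. When
  Δ*P*<sub>sample</sub> ≤ 0 the apparent conductance is reported as infinite
  and the same flag fires.

## The synthetic rig

The simulator emulates the validation campaign's raw data, which are not
required by this package. What it models:

- **Circuit** — exact series-network steady state per sample, with
  temperature-scaled resistances; no transient fluid dynamics (streams are at
  steady state from *t* = 0 unless a fault perturbs them).
- **Sensors** — each reading is gain·*P* + offset + *a* + ε, where ε is
  i.i.d. Gaussian per-reading noise (default SD 0.005 kPa) and *a* is a
  per-stream constant drawn N(0, 0.25 % × 7 kPa) realizing the sensor's
  full-scale accuracy specification. Splitting the error this way matters: a
  datasheet accuracy figure is a bound on systematic error, not a per-reading
  noise floor. The constant term does not average out over a stream, so it
  reproduces the observed height effect — replicate CVs of ~7 % at 10 cm
  versus ~1 % at 45 cm, because a fixed pressure error is a larger fraction
  of a small differential — while the small per-reading term keeps the
  steady-state CV below 0.05 at all heights, consistent with the low (~3 %)
  rejection rate reported for real operation. Within one measurement the
  downstream sensor's accuracy offset is shared between the flow and
  backpressure phases, so the backpressure correction cancels it, as it does
  physically.
- **Faults** — leak: a parallel conductance path from the downstream node,
  which inflates apparent sample conductance by exactly the leak conductance;
  bubble: a transient multiplicative increase of sample resistance (default
  ×5), which breaks the steady-state criterion; sensor offset: an additive
  step on one sensor; stopcock error: the backpressure phase reads the
  flow-phase downstream pressure, collapsing Δ*P*<sub>sample</sub> toward
  zero and driving the apparent conductance far above the colour bound.
- **Reference route** — water-displacement series at heights 45…5 cm,
  volume/time records with relative Gaussian pipette noise (default 1 %),
  analysed by a zero-intercept regression of pressure on viscosity-adjusted
  mass flow. The regression direction uses all heights at once and is robust
  to noise; per-height resistances are returned for diagnostics.

Unstated instrument parameters were fixed once to field-plausible values and
recorded in config: sampling 1 Hz, stream length 600 s, sensor full scale
7 kPa (≈1 psi), backpressure 0.2 kPa (a few cm of immersion). The per-colour
and per-laboratory tubing populations are drawn from the published reference
aggregates (means, min–max, CV) packaged under `peekflow/data`.

What the generator does **not** emulate: warm-up transients, sensor drift
within a stream beyond the constant offset, bubbles in the reference
pipette, operator-dependent height error, or real plant samples (variable
conduit architecture, tissue degradation). Passing closed-loop tests
therefore demonstrates correctness of the computation and QC logic under
the stated error model, not instrument performance on biological material.

## Agreement, precision, accuracy statistics

- **Relative bias** — 100·(mean *K*′ − *K*′<sub>ref</sub>)/*K*′<sub>ref</sub>.
- **Jaccard similarity (JSI)** — intersection over union of the two groups'
  [min, max] ranges, in percent; union length is |A| + |B| − |A∩B| so
  disjoint ranges score 0.
- **Bhattacharyya coefficient (BC)** — 100·Σ√(p₁ᵢp₂ᵢ) over 15 equal-width
  bins spanning the pooled range, each group's counts normalized to
  probabilities. Binning uses the standard half-open convention (ties at
  interior edges fall right; the final bin is closed so maxima are counted).
- **Intersect fraction** — percent of pooled values inside the range
  intersection.
- **Two-sample KS** — exact null distribution when min(n) ≤ 25, asymptotic
  otherwise. At n = 15 per group the exact test is discrete and conservative:
  rejection at p < 0.05 occurs iff D ≥ 8/15, giving a true size of 0.026.
- **Mean difference** — 100·|mean<sub>a</sub> − mean<sub>b</sub>| divided by
  the average of the two group means (a symmetric denominator; configurable
  convention).
- **Precision** — 5th–95th percentile range with linear-interpolation
  percentiles; CV and standard error computed on the values inside
  [q5, q95], so extremes are excluded from dispersion as well as range.
  (Computing them on all data instead shifts CVs by well under a point at
  n ≈ 50; the trimmed convention is the default.)
- **Accuracy** — reference intervals are mean ± full range of *all
  individual reference determinations* for a colour/lab (not per-specimen
  means: the conservative band must absorb displacement-measurement
  scatter). Inclusion rate is the percent of measurements inside the band;
  per-specimen relative deviations are averaged within specimen and combined
  weighted by measurement counts.

## Experiments

Three presets orchestrate the study designs end to end
(`peekflow.experiments` / the `peekflow` CLI): `device_comparison` (three
devices, one blue pair, 25 cm, ≥15 replicates), `interlab` (two labs × three
colours × heights 10/25/45 cm, two sample specimens per colour, ≥5
replicates) and `accuracy_grid` (colours × devices × heights 10/15/25/45 cm
with the 15 cm rung in one laboratory only, four sample specimens per
colour). A single seed is expanded into per-stream child seeds through
`numpy.random.SeedSequence`, so bundles are bit-reproducible. Every summary
number is recomputable from the measurement table the bundle writes; QC
rejections are logged with their flag names. Datasets from different
experiments are kept separate; pooled analyses are done by concatenating
measurement tables, which every summary function accepts.

## Numerical choices and degenerate inputs

- A blocked sample (*R*<sub>sample</sub> = ∞) yields *Q* = 0 and
  *P*<sub>down</sub> = *P*<sub>up</sub> without special-casing errors.
- Head at or below backpressure raises a degenerate-flow error before any
  simulation.
- Zero-width reference sets (all determinations identical) are rejected when
  building intervals; identical point ranges score JSI 100 by convention.
- Calibration requires ≥3 points over ≥2 distinct heights and non-constant
  readings; acceptance is R² > 0.99 on the OLS fit of true pressure on raw
  output (fitted in that direction so the model applies directly to
  streams).
- Problem sizes in the test and acceptance runs — 1000 random circuits for
  the oracle comparison, 200 closed-loop replicates, 100 replicates per
  fault, 500 KS null draws — were chosen as the package's own balance of
  statistical resolution against run time; all complete in seconds.

## Known limitations

- The printed unit convention for *K*′ (kg s⁻¹ kPa⁻¹ with blue-tubing values
  near 0.1) is used as-is throughout; Hagen–Poiseuille evaluation of nominal
  geometries with SI water properties gives far smaller absolute
  conductances, so `hagen_poiseuille_conductance` should be used for ratio
  and scaling arguments (d⁴ law), not absolute comparison against the
  packaged reference table.
- Tubing lengths are not part of the published aggregates; Hagen–Poiseuille
  calls take length explicitly and examples use 1 m placeholders.
- The error model is stationary within a stream; slow drift, temperature
  gradients between reservoirs and electronics effects are out of scope.
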