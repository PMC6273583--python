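# Methods

## Scope and data flow

The package analyses colorimetric AChE-inhibition screens run in 96-well
plates with the Ellman reaction (acetylthiocholine + DTNB, read ~450 nm).
Raw input is a long-form kinetic CSV — one row per (well, timepoint) — with
four pre-enzyme reads at 0/3/6/9 min and one post-enzyme read per well.
The stages are: `synthetic` (data generation), `plate_io` (parsing,
validation, deterministic writing), `ellman` (reduction to percent
inhibition), `dose_response` (4PL fits, IC ladders, activity calls),
`synergy` (combination indices, classification, isobolograms) and `report`
(replicate summaries, selectivity ratios, screen tables).

## Reduction model

The pre-enzyme reads exist to measure spontaneous, non-enzymatic signal
drift. We fit a least-squares line to the four pre-enzyme points per well
(slope in AU/min; the maximum absolute residual is a linearity diagnostic,
flagging `drift_nonlinear` above a configurable threshold, default
0.02 AU). The enzymatic signal is the post-enzyme read minus the last
pre-enzyme read extrapolated forward along the drift line; the post-read
time is taken from the file, not hard-coded, so longer incubations are
handled transparently. Percent inhibition ratios this signal to the mean
signal of all negative-control (solvent) wells on the plate — controls are
pooled plate-wide because the design places no per-column controls.

Two deliberate choices:

* The inhibition formula itself is an interpretation of the assay
  description (which never writes one): drift-corrected increments ratioed
  to the control increment. On noise-free synthetic plates this reduction
  recovers the generator's ground-truth inhibition to better than 1e−9.
* Inhibition values outside [0, 100] are **kept and flagged**
  (`negative_rate` when the corrected signal is negative), never clipped:
  clipping would bias the tails of the downstream curve fits. Clamping is a
  presentation decision left to report rendering.

The read wavelength is treated as metadata only; nothing in the reduction
depends on it.

## Dose–response model

Inhibition vs dose follows the four-parameter logistic
`r(d) = bottom + (top−bottom)·d^h/(d^h + ic50^h)` with `h > 0` and
inhibition rising from the bottom asymptote at dose 0. For screen samples
the asymptotes default to fixed 0/100 — the reference single-agent IC
ladders are exactly consistent with a 0–100 logistic — and can be freed for
partial inhibitors. Viability (MTT) curves reuse the same machinery through
a `descending` flag that fits the reflected response rather than a second
formula.

Fitting is Levenberg–Marquardt least squares on (log ic50, log h) (the log
parameterisation enforces positivity without bounds), multi-started: the
midpoint is seeded at the geometric mean of the doses bracketing
half-maximal response and the slope at each of {0.5, 1, 2, 4}; the lowest
residual sum of squares wins, ties broken by the smallest slope. An
optimiser stall is reported as `converged=False` rather than raised.
`se_ic50` comes from the Jacobian at the optimum via the delta method on
log ic50. Fewer than four distinct doses, or flat responses, are rejected
as unidentifiable.

Inversion to IC_x is closed-form and is the identity against prediction to
1e−9 across (bottom, top). A pair of IC levels determines the 0–100 curve
exactly (`h = ln 81/ln(IC90/IC10)` for the default pair); the bundled
berberine, coptisine **and** palmatine ladders all reproduce their measured
IC50s from their IC10/IC90 pairs within 1%, which is the internal
consistency check shipped as a test.

The screen triage rule: a sample is `inactive` iff it shows less than 80%
inhibition at the screen ceiling (default 1250 µg/mL); exactly 80.0 counts
as active, and a sample never tested up to the ceiling is not called
inactive.

## Combination scoring

The fixed-partner design varies one agent through a strict 1:1 serial
dilution while partners sit at their single-agent IC30s. Both the varied
agent alone and the combination are fitted and inverted to IC ladders
(levels 10…90 step 10 by default, mirroring the reference tables;
configurable). At each level the combination index sums fractional-effect
terms; the partner denominator is the partner's **fixed dose**. This
operational convention is the one that reproduces the reference CI tables
cell-for-cell: recomputing all 81 cells reproduces 8 of the 9 combination
rows at one unit of the last printed digit (the published values were
evidently computed from unrounded ICs, so half-unit re-rounding agreement
is not attainable). The ninth row (palmatine varied / coptisine fixed) is
irreproducible under any single denominator convention we tested (its IC10
cell computes to 0.60 vs a tabulated 0.44) and is retained in the bundled
data but excluded from golden assertions — a documented transcription
inconsistency, not silently "fixed". The literal iso-effect variant
(partner denominator = the partner's own IC_x) is available via
`convention="isoeffect"`, and with no partners both variants reduce to the
classical single-ratio FIC.

The classical Loewe FIC `Σ dᵢ/Dᵢ(x)` is kept as a separate function for
simulation validation: it is the quantity the generator holds fixed, equals
1 for sham combinations by construction, and recovers the generator's τ
within 1% at all nine effect levels on noise-free data.

Classification boundaries are explicit because published threshold wordings
overlap at their edges. The shipped semantics: `schelz` — (0, 0.5] synergy,
(0.5, 1.0] additive, (1.0, 4.0) indifferent, [4.0, ∞) antagonism;
`berenbaum` — <1 synergy, =1 additive, >1 antagonism; `table_bold` — <1
synergy, else no_synergy. The boundary assignments at 0.5, 1.0 and 4.0 are
design decisions, covered by exact tests.

Isobologram coordinates normalise each iso-effect dose pair by the
single-agent doses at that level; a point lies below the unit additivity
line iff its classical FIC < 1. A partner-free input degenerates to a
single axis and is flagged rather than erroring.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
the enzyme chemistry:

* **Single agents** follow the 4PL exactly; fixture parameters use the
  reference alkaloid values (berberine IC50 1.48 µg/mL, h 1.292; coptisine
  1.27, 2.936; palmatine 5.21, 1.992 — slopes solved from each ladder's
  IC10/IC90 pair).
* **Combinations** respond at the effect E solving the generalised Loewe
  relation `Σ dᵢ/Dᵢ(E) = τ` (τ = 1 additive, <1 synergy, >1 antagonism),
  found by bisection to 1e−9 on effect; the dose-fraction sum is strictly
  decreasing in E so the root is unique. Dose combinations too small to
  lift the response off the shared bottom asymptote return the bottom with
  a `below_detection` flag. All agents in a combination must share
  asymptotes (0/100 in practice).
* **Kinetic plates** lay a linear spontaneous drift (default 0.002 AU/min
  from a 0.10 AU baseline) under every well, then add a post-enzyme
  increment of `0.5 AU · (100 − I)/100` at 12 min. Noise lands on
  absorbance reads (additive `sd_abs`) and on enzymatic rates
  (multiplicative `sd_rel`), never on derived inhibition, mimicking the
  instrument. Negative absorbances after noise are clipped at zero and the
  clipping rule is echoed in the ground-truth table metadata. The default
  `sd_abs` of 0.01 AU against the 0.5 AU control window corresponds to ≈2
  inhibition-points of read noise, sized to produce replicate relative SDs
  in the 5–12% range typical of this assay near the IC50; it is a fixture
  choice, not a measured instrument property.

Seeds are explicit (`NoiseModel.seed` or a passed `Generator`), echoed into
output metadata, and identical seeds give byte-identical CSVs. What passing
tests on this generator do **not** show: real plates have edge effects,
substrate depletion at long incubations, compound absorbance overlap and
non-Gaussian outliers; none of these are modelled, which is why the QC
flags (`drift_nonlinear`, `negative_rate`) exist as hooks rather than as
exercised failure modes.

A note on design geometry: under strong synergy (τ = 0.5) a partner pinned
at its IC30 already drives >70% effect on its own, so low iso-effect
contours are unreachable by titrating the varied agent — the titration
inverse raises a clear error in that regime, and the τ-recovery validation
walks iso-effect dose rays (checkerboard geometry) instead, which covers
all nine levels.

## Reporting conventions

Replicate summaries are arithmetic mean ± sample SD (n−1); SD is undefined
(NaN) for a single value. Selectivity ratios display at 2 significant
figures (half-to-even) with the unrounded value retained; CI values display
at 3. Screen tables render inactive samples as `NA` and never-measured
extracts as `n/a`, ordered family-then-species; the rendering is
deterministic and idempotent. Between-group significance testing is out of
scope — the report carries means and SDs only.

## Problem sizes

Simulation-backed tests run on single plates (≤ ~100 wells) with 6–10-point
dilution series in up to triplicate, and 200 seeded repeats for the
coverage check of the IC50 standard error (|IC50 − truth| < 3·SE in ≥95% of
runs). The whole suite completes in a few seconds on one CPU.

## Known limitations

* One post-enzyme read per well: no per-timepoint enzymatic kinetics and no
  Michaelis–Menten mechanism; the reduction is increment-based by design.
* No 5PL/asymmetric curves, no Bayesian fitting, no outlier rejection
  beyond QC flags.
* Synergy scoring covers the fixed-partner FIC/CI and classical Loewe FIC
  only — no Bliss independence, Chou–Talalay median-effect, or
  response-surface models.
* Concentrations are µg/mL throughout (the screen's working unit; one
  reference table header says mg/mL but its values are µg/mL-scaled, and
  the package standardises on µg/mL); molar conversions are out of scope.
* CSV/YAML only; no plate-reader binary formats or Excel.
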