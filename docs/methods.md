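# Methods

## The quantities

**Hydraulic diameter.** For laminar flow in a non-circular duct the
resistance-relevant caliber is `Dh = 4·Ai/Pi` (lumen area `Ai` in mm²,
inner perimeter `Pi` in mm). For any closed cross-section the
isoperimetric inequality `Pi² ≥ 4π·Ai` holds, so `Dh ≤ 2·√(Ai/π)` (the
equal-area diameter), with equality only for circles. Measurement pairs
violating the inequality describe an impossible curve; the package flags
them (`isoperimetric_feasible`) and reports counts, but never silently
drops or repairs them. The ratio `Din/Dh` of the segmentation software's
average inner diameter to `Dh` serves as a non-circularity index; the
Poiseuille factor `100·(r⁻⁴ − 1)` converts a caliber ratio `r` into the
percent change in laminar driving pressure.

**Distensibility.** For an airway observed at two inflations,

    AD = (ΔAi/Ai_MLV) / (ΔV/V_MLV)^(2/3),

where `V` is the air volume of the lung the airway ventilates (right or
left from the label's prefix). The 2/3 power maps the parenchymal volume
expansion onto an equivalent isotropic area expansion, so `AD = 1` means
the airway dilates with the tissue, `AD < 1` a stiffer airway, `AD < 0`
paradoxical constriction. AD is a ratio of ratios and therefore
invariant to area and volume units — asserted by test. The trachea
subtends both lungs and is excluded by default; setting
`proximal_ad_mode="summed"` instead normalizes it by the summed
right+left volumes. Lungs that fail to inflate (`V_TLC ≤ V_MLV`) make AD
meaningless; such records are flagged invalid and retained, never
dropped.

**Aggregation order.** All cohort statistics are means of per-airway
quantities (Dh, percent change, ratios, AD), not quantities of means.
The two orders differ — e.g. the percent change of two group means is
generally not the mean per-airway percent change — and the per-airway
order is the one the summaries here commit to. Group cells with fewer
than `min_n` airways (default 8) are suppressed: kept in the output with
their count, statistics set to NaN, so raising the threshold can only
suppress more cells (a tested monotonicity).

**Statistics.** Paired Student t-tests (closed form, two-sided,
zero-variance differences reported as a degenerate flag rather than a
number) compare states; ordinary least squares with the squared Pearson
correlation as R² quantifies MLV-vs-TLC association and the
area-change-vs-volume-change coupling. Both are cross-checked against
scipy's reference implementations to 1e-10 on 1000 random fixtures. No
multiple-testing correction is applied; α = 0.05 is reported alongside
(0.01 for the Din/Dh state comparison), and interpretation is left to
the reader. The outlier rule flags records with `|AD − mean| > k·SD`
(sample SD, single pass, default k = 2) within a configurable grouping
(`global`, `per-lung-generation` — the default, matching how the
diagnostic distributions are stratified — or `per-region`); flagged
records are excluded from downstream means but kept in every output.

## The synthetic cohort

The generator emulates a 24-subject asthmatic cohort imaged at MLV and
TLC after a methacholine challenge, using the published per-airway
summary tables in `airmorph/reference.py` as its calibration targets.

* **Lung volumes.** Per-lung truncated normals (right MLV
  1.294 ± 0.441 L, TLC 2.286 ± 0.626 L; left 1.136 ± 0.374,
  2.072 ± 0.560), with `corr(V_MLV, V_TLC) = 0.8` within a lung — lung
  size is a subject trait, and independent draws would create
  "non-inflating" subjects no TLC breath-hold produces. TLC > MLV is
  enforced by redraw. The correlation value is a modeling choice (the
  study publishes only marginals).
* **Tree roster.** One slot per published (airway, generation) cell:
  named proximal airways and lobar roots (generations 0–2), segmental
  bronchi (generation 3), and two dotted children per subtree at
  generations 4 and 5. MLV measurements exist only where the published
  table has an MLV entry — at generation 5 only in the six subtrees
  (RB1, RB3, RB6, RB10, LB3, LB10) where matched airways were
  obtainable — and detection probabilities fall with generation (TLC:
  1.0/1.0/1.0/0.95/0.80/0.60 by generation; MLV given TLC:
  1.0/1.0/1.0/0.90/0.75/0.55), chosen to reproduce the published cell
  counts (n ≥ 8 of 24 subjects at the distal cells).
* **Distensibility truth.** Per cell, AD is drawn as a unit-mean
  lognormal subject factor (SD 0.1 at the cohort-typical AD of 0.45)
  times a lower-truncated normal residual whose location is solved
  (Brent) so the post-truncation mean equals the published cell mean —
  truncation at the positivity floor (0.01) therefore does not bias the
  calibration. For generations 0–2, where no AD is published, the
  implied AD is derived from the cell's MLV/TLC mean areas and the
  cohort-mean volume change. Constrictions (AD < 0, magnitude
  |N(0.08, 0.04)| clipped to [0.01, 0.5]) are injected with probability
  0.025, set so the total share of airways whose Dh decreases at TLC —
  injections plus measurement-noise sign flips on barely-dilating
  airways — stays below the 5% rarity the emulated cohort shows. The
  TLC area is then constructed by inverting the AD definition,
  `Ai_TLC = Ai_MLV·(1 + AD·(ΔV/V)^(2/3))`, floored at 5% of the MLV
  area (the floored value is written back as truth), so a noise-free
  cohort lets the pipeline recover every true AD to machine precision —
  a tested round trip.
* **Cross-section shape.** Lumens are ellipses: MLV aspect ratios are
  truncated-normal (SD 0.4, bounds [1.05, 5]) around the ratio solved by
  bisection against the exact elliptic-integral perimeter so that the
  cohort-mean Din/Dh hits 1.124; at TLC every aspect ratio drops by the
  fixed decrement (≈0.118) that moves the ratio target to 1.108 —
  inflation stretches airways toward circularity. Perimeters use
  Ramanujan's second approximation (relative error ≤ 5e-5 for aspect
  ratios ≤ 5, verified against `scipy.special.ellipe` over a 1000-point
  sweep); `Din` is modeled as the equal-area diameter, which makes
  Din > Dh automatic for any non-circular lumen.
* **Measurement corruption.** Independent multiplicative noise (2%
  relative SD) on area, perimeter and diameter, with the noisy perimeter
  floored at the isoperimetric bound so every emitted cross-section
  remains a possible closed curve. Additionally, 1.5% of TLC
  measurements are gross segmentation artifacts: the whole cross-section
  is mis-scaled (area ×(1+|N(1.5, 0.5)|), perimeter and diameter by its
  square root), producing the implausible apparent dilations a 2-SD rule
  exists to remove. This channel matters for calibration: the published
  per-cell statistics are *post-removal* values, so a cohort generated
  from them with no contaminants would have its legitimate tail values
  trimmed by the pipeline's outlier step, biasing the post-removal mean
  AD low; with artifacts present the rule removes mostly true
  contaminants, as it does on real data.
* **Determinism.** One `numpy` Generator seeded per run with a fixed
  draw order; identical (config, seed) gives bit-identical cohorts.
  Every cohort is returned with its ground truth (true AD, aspect
  ratios, noise-free geometry, artifact/constriction/detection flags).

### What the synthetic cohorts do not establish

The generator reproduces the published *marginal* cell statistics and a
handful of cohort-level couplings, not real airway physics. Known gaps:

* The published tables are mutually inconsistent under the elliptical
  model: the printed per-cell perimeters imply near-circular lumens
  (shape factors ≈ 1.05) while the printed Din/Dh ratio is 1.124. The
  generator follows the ratio calibration, so synthetic perimeters run
  ~6–7% above the printed perimeter means and the synthetic tracheal Dh
  is ≈ 12.7/13.7 mm (MLV/TLC) against printed 13.48/14.61. The
  real instrument's "average Din" is evidently not the equal-area
  diameter; reconciling the two would need the unpublished raw contours.
* Synthetic mean Dh change (~18%) exceeds the printed per-airway mean
  (13.5%): TLC areas are built from the distensibility targets, whose
  implied caliber growth at the published volume changes is larger than
  the printed Dh-change column — another internal tension of the
  published tables that the generator resolves in favor of the AD
  definition.
* The generation-3-vs-4 distensibility regression on synthetic cohorts
  is attenuated (R² ≈ 0.2–0.4 full, higher with the discordant LB1
  subtree excluded) relative to the emulated values (0.48/0.74), because
  per-subtree means carry sampling noise on both axes and the generator
  induces no extra between-generation coupling beyond the targets
  themselves.
* One published cell (LB3, generation 4 at MLV: area 2.5 ± 3.15 with a
  perimeter pair duplicating the generation-3 row) is kept as printed
  for the area target but its TLC area follows the AD target — the
  printed TLC/MLV ratio for that cell would imply AD ≈ 3.2, far outside
  the published AD table, and is presumably a typographical slip.
* No anatomical geometry (lengths, angles, branching asymmetry), no
  airway walls, no temporal dynamics, no anatomical variants (e.g.
  absent RB7), and subjects differ only by lung volumes and a scalar
  distensibility factor.

## Numerical choices

* Ellipse aspect-ratio inversion by Brent bisection on the exact
  shape factor, tolerance 1e-8; truncated-normal sampling via inverse
  CDF (`scipy.stats.truncnorm.ppf`) for reproducibility; mean-matched
  truncation locations solved by Brent and cached.
* Circle detection in shape metrics at relative tolerance 1e-9;
  isoperimetric feasibility tested with a 1e-12 relative slack to
  absorb rounding.
* CSV round-trips use `float_precision="round_trip"`; spreadsheet
  round-trips are exact to ~1 ulp (the xlsx writer serializes ~16
  significant digits), and tests compare accordingly.
* Suppressed cells and degenerate tests are NaN plus a boolean flag,
  never a sentinel number.

## Problem sizes

The default cohort is 24 subjects, ≈ 3,000 measurements, ≈ 1,200 matched
airways, and generates plus analyzes in ~1.5 s. Stochastic checks use
20 replicates (calibration: mean Din/Dh within 1.124 ± 0.02, mean AD
within 0.45 ± 0.05, Dh-decrease fraction < 5% on average, ratio ordering
in every replicate) and 50 replicates (parameter recovery: pooled
per-region AD means within two subject-cluster standard errors of the
configured truth in ≥ 90% of region × replicate cells, on an
artifact-free configuration so the estimator is tested under the noise
model rather than under contamination; measured coverage ≈ 94%).
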