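# Methods

## Problem and model

`xerograd` predicts moderate-to-severe (CTCAE grade ≥ 2) xerostomia after
head-and-neck IMRT from three contralateral-parotid features: the planned
mean dose MD (Gy), the average lateral dose gradient GRADX (Gy/mm,
medial-positive) and the medial parotid gland migration PGM (mm) over the
treatment course. Three nested logistic models are compared:

1. `logit P = β₀ + β₁·MD`
2. `… + β₂·GRADX + β₃·MD·GRADX`
3. `… + β₄·PGM`

The scientific rationale is a first-order expansion of the delivered mean
dose under a small rigid medial shift. If the shift grows linearly from 0
to PGM over the course, the time-averaged shift is PGM/2 and

    delivered MD − planned MD = GRADX·PGM/2 + O(PGM²),

with the second-order term bounded by half the maximal lateral curvature of
the dose field times PGM². The test suite verifies this bound on sigmoid
phantoms with whole-voxel daily drift (so nearest-voxel translation is
exact) for PGM up to 3 mm. GRADX is therefore a plan-derived proxy for the
dose increment a migrating gland will receive, and PGM a per-patient
measurement of that migration.

## Feature definitions and numerical choices

* World coordinates are `origin + index·spacing` at voxel centers, 0-based;
  masks must share the dose lattice (no resampling is hidden inside the
  features).
* MD is the arithmetic mean of dose over in-mask voxels (uniform voxel
  volume).
* GRADX uses central differences in the grid interior and one-sided
  stencils at the boundary — exact for affine dose fields — multiplied by
  the gland's `medial_direction` (+1/−1 along the lateral axis), so one
  definition serves both glands and "positive = dose rises toward the
  midline". Whether signed or absolute derivatives should be averaged is a
  genuinely open convention; signed medial-positive is the default and
  `absolute=True` is available.
* Delivered MD is the unweighted mean of per-fraction MDs over a mask
  sequence.

## Migration proxy

PGM is not measured directly: daily setup imaging rarely covers the gland,
so migration is inferred from shrinkage of the external body contour in a
slab at the C2 vertebral level. The chain is

    ΔVC2_c [%] = 100·(VC2_c − VC2_1)/VC2_1
    PGM_c [mm] = −0.413 · ΔVC2_c          (empirical linear coefficient)
    PGM        = PGM_c · end_day/control_day   (linear motion in time)

Two deliberate readings are documented here because the underlying
convention is easy to get wrong:

* **ΔVC2 enters in percent.** A −2 % median volume change with the −0.413
  coefficient gives ≈ 0.83 mm at the control day and ≈ 1.03 mm extrapolated
  to day 40 from a day-28–36 control — consistent magnitudes only on the
  percent scale.
* **Extrapolation passes through the origin at day 0** (fraction 1) and
  scales with elapsed days, not fraction number. The treatment end day is a
  required input (default 40 days ≈ a 30-fraction course); patients' true
  end days should be supplied when known.

The slope is overridable (`MigrationModelParams`) for recalibration. PGM is
patient-level: the C2 proxy cannot distinguish the two glands. Gland
shrinkage/deformation is out of scope — the proxy treats migration as a
rigid medial shift.

## Endpoint

Follow-up reports between 6 and 24 months (bounds inclusive) are pooled per
patient: mean grade, rounded half-up in exact integer arithmetic
(`floor((2s + k)/(2k))`), positive when the pooled grade is ≥ 2. Patients
with no in-window report are dropped with a warning. Text-to-grade mapping
of narrative reports is out of scope; inputs must be numeric grades.

## Estimation and evaluation

* Features are z-scored (population SD, ddof = 0) on the rows the model is
  fitted on; the interaction column is the product of the standardized MD
  and GRADX columns. The unpenalized fit is delegated to statsmodels'
  Logit; ridge fits (`NLL + λ/2·Σβ²`, intercept unpenalized) use the
  package's Newton solver, whose λ = 0 solutions agree with statsmodels to
  1e-5 in the tests. Unpenalized fits on separated data raise an advisory
  `SeparationError`; λ = 1.0 on standardized features is the package's
  small-sample default for simulation studies and the pipeline (≈ 2 events
  per parameter in the 88-patient regime; any mild shrinkage behaves
  similarly, and the ordering results are insensitive to λ in 0.5–2).
* **LPO-CV AUC**: every positive–negative pair is held out, the model refit
  on the rest (standardization recomputed inside the fold — no leakage),
  and the pair scores 1/0.5/0. For training-independent scorers this equals
  the Mann–Whitney AUC exactly, which the tests assert. Inner-fit failures
  can be skipped with a logged count or raised.
* **BCa bootstrap**: patients resampled with replacement stratified by
  outcome class (preserving the events structure); bias constant z₀ from
  the fraction of bootstrap replicates below the point estimate,
  acceleration from jackknife skewness; degenerate bootstrap distributions
  collapse to a point interval with a warning. B defaults to 1,000 (200 in
  the heavier simulation studies).
* **Partial dependence**: 50 grid points spanning the 1st–99th percentile
  of the observed feature, feature forced to each grid value in every row
  (interaction recomputed), predictions averaged; rug marks are the 1–99
  data percentiles. Every PD value equals direct row enumeration (tested
  exactly).
* **Stratification**: median split on GRADX (ties to the low stratum, which
  keeps equal sizes for distinct values and is deterministic), raw-rank
  Mann–Whitney AUC of MD per stratum with "higher MD = higher risk"; an AUC
  below 0.5 is reported together with its flipped value 1 − AUC for the
  reversed risk factor.
* **Concordance screen**: Kendall tau-a by direct pair counting (ties are
  rare for continuous features; tau-b via scipy behind a flag), with the
  conversion concordance probability = (1 + τ)/2 — τ = 0.4 ⇔ 70 %.

## Synthetic-data generator

The generator emulates the *statistical structure* of an 88-patient IMRT
cohort, not its images or anatomy (volumes are analytic phantoms; no
CT/MVCT simulation):

| quantity | default | basis |
| --- | --- | --- |
| contralateral / ipsilateral MD | N(18.6, 5.9²) / N(25.6, 8.9²) Gy | published cohort summary |
| ipsi–contra dependence | Gaussian copula, Kendall τ = 0.5 (ρ = sin πτ/2) | concordance screen τ > 0.4 |
| GRADX | log-normal, median 1.27 Gy/mm, log-SD 0.5 | published median; log-SD chosen once for a plausible ×2.7 95 % spread |
| ΔVC2 | N(−2.0, 4.2²) % | published summary |
| control day / course length | integer U[28, 36] / 40 days | published design; 40 d ≈ 30 fractions |
| baseline C2 slab volume | N(200, 25²) mL | plausible neck cross-section × ~2 cm slab |
| prevalence | 11.4 % | published cohort (10/88) |
| follow-up reports | Poisson mean 4.5 per patient in 6–24 months, ±1 grade noise w.p. 0.1 | ≈ 395 reports / 88 patients |

PGM is produced through the migration chain (ΔVC2 → linear map → temporal
extrapolation), which automatically reproduces the published summaries
(median ≈ 1.03 mm, SD ≈ 2.2 mm, ≈ 68 % migrating medially).

**Outcome mechanism.** The label is Bernoulli with a logit linear in
standardized terms; the intercept is solved on each drawn cohort so the
expected prevalence is 11.4 %. The default coefficients are md 0.25,
gradx 0.59, dose_increment 0.91, where `dose_increment = GRADX·PGM/2` is
the first-order delivered-dose term. They were calibrated analytically —
via the binormal approximation AUC ≈ Φ(s/√2) with s the standard deviation
of the captured linear signal — so that the three nested models have
population AUCs near 0.57 / 0.72 / 0.79, the discrimination pattern the
package is designed to analyse; the simulated 20-cohort means come out at
≈ 0.55 / 0.70 / 0.77. A mechanism driven purely by delivered MD cannot
produce that pattern with these marginals: the 5.9 Gy MD spread dominates
the ≈ 1.8 Gy increment spread, making MD almost as good as the full model.
The weak md coefficient encodes the same phenomenon clinically attributed
to mean-dose homogenization during planning. Passing tests on these cohorts
therefore demonstrate correct estimator behaviour under a plausible
mechanism, not clinical validity on real patients — the generator has
Gaussian/log-normal marginals, independence of MD from migration, a rigid
linear motion model and no measured-image noise.

Determinism: one `numpy` seed per cohort; the pipeline fans a single run
seed out to stage seeds via `SeedSequence.spawn`, and identical seeds give
byte-identical output bundles.

## Known limitations and caveats

* The per-cohort ordering of the three models' LPO AUCs is a *mean*
  property. At the calibrated effect sizes, the model-2 → model-3 AUC gap
  (≈ 0.07) is of the same order as the sampling noise of a 10-event LPO AUC
  (≈ 0.08–0.1), so on any single 88-patient cohort the richer model loses
  to the simpler one roughly a quarter of the time; simulation studies
  should compare means over many cohorts.
* LPO-CV refits one model per positive–negative pair; at n = 88 with 10
  events that is 780 fits per AUC and ~200× that for a bootstrap interval.
  The bundled studies use B = 200 and 20 cohorts to keep a full run in
  minutes on one CPU; B = 1,000 is recommended for reporting.
* The migration slope −0.413 mm/% is borrowed from serial-imaging
  literature, not refit here; users with paired imaging should recalibrate.
* Quasi-separation is a real risk at 10 events / 5 parameters; the advisory
  error plus a small ridge is the supported remedy (no Firth correction).
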