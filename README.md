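# xerograd

Gradient- and migration-aware NTCP modelling of radiation-induced
xerostomia (dry mouth) after head-and-neck radiotherapy.

Modern IMRT plans spare the parotid glands with sharp lateral dose
falloffs, so the *planned* mean gland dose can be a poor predictor of
toxicity: when a gland drifts a millimetre or two toward the midline over a
6–8 week course, its *delivered* dose rises by roughly

    delivered MD − planned MD ≈ GRADX · PGM / 2,

where **MD** is the planned mean dose (Gy), **GRADX** the average lateral
dose gradient inside the gland (Gy/mm, medial-positive) and **PGM** the
medial parotid gland migration over the course (mm). `xerograd` implements
this reasoning end to end for biostatisticians and medical physicists:

* **Dose features** (`dosefeat`): MD and GRADX from a dose grid + structure
  mask (NIfTI or arrays), plus a delivered-dose accumulator over a
  migrating mask sequence.
* **Migration proxy** (`migration`): PGM estimated from the relative change
  of the external body contour in a slab at the C2 vertebra between
  fraction 1 and a control day, via the linear map
  `PGM_c = −0.413 mm · ΔVC2_c[%]` and linear-in-time extrapolation to the
  end of treatment.
* **Endpoint** (`endpoint`): CTCAE follow-up reports at 6–24 months pooled
  per patient (mean grade, half-up rounding) into a binary grade ≥ 2 label.
* **Models** (`model`, `evaluate`): three nested logistic models —
  `σ(β₀ + β·MD)`, `… + GRADX + MD·GRADX`, `… + PGM` — on z-scored features,
  evaluated with leave-pair-out cross-validated AUC, BCa bootstrap
  confidence intervals, 1D/2D partial dependence with percentile rug marks,
  median-GRADX cohort stratification and a Kendall-τ ipsi/contra
  concordance screen.
* **Synthetic cohorts and phantoms** (`simulate`): because clinical
  dose/imaging/toxicity data of this kind are not public, a seeded generator
  reproduces the documented cohort structure (contralateral MD
  18.6 ± 5.9 Gy, GRADX median 1.27 Gy/mm, ΔVC2 −2.0 ± 4.2 %, ~11 %
  prevalence, ipsi/contra Kendall τ ≈ 0.5) so every stage is testable.

## Worked example

```python
import xerograd as xg

sim = xg.simulate_cohort(xg.CohortSimConfig(seed=1))   # 88 patients
table = xg.to_model_table(sim.cohort)

fit = xg.XerostomiaModel(table, xg.MODEL_MD_GRADX_PGM).fit(ridge_lambda=1.0)
print(fit.summary())
```

```
Xerostomia logistic NTCP model
==============================================================
terms: md + gradx + md_x_gradx + pgm
n = 88   events = 8   ridge_lambda = 1   converged = True
--------------------------------------------------------------
term              coef   std err       z    P>|z|
const          -3.1094    0.5903   -5.27    0.000
md             -0.0684    0.4940   -0.14    0.890
gradx           1.3387    0.4477    2.99    0.003
pgm             0.8312    0.4309    1.93    0.054
md_x_gradx      0.2483    0.4609    0.54    0.590
==============================================================
```

The gradient and migration terms carry the signal; the planned mean dose on
its own does not. Cross-validated discrimination makes the same point:

```python
for spec in (xg.MODEL_MD, xg.MODEL_MD_GRADX_PGM):
    ev = xg.evaluate_model(table, spec, ridge_lambda=1.0, n_bootstrap=200, seed=2)
    print(spec.name, ev.auc, (ev.ci_low, ev.ci_high))
```

```
md:           AUC = 0.472 (95% BCa CI 0.160-0.627)
md_gradx_pgm: AUC = 0.852 (95% BCa CI 0.741-0.919)
```

i.e. on this seed the mean-dose-only model is uninformative (AUC ≈ 0.5)
while the full model identifies most toxicity patients. The same pipeline is
available from the shell:

```bash
xerograd run --seed 1 --out results/demo      # simulate → … → evaluate
xerograd features --dose dose.nii.gz --mask parotid.nii.gz --out feat.csv
xerograd migration --volumes volumes.csv --end-day 40 --out migration.csv
```

`xerograd run` writes the cohort/label/migration CSVs, per-model evaluation
JSONs, partial-dependence grids, a stratification report and a checksummed
manifest; the same seed reproduces the bundle byte for byte.

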