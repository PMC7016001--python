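# meniscus-qmri

Stress-MRI analysis of human meniscus functionality — the tissue's response
to compressive loading — for researchers working with quantitative MRI of
loaded cartilage and meniscus samples.

An ex-vivo loading experiment images a wedge-shaped meniscus body sample at
three positions — unloaded (δ₀), 2 bar ≈ 37.1 N (δ₁) and 4 bar ≈ 69.1 N
(δ₂) — and maps the relaxation times T1 (inversion recovery), T1ρ
(spin-lock) and T2 (multi-echo) at each position.  This package implements
the full analysis chain plus a synthetic cohort generator with known ground
truth:

* **Relaxometry** — voxelwise mono-exponential fits
  `S(TE) = A·exp(−TE/T2)`, `S(TSL) = A·exp(−TSL/T1ρ)` and the
  magnitude-inversion-recovery model `S(TI) = |a + b·exp(−TI/T1)|` with
  polarity restoration, solved by variable projection to optimizer
  tolerance, vectorised over pixels.
* **Zonal geometry** — boundary-pixel exclusion (one 8-connectivity
  erosion) and partition of the segmented cross-section into mediolateral
  thirds: apex (I), intermediate (II) and base (III) zones.
* **Response to loading** — per-ROI medians (IQR) per position and the
  per-sample relative change
  `Δᵢ = (value(δᵢ)/value(δ₀) − 1)·100 %`.
* **Biomechanics** — the two-parameter exponential hyperelastic model
  `σ(ε) = c·(exp(bε) − 1)` fitted to unconfined-compression data, with the
  tangent Elastic Modulus `EM(ε) = c·b·exp(bε)` evaluated at 20 % and 80 %
  strain.
* **Histology** — Pauli semiquantitative degeneration scoring (sum 0–18,
  Grades I–IV, Grades III/IV collapsed to ≥III).
* **Cohort statistics** — Kruskal–Wallis across degeneration grades,
  Friedman + Dunn's post-hoc across loading positions, ANOVA/t-tests for Δ
  values with D'Agostino–Pearson normality screening, repeated-measures
  ANOVA for pixel counts, and Spearman correlations between qMRI and
  Elastic Modulus; omnibus α = 0.005.

Real data enter as NIfTI image stacks and masks plus CSV stress–strain
curves and score tables; the `synthetic_cohort` generator produces complete
in-silico cohorts calibrated to published cohort statistics so that every
stage is testable end to end.

## Worked example

```python
from meniscus_qmri import (PhantomSpec, generate_cohort, analyze_sample,
                           summarize_maps, delta_table, fit_exponential)

spec = PhantomSpec(n_samples=9, grade_fractions=(1/3, 1/3, 1/3), seed=42)
cohort = generate_cohort(spec)
sample = cohort.samples[0]          # a grossly intact (Grade-I) sample

states = analyze_sample(sample, spec.apex_side)   # erode, partition, fit maps
summary = summarize_maps(states, sample.sample_id, sample.truth.grade_group)
print(summary[(summary.contrast == "T1rho") & (summary.roi == "I")]
      [["load", "median", "q1", "q3", "pixel_count"]].to_string(index=False))
```

```
  load    median        q1        q3  pixel_count
delta0 33.597424 32.124001 35.077416           79
delta1 50.950110 48.062921 52.604532           69
delta2 46.483344 44.749760 48.495712           56
```

The apex-zone T1ρ median of this intact sample *rises* under loading while
its pixel count falls (the wedge flattens), the physiological response
pattern.  The relative changes and the biomechanical fit:

```python
deltas = delta_table(summary)
apex = deltas[(deltas.roi == "I") & (deltas.contrast == "T1rho")]
print(f"apex T1rho Delta1 = {apex.delta1.iloc[0]:.1f} %, "
      f"Delta2 = {apex.delta2.iloc[0]:.1f} %")

print(fit_exponential(sample.curve).summary())
```

```
apex T1rho Delta1 = 51.6 %, Delta2 = 38.4 %
Exponential stress-strain fit: sigma = c*(exp(b*eps) - 1)
==========================================================
sample:         S01
n points:       101
b (nonlinearity)       6.3332   (se 0.0894)
c [MPa]                0.3698   (se 0.0308)
residual norm          40.706 MPa
EM(20%) [MPa]          8.3116
EM(80%) [MPa]          371.51
```

A positive apex Δ and an Elastic Modulus rising from ~8 MPa at low strain
to ~370 MPa at 80 % strain are typical of intact, strongly strain-stiffening
meniscus tissue.

The whole pipeline (simulate → fit → partition → summarise → statistics →
report tables) runs as one command:

```bash
meniscus-qmri run --out run_dir --seed 1
```

which writes long-format summary CSVs, cohort report tables (absolute
medians with Friedman/Dunn and Kruskal–Wallis results; Δ means ± SD with
t-test and ANOVA results), biomechanics fits, graded Pauli scores,
qMRI–biomechanics correlations and a provenance record with file hashes.
Individual stages are available as `meniscus-qmri
{simulate,fit-maps,partition,response,biomech,score,stats}`.

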