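# shrinkmr

Semi-empirical Bayes calibration of sex-stratified GWAS effect estimates,
embedded in a two-sample Mendelian randomization (MR) toolkit.

## Why

Sex-specific MR needs sex-specific variant–exposure estimates, but one
stratum is often much smaller (e.g. 2,000 women vs 20,000 men in a
veterans' cohort). The small stratum's per-SNP estimates γ̂ are noisy, its
instruments weak (F-statistics near or below 10), and its causal estimates
biased and imprecise. `shrinkmr` calibrates the small stratum's estimates by
borrowing information from the large one *adaptively*: for each SNP a
normal prior built from the donor stratum shrinks the raw estimate toward
the cross-stratum meta-analysis value, with the amount of borrowing
controlled by the observed between-stratum difference.

Three estimators come out of the same normal–normal posterior:

- **FE-meta** — prior N(γ̂_M, σ̂²_M); the posterior is exactly the
  fixed-effects inverse-variance meta-analysis of the two strata.
- **APM** (adaptive posterior mean) — prior mean γ̂_meta, prior variance
  δ² = (γ̂_F − γ̂_M)² + σ̂²_M; posterior mean
  (δ²·γ̂_F + σ̂²_F·γ̂_meta)/(δ² + σ̂²_F). SNPs with strong apparent sex
  differences keep their raw estimate; concordant SNPs are shrunk hard.
- **AW** (adaptive weight) — the APM limit with δ² = (γ̂_F − γ̂_M)².

The posterior mean/SD then replace beta/se in any downstream two-sample MR
method. The package ships the full pipeline: summary-statistic I/O and
allele harmonization, p-value + LD-clump instrument selection,
F-statistics, ten MR estimators (IVW variants, Egger, weighted median,
contamination mixture, constrained ML, RAPS, multivariable IVW), a
sex-difference z-test with BH-FDR, a fully seeded simulator of the
sex-stratified two-sample design, and a replicate-level evaluation harness
(MSE, coverage, rejection rates).

## Worked example

Simulate one replicate of the default design (2,000-female / 20,000-male
exposure GWASs, 100 independent SNPs, MAF 0.3, true β_F = β_M = 0.1),
calibrate the female stratum with APM, and estimate the female causal
effect with RAPS:

```python
from shrinkmr import (SimConfig, simulate_replicate, CalibrationModel,
                      TwoSampleMR, f_statistics, sex_difference_test)
from shrinkmr.evaluate import harmonized_from_aligned

cfg = SimConfig(scenario="fixed_diff", d_size=10, seed=7)
rep = simulate_replicate(cfg, rep_seed=0)

print("raw female mean F:", round(f_statistics(rep.exposure_female).mean_F, 2))
calib = CalibrationModel(rep.exposure_female, rep.exposure_male).fit("apm")
print("APM female mean F:", round(f_statistics(calib.table).mean_F, 2))
print(calib.summary().head(3).round(4).to_string(index=False))

h_F = harmonized_from_aligned(calib.table, rep.outcome_female)
est_F = TwoSampleMR(h_F, calibration="apm").fit("raps")
print(est_F)

h_M = harmonized_from_aligned(rep.exposure_male, rep.outcome_male)
est_M = TwoSampleMR(h_M).fit("raps")
sd = sex_difference_test(est_F, est_M)
print(f"sex difference: {sd.diff:+.4f} (z={sd.statistic:.2f}, p={sd.pvalue:.3f})")
```

Output:

```
raw female mean F: 6.02
APM female mean F: 17.32
variant_id  raw_beta  raw_se  posterior_mean  posterior_sd  weight_on_raw estimator
    rs0001    0.0656  0.0398          0.0697        0.0126         0.0998       apm
    rs0002    0.1209  0.0403          0.1037        0.0267         0.4375       apm
    rs0003    0.0179  0.0397          0.0344        0.0328         0.6840       apm
<CausalEstimate raps: beta=0.0689 (95% CI 0.0292, 0.1086), p=0.000667, n_iv=100>
sex difference: +0.0105 (z=0.36, p=0.721)
```

Reading it: calibration roughly triples the female instrument strength
(mean F 6.0 → 17.3). Per SNP, `weight_on_raw` shows the adaptivity —
rs0001's female and male estimates agree, so it is shrunk hard toward the
meta value (weight 0.10 on the raw estimate), while rs0003 keeps most of
its own signal. The female causal estimate 0.069 (95% CI 0.029–0.109)
covers the truth 0.1, and the sex-difference test is correctly
non-significant since β_F = β_M here.

The same steps are available from the shell:

```sh
shrinkmr simulate --config cfg.yaml --out sim/
shrinkmr calibrate --target sim/exposure_female.tsv --donor sim/exposure_male.tsv \
         --estimator apm --out calibrated.tsv
shrinkmr select-iv --input calibrated.tsv --threshold 1e-5 --out ivs.tsv
shrinkmr mr --exposure sim/exposure_female.tsv --outcome sim/outcome_female.tsv \
         --method raps --calibrate apm --donor sim/exposure_male.tsv --out result.tsv
shrinkmr evaluate --config cfg.yaml --reps 200 --seed 7 --out report.tsv
```

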