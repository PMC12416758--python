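# Methods

## The problem

Sex-stratified Mendelian randomization (MR) is often limited by one stratum's
GWAS sample size. When the female exposure GWAS is an order of magnitude
smaller than the male one, the female variant–exposure estimates
γ̂<sub>jF</sub> are noisy, instruments are weak (per-SNP F-statistics near or
below 10), and downstream causal estimates β̂<sub>F</sub> inherit
weak-instrument bias and poor precision.

`shrinkmr` implements a semi-empirical Bayes calibration that borrows
information from the larger stratum *adaptively* — strongly where the two
strata's estimates look similar, weakly where they differ — and feeds the
calibrated estimates into a standard two-sample MR pipeline.

## The calibration model

For SNP *j*, let (γ̂<sub>F</sub>, σ̂<sub>F</sub>) and (γ̂<sub>M</sub>,
σ̂<sub>M</sub>) be the raw per-stratum estimates with standard errors, and
assume γ̂<sub>F</sub> ~ N(γ<sub>F</sub>, σ̂<sub>F</sub>²) (reasonable at GWAS
sample sizes). A normal prior γ<sub>F</sub> ~ N(θ, τ²) yields a normal
posterior; the three estimators differ only in (θ, τ²):

| estimator | prior mean θ | prior variance τ² | posterior mean |
|---|---|---|---|
| `fe_meta` | γ̂<sub>M</sub> | σ̂<sub>M</sub>² | inverse-variance meta-analysis of the two strata |
| `apm` | γ̂<sub>meta</sub> | δ² = (γ̂<sub>F</sub>−γ̂<sub>M</sub>)² + σ̂<sub>M</sub>² | (δ²·γ̂<sub>F</sub> + σ̂<sub>F</sub>²·γ̂<sub>meta</sub>)/(δ² + σ̂<sub>F</sub>²) |
| `aw` | γ̂<sub>meta</sub> | δ²<sub>AW</sub> = (γ̂<sub>F</sub>−γ̂<sub>M</sub>)² | as APM with δ²<sub>AW</sub> |

Posterior variance is 1/(1/σ̂<sub>F</sub>² + 1/τ²) in all cases, so the
reported SD never exceeds the raw SE. The adaptive posterior mean (APM) is
the workhorse: its prior variance grows with the *observed* sex difference,
so a SNP with a large apparent difference keeps its raw estimate, while a
concordant SNP is shrunk toward the efficient meta-analysis value. The AW
estimator is the limiting form with the donor sampling variance removed from
δ²; when γ̂<sub>F</sub> = γ̂<sub>M</sub> exactly, δ²<sub>AW</sub> = 0 is a
degenerate (infinitely precise) prior and the implementation falls back to
the FE-meta posterior with a `fallback` flag.

Posterior SDs are treated downstream as standard errors without further
inflation, and posterior p-values are recomputed from the two-sided normal
tail of mean/SD. Calibration is symmetric by role: the male stratum can be
calibrated with the female stratum as donor by the same code. Each variant
is calibrated independently; there is no cross-variant pooling.

## The MR layer

Estimators consume allele-harmonized per-variant exposure effects γ̂ (raw or
calibrated) and outcome effects Γ̂ with SEs:

- **Wald ratio** Γ̂/γ̂ with first-order SE σ̂<sub>Γ</sub>/|γ̂|.
- **IVW** (fixed): weighted mean of ratios, weights γ̂²/σ̂<sub>Γ</sub>².
  *Penalized* multiplies weights by min(1, 20·p<sub>j</sub>) where
  p<sub>j</sub> is the χ²₁ tail of the IV's Cochran-Q contribution; *robust*
  replaces the origin regression with an MM-type Tukey fit (statsmodels RLM).
- **Egger**: precision-weighted regression of Γ̂ on γ̂ with intercept
  (average directional pleiotropy), instruments oriented to γ̂ ≥ 0; the
  residual scale multiplier is floored at 1 so underdispersion never shrinks
  the SE.
- **Weighted median**: inverse-first-order-variance weights
  γ̂²/σ̂<sub>Γ</sub>², cumulative-weight interpolation at 0.5; SE by
  parametric bootstrap (1,000 draws, fixed seed).
- **Contamination mixture**: per-IV ratio modelled as valid
  N(β, se<sub>j</sub>²) or invalid N(0, ψ² + se<sub>j</sub>²); hard
  classification at each point of a β grid (range of ratios ± 3 SD, ≥1,000
  points), likelihood-ratio 95% set with multimodality flagged. Auto ψ is
  1.5× the SD of the ratio estimates; a smaller ψ makes the invalid
  component mimic the valid ratios' sampling spread and the hard
  classification then eats the tail nearest zero, biasing the estimate away
  from the null (a known hazard of max-classification mixtures).
- **cML**: profiled bivariate-normal likelihood with exactly K instruments
  allowed free direct effects; coordinate descent alternates invalid-set
  selection (K largest standardized deviations) with a 1-D β optimization;
  K chosen by BIC with n = median min(exposure n, outcome n); SE from the
  profile curvature at the selected K (model averaging not applied).
- **RAPS**: solves the adjusted profile score equations. The residual
  t<sub>j</sub>(β) = (Γ̂<sub>j</sub> − βγ̂<sub>j</sub>)/√(σ̂<sub>Γj</sub>² +
  β²σ̂<sub>γj</sub>² + τ²) is passed through a ψ-function (Tukey c = 4.685
  by default; Huber 1.345 and plain L2 available); the β-score direction
  a<sub>j</sub> = (σ̂<sub>Γj</sub>²γ̂<sub>j</sub> +
  βσ̂<sub>γj</sub>²Γ̂<sub>j</sub>)/v<sup>3/2</sup> has mean zero at the
  truth even under weak instruments. Overdispersion τ² ≥ 0 solves the
  precision-weighted moment equation Σ(ψ(t)t − E[ψ(Z)Z])/v = 0; β and τ²
  are iterated to convergence with the β root bracketed around the IVW
  estimate ± 10 SE and up to 3 jittered restarts. SEs are sandwich
  variances of the β-score.
- **MV-IVW**: weighted regression of Γ̂ on several exposures' effect columns
  without intercept; exposures with identically zero effects are excluded
  and reported as uninformative (SE = ∞); rank-deficient non-trivial designs
  raise.
- **Sex-difference test**: z = (β̂<sub>F</sub> − β̂<sub>M</sub>)/√(se
  <sub>F</sub>² + se<sub>M</sub>²) against the standard normal (GWAS-scale
  degrees of freedom make a t reference indistinguishable), with optional
  Benjamini–Hochberg FDR across a batch.

All intervals are β̂ ± 1.96·se. Binary-trait effects are log-odds ratios
throughout; odds ratios are exp(β) at presentation only.

## Instrument selection

`pvalue_filter` keeps p < threshold (the pipeline default for sparse strata
is 1e-5; genome-wide 5e-8 is available). `greedy_clump` iterates by
ascending p-value and keeps a variant iff no already-kept same-chromosome
variant is both within the window (default 10,000 kb) *and* has r² above the
threshold (default 0.001); ties on p break lexicographically by variant id.
When no LD information is supplied the variants are treated as independent
and clumping reduces to the p-value ordering. Instrument strength is the
squared z-statistic F = (β̂/σ̂)² per variant and its arithmetic mean.

## The simulator

`simulate_replicate` emulates a sex-stratified two-sample design: exposure
GWASs of 2,000 females and 20,000 males, outcome GWASs of 10,000 each, 100
independent biallelic SNPs with allele frequency 0.3, genotypes
Binomial(2, 0.3). Exposure X = Gγ<sub>s</sub> + N(0, 1) per stratum; in the
*independent* outcome panels the exposure is regenerated and
Y = β<sub>s</sub>X + Gα + N(0, 1), with α per-SNP direct (pleiotropic)
effects: zero, balanced N(0, 0.01²), or directional N(0.02, 0.01²).
Per-SNP marginal linear regressions produce summary tables (a vectorized
Newton logistic variant exists behind `binary_traits`, off by default —
continuous traits make the true causal effect exact).

Male baseline effects default to |N(0.08, 0.03²)| (γ̂/σ̂ puts the small
female stratum in the weak-instrument regime, mean F ≈ 6, while the male
stratum is strong, F ≈ 50). Sex-difference scenarios:

- `fixed_diff`: γ<sub>F</sub> = γ<sub>M</sub> + 0.05 on the first `d_size`
  SNPs (default 10);
- `random_diff`: differences N(0, 0.05²) on every SNP, or a configurable
  correlation between the two strata's effects;
- `osa_guided`: a deterministic packaged fixture (`osa_like_fixture`,
  regenerable from its seed) emulating an obstructive-sleep-apnea-like
  architecture — every SNP differs between sexes, female effects are weak
  (γ<sub>F</sub> ≈ 0.3·γ<sub>M</sub> + N(0, 0.02²)) so the female mean F at
  n = 2,000 stays well below 10. It is a synthetic stand-in; the real
  sex-stratified sleep-apnea effect table is not distributed with the
  package.

True causal effects default to β<sub>F</sub> = β<sub>M</sub> = 0.1.
Replicates are bitwise reproducible from (config.seed, rep_seed).

What the simulator does *not* emulate: LD between SNPs, sample overlap
between exposure and outcome GWASs, population stratification, binary-trait
ascertainment, and the exact (unpublished) effect-size distributions of the
motivating cohort. Passing tests therefore demonstrate correctness of the
estimators and the qualitative regime behaviour (weak instruments, shrinkage
gains), not calibration against any particular real dataset.

## Evaluation harness

`run_study` simulates replicates, calibrates each stratum's exposure table
with the other stratum as donor (per requested estimator), fits the
requested MR methods, and aggregates: MSE of β̂<sub>F</sub> about the truth
with Monte Carlo SE (SD of squared errors/√R), 95% CI coverage, rejection
rates of β = 0 and of β<sub>F</sub> = β<sub>M</sub> at α = 0.05, and the
raw-vs-calibrated mean F-statistics. Replicate-level estimator failures are
counted and reported, never silently dropped.

## Benchmark configurations used by the test suite

- **Default design** (the study conditions above): used for the F-gain
  check (APM raises the female mean F more than 3-fold), the weak-instrument
  check (OSA-guided female mean F < 10), the shrinkage-benefit checks
  (MSE of β̂<sub>F</sub> with APM inputs below raw inputs at |D<sub>γ</sub>|
  ∈ {10, 100} and under the OSA regime), and the sex-difference power
  ceiling under weak instruments (≤ 0.4 at a true difference of 0.1).
- **Strong-IV variant of setting 1** (`n_exp_F = 20,000`, otherwise
  default): RAPS coverage of β<sub>F</sub> and type-I error of the
  sex-difference test. With the female exposure GWAS matched to the male
  one, per-SNP female F ≈ 50.
- **Idealized consensus benchmark** (30 SNPs, per-allele effects ~0.3,
  exposure GWASs 100k, outcome GWASs 400k): used only to check that all MR
  methods agree with each other and the truth within Monte Carlo error.
  Per-IV outcome z-statistics ≈ 6 put every estimator in its asymptotic
  regime; at routine GWAS signal strengths the median- and mixture-type
  estimators carry small, well-understood finite-sample biases (weight–noise
  correlation; one-sided absorption by the hard-classified invalid
  component) that a consensus test would otherwise flag.

Replicate counts (200 for F-statistics and consensus, 300 per
shrinkage-benefit condition, 500 for power, 1,000 for type-I/coverage) keep
Monte Carlo error comfortably below the margins being asserted while the
full suite runs on a single CPU in well under half an hour.

## Numerical choices and edge cases

- Degenerate AW prior (exactly equal strata): FE-meta fallback, flagged.
- Exact-fit data (zero residuals): robust regressions short-circuit to the
  OLS solution since the MAD scale collapses; SEs are floored at 1e-12.
- p-values are floored at 1e-300; CIs use 1.96 exactly.
- RAPS ψ-moments E[ψ(Z)Z], E[ψ(Z)²] are computed once by quadrature and
  cached.
- Harmonization: palindromic (A/T, G/C) variants are dropped when the
  minor-allele frequency is within 0.08 of 0.5 in either table
  (`drop_ambiguous` default), oriented by frequency otherwise; strand flips
  are attempted only after direct and swapped matches fail; aligned tables
  disagreeing in frequency by more than 0.2 are excluded (`eaf_mismatch`).
  Variants with a missing frequency degrade to `drop_all` behaviour.
- Greedy clumping treats records without coordinates as always within the
  window (conservative).

## Known limitations

- The contamination-mixture point estimate retains a small away-from-null
  bias whenever β is within a couple of invalid-component SDs of zero; this
  is a property of hard-classification mixture likelihoods, not of this
  implementation.
- cML standard errors come from the profile curvature at the selected K and
  ignore selection uncertainty.
- MVMR conditional instrument-strength diagnostics are not provided.
- Correlated instruments (LD-aware MR) and sample overlap corrections are
  out of scope.
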