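# Methods

## Model

Isoform-level expression is estimated, not observed. For one isoform,
let `Y_i` be sample *i*'s estimated FPKM and `σ0_i` its standard error, both
produced by an expression-estimation program (e.g. Cufflinks). After
normalization and log transformation the package fits, per isoform,

    log(Y_i) = β0 + β1 x_i + β2' z_i + u_i + e_i,
    u_i ~ N(0, σ1_i²),   e_i ~ N(0, τ²),   u_i ⟂ e_i,

where `x_i` is the two-level condition of interest (coded 0/1), `z_i` are
optional covariates, `u_i` is the estimation error of `log(Y_i)` with *known*
variance `σ1_i²`, and `e_i` is biological (between-sample) variation with
unknown variance `τ²`. Marginally `log(Y_i) ~ N(x_i'β, σ1_i² + τ²)`: this is
exactly the random-effects meta-regression model, with each sample playing
the role of a "study" whose squared standard error is known. The hypothesis
of no differential expression is `H0: β1 = 0`.

`σ1_i²` is carried from the FPKM scale to the log scale by the delta method,
`Var[log Y] ≈ σ0² / Y²`, with the observed (normalized, offset-adjusted)
FPKM plugged in for the unobservable `E(Y)`. Zero FPKM values are replaced by
a small offset (default `1e-4`) before taking logs so the transform stays
finite; only exact zeros are touched.

## Estimation

For fixed `τ²` the likelihood is maximized in `β` by weighted least squares
with weights `1/(σ1_i² + τ²)`, giving a one-dimensional profile likelihood in
`τ²`. The ML estimate of `τ²` is found by a bounded Brent search on
`[0, 10·var(y)]` (absolute tolerance `1e-10`), with the `τ² = 0` boundary
evaluated explicitly so boundary solutions are reported as exactly zero.
The search is deterministic; there is no random initialization. `τ²` is
estimated by maximum likelihood rather than REML because the likelihood-ratio
machinery below is defined on the ML likelihood.

`β̂` covariance is the inverse of the weighted normal-equations matrix
evaluated at `τ̂²`.

## Tests

* **t-test.** `t = β̂1 / se(β̂1)` referred to a t distribution on `n − p`
  degrees of freedom, where `p` counts all fixed-effect columns including the
  intercept (`n − 3` for intercept + condition + one covariate). Note the ML
  `τ̂²` carries no degrees-of-freedom correction, so this test is mildly
  anticonservative in small samples (empirically ≈ 0.06 at nominal 0.05 for
  n = 32); the Bartlett-corrected test below is the calibrated option.
* **Bartlett-corrected LR test (BcLR).** `LR = 2(ℓ − ℓ0)` with `ℓ0` the
  maximized log-likelihood after dropping the tested column (re-estimating
  `τ²`). The corrected statistic `BcLR = BCF × LR` is referred to χ²(1). The
  correction factor is estimated by parametric bootstrap: simulate `n_boot`
  datasets from the fitted null model (null WLS mean, marginal variances
  `σ1_i² + τ̂0²`), recompute `LR*` for each with a vectorized golden-section
  profile search, and set `BCF = 1 / mean(LR*)` — the factor that restores the
  defining Bartlett property `E[BCF·LR] = 1` for one degree of freedom. An
  analytic closed-form correction is not provided; the bootstrap (default
  `n_boot = 1000`, minimum 200; fully seeded) is the supported estimator.
  Monte-Carlo noise in `BCF` scales as `√(2/n_boot)` (≈ 10 % at 200 draws).

Negative LR values within `1e-6` (optimizer noise) are clipped to zero;
anything more negative raises a convergence error rather than being silently
accepted.

## Pipeline

Per dataset: (1) median-of-ratios size factors (rows with any zero excluded
from the median; FPKM and SE columns both divided by the factor, since SEs
scale linearly under division by a constant); (2) zero offset + natural log;
(3) delta-method variances; (4) CV filter; (5) per-isoform fit and tests;
(6) Benjamini–Hochberg adjustment over the tested isoforms, each test type
adjusted separately, with DE declared by the strict rule `q < level`.

The **CV filter** drops isoforms whose normalized FPKM (before the log) has
coefficient of variation above 0.4 — sample SD with the `n−1` denominator
over mean — in *either* group, and isoforms whose mean is zero in any group.
High-CV isoforms are typically low-expression isoforms whose delta-method
log-variance approximation is poor; keeping them inflates false positives.
Isoforms whose fit fails to converge are flagged and excluded from the BH
denominator. Bootstrap seeds are derived deterministically per isoform from
the run seed, so results are byte-identical across repeated runs.

## Synthetic data

The generator emulates a two-group isoform study at the level of expression
*estimates* (it does not simulate reads, alignment or deconvolution — those
stages are out of scope). Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_cases`, `n_controls` | 16, 16 | samples per group |
| `frac_de` | 0.30 | fraction of isoforms DE (half up, half down) |
| `fold_change` | 1.25 | case/control fold for DE isoforms |
| `frac_cov_affected` | 0.10 | covariate-driven isoforms (II/III), half DE |
| `cov_fold_per_sd` | 1.35 | fold per covariate SD (≡ 2.5 %/unit for U(18,60)) |
| covariate ranges | U(18,60); cases U(40,85) in III | covariate vs confounder |
| `depth_range` | U(8e6, 1.2e7) | mapped reads per sample |
| `tau_range` | U(0.1, 0.4) | per-isoform biological SD on the log scale |
| `uncertainty_scale` | 1.0 | scales σ1_i² = scale/(count+1) |

Baseline abundance is log-normal (`log FPKM ~ N(log 20, 1)`), a standard
heavy-tailed stand-in for transcript abundance laws; transcript lengths are
log-normal around 1.8 kb (clamped to 200–50 000 bp). The estimation-noise
variance is Poisson-motivated: `σ1_i² = 1/(expected fragment count + 1)`,
floored at `1e-6` and capped at 4, with the expected count from
`FPKM × N × L / 10⁹`. Reported FPKM is `exp(truth + e + u)` and the reported
SE is `FPKM·σ1_i`, which the delta method inverts exactly — so the
meta-regression's distributional assumptions hold *exactly* on the log scale.
Passing calibration tests on these data therefore validates the inference
machinery, not the delta approximation itself on real (skewed,
count-quantized, biased) estimates; the `tau_range` is a chosen magnitude,
not an empirically fitted one. The confounder scenario's per-unit slope is
anchored to the control range so Scenarios II and III share one effect size.

The generator is deterministic under its seed, and truth bookkeeping is
exact: `round(frac_de · n)` DE isoforms split half up / half down (integer
division, down gets the odd one), covariate-affected isoforms split half DE /
half non-DE.

## Evaluation

Empirical FDR = truly non-DE among declared DE (0 when nothing is declared);
power = declared among truly DE, optionally restricted to a mask such as the
covariate-affected DE isoforms; ROC points enumerate every distinct p-value
cutoff with the (0,1) and (1,0) endpoints included.

## Problem sizes

Statistical checks in the test suite and the acceptance script use
desk-scale designs chosen as a deliberate trade-off between Monte-Carlo
resolution and runtime: 2000-isoform datasets with 5 replicate seeds for the
pipeline FDR experiment (bootstrap `n_boot = 200` there), 5000 replicates for
t-test calibration, 2000 replicates (`n_boot = 400`) for the Bartlett
property at n = 8, 50 problems for the grid-search oracle comparison, and
20/10 replicates for the covariate/confounder directional contrasts.

## Known limitations

* The closed-form Bartlett factor is not implemented; only the bootstrap.
* Designs beyond two groups + real covariates (paired samples, time courses)
  are unsupported, as is gene-level aggregation of isoform results.
* The t-test inherits the small-sample anticonservativeness of ML variance
  estimates (see above); use BcLR when calibration matters.
* The Cufflinks reader treats the reported 95 % confidence bounds as a
  symmetric normal interval, `σ0 = (hi − lo)/(2 × 1.959964)`; markedly
  asymmetric bounds are averaged and logged.
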