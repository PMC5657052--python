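# Methods

This note documents the statistical model, the solver, the multi-step
workflow, and the numerical and design choices behind them.

## The model

The package fits the linear phenotype model

    y = mu + X beta_m + X_i X_j beta_e + e,      e ~ N(0, sigma^2),

where `X` is an n x k matrix of normalized feature values (in the
motivating application, miRNA expression mapped to standard-normal
quantiles), `beta_m` are per-feature **main effects**, and `beta_e` are
coefficients of pairwise **epistatic** terms — elementwise products
`X_i * X_j` of two feature columns.  The phenotype in the motivating
application is the natural log of the ordinal AJCC pathological stage
(I–IV mapped to 1–4), treated as continuous.

With k features there are k(k-1)/2 candidate pairs (70,500 for k = 376),
so the design is heavily over-saturated and estimation needs both
sparsity and a significance test per selected term.

## The Empirical Bayesian Elastic Net solver

`eben.core` implements a sparse Bayesian regression with a two-level
prior: each coefficient has

    beta_k | alpha_k  ~  N(0, sigma0^2 / alpha_k),

with a generalized-Gamma hyperprior on the alpha_k controlled by two
elastic-net-like hyperparameters `lambda1`, `lambda2`.  The prior
variance is deliberately scaled by the noise variance `sigma0^2` — the
standard parameterization in this empirical-Bayes family — which makes
every selection statistic below exactly invariant under rescaling of
the response, and makes the posterior mean independent of `sigma0^2`
given the alphas.

Writing `C0 = I + X_A A^-1 X_A^T` for the (noise-normalized) marginal
covariance of the response under the active set A, each candidate
column x_k carries the sparsity/quality statistics

    s_k = x_k^T C0^-1 x_k,        q_k = x_k^T C0^-1 y~ / sigma0,

(deflated by the feature's own contribution when it is in the model:
s <- alpha s/(alpha - s), likewise q).  The marginal log posterior of a
single alpha is

    L(alpha) = 1/2 [ log( alpha/(alpha + 1 + s) ) + q^2/(alpha + 1 + s) ]
               - lambda2 / alpha ,

and a feature may carry a finite alpha only when the strict gate

    q^2 - s > lambda1 + 2 lambda2

holds.  `lambda1` appears only in this gate; `lambda2` additionally
penalizes L.  Setting dL/dalpha = 0 reduces to a quadratic in alpha,

    A a^2 + B a + C = 0,   A = (1+s)/2 - q^2/2 + lambda2,
    B = (1+s)^2/2 + 2 lambda2 (1+s),   C = lambda2 (1+s)^2,

with a positive (maximizing) root iff A < 0; for lambda2 = 0 it
collapses to alpha* = (1+s)^2/(q^2 - 1 - s).  The vectorized scan uses
this exact root; the scalar `optimal_alpha` keeps a bracketed numeric
maximizer as an independent path, and the tests assert the two agree.

### Column scaling

The objective's constants (the `+1` next to `s`, the useful range of
the lambda gate) presume O(1) statistics, i.e. unit-norm columns.  The
solver therefore rescales every candidate column to unit L2 norm
internally and converts `beta`/`se` back to the caller's units on
output (`t`, `p` and predictions are unaffected).  Without this, a
quantile-normalized column has ||x||^2 ≈ n, the gate never binds for
any lambda below ~n, and greedy selection degenerates.

### Greedy coordinate ascent

Starting from an empty model (seeded with the column of largest
absolute correlation with the centered response), each iteration
computes alpha*_k for every candidate, classifies the implied move —
add (inactive, finite alpha*), re-estimate (active, finite), delete
(active, infinite) — and applies the single move with the largest
ascent gain dL = L(alpha*) - L(alpha_current), with L(inf) = 0.  No
positive gain means a no-op.

The noise variance is initialized small, `sigma0^2 = 0.1 y~^T y~ / n`,
and re-estimated **once per outer pass**: greedy moves run at fixed
`sigma0^2` until no positive-gain move remains (or the alpha changes
drop below `alpha_change_tol` / `norm_change_tol`, both 1e-6), then one
evidence update

    sigma0^2 <- ||y~ - X_A beta||^2 / (n - sum_k gamma_k),
    gamma_k = 1 - alpha_k Sigma_kk,

is applied and all statistics are recomputed exactly from scratch.  The
fit has converged when a pass proposes no action and `sigma0^2` is at
its fixed point; a hard cap (`max_iterations = 1000` actions) guards
degenerate cases with a warning.

Within a pass, the S/Q statistics, the posterior covariance
`Sigma = (X_A^T X_A + diag(alpha))^-1` and `beta = Sigma X_A^T y~` are
maintained by the standard rank-one add/delete/re-estimate update
formulas with the active-set Gram cached incrementally; the pass-boundary
recompute bounds any float accumulation, and a test asserts the
incremental and from-scratch paths agree to 1e-8.  When the deflation
denominator `alpha - S` of an active feature is non-positive in floats
(a perfectly fit column at the noise floor), that feature is simply
excluded from candidate moves for the iteration rather than force-deleted
with a spurious infinite gain.

### Inference on selected coefficients

The posterior covariance of beta is `sigma0^2 Sigma`, so each selected
coefficient gets `se = sigma0 sqrt(Sigma_kk)`, `t = beta/se`, and a
two-sided p-value from a Student-t reference with
`df = n - |active| - 1` (the intercept is absorbed in mu).  This is a
posterior shrinkage test, not a selection-adjusted test: p-values of
terms that were selected *because* they looked strong are optimistic,
which is why the workflow's raw 0.05 thresholds (below) control false
discoveries only together with a sparse selection stage.

## Hyperparameter selection

`eben.cv` chooses `(lambda1, lambda2)` by k-fold cross-validated
held-out squared error on a log-spaced grid, default
`{0.001, 0.01, 0.1, 1}^2` with 5 simple-random folds shared across the
grid.  Fold models predict `mu + X_test beta` over their selected
features, with interaction-column centering always taken from the
training rows.

Selection uses the **one-standard-error rule**: the sparsest point
(largest `lambda1 + 2 lambda2`) whose mean error is within one standard
error of the minimum.  On pairwise scans the grid points differ by far
less than the fold-to-fold noise (differences of ~0.02–0.04 against a
fold SE of ~0.1 in the calibration studies), so a literal argmin lets
noise pick a dense model whose spurious terms then survive the raw
p < 0.05 filters; the 1-SE rule is the standard formalization of
"prefer the sparser model for stability".  Strict minimization remains
available (`rule="min"`).  For speed, the exploratory fold fits are
truncated at 300 greedy actions — held-out error stabilizes once the
model composition settles — while the final fit at the chosen point
uses the full budget.

## The four-step workflow

Strong main effects can mask interaction signals in a one-shot joint
scan.  `eben.workflow` therefore runs:

1. **Main scan** — CV-tuned EBEN fit over the k main-effect columns
   only; keep features with p < 0.05.
2. **Phenotype correction** — `y' = y - X'_m beta'_m` over the
   significant main effects (mu is not subtracted; step 3 re-estimates
   its own mean).
3. **Epistasis scan** — CV-tuned EBEN fit over all k(k-1)/2 centered
   product columns only (no main columns), against y'; keep pairs with
   p < 0.05.  Product columns are generated in blocks (default 1,000)
   so the full pair design never has to exist in memory.
4. **Unified refit** — CV-tuned EBEN fit of the selected main + pair
   columns jointly against the *original* y; the final table reports
   the terms that remain significant at p < 0.05.

Each step re-runs CV because the candidate designs differ by orders of
magnitude in width.  No multiple-testing correction is applied by
default (an optional Benjamini–Hochberg adjustment of the final
p-values is exposed via `WorkflowConfig(fdr=True)` / `--fdr`).
Interaction columns are centered raw products of the normalized
features, not re-normalized.

## Preprocessing

`eben.preprocess` turns a raw feature x sample table and clinical stage
labels into model inputs: features missing in strictly more than 20% of
samples are dropped (a feature at exactly the threshold is kept);
remaining missing cells are median-imputed per feature (so imputed
cells share the median's average rank); each feature is mapped onto
standard-normal quantiles, value of rank r (average ranks for ties)
becoming `Phi^-1(r/(n+1))`; constant features map to zero columns with
a warning.  Stage labels collapse substages (IIA → II), map Roman
numerals I–IV to 1–4, and produce `y = ln(stage)`; unmappable samples
are excluded and logged.  Expression and phenotype tables are aligned
on their common samples, in expression order, before any fit.

The rank offset r/(n+1) keeps every quantile strictly inside (0,1);
Blom-type offsets differ by O(1/n) and nothing here depends on the
choice.

## Synthetic data

`eben.synthetic` draws X as i.i.d. standard-normal columns (optionally
with equicorrelation rho, default 0) that are then inverse-quantile-
normalized per column — matching the distribution the pipeline feeds
the solver — and assembles y from planted main effects, planted pair
effects and Gaussian noise.  The standard scenarios used by the
calibration studies:

* recovery — n=300, k=30, three main effects of 0.8, two pair effects
  of 0.6 on disjoint features, noise sd 1;
* null — n=200, k=30, no effects;
* masking — n=300, k=20, one main effect of 2.0 plus one pair effect of
  0.6 on unrelated features.

The phenotype is simulated continuous; `discretize_phenotype` offers a
quartile-binned ln{1..4} mode mimicking staged responses.  What the
generator does **not** emulate: count-level sequencing noise, the
empirical correlation structure of real miRNA panels, batch effects,
or ordinal measurement of the phenotype — so passing calibration here
shows the procedure works under its own model assumptions, not that
those assumptions hold for any particular dataset.

`evaluate_recovery` scores a workflow result against the planted truth:
a planted term counts as recovered iff it appears in the final table;
everything else reported is a false positive.  The replicate-level
false-discovery proportion V/max(R,1) is averaged across replicates —
the standard empirical-FDR estimator.  Vacuously empty truth sides
score power 1.

## Calibration studies

`scripts/acceptance.py --seed S --out results/acceptance.json`
recomputes, from scratch: the closed-form alpha* identity; the maximum
deviation of converged coefficients from a dense posterior computed
independently through the explicit marginal covariance (50 random small
instances); and the three 25-replicate simulation studies above (power,
empirical FDR, median coefficient error; null discovery rate;
anti-masking detection rates of the workflow vs a single joint scan).
`tests/test_acceptance.py` asserts the same properties.  Problem sizes
(25 replicates, n = 200–300, k = 20–30) keep a full run in a few
minutes on one core while leaving the detection problems non-trivial.

## Known limitations

* The Gaussian likelihood treats ln-stage as continuous; no ordinal or
  GLM likelihoods, and no covariate adjustment.
* Only pairwise interactions are modeled; no three-way or higher terms.
* p-values are not selection-adjusted (see above), and no
  multiple-testing correction is applied by default, mirroring the raw
  p < 0.05 design of the workflow.
* The per-feature alpha objective is maximized greedily; like all
  coordinate-ascent selectors it can stop at a local configuration,
  and results depend (deterministically) on the CV fold seed.
* Exact reproduction of published real-data tables is not expected:
  the original analysis' CV grid, fold count and seeds are unknown.
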