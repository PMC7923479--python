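# Methods

## The problem

Epistasis scans for survival outcomes ask, for every pair (or triple) of
SNPs, whether the joint genotype is associated with the hazard of death.
Classic multifactor dimensionality reduction (MDR) answers this by
collapsing the 3^k genotype cells of a k-SNP combination into one binary
attribute — each cell is labeled high (H) or low (L) risk — and then
validating the best combination by cross-validation plus a full permutation
test. The unified-model variant implemented here (UM-MDR) keeps the
dimensionality-reduction step but replaces cross-validation and full
permutation testing with a parametric test of the H/L indicator inside a
Cox regression, at the cost of a small, explicit correction for the fact
that the indicator was chosen by looking at the outcome.

## The two-step procedure

**Step 1 — classification.** For a combination of k SNPs, all n subjects are
partitioned into the 3^k genotype cells. Two rules label a cell H:

* *KM-median rule*: the cell's Kaplan-Meier median survival time is strictly
  below the whole sample's KM median. A cell whose survival curve never
  reaches 1/2, an empty cell, or a cell tying the overall median exactly is
  labeled L — such cells carry no evidence of elevated hazard. The KM median
  is the smallest observed event time t with S(t) <= 1/2.
* *Martingale-residual rule*: the sum over the cell's members of the
  martingale residuals M_i = delta_i − Lambda0_hat(t_i) exp(gamma_hat' z_i)
  from a *reduced* Cox model (adjusting covariates only, never the scanned
  SNPs; covariate-free Nelson-Aalen when there are none) is strictly
  positive, i.e. the cell saw more deaths than the reduced model predicts.
  A zero sum is labeled L.

The per-subject indicator S marks membership in an H cell.

**Step 2 — testing.** A Cox model lambda0(t) exp(alpha S + gamma' Z) is
fitted and W = alpha_hat^2 / Var_hat(alpha_hat) computed. The three variants
differ only in where the covariates enter:

| variant     | step-1 rule                  | step-2 model |
|-------------|------------------------------|--------------|
| KM-UMMDR    | KM median (covariates cannot enter) | S + Z  |
| Cox-UMMDR   | residuals, covariate-free fit | S + Z       |
| Cox2-UMMDR  | residuals, Z-adjusted fit     | S only      |

With `adjust_main=True` the scanned SNPs' additive dosages are appended to
the step-2 design (all variants), so the test targets the interaction beyond
the SNPs' marginal effects.

**Correction.** Because step 1 selects S using the outcome, W is
stochastically larger than chi-square(1) under the null. Its null
distribution is treated as noncentral chi-square(1, q). Since the mean of
that distribution is q + 1, q is estimated by permuting the trait a small
number of times (B = 10 by default; the paper-scale design uses 5–10),
recomputing both steps on each permuted dataset, and setting
q_hat = max(0, mean(W_perm) − 1). By default the permuted statistics of all
combinations are pooled into a single q_hat (per-combination estimation is
available); pooling is what stabilizes the estimate at such small B. The
reported p-value is the upper tail of chi-square(1, q_hat) at W, which
reduces to the central chi-square(1) tail when q_hat = 0.

Inside `UMMDRScan.fit` the B permutations are *shared* across combinations
— each permuted trait is scanned against every combination — which is what
pooling presumes and allows all trait-side precomputations to be reused.
"Permuting the trait" means jointly permuting (time, status, covariate row)
against the genotype rows, preserving the covariate–trait association; it
is implemented, equivalently, as a row permutation of the genotype matrix.

## Numerical core

The scan performs tens of thousands of tiny Cox fits (1–4 columns,
n of a few hundred), so the partial likelihood is maximized by a dedicated
Newton-Raphson routine written over pre-sorted arrays: risk-set sums S0, S1
and the upper triangle of S2 are accumulated in one reversed cumulative sum
per iteration; ties use the Breslow approximation; the baseline cumulative
hazard is the Breslow estimator, which makes in-sample martingale residuals
sum to zero exactly. Fits warm-start from the reduced model's covariate
coefficients. Convergence is declared when the Newton step falls below 1e-8
in absolute value; a step that lowers the likelihood triggers step-halving;
|beta| > 35 is treated as monotone likelihood (no finite MLE). In the scan,
a constant S (all cells one label), a non-converging fit, or a singular
information matrix yields a flagged degenerate record with W = 0 and p = 1
rather than an exception, so exhaustive scans never abort on sparse tables.
The user-facing `fit_cox` raises instead, with diagnostics.

Ranking is by W descending with lexicographic tie-break on SNP indices
(determinism). The built-in multiple-testing options are Bonferroni over
C(p, k) or none (the simulation harness uses none, since the paper-style
operating characteristics are per-pair).

## Classic comparators

KM-MDR and Cox-MDR are provided for power comparisons. Within each of
n_folds cross-validation folds (stratified by event status), cells are
labeled on the training part with the same two step-1 rules; each
combination is scored by the training-set log-rank statistic between its H
and L groups; the fold winner is the top scorer; the overall best is the
modal winner (ties broken by larger mean test-fold log-rank). Significance
uses a permutation test on the mean test-fold log-rank of the best
combination, p = (1 + #{permuted >= observed}) / (M + 1). The original
publications do not restate their internal statistics, so the log-rank
evaluation was chosen as a classifier-agnostic criterion in the spirit of
the survival-MDR literature; this affects comparator power only, not the
UM-MDR methods themselves.

## Synthetic data

The generator reproduces the standard simulation design for this method
family:

* genotypes: unlinked diallelic loci, HWE, dosage ~ Binomial(2, MAF);
* epistasis: a penetrance table f over the causal cells gives
  P(high risk | cell); the latent indicator x is Bernoulli(f). Two-way
  tables are drawn by sampling a direction in the null space of the
  HWE-weighted marginal-sum operator (so every marginal penetrance equals
  the mean penetrance exactly — pure epistasis, no marginal effects) and
  rescaling deviations to hit the target heritability
  h^2 = sum_c P(c)(f_c − f̄)^2 / (f̄(1 − f̄)) to 1e-6. The mean penetrance is
  drawn from a grid on [0.15, 0.85]; draws leaving [0, 1] are rejected.
  A fixed 3-way table (six cells at penetrance 0.2, the classic
  checkerboard model) is built in; note it has weak marginal effects.
* survival: T = scale (−log U e^{−eta})^{1/shape} with eta = alpha x +
  gamma z + delta SNP_main, i.e. a Cox model with Weibull baseline
  Lambda0(t) = (t/scale)^shape. Defaults: shape 5, scale 2, alpha 0.8,
  gamma 0.8, delta 0.5 when a marginal SNP effect is requested, z ~ N(0,1),
  one covariate, no SNP-covariate interaction;
* censoring: C ~ U(0, c). Since P(censored) = E[min(T, c)]/c is smooth and
  decreasing in c, the bound c is calibrated by bisection on a pilot sample
  of 20 000 uncensored event times, hitting the target fraction to well
  within +-0.01 in expectation.

Default study conditions are n = 400 patients, p = 10 SNPs (8 in the
two-way null design, 6 in the three-way null design), the first k SNPs
causal, MAF in {0.2, 0.4} with heritabilities
{0.01, 0.025, 0.05, 0.1, 0.2, 0.3, 0.4} for power (five random tables per
combination), MAF in {0.05, 0.1, 0.2, 0.3, 0.4} x CF in {0, 0.1, 0.3, 0.5}
for Type I error. The null design keeps gamma = 0.8: the hypothesis being
calibrated is "no genotype effect", not "no covariate effect".

What the generator does not emulate: linkage disequilibrium, missing
genotypes, population structure, rare-variant MAFs (< 0.05), informative
censoring, or SNP-covariate interaction. Passing tests therefore speak to
the methods' operating characteristics under idealized GWAS-style
conditions, not to robustness against those features of real data.

## Operating characteristics, as operationalized here

"Type I error" of a scan is reported as the per-pair probability of being
simultaneously top-ranked by W and significant at 0.05 (uncorrected),
averaged over the C(p, k) combinations; the selection-only and
significance-only rates are emitted alongside so alternative readings can
be reconstructed. The nominal selection-only rate under the null is
1/C(p, k): 1/28 ≈ 0.0357 for the two-way design's 8 SNPs and 1/20 = 0.05
for the three-way design's 6 SNPs. Power is the fraction of datasets in
which the causal combination is top-ranked and significant (corrected p for
the UM-MDR variants, permutation p for the comparators); the selection-only
fraction is reported alongside.

Reduced problem sizes used by the test suite and the acceptance script —
200 null datasets per grid cell, 20–25 power replicates with paired seeds,
5 CV folds and 19 permutations for the comparators — were chosen as the
package's own balance of Monte-Carlo error against turnaround; the full
paper-scale designs (1000 null datasets, 100 replicates, 70 models, 10
folds) are reachable through the same functions by changing the size
arguments.

## Known limitations

* The 70 concrete penetrance tables of the original power study are not
  public; tables here are regenerated under the same (MAF, h^2) constraints,
  so power curves match qualitatively, not table-by-table.
* The exact functional behind the published Type I error tables is not
  fully specified; the top-and-significant operationalization used here
  reproduces the conservative, below-the-selection-bound behaviour but sits
  a few thousandths below the published cell values.
* The comparators' cross-validation statistic is a documented design choice
  (log-rank), not a line-by-line reimplementation of the original KM-MDR /
  Cox-MDR code.
* Genotype coding: the classifiers are invariant to relabeling {0,1,2} of
  any SNP, so either homozygote may be coded 0; dosages only enter
  additively when `adjust_main` appends them to the step-2 design.
* Scans are exhaustive; the intended envelope is up to a few hundred SNPs,
  not genome-wide.
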