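# Methods

## The model and the reduction

Survival follows a proportional-hazards model
λ(t | X, Z) = λ0(t) · exp(βX + γ'Z), where X is the genetic attribute of
interest and Z a vector of time-fixed covariates. Cox-MDR scores each
subject by the martingale residual of the *null* fit (β = 0):

    M_i = δ_i − Λ̂0(T_i) · exp(γ̂'Z_i),

with γ̂ maximising the Breslow-tie partial likelihood and Λ̂0 the Breslow
baseline estimator (Nelson–Aalen when no covariates are adjusted). Under
this construction Σ_i M_i = 0 exactly, each M_i ≤ 1, and censored
subjects have M_i ≤ 0 — the tests assert all three. Zero is therefore
the natural classification threshold: for a k-SNP combination, a
genotype cell is labelled high-risk when the sum of training residuals
in it is ≥ 0 (a sum of exactly zero is high; a cell with no training
subjects is low — the conservative default that keeps every test subject
classifiable). Subjects with M_i > 0 act as pseudo-cases, M_i ≤ 0 as
pseudo-controls, and candidate combinations are compared by balanced
accuracy, ½(sensitivity + specificity), so the typically unbalanced
case/control split induced by censoring does not bias selection.

Residuals are computed **once on the full cohort** before the
combination search (the GMDR-style score construction); a
`per_fold_residuals=True` sensitivity mode refits the null model inside
every training fold and scores test subjects with the training baseline.

## Cross-validation and model selection

k-fold splits are stratified by event status (heavily censored small
cohorts otherwise produce event-free folds), dealt round-robin after a
seeded shuffle, and repeated (default 10 × 10-fold; 2-fold × 100 repeats
is the small-sample configuration). The search ranks combinations by
mean testing balanced accuracy, breaking ties by cross-validation
consistency (number of folds in which the combination had the best
training score), then mean training score, then lexicographic SNP tuple.
Folds whose test subjects cannot be scored are recorded as missing, not
dropped silently. With folds = n the split degenerates to leave-one-out
and the evaluation is seed-independent, which the tests assert.

The selected attribute's significance is assessed by permutation: the
phenotype block (time, status, covariates — hence residuals) is permuted
against the genotype rows, cell labels are re-derived per permutation,
and the squared Wald statistic of the binary attribute in a
covariate-adjusted Cox model is compared with the observed one,
p = (1 + #{perm ≥ obs}) / (B + 1). This scheme preserves the
covariate–survival association while breaking every genotype–survival
link, which is the null of interest. The construction behind the
published permutation p-values is not documented anywhere we could
check, so this is the package's own (documented) choice. A fit that
fails inside a permutation counts against the observed statistic
(conservative).

## The Surv-MDR comparator

Surv-MDR labels a cell high-risk when its members show excess deaths
versus the complement sample by the two-sample log-rank statistic
(strictly positive observed-minus-expected; ties and empty cells are
low — zero evidence defaults to low, intentionally mirroring, but not
equal to, Cox-MDR's "≥ 0 is high" rule, whose threshold the source
method states explicitly). Combinations are scored by the high-vs-low
log-rank chi-square signed by the direction of the high group, with the
same fold splits as Cox-MDR for equal seeds. No covariate enters
anywhere, and a mutation test asserts that. We threshold the raw O−E
rather than a standardised statistic; with the variance positive the
two differ only at the boundary O−E = 0, which falls to "low" either
way.

## Numerical choices

* Newton–Raphson with step-halving for all Cox fits; convergence when
  the score max-norm < 1e-8 or the relative log-likelihood change
  < 1e-10; iteration cap 60, reported by name on failure. Breslow tie
  handling throughout (it is what makes the residuals sum to zero
  exactly); Efron is available behind `ties="efron"` for the fitters.
* Λ̂0 is evaluated right-continuously at T_i (the jump at T_i counts when
  δ_i = 1), the standard martingale-residual convention giving M_i ≤ 1.
* Monotone likelihoods (perfectly separating predictors) are detected
  two ways: a coefficient crossing ±50 during iteration, or a
  "converged" fit whose coefficient exceeds 10 with a standard error
  above 100 (the likelihood-supremum signature). Both raise a named
  error rather than returning a spurious estimate.
* Balanced accuracy with one class absent: the absent class contributes
  0 and a degeneracy flag is set; with no scorable subjects the fold is
  missing.
* BH-FDR uses an explicit `m_total` (total tests performed) so a
  reported subset of p-values adjusts against the full screen size.

## The synthetic benchmark

`generate_penetrance` builds two-locus *pure-epistasis* penetrance
functions f (3×3, rows/columns indexed by minor-allele counts) under
Hardy–Weinberg and linkage equilibrium at both loci with a single minor
allele frequency p ∈ {0.2, 0.4}. Writing P(g) for the HWE joint
probabilities and K = Σ P(g) f(g) for the prevalence of the high-risk
status, the heritability is

    h² = Σ_g P(g) (f(g) − K)² / (K (1 − K)),

targeted over {0.1, 0.2, 0.3, 0.4}. The search samples K uniformly on
[0.01, 0.5], draws random deviation tables weighted towards rarer
genotype cells, projects them onto the subspace with zero HWE-weighted
marginal penetrance at both loci (no main effects, to machine
precision), and rescales to hit h² exactly; draws landing outside
[0, 1]⁹ are rejected, with a linear-programming vertex fallback near the
feasibility frontier. Exhausting directions per sampled K keeps the
accepted prevalence roughly uniform over its *feasible* range. That
range is genuinely restricted: under exact zero marginals, h² = 0.4
requires K ≳ 0.28 at MAF 0.2 and K ≳ 0.21 at MAF 0.4 — low-prevalence
high-heritability pure-epistasis models do not exist.

Cohorts draw genotypes for the two causal loci from the joint HWE
distribution, assign high-risk status with probability f(g), and
rejection-sample to exactly 200 high- and 200 low-risk subjects. Eight
null SNPs are added i.i.d. HWE at the same MAF, and the two causal
columns are placed at seeded random positions among the ten. Survival
times come from the Cox–Weibull inverse transform with
Λ0(t) = (t/2)⁵ and hazard multiplier exp(β x + γ z), β = 1,
γ ∈ {0, 1, 2}, z ~ N(0, 0.5) read as variance 0.5 (sd = √0.5 — the
notation is ambiguous; power shifts only mildly under the sd reading);
censoring is U(0, 4), so every observed time is ≤ 4.

Power is the fraction of datasets in which the causal pair tops the
45-pair ranking (for the MDR methods) or in which both causal SNPs reach
Wald p < 0.05 (univariate Cox), averaged over the five models of a
(MAF, h²) combination. The type-I experiment removes the causal columns
(optionally substituting fresh null SNPs to keep the 45-pair geometry)
and reports how often one fixed, pre-designated pair is returned as
best; under exchangeability this is 1/45 ≈ 0.022 (1/28 in the 8-SNP
geometry), and the estimate is asserted against the binomial band around
that value. The published description of this experiment (re-detecting
SNPs that were removed from the data) cannot be implemented as written;
the designated-pair criterion is the coherent reading and matches the
published magnitude.

## What the generator does and does not emulate

It reproduces the benchmark's sampling design — balanced risk-group
quotas, unlinked loci, a single well-behaved covariate, proportional
hazards, uniform censoring. It does not emulate linkage disequilibrium,
genotyping error or missingness, covariate–gene interaction, or
non-proportional hazards, so passing benchmarks here say nothing about
robustness to those. One consequence of *exact* pure epistasis deserves
emphasis: the single-locus genotype distribution is then identical in
the high- and low-risk groups, so the univariate Cox screen has
essentially no power by construction, and both MDR methods must find
the pair from the joint pattern alone. Published versions of this
benchmark rest on a historical catalogue of penetrance tables that is
not available; regenerated zero-marginal models are intrinsically
harder, so power magnitudes at the higher MAF/heritability corner run
below the historical figures even though every qualitative trend
(power increasing in h², the MAF-0.4 advantage of the log-rank variant,
the large gain from covariate adjustment at strong γ) reproduces.

## Benchmark scales

The shipped benchmark scripts use: 5 penetrance models per combination;
100 datasets per model for the power runs at full 10-fold × 10-repeat
CV; 800 null datasets at 10-fold × 2-repeat CV for the type-I run; the
test suite uses 16–40 datasets per model. Binomial standard errors at
these sizes are ±0.02–0.05 and are reported alongside every estimate.

## Known limitations

* k > 3 interactions are possible but guarded by an explicit candidate
  cap; the search is exhaustive, not heuristic.
* The permutation scheme and the Surv-MDR tie rule are documented
  choices where the source methods are silent (see above).
* Real-data mode expects complete phenotype rows; genotype missingness
  is handled per-combination (a subject is excluded only from
  combinations involving a SNP they are missing).
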