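# Methods

## The generalized CMH statistic

For an I × J × K table (trait level i, genotype level j, stratum k) the null
hypothesis is conditional independence Y ⊥ SNP | strata.  Conditional on
the margins of stratum k, the cell-count vector n_k follows a multivariate
hypergeometric law with mean μ_ijk = n_{i+k} n_{+jk} / n_{++k} and
covariance

    Cov(n_ijk, n_i'j'k) = n_{i+k}(δ_ii' n_{++k} − n_{i'+k}) ·
                          n_{+jk}(δ_jj' n_{++k} − n_{+j'k}) /
                          (n_{++k}² (n_{++k} − 1)),

which factorizes as V_k = A_r ⊗ A_c / (n_{++k} − 1) with
A_r = diag(r) − r r'/n over the row margins (A_c likewise for columns).
The implementation exploits this Kronecker structure: B_k V_k B_k' is
computed as (U A_r U') ⊗ (V A_c V') without ever forming the
(IJ) × (IJ) matrix, so a single test costs O(I²J² + IJK) time.

Score matrices: a nominal dimension with L levels uses the (L−1) × L
contrast (I | −1); an ordinal dimension uses one row of scores.  Nominal ×
nominal is the general association test (df (I−1)(J−1)); one ordinal
dimension gives the mean score test; ordinal × ordinal the correlation
test (df 1).  Ordinal scores must be non-decreasing with at least two
distinct values — ties are allowed so that the dominant (0,1,1) and
recessive (0,0,1) genotype codings are expressible as mean-score tests,
alongside additive (0,1,2).  Ordinal traits default to category scores
1..I.

Numerical choices:

* Strata with n_{++k} < 2 carry no information (the variance denominator
  n(n−1) vanishes) and are dropped; all-zero strata are therefore inert.
* If the pooled covariance Σ B_k V_k B_k' is singular (e.g. a genotype
  column absent in every stratum), the Moore–Penrose pseudoinverse is used,
  df is reduced to the matrix rank (singular values above
  max_dim · eps · σ_max), and the result is flagged `rank_deficient`.
  With rank 0 the statistic is defined as 0 with p = 1.
* p-values are the upper chi-square tail; no continuity correction
  anywhere.
* The statistic is clamped at 0 against −1e−16-scale round-off.

Exact identities used as oracles in the tests: at K = 1 the general test
equals (n−1)/n times the Pearson chi-square; the correlation test equals
(n−1) r² for the sample correlation of the two score vectors; on 2 × 2 × K
tables the general test is the classical Mantel–Haenszel statistic without
continuity correction.

## Stratification

`full_cross` assigns one stratum per distinct genotype tuple of the
conditioning set (≤ 3^p).  `mac_sum` stratifies on the per-subject sum of
minor-allele counts over the conditioning set; sums 0..cap−2 are their own
strata and every sum ≥ cap−1 is merged into the last stratum (only the
upper tail is merged — the stated merge criterion is one-sided).  The
default cap of 10 keeps per-stratum counts usable at sample sizes of a few
thousand; it is configurable.  Strata are indexed by sorted distinct
observed keys, so unobserved genotype tuples never create empty strata.

Missingness is handled per test (complete-case): a sample is excluded from
one table only if it is missing the trait, the target SNP, or any
conditioning-set genotype.  This preserves the most data but means
different steps of the search can use slightly different sample subsets
when missingness is present.

## The stepwise search

Forward: every candidate is tested as the column variable of an I × 3 × K
table stratified on the current selected set (K = 1 for the empty set);
the minimum-p candidate enters iff p < entry threshold.  Backward: each
member is tested conditioned on the rest; the maximum-p member leaves iff
p > removal threshold, one per call, repeated until no removal; the step
can be disabled.  When a forward step adds nothing the set is closed, its
members are deleted from the pool, and the search restarts from the empty
set; the procedure ends when a round's first forward step finds nothing.

Determinism and termination: ties on p-value are broken by the larger
statistic, then by input SNP order, so a rerun on identical input is
bit-identical.  A visited-state set and the `max_set_size` bound guard
against forward/backward oscillation; if a state recurs the round is closed
as-is.  Default entry = removal = 5 × 10⁻⁵ (the value used in real-data
applications of the method); the simulation studies use 5 × 10⁻⁴ and
5 × 10⁻³.

The stepwise logistic baseline mirrors this driver exactly but scores a
candidate by the likelihood-ratio test (df ≤ 2) of its two genotype
dummies added to a logistic model containing the selected SNPs' dummies,
fitted by Newton maximum likelihood (statsmodels).  Non-convergence,
separation, or an all-constant dummy is recorded as p = 1 — the sparse-cell
failure mode the CMH variance is immune to.  The baseline is a comparator,
not an alternative implementation of the CMH method.

## Simulator

Disease odds for a subject with causal genotypes (g_1..g_p) are
α ∏_s f(g_s) with f(0) = 1, f(1) = 1+θ₁, f(2) = 1+θ₂; penetrance is
odds/(1+odds).  This is exactly logit P(y=1) = log α + Σ β(g_s) with
β = log(1+θ₁), log(1+θ₂) — the parameter-recovery test fits that logistic
model to a large prospective draw and checks the coefficients.  Defaults
are the canonical study conditions: θ₁ = 0.7, θ₂ = 0.5, causal MAFs from
{0.03, 0.05, 0.1, 0.2}, 1000 cases / 1000 controls, total SNP counts of
100–1000.

* Baseline odds α is solved by bracketed root-finding on log α so that the
  HWE-expected penetrance equals the target prevalence (closed form
  target/(1−target) when θ = 0).  The population prevalence is not dictated
  by the case-control design itself; the default `total_penetrance = 0.1`
  is a conventional complex-disease value and results are reported as
  functions of this setting.
* Retrospective sampling is by rejection: population subjects (causal
  genotypes under HWE and linkage equilibrium, Bernoulli(penetrance)
  status) are drawn in batches until the case and control quotas are
  exactly filled.  Null SNPs are drawn afterwards for the retained subjects
  only — valid because they are independent of the trait by construction.
  Null MAFs default to Uniform(0.05, 0.5) (configurable, including cloning
  the causal MAF).
* With three or more causal SNPs the same multiplicative factor applies per
  locus with the shared θ₁/θ₂ values.
* An ordinal-trait generator reuses the binary linear predictor in a
  proportional-odds law P(Y ≤ m) = expit(c_m − η).  It is an extension for
  exercising the ordinal test paths, not part of the case-control design.

What the generator does *not* emulate: linkage disequilibrium between
markers, population structure, genotyping error, covariates, or epistatic
(non-multiplicative) penetrance.  Passing tests therefore demonstrate the
statistical behaviour of the method under its own model assumptions, not
robustness to those real-data complications.

## Evaluation

Dprob is the mean over replicates of |selected ∩ truth| / |truth|, with
"selected" the union of all discovered sets; power is the fraction of
replicates capturing every causal SNP.  Power ≤ Dprob by construction, and
false positives affect neither measure.  Replicate seeds spawn
deterministically from the master seed, and both methods see identical
replicate datasets.

Problem sizes used by the checked-in studies: the type-I calibration uses
50 markers × 2000 replicates at 1000/1000 samples (100 000 tests); the
acceptance-script variant uses 500 replicates.  The power comparison runs
100 replicates per MAF (50 in the acceptance script) at 100 markers,
1000/1000 samples, threshold 5 × 10⁻³ — a deliberately scaled-down design
whose Dprob/power values carry Monte-Carlo noise of roughly ±0.05; the
qualitative contrast (stepwise CMH ≥ stepwise logistic at rare MAFs, both
saturating at common MAFs) is stable far beyond that noise.

## QC and IO

MAF < 1% or call rate < 95% removes a marker (strict inequalities;
boundary values retained).  LD pruning slides a 50-marker window one
position at a time and drops the positionally later member of any pair
with r² > 0.5 (complete-pairwise-case Pearson correlation of allele
counts); keeping the earlier member matches common tagging practice.  A
sliding window was chosen over disjoint blocks as the reading of
"between 50 adjacent SNPs".  Genotype tables are delimited text (header of
SNP ids, first column sample id, NA/−9 missing) or PLINK additive-recode
`.raw` text; binary PLINK formats are out of scope.

## Known limitations

* The CMH statistic's chi-square null is asymptotic; no exact or
  permutation p-values are provided.
* No homogeneity (Breslow–Day) testing or common odds-ratio estimation.
* The stepwise path performs no multiplicity adjustment beyond the fixed
  entry/removal thresholds; discovered-set p-values are conditional on the
  selection path.
* `full_cross` stratification is exponential in the conditioning-set size
  and is intended only for small sets and for validating `mac_sum`.
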