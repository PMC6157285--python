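# Methods

## The network model

`cgbnet` learns conditional-Gaussian (CG) Bayesian networks over mixed
cohort data. Nodes are typed: continuous (TG levels, age, CpG
beta-values) or discrete (sex, center, and — by default — genotype
dosage as a three-level factor {0,1,2}; a switch treats dosage as
continuous). The CG restriction forbids a continuous parent of a
discrete node, so the joint factorizes as a multinomial over the
discrete nodes times, for each continuous node, one Gaussian linear
regression per configuration of its discrete parents.

### Score

Structures are compared by the decomposable BIC in the convention
score = logLik − (k/2)·ln n, higher better. For a continuous child the
parameter count k sums, over the *observed* configurations of its
discrete parents, an intercept, one slope per continuous parent and a
residual variance. For a discrete child with L levels it is
(L − 1) × Π(parent levels) over the full cartesian product of parent
levels. Per-configuration Gaussian log-likelihoods use the MLE residual
variance (RSS/n_c), which makes Markov-equivalent all-continuous DAGs
score identically (verified to 1e-8 in the tests). n is the number of
complete-case rows for the (child, parents) computation; local scores
are cached by (child, parent-set).

Degenerate configurations — a discrete-parent cell with fewer rows than
regression parameters, or zero residual variance — contribute zero
log-likelihood, are still counted in k, and are logged. No prior
smoothing is applied. The practical effect is that parent sets which
shatter the sample into tiny cells lose likelihood and are disfavoured,
which is the behaviour one wants from an unpenalized ML fit.

### Constraints and search

A `ConstraintSet` carries whitelist edges (must be present, fixed
direction), blacklist edges (forbidden) and no-parent nodes. The
drug-response analysis uses: whitelist TG2 → TG4 (so the fitted network
models change in TG), no parents for SNPs and for the categorical
covariates sex/center, and a blacklist of every post-treatment CpG into
TG2 (time ordering).

Hill-climbing starts from the whitelist-only graph and repeatedly
applies the best strictly-improving operation among all valid adds,
deletes and reverses, enumerated in a fixed deterministic order. Two
numerical choices matter:

* **Tie-breaking is randomized** (uniform over moves within 1e-9 of the
  best). For score-equivalent orientations this is what lets bootstrap
  direction probabilities approach 0.5 instead of collapsing to an
  enumeration artifact.
* **Restarts** (default 10) perturb the incumbent local optimum by
  2 × (#nodes) random valid additions/deletions and re-climb, keeping
  the best network seen. Restart count is configurable down to 0 for
  bootstrap-heavy runs.

An exhaustive enumerator (≤ 5 nodes; three states per unordered pair,
filtered for acyclicity and constraints) provides the independent
optimum against which the search is tested: with 20 restarts the climber
reaches the global BIC optimum on ≥ 95 of 100 random 4-node mixed
problems.

### Bootstrap averaging

The averaged network refits the climber on B row-resamples (B = 1000 by
default; the full restart schedule is reused unless lowered). Strength
of a pair = fraction of replicates containing the edge in either
direction; direction of an orientation = fraction among those
replicates. Pairs never observed are reported as missing, not as 0.5.
Whitelisted edges therefore have strength 1 and direction 1 by
construction.

The significance cutoff on strengths is the L1/ECDF estimator: the
ideal averaged network has only 0- and 1-strength edges, so its CDF is
flat at some level c on [0, 1); the estimator brute-forces the observed
strength values (plus 0) as candidate cutoffs t, sets c to the ECDF at
t, and keeps the t minimizing the L1 distance between the empirical
strength CDF and the flat level. Retention is strict (> t), which is the
convention under which an edge whose strength exactly equals the cutoff
is dropped. A fixed user cutoff is accepted everywhere the estimator is.

## Regression stages

All scans are ordinary least squares on complete cases, with two-sided
p-values from the t distribution on n − k df. Individuals are treated
as unrelated; no mixed-model relatedness adjustment is applied (the
simulator generates unrelated individuals, and a pluggable variance
structure would slot in at `fit_ols` if family data were ever used).

* Per-visit EWAS: log TG (visit 2 or 4) on each CpG with age, sex,
  center and 4 principal components of the tested CpG matrix (PCs are
  recomputed per scan from exactly the CpGs entering it).
* Change-model scans: log TG4 on the marker with log TG2 among the
  covariates. TG is logged internally throughout — including the TG2
  covariate — consistent with the log-scale generative model.
* MAF filter: SNPs with minor allele frequency ≤ 0.01 are excluded;
  monomorphic markers are skipped with a logged warning.
* Scan summaries: Bonferroni threshold α/m (significance is strict
  less-than) and the genomic-control factor λ = median χ²₁ / 0.4549.
  Note λ's median-based estimator has sampling sd ≈ 2.33/√m on a null
  scan, so bands around 1 should be read against the scan size.

## The synthetic cohort generator

The generator emulates the drug-trial study conditions and is the
package's test bed. Defaults (all overridable in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| n_individuals | 1000 | unrelated individuals |
| snps | 5 causal | h² = 0.125/0.075/0.100/0.025/0.050, MAF 0.3, one paired CpG each |
| n_null_cpgs | 500 | CpGs with no causal role |
| methylation_propensity_sd | 1.0 | sd of the shared per-individual logit shift |
| methylation_noise_sd | 1.0 | per-cell logit noise |
| tg2_log_mean / tg2_log_sd | 4.7 / 0.5 | pre-treatment log TG (~110 mg/dL) |
| drug_mean_effect | −0.25 | mean log-TG shift under treatment (~22% drop) |
| residual_sd | 0.25 | unexplained sd of the log-TG change |
| covariate_effects | 0 | age/sex/center effects on the change |
| modification_mode | proportional | m(M) = M; also complement (1−M) and none |

Generative model: genotypes are Binomial(2, p) (Hardy–Weinberg; MAF
floor 0.01); CpG beta-values are expit(μ_j + a_i + e_ij) with
a_i ~ N(0, propensity_sd²), which induces the positive inter-CpG
correlation seen when individuals are globally hyper-/hypo-methylated;
log TG2 ~ N(4.7, 0.5²); and

log TG4 = log TG2 + drug effect + Σ_k β_k·G_k·m(M_k) + covariates + ε.

**Heritability calibration.** The target h² of each SNP is defined in
the no-epigenetics regime (modification_mode = "none", where m(M) is the
paired CpG's mean as a constant). The analytic change variance solves
total_var = (cov_var + residual_sd²)/(1 − Σ h²), the raw slope is
s_k = √(h²·total_var / 2p(1−p)), and the stored coefficient is
β_k = s_k / E[m(M_k)] so that the mean effect — and hence the marginal
R² of the change on dosage — equals h² exactly in that regime (verified
at n = 100 000 within 3 Monte-Carlo SEs for all five design values).
total_var and the realized β_k are written to the truth record.

**Modifier CpGs sit at mid-range methylation** (baseline logit 0), a
design choice with two motivations: biologically, effect-modifying CpGs
are drawn from the variable mid-methylation regime rather than from
near-fixed sites; numerically, the multiplicative term β·G·M carries a
marginal CpG main effect proportional to E[G]/E[M], which the 1/E[M]
factor would amplify arbitrarily for low-methylation CpGs. Even at
mid-range baselines that marginal effect is nonzero — a real property of
multiplicative modification, which is why the change-model EWAS is only
guaranteed null for the *null* CpGs (and for all CpGs when
modification_mode = "none").

**What the generator does not emulate:** family/pedigree structure (the
bootstrap resamples rows iid accordingly), more than two visits,
epigenome-scale CpG counts, genomic marker maps, batch effects beyond
the shared propensity, and confounding between methylation and
genotype. Tests passing on this generator therefore certify the
statistical machinery — calibration, constraint soundness, search
optimality, averaging arithmetic — not robustness to relatedness or
cell-type confounding in real cohorts.

## Problem sizes used in the checked examples

The suite's calibration checks run at the sizes their statistics need:
heritability recovery at n = 100 000; search-vs-oracle agreement on 100
seeded 4-node problems with 20 restarts; constraint soundness over 200
bootstrap refits of a 12-node network at n = 500 (restarts = 2 inside
the bootstrap, a configurable schedule); strength/direction calibration
on a bivariate r = 0.9 cohort, n = 1000, B = 500; null-scan calibration
on one 500-null-CpG cohort at n = 1000. These are the package's declared
reference configurations; all are driven by fixed seeds and rerun from
scratch on every test invocation.

## Known limitations

* No parameter estimation beyond what scoring needs, no inference
  queries on the fitted network, no MCMC/tabu structure search.
* The L1/ECDF threshold is one defensible estimator of the strength
  cutoff, not the only one; a fixed cutoff can always be supplied.
* Discrete nodes take their level sets from the observed data (except
  genotypes, fixed at {0,1,2}); bootstrap replicates that drop a rare
  level are scored over the observed levels of the resample.
* Empty-cell handling (zero likelihood, no smoothing) makes scores of
  very fine discrete partitions conservative at small n.
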