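# Methods

This note documents the statistical models implemented in `pinegs`, the
defaults chosen where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical decisions that affect
results.

## Study design emulated by the generator

The generator (`pinegs.simdata`) reproduces the structure of an
open-pollinated conifer progeny trial: a clone bank of plus-tree founders
(default 49) supplies seed through open pollination; the first
`n_families` founders (default 44) act as seed parents; progeny are planted
across `n_sites` sites (default 6, with unequal totals
609/726/456/380/247/225 — 2,643 trees) in randomized blocks (default 5 per
site).  Family representation within a site is drawn from a Dirichlet
distribution, so the design is unbalanced in the way field trials are —
this unbalance is exactly why individual heritability is estimated by a
mixed model rather than plain ANOVA.

**Mating.** Every progeny's dam is recorded; the sire is the dam itself
with probability `selfing_rate` and otherwise a uniform draw from the other
founders (the clone bank is the pollen pool; outside pollen is not modeled —
it would only dilute relatedness and adds a parameter with no checkable
consequence).  The recorded pedigree lists all sires as unknown, as open
pollination does; the realized sires are retained in the simulation truth
for validation only.  `selfing_rate` defaults to 0.05: conifers are largely
outcrossing with a small realized selfing fraction, and the value is a free
parameter of the orchard that nothing downstream is calibrated against.

**Genetics.** Founder genotypes are Hardy–Weinberg draws at per-marker
minor-allele frequencies uniform on `[maf_min, 0.5]`; inheritance is
Mendelian with unlinked markers (no linkage map — relatedness, not LD decay,
drives every quantity the pipeline computes).  `n_qtl` markers (default
2,000 of 17,074) carry trait effects.

**Traits and G×E.** Three traits (DBH, height, straightness) carry their
own marker effects; volume is derived deterministically as DBH² × height,
preserving the real dependency among the growth traits.  For each trait the
per-site marker-effect vectors are drawn from an exchangeable multivariate
normal with correlation `type_b_corr`, which makes the cross-site
correlation of breeding values approximate the type-B genetic correlation
directly.  Phenotype = trait mean + site effect + block effect +
site-specific additive value + residual, on a standardized latent scale
mapped linearly to plausible units (DBH 0.25 ± 0.04 m, height 12 ± 1.5 m,
straightness 2.5 ± 0.6).  Per site and trait the additive values are
rescaled so the realized latent-scale h² matches the target
(`h2_per_site_trait`); with `residual_sd = 0` the rescaling is skipped and
the phenotype minus fixed effects equals the true breeding value exactly.
The six-site default h² matrix spans 0.05–0.72 across sites and traits,
the weak-to-strong range conifer progeny tests report.

With few founders and a finite QTL panel the *realized* cross-site
correlation of breeding values scatters substantially around
`type_b_corr` (family structure induces long-range dependence among
markers); recovery tests therefore compare estimates against the realized
truth recorded in `SimTruth`, not only the nominal target.

**QC degradation.** Missing calls are introduced at per-marker Beta rates
(mean `missing_rate`) modulated by a unit-mean per-sample factor, so some
markers fall below call-rate thresholds and occasional samples fail
sample-level QC.  The chip metrics (FLD, HetSO, HomRO, DQC) are synthetic
numeric columns drawn from configurable distributions; they carry no
biology and exist so the filters have a nontrivial partition to act on.

**Variance bookkeeping.** `SimTruth` records realized (finite-sample)
variances per site and trait — additive, block, residual, and an explicit
cross-covariance remainder — so the recorded terms sum to the total
phenotypic variance to floating-point precision.  Realized h² is defined as
`var(g)/(var(g)+var(e))`, with site and block treated as fixed.

**What passing tests do not show.** The generator has no linkage map, no
multi-generation pedigree, no dominance or epistasis, no spatial field
trend, and genotyping error only as missingness.  Results on synthetic data
therefore validate the estimators' internal consistency and the qualitative
behavior of the pipeline (e.g. the between-region penalty under low type-B
correlation), not field-data magnitudes.

## Trait derivation

From tabulated stem measurements: DBH = circumference at 1.2 m divided by
π; volume = DBH² × height (an index, deliberately not a taper-equation
volume); straightness = −ln(SD of six centerline deviations at heights
0.5–5.5 m).  The SD uses the sample convention (n−1; switchable), and a
zero SD — impossible for a real laser scan but reachable in synthetic or
rounded data — is floored at 1e−6 m (sub-millimeter noise floor), capping
the score at ≈ 13.8 and keeping downstream models finite.

## Quality control

Samples first, then markers, matching the chip-analysis order: samples with
call rate < 0.97 or DQC < 0.82 are excluded; MAF is then recomputed on the
survivors; marker presets are *loose* (MAF ≥ 0.05 only), *moderate*
(+ CR ≥ 0.97, FLD ≥ 3.6) and *strict* (+ CR ≥ 0.99, FLD ≥ 5, HetSO ≥ 0,
HomRO ≥ 0).  "Markers showing genotype variation" is implemented literally
as MAF > 0.  Imputation defaults to per-marker mean dosage — the standard
missing-data treatment for a centered-dosage GRM, exactly
frequency-preserving — with a seeded Hardy–Weinberg draw (`hw`) for
consumers needing hard calls.  Phasing-based imputation is out of scope.

## Kinship

The NRM uses the tabular method with all unknown parents treated as one
unrelated, non-inbred base population, which yields the classical 0.25 for
open-pollinated maternal sibs.  The GRM is VanRaden method 1,
`G = ZZ′/(2Σp(1−p))`.  By default `p` is estimated from the analyzed
sample (no base-population frequencies are available for real data); this
makes `G` column-centered, so mean coefficients of relative pairs are
*deflated* relative to pedigree expectations — an intrinsic property, not a
bug.  `build_grm(..., freqs=...)` accepts base-population (e.g. founder)
frequencies, under which the mean genomic relationship of half-sib and
parent–offspring pairs converges to 0.25 and 0.5; the agreement tests use
this mode.

## REML and BLUP

Single-kernel animal model fitted by EM-REML in the eigenbasis of `K`: one
symmetric eigendecomposition, then O(n·p) per iteration with an exact
restricted likelihood.  EM updates are monotone in the REML criterion
(asserted on every fit); Aitken extrapolation is attempted every third
iteration and accepted only if it improves the criterion.  Convergence:
relative log-likelihood change < 1e−8, max 1,000 iterations;
non-convergence flags the result rather than raising.  Components are
floored at 1e−6 × phenotypic variance — boundary heritabilities are
reported as ≈ 0, not errors.  `K` need only be PSD (negative eigenvalues
are clipped at 0 with a warning); a blending repair
(`0.99 K + 0.01 I`) exists on `RelationshipMatrix.psd_repair` for consumers
that require strict positive definiteness.  Standard errors come from the
inverse expected REML information; the h² SE uses the delta method, and the
significance of h² > 0 is a one-sided z-test.

Fixed effects are treatment-coded factors — block for one-site fits, site
for combined fits — and aliased designs raise an error naming the aliased
levels.  Unphenotyped kernel members receive predictions through the
relationship structure (`u_all = σ²_a K[all,obs] V⁻¹(y − Xb̂)`), which is
how cross-validation test sets are scored; GBLUP solved this way is
algebraically identical to ridge regression on centered dosages with
λ = c·σ²_e/σ²_a, a property tested to 1e−6.

**Family ANOVA.** Variance components for the block/family models come from
sequential (type-I) sums of squares equated to their expectations, with the
expected-mean-squares coefficients computed numerically from realized cell
counts (Frobenius norms of projection differences).  On balanced data this
reduces exactly to the textbook two-way EMS table (tested); on unbalanced —
even incomplete — designs it remains valid, so the precondition of fully
filled block×family cells is not enforced.  Negative moment estimates are
reported raw and truncated.  Family heritability uses the family-mean form
`h²_f = σ²_F / (σ²_F + σ²_SF/s + σ²_BF/(s·b) + σ²_e/(s·b·n̄))` with `s`
sites, `b` blocks and `n̄` the harmonic mean of nonempty cell counts; the
denominator's square root doubles as the family-mean phenotypic SD used in
the family-selection gain.

**Type-B correlation.** A bivariate two-site model with site-specific
additive effects sharing one kernel (`cov = σ_a12 K`), site fixed effects
and site-specific residual variances, fitted by direct REML over the
5-parameter covariance (Nelder-Mead on log-variances and atanh r).  The
estimate is flagged undefined when either additive variance collapses to
the boundary; a site paired with itself returns 1 by construction.

## Bayesian whole-genome regression

Single-site Gibbs samplers (numba-compiled, bitwise reproducible per seed)
for BRR, Bayesian LASSO, Bayes A, Bayes B and Bayes C over
`y = 1μ + Zβ + e` with centered dosages.  Fixed effects beyond the
intercept are removed by training-data least squares before sampling — one
fixed-effect policy for the whole pipeline.  Production default 20,000
iterations, burn-in 2,000, thinning 5 (exposed in `ChainConfig`; tests use
shorter chains at the stated saved-sample counts).  Hyperpriors follow the
customary heuristic: scaled-inverse-χ² with df 5 whose prior *mode* assigns
a fraction R² = 0.5 of the phenotypic variance to markers and the rest to
the residual; the LASSO rate λ² is initialized from the same partition and
updated under a Gamma(1.1, ·) hyperprior; π (the exclusion probability of
Bayes B/C) defaults to 0.99 with a switch to sample it from its Beta full
conditional.  A fixed π = 0.99 imposes an oligogenic architecture; on
polygenic traits the point-mass models then legitimately underperform, so
cross-model agreement is expected — and asserted — only with π estimated.
The π chain mixes slowly from extreme starting values; start it near 0.5
when estimating.  Effective sample sizes use the initial-positive-sequence
autocorrelation estimator.

## Cross-validation scenarios and metrics

Within-region (k-fold inside one site), between-region (train on the other
sites, predict one site; the test site is also split into the same k
subsets so a fold-mean ± SE comparable to the CV scenarios can be quoted,
with the unsplit value reported alongside) and combined-region (k-fold over
all sites, site-stratified folds).  Folds are canonicalized on sorted ids,
making every scenario invariant to input row order.  Fold SE is the SD of
per-fold correlations divided by √k.

*Accuracy* correlates test-set GEBVs with reference EBVs from a pedigree
ABLUP fitted **once on all phenotypes** — the forest-tree convention for a
true-breeding-value stand-in.  This is knowingly circular (the reference
saw the test phenotypes), so *predictive ability* — correlation with the
fixed-effect-adjusted phenotype, leakage-free because the adjustment is
estimated on training data only — is always reported next to it, and on
simulated data a third metric correlates GEBVs with the generator's true
breeding values.  A fixed-effect level unseen in training (the held-out
region in the between-region scenario) contributes only a fold-constant,
which Pearson correlation ignores.  Standardized ratios divide genomic
predictive ability by the pedigree model's (undefined and flagged when the
latter is ≤ 0) and by √h² (undefined when h² ≤ 0).

## Genetic gain

`i(p) = φ(Φ⁻¹(1−p))/p` exactly (no finite-population correction — the
normal-distribution assumption is taken at face value); annual gains are
`i·h²·σ_P/t` (phenotypic selection, t = 30 y), `i·h²_f·σ_F̄/t` (family
selection, t = 45 y: phenotyping plus a progeny test) and `i·r·σ_A/t`
(genomic selection, t = 15 y: age of reproduction).  σ_A = √σ²_GRM and
σ_P = √(σ²_GRM + σ²_e) from the combined REML fit; the family σ comes from
the family-ANOVA denominator.  Percent-per-year reporting divides by a
supplied trait mean.

## Pipeline and reproducibility

Stages run in a fixed order (simulate/ingest → sample QC → marker QC →
impute → kinship → fits → scenarios → gains); every output CSV carries a
stage comment, and the manifest records the configuration snapshot, seed,
version, per-stage timings and SHA-256 digests of all outputs.  The run
digest hashes configuration + seed + output digests (timings excluded), so
identical seeds reproduce identical digests — asserted in the test suite at
500 trees × 2,000 markers × 3 sites.  `--resume` reloads stages whose
outputs already exist.  All randomness descends from the single master
seed; each generator stage draws from its own child stream, so adding a
later stage never perturbs an earlier one.

Test and acceptance problem sizes (a few hundred trees, 0.4–2 k markers,
5–20 Monte-Carlo replicates) were chosen as the smallest designs at which
the checked quantities are statistically stable; the production defaults
remain the full trial scale.

## Known limitations

* Accuracy against full-data pedigree EBVs inherits that reference's
  circularity; treat it as the field's convention, not an unbiased metric.
* The bivariate type-B fit is O(n³) per likelihood evaluation; it is meant
  for site pairs (hundreds of trees), not the pooled trial.
* Bayes B/C with fixed extreme π are sensitive to the assumed architecture;
  estimate π unless a sparse architecture is known.
* Mean-dosage imputation underestimates genotype uncertainty at very low
  call rates; no phasing-based alternative is provided.
* No dominance/epistatic kernels, no single-step blending of NRM and GRM,
  no spatial adjustment.
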