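# Methods

`twinherit` analyses a classical twin cohort for myopia: it classifies
refractive status from per-eye refraction, estimates the heritability of
spherical equivalent from the contrast between monozygotic (MZ) and
dizygotic (DZ) intrapair correlations, and tests two candidate SNPs
(rs634990 near *GJD2*, rs8027411 in *RASGRF1*) for case-control
association with myopia. A synthetic cohort generator with the same
statistical structure makes every stage testable end to end.

## Refraction and classification

Each eye is summarised by the spherical equivalent SE = sphere +
cylinder/2 (diopters, minus-cylinder convention; plus-cylinder records
can be transposed, which leaves SE unchanged). A subject is assigned to
the **myopia** group when at least one eye has SE ≤ −0.5 D, to the
**emmetropia** group when both eyes lie within ±0.49 D, and is otherwise
**excluded** (hyperopia and other refractive errors). The "≥ 0.5 D"
myopia criterion is read on the signed scale as SE ≤ −0.5 D, since
myopic SE is negative and the emmetropic band is ±0.49 D. The gap
(−0.50, −0.49) is vacuous at the 2-decimal precision of clinical
refraction; inputs are not rounded before classification.

Myopia degree is graded mild (−3 < SE ≤ −0.5), medium (−6 < SE ≤ −3) or
high (SE ≤ −6). The interval boundaries −3 D and −6 D are assigned to
the more severe class; the source thresholds are quoted without closure,
so this is a package convention, stated once and applied consistently.

Per-subject analyses need a single SE value; the **analysis-eye policy**
is `right_eye` (default, matching the usual plotting of right-eye
refraction), `mean`, or `worse_eye`. Group assignment always uses both
eyes. When the analysis eye is non-myopic but the subject is in the
myopia group (discordant eyes), the degree falls back to the worse eye
so that every myopia-group subject carries a degree — otherwise the
default right-eye policy would leave left-eye-only myopes ungraded.

## Twin statistics

Intrapair Pearson correlations are computed on pairs in recorded order
(twin 1 vs twin 2), separately by zygosity and refractive stratum. A
double-entry (intraclass) option exists but is not the default: with
ordered pairs the Fisher-z interval reproduces the reference confidence
bounds at the documented sample sizes. Confidence intervals use the
Fisher transform z = atanh(r), approximately normal with SD 1/√(n−3),
with the normal critical value (1.959964 at 95%); p-values come from the
t statistic r√((n−2)/(1−r²)) on n−2 df.

Heritability uses Falconer's estimator h² = 2(r_MZ − r_DZ), which
recovers the additive-genetic variance share a² under the ACE model
(r_MZ = a² + c², r_DZ = a²/2 + c²) and the equal-environments
assumption. It is reported both raw and clamped to [0, 1]; the raw value
is the primary one. Because the estimator has no convenient analytic
standard error, uncertainty comes from a percentile bootstrap that
resamples **pairs** (not individuals), independently within the MZ and
DZ lists; resamples with zero trait variance are redrawn and counted.
The bootstrap seed is mandatory, so runs are exactly reproducible.

Pair-level stratification is ambiguous when co-twins fall in different
groups. The default policy (`either_myopic`) places a pair in the
myopia stratum if either twin is myopic and in the emmetropia stratum
only when both twins are emmetropic; `concordant_only` and `twin1` are
available alternatives. This is a package choice among defensible rules,
not a claim about how any particular study resolved it.

Cohort descriptives (pair counts by sex composition; mean ± SE, median,
min, max of age and per-eye SE) are compared between zygosity groups
with the Pearson chi-square test (no continuity correction) for sex
composition and the Mann-Whitney U test (normal approximation with
midranks, tie-corrected variance and continuity correction) for the
quantitative variables. No multiple-testing correction is applied
anywhere; reports carry a note saying so.

## Genetic association

Genotypes are unordered allele pairs ("TC" ≡ "CT"), validated against
each SNP's declared allele set; missing calls are excluded per SNP
(pairwise deletion), so the two loci may have different genotyped N.
Allele frequencies follow from genotype counts; the minor allele is the
less frequent one. Hardy-Weinberg equilibrium is tested with the 1-df
Pearson chi-square against expected counts p²N, 2pqN, q²N at the sample
allele frequency; a conditional exact test is available as an option.

Five genetic models encode genotype effects, oriented by an explicit
risk allele (C for rs634990, G for rs8027411 by default — orientation
is configuration, never inferred from frequency):

* codominant — two indicators (heterozygote, risk homozygote), other
  homozygote as reference;
* dominant — (risk-hom + het) vs other-hom;
* recessive — (het + other-hom) vs risk-hom, i.e. the printed
  "(CT + TT) versus CC" contrast;
* overdominant — both homozygotes vs heterozygote;
* additive — risk-allele count 0/1/2.

Association fits are unadjusted logistic regressions of case status
(myopia vs emmetropia) on the encoded genotype, by iteratively
reweighted least squares with step-halving; convergence at maximum
absolute score < 1e-8 or relative log-likelihood change < 1e-10, at
most 50 iterations. Coefficients diverging past |β| > 15 are treated as
(quasi-)separation and reported through the Haldane-Anscombe-corrected
contingency estimator instead, never silently. Odds ratios carry 95%
Wald intervals exp(β ± 1.96·se); for 2×2 tables the Woolf interval
exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) is used, with 0.5 added to every
cell only when a zero cell occurs and the correction is requested. With
a single binary covariate the logistic and contingency estimators agree
exactly (to numerical precision), which the test suite exploits as a
cross-check; an external maximum-likelihood implementation
(statsmodels) serves as an independent oracle in tests.

Age/sex covariates can be supplied in configuration, but the default is
the unadjusted model: published "multivariate" odds ratios from
comparable analyses depend on unspecified adjustment sets and are
treated as context, not as reproduction targets.

The two-locus analysis forms the 9 ordered genotype combinations of
rs634990 × rs8027411 and, for each, compares carriers of that
combination against carriers of any other (subjects genotyped at both
loci only). The degree-stratified table counts the three genotypes per
SNP and the nine combinations within high / medium / mild myopia and
the emmetropic controls; every odds-ratio row in every output carries
the counts it was computed from.

Subject-level independence is assumed for association. A one-per-pair
filter is available (default off, logged prominently when on) for
designs where both co-twins were genotyped.

## Synthetic cohorts

The generator draws twin pairs with:

* an ACE-structured trait: trait = μ + A + C + E with variances a²σ²,
  c²σ², e²σ². MZ co-twins share A and C; for DZ co-twins A is split into
  a shared and a twin-specific component of variance a²σ²/2 each, so
  Corr(A1, A2) = 0.5 structurally (no correlated-noise shortcut). This
  gives population r_MZ = a² + c² and r_DZ = a²/2 + c² by construction.
* genotypes by gamete dropping: two parents are drawn as HWE genotypes
  and each DZ twin receives one independently chosen allele per parent,
  while MZ twins share a single gamete pair. MZ genotype concordance is
  exactly 1, the DZ additive correlation is the full-sib 1/2, and the
  marginal distribution stays HWE at the configured MAF.
* an optional genotype effect: the trait is shifted by −effect_d
  diopters per risk allele (identical for MZ co-twins by construction).
  Case status then derives from the classification rule applied to the
  trait, mirroring a real cohort design, so the per-allele odds
  multiplier is *induced* rather than specified; it is calibrated by
  brute force on a large reference simulation before recovery tests
  assert anything (see validation below).
* per-eye decomposition: each eye's SE is the trait plus Gaussian
  inter-eye noise; cylinder is a non-positive half-normal draw and
  sphere is back-solved as SE − cylinder/2, so recomputing the
  spherical equivalent recovers the per-eye SE exactly.

Default parameters mirror the cohort the package analyses: 135 MZ + 95
DZ pairs, ages uniform on 18–40 (shared within pair), sexes balanced
(MZ co-twins same-sex, DZ co-twins independent), μ = −1.3 D and
σ = 1.7 D (chosen to match the reported mean and standard error of
spherical equivalent at the reported sample size), a² = 0.672, c² = 0,
e² = 0.328, MAFs 0.476 and 0.486, inter-eye SD 0.25 D, cylinder scale
0.5 D, genotype effects 0. One RNG stream per run is seeded from the
configuration; the whole cohort is byte-reproducible from the seed.

What the generator does **not** emulate: the skewed, zero-inflated
shape of real refraction distributions (a single Gaussian matched to
the reported moments yields a higher myopia fraction and a smaller
emmetropic group than a real clinic sample); ascertainment and
recruitment effects; equal-environments violations; assortative mating;
X-linkage; gene-environment interaction; and any linkage disequilibrium
between the two loci (simulated independently). Passing recovery tests
therefore shows the estimators are correct *under their own
assumptions*, not that those assumptions hold in real cohorts.

## Validation experiments

`twinherit.validation` packages the simulation checks used by the test
suite and the acceptance script:

* Falconer recovery on population-level ACE pairs (20 000 MZ + 20 000
  DZ), with and without shared environment — the estimator should land
  within sampling error of a² in both cases;
* MZ genotype concordance and DZ additive genotype correlation
  (50 000 pairs);
* type-I error of the HWE chi-square at nominal 0.05 on multinomial
  draws (N = 272, MAF 0.476, 2 000 replicates);
* coverage of the additive-model Wald CI: with a 0.3 D per-allele
  effect, the induced odds ratio is calibrated by an additive logistic
  fit on a 5×10⁵-pair reference simulation (one twin per pair), then
  200 replicates of 1 500 cases / 1 500 controls (again one twin per
  pair, preserving independence) are checked for CI coverage of that
  value. The additive logistic model is mildly misspecified under
  threshold-liability generation, so the calibrated value depends
  slightly on the case-control ratio of the calibration sample; at this
  effect size the cohort-design and 1:1-design calibrations differ by
  about 1.4% in the odds ratio and coverage clears 0.9 against either.

Problem sizes were chosen so each experiment's Monte-Carlo error is
small against the tolerance it is checked to, while the whole suite
stays comfortably fast on a single core.

## Numerical choices and degenerate inputs

* |r| = 1 degenerates the Fisher interval to (r, r), flagged by width 0;
  n < 4 leaves the CI undefined (NaN bounds).
* Zero-variance samples, single-class outcomes, monomorphic SNPs and
  zero table margins raise typed errors rather than returning NaN.
* All-tied Mann-Whitney input returns p = 1 with U = n₁n₂/2.
* MAF ties at 0.5 resolve to the lexicographically smaller allele.
* Bootstrap resamples with zero variance are redrawn and counted.
* CSV numbers use '.' decimals, UTF-8, no locale-dependent parsing.

## Known limitations

* Falconer's estimator is a method-of-moments contrast, not a
  likelihood fit; full ACE/ADE structural-equation modelling is out of
  scope by design.
* Association treats subjects as unrelated; including both DZ co-twins
  understates standard errors slightly unless the one-per-pair filter
  is enabled.
* Stratum-specific correlations condition on the classified trait, so
  selection can shift them away from the population ACE values; the
  study-scale simulation check quantifies this (the replicate-mean
  Falconer estimate stays within ~0.05 of a² at 230 pairs, with large
  per-replicate spread).
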