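# twinherit

Twin-study analysis of myopia: refractive classification, heritability
of spherical equivalent from the classical MZ/DZ design, and candidate
SNP association (rs634990 near *GJD2*, rs8027411 in *RASGRF1*) — plus a
synthetic twin-cohort generator that makes every stage testable.

## The scientific problem

In a classical twin study, monozygotic (MZ) twins share all their
genes while dizygotic (DZ) twins share on average half of their
segregating genes; both share their rearing environment. If a trait is
heritable, MZ co-twins should therefore resemble each other more than
DZ co-twins, and under the ACE variance-decomposition model the
intrapair correlations satisfy r_MZ = a² + c² and r_DZ = a²/2 + c²
(a² additive-genetic, c² shared-environment, e² unique-environment
variance shares). Falconer's estimator turns the contrast into a
heritability estimate:

    h² = 2 × (r_MZ − r_DZ)

`twinherit` implements this pipeline for refractive error: per-eye
spherical equivalent (SE = sphere + cylinder/2), classification into
myopia (SE ≤ −0.5 D in at least one eye) and emmetropia (both eyes
within ±0.49 D) with mild/medium/high degree grading at −3 D and −6 D,
intrapair Pearson correlations with Fisher-z confidence intervals, a
pair-resampling bootstrap for h², and unadjusted logistic-regression
association of myopia with two candidate SNPs under five genetic models
(codominant, dominant, recessive, overdominant, additive), including
two-locus genotype combinations and degree-stratified tables.

A simulator generates cohorts with the same structure — ACE traits with
exact twin correlations, genotypes by gamete dropping (MZ concordance
1, DZ full-sib correlation 1/2, Hardy-Weinberg marginals), optional
genotype effects on the trait, and per-eye decomposition — so the
estimators can be validated by parameter recovery.

## Worked example

Simulate a cohort at the default study size (135 MZ + 95 DZ pairs),
classify it, and estimate heritability in the myopic stratum:

```python
from twinherit.synthetic_cohort import SimulationConfig, simulate_cohort
from twinherit.refraction import classify_cohort
from twinherit.twin_stats import stratify_pairs, estimate_heritability

sim = simulate_cohort(SimulationConfig(seed=20240915))
classified = classify_cohort(sim.cohort)
print(classified["group"].value_counts().to_dict())

pairs = stratify_pairs(classified)              # one row per pair
myo = pairs[pairs["stratum"] == "myopia"]
mz = myo[myo["zygosity"] == "MZ"][["x1", "x2"]].to_numpy()
dz = myo[myo["zygosity"] == "DZ"][["x1", "x2"]].to_numpy()
est = estimate_heritability(mz, dz, n_boot=1000, seed=7)
print(f"r_MZ = {est.r_mz.r:.3f} "
      f"(95% CI {est.r_mz.ci_low:.3f} to {est.r_mz.ci_high:.3f})")
print(f"r_DZ = {est.r_dz.r:.3f} "
      f"(95% CI {est.r_dz.ci_low:.3f} to {est.r_dz.ci_high:.3f})")
print(f"h2   = {est.h2_raw:.3f} "
      f"(bootstrap 95% CI {est.boot_ci_low:.3f} to {est.boot_ci_high:.3f})")
```

Output:

```
{'myopia': 329, 'excluded': 81, 'emmetropia': 50}
r_MZ = 0.476 (95% CI 0.313 to 0.612)
r_DZ = 0.180 (95% CI -0.029 to 0.374)
h2   = 0.591 (bootstrap 95% CI 0.124 to 1.006)
```

SNP association from genotype counts (CC/CT/TT for cases and controls):

```python
from twinherit.genetic_assoc import GenotypeCounts, model_association

case = GenotypeCounts("rs634990", ("C", "T"), 56, 147, 69)
ctrl = GenotypeCounts("rs634990", ("C", "T"), 20, 48, 32)
for model in ("dominant", "recessive", "additive"):
    for r in model_association(case, ctrl, model):
        print(f"{r.label}: OR {r.or_point:.2f} "
              f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}), p={r.p:.3f}")
```

```
dominant (CC+CT) vs TT: OR 1.38 (95% CI 0.84-2.29), p=0.203
recessive (CT+TT) vs CC: OR 0.96 (95% CI 0.54-1.71), p=0.901
additive per C allele: OR 1.17 (95% CI 0.83-1.63), p=0.369
```

### Command line

```sh
$ twinherit simulate --seed 3 --n-mz 135 --n-dz 95 --out cohort.csv
wrote 460 subjects to cohort.csv
$ twinherit report --cohort cohort.csv --seed 5 --out-dir report
INFO cohort: 460 subjects, 230 pairs
INFO h2_raw=0.4277 (bootstrap seed 5)
INFO pipeline complete: status=ok
report written to report (status=ok)
$ ls report
classified.tsv  report.json  run.log  table1_descriptives.tsv
table2_genotype_frequencies.tsv  table3_rs634990_models.tsv
table4_rs8027411_models.tsv  table5_combinations.tsv
table6_degree_stratified.tsv
```

`report.json` holds every correlation, heritability and odds-ratio
estimate together with the counts it was computed from; `run.log`
records seeds, versions and filter tallies. Reruns with the same input
and seed are byte-identical. Subcommands `classify`, `twinstats` and
`assoc` run individual stages.

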