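"""Cohort file formats, run configuration and the pipeline driver.

The cohort lives in a plain CSV ('.' decimal separator, UTF-8) with one
row per subject and exactly two subjects per twin pair:

    subject_id, pair_id, zygosity, sex, age_years,
    od_sphere, od_cylinder, os_sphere, os_cylinder,
    rs634990, rs8027411

Genotype columns hold unordered genotype strings ("CC", "CT", ...;
empty = missing).  ``run_pipeline`` ties the stages together
(classification -> twin statistics -> association) and emits TSV
tables, a JSON results document and a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import genetic_assoc as ga
from . import refraction, twin_stats
from .errors import TwinheritError, ValidationError

logger = logging.getLogger("twinherit")

COHORT_COLUMNS = [
    "subject_id", "pair_id", "zygosity", "sex", "age_years",
    "od_sphere", "od_cylinder", "os_sphere", "os_cylinder",
    "rs634990", "rs8027411",
]

_NUMERIC = ["age_years", "od_sphere", "od_cylinder", "os_sphere",
            "os_cylinder"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration; every field validated before computation."""

    seed: int = 0
    analysis_eye_policy: str = "right_eye"
    pair_stratification: str = "either_myopic"
    ci_level: float = 0.95
    n_boot: int = 1000
    models: tuple[str, ...] = ga.GENETIC_MODELS
    risk_alleles: dict = field(
        default_factory=lambda: {"rs634990": "C", "rs8027411": "G"}
    )
    correction: str = "haldane"
    one_per_pair: bool = False
    age_range: tuple[float, float] = (18.0, 40.0)

    def __post_init__(self):
        if self.analysis_eye_policy not in refraction.ANALYSIS_EYE_POLICIES:
            raise TwinheritError(
                f"unknown analysis-eye policy {self.analysis_eye_policy!r}"
            )
        if not (0.5 < self.ci_level < 1.0):
            raise TwinheritError("ci_level must lie in (0.5, 1)")
        for m in self.models:
            if m not in ga.GENETIC_MODELS:
                raise TwinheritError(f"unknown genetic model {m!r}")

    def snp_definitions(self) -> dict[str, ga.SnpDefinition]:
        out = {}
        for snp_id, base in ga.DEFAULT_SNPS.items():
            risk = self.risk_alleles.get(snp_id, base.risk_allele)
            out[snp_id] = ga.SnpDefinition(snp_id, base.alleles, risk)
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TwinheritError(f"unknown config keys: {sorted(unknown)}")
        for key in ("models",):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["models"] = list(self.models)
        d["age_range"] = list(self.age_range)
        return d


def read_cohort(
    path,
    age_range: tuple[float, float] = (18.0, 40.0),
) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Per-row problems are collected (with line numbers) and raised
    together as :class:`ValidationError`; genotype strings are
    normalised to unordered form ("TC" -> "CT").
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    errors = []
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError([f"missing columns: {missing_cols}"])
    df = df[COHORT_COLUMNS].copy()
    for col in _NUMERIC:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        for idx in df.index[bad]:
            errors.append(
                f"line {idx + 2}: malformed numeric {col}={df.at[idx, col]!r}"
            )
        df[col] = parsed
    for idx, z in df["zygosity"].items():
        if z not in ("MZ", "DZ"):
            errors.append(f"line {idx + 2}: unknown zygosity {z!r}")
    for idx, s in df["sex"].items():
        if s not in ("M", "F"):
            errors.append(f"line {idx + 2}: unknown sex {s!r}")
    lo, hi = age_range
    for idx, a in df["age_years"].items():
        if pd.notna(a) and not (lo <= a <= hi):
            errors.append(
                f"line {idx + 2}: age {a} outside plausible range "
                f"[{lo}, {hi}]"
            )
    for snp_id, snp in ga.DEFAULT_SNPS.items():
        normalized = []
        for idx, g in df[snp_id].items():
            try:
                norm = ga.normalize_genotype(g, snp)
                normalized.append("" if norm is None else norm)
            except TwinheritError as exc:
                errors.append(f"line {idx + 2}: {exc}")
                normalized.append("")
        df[snp_id] = normalized
    sizes = df.groupby("pair_id").size()
    for pair_id, n in sizes.items():
        if n != 2:
            errors.append(
                f"pair {pair_id!r} has {n} member(s), expected exactly 2"
            )
    if df["subject_id"].duplicated().any():
        dups = df["subject_id"][df["subject_id"].duplicated()].tolist()
        errors.append(f"duplicate subject ids: {dups}")
    for _, sub in df.groupby("pair_id"):
        if sub["zygosity"].nunique() > 1:
            errors.append(
                f"pair {sub['pair_id'].iloc[0]!r} mixes zygosity labels"
            )
    if errors:
        raise ValidationError(errors)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table in the standard CSV schema."""
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def to_subject_records(cohort: pd.DataFrame) -> list[refraction.SubjectRecord]:
    """Materialise :class:`SubjectRecord` objects from a cohort frame."""
    records = []
    for _, row in cohort.iterrows():
        records.append(refraction.SubjectRecord(
            subject_id=row["subject_id"],
            pair_id=row["pair_id"],
            zygosity=row["zygosity"],
            sex=row["sex"],
            age=float(row["age_years"]),
            od=refraction.EyeMeasurement(
                "OD", float(row["od_sphere"]), float(row["od_cylinder"])),
            os=refraction.EyeMeasurement(
                "OS", float(row["os_sphere"]), float(row["os_cylinder"])),
            genotypes={
                snp: (row[snp] or None) for snp in ga.DEFAULT_SNPS
            },
        ))
    return records


def read_vcf_genotypes(path, snps=None) -> pd.DataFrame:
    """Genotype strings per sample from a minimal VCF (GT field, diploid).

    Returns a frame indexed by sample with one column per declared SNP
    found in the file; unphased and phased GT separators are accepted.
    Requires cyvcf2 (lazy import).
    """
    from cyvcf2 import VCF

    snps = snps or ga.DEFAULT_SNPS
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data = {}
    for variant in vcf:
        snp = snps.get(variant.ID)
        if snp is None:
            continue
        alleles = [variant.REF] + list(variant.ALT)
        column = []
        for gt in variant.genotypes:  # [allele1, allele2, phased]
            i, j = gt[0], gt[1]
            if i < 0 or j < 0:
                column.append("")
            else:
                column.append("".join(sorted(alleles[i] + alleles[j])))
        data[variant.ID] = column
    return pd.DataFrame(data, index=samples)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _association_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(dict(
            label=r.label, or_point=r.or_point, ci_low=r.ci_low,
            ci_high=r.ci_high, p=r.p, method=r.method,
            estimable=r.estimable, counts=json.dumps(_jsonable(r.counts)),
        ))
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    cohort: pd.DataFrame | str | Path,
    outdir: str | Path,
) -> dict:
    """Run classification, twin statistics and association end to end.

    Writes Table-1..6-shaped TSVs, ``report.json`` and ``run.log`` into
    ``outdir`` and returns the report dictionary.  Stages that cannot
    be computed (e.g. an empty stratum) are reported as not estimable;
    the report's ``status`` is ``"partial"`` in that case, ``"ok"``
    otherwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    status = "ok"
    try:
        if not isinstance(cohort, pd.DataFrame):
            cohort = read_cohort(cohort, age_range=config.age_range)
        logger.info("cohort: %d subjects, %d pairs", len(cohort),
                    cohort["pair_id"].nunique())
        logger.info("config: %s", json.dumps(config.to_dict()))

        classified = refraction.classify_cohort(
            cohort, policy=config.analysis_eye_policy
        )
        classified.to_csv(outdir / "classified.tsv", sep="\t", index=False)

        report = {"config": config.to_dict(), "n_subjects": len(classified)}
        report["group_counts"] = (
            classified["group"].value_counts().to_dict()
        )
        report["degree_counts"] = (
            classified.loc[classified["group"] == "myopia", "degree"]
            .value_counts().to_dict()
        )

        # ---- Table 1: descriptives + MZ-vs-DZ comparison tests
        desc = twin_stats.describe_cohort(classified)
        desc.to_csv(outdir / "table1_descriptives.tsv", sep="\t", index=False)
        try:
            report["zygosity_tests"] = twin_stats.zygosity_comparison_tests(
                classified
            )
        except TwinheritError as exc:
            logger.warning("zygosity comparison not estimable: %s", exc)
            report["zygosity_tests"] = {"not_estimable": str(exc)}
            status = "partial"

        # ---- correlations and heritability, per stratum
        pairs = twin_stats.stratify_pairs(
            classified, policy=config.pair_stratification
        )
        corr = {}
        for stratum in ("myopia", "emmetropia"):
            corr[stratum] = {}
            for zyg in ("MZ", "DZ"):
                sel = pairs[(pairs["stratum"] == stratum)
                            & (pairs["zygosity"] == zyg)]
                try:
                    est = twin_stats.pearson_r(
                        sel["x1"], sel["x2"], level=config.ci_level
                    )
                    corr[stratum][zyg] = dataclasses.asdict(est)
                except TwinheritError as exc:
                    corr[stratum][zyg] = {"not_estimable": str(exc)}
        report["correlations"] = corr

        myo = pairs[pairs["stratum"] == "myopia"]
        mz = myo[myo["zygosity"] == "MZ"][["x1", "x2"]].to_numpy()
        dz = myo[myo["zygosity"] == "DZ"][["x1", "x2"]].to_numpy()
        try:
            h2 = twin_stats.estimate_heritability(
                mz, dz, level=config.ci_level, n_boot=config.n_boot,
                seed=config.seed,
            )
            report["heritability"] = dataclasses.asdict(h2)
            logger.info("h2_raw=%.4f (bootstrap seed %d)", h2.h2_raw,
                        config.seed)
        except TwinheritError as exc:
            logger.warning("heritability not estimable: %s", exc)
            report["heritability"] = {"not_estimable": str(exc)}
            status = "partial"

        # ---- association: myopia cases vs emmetropia controls
        assoc_df = classified[
            classified["group"].isin(["myopia", "emmetropia"])
        ].copy()
        if config.one_per_pair:
            before = len(assoc_df)
            assoc_df = assoc_df.sort_values("subject_id").groupby(
                "pair_id", as_index=False
            ).first()
            logger.info(
                "one-per-pair filter: kept %d of %d subjects",
                len(assoc_df), before,
            )
        snps = config.snp_definitions()
        y = (assoc_df["group"] == "myopia").astype(int).to_numpy()

        table2_rows = []
        models_out = {}
        for snp_id, snp in snps.items():
            counts_all = ga.genotype_counts(assoc_df[snp_id], snp)
            row = {"snp_id": snp_id, "n": counts_all.n,
                   "n_missing": counts_all.n_missing}
            row.update(counts_all.as_dict())
            if counts_all.n > 0:
                allele, maf = ga.minor_allele_frequency(counts_all)
                row["minor_allele"] = allele
                row["maf"] = maf
                try:
                    chi2, p = ga.hwe_test(counts_all)
                    row["hwe_chi2"], row["hwe_p"] = chi2, p
                except TwinheritError as exc:
                    row["hwe_p"] = None
                    logger.warning("HWE undefined for %s: %s", snp_id, exc)
            table2_rows.append(row)

            case_counts = ga.genotype_counts(
                assoc_df.loc[y == 1, snp_id], snp)
            ctrl_counts = ga.genotype_counts(
                assoc_df.loc[y == 0, snp_id], snp)
            snp_models = []
            for model in config.models:
                try:
                    snp_models.extend(ga.model_association(
                        case_counts, ctrl_counts, model, snp))
                except TwinheritError as exc:
                    logger.warning("%s %s model not estimable: %s",
                                   snp_id, model, exc)
                    status = "partial"
            models_out[snp_id] = snp_models
        table2 = pd.DataFrame(table2_rows)
        table2.to_csv(outdir / "table2_genotype_frequencies.tsv",
                      sep="\t", index=False)
        report["genotype_summary"] = _jsonable(table2_rows)

        for i, (snp_id, results) in enumerate(models_out.items(), start=3):
            frame = _association_frame(results)
            frame.to_csv(outdir / f"table{i}_{snp_id}_models.tsv",
                         sep="\t", index=False)
        report["model_associations"] = {
            k: _jsonable(v) for k, v in models_out.items()
        }

        combos = ga.combination_analysis(
            assoc_df["rs634990"], assoc_df["rs8027411"], y,
            snp1=snps["rs634990"], snp2=snps["rs8027411"],
        )
        _association_frame(combos).to_csv(
            outdir / "table5_combinations.tsv", sep="\t", index=False)
        report["combination_associations"] = _jsonable(combos)

        table6 = ga.degree_stratified_table(
            classified, snp1=snps["rs634990"], snp2=snps["rs8027411"])
        table6.to_csv(outdir / "table6_degree_stratified.tsv", sep="\t")
        report["degree_stratified"] = _jsonable(
            table6.to_dict(orient="index"))

        report["status"] = status
        report["note"] = (
            "No multiple-testing correction is applied anywhere in this "
            "report."
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        logger.info("pipeline complete: status=%s", status)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
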