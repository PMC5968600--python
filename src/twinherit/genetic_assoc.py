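"""Candidate-SNP case-control association for myopia.

Covers genotype summaries (counts, minor-allele frequency,
Hardy-Weinberg equilibrium), single-SNP association under five genetic
models (codominant, dominant, recessive, overdominant, additive) fitted
by logistic regression, two-locus genotype-combination odds ratios, and
the degree-of-myopia stratified genotype table.

The two candidate loci are rs634990 near GJD2 (alleles C/T) and
rs8027411 in RASGRF1 (alleles G/T); any diallelic SNP can be declared
via :class:`SnpDefinition`.  All odds ratios carry 95% Wald confidence
intervals; 2x2 tables with zero cells use the Haldane-Anscombe 0.5
correction only when explicitly requested, never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DataError,
    DegenerateDataError,
    SeparationError,
    UndefinedOddsRatioError,
    UndefinedTestError,
)

GENETIC_MODELS = ("codominant", "dominant", "recessive", "overdominant",
                  "additive")

#: Critical value for 95% Wald/Woolf intervals (normal quantile).
Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class SnpDefinition:
    """A diallelic SNP: identifier, declared alleles and risk allele."""

    snp_id: str
    alleles: tuple[str, str]
    risk_allele: str

    def __post_init__(self):
        if self.risk_allele not in self.alleles:
            raise ConfigurationError(
                f"risk allele {self.risk_allele!r} not among declared "
                f"alleles {self.alleles} for {self.snp_id}"
            )

    @property
    def genotype_classes(self) -> tuple[str, str, str]:
        a, b = sorted(self.alleles)
        return (a + a, a + b, b + b)


DEFAULT_SNPS: dict[str, SnpDefinition] = {
    "rs634990": SnpDefinition("rs634990", ("C", "T"), "C"),
    "rs8027411": SnpDefinition("rs8027411", ("G", "T"), "G"),
}


def normalize_genotype(genotype: Optional[str], snp: SnpDefinition) -> Optional[str]:
    """Canonical unordered genotype string (alphabetical, 'TC' -> 'CT').

    Empty/None/NaN is missing (returns None).  Alleles outside the
    SNP's declared set raise :class:`DataError`.
    """
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return None
    g = str(genotype).strip().upper()
    if g in ("", "NA", "NAN", "."):
        return None
    if len(g) != 2:
        raise DataError(f"{snp.snp_id}: malformed genotype {genotype!r}")
    for allele in g:
        if allele not in snp.alleles:
            raise DataError(
                f"{snp.snp_id}: allele {allele!r} outside declared set "
                f"{snp.alleles}"
            )
    return "".join(sorted(g))


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one SNP (aa / ab / bb, alleles sorted)."""

    snp_id: str
    alleles: tuple[str, str]
    n_aa: int
    n_ab: int
    n_bb: int
    n_missing: int = 0

    def __post_init__(self):
        if min(self.n_aa, self.n_ab, self.n_bb, self.n_missing) < 0:
            raise DataError("negative genotype count")

    @property
    def n(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    def as_dict(self) -> dict[str, int]:
        a, b = sorted(self.alleles)
        return {a + a: self.n_aa, a + b: self.n_ab, b + b: self.n_bb}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Case-control 2x2 counts: (exposed, unexposed) x (case, control)."""

    a: float  # exposed cases
    b: float  # unexposed cases
    c: float  # exposed controls
    d: float  # unexposed controls

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DataError("negative cell count")
        if self.a + self.b + self.c + self.d <= 0:
            raise DataError("empty table")


@dataclass(frozen=True)
class AssociationResult:
    """One odds-ratio row: label, Exp(B), 95% CI, p, and its counts."""

    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    counts: dict = field(default_factory=dict)
    method: str = "logistic"
    estimable: bool = True


def genotype_counts(
    calls: Iterable[Optional[str]], snp: SnpDefinition
) -> GenotypeCounts:
    """Tally genotype classes for one SNP; missing calls counted apart."""
    classes = snp.genotype_classes
    tally = {c: 0 for c in classes}
    missing = 0
    for call in calls:
        g = normalize_genotype(call, snp)
        if g is None:
            missing += 1
        else:
            tally[g] += 1
    return GenotypeCounts(
        snp_id=snp.snp_id,
        alleles=tuple(sorted(snp.alleles)),
        n_aa=tally[classes[0]],
        n_ab=tally[classes[1]],
        n_bb=tally[classes[2]],
        n_missing=missing,
    )


def minor_allele_frequency(counts: GenotypeCounts) -> tuple[str, float]:
    """Minor allele and its sample frequency (2*n_aa + n_ab)/(2N).

    Ties at 0.5 resolve to the lexicographically smaller allele.
    """
    if counts.n == 0:
        raise DegenerateDataError(f"{counts.snp_id}: no genotyped subjects")
    a, b = counts.alleles
    freq_a = (2 * counts.n_aa + counts.n_ab) / (2.0 * counts.n)
    if freq_a < 0.5 or (freq_a == 0.5 and a < b):
        return a, freq_a
    return b, 1.0 - freq_a


def hwe_test(counts: GenotypeCounts, method: str = "chi2") -> tuple[float, float]:
    """Hardy-Weinberg equilibrium test from genotype counts.

    ``chi2`` (default): 1-df Pearson chi-square of observed vs expected
    counts (p^2 N, 2pq N, q^2 N) at the sample allele frequency.
    ``exact``: conditional exact test summing heterozygote-count
    probabilities no larger than the observed one.
    Monomorphic samples leave the test undefined.
    """
    n = counts.n
    if n == 0:
        raise DegenerateDataError(f"{counts.snp_id}: no genotyped subjects")
    p = (2 * counts.n_aa + counts.n_ab) / (2.0 * n)
    if p == 0.0 or p == 1.0:
        raise DegenerateDataError(f"{counts.snp_id}: monomorphic sample")
    if method == "chi2":
        expected = np.array([p * p * n, 2 * p * (1 - p) * n,
                             (1 - p) * (1 - p) * n])
        observed = np.array([counts.n_aa, counts.n_ab, counts.n_bb],
                            dtype=float)
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        return chi2, float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return float("nan"), _hwe_exact_p(counts.n_aa, counts.n_ab, counts.n_bb)
    raise ConfigurationError(f"unknown HWE method {method!r}")


def _hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Conditional exact HWE p-value.

    Conditions on the allele counts and sums the probability of every
    heterozygote count whose probability does not exceed the observed
    one.  Probabilities are built by the standard ratio recurrence from
    the mode, which is numerically stable for the sample sizes here.
    """
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # P(h) / P(h-2) = 4 * n_r_hom * n_c_hom / (h * (h - 1)) with the
        # homozygote counts at heterozygote count h-2
        prev_rare_hom = (n_rare - hets[i - 1]) // 2
        prev_comm_hom = n - hets[i - 1] - prev_rare_hom
        logp[i] = logp[i - 1] + np.log(
            4.0 * prev_rare_hom * prev_comm_hom / (h * (h - 1.0))
        )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = float(probs[np.where(hets == n_ab)[0][0]])
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def encode_model(
    genotype: str, model: str, snp: SnpDefinition
):
    """Encode a genotype under a genetic model, oriented by risk allele.

    dominant: 1 for risk-homozygote or heterozygote vs other homozygote;
    recessive: 1 for heterozygote or other homozygote vs risk-homozygote
    (the printed contrast "(het + other-hom) versus risk-hom");
    overdominant: 1 for either homozygote vs heterozygote;
    additive: risk-allele count 0/1/2;
    codominant: pair of indicators (heterozygote, risk homozygote) with
    the other homozygote as reference.
    """
    g = normalize_genotype(genotype, snp)
    if g is None:
        raise DataError("cannot encode a missing genotype")
    risk = snp.risk_allele
    other = [x for x in snp.alleles if x != risk][0]
    risk_hom = risk + risk
    other_hom = other + other
    het = "".join(sorted(risk + other))
    if model == "dominant":
        return 1 if g in (risk_hom, het) else 0
    if model == "recessive":
        return 1 if g in (het, other_hom) else 0
    if model == "overdominant":
        return 1 if g in (risk_hom, other_hom) else 0
    if model == "additive":
        return sum(1 for allele in g if allele == risk)
    if model == "codominant":
        return (1 if g == het else 0, 1 if g == risk_hom else 0)
    raise ConfigurationError(
        f"unknown genetic model {model!r}; expected one of {GENETIC_MODELS}"
    )


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit: coefficient table and diagnostics."""

    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def result(self, term: str, counts: Optional[dict] = None,
               label: Optional[str] = None) -> AssociationResult:
        """Wald odds-ratio summary for one coefficient."""
        j = self.terms.index(term)
        b, s = float(self.beta[j]), float(self.se[j])
        z = b / s if s > 0 else float("inf")
        return AssociationResult(
            label=label or term,
            or_point=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * s)),
            ci_high=float(np.exp(b + Z95 * s)),
            p=float(2.0 * stats.norm.sf(abs(z))),
            counts=counts or {},
            method="logistic",
        )


def logistic_fit(
    X,
    y,
    weights=None,
    add_intercept: bool = True,
    term_names: Optional[Sequence[str]] = None,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    loglik_rtol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Converges when the maximum absolute score drops below ``score_tol``
    or the relative log-likelihood change below ``loglik_rtol``.
    Frequency ``weights`` allow aggregated (grouped) data.  Diverging
    coefficients (|beta| > 15 on any term) indicate complete or
    quasi-complete separation and raise :class:`SeparationError`
    advising the corrected contingency estimator.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if X.shape[0] != len(y) or len(w) != len(y):
        raise ValueError("X, y and weights must align on observations")
    n_cov = X.shape[1]
    if n_cov > 0 and np.any(np.ptp(X, axis=0) == 0):
        raise DegenerateDataError("a covariate is constant")
    y_mean = np.average(y, weights=w)
    if y_mean <= 0 or y_mean >= 1:
        raise DegenerateDataError("outcome has a single class")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + [
            term_names[i] if term_names else f"x{i}" for i in range(n_cov)
        ]
    else:
        names = list(term_names) if term_names else [f"x{i}" for i in range(n_cov)]

    def loglik(b):
        mu = np.clip(1.0 / (1.0 + np.exp(-(X @ b))), 1e-12, 1 - 1e-12)
        return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))

    beta = np.zeros(X.shape[1])
    if add_intercept:
        beta[0] = np.log(y_mean / (1.0 - y_mean))
    ll_old = loglik(beta)
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        score = X.T @ (w * (y - mu))
        info = (X * (w * mu * (1 - mu))[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or collinearity); "
                "use contingency_or with the Haldane-Anscombe correction"
            ) from exc
        # step-halving keeps a Newton overshoot from being mistaken for
        # separation; a genuinely diverging fit keeps improving as beta
        # grows and still trips the guard below
        candidate = beta + step
        halvings = 0
        while loglik(candidate) < ll_old and halvings < 20:
            step = step / 2.0
            candidate = beta + step
            halvings += 1
        beta = candidate
        if np.any(np.abs(beta) > 15):
            raise SeparationError(
                "coefficients diverging (|beta| > 15): separation detected; "
                "use contingency_or with the Haldane-Anscombe correction"
            )
        ll = loglik(beta)
        if np.max(np.abs(score)) < score_tol or (
            abs(ll - ll_old) < loglik_rtol * (abs(ll_old) + 1e-30)
        ):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    info = (X * (w * mu * (1 - mu))[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        terms=tuple(names), beta=beta, se=se, loglik=ll_old,
        n_iter=it, converged=converged,
    )


def contingency_or(
    table: ContingencyTable2x2, correction: str = "none"
) -> AssociationResult:
    """Odds ratio (a*d)/(b*c) with the Woolf log-scale 95% CI.

    ``correction='haldane'`` adds 0.5 to every cell when any cell is
    zero (Haldane-Anscombe); with ``'none'`` a zero cell leaves the OR
    undefined and raises.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if correction not in ("none", "haldane"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    corrected = False
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise UndefinedOddsRatioError(
                "zero cell in 2x2 table; request the Haldane-Anscombe "
                "correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_point = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = np.log(or_point) / se_log
    return AssociationResult(
        label="2x2",
        or_point=float(or_point),
        ci_low=float(np.exp(np.log(or_point) - Z95 * se_log)),
        ci_high=float(np.exp(np.log(or_point) + Z95 * se_log)),
        p=float(2.0 * stats.norm.sf(abs(z))),
        counts=dict(a=table.a, b=table.b, c=table.c, d=table.d,
                    haldane=corrected),
        method="contingency" + ("+haldane" if corrected else ""),
    )


def _expand_counts(case: GenotypeCounts, control: GenotypeCounts, snp):
    """Subject-level genotype strings and outcomes from grouped counts."""
    classes = snp.genotype_classes
    genos, ys, ws = [], [], []
    for cls, n_case, n_ctrl in zip(
        classes,
        (case.n_aa, case.n_ab, case.n_bb),
        (control.n_aa, control.n_ab, control.n_bb),
    ):
        if n_case > 0:
            genos.append(cls); ys.append(1.0); ws.append(n_case)
        if n_ctrl > 0:
            genos.append(cls); ys.append(0.0); ws.append(n_ctrl)
    return genos, np.array(ys), np.array(ws, dtype=float)


def model_association(
    case: GenotypeCounts,
    control: GenotypeCounts,
    model: str,
    snp: Optional[SnpDefinition] = None,
) -> list[AssociationResult]:
    """Case-control association for one SNP under one genetic model.

    Expands the genotype counts to grouped subject-level encodings and
    fits the logistic model; the codominant model returns two rows (one
    per non-reference genotype), every other model a single row.  By
    construction the single-indicator models reproduce the odds ratio
    of the corresponding collapsed 2x2 table.
    """
    if snp is None:
        snp = DEFAULT_SNPS.get(case.snp_id)
        if snp is None:
            raise ConfigurationError(
                f"no SNP definition for {case.snp_id!r}; pass snp="
            )
    if case.snp_id != control.snp_id or case.alleles != control.alleles:
        raise ConfigurationError("case/control counts refer to different SNPs")
    genos, y, w = _expand_counts(case, control, snp)
    risk = snp.risk_allele
    other = [x for x in snp.alleles if x != risk][0]
    het = "".join(sorted(risk + other))
    case_d, ctrl_d = case.as_dict(), control.as_dict()
    counts = {"case": case_d, "control": ctrl_d}

    if model == "codominant":
        enc = np.array([encode_model(g, "codominant", snp) for g in genos],
                       dtype=float)
        fit = logistic_fit(enc, y, weights=w,
                           term_names=["het", "risk_hom"])
        return [
            fit.result("het", counts,
                       label=f"codominant {het} vs {other*2}"),
            fit.result("risk_hom", counts,
                       label=f"codominant {risk*2} vs {other*2}"),
        ]
    enc = np.array([[encode_model(g, model, snp)] for g in genos],
                   dtype=float)
    fit = logistic_fit(enc, y, weights=w, term_names=[model])
    labels = {
        "dominant": f"dominant ({risk*2}+{het}) vs {other*2}",
        "recessive": f"recessive ({het}+{other*2}) vs {risk*2}",
        "overdominant": f"overdominant ({risk*2}+{other*2}) vs {het}",
        "additive": f"additive per {risk} allele",
    }
    return [fit.result(model, counts, label=labels[model])]


def combination_analysis(
    genotypes1: Sequence[Optional[str]],
    genotypes2: Sequence[Optional[str]],
    outcome: Sequence[int],
    snp1: SnpDefinition = DEFAULT_SNPS["rs634990"],
    snp2: SnpDefinition = DEFAULT_SNPS["rs8027411"],
) -> list[AssociationResult]:
    """Two-locus genotype-combination odds ratios (9 ordered combinations).

    For each of the 3x3 genotype combinations the odds of being a case
    are compared between carriers of that combination and carriers of
    any other, via a single-indicator logistic fit.  Subjects missing
    either genotype are dropped (pairwise deletion).  On separation the
    Haldane-corrected contingency estimator is substituted and the row
    is marked accordingly; combinations absent from both classes are
    flagged not estimable.
    """
    y = np.asarray(outcome, dtype=float)
    combos = []
    keep_g1, keep_g2, keep_y = [], [], []
    for g1, g2, yy in zip(genotypes1, genotypes2, y):
        n1 = normalize_genotype(g1, snp1)
        n2 = normalize_genotype(g2, snp2)
        if n1 is None or n2 is None:
            continue
        keep_g1.append(n1); keep_g2.append(n2); keep_y.append(yy)
    keep_y = np.asarray(keep_y)
    results = []
    for c1 in snp1.genotype_classes:
        for c2 in snp2.genotype_classes:
            label = f"{c1}+{c2}"
            indicator = np.array(
                [1.0 if (a == c1 and b == c2) else 0.0
                 for a, b in zip(keep_g1, keep_g2)]
            )
            a = float(np.sum(indicator * keep_y))          # carrier cases
            b = float(np.sum((1 - indicator) * keep_y))    # other cases
            c = float(np.sum(indicator * (1 - keep_y)))    # carrier controls
            d = float(np.sum((1 - indicator) * (1 - keep_y)))
            counts = dict(carrier_cases=a, other_cases=b,
                          carrier_controls=c, other_controls=d)
            if a + c == 0:
                results.append(AssociationResult(
                    label=label, or_point=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"),
                    p=float("nan"), counts=counts,
                    method="none", estimable=False,
                ))
                continue
            try:
                fit = logistic_fit(indicator[:, None], keep_y,
                                   term_names=["combo"])
                res = fit.result("combo", counts, label=label)
            except (SeparationError, DegenerateDataError):
                res = contingency_or(
                    ContingencyTable2x2(a, b, c, d), correction="haldane"
                )
                res = AssociationResult(
                    label=label, or_point=res.or_point, ci_low=res.ci_low,
                    ci_high=res.ci_high, p=res.p, counts=counts,
                    method=res.method,
                )
            results.append(res)
    return results


def degree_stratified_table(
    classified: pd.DataFrame,
    snp1: SnpDefinition = DEFAULT_SNPS["rs634990"],
    snp2: SnpDefinition = DEFAULT_SNPS["rs8027411"],
) -> pd.DataFrame:
    """Genotype and two-locus combination counts by myopia degree.

    Rows: high / medium / mild myopia and the emmetropic controls.
    Columns: the three genotype classes of each SNP and the nine
    ordered combinations (combination cells count only subjects
    genotyped at both loci).
    """
    strata = [("high", lambda d: (d["group"] == "myopia") & (d["degree"] == "high")),
              ("medium", lambda d: (d["group"] == "myopia") & (d["degree"] == "medium")),
              ("mild", lambda d: (d["group"] == "myopia") & (d["degree"] == "mild")),
              ("control", lambda d: d["group"] == "emmetropia")]
    combo_cols = [f"{c1}+{c2}" for c1 in snp1.genotype_classes
                  for c2 in snp2.genotype_classes]
    columns = (["n"] + [f"{snp1.snp_id}:{c}" for c in snp1.genotype_classes]
               + [f"{snp2.snp_id}:{c}" for c in snp2.genotype_classes]
               + combo_cols)
    rows = {}
    for name, mask_fn in strata:
        sub = classified[mask_fn(classified)] if len(classified) else classified
        row = dict.fromkeys(columns, 0)
        row["n"] = len(sub)
        g1 = [normalize_genotype(g, snp1)
              for g in (sub[snp1.snp_id] if snp1.snp_id in sub.columns else [])]
        g2 = [normalize_genotype(g, snp2)
              for g in (sub[snp2.snp_id] if snp2.snp_id in sub.columns else [])]
        for g in g1:
            if g is not None:
                row[f"{snp1.snp_id}:{g}"] += 1
        for g in g2:
            if g is not None:
                row[f"{snp2.snp_id}:{g}"] += 1
        for a, b in zip(g1, g2):
            if a is not None and b is not None:
                row[f"{a}+{b}"] += 1
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)
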