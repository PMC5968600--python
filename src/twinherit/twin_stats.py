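"""Intrapair correlation, Falconer heritability and cohort descriptives.

The classical twin design contrasts monozygotic (MZ) pairs, who share
all segregating genes, with dizygotic (DZ) pairs, who share half on
average.  Under equal environments the intrapair Pearson correlations
satisfy r_MZ = a2 + c2 and r_DZ = a2/2 + c2 (a2 additive-genetic, c2
shared-environment variance proportions), so Falconer's estimator

    h2 = 2 * (r_MZ - r_DZ)

recovers the narrow-sense heritability a2.  Correlation confidence
intervals use the Fisher z transform; heritability uncertainty is
quantified by a pair-resampling bootstrap (the point estimator itself
carries no analytic standard error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    UndefinedTestError,
)


@dataclass(frozen=True)
class PairedTrait:
    """Trait values of the two members of one twin pair, recorded order."""

    pair_id: str
    zygosity: str
    x1: float
    x2: float


@dataclass(frozen=True)
class CorrelationEstimate:
    """Pearson correlation with Fisher-z CI and t-test p-value."""

    r: float
    n: int
    ci_low: float
    ci_high: float
    level: float
    p: float


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Falconer heritability, raw and clamped, with optional bootstrap CI."""

    r_mz: CorrelationEstimate
    r_dz: CorrelationEstimate
    h2_raw: float
    h2: float
    boot_ci_low: Optional[float] = None
    boot_ci_high: Optional[float] = None
    n_boot: Optional[int] = None
    seed: Optional[int] = None


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation.

    z = atanh(r) is approximately normal with standard deviation
    1/sqrt(n-3); the bounds are tanh(z -/+ z_crit/sqrt(n-3)).

    Parameters
    ----------
    r : correlation in (-1, 1); at |r| = 1 the interval degenerates to
        (r, r).
    n : number of pairs, at least 4.
    level : two-sided confidence level.
    """
    if n < 4:
        raise InsufficientDataError(f"Fisher CI needs n >= 4 pairs, got {n}")
    if abs(r) >= 1.0:
        return (float(r), float(r))
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def pearson_r(
    x1: Sequence[float],
    x2: Sequence[float],
    level: float = 0.95,
) -> CorrelationEstimate:
    """Sample Pearson correlation of twin-1 vs twin-2 trait values.

    The p-value is the two-sided t-test with n-2 degrees of freedom on
    t = r*sqrt((n-2)/(1-r^2)); the CI is the Fisher-z interval (NaN
    bounds for n < 4, where it is undefined).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = len(x1)
    if len(x2) != n:
        raise ValueError("x1 and x2 must have equal length")
    if n < 3:
        raise InsufficientDataError(f"need at least 3 pairs, got {n}")
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise DegenerateDataError("zero variance in one coordinate")
    r = float(np.corrcoef(x1, x2)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    if n >= 4:
        lo, hi = fisher_ci(r, n, level)
    else:
        lo, hi = float("nan"), float("nan")
    return CorrelationEstimate(r=r, n=n, ci_low=lo, ci_high=hi, level=level, p=p)


def falconer_h2(
    r_mz: CorrelationEstimate | float,
    r_dz: CorrelationEstimate | float,
) -> HeritabilityEstimate:
    """Falconer heritability h2 = 2*(r_MZ - r_DZ).

    Both the raw value and the clamp to [0, 1] are reported; raw values
    above 1 (or below 0) indicate sampling noise or assumption
    violations and are preserved for inspection.
    """
    r_mz = _as_estimate(r_mz)
    r_dz = _as_estimate(r_dz)
    h2_raw = 2.0 * (r_mz.r - r_dz.r)
    return HeritabilityEstimate(
        r_mz=r_mz,
        r_dz=r_dz,
        h2_raw=h2_raw,
        h2=min(1.0, max(0.0, h2_raw)),
    )


def _as_estimate(r) -> CorrelationEstimate:
    if isinstance(r, CorrelationEstimate):
        return r
    return CorrelationEstimate(
        r=float(r), n=0, ci_low=float("nan"), ci_high=float("nan"),
        level=0.95, p=float("nan"),
    )


def bootstrap_h2(
    mz_pairs,
    dz_pairs,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float, int]:
    """Percentile bootstrap CI for h2_raw, resampling pairs within zygosity.

    Pairs (not individuals) are resampled with replacement,
    independently within the MZ and the DZ list, and Falconer's
    estimator is recomputed per replicate.  Resamples with zero trait
    variance are redrawn; their count is returned as the third element.
    Deterministic given ``seed``.
    """
    if n_boot < 200:
        raise InsufficientDataError("n_boot must be at least 200")
    mz = np.atleast_2d(np.asarray(mz_pairs, dtype=float))
    dz = np.atleast_2d(np.asarray(dz_pairs, dtype=float))
    rng = np.random.default_rng(seed)
    h2s = np.empty(n_boot)
    n_redrawn = 0
    for b in range(n_boot):
        while True:
            mi = rng.integers(0, len(mz), len(mz))
            di = rng.integers(0, len(dz), len(dz))
            m = mz[mi]
            d = dz[di]
            if (
                np.std(m[:, 0]) > 0 and np.std(m[:, 1]) > 0
                and np.std(d[:, 0]) > 0 and np.std(d[:, 1]) > 0
            ):
                break
            n_redrawn += 1
        r_m = np.corrcoef(m[:, 0], m[:, 1])[0, 1]
        r_d = np.corrcoef(d[:, 0], d[:, 1])[0, 1]
        h2s[b] = 2.0 * (r_m - r_d)
    alpha = 1.0 - level
    lo, hi = np.quantile(h2s, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), n_redrawn


def estimate_heritability(
    mz_pairs,
    dz_pairs,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> HeritabilityEstimate:
    """Full heritability estimate from raw paired traits.

    Computes the MZ and DZ intrapair correlations, Falconer's h2 and a
    pair-resampling bootstrap CI in one call.
    """
    mz = np.atleast_2d(np.asarray(mz_pairs, dtype=float))
    dz = np.atleast_2d(np.asarray(dz_pairs, dtype=float))
    r_mz = pearson_r(mz[:, 0], mz[:, 1], level)
    r_dz = pearson_r(dz[:, 0], dz[:, 1], level)
    point = falconer_h2(r_mz, r_dz)
    lo, hi, _ = bootstrap_h2(mz, dz, n_boot=n_boot, seed=seed, level=level)
    return HeritabilityEstimate(
        r_mz=r_mz, r_dz=r_dz, h2_raw=point.h2_raw, h2=point.h2,
        boot_ci_low=lo, boot_ci_high=hi, n_boot=n_boot, seed=seed,
    )


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation (midranks, tie-corrected
    variance, continuity correction), two-sided.

    Returns (U, p) where U counts pairwise wins of ``x`` over ``y``
    (ties count one half).  When every value across both samples is
    tied the test is degenerate and p = 1 is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p).  A zero row or column
    margin leaves expected counts undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise UndefinedTestError("table must be at least 2x2")
    if np.any(t < 0):
        raise UndefinedTestError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise UndefinedTestError("zero row/column margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def stratify_pairs(
    classified: pd.DataFrame,
    trait_col: str = "se_analysis",
    policy: str = "either_myopic",
) -> pd.DataFrame:
    """Build the pair-level trait table, stratified by refractive group.

    One row per pair with columns ``pair_id, zygosity, stratum, x1, x2``
    (x1/x2 in recorded subject order).  ``policy`` decides the stratum
    of a pair from its two subject-level groups:

    - ``either_myopic`` (default): myopia if either twin is myopic;
      emmetropia only if both twins are emmetropic; else excluded.
    - ``concordant_only``: a pair enters a stratum only when both twins
      share that group.
    - ``twin1``: the stratum of the first-recorded twin.
    """
    rows = []
    for pair_id, sub in classified.groupby("pair_id", sort=True):
        if len(sub) != 2:
            raise UndefinedTestError(
                f"pair {pair_id} has {len(sub)} members, expected 2"
            )
        g1, g2 = sub["group"].tolist()
        if policy == "either_myopic":
            if "myopia" in (g1, g2):
                stratum = "myopia"
            elif g1 == g2 == "emmetropia":
                stratum = "emmetropia"
            else:
                stratum = "excluded"
        elif policy == "concordant_only":
            stratum = g1 if g1 == g2 else "excluded"
        elif policy == "twin1":
            stratum = g1
        else:
            raise UndefinedTestError(f"unknown stratification policy {policy!r}")
        x = sub[trait_col].tolist()
        rows.append(
            dict(
                pair_id=pair_id,
                zygosity=sub["zygosity"].iloc[0],
                stratum=stratum,
                x1=x[0],
                x2=x[1],
            )
        )
    return pd.DataFrame(
        rows, columns=["pair_id", "zygosity", "stratum", "x1", "x2"]
    )


def describe_cohort(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-zygosity descriptives: pair counts by sex composition, and
    mean +/- standard error, median, min, max of age and per-eye SE.

    Returns a tidy frame with columns ``zygosity, variable, statistic,
    value``.  The standard error of a single observation is NaN.
    """
    if classified.empty:
        raise InsufficientDataError("empty cohort")
    rows = []

    def _num(zyg, var, values):
        v = np.asarray(values, dtype=float)
        n = len(v)
        se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        for stat_name, val in [
            ("n", float(n)),
            ("mean", float(np.mean(v))),
            ("se", se),
            ("median", float(np.median(v))),
            ("min", float(np.min(v))),
            ("max", float(np.max(v))),
        ]:
            rows.append(dict(zygosity=zyg, variable=var,
                             statistic=stat_name, value=val))

    for zyg, sub in classified.groupby("zygosity", sort=True):
        comp = {"MM": 0, "FF": 0, "MF": 0}
        for _, pair in sub.groupby("pair_id"):
            key = "".join(sorted(pair["sex"], reverse=True))  # M sorts first
            comp[key] = comp.get(key, 0) + 1
        rows.append(dict(zygosity=zyg, variable="pairs",
                         statistic="male", value=float(comp.get("MM", 0))))
        rows.append(dict(zygosity=zyg, variable="pairs",
                         statistic="female", value=float(comp.get("FF", 0))))
        rows.append(dict(zygosity=zyg, variable="pairs",
                         statistic="mixed", value=float(comp.get("MF", 0))))
        rows.append(dict(zygosity=zyg, variable="pairs",
                         statistic="total", value=float(sub["pair_id"].nunique())))
        _num(zyg, "age_years", sub["age_years"])
        for col in ("se_od", "se_os"):
            if col in sub.columns:
                _num(zyg, col, sub[col])
    return pd.DataFrame(rows)


def zygosity_comparison_tests(classified: pd.DataFrame) -> dict:
    """MZ-vs-DZ comparison p-values: chi-square on the pair sex
    composition, Mann-Whitney on age and per-eye spherical equivalent.
    """
    desc = {}
    by_z = {z: s for z, s in classified.groupby("zygosity")}
    if set(by_z) != {"MZ", "DZ"}:
        raise InsufficientDataError("need both MZ and DZ subjects")

    def _sex_counts(sub):
        counts = {"MM": 0, "FF": 0, "MF": 0}
        for _, pair in sub.groupby("pair_id"):
            key = "".join(sorted(pair["sex"], reverse=True))
            key = key if key in counts else "MF"
            counts[key] += 1
        return counts

    mz_c = _sex_counts(by_z["MZ"])
    dz_c = _sex_counts(by_z["DZ"])
    cols = [k for k in ("MM", "FF", "MF") if mz_c[k] + dz_c[k] > 0]
    table = [[mz_c[k] for k in cols], [dz_c[k] for k in cols]]
    stat, df, p = chi_square_independence(table)
    desc["sex_composition"] = dict(chi2=stat, df=df, p=p, table=table,
                                   columns=cols)
    for var in ("age_years", "se_od", "se_os"):
        if var in classified.columns:
            u, p = mann_whitney_u(by_z["MZ"][var], by_z["DZ"][var])
            desc[var] = dict(U=u, p=p)
    return desc


def plot_twin_scatter(pairs: pd.DataFrame, ax=None, **scatter_kw):
    """Scatter of twin-1 vs twin-2 trait values (one point per pair).

    Requires matplotlib; imported lazily so the plotting dependency
    stays optional.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pairs["x1"], pairs["x2"], **scatter_kw)
    ax.set_xlabel("twin 1 spherical equivalent (D)")
    ax.set_ylabel("twin 2 spherical equivalent (D)")
    return ax
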