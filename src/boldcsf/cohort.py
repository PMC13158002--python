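"""Participant screening, demographics tests, group comparison and
clinical correlation analysis with Bonferroni control.

Conventions chosen to match the study's SPSS workflow: pooled-variance
Student t for the group comparison, Pearson chi-square without continuity
correction for sex, Mann-Whitney for continuous demographics, and a fixed
alpha/m Bonferroni threshold for the five clinical correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SubjectRecord",
    "EligibilityRules",
    "GroupComparison",
    "CorrelationResult",
    "CLINICAL_VARIABLES",
    "screen_participants",
    "chi_square_2x2",
    "mann_whitney",
    "ttest_from_summary",
    "group_ttest",
    "adjusted_group_model",
    "clinical_correlations",
    "effect_size_r2",
    "records_to_frame",
]

#: Clinical variables entering the correlation family (m = 5).
CLINICAL_VARIABLES = ("bqds", "duration", "daily_dose", "hama14", "hamd24")


@dataclass
class SubjectRecord:
    """One participant: identity, group, demographics, clinical scores and
    the computed coupling metric."""

    id: str
    group: str  # "BQD" or "HC"
    sex: str | None = None  # "M" or "F"
    age: float | None = None
    education: float | None = None
    bqds: float | None = None
    duration: float | None = None
    daily_dose: float | None = None
    hama14: float | None = None
    hamd24: float | None = None
    coupling: float | None = None
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.group not in ("BQD", "HC"):
            raise ValueError(f"group must be 'BQD' or 'HC', got {self.group!r}")


@dataclass
class EligibilityRules:
    """Inclusion thresholds: BQD arm requires BQDS strictly greater than
    ``bqds_min_exclusive`` with anxiety/depression scores not exceeding
    their caps; both arms require age within bounds."""

    min_age: float = 18.0
    max_age: float = 60.0
    bqds_min_exclusive: float = 4.0
    hama_max: float = 7.0
    hamd_max: float = 7.0

    def __post_init__(self) -> None:
        if not self.min_age < self.max_age:
            raise ValueError("min_age must be < max_age")


@dataclass
class GroupComparison:
    t: float
    df: float
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    variant: str = "pooled"


@dataclass
class CorrelationResult:
    variable: str
    r: float | None
    n: int
    p_uncorrected: float | None
    m_tests: int
    alpha: float
    corrected_threshold: float
    significant_after_correction: bool
    computable: bool = True


def screen_participants(
    records: Iterable[SubjectRecord], rules: EligibilityRules | None = None
) -> tuple[list[SubjectRecord], list[tuple[SubjectRecord, str]]]:
    """Apply the eligibility rules; returns (included, excluded-with-reason)."""
    rules = rules or EligibilityRules()
    included: list[SubjectRecord] = []
    excluded: list[tuple[SubjectRecord, str]] = []
    for rec in records:
        reason = _screen_one(rec, rules)
        if reason is None:
            included.append(rec)
        else:
            excluded.append((rec, reason))
    return included, excluded


def _screen_one(rec: SubjectRecord, rules: EligibilityRules) -> str | None:
    if rec.age is None:
        return "missing: age"
    if not rules.min_age <= rec.age <= rules.max_age:
        return f"age {rec.age} outside [{rules.min_age}, {rules.max_age}]"
    if rec.group == "BQD":
        for name in ("bqds", "hama14", "hamd24"):
            if getattr(rec, name) is None:
                return f"missing: {name}"
        if not rec.bqds > rules.bqds_min_exclusive:
            return f"bqds {rec.bqds} not greater than {rules.bqds_min_exclusive}"
        if rec.hamd24 > rules.hamd_max:
            return f"hamd24 {rec.hamd24} exceeds {rules.hamd_max}"
        if rec.hama14 > rules.hama_max:
            return f"hama14 {rec.hama14} exceeds {rules.hama_max}"
    return None


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, NO continuity correction) for the table
    [[a, b], [c, d]]; returns (chi2, two-sided p)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    n = table.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m <= 0 for m in margins):
        raise ValueError("all table margins must be positive")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins, dtype=float)
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration for small untied samples (n1 + n2 <= 12); otherwise
    the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ttest_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> GroupComparison:
    """Pooled-variance Student two-sample t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(
        t=float(t), df=float(df), p=p,
        mean1=mean1, sd1=sd1, n1=n1, mean2=mean2, sd2=sd2, n2=n2,
    )


def _coupling_by_group(records: Iterable[SubjectRecord]) -> dict[str, np.ndarray]:
    out: dict[str, list[float]] = {"BQD": [], "HC": []}
    for rec in records:
        if rec.qc_pass and rec.coupling is not None:
            out[rec.group].append(rec.coupling)
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def group_ttest(records: Iterable[SubjectRecord]) -> GroupComparison:
    """Pooled two-sample t on per-subject coupling strengths (BQD vs HC),
    over QC-passing subjects only."""
    groups = _coupling_by_group(records)
    bqd, hc = groups["BQD"], groups["HC"]
    if bqd.size < 2 or hc.size < 2:
        raise ValueError("each group needs >= 2 QC-passing coupling values")
    return ttest_from_summary(
        float(bqd.mean()), float(bqd.std(ddof=1)), bqd.size,
        float(hc.mean()), float(hc.std(ddof=1)), hc.size,
    )


def adjusted_group_model(
    records: Iterable[SubjectRecord],
    covariates: Sequence[str] = ("sex", "age", "education"),
    sex_reference: str = "F",
) -> pd.DataFrame:
    """OLS of coupling on a group indicator (BQD = 1) plus covariates.

    Sex is coded 0/1 against ``sex_reference``.  Returns the coefficient
    table (coef, se, t, p) indexed by term; the ``group`` row carries the
    covariate-adjusted group effect.
    """
    rows = []
    for rec in records:
        if not rec.qc_pass or rec.coupling is None:
            continue
        row = {"coupling": rec.coupling, "group": 1.0 if rec.group == "BQD" else 0.0}
        for cov in covariates:
            val = getattr(rec, cov)
            if cov == "sex" and val is not None:
                val = 0.0 if val == sex_reference else 1.0
            row[cov] = val
        rows.append(row)
    frame = pd.DataFrame(rows).dropna()
    n_params = 2 + len(covariates)
    if len(frame) <= n_params + 1:
        raise ValueError(f"need more than {n_params + 1} complete records, got {len(frame)}")
    X = sm.add_constant(frame[["group", *covariates]])
    for col in X.columns:
        if col != "const" and X[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} has zero variance (rank deficient)")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates)")
    fit = sm.OLS(frame["coupling"], X).fit()
    return pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the exact t transform,
    t = r*sqrt(n-2)/sqrt(1-r^2), df = n-2."""
    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def clinical_correlations(
    records: Iterable[SubjectRecord],
    variables: Sequence[str] = CLINICAL_VARIABLES,
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Exploratory Pearson correlations between coupling and each clinical
    variable in the BQD arm, with a fixed Bonferroni threshold alpha/m.

    Missing data are handled pairwise-complete per variable; a constant
    variable is reported as not computable rather than raising.
    """
    m = len(variables)
    threshold = alpha / m
    recs = [r for r in records if r.group == "BQD" and r.qc_pass and r.coupling is not None]
    results: list[CorrelationResult] = []
    for var in variables:
        pairs = [(r.coupling, getattr(r, var)) for r in recs if getattr(r, var) is not None]
        if len(pairs) < 3:
            results.append(CorrelationResult(var, None, len(pairs), None, m, alpha,
                                             threshold, False, computable=False))
            continue
        c = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        if np.ptp(v) == 0 or np.ptp(c) == 0:
            results.append(CorrelationResult(var, None, len(pairs), None, m, alpha,
                                             threshold, False, computable=False))
            continue
        r, p = pearson_with_p(c, v)
        results.append(CorrelationResult(var, r, len(pairs), p, m, alpha,
                                         threshold, p < threshold))
    return results


def effect_size_r2(r: float) -> float:
    """Squared correlation coefficient."""
    if abs(r) > 1.0:
        raise ValueError(f"|r| must not exceed 1, got {r}")
    return float(r * r)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
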