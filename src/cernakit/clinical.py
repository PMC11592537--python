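"""Matched case-control statistical toolkit.

Group-comparison tests (Pearson chi-square without continuity correction,
Mann-Whitney with tie-corrected normal approximation, pooled t), Spearman
correlation, the 2^-ddCt relative-expression transform, unconditional and
conditional logistic regression, greedy sex/age matching, the
discordant-pair sample-size formula, and a Table-style cohort summary.

Conventions follow common clinical-statistics software defaults: no Yates
correction on the chi-square, no continuity correction on the
Mann-Whitney Z, two-sided p values throughout, Wald confidence intervals
for odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]], no
    continuity correction; p from the upper tail of chi-square(1).

    The statistic is ``n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty table")
    margins = np.array([a + b, c + d, a + c, b + d], dtype=float)
    if (margins == 0).any():
        raise ValueError("chi-square undefined: a margin is zero")
    stat = n * (a * d - b * c) ** 2 / margins.prod()
    return float(stat), float(stats.chi2.sf(stat, df=1))


def mann_whitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with mid-ranks and the tie-corrected normal Z.

    Returns ``(U, Z, p)`` where U counts pairs in which an ``x`` value
    exceeds a ``y`` value (ties half), Z is signed by the mean rank of
    ``x`` relative to expectation, and p is the two-sided normal tail
    without continuity correction.  All-tied data gives Z = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    m, n = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    U = float(ranks[:m].sum() - m * (m + 1) / 2)
    mu = m * n / 2
    N = m + n
    _, counts = np.unique(allv, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = m * n / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return U, 0.0, 1.0
    z = (U - mu) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return U, float(z), min(p, 1.0)


def students_t(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t-test, two-sided."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation on mid-ranks; p via the t approximation
    with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCt method: the target Ct is
    normalised to the reference gene, then to the calibrator sample."""
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))


@dataclass
class LogisticFit:
    """Per-covariate Wald summary of a logistic regression."""

    table: pd.DataFrame | None
    converged: bool
    separated: bool
    n: int

    def odds_ratio(self, name: str) -> float:
        if self.table is None:
            raise ValueError("no estimates available (separation or failure)")
        return float(self.table.loc[name, "or"])


def fit_logistic(
    outcome,
    covariates: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    Fitting is Newton-type iteratively reweighted least squares (50
    iterations, score tolerance 1e-8).  Perfect separation is flagged and
    no estimates are returned.
    """
    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates)
    if names is not None:
        X.columns = names
    X = X.astype(float)
    if X.shape[0] != len(y):
        raise ValueError("outcome and covariates have different lengths")
    if (X.nunique() <= 1).any():
        const = list(X.columns[X.nunique() <= 1])
        raise ValueError(f"constant covariates: {const}")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than covariates")

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )

    design = sm.add_constant(X, prepend=True) if add_intercept else X
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(
                method="newton", maxiter=50, tol=1e-8, disp=0
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return LogisticFit(table=None, converged=False, separated=True, n=len(y))
    if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 30:
        return LogisticFit(table=None, converged=False, separated=True, n=len(y))
    coefs = fit.params
    ses = fit.bse
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - z * ses),
            "ci_high": np.exp(coefs + z * ses),
            "p": 2 * stats.norm.sf(np.abs(coefs / ses)),
        }
    )
    return LogisticFit(table=table, converged=True, separated=False, n=len(y))


def fit_conditional_logistic(
    outcome, covariates: pd.DataFrame, pair_ids
) -> LogisticFit:
    """Conditional (matched-pair) logistic regression; an extension beyond
    the unconditional default used for the published tables."""
    import statsmodels.api as sm
    from statsmodels.discrete.conditional_models import ConditionalLogit

    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates).astype(float)
    try:
        fit = ConditionalLogit(y, X, groups=np.asarray(pair_ids)).fit(disp=0)
    except Exception:
        return LogisticFit(table=None, converged=False, separated=True, n=len(y))
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "or": np.exp(fit.params),
            "ci_low": np.exp(fit.params - z * fit.bse),
            "ci_high": np.exp(fit.params + z * fit.bse),
            "p": 2 * stats.norm.sf(np.abs(fit.params / fit.bse)),
        }
    )
    return LogisticFit(table=table, converged=True, separated=False, n=len(y))


@dataclass
class SampleSizeResult:
    pairs: int
    discordant_pairs: float
    p_exposed_case: float
    p_discordant: float
    p_given_discordant: float


def matched_sample_size(
    p0: float, odds_ratio: float, alpha: float = 0.05, beta: float = 0.15
) -> SampleSizeResult:
    """Discordant-pair (Schlesselman) sample size for a 1:1 matched design.

    With P = OR/(1+OR), the required discordant pairs are
    ``m = [z_{a/2}/2 + z_b sqrt(P(1-P))]^2 / (P - 1/2)^2`` and the total
    pairs are ``ceil(m / p_discordant)`` where
    ``p_discordant = p1 (1-p0) + p0 (1-p1)`` and
    ``p1 = OR p0 / (1 + p0 (OR - 1))``.
    """
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    if odds_ratio == 1:
        raise ValueError("odds_ratio = 1 gives an infinite sample size")
    if not (0 < alpha < 1 and 0 < beta < 1):
        raise ValueError("alpha and beta must be in (0, 1)")
    P = odds_ratio / (1 + odds_ratio)
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(1 - beta)
    m = (z_a / 2 + z_b * np.sqrt(P * (1 - P))) ** 2 / (P - 0.5) ** 2
    p1 = odds_ratio * p0 / (1 + p0 * (odds_ratio - 1))
    p_disc = p1 * (1 - p0) + p0 * (1 - p1)
    pairs = int(np.ceil(m / p_disc))
    return SampleSizeResult(
        pairs=pairs,
        discordant_pairs=float(m),
        p_exposed_case=float(p1),
        p_discordant=float(p_disc),
        p_given_discordant=float(P),
    )


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns case_id, control_id, case_age, control_age, sex
    unmatched_cases: list[str]

    @property
    def complete(self) -> bool:
        return not self.unmatched_cases


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    age_window: float = 3.0,
    id_col: str = "subject_id",
    age_col: str = "age",
    sex_col: str = "sex",
) -> MatchResult:
    """Greedy 1:1 matching: cases in ascending age order each take the
    same-sex unused control nearest in age within the window."""
    case_ids = set(cases[id_col])
    if case_ids & set(pool[id_col]):
        raise ValueError("pool overlaps cases")
    available = pool[[id_col, age_col, sex_col]].copy()
    used: set[str] = set()
    rows = []
    unmatched = []
    for _, case in cases.sort_values([age_col, id_col]).iterrows():
        cand = available[
            (available[sex_col] == case[sex_col])
            & (~available[id_col].isin(used))
            & ((available[age_col] - case[age_col]).abs() <= age_window)
        ]
        if cand.empty:
            unmatched.append(case[id_col])
            continue
        gap = (cand[age_col] - case[age_col]).abs()
        best = cand.loc[gap.sort_values(kind="stable").index[0]]
        used.add(best[id_col])
        rows.append(
            {
                "case_id": case[id_col],
                "control_id": best[id_col],
                "case_age": case[age_col],
                "control_age": best[age_col],
                "sex": case[sex_col],
            }
        )
    return MatchResult(
        pairs=pd.DataFrame(
            rows, columns=["case_id", "control_id", "case_age", "control_age", "sex"]
        ),
        unmatched_cases=unmatched,
    )


def _is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(values) == 0 or len(values) < 3:
        return False
    try:
        return stats.shapiro(values).pvalue >= alpha
    except Exception:
        return False


def summarize_cohort(
    table: pd.DataFrame,
    binary_vars: list[str],
    continuous_vars: list[str],
    group_col: str = "group",
    case_label: str = "CHD",
    normality_overrides: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-variable two-group summary in the clinical-table layout.

    Binary variables: count (%) per group with the chi-square test.
    Continuous variables: mean +/- SD with the pooled t-test when both
    groups pass Shapiro-Wilk at 0.05 (or the user override), otherwise
    median (Q1, Q3) with the Mann-Whitney test.
    """
    overrides = normality_overrides or {}
    is_case = table[group_col] == case_label
    case = table[is_case]
    ctrl = table[~is_case]
    rows = []
    for var in binary_vars:
        a = int(ctrl[var].sum())
        b = int((1 - ctrl[var]).sum())
        c = int(case[var].sum())
        d = int((1 - case[var]).sum())
        stat, p = chi_square_2x2(a, b, c, d)
        rows.append(
            {
                "variable": var,
                "type": "binary",
                "control_summary": f"{a} ({100 * a / max(a + b, 1):.1f})",
                "case_summary": f"{c} ({100 * c / max(c + d, 1):.1f})",
                "test": "chi-square",
                "statistic": stat,
                "p": p,
            }
        )
    for var in continuous_vars:
        xv = case[var].to_numpy(dtype=float)
        yv = ctrl[var].to_numpy(dtype=float)
        normal = overrides.get(var, _is_normal(xv) and _is_normal(yv))
        if normal:
            stat, p = students_t(xv, yv)
            summ_c = f"{yv.mean():.2f} ± {yv.std(ddof=1):.2f}"
            summ_x = f"{xv.mean():.2f} ± {xv.std(ddof=1):.2f}"
            test = "t"
        else:
            if np.ptp(np.concatenate([xv, yv])) == 0:
                stat, p = 0.0, 1.0
            else:
                _, stat, p = mann_whitney(xv, yv)
            q = lambda v: np.percentile(v, [50, 25, 75])
            mc, q1c, q3c = q(yv)
            mx, q1x, q3x = q(xv)
            summ_c = f"{mc:.2f} ({q1c:.2f}, {q3c:.2f})"
            summ_x = f"{mx:.2f} ({q1x:.2f}, {q3x:.2f})"
            test = "mann-whitney"
        rows.append(
            {
                "variable": var,
                "type": "continuous",
                "control_summary": summ_c,
                "case_summary": summ_x,
                "test": test,
                "statistic": float(stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)
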