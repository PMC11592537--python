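"""Incremental-biomarker evaluation: ROC/AUC, DeLong, continuous NRI, IDI.

The AUC is the Mann-Whitney concordance probability (half credit for
ties).  Its variance, and the covariance of two correlated AUCs computed
on the same subjects, come from DeLong's structural components, built
here from mid-ranks in O(n log n).  Reclassification of a base risk
model against an augmented one is quantified by the category-free net
reclassification improvement (NRI, range [-2, 2]) and the integrated
discrimination improvement (IDI), both with Wald-type asymptotic
confidence intervals on the raw index scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from cernakit.containers import ModelComparison

_Z95 = 1.959963984540054


def _check_labels(labels: np.ndarray) -> None:
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")


def _structural_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong's per-subject structural components.

    V10[i] is the placement of case i among controls (fraction of
    controls scoring below, ties half); V01[j] the mirror for controls.
    """
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores, labels) -> tuple[float, tuple[float, float]]:
    """AUC with a DeLong 95% confidence interval, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    auc, v10, v01 = _structural_components(scores, labels)
    var = _delong_variance(v10, v01)
    half = _Z95 * np.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = len(v10), len(v01)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float]:
    """Two-sided DeLong test for the difference of two correlated AUCs.

    The scores must be paired (same subjects).  Returns
    ``(delta_auc, z, p)``; identical scores give z = 0, p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape:
        raise ValueError("scores must be paired on identical subjects")
    _check_labels(labels)
    auc_a, v10_a, v01_a = _structural_components(scores_a, labels)
    auc_b, v10_b, v01_b = _structural_components(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    cov10 = np.cov(v10_a, v10_b, ddof=1)[0, 1] if m > 1 else 0.0
    cov01 = np.cov(v01_a, v01_b, ddof=1)[0, 1] if n > 1 else 0.0
    var = (
        _delong_variance(v10_a, v01_a)
        + _delong_variance(v10_b, v01_b)
        - 2 * (cov10 / m + cov01 / n)
    )
    delta = auc_a - auc_b
    if var <= 1e-16:
        return float(delta), 0.0, 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(z), float(2 * stats.norm.sf(abs(z)))


def idi(p_base, p_aug, labels) -> tuple[float, tuple[float, float], float]:
    """Integrated discrimination improvement: the change in discrimination
    slope, i.e. (mean prob gain in events) - (mean prob gain in
    nonevents), with the paired-difference Wald SE."""
    p_base = np.asarray(p_base, dtype=float)
    p_aug = np.asarray(p_aug, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    d = p_aug - p_base
    de, dn = d[labels == 1], d[labels == 0]
    value = float(de.mean() - dn.mean())
    se = np.sqrt(
        (de.var(ddof=1) / len(de) if len(de) > 1 else 0.0)
        + (dn.var(ddof=1) / len(dn) if len(dn) > 1 else 0.0)
    )
    if se <= 0:
        return value, (value, value), 1.0
    ci = (max(-1.0, value - _Z95 * se), min(1.0, value + _Z95 * se))
    p = float(2 * stats.norm.sf(abs(value / se)))
    return value, ci, p


def continuous_nri(p_base, p_aug, labels) -> tuple[float, tuple[float, float], float]:
    """Category-free net reclassification improvement.

    NRI = [P(up | event) - P(down | event)] +
    [P(down | nonevent) - P(up | nonevent)], where up/down is any
    increase/decrease of the predicted probability and exact ties count
    in neither direction.
    """
    p_base = np.asarray(p_base, dtype=float)
    p_aug = np.asarray(p_aug, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    d = p_aug - p_base
    de, dn = d[labels == 1], d[labels == 0]
    up_e, down_e = float((de > 0).mean()), float((de < 0).mean())
    up_n, down_n = float((dn > 0).mean()), float((dn < 0).mean())
    value = (up_e - down_e) + (down_n - up_n)
    var_e = (up_e + down_e - (up_e - down_e) ** 2) / len(de)
    var_n = (up_n + down_n - (up_n - down_n) ** 2) / len(dn)
    se = np.sqrt(var_e + var_n)
    if se <= 0:
        return value, (value, value), 1.0
    ci = (max(-2.0, value - _Z95 * se), min(2.0, value + _Z95 * se))
    p = float(2 * stats.norm.sf(abs(value / se)))
    return value, ci, p


def youden_operating_point(scores, labels) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity - 1 (Youden's J),
    predicting positive at score >= threshold; ties broken toward the
    higher-specificity (larger) threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    best = None
    for thr in np.unique(scores):  # ascending: later candidates have higher specificity
        sens = float((pos >= thr).mean())
        spec = float((neg < thr).mean())
        j = sens + spec - 1
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or thr > best[1]:
                best = (j, float(thr), sens, spec)
    _, thr, sens, spec = best
    return thr, sens, spec


def fit_probabilities(
    cohort: pd.DataFrame,
    covariates: list[str],
    group_col: str = "group",
    case_label: str = "CHD",
    log2_markers: tuple[str, ...] = (),
):
    """In-sample predicted probabilities from a logistic fit (None when
    the fit separates or fails to converge)."""
    import statsmodels.api as sm

    y = (cohort[group_col] == case_label).astype(float).to_numpy()
    X = cohort[covariates].astype(float).copy()
    for name in log2_markers:
        if name in X.columns:
            X[name] = np.log2(X[name])
    design = sm.add_constant(X.to_numpy(), prepend=True)
    try:
        fit = sm.Logit(y, design).fit(method="newton", maxiter=50, tol=1e-8, disp=0)
    except Exception:
        return None, y
    if not fit.mle_retvals.get("converged", False):
        return None, y
    return fit.predict(design), y


def compare_models(
    cohort: pd.DataFrame,
    base: list[str],
    markers: list[str],
    group_col: str = "group",
    case_label: str = "CHD",
    log_transform_markers: bool = True,
    model_name: str | None = None,
) -> ModelComparison:
    """Fit base and base+markers logistic models and compare them by
    AUC/DeLong, IDI and continuous NRI on in-sample probabilities.

    Relative-expression markers are log2-transformed before entering the
    model (``log_transform_markers``), matching their multiplicative
    scale.  An empty marker list compares the base model to itself and
    returns zero improvements.
    """
    missing = [c for c in base + markers if c not in cohort.columns]
    if missing:
        raise ValueError(f"covariates absent from cohort: {missing}")
    log2_markers = tuple(markers) if log_transform_markers else ()
    p_base, y = fit_probabilities(cohort, base, group_col, case_label)
    p_aug, _ = fit_probabilities(
        cohort, base + markers, group_col, case_label, log2_markers
    )
    name = model_name or ("base" if not markers else "base + " + " + ".join(markers))
    if p_base is None or p_aug is None:
        return ModelComparison(
            model_name=name,
            auc_base=np.nan, auc_base_ci=(np.nan, np.nan),
            auc_augmented=np.nan, auc_augmented_ci=(np.nan, np.nan),
            delong_p=np.nan, idi=np.nan, idi_ci=(np.nan, np.nan), idi_p=np.nan,
            nri=np.nan, nri_ci=(np.nan, np.nan), nri_p=np.nan,
            n=len(y), converged=False,
        )
    labels = y.astype(int)
    auc_b, ci_b = roc_auc(p_base, labels)
    auc_a, ci_a = roc_auc(p_aug, labels)
    _, _, delong_p = delong_test(p_aug, p_base, labels)
    idi_v, idi_ci, idi_p = idi(p_base, p_aug, labels)
    nri_v, nri_ci, nri_p = continuous_nri(p_base, p_aug, labels)
    return ModelComparison(
        model_name=name,
        auc_base=auc_b,
        auc_base_ci=ci_b,
        auc_augmented=auc_a,
        auc_augmented_ci=ci_a,
        delong_p=delong_p,
        idi=idi_v,
        idi_ci=idi_ci,
        idi_p=idi_p,
        nri=nri_v,
        nri_ci=nri_ci,
        nri_p=nri_p,
        n=len(labels),
    )


def comparison_report(
    cohort: pd.DataFrame,
    base: list[str],
    marker_sets: dict[str, list[str]],
    **kwargs,
) -> pd.DataFrame:
    """One comparison row per augmentation (the published-table layout)."""
    rows = []
    base_cmp = compare_models(cohort, base, [], model_name="clinical model", **kwargs)
    row = base_cmp.as_row()
    row.update({"auc": base_cmp.auc_base,
                "auc_ci_low": base_cmp.auc_base_ci[0],
                "auc_ci_high": base_cmp.auc_base_ci[1],
                "delong_p_vs_base": np.nan, "idi": np.nan, "nri": np.nan,
                "idi_p": np.nan, "nri_p": np.nan,
                "idi_ci_low": np.nan, "idi_ci_high": np.nan,
                "nri_ci_low": np.nan, "nri_ci_high": np.nan})
    rows.append(row)
    for name, markers in marker_sets.items():
        rows.append(
            compare_models(
                cohort, base, markers, model_name=name, **kwargs
            ).as_row()
        )
    return pd.DataFrame(rows)
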