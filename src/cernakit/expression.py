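"""Expression preprocessing and differential-expression screening.

Quantile normalisation, ComBat batch adjustment (parametric empirical
Bayes, with the biological group preserved as a covariate), a fold-change
plus t-test screen with the conventional linear-scale |FC| threshold, a
set intersection against an immune-gene list, and a one-sided
hypergeometric over-representation test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from cernakit.containers import ExpressionMatrix, GROUP_CASE, GROUP_CONTROL

_EPS_VAR = 1e-12


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (row-wise mean) quantile profile.

    Ties within a sample receive the mean of the reference values across
    the tied rank span, so permutation-equivalent columns map to exactly
    the same multiset of values.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        starts = np.r_[0, np.nonzero(np.diff(sorted_vals))[0] + 1]
        ends = np.r_[starts[1:], len(col)]
        run_means = (ref_cum[ends] - ref_cum[starts]) / (ends - starts)
        out[order, j] = np.repeat(run_means, ends - starts)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values)


def combat_adjust(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove batch location/scale effects by parametric empirical-Bayes
    adjustment (ComBat), preserving the case/control effect as a model
    covariate.

    Refuses to run when any batch contains only one group: batch and
    group would be confounded and the batch effect unidentifiable.
    """
    if matrix.batches is None:
        raise ValueError("combat_adjust requires batch labels")
    counts = matrix.batches.value_counts()
    if (counts < 2).any():
        small = list(counts.index[counts < 2])
        raise ValueError(f"each batch needs >=2 samples; too small: {small}")
    if len(counts) < 2:
        warnings.warn("single batch: combat_adjust is the identity transform")
        return matrix.copy_with(matrix.values.copy())
    cross = pd.crosstab(matrix.batches, matrix.groups)
    if ((cross > 0).sum(axis=1) < 2).any():
        raise ValueError(
            "batch is confounded with group (some batch contains a single group); "
            "the batch effect is not identifiable"
        )

    import anndata

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import scanpy as sc

        adata = anndata.AnnData(
            X=matrix.values.to_numpy(dtype=float).T,
            obs=pd.DataFrame(
                {
                    "batch": pd.Categorical(matrix.batches.values),
                    # numeric indicator: a full-rank design alongside the
                    # one-hot batch columns
                    "group": (matrix.groups.values == GROUP_CASE).astype(float),
                },
                index=matrix.values.columns.astype(str),
            ),
        )
        corrected = sc.pp.combat(adata, key="batch", covariates=["group"], inplace=False)
    values = pd.DataFrame(
        np.asarray(corrected).T, index=matrix.values.index, columns=matrix.values.columns
    )
    return matrix.copy_with(values)


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    method: str = "student",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Two-group fold-change + t-test screen on a log2 matrix.

    Fold change is ``2**(mean_case - mean_control)``; a feature passes
    when the two-sided p is below ``p_threshold`` and the linear-scale
    magnitude ``max(FC, 1/FC)`` is at least ``fc_threshold``.  No
    multiplicity correction is applied by default; Benjamini-Hochberg is
    available behind ``bh_correction``.

    Returns a DataFrame with columns feature_id, fc, log2fc, p, direction,
    passes, flagged (the zero-variance epsilon guard).
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear scale)")
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    if method not in {"student", "welch"}:
        raise ValueError("method must be 'student' or 'welch'")
    case = matrix.values[matrix.case_samples].to_numpy(dtype=float)
    ctrl = matrix.values[matrix.control_samples].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need >=2 samples")

    m1, m2 = case.mean(axis=1), ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    log2fc = m1 - m2

    flagged = (v1 + v2) < _EPS_VAR
    if method == "student":
        pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(np.maximum(pooled, _EPS_VAR) * (1 / n1 + 1 / n2))
        t = log2fc / se
        p = 2 * stats.t.sf(np.abs(t), df=n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        se = np.sqrt(np.maximum(se2, _EPS_VAR))
        t = log2fc / se
        df = np.where(
            se2 > _EPS_VAR,
            se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)) + _EPS_VAR),
            n1 + n2 - 2,
        )
        p = 2 * stats.t.sf(np.abs(t), df=df)
    # identical groups with zero variance: no evidence against the null
    p = np.where(flagged & (np.abs(log2fc) < 1e-12), 1.0, p)

    p_screen = p
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        p_screen = multipletests(p, method="fdr_bh")[1]
    fc = 2.0**log2fc
    magnitude = np.maximum(fc, 1.0 / fc)
    passes = (p_screen < p_threshold) & (magnitude >= fc_threshold)
    direction = np.where(log2fc < 0, "down", "up")  # exact tie resolved as "up"
    return pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "fc": fc,
            "log2fc": log2fc,
            "p": p_screen,
            "direction": direction,
            "passes": passes,
            "flagged": flagged,
        }
    ).set_index("feature_id", drop=False)


def de_directions(de: pd.DataFrame) -> dict[str, str]:
    """Map of feature id -> direction for features passing the screen."""
    hits = de[de["passes"]]
    return dict(zip(hits["feature_id"], hits["direction"]))


def intersect_gene_sets(
    degs: dict[str, str] | set[str], immune_genes: set[str] | list[str]
) -> dict[str, str] | set[str]:
    """Exact intersection; directions carried through when provided."""
    immune = set(immune_genes)
    if isinstance(degs, dict):
        return {g: d for g, d in degs.items() if g in immune}
    return set(degs) & immune


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_gene: pd.Series | dict
) -> ExpressionMatrix:
    """Collapse probe-level rows to genes, keeping the probe with the
    highest mean intensity per gene (unmapped probes are dropped)."""
    mapping = pd.Series(probe_to_gene)
    means = matrix.values.mean(axis=1)
    keep: dict[str, str] = {}
    for probe, gene in mapping.items():
        if probe not in matrix.values.index:
            continue
        if gene not in keep or means[probe] > means[keep[gene]]:
            keep[gene] = probe
    genes = sorted(keep)
    values = matrix.values.loc[[keep[g] for g in genes]]
    values.index = genes
    return matrix.copy_with(values)


def enrichment_test(
    query: set[str] | list[str],
    annotation: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    p is the upper-tail probability of drawing at least the observed
    overlap when ``len(query)`` genes are sampled from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, genes in annotation.items():
        genes = set(genes) & universe
        k = len(genes & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), N))
        expected = N * len(genes) / M
        rows.append(
            {
                "set": name,
                "set_size": len(genes),
                "overlap": k,
                "expected": expected,
                "fold_enrichment": (k / expected) if expected > 0 else np.nan,
                "p": p,
                "significant": p < 0.05,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["p", "set"])
        .reset_index(drop=True)
    )
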