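"""Synthetic-data generators: every pipeline input with known ground truth.

The generators draw from named substreams of the blueprint seed, so the
same blueprint always yields byte-identical outputs and changing one
stage's draws does not perturb the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cernakit.blueprint import StudyBlueprint
from cernakit.containers import (
    ExpressionMatrix,
    GROUP_CASE,
    GROUP_CONTROL,
    validate_interaction_table,
)

LOG2_BASELINE_MEAN = 8.0
LOG2_BASELINE_SD = 2.0
SAMPLE_OFFSET_SD = 0.1
BATCH_FEATURE_SD = 0.3


@dataclass
class TruthRecord:
    """Ground truth realised by the generators, reproducible from the blueprint."""

    seed: int
    de_circ: dict[str, float] = field(default_factory=dict)
    de_gene: dict[str, float] = field(default_factory=dict)
    immune_genes: list[str] = field(default_factory=list)
    network_nodes: dict[str, list[str]] = field(default_factory=dict)
    network_edges: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    ppi_edges: list[tuple[str, str]] = field(default_factory=list)
    designed_hubs: list[str] = field(default_factory=list)
    marker_effects: dict[str, float] = field(default_factory=dict)


def simulate_array(blueprint: StudyBlueprint) -> ExpressionMatrix:
    """Small two-group circRNA array on the log2 scale.

    Per-feature baselines are Gaussian on log2 (log-normal intensities),
    planted features are shifted by their true log2 fold change in cases,
    and each sample gets a small global brightness offset for the
    quantile-normalisation stage to remove.
    """
    rng = blueprint.rng("array")
    ids = blueprint.circ_feature_ids()
    n = blueprint.n_samples_per_group_array
    samples = [f"array_ctrl_{i+1}" for i in range(n)] + [
        f"array_case_{i+1}" for i in range(n)
    ]
    base = rng.normal(LOG2_BASELINE_MEAN, LOG2_BASELINE_SD, size=len(ids))
    noise = rng.normal(0.0, blueprint.noise_sd, size=(len(ids), 2 * n))
    offsets = rng.normal(0.0, SAMPLE_OFFSET_SD, size=2 * n)
    values = base[:, None] + noise + offsets[None, :]
    shift = np.array([blueprint.planted_de_circ.get(f, 0.0) for f in ids])
    values[:, n:] += shift[:, None]
    groups = pd.Series(
        [GROUP_CONTROL] * n + [GROUP_CASE] * n, index=samples, name="group"
    )
    return ExpressionMatrix(pd.DataFrame(values, index=ids, columns=samples), groups)


def simulate_batched_expression(blueprint: StudyBlueprint) -> ExpressionMatrix:
    """Merged multi-batch gene-expression matrix, pre-batch-correction.

    Each batch applies a per-feature additive location effect (centred on
    the batch's nominal shift) and a multiplicative scale effect on the
    noise — the state ComBat is meant to clean up.
    """
    if len(blueprint.batch_sizes) < 2:
        warnings.warn("single batch requested: no batch effect applied")
    rng = blueprint.rng("batched")
    ids = blueprint.gene_feature_ids()
    base = rng.normal(LOG2_BASELINE_MEAN, LOG2_BASELINE_SD, size=len(ids))
    shift = np.array([blueprint.planted_de_gene.get(f, 0.0) for f in ids])

    cols: list[np.ndarray] = []
    samples: list[str] = []
    groups: list[str] = []
    batches: list[str] = []
    multi = len(blueprint.batch_sizes) > 1
    for b, (n_case, n_ctrl) in enumerate(blueprint.batch_sizes):
        add = blueprint.batch_additive[b] if multi else 0.0
        scale = blueprint.batch_scale[b] if multi else 1.0
        gamma = rng.normal(add, BATCH_FEATURE_SD, size=len(ids)) if multi else np.zeros(len(ids))
        n_b = n_case + n_ctrl
        noise = rng.normal(0.0, blueprint.noise_sd * scale, size=(len(ids), n_b))
        block = base[:, None] + gamma[:, None] + noise
        block[:, :n_case] += shift[:, None]
        cols.append(block)
        samples += [f"b{b+1}_case_{i+1}" for i in range(n_case)] + [
            f"b{b+1}_ctrl_{i+1}" for i in range(n_ctrl)
        ]
        groups += [GROUP_CASE] * n_case + [GROUP_CONTROL] * n_ctrl
        batches += [f"batch{b+1}"] * n_b
    values = pd.DataFrame(np.concatenate(cols, axis=1), index=ids, columns=samples)
    return ExpressionMatrix(
        values,
        pd.Series(groups, index=samples, name="group"),
        pd.Series(batches, index=samples, name="batch"),
    )


def _sample_decoy_pairs(
    rng: np.random.Generator,
    sources: list[str],
    targets: list[str],
    n: int,
    taken: set[tuple[str, str]],
) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    guard = 0
    while len(out) < n:
        s = sources[rng.integers(len(sources))]
        t = targets[rng.integers(len(targets))]
        if (s, t) not in taken:
            taken.add((s, t))
            out.append((s, t))
        guard += 1
        if guard > 100 * n + 1000:
            raise RuntimeError("could not draw enough distinct decoy pairs")
    return out


def simulate_interactions(
    blueprint: StudyBlueprint,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """circRNA-miRNA and miRNA-gene interaction tables.

    The tables contain every truth edge plus three decoy families, each
    of which a pipeline stage is responsible for removing: low-confidence
    miRNA-gene rows (confidence filter), rows whose miRNA appears on only
    one side (miRNA-overlap step), and direction-inconsistent pairings
    (ceRNA consistency filter).
    """
    truth = blueprint.network_truth
    if truth is None:
        raise ValueError("blueprint has no network_truth")
    rng = blueprint.rng("interactions")

    # disjoint decoy miRNA pools per table, so that the miRNA-overlap step
    # removes every high-confidence decoy
    decoy_mirs_cm = [f"mir_dc{i:03d}" for i in range(1, 41)]
    decoy_mirs_mg = [f"mir_dg{i:03d}" for i in range(1, 41)]
    circ_pool = sorted(blueprint.planted_de_circ) or truth.circrnas

    cm_rows = [
        {"source": c, "target": m, "edge_type": "circ-mir", "confidence": "very high"}
        for c, m in truth.circ_mir_edges
    ]
    taken = set(truth.circ_mir_edges)
    for c, m in _sample_decoy_pairs(
        rng, circ_pool, decoy_mirs_cm, blueprint.n_decoy_circ_mir, taken
    ):
        cm_rows.append(
            {"source": c, "target": m, "edge_type": "circ-mir", "confidence": "very high"}
        )

    mg_rows = [
        {"source": m, "target": g, "edge_type": "mir-gene", "confidence": "very high"}
        for m, g in truth.mir_gene_edges
    ]
    for m, g in blueprint.inconsistent_mir_gene_edges:
        mg_rows.append(
            {"source": m, "target": g, "edge_type": "mir-gene", "confidence": "very high"}
        )
    taken = set(truth.mir_gene_edges) | set(blueprint.inconsistent_mir_gene_edges)
    gene_pool = truth.genes
    for m, g in _sample_decoy_pairs(
        rng, decoy_mirs_mg, gene_pool, blueprint.n_decoy_mir_gene_overlap, taken
    ):
        mg_rows.append(
            {"source": m, "target": g, "edge_type": "mir-gene", "confidence": "very high"}
        )
    low_classes = ["high", "medium", "low"]
    mir_pool = truth.mirnas + decoy_mirs_cm + decoy_mirs_mg
    wide_gene_pool = sorted(set(blueprint.planted_de_gene) | set(gene_pool))
    for m, g in _sample_decoy_pairs(
        rng, mir_pool, wide_gene_pool, blueprint.n_decoy_mir_gene_lowconf, taken
    ):
        mg_rows.append(
            {
                "source": m,
                "target": g,
                "edge_type": "mir-gene",
                "confidence": low_classes[rng.integers(3)],
            }
        )

    circ_mir = validate_interaction_table(pd.DataFrame(cm_rows))
    mir_gene = validate_interaction_table(pd.DataFrame(mg_rows))
    return circ_mir, mir_gene


def simulate_ppi(blueprint: StudyBlueprint) -> pd.DataFrame:
    """PPI edge list with combined scores: truth edges above the 0.4
    cutoff, decoys at or below it (including one exactly at 0.4, which the
    strict filter must drop)."""
    ppi = blueprint.ppi_truth
    truth = blueprint.network_truth
    if ppi is None or truth is None:
        raise ValueError("blueprint has no ppi_truth/network_truth")
    rng = blueprint.rng("ppi")
    rows = [
        {
            "source": a,
            "target": b,
            "edge_type": "gene-gene",
            "confidence": round(float(rng.uniform(0.45, 0.999)), 3),
        }
        for a, b in ppi.edges
    ]
    taken = {(a, b) for a, b in ppi.edges} | {(b, a) for a, b in ppi.edges}
    genes = truth.genes
    decoys = _sample_decoy_pairs(rng, genes, genes, 9, taken | {(g, g) for g in genes})
    scores = [0.4] + [round(float(s), 3) for s in rng.uniform(0.15, 0.39, size=8)]
    for (a, b), s in zip(decoys, scores):
        rows.append({"source": a, "target": b, "edge_type": "gene-gene", "confidence": s})
    return validate_interaction_table(pd.DataFrame(rows))


#: control/case log-medians and log-sd for the continuous clinical indexes
_CONTINUOUS_CLINICAL = {
    "PLR": (120.21, 134.36, 0.35),
    "NLR": (2.19, 2.70, 0.40),
    "MLR": (0.21, 0.22, 0.40),
    "hs_CRP": (1.15, 1.50, 1.00),
}

AGE_MEAN = 61.7
AGE_SD = 10.9
MALE_FRACTION = 0.6


def simulate_cohort(blueprint: StudyBlueprint) -> pd.DataFrame:
    """1:1 sex- and age-matched case-control cohort.

    Each pair shares a sex and ages within +/-3 years.  Binary covariates
    are Bernoulli at the per-group prevalences.  Marker levels are drawn
    as equal-variance Gaussians on the log2 scale whose case-control mean
    shift equals ln(OR); by Bayes' rule the implied conditional law of
    case status given the marker is exactly the logistic model with the
    blueprint's odds ratio per SD.  Stored marker columns are 2**z, i.e.
    strictly positive relative-expression units.
    """
    rng = blueprint.rng("cohort")
    n = blueprint.cohort_size_per_group
    rows = []
    for i in range(n):
        sex = "M" if rng.random() < MALE_FRACTION else "F"
        age_case = int(np.clip(round(rng.normal(AGE_MEAN, AGE_SD)), 35, 90))
        age_ctrl = int(np.clip(age_case + rng.integers(-3, 4), 35, 90))
        for group, age in ((GROUP_CONTROL, age_ctrl), ("CHD", age_case)):
            gi = 1 if group == "CHD" else 0
            row = {
                "subject_id": f"S{2*i + gi + 1:03d}",
                "pair_id": f"P{i+1:03d}",
                "group": group,
                "sex": sex,
                "age": age,
            }
            for cov, (p_ctrl, p_case) in blueprint.covariate_prevalences.items():
                row[cov] = int(rng.random() < (p_case if gi else p_ctrl))
            for name, (med_c, med_x, sd) in _CONTINUOUS_CLINICAL.items():
                med = med_x if gi else med_c
                row[name] = float(np.exp(rng.normal(np.log(med), sd)))
            for marker, odds_ratio in blueprint.marker_effects.items():
                shift = np.log(odds_ratio) if gi else 0.0
                row[marker] = float(2.0 ** rng.normal(shift, 1.0))
            rows.append(row)
    table = pd.DataFrame(rows)
    _check_pairs(table)
    return table


def _check_pairs(table: pd.DataFrame) -> None:
    for pair_id, sub in table.groupby("pair_id"):
        if sorted(sub["group"]) != ["CHD", "control"]:
            raise RuntimeError(f"pair {pair_id} is not one case plus one control")
        if sub["sex"].nunique() != 1:
            raise RuntimeError(f"pair {pair_id} mixes sexes")
        if abs(sub["age"].iloc[0] - sub["age"].iloc[1]) > 3:
            raise RuntimeError(f"pair {pair_id} exceeds the age window")


def realize_truth(blueprint: StudyBlueprint) -> TruthRecord:
    """Collect the ground truth implied by the blueprint."""
    truth = blueprint.network_truth
    record = TruthRecord(
        seed=blueprint.seed,
        de_circ=dict(blueprint.planted_de_circ),
        de_gene=dict(blueprint.planted_de_gene),
        immune_genes=blueprint.immune_gene_ids(),
        marker_effects=dict(blueprint.marker_effects),
    )
    if truth is not None:
        record.network_nodes = {
            "circ": truth.circrnas,
            "mir": truth.mirnas,
            "gene": truth.genes,
        }
        record.network_edges = {
            "circ-mir": list(truth.circ_mir_edges),
            "mir-gene": list(truth.mir_gene_edges),
        }
    if blueprint.ppi_truth is not None:
        record.ppi_edges = list(blueprint.ppi_truth.edges)
        record.designed_hubs = list(blueprint.ppi_truth.designed_hubs)
    return record
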