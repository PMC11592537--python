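"""Plain-text readers/writers for the pipeline's file formats.

Expression matrices travel as TSV (first column ``feature_id``, header
row of sample ids) with a sample-metadata TSV (sample_id, group, batch);
interaction tables as TSV (source, target, edge_type, confidence);
cohorts as CSV, one row per subject.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from cernakit.containers import ExpressionMatrix, validate_interaction_table


def write_expression(matrix: ExpressionMatrix, values_path, meta_path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(values_path, sep="\t")
    meta = pd.DataFrame({"sample_id": matrix.values.columns, "group": matrix.groups.values})
    if matrix.batches is not None:
        meta["batch"] = matrix.batches.values
    meta.to_csv(meta_path, sep="\t", index=False)


def read_expression(values_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    batches = meta["batch"] if "batch" in meta.columns else None
    return ExpressionMatrix(values=values, groups=meta["group"], batches=batches)


def write_interactions(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    return validate_interaction_table(pd.read_csv(path, sep="\t"))


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
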