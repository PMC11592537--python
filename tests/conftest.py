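import dataclasses

import numpy as np
import pandas as pd
import pytest

from cernakit.blueprint import paper_scale_blueprint
from cernakit.containers import ExpressionMatrix
from cernakit.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def blueprint():
    return paper_scale_blueprint(seed=101)


@pytest.fixture(scope="session")
def pipeline_summary(blueprint, tmp_path_factory):
    """One full pipeline run shared by the construction-level checks."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    return run_pipeline(RunConfig(blueprint=blueprint, outdir=outdir))


@pytest.fixture
def small_matrix():
    """4 features x 6 samples with a known strong group effect on feat_1."""
    rng = np.random.default_rng(5)
    values = pd.DataFrame(
        rng.normal(8.0, 0.1, size=(4, 6)),
        index=[f"feat_{i}" for i in range(1, 5)],
        columns=[f"s{i}" for i in range(1, 7)],
    )
    values.loc["feat_1", ["s4", "s5", "s6"]] += 2.0
    groups = pd.Series(
        ["control"] * 3 + ["case"] * 3, index=values.columns, name="group"
    )
    return ExpressionMatrix(values, groups)


def make_blueprint(**overrides):
    return dataclasses.replace(paper_scale_blueprint(seed=202), **overrides)
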