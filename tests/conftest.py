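import numpy as np
import pandas as pd
import pytest

from cernet.dge import ExpressionDataset, test_differential
from cernet.simulate import SimulationConfig, generate_dataset, write_fixture_bundle

# the package API function is not a pytest test
test_differential.__test__ = False


@pytest.fixture(scope="session")
def default_bundle():
    """One deterministic synthetic bundle shared across read-only tests."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture()
def fixture_dir(tmp_path, default_bundle):
    write_fixture_bundle(default_bundle, tmp_path)
    return tmp_path


@pytest.fixture()
def clean_bundle():
    """Bundle with no decoy target pairs: assembled triplets must equal
    the planted axes exactly."""
    return generate_dataset(SimulationConfig(seed=7, decoy_pair_rate=0.0))


def make_dataset(case_rows, ctrl_rows, feature_ids=None) -> ExpressionDataset:
    """Tiny ExpressionDataset from per-feature case/control value lists."""
    case = np.atleast_2d(np.asarray(case_rows, dtype=float))
    ctrl = np.atleast_2d(np.asarray(ctrl_rows, dtype=float))
    n_feat = case.shape[0]
    ids = feature_ids or [f"f{i}" for i in range(n_feat)]
    samples = [f"case_{j}" for j in range(case.shape[1])] + [
        f"ctrl_{j}" for j in range(ctrl.shape[1])
    ]
    matrix = pd.DataFrame(
        np.hstack([case, ctrl]), index=ids, columns=samples
    )
    groups = pd.Series(
        ["TAD"] * case.shape[1] + ["CON"] * ctrl.shape[1], index=samples
    )
    return ExpressionDataset(matrix, groups)
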