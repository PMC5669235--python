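import numpy as np
import pytest

import nanoqsar as nq
from nanoqsar.dataset import ModelingTable, SplitStatus, Topology


@pytest.fixture(scope="session")
def bundled_records():
    return nq.load_bundled_dataset()


@pytest.fixture(scope="session")
def table1(bundled_records):
    return nq.build_modeling_table(bundled_records, variant="table1")


@pytest.fixture(scope="session")
def table3(bundled_records):
    return nq.build_modeling_table(bundled_records, variant="table3")


def make_table(X, y, n_test=5, topology=Topology.PURE):
    """Synthetic modeling table from a raw (n, 3) descriptor matrix; the
    last ``n_test`` rows are the external test set."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    statuses = [SplitStatus.TRAINING] * n
    for i in range(n_test):
        statuses[n - 1 - i] = SplitStatus.TEST
    return ModelingTable(
        labels=[f"s{i}" for i in range(n)],
        topology=[topology] * n,
        bet_surface=X[:, 0],
        size_min=X[:, 1],
        size_max=X[:, 1] + np.abs(X[:, 2]),
        ec50=y,
        split_status=statuses,
        ec50_variant="synthetic",
    )


def random_descriptors(rng, n):
    """Descriptors spanning panel-like ranges."""
    return np.column_stack([
        rng.uniform(130, 190, n),
        rng.uniform(3, 60, n),
        rng.uniform(0, 140, n),
    ])


@pytest.fixture(scope="session")
def signal_table():
    """A table whose EC50 carries a strong smooth descriptor dependence
    (quadratic with interaction) plus small noise: the GP can genuinely
    learn it, unlike the bundled panel."""
    rng = np.random.default_rng(42)
    n = 30
    X = random_descriptors(rng, n)
    z = (X - X.mean(0)) / X.std(0, ddof=1)
    y = (180 + 35 * z[:, 0] - 25 * z[:, 1] + 15 * z[:, 0] * z[:, 1]
         + 10 * z[:, 2] ** 2 + rng.normal(0, 3, n))
    return make_table(X, y, n_test=5)


@pytest.fixture(scope="session")
def signal_model(signal_table):
    tr = signal_table.subset(signal_table.training_mask)
    cfg, s2, _ = nq.select_hyperparameters(tr.descriptor_matrix(), tr.ec50)
    model = nq.gp_fit(tr.descriptor_matrix(), tr.ec50, cfg, s2)
    return model, cfg, s2
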