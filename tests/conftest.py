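import numpy as np
import pytest

from dconet.cohort_io import AlterationMatrix, TreatmentArm
from dconet.simulate import SimulationConfig, simulate_alterations


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 genes with a simple known pattern."""
    status = np.array(
        [
            [1, 0, 1],
            [1, 1, 0],
            [0, 1, 0],
            [0, 0, 1],
        ],
        dtype=np.uint8,
    )
    return AlterationMatrix(["s1", "s2", "s3", "s4"], ["gA", "gB", "gC"], status)


@pytest.fixture
def planted_cohort():
    """Default desk-scale synthetic cohort (40 responders / 40 non-responders)."""
    cfg = SimulationConfig(seed=7)
    matrix, arm, truth = simulate_alterations(cfg)
    return cfg, matrix, arm, truth


@pytest.fixture
def separable_arm():
    """An arm whose response is almost perfectly encoded by one gene."""
    rng = np.random.default_rng(11)
    n = 40
    genes = [f"g{i}" for i in range(6)]
    status = (rng.random((2 * n, 6)) < 0.15).astype(np.uint8)
    labels = np.array([True] * n + [False] * n)
    status[:, 0] = np.where(labels, rng.random(2 * n) < 0.9, rng.random(2 * n) < 0.05)[
        : 2 * n
    ]
    samples = [f"s{i}" for i in range(2 * n)]
    matrix = AlterationMatrix(samples, genes, status)
    arm = TreatmentArm("TX", {s: bool(l) for s, l in zip(samples, labels)})
    return matrix, arm
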