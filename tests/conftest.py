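import numpy as np
import pytest

from gsaa import PairedGeneSetData

# Worked 5-sample toy: 3 predictor genes, 2 target genes.
TOY_X = np.array([
    [-0.38, 0.27, 1.82],
    [-0.24, 0.36, 0.94],
    [-0.32, -0.36, -0.62],
    [-0.05, 0.25, 0.37],
    [0.05, 0.09, 0.02],
])
TOY_Y = np.array([
    [0.17, 1.88],
    [4.33, 1.83],
    [-0.87, 0.61],
    [-2.37, 0.43],
    [2.55, 2.03],
])


@pytest.fixture
def toy_xy():
    return TOY_X.copy(), TOY_Y.copy()


@pytest.fixture
def toy_pair():
    return PairedGeneSetData(
        X=TOY_X.copy(), Y=TOY_Y.copy(),
        sample_ids=[f"r{i}" for i in range(1, 6)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
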