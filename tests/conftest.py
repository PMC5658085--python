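import numpy as np
import pandas as pd
import pytest

from chemosens.simulate import SyntheticSpec, generate


@pytest.fixture
def tiny_expr():
    """3-probe x 2-sample matrix with hand-written values."""
    return pd.DataFrame(
        [[1.5, 2.5], [3.0, 4.0], [5.25, 6.75]],
        index=["P001", "P002", "P003"],
        columns=["S1", "S2"],
    )


@pytest.fixture(scope="session")
def small_panel():
    """Fast planted panel: 40 samples x 120 probes, 8 informative at 2 SD."""
    spec = SyntheticSpec(
        n_samples=40, n_probes=120, n_informative=8, effect_size=2.0, seed=11
    )
    expr, responses, truth = generate(spec)
    return spec, expr, responses, truth


@pytest.fixture
def separable_toy():
    """Well-separated 2-cluster data: 10 samples, 5 features, labels +-1."""
    rng = np.random.default_rng(3)
    n_half, p = 5, 5
    pos = rng.normal(3.0, 0.3, size=(n_half, p))
    neg = rng.normal(-3.0, 0.3, size=(n_half, p))
    X = pd.DataFrame(
        np.vstack([pos, neg]).T,
        index=[f"P{i}" for i in range(p)],
        columns=[f"S{j}" for j in range(2 * n_half)],
    )
    y = np.array([1] * n_half + [-1] * n_half)
    return X, y
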