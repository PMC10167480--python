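import warnings

import numpy as np
import pandas as pd
import pytest

from progulons import ModuleSpec, RatioMatrix, simulate_proteomehd

# sklearn's OPTICS emits a harmless divide-by-zero warning when duplicate
# points yield zero reachability; keep test output clean.
warnings.filterwarnings(
    "ignore", message="divide by zero", category=RuntimeWarning,
)


@pytest.fixture
def tiny_matrix() -> RatioMatrix:
    """3 proteins x 2 experiments with one missing cell."""
    df = pd.DataFrame(
        {"e1": [0.5, np.nan, -0.3], "e2": [1.0, 0.2, 0.4]},
        index=pd.Index(["p1", "p2", "p3"], name="protein_id"),
    )
    return RatioMatrix(df)


@pytest.fixture(scope="session")
def planted_matrix():
    """One tight 12-member module over 80 background proteins."""
    m, truth = simulate_proteomehd(
        n_proteins=92, n_experiments=40,
        modules=[ModuleSpec.from_rho(12, 0.9)], rng_seed=7,
    )
    return m, truth


def random_ratio_frame(n_prot: int, n_exp: int, missing: float,
                       seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_prot, n_exp)).round(4)
    mask = rng.random((n_prot, n_exp)) < missing
    vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(
        vals,
        index=pd.Index([f"P{i:04d}" for i in range(n_prot)], name="protein_id"),
        columns=[f"exp{j}" for j in range(n_exp)],
    )
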