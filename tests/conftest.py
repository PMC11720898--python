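import numpy as np
import pytest

from dfnckit import synth
from dfnckit.fnc import to_edges


@pytest.fixture(scope="session")
def two_state_windows():
    """200 windowed-FNC edge vectors from the two-hidden-state model.

    K=10 networks, half the windows per state (weak mean off-diagonal
    r=0.1 vs strong 0.45, block-structured patterns), each window's
    correlation matrix estimated from 50 state-consistent samples.
    Returns (z_edges, labels).
    """
    rng = np.random.default_rng(20240917)
    K, n_windows, w = 10, 200, 50
    covs = synth.two_state_covs(K)
    chol = [np.linalg.cholesky(c) for c in covs]
    labels = np.repeat([0, 1], n_windows // 2)
    edges = np.empty((n_windows, K * (K - 1) // 2))
    for i, s in enumerate(labels):
        x = rng.standard_normal((w, K)) @ chol[s].T
        edges[i] = to_edges(np.corrcoef(x, rowvar=False))
    return np.arctanh(edges), labels


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject synthetic cohort with a planted GA effect on edge (0, 1)."""
    return synth.gen_cohort(
        12, effect_spec={(0, 1): {"ga": 0.02}}, K=6, T=400, seed=7
    )
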