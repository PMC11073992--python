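import itertools

import numpy as np
import pandas as pd
import pytest

import zeitgeist as zg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_patterns():
    """8 participants x 6 features, fixed values, for oracle comparisons."""
    r = np.random.default_rng(7)
    return zg.PatternMatrix(r.normal(size=(8, 6)),
                            [f"P{i}" for i in range(8)], "toy")


@pytest.fixture(scope="session")
def crossed_dyads():
    """Small doubled dyad table generated from a known crossed LMM."""
    r = np.random.default_rng(11)
    n_sub, n_t = 15, 3
    u = r.normal(0, 0.3, n_sub)
    w = r.normal(0, 0.2, n_t)
    lon = r.normal(0, 1, n_sub)
    rows = []
    for t in range(n_t):
        for i, j in itertools.combinations(range(n_sub), 2):
            x = (lon[i] + lon[j]) / 2
            y = 0.5 - 0.3 * x + u[i] + u[j] + w[t] + r.normal(0, 0.5)
            rows.append((f"P{i}", f"P{j}", f"T{t}", x, y))
    return pd.DataFrame(rows, columns=["participant1", "participant2",
                                       "target", "mean_loneliness",
                                       "similarity"])


def ak_dataset(seed, n=30, features=200, targets=3, effect=None, **kw):
    """Generate an ak/null dataset and its undoubled dyad table."""
    from zeitgeist.pipeline import build_dyad_table
    if effect is None:
        cfg = zg.SyntheticConfig(n_participants=n, n_features=features,
                                 n_targets=targets, scenario="null",
                                 seed=seed, **kw)
    else:
        probe = zg.SyntheticConfig(n_participants=n, n_features=features,
                                   n_targets=targets, scenario="ak",
                                   idiosyncrasy_slope=1e-9, **kw)
        cfg = zg.SyntheticConfig(n_participants=n, n_features=features,
                                 n_targets=targets, scenario="ak",
                                 idiosyncrasy_slope=zg.slope_for_effect(
                                     effect, probe),
                                 seed=seed, **kw)
    ds = zg.generate_patterns(cfg)
    return ds, build_dyad_table(ds)
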