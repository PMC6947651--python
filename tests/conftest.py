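import numpy as np
import pytest

import penirf as pf


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def linear_dataset(rng):
    """y = 2*x0 + small noise, 9 pure-noise features: one planted parent."""
    X = rng.standard_normal((150, 10))
    y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(150)
    return pf.Dataset(X, y=y)


@pytest.fixture
def chain_network():
    """g0 -> g1 -> g2 with unit effects and small noise."""
    return pf.PlantedNetwork(
        gene_ids=["g0", "g1", "g2"],
        edges=[("g0", "g1", 1.0), ("g1", "g2", 1.0)],
        noise_sd=0.1,
    )


def brute_force_best_split(X, y):
    """Independent exhaustive oracle: every feature, every midpoint threshold.

    Scores raw sum-of-squared-deviations decrease; ties break toward the
    lowest feature index then lowest threshold (strict improvement only).
    """

    def ss(v):
        return float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0

    best = None  # (decrease, feature, threshold)
    parent = ss(y)
    for f in range(X.shape[1]):
        u = np.unique(X[:, f])
        for v1, v2 in zip(u[:-1], u[1:]):
            thr = 0.5 * (v1 + v2)
            mask = X[:, f] <= thr
            dec = parent - ss(y[mask]) - ss(y[~mask])
            prev = 0.0 if best is None else best[0]
            if dec > prev + 1e-9 * (1.0 + prev):
                best = (dec, f, thr)
    return best
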