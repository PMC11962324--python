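"""Independent oracles shared by the unit and acceptance suites.

The brute-force HMM oracle enumerates every hidden-state path and computes
emission densities with scipy directly, independent of the package's
forward-backward implementation.
"""

import itertools

import numpy as np
from scipy.stats import norm

from moodcast.hmm import HHMMParams


def random_params(rng: np.random.Generator, K: int, Fc: int, with_bern: bool = True) -> HHMMParams:
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    return HHMMParams(
        start_probs=rng.dirichlet(np.ones(K)),
        transition=A,
        gauss_means=rng.normal(0, 1.5, (K, Fc)),
        gauss_sds=rng.uniform(0.4, 1.5, (K, Fc)),
        bern_p=rng.uniform(0.1, 0.9, K) if with_bern else None,
    )


def random_sequence(rng: np.random.Generator, T: int, Fc: int, with_bern: bool, missing: float) -> np.ndarray:
    X = rng.normal(0, 1.5, (T, Fc + (1 if with_bern else 0)))
    if with_bern:
        X[:, Fc] = rng.integers(0, 2, T)
    X[rng.random(X.shape) < missing] = np.nan
    return X


def brute_force_posterior(params: HHMMParams, seq: np.ndarray):
    """Exhaustive path enumeration: returns (gamma, log_likelihood)."""
    T = len(seq)
    K = params.K
    Fc = params.n_continuous

    def emit(t, k):
        p = 1.0
        for f in range(Fc):
            if not np.isnan(seq[t, f]):
                p *= norm.pdf(seq[t, f], params.gauss_means[k, f], params.gauss_sds[k, f])
        if params.bern_p is not None and not np.isnan(seq[t, Fc]):
            pb = params.bern_p[k]
            p *= pb if seq[t, Fc] == 1 else 1 - pb
        return p

    gamma = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = params.start_probs[path[0]] * emit(0, path[0])
        for t in range(1, T):
            p *= params.transition[path[t - 1], path[t]] * emit(t, path[t])
        total += p
        for t in range(T):
            gamma[t, path[t]] += p
    return gamma / total, np.log(total)
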