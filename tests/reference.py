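"""Independent reference implementations used as oracles in tests.

These deliberately avoid the package's own code paths: densities come from
scipy.stats, normalization is done with plain loops/arrays, and the EM
iteration follows the textbook recipe for a Gaussian mixture with free
mixing weights.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def em_iterate(X, means, covs, weights, n_iter):
    """Vanilla MoG-EM: returns (means, covs, weights) after n_iter iterations."""
    means = np.array(means, dtype=float)
    covs = np.array(covs, dtype=float)
    weights = np.array(weights, dtype=float)
    C = len(weights)
    N = len(X)
    for _ in range(n_iter):
        dens = np.column_stack([
            multivariate_normal.pdf(X, mean=means[c], cov=covs[c]) for c in range(C)])
        num = dens * weights
        r = num / num.sum(axis=1, keepdims=True)
        Nc = r.sum(axis=0)
        weights = Nc / N
        for c in range(C):
            means[c] = r[:, c] @ X / Nc[c]
            diff = X - means[c]
            covs[c] = (r[:, c, None] * diff).T @ diff / Nc[c]
    return means, covs, weights


def exact_log_marginal(X, pi_per_spike, means, covs):
    """Log marginal likelihood by enumerating every assignment vector.

    ``pi_per_spike`` is (N, C): the mixing proportions that apply to each
    spike.  Exponential in N — only for tiny instances.
    """
    N, C = pi_per_spike.shape
    dens = np.column_stack([
        multivariate_normal.pdf(X, mean=means[c], cov=covs[c]) for c in range(C)])
    total = 0.0
    for assign in itertools.product(range(C), repeat=N):
        p = 1.0
        for i, z in enumerate(assign):
            p *= pi_per_spike[i, z] * dens[i, z]
        total += p
    return float(np.log(total))


def mog_loglik(X, pi_per_spike, means, covs):
    """Direct per-spike mixture log-likelihood (independent-sum route)."""
    C = pi_per_spike.shape[1]
    dens = np.column_stack([
        multivariate_normal.pdf(X, mean=means[c], cov=covs[c]) for c in range(C)])
    return float(np.log((pi_per_spike * dens).sum(axis=1)).sum())
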