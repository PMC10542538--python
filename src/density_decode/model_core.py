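"""Generative-model mathematics shared by the encoder and decoder.

The model: in trial k, time bin t, each mixture component c fires at a rate
that depends on behavior through a generalized linear model,

    lambda_ctk = link(theta_c' u_tk),     u_tk = [1, y_tk, ...],

the mixing proportion is the normalized rate pi_ctk = lambda_ctk / sum_c'
lambda_c'tk, spike assignments are Categorical(pi_tk), and spike features
are Gaussian given the assignment, s ~ N(mu_c, Sigma_c).  The link is
strictly positive (softplus by default; exp available).

This module evaluates rates, proportions, component log-densities,
posterior responsibilities (the E step), and the evidence lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import expit, logsumexp

from .data_model import BehaviorSet, EncoderParams, MoGComponents, SpikeTable

_LN2 = float(np.log(2.0))


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + e^x), computed without overflow."""
    return np.logaddexp(0.0, x)


def softplus_inv(y: np.ndarray) -> np.ndarray:
    """Inverse of softplus on (0, inf): log(e^y - 1), stable for small/large y."""
    y = np.asarray(y, dtype=np.float64)
    with np.errstate(over="ignore"):
        out = y + np.log1p(-np.exp(-y))
    return out


@dataclass
class RateDesign:
    """Maps (t, y_k) to the GLM design vector u_tk.

    The default design is intercept + current behavior value, so each
    component has coefficients theta_c = (b_c, w_c).  ``n_lags`` adds lagged
    behavior values (zero-padded at trial start); ``time_onehot`` appends a
    one-hot encoding of the time bin.  ``link`` selects the positive inverse
    link ('softplus' or 'exp').
    """

    link: str = "softplus"
    n_lags: int = 0
    time_onehot: bool = False

    def __post_init__(self) -> None:
        if self.link not in ("softplus", "exp"):
            raise ValueError(f"unknown link {self.link!r}")

    def n_params(self, T: int) -> int:
        return 2 + self.n_lags + (T if self.time_onehot else 0)

    def design_matrix(self, behavior: BehaviorSet | np.ndarray, T: int) -> np.ndarray:
        """Design tensor U of shape (K, T, P) with U[k, t] = u_tk."""
        y = behavior.per_bin(T) if isinstance(behavior, BehaviorSet) else np.asarray(behavior)
        if y.ndim == 1:
            y = np.repeat(y[:, None], T, axis=1)
        K = y.shape[0]
        cols = [np.ones((K, T)), y]
        for lag in range(1, self.n_lags + 1):
            shifted = np.zeros_like(y)
            shifted[:, lag:] = y[:, :-lag]
            cols.append(shifted)
        U = np.stack(cols, axis=2)
        if self.time_onehot:
            U = np.concatenate([U, np.broadcast_to(np.eye(T), (K, T, T))], axis=2)
        return U

    def apply_link(self, a: np.ndarray) -> np.ndarray:
        return softplus(a) if self.link == "softplus" else np.exp(a)

    def link_grad_over_link(self, a: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """d(link)/da evaluated at a, divided by link(a) — used by gradients."""
        if self.link == "softplus":
            return expit(a) / lam
        return np.ones_like(a)


def rates(theta: EncoderParams | np.ndarray, behavior: BehaviorSet | np.ndarray,
          design: RateDesign, T: int | None = None) -> np.ndarray:
    """Firing rates lambda_ctk as a strictly positive (C, T, K) array."""
    th = theta.mean if isinstance(theta, EncoderParams) else np.atleast_2d(theta)
    if T is None:
        if isinstance(behavior, BehaviorSet) and behavior.kind == "continuous":
            T = behavior.values.shape[1]
        elif isinstance(behavior, np.ndarray) and behavior.ndim == 2:
            T = behavior.shape[1]
        else:
            raise ValueError("T must be given for trial-level behavior")
    U = design.design_matrix(behavior, T)  # (K, T, P)
    if th.shape[1] != U.shape[2]:
        raise ValueError(
            f"coefficient dimension {th.shape[1]} does not match design dimension {U.shape[2]}"
        )
    a = np.einsum("cp,ktp->ctk", th, U)
    return design.apply_link(a)


def mixing_proportions(lam: np.ndarray) -> np.ndarray:
    """Normalize rates over components: pi_ctk = lambda_ctk / sum_c' lambda_c'tk."""
    lam = np.asarray(lam, dtype=np.float64)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("rates must be strictly positive and finite")
    return lam / lam.sum(axis=0, keepdims=True)


def log_component_densities(spikes: SpikeTable | np.ndarray,
                            mog: MoGComponents) -> np.ndarray:
    """log N(s_i; mu_c, Sigma_c) for every spike and component, shape (N, C).

    Computed through the Cholesky factor of each covariance; raises naming the
    offending component if a factorization fails.
    """
    X = spikes.features if isinstance(spikes, SpikeTable) else np.atleast_2d(spikes)
    N, D = X.shape
    out = np.empty((N, mog.C))
    for c in range(mog.C):
        try:
            L = np.linalg.cholesky(mog.covariances[c])
        except np.linalg.LinAlgError as e:
            raise ValueError(f"covariance of component {c} is not positive-definite") from e
        diff = X - mog.means[c]
        sol = solve_triangular(L, diff.T, lower=True)
        maha = np.sum(sol ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, c] = -0.5 * (D * np.log(2.0 * np.pi) + logdet + maha)
    return out


def responsibilities(logdens: np.ndarray, pi: np.ndarray, trials: np.ndarray,
                     bins: np.ndarray) -> np.ndarray:
    """Posterior assignment probabilities r_i(c) ∝ pi_{c,t_i,k_i} N(s_i; eta_c).

    Log-sum-exp stabilized; each row sums to one.
    """
    logpi = np.log(pi)  # (C, T, K)
    logw = logdens + logpi[:, bins, trials].T  # (N, C)
    logw -= logsumexp(logw, axis=1, keepdims=True)
    r = np.exp(logw)
    # after stabilization every row has a unit-sum by construction
    assert np.all(np.isfinite(r))
    return r


def weighted_mog_loglik(logdens: np.ndarray, pi: np.ndarray, trials: np.ndarray,
                        bins: np.ndarray) -> float:
    """Exact log-likelihood sum_i log sum_c pi_c N(s_i; eta_c) of all spikes."""
    logpi = np.log(pi)
    return float(logsumexp(logdens + logpi[:, bins, trials].T, axis=1).sum())


@dataclass
class PriorSpec:
    """Priors for the encoder: p(theta_c) and p(y).

    ``theta`` is 'gaussian' (isotropic, mean 0, variance ``theta_var``) or
    'flat'.  ``bernoulli_p`` is the prior success probability for binary
    behavior; continuous behavior takes a zero-mean squared-exponential GP
    prior with the given lengthscale (in bins) and variance.
    """

    theta: str = "gaussian"
    theta_var: float = 1.0
    bernoulli_p: float = 0.5
    gp_lengthscale: float = 5.0
    gp_variance: float = 1.0

    def log_prior_theta(self, th: np.ndarray) -> float:
        if self.theta == "flat":
            return 0.0
        return float(-0.5 * np.sum(th ** 2) / self.theta_var
                     - 0.5 * th.size * np.log(2 * np.pi * self.theta_var))

    def grad_log_prior_theta(self, th: np.ndarray) -> np.ndarray:
        if self.theta == "flat":
            return np.zeros_like(th)
        return -th / self.theta_var

    def gp_covariance(self, T: int) -> np.ndarray:
        t = np.arange(T)
        K = self.gp_variance * np.exp(-0.5 * ((t[:, None] - t[None, :]) / self.gp_lengthscale) ** 2)
        return K + 1e-6 * np.eye(T)


def elbo(spikes: SpikeTable, behavior: BehaviorSet, mog: MoGComponents,
         theta: EncoderParams, design: RateDesign, resp: np.ndarray,
         prior_spec: PriorSpec | None = None) -> float:
    """Evidence lower bound under the mean-field factorization q(z) q(theta).

    With q(theta) a point mass at its mean (the default point-estimated
    mode), the bound is

        sum_i sum_c r_ic [ log pi_{c,t_i,k_i} + log N(s_i; eta_c) - log r_ic ]
        + log p(theta_mean),

    which for the exact E-step responsibilities collapses to the marginal
    log-likelihood of the spikes plus the prior term.  Raises if any term is
    non-finite.
    """
    prior_spec = prior_spec or PriorSpec(theta="flat")
    lam = rates(theta, behavior, design, spikes.T)
    pi = mixing_proportions(lam)
    logdens = log_component_densities(spikes, mog)
    logpi = np.log(pi)[:, spikes.bins, spikes.trials].T  # (N, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(resp > 0, resp * np.log(resp), 0.0)
    data_term = float(np.sum(resp * (logpi + logdens)) - np.sum(ent))
    prior_term = prior_spec.log_prior_theta(theta.mean)
    val = data_term + prior_term
    if not np.isfinite(val):
        raise FloatingPointError(
            f"non-finite ELBO: data_term={data_term}, prior_term={prior_term}"
        )
    return val


def standardize_features(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each feature dimension; returns (Xs, mean, scale), invertible.

    Positions in µm and amplitudes in standard units live on very different
    scales, so the mixture is always fit in standardized coordinates.
    """
    mean = X.mean(axis=0) if len(X) else np.zeros(X.shape[1])
    scale = X.std(axis=0) if len(X) else np.ones(X.shape[1])
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale
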