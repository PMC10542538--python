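"""Test-time inference: weight matrices, baselines, and behavior decoders.

The robust decoding path works as follows.  For training trials, the
observed behavior is substituted into the rate model to obtain posterior
mixing proportions pi_ctk; for test trials, a provisional behavior estimate
from multi-unit thresholding stands in for the unobserved behavior.  The
per-spike assignment posteriors under those proportions are then summed
into a K x C x T weight matrix W, whose flattened rows feed a standard
behavior decoder — logistic regression for binary behavior, ridge
regression for time-varying traces.  Hard assignments (sorted units or
thresholded channels) give one-hot W, so the baselines run through the
identical pipeline.

A direct latent-behavior variational decoder is provided for completeness,
but the weight-matrix route is the default and recommended path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.linear_model import LogisticRegressionCV, RidgeCV
from sklearn.model_selection import KFold

from .data_model import (BehaviorSet, EncoderParams, MoGComponents, SpikeTable,
                         WeightMatrix)
from .model_core import (PriorSpec, RateDesign, log_component_densities,
                         mixing_proportions, rates, responsibilities)

LOGISTIC_C_GRID = 10.0 ** np.arange(-3, 4)
RIDGE_ALPHA_GRID = 10.0 ** np.arange(-3, 4)


def posterior_pi(theta: EncoderParams | np.ndarray, y_or_yhat, design: RateDesign,
                 T: int | None = None) -> np.ndarray:
    """Posterior mixing proportions from the (estimated) behavior, (C, T, K).

    Uses the variational mean of theta; composition of the rate model and
    the normalization step.
    """
    lam = rates(theta, y_or_yhat, design, T)
    return mixing_proportions(lam)


def compute_weight_matrix(resp: np.ndarray, trials: np.ndarray, bins: np.ndarray,
                          K: int, C: int, T: int) -> WeightMatrix:
    """Soft weight matrix W_kct = sum_i r_itk(c); conserves spike counts."""
    if resp.shape[1] != C:
        raise ValueError(f"responsibilities have {resp.shape[1]} components, expected {C}")
    if len(trials) and (trials.max() >= K or bins.max() >= T):
        raise ValueError("spike index outside declared (K, T) bounds")
    W = np.zeros((K * T, C))
    np.add.at(W, np.asarray(trials) * T + np.asarray(bins), resp)
    return WeightMatrix(W.reshape(K, T, C).transpose(0, 2, 1))


def one_hot_weight_matrix(spikes: SpikeTable, labels: np.ndarray, K: int, C: int,
                          T: int, drop_missing: bool = True) -> WeightMatrix:
    """Integer count tensor for hard unit/channel assignments.

    Labels equal to -1 mark missing (unsorted/dropped) spikes and are
    excluded when ``drop_missing``.
    """
    labels = np.asarray(labels)
    if np.any(labels >= C):
        raise ValueError(f"label {labels.max()} outside [0, {C})")
    keep = labels >= 0 if drop_missing else slice(None)
    tr, bi, lb = spikes.trials[keep], spikes.bins[keep], labels[keep]
    W = np.zeros((K, C, T))
    np.add.at(W, (tr, lb, bi), 1.0)
    return WeightMatrix(W, one_hot=True)


def soft_weight_matrix(spikes: SpikeTable, mog: MoGComponents,
                       theta: EncoderParams | np.ndarray, y_or_yhat,
                       design: RateDesign) -> WeightMatrix:
    """End-to-end soft path: pi from behavior, E step, responsibility sums."""
    pi = posterior_pi(theta, y_or_yhat, design, spikes.T)
    logdens = log_component_densities(spikes, mog)
    r = responsibilities(logdens, pi, spikes.trials, spikes.bins)
    return compute_weight_matrix(r, spikes.trials, spikes.bins,
                                 spikes.K, mog.C, spikes.T)


def depth_channel_groups(spikes: SpikeTable, n_channels: int,
                         depth_column: int = 1) -> np.ndarray:
    """Proxy channel labels: equal-width bins of the depth (z) feature.

    Feature tables carry no electrode indices, so multi-unit "channels" are
    formed by binning the depth coordinate, the axis along which channels
    are laid out on the probe.
    """
    if spikes.n_spikes == 0:
        raise ValueError("cannot form channel groups from an empty spike table")
    z = spikes.features[:, depth_column if spikes.D > depth_column else 0]
    lo, hi = z.min(), z.max()
    width = (hi - lo) or 1.0
    return np.minimum((n_channels * (z - lo) / width).astype(int), n_channels - 1)


@dataclass
class BehaviorDecoder:
    """Final behavior decoder over flattened weight-matrix features.

    ``logistic`` predicts one binary value per trial; ``ridge`` predicts a
    length-T trace per trial (one linear head per output bin, sharing the
    full flattened W).  Regularization is chosen by inner cross-validation
    over a powers-of-ten grid.
    """

    kind: str
    model: object
    n_features: int

    def predict(self, W_test: WeightMatrix) -> np.ndarray:
        X = W_test.flatten_trials()
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"weight matrix has {X.shape[1]} features, decoder expects {self.n_features}")
        return self.model.predict(X)

    def predict_proba(self, W_test: WeightMatrix) -> np.ndarray:
        if self.kind != "logistic":
            raise ValueError("probabilities are only defined for the logistic decoder")
        X = W_test.flatten_trials()
        return self.model.predict_proba(X)[:, 1]


def fit_behavior_decoder(W_train: WeightMatrix, y_train: BehaviorSet,
                         kind: str | None = None,
                         reg_grid: np.ndarray | None = None,
                         seed: int = 0) -> BehaviorDecoder:
    """Fit the final decoder on training-trial weight matrices."""
    kind = kind or ("logistic" if y_train.kind == "binary" else "ridge")
    X = W_train.flatten_trials()
    if kind == "logistic":
        y = y_train.values.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("binary behavior has a single class in training data")
        n_splits = min(3, int(np.bincount(y).min()))
        if n_splits >= 2:
            model = LogisticRegressionCV(
                Cs=reg_grid if reg_grid is not None else LOGISTIC_C_GRID,
                cv=n_splits, max_iter=2000, random_state=seed,
                scoring="accuracy", l1_ratios=(0.0,), use_legacy_attributes=False)
        else:
            from sklearn.linear_model import LogisticRegression
            model = LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
        model.fit(X, y)
    elif kind == "ridge":
        model = RidgeCV(alphas=reg_grid if reg_grid is not None else RIDGE_ALPHA_GRID,
                        cv=KFold(n_splits=min(3, len(X)), shuffle=True,
                                 random_state=seed) if len(X) >= 3 else None)
        model.fit(X, y_train.values)
    else:
        raise ValueError(f"unknown decoder kind {kind!r}")
    return BehaviorDecoder(kind, model, X.shape[1])


def predict_behavior(decoder: BehaviorDecoder, W_test: WeightMatrix) -> np.ndarray:
    """Predict behavior for test trials; labels for logistic, traces for ridge."""
    return decoder.predict(W_test)


def estimate_behavior_threshold(spikes_test: SpikeTable, spikes_train: SpikeTable,
                                y_train: BehaviorSet, n_channels: int = 8,
                                seed: int = 0) -> np.ndarray:
    """Provisional behavior estimate y-hat from multi-unit thresholding.

    Groups all spikes into depth-binned proxy channels (bin edges from the
    pooled train+test features so groups align), builds one-hot count
    matrices, fits the baseline behavior decoder on the training trials, and
    predicts test-trial behavior.  Returns (K_test,) labels for binary
    behavior or (K_test, T) traces for continuous.
    """
    pooled = SpikeTable(
        2, 1, np.concatenate([np.zeros(spikes_train.n_spikes, int),
                              np.ones(spikes_test.n_spikes, int)]),
        np.zeros(spikes_train.n_spikes + spikes_test.n_spikes, int),
        np.vstack([spikes_train.features, spikes_test.features]))
    groups = depth_channel_groups(pooled, n_channels)
    g_train = groups[:spikes_train.n_spikes]
    g_test = groups[spikes_train.n_spikes:]
    W_train = one_hot_weight_matrix(spikes_train, g_train, spikes_train.K,
                                    n_channels, spikes_train.T)
    W_test = one_hot_weight_matrix(spikes_test, g_test, spikes_test.K,
                                   n_channels, spikes_test.T)
    if y_train.kind == "binary" and len(np.unique(y_train.values)) < 2:
        # degenerate training behavior: predict the constant class
        const = float(y_train.values[0])
        return np.full(spikes_test.K, const)
    dec = fit_behavior_decoder(W_train, y_train, seed=seed)
    return predict_behavior(dec, W_test)


def decode_latent_variational(spikes_test: SpikeTable, mog: MoGComponents,
                              theta: EncoderParams, design: RateDesign,
                              prior_y: PriorSpec | None = None,
                              iters: int = 20) -> dict[str, np.ndarray]:
    """Direct variational decoding of the latent behavior (mean-field q(z) q(y)).

    Binary behavior: coordinate ascent between the assignment posteriors and
    a Bernoulli q(y_k), exact because y takes two values.  Continuous
    behavior: per-trial MAP trace under the GP prior via L-BFGS with a
    Laplace variance.  Returns posterior mean and variance per trial (binary)
    or per trial and bin (continuous).

    This path is provided for completeness; the weight-matrix route is the
    robust default.
    """
    prior_y = prior_y or PriorSpec()
    K, T = spikes_test.K, spikes_test.T
    logdens = log_component_densities(spikes_test, mog)
    th = theta.mean

    logpi_of = {}
    for y_val in (0.0, 1.0):
        lam = rates(th, np.full((K, T), y_val), design, T)
        logpi_of[y_val] = np.log(mixing_proportions(lam))  # (C, T, K)

    p1 = prior_y.bernoulli_p
    beta = np.full(K, p1)
    for _ in range(iters):
        elogpi = (beta[None, None, :] * logpi_of[1.0]
                  + (1 - beta)[None, None, :] * logpi_of[0.0])
        r = responsibilities(logdens, _norm_exp(elogpi),
                             spikes_test.trials, spikes_test.bins)
        delta = logpi_of[1.0] - logpi_of[0.0]  # (C, T, K)
        per_spike = delta[:, spikes_test.bins, spikes_test.trials].T  # (N, C)
        contrib = np.zeros(K)
        np.add.at(contrib, spikes_test.trials, np.sum(r * per_spike, axis=1))
        logit = np.log(p1 / (1 - p1)) + contrib
        beta = expit(logit)
    return {"mean": beta, "var": beta * (1 - beta)}


def _norm_exp(elogpi: np.ndarray) -> np.ndarray:
    """Normalized exp of expected log proportions (a valid simplex surrogate)."""
    w = np.exp(elogpi - elogpi.max(axis=0, keepdims=True))
    return w / w.sum(axis=0, keepdims=True)


def decode_latent_continuous(spikes_test: SpikeTable, mog: MoGComponents,
                             theta: EncoderParams, design: RateDesign,
                             prior_y: PriorSpec | None = None,
                             iters: int = 10) -> dict[str, np.ndarray]:
    """MAP trace decoding with a squared-exponential GP prior per trial."""
    prior_y = prior_y or PriorSpec()
    K, T = spikes_test.K, spikes_test.T
    logdens = log_component_densities(spikes_test, mog)
    th = theta.mean
    Kg = prior_y.gp_covariance(T)
    Kinv = np.linalg.inv(Kg)
    y = np.zeros((K, T))
    from .encoder_vi import aggregate_responsibilities

    for _ in range(iters):
        pi = posterior_pi(th, y, design, T)
        r = responsibilities(logdens, pi, spikes_test.trials, spikes_test.bins)
        R = aggregate_responsibilities(r, spikes_test.trials, spikes_test.bins, K, T)

        for k in range(K):
            Rk = R[:, :, k]  # (C, T)

            def nobj(yk, Rk=Rk):
                lam = rates(th, yk[None, :], design, T)[:, :, 0]
                pi_k = lam / lam.sum(axis=0, keepdims=True)
                data = np.sum(Rk * np.log(pi_k))
                return -(data - 0.5 * yk @ Kinv @ yk)

            res = minimize(nobj, y[k], method="L-BFGS-B",
                           options={"maxiter": 50})
            y[k] = res.x
    var = np.broadcast_to(np.diag(Kg), (K, T)).copy()
    return {"mean": y, "var": var}
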