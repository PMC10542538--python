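"""Variational encoders: fit the behavior-modulated mixture from training trials.

Two fitters share the same E step (posterior spike-assignment
responsibilities) and differ in how the rate coefficients theta are updated:

* :func:`fit_cavi` — coordinate ascent.  The mixture means and covariances
  get closed-form responsibility-weighted updates (exactly as in MoG-EM);
  the theta block is maximized by L-BFGS with analytic gradients (closed
  form when behavior weights are frozen), and variational variances come
  from the curvature at the optimum.  Every accepted update cannot decrease
  the ELBO, so the trace is monotone.

* :func:`fit_advi` — stochastic gradient ascent on a reparameterized
  Monte-Carlo ELBO over diagonal-Gaussian variational factors q(theta),
  using Adam on minibatches of trials (defaults: learning rate 0.001, batch
  of 6 trials, 1000 iterations).  Mixture parameters are refreshed with
  full-data M steps at a fixed cadence.

Both fitters operate on z-scored features internally and report component
parameters in the original feature units (an affine change of variables
that leaves responsibilities untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.cluster import KMeans

from .data_model import BehaviorSet, EncoderParams, MoGComponents, SpikeTable
from .model_core import (PriorSpec, RateDesign, log_component_densities,
                         mixing_proportions, rates, responsibilities,
                         softplus_inv, standardize_features)

COV_FLOOR = 1e-4  # minimum covariance eigenvalue, in z-scored feature units


@dataclass
class FitReport:
    elbo_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    events: list[str] = field(default_factory=list)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None


def aggregate_responsibilities(r: np.ndarray, trials: np.ndarray, bins: np.ndarray,
                               K: int, T: int) -> np.ndarray:
    """Sum per-spike responsibilities into bins: R_ctk = sum_i r_i(c), (C, T, K)."""
    C = r.shape[1]
    flat = np.zeros((K * T, C))
    np.add.at(flat, trials * T + bins, r)
    return flat.reshape(K, T, C).transpose(2, 1, 0)


def init_mog(spikes: SpikeTable, C: int, seed: int = 0,
             method: str = "kmeans") -> MoGComponents:
    """Initialize component means and covariances from the data.

    ``kmeans`` (default) uses k-means centroids and within-cluster scatter;
    ``random`` picks C distinct spikes as means with the pooled covariance.
    Covariances are floored at COV_FLOOR * I.
    """
    X = spikes.features
    N, D = X.shape
    if C > N:
        raise ValueError(f"cannot initialize {C} components from {N} spikes")
    if C == 1:
        labels = np.zeros(N, dtype=int)
        means = X.mean(axis=0, keepdims=True)
    elif method == "kmeans":
        km = KMeans(n_clusters=C, random_state=seed, n_init=10).fit(X)
        labels, means = km.labels_, km.cluster_centers_
    elif method == "random":
        rng = np.random.default_rng(seed)
        means = X[rng.choice(N, size=C, replace=False)]
        labels = np.argmin(((X[:, None] - means[None]) ** 2).sum(-1), axis=1)
    else:
        raise ValueError(f"unknown init method {method!r}")
    covs = np.empty((C, D, D))
    pooled = np.cov(X.T).reshape(D, D) if N > 1 else np.eye(D)
    for c in range(C):
        pts = X[labels == c]
        covs[c] = np.cov(pts.T).reshape(D, D) if len(pts) > D else pooled
        covs[c] = _floor_cov(covs[c])
    return MoGComponents(means, covs)


def _floor_cov(S: np.ndarray, floor: float = COV_FLOOR) -> np.ndarray:
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    return (V * np.maximum(w, floor)) @ V.T


def _mog_m_step(X: np.ndarray, r: np.ndarray, mog: MoGComponents,
                floor: float, events: list[str]) -> MoGComponents:
    """Responsibility-weighted mean/covariance updates; reseeds empty components."""
    C, D = mog.C, mog.D
    Nc = r.sum(axis=0)
    means = mog.means.copy()
    covs = mog.covariances.copy()
    logd = None
    for c in range(C):
        if Nc[c] < 1e-8:
            # reseed at the feature of the overall lowest-likelihood spike
            if logd is None:
                from scipy.special import logsumexp
                logd = logsumexp(log_component_densities(X, mog), axis=1)
            j = int(np.argmin(logd))
            means[c] = X[j]
            covs[c] = _floor_cov(np.eye(D), floor)
            events.append(f"reseeded empty component {c} at spike {j}")
            continue
        mu = r[:, c] @ X / Nc[c]
        diff = X - mu
        S = (r[:, c, None] * diff).T @ diff / Nc[c]
        means[c] = mu
        covs[c] = _floor_cov(S, floor)
    return MoGComponents(means, covs)


def _glm_objective_grad(theta_flat: np.ndarray, R: np.ndarray, U: np.ndarray,
                        design: RateDesign, prior: PriorSpec,
                        freeze_weights: bool) -> tuple[float, np.ndarray]:
    """Negative coupling term -[sum R_ctk log pi_ctk + log p(theta)] and gradient.

    R is (C, T, K) aggregated responsibilities, U is (K, T, P).
    """
    C = R.shape[0]
    P = U.shape[2]
    th = theta_flat.reshape(C, P)
    a = np.einsum("cp,ktp->ctk", th, U)
    lam = design.apply_link(a)
    S = lam.sum(axis=0, keepdims=True)
    Ntk = R.sum(axis=0, keepdims=True)
    obj = float(np.sum(R * (np.log(lam) - np.log(S)))) + prior.log_prior_theta(th)
    dlam = (R / lam - Ntk / S) * design.link_grad_over_link(a, lam) * lam
    grad = np.einsum("ctk,ktp->cp", dlam, U) + prior.grad_log_prior_theta(th)
    if freeze_weights:
        grad[:, 1:] = 0.0
    return -obj, -grad.ravel()


def _update_theta(theta: np.ndarray, R: np.ndarray, U: np.ndarray,
                  design: RateDesign, prior: PriorSpec,
                  freeze_weights: bool) -> np.ndarray:
    """Maximize the theta coordinate of the ELBO; never returns a worse point."""
    C, P = theta.shape
    if freeze_weights and prior.theta == "flat" and design.link == "softplus" \
            and not np.any(theta[:, 1:]):
        # behavior-free case: pi is constant over (t, k) and the optimum is
        # pi_c = R_c / N in closed form, matching the MoG-EM weight update
        Rc = np.maximum(R.sum(axis=(1, 2)), 1e-300)
        out = theta.copy()
        out[:, 0] = softplus_inv(Rc / Rc.sum())
        return out
    f0, _ = _glm_objective_grad(theta.ravel(), R, U, design, prior, freeze_weights)
    res = minimize(_glm_objective_grad, theta.ravel(), jac=True,
                   args=(R, U, design, prior, freeze_weights),
                   method="L-BFGS-B", options={"maxiter": 200, "gtol": 1e-9})
    if res.fun <= f0:
        out = res.x.reshape(C, P)
        if freeze_weights:
            out[:, 1:] = theta[:, 1:]
        return out
    return theta


def _theta_variance(theta: np.ndarray, R: np.ndarray, U: np.ndarray,
                    design: RateDesign, prior: PriorSpec,
                    freeze_weights: bool) -> np.ndarray:
    """Laplace variances: inverse diagonal curvature of the theta coordinate."""
    h = 1e-4
    flat = theta.ravel()
    _, g0 = _glm_objective_grad(flat, R, U, design, prior, freeze_weights)
    var = np.empty_like(flat)
    for j in range(flat.size):
        x = flat.copy()
        x[j] += h
        _, g1 = _glm_objective_grad(x, R, U, design, prior, freeze_weights)
        curv = (g1[j] - g0[j]) / h  # curvature of the negative objective
        var[j] = 1.0 / max(curv, 1e-6)
    return var.reshape(theta.shape)


def _prepare(spikes: SpikeTable, standardize: bool):
    if standardize:
        Xs, mu, sc = standardize_features(spikes.features)
        return SpikeTable(spikes.K, spikes.T, spikes.trials, spikes.bins, Xs), mu, sc
    D = spikes.D
    return spikes, np.zeros(D), np.ones(D)


def _unstandardize_mog(mog: MoGComponents, mu: np.ndarray, sc: np.ndarray) -> MoGComponents:
    means = mog.means * sc + mu
    covs = mog.covariances * sc[None, :, None] * sc[None, None, :]
    return MoGComponents(means, covs)


def _init_theta(C: int, P: int) -> np.ndarray:
    th = np.zeros((C, P))
    th[:, 0] = softplus_inv(1.0)  # unit rate, uniform mixing at start
    return th


def _full_elbo(logdens, pi, trials, bins, theta, prior) -> float:
    """Marginal log-likelihood of the spikes (the ELBO at the exact E step)."""
    from scipy.special import logsumexp
    ll = float(logsumexp(logdens + np.log(pi)[:, bins, trials].T, axis=1).sum())
    return ll + prior.log_prior_theta(theta)


def fit_cavi(spikes: SpikeTable, behavior: BehaviorSet, C: int,
             design: RateDesign | None = None, prior_spec: PriorSpec | None = None,
             max_iter: int = 50, tol: float = 1e-6, seed: int = 0, *,
             init: MoGComponents | None = None, init_theta: np.ndarray | None = None,
             freeze_behavior_weights: bool = False, standardize: bool = True,
             update_covariances: bool = True, cov_floor: float = COV_FLOOR,
             ) -> tuple[MoGComponents, EncoderParams, FitReport]:
    """Coordinate-ascent variational fit of the behavior-modulated mixture.

    Alternates the E step (responsibilities) with closed-form mixture updates
    and a block maximization of the rate coefficients.  Stops after
    ``max_iter`` iterations (the default of 50 is ample in practice) or when
    the ELBO improves by less than ``tol`` (relative).  Returns fitted
    components in original feature units, the variational posterior over
    theta, and a report with the ELBO trace.
    """
    design = design or RateDesign()
    prior = prior_spec or PriorSpec()
    report = FitReport()
    work, fmean, fscale = _prepare(spikes, standardize)
    report.feature_mean, report.feature_scale = fmean, fscale

    mog = init if init is not None else init_mog(work, C, seed=seed)
    theta = init_theta.copy() if init_theta is not None else _init_theta(
        C, design.n_params(spikes.T))
    U = design.design_matrix(behavior, spikes.T)

    lam = design.apply_link(np.einsum("cp,ktp->ctk", theta, U))
    pi = mixing_proportions(lam)
    logdens = log_component_densities(work, mog)
    report.elbo_trace.append(_full_elbo(logdens, pi, work.trials, work.bins,
                                        theta, prior))
    for it in range(max_iter):
        r = responsibilities(logdens, pi, work.trials, work.bins)
        mog = _mog_m_step(work.features, r, mog, cov_floor, report.events)
        if not update_covariances:
            mog = MoGComponents(mog.means, (init or mog).covariances)
        R = aggregate_responsibilities(r, work.trials, work.bins, spikes.K, spikes.T)
        theta = _update_theta(theta, R, U, design, prior, freeze_behavior_weights)

        lam = design.apply_link(np.einsum("cp,ktp->ctk", theta, U))
        pi = mixing_proportions(lam)
        logdens = log_component_densities(work, mog)
        e = _full_elbo(logdens, pi, work.trials, work.bins, theta, prior)
        report.elbo_trace.append(e)
        report.n_iter = it + 1
        prev = report.elbo_trace[-2]
        if abs(e - prev) < tol * (1.0 + abs(e)):
            report.converged = True
            break

    if max_iter > 0:
        r = responsibilities(logdens, pi, work.trials, work.bins)
        R = aggregate_responsibilities(r, work.trials, work.bins, spikes.K, spikes.T)
        var = _theta_variance(theta, R, U, design, prior, freeze_behavior_weights)
    else:
        var = np.ones_like(theta)
    params = EncoderParams(theta, np.maximum(var, 1e-12))
    return _unstandardize_mog(mog, fmean, fscale), params, report


class _Adam:
    def __init__(self, shape, lr):
        self.lr = lr
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, x, grad):
        self.t += 1
        self.m = 0.9 * self.m + 0.1 * grad
        self.v = 0.999 * self.v + 0.001 * grad ** 2
        mhat = self.m / (1 - 0.9 ** self.t)
        vhat = self.v / (1 - 0.999 ** self.t)
        return x + self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def fit_advi(spikes: SpikeTable, behavior: BehaviorSet, C: int,
             design: RateDesign | None = None, prior_spec: PriorSpec | None = None,
             iters: int = 1000, lr: float = 0.001, batch_trials: int = 6,
             seed: int = 0, *, init: MoGComponents | None = None,
             init_theta: np.ndarray | None = None, standardize: bool = True,
             cov_floor: float = COV_FLOOR, mog_refresh: int = 25,
             freeze_behavior_weights: bool = False,
             ) -> tuple[MoGComponents, EncoderParams, FitReport]:
    """Stochastic variational fit with reparameterized gradients and Adam.

    Each iteration draws a minibatch of trials, computes responsibilities for
    its spikes, samples theta from the diagonal-Gaussian q, and takes one
    Adam step on the Monte-Carlo ELBO gradient (data term rescaled by
    K / batch).  Mixture means/covariances are refreshed by a full-data M
    step every ``mog_refresh`` iterations.  Aborts with the last finite
    snapshot if the objective diverges.
    """
    design = design or RateDesign()
    prior = prior_spec or PriorSpec()
    report = FitReport()
    rng = np.random.default_rng(seed)
    work, fmean, fscale = _prepare(spikes, standardize)
    report.feature_mean, report.feature_scale = fmean, fscale
    K, T = spikes.K, spikes.T

    mog = init if init is not None else init_mog(work, C, seed=seed)
    P = design.n_params(T)
    m = init_theta.copy() if init_theta is not None else _init_theta(C, P)
    log_sigma = np.full((C, P), -3.0)
    U = design.design_matrix(behavior, T)
    opt_m, opt_s = _Adam((C, P), lr), _Adam((C, P), lr)

    # per-trial spike row lists for cheap minibatching
    order = np.argsort(work.trials, kind="stable")
    bounds = np.searchsorted(work.trials[order], np.arange(K + 1))
    trial_rows = [order[bounds[k]:bounds[k + 1]] for k in range(K)]
    logdens_all = log_component_densities(work, mog)

    def full_elbo_at_mean():
        lam = design.apply_link(np.einsum("cp,ktp->ctk", m, U))
        pi = mixing_proportions(lam)
        return _full_elbo(logdens_all, pi, work.trials, work.bins, m, prior)

    report.elbo_trace.append(full_elbo_at_mean())
    batch_trials = min(batch_trials, K)
    scale = K / batch_trials
    for it in range(iters):
        kb = rng.choice(K, size=batch_trials, replace=False)
        rows = np.concatenate([trial_rows[k] for k in kb])
        # batch E step at the variational mean
        Ub = U[kb]  # (B, T, P)
        lam_b = design.apply_link(np.einsum("cp,btp->cbt", m, Ub)).transpose(0, 2, 1)
        pi_b = mixing_proportions(lam_b)  # (C, T, B)
        remap = {k: i for i, k in enumerate(kb)}
        b_trials = np.array([remap[k] for k in work.trials[rows]], dtype=int)
        b_bins = work.bins[rows]
        r = responsibilities(logdens_all[rows], pi_b, b_trials, b_bins)
        R = aggregate_responsibilities(r, b_trials, b_bins, batch_trials, T)

        eps = rng.standard_normal((C, P))
        sigma = np.exp(log_sigma)
        th = m + sigma * eps
        neg, ngrad = _glm_objective_grad(th.ravel(), R * scale, Ub, design,
                                         PriorSpec(theta="flat"), freeze_behavior_weights)
        g_theta = -ngrad.reshape(C, P) + prior.grad_log_prior_theta(th)
        if not np.all(np.isfinite(g_theta)):
            report.events.append(f"non-finite gradient at iteration {it}; aborting")
            break
        m = opt_m.step(m, g_theta)
        log_sigma = opt_s.step(log_sigma, g_theta * sigma * eps + 1.0)
        log_sigma = np.clip(log_sigma, -10.0, 2.0)
        if freeze_behavior_weights:
            m[:, 1:] = 0.0

        if (it + 1) % mog_refresh == 0 or it == iters - 1:
            lam = design.apply_link(np.einsum("cp,ktp->ctk", m, U))
            pi = mixing_proportions(lam)
            r_all = responsibilities(logdens_all, pi, work.trials, work.bins)
            mog = _mog_m_step(work.features, r_all, mog, cov_floor, report.events)
            logdens_all = log_component_densities(work, mog)
            e = full_elbo_at_mean()
            if not np.isfinite(e):
                report.events.append(f"non-finite ELBO at iteration {it}; aborting")
                break
            report.elbo_trace.append(e)
        report.n_iter = it + 1

    report.converged = report.n_iter == iters
    params = EncoderParams(m, np.exp(2 * log_sigma))
    return _unstandardize_mog(mog, fmean, fscale), params, report
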