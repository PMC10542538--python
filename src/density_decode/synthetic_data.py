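"""Synthetic session generator: exact ancestral sampling from the model.

Generates K trials x T bins of spikes from C Gaussian components whose
mixing proportions are modulated by a generated behavior signal, together
with the full ground truth (per-spike component labels, true mixing
proportions, true rate coefficients and component parameters).  This makes
inference correctness testable by parameter recovery without any recorded
data.

Behavior generators: binary choices are Bernoulli(p) per trial; continuous
traces are zero-mean Gaussian-process draws per trial with a
squared-exponential kernel, emulating smooth signals like wheel speed.
Spike counts per bin are Poisson with mean proportional to the summed
component rates (default), so the behavior signal is also identifiable from
counts alone, or a fixed per-bin budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import BehaviorSet, MoGComponents, SpikeTable
from .model_core import RateDesign, mixing_proportions


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated session.

    ``theta`` is the (C, P) matrix of true rate coefficients (intercept and
    behavior weight per component).  If ``means``/``covariances`` are omitted
    they are placed deterministically on a circle with radius set by
    ``separation`` (in units of the unit component SD).  ``base_rate`` is the
    expected number of spikes per component per bin at rate 1; with
    ``poisson_counts=False`` every bin gets exactly ``fixed_budget`` spikes.
    """

    K: int = 40
    T: int = 30
    C: int = 2
    D: int = 2
    theta: np.ndarray | None = None
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    separation: float = 6.0
    behavior_kind: str = "binary"
    bernoulli_p: float = 0.5
    gp_lengthscale: float = 5.0
    gp_variance: float = 1.0
    base_rate: float = 10.0
    poisson_counts: bool = True
    fixed_budget: int = 20
    link: str = "softplus"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.K, self.T, self.C, self.D) <= 0:
            raise ValueError("K, T, C, D must all be positive")
        if self.theta is None:
            # alternate the sign of the behavior weight across components so
            # that behavior shifts mass between components
            w = 1.5 * np.where(np.arange(self.C) % 2 == 0, 1.0, -1.0)
            self.theta = np.column_stack([np.ones(self.C), w])
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=np.float64))
        if self.means is None:
            if self.D == 1:
                locs = np.linspace(-1.0, 1.0, self.C) if self.C > 1 else np.zeros(1)
                self.means = (self.separation / 2.0) * locs[:, None]
            else:
                # components spread along the depth axis (dim 1), the axis
                # channels are laid out on, with alternating width offsets
                z = self.separation * (np.arange(self.C) - (self.C - 1) / 2.0)
                x = (self.separation / 3.0) * np.where(
                    np.arange(self.C) % 2 == 0, 1.0, -1.0)
                self.means = np.zeros((self.C, self.D))
                self.means[:, 0] = x
                self.means[:, 1] = z
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        if self.covariances is None:
            self.covariances = np.broadcast_to(np.eye(self.D),
                                               (self.C, self.D, self.D)).copy()
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        # SPD check happens in MoGComponents at simulation time

    def mog(self) -> MoGComponents:
        return MoGComponents(self.means, self.covariances)

    def design(self) -> RateDesign:
        n_extra = self.theta.shape[1] - 2
        return RateDesign(link=self.link, n_lags=max(n_extra, 0))


@dataclass
class SyntheticSession:
    """A simulated session plus its complete ground truth."""

    spikes: SpikeTable
    behavior: BehaviorSet
    labels: np.ndarray          # per-spike true component, aligned with spikes rows
    pi_true: np.ndarray         # (C, T, K)
    theta_true: np.ndarray      # (C, P)
    mog_true: MoGComponents
    config: SimulationConfig


def _sample_behavior(cfg: SimulationConfig, rng: np.random.Generator) -> BehaviorSet:
    if cfg.behavior_kind == "binary":
        return BehaviorSet("binary", rng.binomial(1, cfg.bernoulli_p, size=cfg.K))
    t = np.arange(cfg.T)
    K_se = cfg.gp_variance * np.exp(-0.5 * ((t[:, None] - t[None, :]) / cfg.gp_lengthscale) ** 2)
    L = np.linalg.cholesky(K_se + 1e-9 * np.eye(cfg.T))
    traces = rng.standard_normal((cfg.K, cfg.T)) @ L.T
    return BehaviorSet("continuous", traces)


def simulate_session(cfg: SimulationConfig) -> SyntheticSession:
    """Draw one session by ancestral sampling; deterministic given cfg.seed.

    For each (k, t): rates lambda_ctk from the true coefficients and the
    generated behavior, proportions by normalization, a Poisson (or fixed)
    spike count, categorical component labels, then Gaussian features.
    """
    rng = np.random.default_rng(cfg.seed)
    mog = cfg.mog()
    design = cfg.design()
    behavior = _sample_behavior(cfg, rng)

    U = design.design_matrix(behavior, cfg.T)              # (K, T, P)
    if cfg.theta.shape[1] != U.shape[2]:
        raise ValueError("theta dimension does not match the rate design")
    lam = design.apply_link(np.einsum("cp,ktp->ctk", cfg.theta, U))
    pi = mixing_proportions(lam)                           # (C, T, K)

    chols = mog.cholesky()
    trials, bins, labels, feats = [], [], [], []
    for k in range(cfg.K):
        for t in range(cfg.T):
            if cfg.poisson_counts:
                n = rng.poisson(cfg.base_rate * lam[:, t, k].sum())
            else:
                n = cfg.fixed_budget
            if n == 0:
                continue
            z = rng.choice(cfg.C, size=n, p=pi[:, t, k])
            eps = rng.standard_normal((n, cfg.D))
            s = mog.means[z] + np.einsum("ndj,nj->nd", chols[z], eps)
            trials.append(np.full(n, k))
            bins.append(np.full(n, t))
            labels.append(z)
            feats.append(s)

    if trials:
        spikes = SpikeTable(cfg.K, cfg.T, np.concatenate(trials),
                            np.concatenate(bins), np.concatenate(feats))
        labels = np.concatenate(labels)
    else:
        spikes = SpikeTable(cfg.K, cfg.T, np.empty(0, int), np.empty(0, int),
                            np.empty((0, cfg.D)))
        labels = np.empty(0, dtype=int)
    return SyntheticSession(spikes, behavior, labels, pi, cfg.theta.copy(), mog, cfg)


MISSING = -1


def simulate_sorting_labels(session: SyntheticSession, contamination: float,
                            miss_rate: float, seed: int) -> np.ndarray:
    """Degrade the true labels to mimic an imperfect spike sorter.

    A ``contamination`` fraction of spikes is relabeled uniformly to a wrong
    unit; a ``miss_rate`` fraction is dropped (label = MISSING = -1).  With
    both at zero the output equals the truth.
    """
    if not (0 <= contamination < 1 and 0 <= miss_rate < 1):
        raise ValueError("contamination and miss_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    C = session.config.C
    labels = session.labels.copy()
    n = len(labels)
    if C > 1 and contamination > 0:
        flip = rng.random(n) < contamination
        offset = rng.integers(1, C, size=n)
        labels[flip] = (labels[flip] + offset[flip]) % C
    if miss_rate > 0:
        labels[rng.random(n) < miss_rate] = MISSING
    return labels
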