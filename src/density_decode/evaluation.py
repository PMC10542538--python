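"""Cross-validated evaluation of the density decoder against baselines.

Runs 5-fold cross-validation over trials: on each fold the encoder is fit
on the training trials only, weight matrices are built with observed
behavior for train trials and the thresholding-based provisional estimate
for test trials, and the final behavior decoder is fit and scored.
Baselines (multi-unit thresholding, sorted units, sorted "good" units) go
through the identical pipeline with one-hot weight matrices.

Continuous behaviors are scored by the coefficient of determination R^2,
pooled over bins and trials within each fold; binary behaviors by accuracy.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .data_model import BehaviorSet, SpikeTable
from .decoding import (depth_channel_groups, estimate_behavior_threshold,
                       fit_behavior_decoder, one_hot_weight_matrix,
                       predict_behavior, soft_weight_matrix)
from .encoder_vi import fit_advi, fit_cavi
from .model_core import PriorSpec, RateDesign
from .synthetic_data import MISSING, SyntheticSession, simulate_sorting_labels

METHODS = ("density", "thresholded", "sorted_all", "sorted_good")


def kfold_split(K: int, folds: int, seed: int) -> np.ndarray:
    """Seeded near-equal disjoint partition; returns the fold id of each trial."""
    if folds > K:
        raise ValueError(f"cannot split {K} trials into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(K)
    out = np.empty(K, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        out[chunk] = f
    return out


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot, pooled over all entries; NaN if y_true is constant."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        return float("nan")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch between y_true and y_pred")
    return float(np.mean(y_true == y_pred))


@dataclass
class CVResult:
    metric: str
    per_fold: list[float]
    fold_assignment: np.ndarray
    predictions: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_fold))

    @property
    def std(self) -> float:
        return float(np.std(self.per_fold))


@dataclass
class ExperimentConfig:
    """Everything one cross-validated comparison needs.

    ``session`` supplies spikes + behavior (+ truth when simulated);
    ``sorted_labels`` feeds the sorted baselines (defaults to degraded truth
    labels when the session is synthetic), and ``good_units`` restricts the
    "good"-unit baseline.
    """

    C: int = 2
    n_channels: int = 8
    folds: int = 5
    seed: int = 0
    encoder: str = "auto"  # cavi for binary, advi for continuous
    methods: tuple[str, ...] = METHODS
    design: RateDesign = field(default_factory=RateDesign)
    prior: PriorSpec = field(default_factory=PriorSpec)
    cavi_max_iter: int = 50
    advi_iters: int = 1000
    advi_lr: float = 0.001
    advi_batch_trials: int = 6
    sorting_contamination: float = 0.1
    sorting_miss_rate: float = 0.1
    good_unit_fraction: float = 0.5


def _score(y_true: BehaviorSet, y_pred: np.ndarray) -> float:
    if y_true.kind == "binary":
        return accuracy(y_true.values, y_pred)
    return r2_score(y_true.values, y_pred)


def run_experiment(session, config: ExperimentConfig,
                   sorted_labels: np.ndarray | None = None,
                   good_units: np.ndarray | None = None) -> dict[str, CVResult]:
    """Cross-validated decoding comparison on one session.

    ``session`` is a SyntheticSession or any object with ``spikes`` and
    ``behavior`` attributes.  Returns one CVResult per requested method.
    Test-trial behavior is used exclusively for scoring.
    """
    spikes: SpikeTable = session.spikes
    behavior: BehaviorSet = session.behavior
    K, T = spikes.K, spikes.T
    if behavior.K != K:
        raise ValueError(f"behavior has {behavior.K} trials, spikes declare {K}")

    if sorted_labels is None and isinstance(session, SyntheticSession):
        need_sorted = any(m.startswith("sorted") for m in config.methods)
        if need_sorted:
            sorted_labels = simulate_sorting_labels(
                session, config.sorting_contamination, config.sorting_miss_rate,
                seed=config.seed + 10_000)
    n_units = None
    if sorted_labels is not None:
        n_units = int(sorted_labels.max()) + 1 if np.any(sorted_labels >= 0) else 1
        if good_units is None:
            rng = np.random.default_rng(config.seed + 20_000)
            n_good = max(1, int(round(config.good_unit_fraction * n_units)))
            good_units = np.sort(rng.choice(n_units, size=n_good, replace=False))

    channel_groups = depth_channel_groups(spikes, config.n_channels)
    fold_of = kfold_split(K, config.folds, config.seed)
    results = {m: CVResult(metric="accuracy" if behavior.kind == "binary" else "r2",
                           per_fold=[], fold_assignment=fold_of)
               for m in config.methods}

    for f in range(config.folds):
        train_ids = np.flatnonzero(fold_of != f)
        test_ids = np.flatnonzero(fold_of == f)
        sp_tr, rows_tr = spikes.restrict_trials(train_ids)
        sp_te, rows_te = spikes.restrict_trials(test_ids)
        y_tr = behavior.subset(train_ids)
        y_te = behavior.subset(test_ids)

        fitted = None
        yhat_te = None
        for method in config.methods:
            if method == "density":
                if fitted is None:
                    fitted = _fit_encoder(sp_tr, y_tr, config)
                mog, theta, _ = fitted
                W_tr = soft_weight_matrix(sp_tr, mog, theta, y_tr, config.design)
                if yhat_te is None:
                    yhat_te = estimate_behavior_threshold(
                        sp_te, sp_tr, y_tr, config.n_channels, seed=config.seed)
                W_te = soft_weight_matrix(sp_te, mog, theta, yhat_te, config.design)
            elif method == "thresholded":
                W_tr = one_hot_weight_matrix(sp_tr, channel_groups[rows_tr],
                                             sp_tr.K, config.n_channels, T)
                W_te = one_hot_weight_matrix(sp_te, channel_groups[rows_te],
                                             sp_te.K, config.n_channels, T)
            elif method in ("sorted_all", "sorted_good"):
                if sorted_labels is None:
                    raise ValueError(f"method {method!r} requires sorted unit labels")
                lab = sorted_labels.copy()
                if method == "sorted_good":
                    lab[~np.isin(lab, good_units)] = MISSING
                W_tr = one_hot_weight_matrix(sp_tr, lab[rows_tr], sp_tr.K, n_units, T)
                W_te = one_hot_weight_matrix(sp_te, lab[rows_te], sp_te.K, n_units, T)
            else:
                raise ValueError(f"unknown method {method!r}")

            dec = fit_behavior_decoder(W_tr, y_tr, seed=config.seed)
            pred = predict_behavior(dec, W_te)
            results[method].per_fold.append(_score(y_te, pred))
            results[method].predictions[f] = pred
    return results


def _fit_encoder(sp_tr: SpikeTable, y_tr: BehaviorSet, config: ExperimentConfig):
    enc = config.encoder
    if enc == "auto":
        enc = "cavi" if y_tr.kind == "binary" else "advi"
    if enc == "cavi":
        return fit_cavi(sp_tr, y_tr, config.C, config.design, config.prior,
                        max_iter=config.cavi_max_iter, seed=config.seed)
    return fit_advi(sp_tr, y_tr, config.C, config.design, config.prior,
                    iters=config.advi_iters, lr=config.advi_lr,
                    batch_trials=config.advi_batch_trials, seed=config.seed)


def provenance(config: ExperimentConfig, session_seed: int | None = None) -> dict:
    """JSON-serializable run fingerprint: config fields plus a content hash."""
    d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
         for k, v in vars(config).items()
         if isinstance(v, (int, float, str, tuple, list, np.ndarray))}
    if session_seed is not None:
        d["session_seed"] = session_seed
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    d["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
    return d
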