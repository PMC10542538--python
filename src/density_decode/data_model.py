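"""Domain containers and columnar I/O for spike-feature sessions.

A session is ``K`` trials, each divided into ``T`` equal time bins.  Every
detected spike carries a trial index, a bin index, and a ``D``-dimensional
feature vector — by default the spike's localized position along the probe
width (x, µm) and depth (z, µm) plus its maximum peak-to-peak amplitude in
standard units.  Behavior is either one binary value per trial (e.g. a
left/right choice) or a length-``T`` continuous trace per trial (e.g. wheel
speed).

All containers validate their invariants on construction; readers and
writers use plain CSV (with a header) or an HDF5 layout for large sessions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A container invariant does not hold for the declared (K, T) bounds."""


@dataclass
class SpikeTable:
    """Per-spike features with (trial, bin) indices.

    Parameters
    ----------
    K, T : int
        Number of trials and of time bins per trial.
    trials, bins : int arrays of shape (N,)
        Trial and bin index of each spike, 0-based.
    features : float array of shape (N, D)
        One feature vector per spike.
    """

    K: int
    T: int
    trials: np.ndarray
    bins: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=np.int64).ravel()
        self.bins = np.asarray(self.bins, dtype=np.int64).ravel()
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))
        if self.features.shape[0] == 0:
            self.features = self.features.reshape(0, max(self.features.shape[1], 1))
        self.validate()

    def validate(self) -> None:
        if self.K <= 0 or self.T <= 0:
            raise ValidationError(f"K and T must be positive, got K={self.K}, T={self.T}")
        n = len(self.trials)
        if len(self.bins) != n or self.features.shape[0] != n:
            raise ValidationError(
                f"inconsistent row counts: {n} trials, {len(self.bins)} bins, "
                f"{self.features.shape[0]} feature rows"
            )
        bad = np.flatnonzero((self.trials < 0) | (self.trials >= self.K))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: trial index {self.trials[bad[0]]} outside [0, {self.K})"
            )
        bad = np.flatnonzero((self.bins < 0) | (self.bins >= self.T))
        if bad.size:
            raise ValidationError(
                f"row {bad[0]}: bin index {self.bins[bad[0]]} outside [0, {self.T})"
            )
        if not np.all(np.isfinite(self.features)):
            row = int(np.flatnonzero(~np.isfinite(self.features).all(axis=1))[0])
            raise ValidationError(f"row {row}: non-finite feature value")

    @property
    def n_spikes(self) -> int:
        return len(self.trials)

    @property
    def D(self) -> int:
        return self.features.shape[1]

    def counts(self) -> np.ndarray:
        """Spike counts n_tk as a (K, T) integer array."""
        out = np.zeros((self.K, self.T), dtype=np.int64)
        np.add.at(out, (self.trials, self.bins), 1)
        return out

    def sorted_copy(self) -> "SpikeTable":
        """Rows ordered by (trial, bin, insertion) — the canonical file order."""
        order = np.lexsort((np.arange(self.n_spikes), self.bins, self.trials))
        return SpikeTable(self.K, self.T, self.trials[order], self.bins[order],
                          self.features[order])

    def subset(self, mask: np.ndarray) -> "SpikeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            mask = np.flatnonzero(mask)
        return SpikeTable(self.K, self.T, self.trials[mask], self.bins[mask],
                          self.features[mask])

    def restrict_trials(self, trial_ids: np.ndarray) -> tuple["SpikeTable", np.ndarray]:
        """Keep spikes from ``trial_ids`` and renumber trials 0..len-1.

        Returns the restricted table and the row indices kept (for carrying
        along per-spike side information such as unit labels).
        """
        trial_ids = np.asarray(trial_ids, dtype=np.int64)
        remap = -np.ones(self.K, dtype=np.int64)
        remap[trial_ids] = np.arange(len(trial_ids))
        keep = np.flatnonzero(remap[self.trials] >= 0)
        return (
            SpikeTable(len(trial_ids), self.T, remap[self.trials[keep]],
                       self.bins[keep], self.features[keep]),
            keep,
        )


@dataclass
class BehaviorSet:
    """Per-trial behavior: binary scalar or length-T continuous trace.

    ``values`` has shape (K,) with entries in {0, 1} for ``kind='binary'``,
    or shape (K, T) for ``kind='continuous'``.
    """

    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous"):
            raise ValidationError(f"unknown behavior kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def K(self) -> int:
        return self.values.shape[0]

    def per_bin(self, T: int) -> np.ndarray:
        """Behavior as a (K, T) array; binary trial values broadcast over bins."""
        if self.kind == "binary":
            return np.repeat(self.values[:, None], T, axis=1)
        return self.values

    def subset(self, trial_ids: np.ndarray) -> "BehaviorSet":
        return BehaviorSet(self.kind, self.values[np.asarray(trial_ids)])


def validate_behavior(b: BehaviorSet, K: int, T: int) -> None:
    """Raise ValidationError unless ``b`` is a valid behavior for (K, T)."""
    if b.values.shape[0] != K:
        raise ValidationError(f"expected {K} trials of behavior, got {b.values.shape[0]}")
    if not np.all(np.isfinite(b.values)):
        raise ValidationError("behavior contains non-finite values")
    if b.kind == "binary":
        if b.values.ndim != 1:
            raise ValidationError(f"binary behavior must be 1-D, got shape {b.values.shape}")
        if not np.all(np.isin(b.values, (0.0, 1.0))):
            bad = b.values[~np.isin(b.values, (0.0, 1.0))][0]
            raise ValidationError(f"binary behavior value {bad} is not 0 or 1")
    else:
        if b.values.ndim != 2 or b.values.shape[1] != T:
            raise ValidationError(
                f"continuous behavior must have shape ({K}, {T}), got {b.values.shape}"
            )


@dataclass
class MoGComponents:
    """Gaussian component parameters η_c = (μ_c, Σ_c), c = 1..C."""

    means: np.ndarray        # (C, D)
    covariances: np.ndarray  # (C, D, D)

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        if self.covariances.shape != (self.C, self.D, self.D):
            raise ValidationError(
                f"covariances shape {self.covariances.shape} does not match "
                f"C={self.C}, D={self.D}"
            )
        self.cholesky()  # SPD check

    @property
    def C(self) -> int:
        return self.means.shape[0]

    @property
    def D(self) -> int:
        return self.means.shape[1]

    def cholesky(self) -> np.ndarray:
        chols = np.empty_like(self.covariances)
        for c in range(self.C):
            sym_err = np.abs(self.covariances[c] - self.covariances[c].T).max()
            if sym_err > 1e-8:
                raise ValidationError(f"covariance of component {c} is not symmetric")
            try:
                chols[c] = np.linalg.cholesky(self.covariances[c])
            except np.linalg.LinAlgError as e:
                raise ValidationError(
                    f"covariance of component {c} is not positive-definite"
                ) from e
        return chols


@dataclass
class EncoderParams:
    """Variational posterior over per-component rate coefficients θ_c.

    ``mean`` and ``var`` are (C, P): posterior mean and (diagonal) variance of
    each coefficient; column 0 is the intercept, remaining columns multiply
    the rate-design covariates.
    """

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        self.var = np.atleast_2d(np.asarray(self.var, dtype=np.float64))
        if self.mean.shape != self.var.shape:
            raise ValidationError(
                f"coefficient mean shape {self.mean.shape} != var shape {self.var.shape}"
            )
        if np.any(self.var <= 0):
            raise ValidationError("posterior variances must be strictly positive")

    @property
    def C(self) -> int:
        return self.mean.shape[0]

    @property
    def P(self) -> int:
        return self.mean.shape[1]


@dataclass
class WeightMatrix:
    """K × C × T tensor of per-(trial, component, bin) spike-count mass.

    Soft weights sum the posterior assignment probabilities of each spike over
    components; one-hot weights are integer spike counts per sorted unit or
    thresholded channel.
    """

    values: np.ndarray
    one_hot: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"weight matrix must be 3-D, got shape {self.values.shape}")
        if np.any(self.values < 0):
            raise ValidationError("weight matrix entries must be nonnegative")
        if self.one_hot and np.abs(self.values - np.round(self.values)).max() > 0:
            raise ValidationError("one-hot weight matrix entries must be integers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def flatten_trials(self) -> np.ndarray:
        """Per-trial feature rows for the behavior decoder, shape (K, C*T)."""
        K = self.values.shape[0]
        return self.values.reshape(K, -1)


# ---------------------------------------------------------------------------
# columnar I/O
# ---------------------------------------------------------------------------

def write_spike_table(table: SpikeTable, path: str | os.PathLike) -> None:
    """Write a SpikeTable to CSV (``.h5``/``.hdf5`` suffix selects HDF5).

    Row order is deterministic: (trial, bin, insertion order).
    """
    t = table.sorted_copy()
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "w") as f:
            g = f.create_group("spikes")
            g.create_dataset("index", data=np.stack([t.trials, t.bins], axis=1))
            g.create_dataset("features", data=t.features)
            f.attrs["K"], f.attrs["T"], f.attrs["D"] = table.K, table.T, table.D
        return
    cols = {"trial": t.trials, "bin": t.bins}
    for d in range(t.D):
        cols[f"f{d}"] = t.features[:, d]
    # %.17g guarantees bit-exact float round-trips through text
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_spike_table(path: str | os.PathLike, K: int, T: int) -> SpikeTable:
    """Read a SpikeTable written by :func:`write_spike_table`.

    Rows may arrive unordered; the returned table is index-normalized
    (canonical row order). Validation errors name the offending row.
    """
    path = os.fspath(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            idx = f["spikes/index"][...]
            feats = f["spikes/features"][...]
        return SpikeTable(K, T, idx[:, 0], idx[:, 1], feats).sorted_copy()
    df = pd.read_csv(path, float_precision="round_trip")
    feat_cols = [c for c in df.columns if c.startswith("f")]
    feats = df[feat_cols].to_numpy(dtype=np.float64)
    if len(df) == 0:
        feats = feats.reshape(0, max(len(feat_cols), 1))
    return SpikeTable(K, T, df["trial"].to_numpy(), df["bin"].to_numpy(),
                      feats).sorted_copy()


def write_behavior(b: BehaviorSet, path: str | os.PathLike) -> None:
    path = os.fspath(path)
    if b.kind == "binary":
        pd.DataFrame({"trial": np.arange(b.K), "value": b.values.astype(int)}).to_csv(
            path, index=False)
    else:
        K, T = b.values.shape
        trial = np.repeat(np.arange(K), T)
        tbin = np.tile(np.arange(T), K)
        pd.DataFrame({"trial": trial, "bin": tbin,
                      "value": b.values.ravel()}).to_csv(path, index=False,
                                                         float_format="%.17g")


def read_behavior(path: str | os.PathLike, kind: str, K: int, T: int) -> BehaviorSet:
    df = pd.read_csv(path)
    if kind == "binary":
        vals = np.zeros(K)
        vals[df["trial"].to_numpy()] = df["value"].to_numpy()
    else:
        vals = np.zeros((K, T))
        vals[df["trial"].to_numpy(), df["bin"].to_numpy()] = df["value"].to_numpy()
    b = BehaviorSet(kind, vals)
    validate_behavior(b, K, T)
    return b
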