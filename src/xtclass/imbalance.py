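"""Class-imbalance resamplers, implemented from their definitions.

Random oversampling, SMOTE, Edited Nearest Neighbours cleaning, and
the combined SMOTE+ENN the pipeline uses by default.  Distances are
Euclidean on internally z-scored features (heterogeneous descriptor
scales would otherwise dominate); outputs are returned on the original
scale and surviving original rows are never modified.  All neighbour
ties break by sample index, so runs are reproducible bit for bit.

Resampling belongs on training data only — the learn module applies it
inside training folds/splits, never to evaluation rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import XtclassError

METHODS = ("random", "smote", "smote_enn")


@dataclass(frozen=True)
class ResampleConfig:
    """Resampling parameters.

    method        one of random / smote / smote_enn
    k_smote       neighbours used to synthesize minority samples
    k_enn         neighbours used by the ENN cleaning rule
    seed          RNG seed (all randomness flows from it)
    target_ratio  minority/majority ratio after oversampling
    """

    method: str = "smote_enn"
    k_smote: int = 5
    k_enn: int = 3
    seed: int = 0
    target_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise XtclassError(f"unknown resampling method {self.method!r}")
        if self.k_smote < 1 or self.k_enn < 1:
            raise XtclassError("neighbour counts must be >= 1")
        if not (0 < self.target_ratio <= 1):
            raise XtclassError("target_ratio must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k_smote": self.k_smote,
            "k_enn": self.k_enn,
            "seed": self.seed,
            "target_ratio": self.target_ratio,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ResampleConfig":
        return cls(**doc)


def _as_arrays(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise XtclassError("X must be 2-D with one label per row")
    return X, y


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _minority_label(y: np.ndarray) -> int:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise XtclassError("resampling expects exactly two classes")
    return int(classes[np.argmin(counts)])


def _knn_indices(Z: np.ndarray, query: np.ndarray, k: int,
                 exclude_self: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest rows of Z to each query row.

    Ties in distance break by row index (stable sort).  *exclude_self*
    gives, per query, a row index to drop (or -1).
    """
    d2 = ((query[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    if exclude_self is not None:
        for qi, si in enumerate(exclude_self):
            if si >= 0:
                d2[qi, si] = np.inf
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def random_oversample(X, y, cfg: ResampleConfig):
    """Duplicate random minority rows until the target ratio is met."""
    X, y = _as_arrays(X, y)
    minority = _minority_label(y)
    min_idx = np.flatnonzero(y == minority)
    n_min, n_maj = min_idx.size, y.size - min_idx.size
    n_new = max(0, int(round(cfg.target_ratio * n_maj)) - n_min)
    rng = np.random.default_rng(cfg.seed)
    pick = rng.choice(min_idx, size=n_new, replace=True)
    return np.vstack([X, X[pick]]), np.concatenate([y, y[pick]])


def smote(X, y, cfg: ResampleConfig):
    """SMOTE: interpolate synthetic minority rows between neighbours.

    Each synthetic row is x + u·(x_nn − x) with u ~ Uniform(0, 1) and
    x_nn one of the k_smote nearest minority neighbours of x.
    """
    X, y = _as_arrays(X, y)
    minority = _minority_label(y)
    min_idx = np.flatnonzero(y == minority)
    n_min, n_maj = min_idx.size, y.size - min_idx.size
    if n_min < 2:
        raise XtclassError("SMOTE needs at least 2 minority samples")
    if cfg.k_smote >= n_min:
        raise XtclassError(
            f"k_smote={cfg.k_smote} must be < minority count {n_min}"
        )
    n_new = max(0, int(round(cfg.target_ratio * n_maj)) - n_min)
    if n_new == 0:
        return X.copy(), y.copy()
    Zmin = _zscore(X)[min_idx]
    nn = _knn_indices(Zmin, Zmin, cfg.k_smote,
                      exclude_self=np.arange(n_min))
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, cfg.k_smote, size=n_new)
    u = rng.random(n_new)
    a = X[min_idx[base]]
    b = X[min_idx[nn[base, pick]]]
    synthetic = a + u[:, None] * (b - a)
    return (
        np.vstack([X, synthetic]),
        np.concatenate([y, np.full(n_new, minority)]),
    )


def enn_clean(X, y, cfg: ResampleConfig):
    """Edited Nearest Neighbours cleaning.

    A sample is removed when strictly more than half of its k_enn
    nearest neighbours (self excluded) carry a different label; all
    removals are decided on the original neighbourhood structure and
    applied in one pass.  Returns (X', y', kept_indices).
    """
    X, y = _as_arrays(X, y)
    n = y.size
    if n < cfg.k_enn + 1:
        raise XtclassError(
            f"ENN needs more than k_enn={cfg.k_enn} samples, got {n}"
        )
    Z = _zscore(X)
    nn = _knn_indices(Z, Z, cfg.k_enn, exclude_self=np.arange(n))
    disagree = (y[nn] != y[:, None]).sum(axis=1)
    keep = disagree <= cfg.k_enn / 2
    return X[keep], y[keep], np.flatnonzero(keep)


def resample(X, y, cfg: ResampleConfig, logger=None):
    """Dispatch on cfg.method; smote_enn = SMOTE followed by ENN."""
    X, y = _as_arrays(X, y)
    before = np.bincount(y, minlength=2)
    if cfg.method == "random":
        Xr, yr = random_oversample(X, y, cfg)
    elif cfg.method == "smote":
        Xr, yr = smote(X, y, cfg)
    else:
        Xr, yr = smote(X, y, cfg)
        Xr, yr, _ = enn_clean(Xr, yr, cfg)
        if np.unique(yr).size < 2:
            # ENN wiped a class; fall back to the SMOTE output
            Xr, yr = smote(X, y, cfg)
    after = np.bincount(yr, minlength=2)
    if logger is not None:
        logger.info(
            "resample(%s): class counts %s -> %s",
            cfg.method, before.tolist(), after.tolist(),
        )
    return Xr, yr
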