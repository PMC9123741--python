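"""Model training, feature selection, evaluation and prediction.

The learner itself is a contract (fit / probability prediction /
per-feature importance) with a gradient-boosted tree backend (XGBoost);
the substance of this module is the pipeline around it:

* stratified 70/30 splitting,
* recursive feature elimination with cross-validation (RFECV) where
  resampling is confined to each fold's training part and the model
  size is chosen by the one-standard-error rule,
* an imbalance-aware metric suite computed from first principles
  (ROC AUC via the Mann-Whitney rank statistic, average precision as
  the step-wise PR integral),
* decision-threshold recalibration: the default 0.5 cut ("Model 1")
  can be replaced by a strict precision-oriented cut, 0.98 by default
  ("Model 2"), classifying only near-certain candidates as positive.

The statsmodels-style surface is :class:`XyloseTransportModel` (built
from a feature matrix and labels) whose ``fit()`` returns a
:class:`XyloseTransportResults` carrying the trained bundle, the
selection curve, importances, and evaluation/prediction methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .imbalance import ResampleConfig, resample
from .seqio import XtclassError

FORMAT_VERSION = 1

DEFAULT_THRESHOLD = 0.5
STRICT_THRESHOLD = 0.98
NEAR_MISS_MARGIN = 0.05
IMPORTANCE_REPORT_ROWS = 13


# ---------------------------------------------------------------------------
# splitting


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise XtclassError("train_fraction must lie strictly in (0, 1)")


def split(X: pd.DataFrame, y: pd.Series, cfg: SplitConfig):
    """Seeded (stratified) partition into train and test."""
    y = pd.Series(np.asarray(y, dtype=int), index=X.index)
    if cfg.stratified and y.value_counts().min() < 2:
        raise XtclassError(
            "stratified split needs at least 2 samples per class"
        )
    idx_train, idx_test = train_test_split(
        np.arange(len(X)),
        train_size=cfg.train_fraction,
        stratify=y.to_numpy() if cfg.stratified else None,
        random_state=cfg.seed,
    )
    idx_train.sort()
    idx_test.sort()
    return (
        X.iloc[idx_train], y.iloc[idx_train],
        X.iloc[idx_test], y.iloc[idx_test],
    )


# ---------------------------------------------------------------------------
# learner contract


class GradientBoostingLearner:
    """Gradient-boosted decision-tree backend satisfying the contract:
    ``fit``, ``predict_proba`` (positive-class probability) and
    ``importances`` (non-negative per-feature scores)."""

    # tree_method="exact" places split thresholds at midpoints between
    # adjacent training values, so wide empty margins (e.g. the gap the
    # profile-HMM score opens between classes) are split through the
    # middle rather than at a histogram edge hugging one class — that
    # matters for generalization to held-out sequences with weaker
    # motif matches.  Matrices here are small, so exact search is cheap.
    DEFAULTS = dict(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.2,
        tree_method="exact",
        n_jobs=1,
        eval_metric="logloss",
        verbosity=0,
    )

    def __init__(self, seed: int = 0, **params):
        self.seed = seed
        self.params = {**self.DEFAULTS, **params}
        self._clf = None

    def clone(self) -> "GradientBoostingLearner":
        return GradientBoostingLearner(seed=self.seed, **self.params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostingLearner":
        import xgboost as xgb

        if np.unique(y).size < 2:
            raise XtclassError("training data contains a single class")
        self._clf = xgb.XGBClassifier(random_state=self.seed, **self.params)
        self._clf.fit(np.asarray(X, dtype=np.float32), np.asarray(y))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise XtclassError("learner is not fitted")
        return self._clf.predict_proba(np.asarray(X, dtype=np.float32))[:, 1]

    def importances(self) -> np.ndarray:
        if self._clf is None:
            raise XtclassError("learner is not fitted")
        return np.asarray(self._clf.feature_importances_, dtype=float)

    # --- serialization -----------------------------------------------------

    def save_raw(self) -> str:
        return self._clf.get_booster().save_raw("json").decode()

    @classmethod
    def load_raw(cls, raw: str, seed: int, params: dict) -> "GradientBoostingLearner":
        import xgboost as xgb

        self = cls(seed=seed, **params)
        clf = xgb.XGBClassifier(random_state=seed, **self.params)
        clf.load_model(bytearray(raw.encode()))
        self._clf = clf
        return self


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Confusion counts, point metrics and curve points for one model."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    roc_auc: float | None
    average_precision: float | None
    threshold: float
    precision_defined: bool = True
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_points: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "tn": self.tn, "fn": self.fn},
            "precision": self.precision,
            "precision_defined": self.precision_defined,
            "recall": self.recall,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "roc_auc": self.roc_auc,
            "average_precision": self.average_precision,
            "threshold": self.threshold,
        }


def roc_auc(y: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC AUC via the Mann-Whitney rank statistic with tie mid-ranks."""
    y = np.asarray(y, dtype=int)
    npos = int(y.sum())
    nneg = y.size - npos
    if npos == 0 or nneg == 0:
        return None
    ranks = rankdata(scores)
    return float(
        (ranks[y == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    )


def average_precision(y: np.ndarray, scores: np.ndarray) -> float | None:
    """Step-wise precision-recall integral AP = Σ (R_i − R_{i−1}) · P_i."""
    y = np.asarray(y, dtype=int)
    npos = int(y.sum())
    if npos == 0:
        return None
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    ys = y[order]
    ss = np.asarray(scores, dtype=float)[order]
    tp = np.cumsum(ys)
    pred = np.arange(1, y.size + 1)
    # evaluate only at the last index of each tied-score group
    last = np.flatnonzero(np.diff(ss, append=-np.inf) != 0)
    prec = tp[last] / pred[last]
    rec = tp[last] / npos
    prev = np.concatenate([[0.0], rec[:-1]])
    return float(np.sum((rec - prev) * prec))


def roc_curve_points(y, scores) -> list[tuple[float, float]]:
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    npos, nneg = int(y.sum()), int((1 - y).sum())
    pts = [(0.0, 0.0)]
    order = np.argsort(-scores, kind="stable")
    ys, ss = y[order], scores[order]
    tp = fp = 0
    for i in range(y.size):
        tp += ys[i]
        fp += 1 - ys[i]
        if i + 1 == y.size or ss[i + 1] != ss[i]:
            pts.append(
                (fp / nneg if nneg else 0.0, tp / npos if npos else 0.0)
            )
    return pts


def pr_curve_points(y, scores) -> list[tuple[float, float]]:
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    npos = int(y.sum())
    order = np.argsort(-scores, kind="stable")
    ys, ss = y[order], scores[order]
    pts = []
    tp = 0
    for i in range(y.size):
        tp += ys[i]
        if i + 1 == y.size or ss[i + 1] != ss[i]:
            pts.append((tp / npos if npos else 0.0, tp / (i + 1)))
    return pts


def evaluate_scores(
    y, scores, threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """Full metric suite for probability scores at a decision threshold."""
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise XtclassError("cannot evaluate on an empty set")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    tnr = tn / (tn + fp) if (tn + fp) else 0.0
    accuracy = (tp + tn) / y.size
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, accuracy=accuracy,
        balanced_accuracy=(recall + tnr) / 2 if (tp + fn) and (tn + fp)
        else accuracy,
        mcc=float(mcc),
        roc_auc=roc_auc(y, scores),
        average_precision=average_precision(y, scores),
        threshold=threshold,
        precision_defined=precision_defined,
        roc_points=roc_curve_points(y, scores),
        pr_points=pr_curve_points(y, scores),
    )


# ---------------------------------------------------------------------------
# RFECV


@dataclass
class RfecvResult:
    selected_features: list[str]
    n_selected: int
    curve: pd.DataFrame          # columns: n_features, mean_score, se
    ranking: dict[str, int]      # 1 = kept longest


def _elimination_schedule(n: int, step, min_features: int = 1) -> list[int]:
    """Feature counts visited by the elimination, descending to the floor."""
    floor = min(min_features, n)
    counts = [n]
    while counts[-1] > floor:
        cur = counts[-1]
        drop = (
            max(1, int(np.floor(step * cur))) if 0 < step < 1
            else max(1, int(step))
        )
        counts.append(max(floor, cur - drop))
    return counts


def _eliminate(
    Xtr: np.ndarray, ytr: np.ndarray, learner, step,
    min_features: int = 1, score_fn=None,
) -> tuple[list[np.ndarray], list[float]]:
    """Run recursive elimination; return visited index sets and scores."""
    floor = min(min_features, Xtr.shape[1])
    current = np.arange(Xtr.shape[1])
    sets, scores = [], []
    while True:
        fitted = learner.clone().fit(Xtr[:, current], ytr)
        sets.append(current.copy())
        if score_fn is not None:
            scores.append(score_fn(fitted, current))
        if current.size <= floor:
            break
        imp = fitted.importances()
        drop = (
            max(1, int(np.floor(step * current.size))) if 0 < step < 1
            else max(1, int(step))
        )
        drop = min(drop, current.size - floor)
        # lowest-importance features go; ties break by column index
        order = np.argsort(imp, kind="stable")
        current = np.delete(current, np.sort(order[:drop]))
    return sets, scores


_METRICS = {
    "average_precision": average_precision,
    "roc_auc": roc_auc,
}


def rfecv(
    X: pd.DataFrame,
    y,
    learner: GradientBoostingLearner | None = None,
    step=1,
    folds: int = 5,
    metric: str = "average_precision",
    resample_cfg: ResampleConfig | None = None,
    min_features: int = 1,
    seed: int = 0,
) -> RfecvResult:
    """Recursive feature elimination with cross-validated model sizing.

    Within each stratified fold the training part is resampled, the
    learner is fitted and features are eliminated stepwise, recording
    the validation metric at each feature count.  The final size is the
    smallest count whose mean cross-fold score is within one standard
    error of the maximum; a last elimination pass on the full training
    split names the selected set.
    """
    if folds < 2:
        raise XtclassError("rfecv needs at least 2 folds")
    if metric not in _METRICS:
        raise XtclassError(f"unknown rfecv metric {metric!r}")
    metric_fn = _METRICS[metric]
    y = np.asarray(y, dtype=int)
    learner = learner if learner is not None else GradientBoostingLearner(seed)
    Xv = X.to_numpy(dtype=float)
    counts = _elimination_schedule(X.shape[1], step, min_features)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = np.empty((folds, len(counts)))
    for fi, (tr, va) in enumerate(skf.split(Xv, y)):
        Xtr, ytr = Xv[tr], y[tr]
        if resample_cfg is not None:
            Xtr, ytr = resample(Xtr, ytr, resample_cfg)
        Xva, yva = Xv[va], y[va]
        if np.unique(yva).size < 2:
            raise XtclassError(
                f"fold {fi} validation part is single-class; "
                "reduce folds or rebalance"
            )

        def _score(fitted, idx):
            val = metric_fn(yva, fitted.predict_proba(Xva[:, idx]))
            if val is None:
                raise XtclassError("metric undefined on a validation fold")
            return val

        _, scores = _eliminate(
            Xtr, ytr, learner, step, min_features, score_fn=_score
        )
        fold_scores[fi] = scores
    means = fold_scores.mean(axis=0)
    ses = fold_scores.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmax(means))
    cutoff = means[best] - ses[best]
    eligible = [
        i for i in range(len(counts)) if means[i] >= cutoff
    ]
    chosen_i = max(eligible, key=lambda i: (-counts[i], i))
    n_selected = counts[chosen_i]

    Xtr, ytr = Xv, y
    if resample_cfg is not None:
        Xtr, ytr = resample(Xtr, ytr, resample_cfg)
    sets, _ = _eliminate(Xtr, ytr, learner, step, min_features)
    final = next(s for s, c in zip(sets, counts) if c == n_selected)
    # rank 1 = survived every elimination round on the full split
    ranking = {}
    for name_i, name in enumerate(X.columns):
        survived = sum(name_i in s for s in sets)
        ranking[name] = len(sets) - survived + 1
    curve = pd.DataFrame(
        {"n_features": counts, "mean_score": means, "se": ses}
    )
    return RfecvResult(
        selected_features=[X.columns[i] for i in final],
        n_selected=n_selected,
        curve=curve,
        ranking=ranking,
    )


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """A trained classifier plus everything needed to reuse it."""

    learner: GradientBoostingLearner
    selected_features: list[str]
    threshold: float = DEFAULT_THRESHOLD
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise XtclassError("threshold must lie strictly in (0, 1)")

    def probabilities(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise XtclassError(
                f"candidate matrix lacks selected feature(s): {missing[:5]}"
            )
        return self.learner.predict_proba(
            X[self.selected_features].to_numpy(dtype=float)
        )


def config_hash(doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(doc, sort_keys=True).encode()
    ).hexdigest()[:16]


def fit(
    X: pd.DataFrame,
    y,
    selected_features: list[str] | None = None,
    learner: GradientBoostingLearner | None = None,
    resample_cfg: ResampleConfig | None = None,
    seed: int = 0,
    metadata: dict | None = None,
) -> ModelBundle:
    """Resample the training split, fit the learner, record importances."""
    y = np.asarray(y, dtype=int)
    selected = (
        list(selected_features) if selected_features is not None
        else list(X.columns)
    )
    missing = [f for f in selected if f not in X.columns]
    if missing:
        raise XtclassError(f"selected features not in matrix: {missing[:5]}")
    learner = learner if learner is not None else GradientBoostingLearner(seed)
    Xs = X[selected].to_numpy(dtype=float)
    if resample_cfg is not None:
        Xs, y = resample(Xs, y, resample_cfg)
    if np.unique(y).size < 2:
        raise XtclassError("single-class training data after resampling")
    fitted = learner.clone().fit(Xs, y)
    imp = fitted.importances()
    total = imp.sum()
    frac = imp / total if total > 0 else imp
    table = (
        pd.DataFrame({"feature": selected, "importance": frac})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    meta = dict(metadata or {})
    meta.update(
        seed=seed,
        class_counts=np.bincount(y, minlength=2).tolist(),
        resample=resample_cfg.to_dict() if resample_cfg else None,
        learner_params=learner.params,
        importance_table=table.to_dict(orient="list"),
    )
    meta["config_hash"] = config_hash(
        {k: v for k, v in meta.items() if k != "importance_table"}
    )
    return ModelBundle(
        learner=fitted,
        selected_features=selected,
        threshold=DEFAULT_THRESHOLD,
        metadata=meta,
    )


def evaluate(bundle: ModelBundle, X: pd.DataFrame, y) -> MetricsReport:
    """Metric suite for the bundle on held-out data at its threshold."""
    return evaluate_scores(y, bundle.probabilities(X), bundle.threshold)


def calibrate_threshold(
    bundle: ModelBundle,
    X_val: pd.DataFrame | None = None,
    y_val=None,
    mode: str = "fixed",
    value: float = STRICT_THRESHOLD,
) -> ModelBundle:
    """Set the decision threshold.

    ``fixed`` assigns *value* verbatim (the strict precision-oriented
    default is 0.98); ``precision_floor`` sweeps the unique predicted
    probabilities on validation data and picks the lowest threshold
    whose precision reaches *value*, erroring with the best achievable
    precision when the floor is unattainable.
    """
    if mode == "fixed":
        return replace(bundle, threshold=value)
    if mode != "precision_floor":
        raise XtclassError(f"unknown calibration mode {mode!r}")
    if X_val is None or y_val is None:
        raise XtclassError("precision_floor calibration needs validation data")
    y_val = np.asarray(y_val, dtype=int)
    if np.unique(y_val).size < 2:
        raise XtclassError("validation data must contain both classes")
    probs = bundle.probabilities(X_val)
    best_prec, best_thr, hit = -1.0, None, None
    for thr in sorted(np.unique(probs)):
        pred = probs >= thr
        if pred.sum() == 0:
            continue
        prec = (pred & (y_val == 1)).sum() / pred.sum()
        if prec > best_prec:
            best_prec, best_thr = prec, thr
        if prec >= value and hit is None:
            hit = thr
    if hit is None:
        raise XtclassError(
            f"precision floor {value} unattainable; best achievable is "
            f"{best_prec:.4f} at threshold {best_thr}"
        )
    return replace(bundle, threshold=float(hit))


def predict(bundle: ModelBundle, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sequence probability, class and near-miss flag.

    ``near_miss`` marks candidates just under the cut (within 0.05),
    the ones a slightly laxer threshold would have accepted.
    """
    probs = bundle.probabilities(X)
    cls = (probs >= bundle.threshold).astype(int)
    near = (probs >= bundle.threshold - NEAR_MISS_MARGIN) & (cls == 0)
    out = pd.DataFrame(
        {
            "probability": probs,
            "predicted": cls,
            "near_miss": near,
        },
        index=X.index,
    )
    out.index.name = "id"
    return out


def serialize(bundle: ModelBundle, path) -> None:
    doc = {
        "format": "xtclass-model",
        "version": FORMAT_VERSION,
        "threshold": bundle.threshold,
        "selected_features": bundle.selected_features,
        "metadata": bundle.metadata,
        "learner": {
            "seed": bundle.learner.seed,
            "params": bundle.learner.params,
            "booster": bundle.learner.save_raw(),
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def deserialize(path) -> ModelBundle:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "xtclass-model" or doc.get("version") != FORMAT_VERSION:
        raise XtclassError(f"unsupported model file {path}")
    for key in ("threshold", "selected_features", "learner"):
        if key not in doc:
            raise XtclassError(f"model file {path} lacks field {key!r}")
    learner = GradientBoostingLearner.load_raw(
        doc["learner"]["booster"],
        seed=doc["learner"]["seed"],
        params=doc["learner"]["params"],
    )
    return ModelBundle(
        learner=learner,
        selected_features=list(doc["selected_features"]),
        threshold=float(doc["threshold"]),
        metadata=doc.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# statsmodels-style surface


class XyloseTransportModel:
    """Classifier of xylose-transport capacity over a feature matrix.

    Parameters
    ----------
    X : feature matrix (rows = sequences, named columns)
    y : binary labels aligned with X (1 = xylose transporter)
    resample_cfg : imbalance correction applied to training data only
    rfecv_step, rfecv_folds, rfecv_metric : feature-selection settings;
        ``rfecv_step=None`` disables selection (all features kept)
    seed : seeds every stochastic component
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        resample_cfg: ResampleConfig | None = None,
        rfecv_step=1,
        rfecv_folds: int = 5,
        rfecv_metric: str = "average_precision",
        rfecv_min_features: int = 1,
        learner: GradientBoostingLearner | None = None,
        seed: int = 0,
    ):
        self.X = X
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != self.y.size:
            raise XtclassError("X and y lengths differ")
        self.resample_cfg = resample_cfg
        self.rfecv_step = rfecv_step
        self.rfecv_folds = rfecv_folds
        self.rfecv_metric = rfecv_metric
        self.rfecv_min_features = rfecv_min_features
        self.seed = seed
        self.learner = (
            learner if learner is not None else GradientBoostingLearner(seed)
        )

    @classmethod
    def from_dataset(cls, dataset, features: pd.DataFrame, **kwargs):
        y = [dataset.labels[i] for i in features.index]
        return cls(features, y, **kwargs)

    def fit(self) -> "XyloseTransportResults":
        selection = None
        selected = list(self.X.columns)
        if self.rfecv_step is not None and self.X.shape[1] > 1:
            selection = rfecv(
                self.X, self.y,
                learner=self.learner,
                step=self.rfecv_step,
                folds=self.rfecv_folds,
                metric=self.rfecv_metric,
                resample_cfg=self.resample_cfg,
                min_features=self.rfecv_min_features,
                seed=self.seed,
            )
            selected = selection.selected_features
        bundle = fit(
            self.X, self.y,
            selected_features=selected,
            learner=self.learner,
            resample_cfg=self.resample_cfg,
            seed=self.seed,
        )
        return XyloseTransportResults(self, bundle, selection)


class XyloseTransportResults:
    """Fit results: trained bundle, selection curve, importances."""

    def __init__(self, model, bundle: ModelBundle, selection: RfecvResult | None):
        self.model = model
        self.bundle = bundle
        self.selection = selection

    @property
    def selected_features(self) -> list[str]:
        return self.bundle.selected_features

    @property
    def importances(self) -> pd.DataFrame:
        return pd.DataFrame(self.bundle.metadata["importance_table"])

    def evaluate(self, X: pd.DataFrame, y) -> MetricsReport:
        return evaluate(self.bundle, X, y)

    def calibrate(self, mode: str = "fixed", value: float = STRICT_THRESHOLD,
                  X_val=None, y_val=None) -> "XyloseTransportResults":
        new = calibrate_threshold(
            self.bundle, X_val, y_val, mode=mode, value=value
        )
        return XyloseTransportResults(self.model, new, self.selection)

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        return predict(self.bundle, X)

    def save(self, path) -> None:
        serialize(self.bundle, path)

    def summary(self, top: int = IMPORTANCE_REPORT_ROWS) -> str:
        lines = [
            "Xylose transport capacity classifier",
            "=" * 52,
            f"features in        {self.model.X.shape[1]:>6d}",
            f"features selected  {len(self.selected_features):>6d}",
            f"decision threshold {self.bundle.threshold:>9.2f}",
            f"training class counts (pos, neg): "
            f"{tuple(reversed(self.bundle.metadata['class_counts']))}",
            "-" * 52,
            f"top {min(top, len(self.selected_features))} features by "
            f"importance (gain fraction):",
        ]
        table = self.importances.head(top)
        for _, row in table.iterrows():
            lines.append(f"  {row['feature']:<32s} {row['importance']:.4f}")
        return "\n".join(lines)
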