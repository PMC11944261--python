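"""Base-model surrogates, stacked weight extraction and the meta-learners.

The pipeline trains two base networks — one on the 52 TD values, one on
the 52 PD values, each augmented with 4 clinical covariates (age, gender,
race, follow-up time) — whose heads predict the rule-based criterion
verdicts assigned to that map kind.  Each trained network is then reduced
to a per-sample 64-vector: the penultimate-layer activations weighted
elementwise by the network's output-layer weight vector (averaged across
heads).  TD-net 64 + PD-net 64 + the 4 clinical covariates give the
132-dimensional stacked feature vector on which the three meta-learners
(logistic regression, gradient-boosted trees, MLP) are trained against
the clinical glaucoma labels.

The weighted-activation construction is one of three selectable variants
(``weighted`` (default), ``activations``, ``weights``); see the methods
note for why the default was chosen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .nn import MiniMLP
from .cohort import Cohort
from .normative import VFExam

__all__ = [
    "BaseFeatureVector",
    "BaseModelBundle",
    "MetaModel",
    "build_features",
    "hyperparameter_search",
    "train_base",
    "extract_meta_features",
    "train_meta",
    "predict",
    "PENULTIMATE_WIDTH",
    "META_DIM",
    "TD_CRITERIA",
    "PD_CRITERIA",
]

PENULTIMATE_WIDTH = 64
META_DIM = 2 * PENULTIMATE_WIDTH + 4

# Criterion-to-map assignment of the base networks.
TD_CRITERIA = ("LoGTS", "UKGTS", "Kang")
PD_CRITERIA = ("HAP2_p1", "Foster")

CLINICAL_COLUMNS = ("age", "gender", "race", "follow_up")


@dataclass
class BaseFeatureVector:
    """56-dimensional base input: 52 deviations + 4 clinical covariates.

    Continuous columns are z-scored with train-split statistics recorded
    on the object; the integer gender/race encodings are persisted
    alongside so the mapping is explicit and reusable.
    """

    X: np.ndarray  # (n, 56) standardized
    sample_ids: List[Tuple[str, str]]  # (patient_id, eye)
    mean: np.ndarray
    scale: np.ndarray
    map_kind: str
    encodings: Dict[str, Dict[str, int]] = field(default_factory=dict)

    def transform_like(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.mean) / self.scale


def _impute_median(X: np.ndarray) -> np.ndarray:
    """Column-median imputation of missing cells."""
    X = X.copy()
    for j in range(X.shape[1]):
        col = X[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            if not np.isfinite(med):
                med = 0.0
            col[bad] = med
    return X


def build_features(cohort: Cohort, map_kind: str,
                   stats_from: Optional[BaseFeatureVector] = None) -> BaseFeatureVector:
    """Assemble the per-eye 56-vector from the most recent exam of each eye.

    Deviation columns come from the exam's TD or PD map; missing cells are
    median-imputed; standardization statistics are computed here or reused
    from ``stats_from`` (the train-split object) for held-out data.
    """
    if map_kind not in ("TD", "PD"):
        raise ValueError(f"map_kind must be 'TD' or 'PD', got {map_kind!r}")
    ids, rows = [], []
    for (pid, eye), exams in sorted(cohort.eyes().items()):
        exam = exams[-1]
        dev = exam.td if map_kind == "TD" else exam.pd
        dev = np.full(52, np.nan) if dev is None else dev
        clin = [exam.age, exam.gender, exam.race, exam.follow_up]
        rows.append(np.concatenate([dev, clin]))
        ids.append((pid, eye))
    X = _impute_median(np.array(rows, dtype=float))
    if stats_from is None:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        # leave categorical encodings on their integer scale
        for j in (53, 54):  # gender, race columns
            mean[j], scale[j] = 0.0, 1.0
        scale[scale == 0] = 1.0
    else:
        mean, scale = stats_from.mean, stats_from.scale
    return BaseFeatureVector(
        X=(X - mean) / scale,
        sample_ids=ids,
        mean=mean,
        scale=scale,
        map_kind=map_kind,
        encodings={"gender": {"female": 0, "male": 1},
                   "race": {"white": 0, "black": 1, "asian": 2,
                            "native": 3, "other": 4}},
    )


@dataclass
class BaseModelBundle:
    """A trained base network plus its provenance."""

    map_kind: str
    network: MiniMLP
    heads: Tuple[str, ...]
    features: BaseFeatureVector
    cv_table: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.network.hidden[-1] != PENULTIMATE_WIDTH:
            raise ValueError(
                f"penultimate width must be {PENULTIMATE_WIDTH} so meta-features "
                f"have dimension {META_DIM}"
            )


HYPER_GRID = {
    "activation": ("softmax", "relu", "sigmoid"),
    "lr": (1e-2, 1e-3, 1e-5),
    "optimizer": ("sgd", "rmsprop", "adam"),
}

_PREFERRED = ("sigmoid", 1e-3, "adam")


def hyperparameter_search(X: np.ndarray, y: np.ndarray,
                          grid: Mapping[str, Sequence] = HYPER_GRID,
                          folds: int = 5, seed: int = 0,
                          max_epochs: int = 25,
                          hidden: Sequence[int] = (128, PENULTIMATE_WIDTH),
                          ) -> Tuple[dict, pd.DataFrame]:
    """Exhaustive grid search with stratified k-fold cross-validation.

    Returns the best configuration (argmax mean validation accuracy, ties
    broken in favour of (sigmoid, 1e-3, adam) then first-seen order) and
    the full score table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold "
            "stratified cross-validation"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    records = []
    configs = list(itertools.product(*grid.values()))
    names = list(grid.keys())
    for order, values in enumerate(configs):
        cfg = dict(zip(names, values))
        fold_scores = []
        for k, (tr, va) in enumerate(splits):
            net = MiniMLP(
                n_in=X.shape[1], hidden=hidden, n_out=1,
                activation=cfg["activation"], optimizer=cfg["optimizer"],
                lr=cfg["lr"], max_epochs=max_epochs, patience=3,
                validation_fraction=0.0, seed=seed + 1000 * k,
            )
            net.fit(X[tr], y[tr])
            fold_scores.append(net.score(X[va], y[va]))
        records.append({**cfg, "order": order,
                        "mean_score": float(np.mean(fold_scores)),
                        "fold_scores": fold_scores})
    table = pd.DataFrame(records)
    pref = [
        0 if (r["activation"], r["lr"], r["optimizer"]) == _PREFERRED else 1
        for _, r in table.iterrows()
    ]
    table = table.assign(_pref=pref)
    best = table.sort_values(["mean_score", "_pref", "order"],
                             ascending=[False, True, True]).iloc[0]
    config = {k: best[k] for k in names}
    return config, table.drop(columns="_pref")


def train_base(features: BaseFeatureVector, labels: pd.DataFrame,
               heads: Sequence[str], seed: int = 0,
               activation: str = "sigmoid", optimizer: str = "adam",
               lr: float = 1e-3, max_epochs: int = 25, patience: int = 3,
               hidden: Sequence[int] = (128, PENULTIMATE_WIDTH)) -> BaseModelBundle:
    """Train one multi-head base network on criterion verdicts.

    ``labels`` is the verdict table from the criteria module (one row per
    (patient_id, eye), one binary column per criterion); ``heads`` names
    the columns this network predicts.
    """
    idx = labels.set_index(["patient_id", "eye"])
    Y = np.array([[idx.loc[sid, h] for h in heads] for sid in features.sample_ids],
                 dtype=float)
    net = MiniMLP(
        n_in=features.X.shape[1], hidden=hidden, n_out=len(heads),
        activation=activation, optimizer=optimizer, lr=lr,
        max_epochs=max_epochs, patience=patience,
        validation_fraction=0.1, seed=seed,
    )
    net.fit(features.X, Y)
    return BaseModelBundle(map_kind=features.map_kind, network=net,
                           heads=tuple(heads), features=features)


def extract_meta_features(td_bundle: BaseModelBundle, pd_bundle: BaseModelBundle,
                          td_X: np.ndarray, pd_X: np.ndarray,
                          clinical: np.ndarray,
                          variant: str = "weighted") -> np.ndarray:
    """Per-sample 132-dimensional stacked feature vector.

    ``weighted`` (default): penultimate activations elementwise times the
    head-averaged output-layer weight vector, per network.
    ``activations``: raw penultimate activations.  ``weights``: the
    head-averaged output weight vector broadcast to every sample.
    """
    if clinical.shape[1] != 4:
        raise ValueError("clinical covariate block must have 4 columns")

    def block(bundle: BaseModelBundle, X: np.ndarray) -> np.ndarray:
        acts = bundle.network.hidden_activations(X)
        if acts.shape[1] != PENULTIMATE_WIDTH:
            raise ValueError("penultimate width mismatch")
        w = bundle.network.output_weights.mean(axis=1)
        if variant == "weighted":
            return acts * w
        if variant == "activations":
            return acts
        if variant == "weights":
            return np.tile(w, (X.shape[0], 1))
        raise ValueError(f"unknown meta-feature variant {variant!r}")

    meta = np.hstack([block(td_bundle, td_X), block(pd_bundle, pd_X), clinical])
    assert meta.shape[1] == META_DIM
    return meta


@dataclass
class MetaModel:
    """A trained meta-learner with a uniform predict_proba surface."""

    kind: str  # "lr" | "xgb" | "mlp"
    model: object
    fitted: bool = True

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("meta-model is not trained")
        if self.kind == "mlp":
            return self.model.predict_proba(X).ravel()
        return self.model.predict_proba(X)[:, 1]


def train_meta(meta_X: np.ndarray, labels: np.ndarray, kind: str,
               seed: int = 0) -> MetaModel:
    """Train one meta-learner on the stacked features.

    lr: L2 logistic regression (lbfgs, C=1.0); xgb: gradient-boosted trees
    (eta 0.3, max depth 6, 25 rounds, single thread for determinism);
    mlp: 128/64/1 with batch-norm + ReLU hidden blocks, dropout 0.08,
    Adam at 0.0031 with weight decay 1e-3, batch 32, 25 epochs.
    """
    y = np.asarray(labels, dtype=int).ravel()
    if len(np.unique(y)) < 2:
        raise ValueError("meta-learner training needs both classes present")
    if kind == "lr":
        model = LogisticRegression(C=1.0, solver="lbfgs",
                                   max_iter=2000, random_state=seed)
        model.fit(meta_X, y)
    elif kind == "xgb":
        model = XGBClassifier(
            learning_rate=0.3, max_depth=6, booster="gbtree",
            n_estimators=25, n_jobs=1, random_state=seed,
            tree_method="hist", eval_metric="logloss",
        )
        model.fit(meta_X, y)
    elif kind == "mlp":
        model = MiniMLP(
            n_in=meta_X.shape[1], hidden=(128, 64), n_out=1,
            activation="relu", batch_norm=True, dropout=0.08,
            optimizer="adam", lr=0.0031, weight_decay=1e-3,
            batch_size=32, max_epochs=25, patience=25,
            validation_fraction=0.1, seed=seed,
        )
        model.fit(meta_X, y.astype(float))
    else:
        raise ValueError(f"unknown meta-learner kind {kind!r}")
    return MetaModel(kind=kind, model=model)


def predict(meta_model: MetaModel, meta_X: np.ndarray,
            threshold: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """Per-sample glaucoma probability and thresholded label."""
    p = meta_model.predict_proba(np.asarray(meta_X, dtype=float))
    if np.any(p < 0) or np.any(p > 1):
        raise AssertionError("probabilities escaped [0, 1]")
    return p, (p >= threshold).astype(int)
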