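"""Expression-level classifiers under protein-grouped cross-validation.

Three model families distinguish the high/medium/low expression levels:
an RBF SVM and a random forest (both grid-searched by an inner 3-fold
score) and a small feed-forward network (two hidden layers of 200 units,
Adam, squared-error loss against one-hot targets, 200 epochs, softmax at
inference).  Cross-validation folds are assigned at the protein level so
that all images of a protein land in the same fold, and stepwise
discriminant feature selection runs inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import sda_select
from .synthetic import LEVELS

__all__ = [
    "Dataset",
    "CVPlan",
    "PredictionResult",
    "EvaluationReport",
    "SVM_C_GRID",
    "SVM_GAMMA_GRID",
    "RF_TREE_GRID",
    "grouped_kfold",
    "train_model",
    "predict",
    "cross_validate",
    "evaluate",
]

SVM_C_GRID = tuple(2.0**e for e in range(-3, 8))
SVM_GAMMA_GRID = tuple(2.0**e for e in range(-9, 2))
RF_TREE_GRID = (100, 300, 500)


@dataclass
class Dataset:
    features: np.ndarray
    labels: np.ndarray
    protein_ids: np.ndarray
    image_ids: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.protein_ids = np.asarray(self.protein_ids)
        self.image_ids = np.asarray(self.image_ids)
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.protein_ids) == len(self.image_ids) == n):
            raise ValueError("dataset columns must be aligned")
        if np.unique(self.labels).size < 2:
            raise ValueError("dataset must contain at least two classes")

    def subset(self, mask: np.ndarray) -> "Dataset":
        return Dataset(
            self.features[mask],
            self.labels[mask],
            self.protein_ids[mask],
            self.image_ids[mask],
        )


@dataclass
class CVPlan:
    k: int
    assignment: dict[str, int]  # protein_id -> fold
    seed: int = 0

    def fold_of(self, protein_ids: np.ndarray) -> np.ndarray:
        return np.array([self.assignment[p] for p in protein_ids])


@dataclass
class PredictionResult:
    """Class probabilities over (high, medium, low) and the argmax label."""

    probs: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (3,):
            raise ValueError("probs must be a 3-vector over (high, medium, low)")
        if np.any(self.probs < -1e-9) or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must form a probability simplex")
        if not self.label:
            self.label = LEVELS[int(np.argmax(self.probs))]


@dataclass
class EvaluationReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def summary(self) -> str:
        lines = [
            f"accuracy  : {self.accuracy:.4f}",
            f"recall    : {self.recall:.4f} (macro)",
            f"precision : {self.precision:.4f} (macro)",
            f"F1-score  : {self.f1:.4f} (macro)",
            "confusion (rows true, cols predicted; order high/medium/low):",
        ]
        for lev, row in zip(LEVELS, self.confusion):
            lines.append(f"  {lev:<7}" + "".join(f"{int(v):>7d}" for v in row))
        return "\n".join(lines)


def grouped_kfold(protein_ids, k: int = 10, seed: int = 0, labels=None) -> CVPlan:
    """Deal shuffled proteins round-robin into k folds, stratified by label.

    All images of a protein share its fold.  When ``labels`` (aligned with
    ``protein_ids``) are given, proteins are ordered by their modal label
    before the deal, so folds are approximately label-balanced; without
    labels the deal is a plain shuffled round-robin.  Stratification keeps
    every training set's class balance close to the cohort's, which
    matters for small folds.
    """
    protein_ids = np.asarray(protein_ids)
    proteins = np.unique(protein_ids)
    if proteins.size < k:
        raise ValueError(f"{proteins.size} proteins cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(proteins))
    if labels is not None:
        labels = np.asarray(labels)
        modal: dict[str, str] = {}
        for p in order:
            labs, counts = np.unique(labels[protein_ids == p], return_counts=True)
            modal[str(p)] = str(labs[np.argmax(counts)])
        rank = {lev: i for i, lev in enumerate(LEVELS)}
        order.sort(key=lambda p: rank.get(modal[str(p)], len(LEVELS)))
    assignment = {str(p): i % k for i, p in enumerate(order)}
    return CVPlan(k=k, assignment=assignment, seed=seed)


class _DNN:
    """Two-hidden-layer (200x200) MSE-trained network with softmax outputs.

    Targets are one-hot class vectors in (high, medium, low) order; the
    network is a multi-output regressor optimized with Adam for 200
    epochs, and the three linear outputs are softmax-normalized at
    inference to yield simplex probabilities.
    """

    def __init__(self, seed: int = 0, epochs: int = 200):
        self.net = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        hidden_layer_sizes=(200, 200),
                        activation="relu",
                        solver="adam",
                        max_iter=epochs,
                        random_state=seed,
                    ),
                ),
            ]
        )
        self.classes_ = np.array(LEVELS)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_DNN":
        onehot = np.zeros((len(y), 3))
        for i, lab in enumerate(y):
            onehot[i, LEVELS.index(lab)] = 1.0
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence at fixed epoch budget
            self.net.fit(x, onehot)
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(self.net.predict(x))
        z = raw - raw.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def train_model(
    features: np.ndarray,
    labels,
    kind: str = "svm",
    seed: int = 0,
    c_grid=SVM_C_GRID,
    gamma_grid=SVM_GAMMA_GRID,
    tree_grid=RF_TREE_GRID,
    epochs: int = 200,
):
    """Fit one classifier of ``kind`` in {'svm', 'rf', 'dnn'}.

    SVM and RF hyperparameters are grid-searched with an inner 3-fold
    accuracy score on the training data; the SVM is refit with
    probability outputs (Platt scaling) at the best (C, gamma).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    if kind == "svm":
        base = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
        grid = {"svc__C": list(c_grid), "svc__gamma": list(gamma_grid)}
        gs = GridSearchCV(base, grid, cv=3, n_jobs=1)
        gs.fit(x, y)
        best = gs.best_params_
        tuned = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        kernel="rbf",
                        C=best["svc__C"],
                        gamma=best["svc__gamma"],
                        random_state=seed,
                    ),
                ),
            ]
        )
        # Platt-scaled probability outputs at the tuned (C, gamma)
        model = CalibratedClassifierCV(tuned, method="sigmoid", cv=3, ensemble=False)
        model.fit(x, y)
        return model
    if kind == "rf":
        gs = GridSearchCV(
            RandomForestClassifier(random_state=seed),
            {"n_estimators": list(tree_grid)},
            cv=3,
            n_jobs=1,
        )
        gs.fit(x, y)
        model = RandomForestClassifier(
            n_estimators=gs.best_params_["n_estimators"], random_state=seed
        )
        model.fit(x, y)
        return model
    if kind == "dnn":
        return _DNN(seed=seed, epochs=epochs).fit(x, y)
    raise ValueError(f"unknown model kind {kind!r}")


def _proba_in_level_order(model, x: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(np.asarray(x, dtype=float))
    classes = [str(c) for c in model.classes_] if hasattr(model, "classes_") else list(LEVELS)
    if hasattr(model, "named_steps"):  # pipeline
        classes = [str(c) for c in model.named_steps[list(model.named_steps)[-1]].classes_]
    order = []
    for lev in LEVELS:
        if lev in classes:
            order.append(classes.index(lev))
        else:
            order.append(None)
    out = np.zeros((proba.shape[0], 3))
    for i, pos in enumerate(order):
        if pos is not None:
            out[:, i] = proba[:, pos]
    out /= out.sum(axis=1, keepdims=True)
    return out


def predict(model, features: np.ndarray) -> list[PredictionResult]:
    """Per-row probability vectors over (high, medium, low) plus argmax labels.

    Argmax ties resolve to the earlier class in the fixed high > medium >
    low order.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    proba = _proba_in_level_order(model, x)
    return [PredictionResult(probs=p) for p in proba]


def evaluate(predictions: list[PredictionResult], labels) -> EvaluationReport:
    """Accuracy, macro recall/precision/F1 and the 3x3 confusion matrix.

    Per-class precision/recall default to 0 when undefined (zero
    division); rows of the confusion matrix are true levels, columns
    predicted, both in (high, medium, low) order.
    """
    y_true = list(labels)
    if len(predictions) == 0 or len(y_true) != len(predictions):
        raise ValueError("predictions and labels must be non-empty and aligned")
    y_pred = [p.label for p in predictions]
    conf = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[LEVELS.index(t), LEVELS.index(p)] += 1
    accuracy = float(np.trace(conf)) / conf.sum()
    precisions, recalls, f1s = [], [], []
    for i in range(3):
        tp = conf[i, i]
        col = conf[:, i].sum()
        row = conf[i, :].sum()
        prec = tp / col if col else 0.0
        rec = tp / row if row else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return EvaluationReport(
        accuracy=accuracy,
        recall=float(np.mean(recalls)),
        precision=float(np.mean(precisions)),
        f1=float(np.mean(f1s)),
        confusion=conf,
    )


def cross_validate(
    data: Dataset,
    kind: str = "svm",
    plan: CVPlan | None = None,
    sda_params: dict | None = None,
    seed: int = 0,
    **train_kwargs,
) -> tuple[EvaluationReport, "pd.DataFrame"]:
    """Protein-grouped k-fold CV with per-fold SDA feature selection.

    Per fold: stepwise discriminant selection runs on the training
    portion only; the model trains on the selected columns and predicts
    the held-out images.  Metrics are pooled over all held-out
    predictions.  Returns the report and a per-image prediction table
    (image_id, protein_id, true label, p_high/p_medium/p_low, label).

    ``sda_params`` are forwarded to :func:`ihcscreen.selection.sda_select`;
    pass ``sda_params={'skip': True}`` to disable selection.
    """
    import pandas as pd

    if plan is None:
        plan = grouped_kfold(data.protein_ids, k=10, seed=seed, labels=data.labels)
    missing = set(np.unique(data.protein_ids)) - set(plan.assignment)
    if missing:
        raise ValueError(f"CV plan does not cover proteins {sorted(missing)}")
    folds = plan.fold_of(data.protein_ids)
    sda_params = dict(sda_params or {})
    skip_sda = sda_params.pop("skip", False)

    rows = []
    all_preds: list[PredictionResult] = []
    all_true: list[str] = []
    for f in range(plan.k):
        test_mask = folds == f
        if not test_mask.any():
            continue
        train = data.subset(~test_mask)
        x_test = data.features[test_mask]
        y_test = data.labels[test_mask]
        if skip_sda:
            cols = np.arange(data.features.shape[1])
        else:
            cols = np.asarray(
                sda_select(train.features, train.labels, **sda_params).selected
            )
        model = train_model(
            train.features[:, cols], train.labels, kind=kind, seed=seed, **train_kwargs
        )
        preds = predict(model, x_test[:, cols])
        all_preds.extend(preds)
        all_true.extend(y_test)
        for img, prot, lab, pr in zip(
            data.image_ids[test_mask], data.protein_ids[test_mask], y_test, preds
        ):
            rows.append(
                {
                    "image_id": img,
                    "protein_id": prot,
                    "true_label": lab,
                    "p_high": pr.probs[0],
                    "p_medium": pr.probs[1],
                    "p_low": pr.probs[2],
                    "label": pr.label,
                    "fold": f,
                }
            )
    report = evaluate(all_preds, all_true)
    return report, pd.DataFrame(rows)
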