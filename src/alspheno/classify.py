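"""The study's three classifiers and their cross-validated evaluation.

* CART: a Gini-split binary decision tree with cost-complexity pruning,
  the pruning strength chosen by internal cross-validation.
* Random Forest: 100-tree bootstrap ensemble, sqrt(p) features per
  split, with out-of-bag (OOB) error and Gini-decrease variable
  importance.
* Neural network: two hidden layers sized by the geometric pyramid
  rule — r = (n_in / n_out)^(1/3), h1 = round(n_out * r^2),
  h2 = round(n_out * r) — trained by gradient descent with momentum
  0.9 for up to 5000 epochs on standardized inputs (sigmoid hidden
  units, softmax output).

Evaluation uses stratified k-fold cross-validation (default k = 5);
every subject is predicted exactly once and the pooled predictions are
summarized in a :class:`ClassifierReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

__all__ = [
    "NNArchitecture",
    "ClassifierReport",
    "pyramid_hidden_sizes",
    "train_cart",
    "train_random_forest",
    "train_neural_network",
    "cross_validate",
    "classification_report",
]

METHODS = ("cart", "rf", "nn")


def pyramid_hidden_sizes(n_in: int, n_out: int) -> tuple[int, int]:
    """Hidden-layer sizes from the geometric pyramid rule (round half up)."""
    if n_in < 1 or n_out < 1:
        raise ValueError("n_in and n_out must be positive")
    r = (n_in / n_out) ** (1.0 / 3.0)
    h1 = max(1, int(np.floor(n_out * r * r + 0.5)))
    h2 = max(1, int(np.floor(n_out * r + 0.5)))
    return h1, h2


@dataclass
class NNArchitecture:
    n_in: int
    n_out: int
    momentum: float = 0.9
    epochs: int = 5000
    folds: int = 5
    learning_rate: float = 0.01

    @property
    def r(self) -> float:
        return (self.n_in / self.n_out) ** (1.0 / 3.0)

    @property
    def hidden_sizes(self) -> tuple[int, int]:
        return pyramid_hidden_sizes(self.n_in, self.n_out)


@dataclass
class ClassifierReport:
    classes: list[int]
    confusion: np.ndarray  # true x predicted counts
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    accuracy: float  # percent
    oob_error: float | None = None
    importance: dict[str, float] | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "precision": {str(k): v for k, v in self.precision.items()},
            "recall": {str(k): v for k, v in self.recall.items()},
            "f1": {str(k): v for k, v in self.f1.items()},
            "accuracy": self.accuracy,
            "oob_error": self.oob_error,
            "importance": self.importance,
            **({"extra": self.extra} if self.extra else {}),
        }


def classification_report(y_true, y_pred,
                          classes: list[int] | None = None) -> ClassifierReport:
    """Confusion matrix (true rows) and per-class precision/recall/F1.

    Undefined ratios (no predictions or no support for a class) are 0
    by convention; accuracy is reported in percent.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if classes is None:
        classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    conf = _sk_confusion(y_true, y_pred, labels=classes)
    precision, recall, f1 = {}, {}, {}
    for i, c in enumerate(classes):
        tp = conf[i, i]
        pred_c = conf[:, i].sum()
        true_c = conf[i, :].sum()
        p = tp / pred_c if pred_c else 0.0
        r = tp / true_c if true_c else 0.0
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) else 0.0
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    return ClassifierReport(classes=list(classes), confusion=conf,
                            precision=precision, recall=recall, f1=f1,
                            accuracy=float(accuracy))


def _check_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes in the training data")


def train_cart(t: FeatureTable, seed: int = 0,
               pruning_folds: int = 3) -> tuple[DecisionTreeClassifier,
                                                ClassifierReport]:
    """Gini decision tree with cost-complexity pruning.

    The pruning parameter alpha is chosen from the tree's own
    cost-complexity path by internal stratified cross-validation on the
    training data (largest alpha within the best mean accuracy, i.e.
    the simplest tree among the winners).
    """
    X, y = t.X, t.y
    _check_classes(y)
    path = DecisionTreeClassifier(criterion="gini", random_state=seed) \
        .cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    if len(alphas) > 1:
        min_count = np.bincount(y).min() if y.min() >= 0 else 1
        k = int(min(pruning_folds, max(2, min_count)))
        scores = []
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        for a in alphas:
            accs = []
            for tr, te in folds:
                clf = DecisionTreeClassifier(criterion="gini", ccp_alpha=a,
                                             random_state=seed)
                clf.fit(X[tr], y[tr])
                accs.append((clf.predict(X[te]) == y[te]).mean())
            scores.append(np.mean(accs))
        best = max(range(len(alphas)),
                   key=lambda i: (round(scores[i], 12), alphas[i]))
        alpha = float(alphas[best])
    else:
        alpha = 0.0
    model = DecisionTreeClassifier(criterion="gini", ccp_alpha=alpha,
                                   random_state=seed)
    model.fit(X, y)
    report = classification_report(y, model.predict(X))
    report.importance = dict(zip(t.feature_names,
                                 model.feature_importances_.tolist()))
    report.extra = {"ccp_alpha": alpha, "n_leaves": int(model.get_n_leaves())}
    return model, report


def train_random_forest(t: FeatureTable, seed: int = 0,
                        n_trees: int = 100
                        ) -> tuple[RandomForestClassifier, ClassifierReport]:
    """100-tree Gini Random Forest with OOB error and variable importance."""
    X, y = t.X, t.y
    _check_classes(y)
    model = RandomForestClassifier(n_estimators=n_trees, criterion="gini",
                                   max_features="sqrt", oob_score=True,
                                   bootstrap=True, random_state=seed)
    model.fit(X, y)
    report = classification_report(y, model.predict(X))
    report.oob_error = float(1.0 - model.oob_score_)
    report.importance = dict(zip(t.feature_names,
                                 model.feature_importances_.tolist()))
    return model, report


def build_neural_network(arch: NNArchitecture, seed: int = 0) -> Pipeline:
    h1, h2 = arch.hidden_sizes
    mlp = MLPClassifier(hidden_layer_sizes=(h1, h2), activation="logistic",
                        solver="sgd", learning_rate_init=arch.learning_rate,
                        momentum=arch.momentum, nesterovs_momentum=False,
                        max_iter=arch.epochs, tol=1e-6, n_iter_no_change=50,
                        random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("mlp", mlp)])


def train_neural_network(t: FeatureTable, arch: NNArchitecture | None = None,
                         seed: int = 0) -> tuple[Pipeline, ClassifierReport]:
    """Pyramid-rule MLP on standardized inputs (softmax class scores)."""
    X, y = t.X, t.y
    _check_classes(y)
    n_out = len(np.unique(y))
    if arch is None:
        arch = NNArchitecture(n_in=X.shape[1], n_out=n_out)
    if arch.n_in != X.shape[1]:
        raise ValueError(f"architecture n_in={arch.n_in} != {X.shape[1]} features")
    model = build_neural_network(arch, seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter
        model.fit(X, y)
    report = classification_report(y, model.predict(X))
    report.extra = {"hidden_sizes": list(arch.hidden_sizes)}
    return model, report


def _fit_for_method(method: str, t: FeatureTable, seed: int):
    if method == "cart":
        return train_cart(t, seed=seed)
    if method == "rf":
        return train_random_forest(t, seed=seed)
    if method == "nn":
        return train_neural_network(t, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def cross_validate(method: str, t: FeatureTable, k: int = 5, seed: int = 0,
                   impute_per_fold: bool = False) -> ClassifierReport:
    """Stratified k-fold CV; every subject is predicted exactly once.

    With ``impute_per_fold=True`` missing values are filled with the
    *training-fold* column means (leakage-free variant); by default the
    table is expected to be already imputed on the full dataset.
    """
    from .features import FeatureTable as FT

    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    y = t.y
    counts = np.bincount(y, minlength=5)
    small = [c for c in np.unique(y) if counts[c] < k]
    if small:
        raise ValueError(f"class(es) {small} have fewer than k={k} members")
    if not impute_per_fold and np.isnan(t.X).any():
        raise ValueError("table has missing values; impute first or "
                         "use impute_per_fold=True")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    oob, importances = [], []
    for fold, (tr, te) in enumerate(skf.split(t.X, y)):
        data_tr = t.data.iloc[tr]
        data_te = t.data.iloc[te]
        if impute_per_fold:
            means = data_tr.mean()
            data_tr = data_tr.fillna(means)
            data_te = data_te.fillna(means)
        t_tr = FT(data_tr.copy(), t.labels.iloc[tr].copy())
        model, rep = _fit_for_method(method, t_tr, seed=seed + fold)
        y_pred[te] = (model.predict(data_te.to_numpy(float))
                      .astype(int))
        if rep.oob_error is not None:
            oob.append(rep.oob_error)
        if rep.importance is not None:
            importances.append(rep.importance)
    report = classification_report(y, y_pred,
                                   classes=sorted(np.unique(y).tolist()))
    if oob:
        report.oob_error = float(np.mean(oob))
    if importances:
        keys = list(importances[0])
        report.importance = {
            n: float(np.mean([imp[n] for imp in importances])) for n in keys}
    report.extra = {"method": method, "k": k, "seed": seed}
    return report
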