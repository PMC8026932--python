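"""Recurrence classification: FLD / KNN / SVM-RBF with sequential forward
selection, class-balanced subset ensembles and leave-one-out cross-validation.

Pipeline per outer LOO fold (everything is recomputed from the n-1 training
patients only -- no statistic, feature choice or subset draw ever sees the
held-out patient):

1. Z-score statistics from the training rows; both sides transformed.
2. Seven balanced subsets: all minority-class training patients plus an
   equal-size random draw (without replacement) from the majority class.
3. Per subset: sequential forward selection (greedy, <= 3 features,
   inner-LOO balanced accuracy criterion, stop when no addition improves),
   then hyperparameter selection (KNN's k, SVM's C/gamma grid) by the same
   criterion on the selected features, then a final fit.
4. The held-out patient receives 7 votes; majority (>= 4) decides the label
   and the vote fraction is the ensemble score used for the ROC.

Recurrence is the positive class throughout.  KNN breaks distance ties by
lower training index and even-k vote ties toward recurrence (the clinically
costly miss); both rules are part of the contract and covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

try:  # low-level libsvm binding: same solver as SVC, ~20x less call overhead
    from sklearn.svm import _libsvm
    _libsvm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - fallback to the public estimator
    _libsvm = None

from .features import FEATURE_NAMES, apply_zscore, zscore_normalize
from .simulate import derive_rng, derive_seed

__all__ = [
    "ClassifierConfig",
    "FLDModel",
    "SubsetModel",
    "FoldResult",
    "ModelReport",
    "train_fld",
    "fld_score",
    "knn_predict",
    "svm_param_grid",
    "grid_search_svm",
    "inner_loo_balanced_accuracy",
    "sequential_forward_select",
    "balanced_subset_ensemble",
    "loo_evaluate",
    "metrics_from_confusion",
]

POSITIVE = "recurrence"


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier family plus the fixed search grids."""

    family: str = "knn"                     # "fld" | "knn" | "svm"
    k_values: tuple[int, ...] = (1, 2, 3, 4, 5)
    knn_k: int | None = None                # fixed k; None = tuned inner-LOO
    c_exponents: tuple[int, ...] = tuple(range(11))      # C = 2^0 .. 2^10
    gamma_exponents: tuple[int, ...] = tuple(range(11))  # gamma = 2^0 .. 2^10
    max_features: int = 3
    n_subsets: int = 7
    seed: int = 0
    # mid-grid defaults used while the feature subset is being grown
    sfs_knn_k: int = 3
    sfs_svm_c: float = 32.0
    sfs_svm_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("fld", "knn", "svm"):
            raise ValueError("family must be one of fld/knn/svm")
        if self.max_features > 3:
            raise ValueError("max_features is capped at 3")
        if self.n_subsets % 2 == 0:
            raise ValueError("n_subsets must be odd so majority votes "
                             "cannot tie")


# --------------------------------------------------------------------------
# base learners
# --------------------------------------------------------------------------

@dataclass
class FLDModel:
    weights: np.ndarray
    threshold: float


def train_fld(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6) -> FLDModel:
    """Fisher's linear discriminant: w ~ S_w^-1 (mu1 - mu0).

    Threshold at the projected class-mean midpoint.  A ridge of 1e-6 engages
    when the pooled within-class scatter is singular.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    x1, x0 = X[y == 1], X[y == 0]
    mu1, mu0 = x1.mean(axis=0), x0.mean(axis=0)
    sw = ((x1 - mu1).T @ (x1 - mu1)) + ((x0 - mu0).T @ (x0 - mu0))
    diff = mu1 - mu0
    try:
        w = np.linalg.solve(sw, diff)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        w = np.linalg.solve(sw + ridge * np.eye(sw.shape[0]), diff)
    thr = float(w @ (mu1 + mu0) / 2.0)
    return FLDModel(weights=w, threshold=thr)


def fld_score(model: FLDModel, X: np.ndarray) -> np.ndarray:
    return np.asarray(X, dtype=float) @ model.weights - model.threshold


def knn_predict(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
                k: int) -> tuple[np.ndarray, np.ndarray]:
    """K-nearest-neighbour labels and recurrence-fraction scores.

    Euclidean distances; distance ties break toward the lower training
    index (stable argsort); even-k vote ties predict recurrence.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    if k > len(X_train):
        raise ValueError("k exceeds the number of training samples")
    d2 = ((X_test[:, None, :] - X_train[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")
    votes = y_train[order[:, :k]]
    score = votes.mean(axis=1)
    labels = (score >= 0.5).astype(int)
    return labels, score


def svm_param_grid(config: ClassifierConfig) -> list[tuple[float, float]]:
    """The (C, gamma) grid: integer exponents, 11 x 11 = 121 pairs."""
    return [(2.0**ce, 2.0**ge)
            for ce in config.c_exponents for ge in config.gamma_exponents]


def _fit_svm(X: np.ndarray, y: np.ndarray, c: float, gamma: float) -> SVC:
    clf = SVC(C=c, gamma=gamma, kernel="rbf")
    clf.fit(X, y)
    return clf


# --------------------------------------------------------------------------
# inner-LOO criterion
# --------------------------------------------------------------------------

def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    sens = (y_pred[pos] == 1).mean() if pos.any() else 0.0
    spec = (y_pred[neg] == 0).mean() if neg.any() else 0.0
    return 0.5 * (float(sens) + float(spec))


def _loo_predictions(X: np.ndarray, y: np.ndarray, family: str,
                     params: dict) -> np.ndarray:
    n = len(y)
    pred = np.empty(n, dtype=int)
    idx = np.arange(n)
    if family == "knn":
        k = params["k"]
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")
        kk = min(k, n - 1)
        votes = y[order[:, :kk]]
        pred = (votes.mean(axis=1) >= 0.5).astype(int)
        return pred
    if family == "svm":
        Xc = np.ascontiguousarray(X, dtype=np.float64)
        yf = np.ascontiguousarray(y, dtype=np.float64)
    for i in idx:
        tr = idx != i
        ytr = y[tr]
        if len(np.unique(ytr)) < 2:
            pred[i] = int(ytr[0])
            continue
        if family == "fld":
            m = train_fld(X[tr], ytr)
            pred[i] = int(fld_score(m, X[i:i + 1])[0] > 0)
        elif _libsvm is not None:
            fit = _libsvm.fit(np.ascontiguousarray(Xc[tr]), yf[tr],
                              svm_type=0, kernel="rbf",
                              C=float(params["c"]),
                              gamma=float(params["gamma"]))
            support, sv, n_sv, sv_coef, intercept = fit[:5]
            p = _libsvm.predict(Xc[i:i + 1], support, sv, n_sv, sv_coef,
                                intercept, svm_type=0, kernel="rbf",
                                gamma=float(params["gamma"]))
            pred[i] = int(p[0])
        else:  # pragma: no cover
            clf = _fit_svm(X[tr], ytr, params["c"], params["gamma"])
            pred[i] = int(clf.predict(X[i:i + 1])[0])
    return pred


def inner_loo_balanced_accuracy(X: np.ndarray, y: np.ndarray, family: str,
                                params: dict) -> float:
    """Leave-one-out balanced accuracy of a base learner on (X, y)."""
    return _balanced_accuracy(y, _loo_predictions(X, y, family, params))


# --------------------------------------------------------------------------
# sequential forward selection + hyperparameter choice per subset
# --------------------------------------------------------------------------

def _sfs_params(config: ClassifierConfig) -> dict:
    if config.family == "knn":
        return {"k": config.knn_k or config.sfs_knn_k}
    if config.family == "svm":
        return {"c": config.sfs_svm_c, "gamma": config.sfs_svm_gamma}
    return {}


def sequential_forward_select(X: np.ndarray, y: np.ndarray,
                              config: ClassifierConfig,
                              candidates: Sequence[int] | None = None
                              ) -> tuple[list[int], list[float]]:
    """Greedy forward selection of <= max_features columns.

    At each step the candidate maximizing the inner-LOO balanced accuracy is
    added (ties -> lower column index); selection stops when no addition
    strictly improves the criterion.  Returns the selected column indices and
    the criterion value after each accepted step (non-decreasing).
    """
    if candidates is None:
        candidates = range(X.shape[1])
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate feature")
    params = _sfs_params(config)
    selected: list[int] = []
    path: list[float] = []
    best = -np.inf
    while len(selected) < config.max_features:
        step_best, step_feat = -np.inf, None
        for c in candidates:
            if c in selected:
                continue
            score = inner_loo_balanced_accuracy(
                X[:, selected + [c]], y, config.family, params)
            if score > step_best:
                step_best, step_feat = score, c
        if step_feat is None or step_best <= best and selected:
            break
        selected.append(step_feat)
        best = step_best
        path.append(best)
    return selected, path


@dataclass
class SubsetModel:
    """One balanced subset's selected features and fitted classifier."""

    family: str
    feature_idx: list[int]
    subset_rows: np.ndarray         # row indices into the fold's training set
    params: dict
    fld: FLDModel | None = None
    svc: SVC | None = None
    X_sub: np.ndarray | None = None
    y_sub: np.ndarray | None = None
    sfs_path: list[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, decision scores) for rows of normalized features."""
        Xs = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_idx]
        if self.family == "fld":
            s = fld_score(self.fld, Xs)
            return (s > 0).astype(int), s
        if self.family == "knn":
            return knn_predict(self.X_sub, self.y_sub, Xs, self.params["k"])
        s = self.svc.decision_function(Xs)
        return (s > 0).astype(int), s

    def describe(self) -> tuple:
        """Hashable description of the trained model (leakage checks)."""
        if self.family == "fld":
            extra = (tuple(np.round(self.fld.weights, 12)),
                     round(self.fld.threshold, 12))
        elif self.family == "knn":
            extra = (self.params["k"],)
        else:
            extra = (self.params["c"], self.params["gamma"],
                     tuple(np.round(self.svc.dual_coef_.ravel(), 10)))
        return (self.family, tuple(self.feature_idx),
                tuple(self.subset_rows.tolist()), extra)


def _tune_and_fit(X: np.ndarray, y: np.ndarray, feature_idx: list[int],
                  subset_rows: np.ndarray, config: ClassifierConfig,
                  sfs_path: list[float]) -> SubsetModel:
    Xs = X[:, feature_idx]
    model = SubsetModel(family=config.family, feature_idx=list(feature_idx),
                        subset_rows=subset_rows, params={},
                        sfs_path=sfs_path)
    if config.family == "fld":
        model.fld = train_fld(Xs, y)
    elif config.family == "knn":
        if config.knn_k is not None:
            k = config.knn_k
        else:
            best, k = -np.inf, config.k_values[0]
            for kk in config.k_values:
                if kk > len(y) - 1:
                    continue
                s = inner_loo_balanced_accuracy(Xs, y, "knn", {"k": kk})
                if s > best:
                    best, k = s, kk
        model.params = {"k": k}
        model.X_sub, model.y_sub = Xs, y
    else:
        best, choice = -np.inf, (2.0**0, 2.0**0)
        for c, g in svm_param_grid(config):
            s = inner_loo_balanced_accuracy(Xs, y, "svm",
                                            {"c": c, "gamma": g})
            if s > best:
                best, choice = s, (c, g)
        model.params = {"c": choice[0], "gamma": choice[1]}
        model.svc = _fit_svm(Xs, y, *choice)
    return model


def grid_search_svm(X: np.ndarray, y: np.ndarray, config: ClassifierConfig
                    ) -> tuple[float, float, SVC]:
    """Best (C, gamma) by inner-LOO balanced accuracy, plus the fitted SVM."""
    m = _tune_and_fit(X, y, list(range(X.shape[1])),
                      np.arange(len(y)), ClassifierConfig(
                          family="svm", c_exponents=config.c_exponents,
                          gamma_exponents=config.gamma_exponents), [])
    return m.params["c"], m.params["gamma"], m.svc


def balanced_subset_ensemble(X: np.ndarray, y: np.ndarray,
                             config: ClassifierConfig,
                             rng_seed: int) -> list[SubsetModel]:
    """Fit the 7-subset ensemble on a fold's (normalized) training data.

    Each subset keeps every minority-class patient and downsamples the
    majority class to the same size (without replacement within a subset,
    independently across subsets).
    """
    y = np.asarray(y)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    minority, majority = (idx1, idx0) if len(idx1) <= len(idx0) \
        else (idx0, idx1)
    if len(minority) < 2:
        raise ValueError("minority class must have >= 2 training patients")
    models = []
    for s in range(config.n_subsets):
        rng = derive_rng(rng_seed, s)
        if len(majority) > len(minority):
            draw = rng.choice(majority, size=len(minority), replace=False)
        else:
            draw = majority
        rows = np.sort(np.concatenate([minority, draw]))
        Xs, ys = X[rows], y[rows]
        feats, path = sequential_forward_select(Xs, ys, config)
        models.append(_tune_and_fit(Xs, ys, feats, rows, config, path))
    return models


# --------------------------------------------------------------------------
# outer leave-one-out evaluation
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out: str
    true_label: int
    votes: list[int]
    ensemble_label: int
    ensemble_score: float          # vote fraction in {0/7 .. 7/7}
    mean_decision: float           # mean subset decision value (fld/svm)
    selected_features: list[list[str]]
    model_descriptions: list[tuple]


@dataclass
class ModelReport:
    family: str
    n: int
    tp: int
    fn: int
    tn: int
    fp: int
    sensitivity: float             # %
    specificity: float             # %
    accuracy: float                # %
    auc: float
    feature_frequency: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "family": self.family, "n": self.n,
            "confusion": {"tp": self.tp, "fn": self.fn,
                          "tn": self.tn, "fp": self.fp},
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
            "auc": self.auc,
            "feature_frequency": self.feature_frequency,
        }


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int
                           ) -> tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %) with recurrence positive."""
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    return sens, spec, acc


def _fit_fold(train_table: pd.DataFrame, config: ClassifierConfig,
              fold_seed: int
              ) -> tuple[list[SubsetModel], pd.DataFrame]:
    """Everything trainable for one fold, from training rows only."""
    norm, stats_df = zscore_normalize(train_table)
    X = norm[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = (train_table["label"] == POSITIVE).to_numpy(dtype=int)
    models = balanced_subset_ensemble(X, y, config, fold_seed)
    return models, stats_df


def loo_evaluate(table: pd.DataFrame, config: ClassifierConfig
                 ) -> tuple[list[FoldResult], ModelReport]:
    """Leave-one-out evaluation of the balanced-ensemble classifier.

    Fold seeds derive from (config.seed, fold index) only, so a fold's
    training is a pure function of the training rows -- perturbing the
    held-out patient cannot change that fold's models.
    """
    if len(table) < 10:
        raise ValueError("need n >= 10 patients for LOO evaluation")
    folds: list[FoldResult] = []
    for i, pid in enumerate(table.index):
        try:
            train = table.drop(index=pid)
            models, stats_df = _fit_fold(train, config,
                                         derive_seed(config.seed, i))
            held = apply_zscore(table.loc[[pid]], stats_df)
            xh = held[list(FEATURE_NAMES)].to_numpy(dtype=float)
            votes, decisions = [], []
            for m in models:
                lab, dec = m.predict(xh)
                votes.append(int(lab[0]))
                decisions.append(float(dec[0]))
            n_pos = sum(votes)
            folds.append(FoldResult(
                held_out=str(pid),
                true_label=int(table.loc[pid, "label"] == POSITIVE),
                votes=votes,
                ensemble_label=int(n_pos * 2 > config.n_subsets),
                ensemble_score=n_pos / config.n_subsets,
                mean_decision=float(np.mean(decisions)),
                selected_features=[[FEATURE_NAMES[j] for j in m.feature_idx]
                                   for m in models],
                model_descriptions=[m.describe() for m in models],
            ))
        except Exception as exc:
            raise RuntimeError(f"LOO fold failed for patient {pid}") from exc
    report = summarize_folds(folds, config.family)
    return folds, report


def summarize_folds(folds: list[FoldResult], family: str) -> ModelReport:
    y = np.array([f.true_label for f in folds])
    pred = np.array([f.ensemble_label for f in folds])
    score = np.array([f.ensemble_score for f in folds])
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    sens, spec, acc = metrics_from_confusion(tp, fn, tn, fp)
    auc = float(roc_auc_score(y, score)) if len(np.unique(y)) == 2 else np.nan
    freq: dict[str, int] = {}
    for f in folds:
        for feats in f.selected_features:
            for name in feats:
                freq[name] = freq.get(name, 0) + 1
    return ModelReport(family=family, n=len(folds), tp=tp, fn=fn, tn=tn,
                       fp=fp, sensitivity=sens, specificity=spec,
                       accuracy=acc, auc=auc,
                       feature_frequency=dict(sorted(freq.items())))
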