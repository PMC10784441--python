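"""Candidate classifiers, leave-one-out evaluation, signatures and fusion.

Five model families (logistic regression, RBF-kernel SVM, random forest,
k-nearest neighbors, one-hidden-layer neural network) are tuned by grid
search over nested prefixes of the LASSO-ranked features and family
hyperparameters using stratified 10-fold cross-validated accuracy.  The
winning family per region — chosen by leave-one-out (LOOCV) accuracy, with
AUC and a fixed family order as tie-breaks — becomes that region's
signature.  Signature scores entering the fusion model are always the
out-of-fold LOOCV probabilities, so no case ever influences its own score;
the fusion is a logistic regression over the two signature scores with Wald
tests and variance inflation factors from a multivariate fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .select import bootstrap_auc_ci

FAMILY_ORDER = ("LR", "SVM", "RF", "KNN", "ANN")  # tie-break order, simplest first

#: Hyperparameter grids, ordered by increasing capacity within each family.
DEFAULT_GRIDS = {
    "LR": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "SVM": [
        {"C": c, "gamma_factor": g} for c in (0.1, 1.0, 10.0) for g in (0.5, 1.0, 2.0)
    ],
    "KNN": [{"n_neighbors": k} for k in (9, 7, 5, 3)],
    "RF": [
        {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (3, 5, None)
    ],
    "ANN": [{"hidden": h} for h in (4, 8, 16)],
}

#: Reduced grids for scaled-down studies (same families, one or two points each).
FAST_GRIDS = {
    "LR": [{"C": c} for c in (0.1, 1.0)],
    "SVM": [{"C": 1.0, "gamma_factor": 1.0}, {"C": 10.0, "gamma_factor": 1.0}],
    "KNN": [{"n_neighbors": 5}],
    "RF": [{"n_estimators": 10, "max_depth": 3}],
    "ANN": [{"hidden": 8}],
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    params: dict
    features: list
    cv_accuracy: float = np.nan


@dataclass
class CVResult:
    """Per-case LOOCV record with bootstrap confidence intervals."""

    probabilities: np.ndarray  # P(benefit) for each held-out case
    predictions: np.ndarray
    labels: np.ndarray
    accuracy: float
    accuracy_ci: tuple
    auc: float
    auc_ci: tuple
    confusion: np.ndarray  # rows: true 0/1, cols: predicted 0/1


@dataclass
class Signature:
    region: str
    spec: ModelSpec
    cv: CVResult
    model: object  # final estimator refit on all cases
    oof_scores: np.ndarray  # = cv.probabilities; inputs to fusion
    candidates: dict = field(default_factory=dict)  # family -> CVResult


def make_estimator(family: str, params: dict, X: np.ndarray, seed: int = 0):
    """Instantiate one configured sklearn estimator (with predict_proba)."""
    if family == "LR":
        return LogisticRegression(C=params["C"], max_iter=5000)
    if family == "SVM":
        var = X.var()
        gamma = params["gamma_factor"] / (X.shape[1] * var) if var > 0 else "scale"
        # Platt-scaled probabilities via the calibration wrapper
        return CalibratedClassifierCV(
            SVC(C=params["C"], gamma=gamma, kernel="rbf", random_state=seed),
            method="sigmoid",
            ensemble=False,
            cv=3,
        )
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=min(params["n_neighbors"], len(X) - 1))
    if family == "RF":
        return RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_depth=params["max_depth"],
            random_state=seed,
        )
    if family == "ANN":
        # lbfgs converges far faster than SGD on cohort-sized (n ~ 52) data
        return MLPClassifier(
            hidden_layer_sizes=(params["hidden"],),
            solver="lbfgs",
            max_iter=300,
            random_state=seed,
        )
    raise ValueError(f"unknown model family {family!r}")


def _cv_accuracy(family, params, X, y, folds, seed):
    # stratification degrades gracefully when the minority class is small
    n_splits = max(2, min(folds, int(np.bincount(y).min())))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        est = make_estimator(family, params, X[tr], seed)
        est.fit(X[tr], y[tr])
        accs.append((est.predict(X[te]) == y[te]).mean())
    return float(np.mean(accs))


def tune_model(
    family: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    feature_order: list[str],
    folds: int = 10,
    seed: int = 0,
    grid: list[dict] | None = None,
    max_features: int | None = None,
) -> ModelSpec:
    """Joint grid search over nested feature prefixes and hyperparameters.

    Candidates are prefixes of ``feature_order`` (LASSO support by descending
    |coefficient|) crossed with the family grid; the winner maximizes mean
    stratified CV accuracy, ties preferring fewer features, then lower
    capacity (earlier grid point).  ``max_features`` caps the prefix length.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[family]
    if not grid or not feature_order:
        raise ValueError("empty hyperparameter grid or feature list")
    if max_features is not None:
        feature_order = feature_order[:max_features]
    y = np.asarray(labels)
    best = None
    for n_feat in range(1, len(feature_order) + 1):
        feats = feature_order[:n_feat]
        X = table[feats].to_numpy(dtype=np.float64)
        for gi, params in enumerate(grid):
            acc = _cv_accuracy(family, params, X, y, folds, seed)
            key = (acc, -n_feat, -gi)  # maximize acc; ties -> fewer features, lower capacity
            if best is None or key > best[0]:
                best = (key, ModelSpec(family, params, feats, acc))
    return best[1]


def loocv(
    spec: ModelSpec,
    table: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_boot: int = 2000,
) -> CVResult:
    """Leave-one-out cross-validation of a configured model.

    Each case is predicted by a model refit on the remaining n-1 cases.
    Accuracy CI: percentile bootstrap over the per-case correctness vector;
    AUC over the pooled held-out probabilities with a case bootstrap.
    """
    y = np.asarray(labels)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 cases")
    X = table[spec.features].to_numpy(dtype=np.float64)
    probs = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        est = make_estimator(spec.family, spec.params, X[tr], seed)
        est.fit(X[tr], y[tr])
        cls = list(est.classes_)
        if len(cls) == 1:  # degenerate single-class fold: constant probability
            probs[i] = float(cls[0])
        else:
            probs[i] = est.predict_proba(X[i : i + 1])[0, cls.index(1)]
    preds = (probs >= 0.5).astype(int)
    correct = (preds == y).astype(float)
    accuracy = float(correct.mean())
    auc = float(roc_auc_score(y, probs)) if len(np.unique(y)) == 2 else np.nan
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        acc_boot = correct[rng.integers(0, n, (n_boot, n))].mean(axis=1)
        acc_ci = tuple(np.percentile(acc_boot, [2.5, 97.5]))
        auc_ci = bootstrap_auc_ci(probs, y, n_boot=n_boot, seed=seed)
    else:
        acc_ci = (np.nan, np.nan)
        auc_ci = (np.nan, np.nan)
    conf = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, preds):
        conf[t, p] += 1
    return CVResult(probs, preds, y, accuracy, acc_ci, auc, auc_ci, conf)


def build_signature(
    region: str,
    table: pd.DataFrame,
    labels: np.ndarray,
    feature_order: list[str],
    folds: int = 10,
    seed: int = 0,
    grids: dict | None = None,
    families: tuple = FAMILY_ORDER,
    max_features: int | None = None,
    n_boot: int = 2000,
) -> Signature:
    """Tune all five families, evaluate each by LOOCV, keep the winner.

    Winner: highest LOOCV accuracy; ties by higher LOOCV AUC, then the fixed
    family order LR < SVM < RF < KNN < ANN.  The final model is refit on all
    cases; the out-of-fold LOOCV probabilities are kept as the signature
    scores for fusion.
    """
    grids = grids or DEFAULT_GRIDS
    y = np.asarray(labels)
    results = {}
    specs = {}
    for family in families:
        spec = tune_model(
            family,
            table,
            y,
            feature_order,
            folds=folds,
            seed=seed,
            grid=grids[family],
            max_features=max_features,
        )
        specs[family] = spec
        results[family] = loocv(spec, table, y, seed=seed, n_boot=n_boot)
    rank = {f: i for i, f in enumerate(FAMILY_ORDER)}
    winner = max(
        results,
        key=lambda f: (results[f].accuracy, results[f].auc, -rank[f]),
    )
    spec = specs[winner]
    X = table[spec.features].to_numpy(dtype=np.float64)
    final = make_estimator(winner, spec.params, X, seed)
    final.fit(X, y)
    return Signature(
        region=region,
        spec=spec,
        cv=results[winner],
        model=final,
        oof_scores=results[winner].probabilities,
        candidates=results,
    )


class CollinearityError(ValueError):
    """Signature scores are (near-)perfectly collinear; fusion refused."""


@dataclass
class CombinedModel:
    coef: np.ndarray
    pvalues: dict
    vif: dict
    scores: np.ndarray  # out-of-fold fused probabilities
    auc: float
    auc_ci: tuple
    model: object


def combine_signatures(
    scores1: np.ndarray,
    scores2: np.ndarray,
    labels: np.ndarray,
    names: tuple[str, str] = ("signature1", "signature2"),
    seed: int = 0,
    n_boot: int = 2000,
) -> CombinedModel:
    """Logistic-regression fusion of two signature score columns.

    Inputs should be out-of-fold scores.  Reports per-signature Wald P values
    and VIFs from the multivariate fit; refuses fusion of perfectly collinear
    scores (VIF sentinel +inf).  The combined score for each case comes from
    a leave-one-out refit of the fusion model, and its AUC carries a
    case-bootstrap CI.
    """
    s1 = np.asarray(scores1, dtype=np.float64)
    s2 = np.asarray(scores2, dtype=np.float64)
    y = np.asarray(labels)
    n = len(y)
    if np.allclose(s1, s2) or (np.std(s1) > 0 and np.std(s2) > 0 and abs(np.corrcoef(s1, s2)[0, 1]) > 1 - 1e-10):
        raise CollinearityError("signature scores are perfectly collinear (VIF = inf); fusion refused")
    Xd = sm.add_constant(np.column_stack([s1, s2]))
    try:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        coef = np.asarray(fit.params)
        pvalues = {names[0]: float(fit.pvalues[1]), names[1]: float(fit.pvalues[2])}
    except Exception:  # perfect separation: Wald inference is not identified
        fit = None
        coef = np.full(3, np.nan)
        pvalues = {names[0]: np.nan, names[1]: np.nan}
    vif = {
        names[0]: float(variance_inflation_factor(Xd, 1)),
        names[1]: float(variance_inflation_factor(Xd, 2)),
    }
    # leak-free combined scores by leave-one-out refit of the fusion LR
    X2 = np.column_stack([s1, s2])
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        clf = LogisticRegression(max_iter=5000)
        clf.fit(X2[tr], y[tr])
        scores[i] = clf.predict_proba(X2[i : i + 1])[0, list(clf.classes_).index(1)]
    auc = float(roc_auc_score(y, scores))
    auc_ci = bootstrap_auc_ci(scores, y, n_boot=n_boot, seed=seed)
    return CombinedModel(
        coef=coef,
        pvalues=pvalues,
        vif=vif,
        scores=scores,
        auc=auc,
        auc_ci=auc_ci,
        model=fit,
    )


def threshold_analysis(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Accuracy, sensitivity, specificity, Youden index and F1 at 101 thresholds.

    A case scores positive when its probability is >= the threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must be probabilities in [0, 1]")
    y = np.asarray(labels)
    rows = []
    for t in np.round(np.arange(0, 1.001, 0.01), 2):
        pred = (scores >= t).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        sens = tp / (tp + fn) if (tp + fn) else 0.0
        spec = tn / (tn + fp) if (tn + fp) else 0.0
        prec = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
        rows.append(
            {
                "threshold": t,
                "accuracy": (tp + tn) / len(y),
                "sensitivity": sens,
                "specificity": spec,
                "youden": sens + spec - 1.0,
                "f1": f1,
            }
        )
    return pd.DataFrame(rows)


def majority_class_loocv_accuracy(labels: np.ndarray) -> float:
    """LOOCV accuracy of the constant majority-class predictor."""
    y = np.asarray(labels)
    n = len(y)
    correct = 0
    for i in range(n):
        rest = np.delete(y, i)
        counts = np.bincount(rest, minlength=2)
        # ties predict class 0 (non-benefit), the cohort's larger class
        pred = int(np.argmax(counts))
        correct += int(pred == y[i])
    return correct / n
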