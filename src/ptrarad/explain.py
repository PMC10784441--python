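"""Shapley-value model explanation and descriptive cohort analytics.

Two independent attribution routes are provided: exact Shapley enumeration
over all feature coalitions (feasible up to ~15 features; absent features
are marginalized over a background set), and the KernelSHAP estimator — a
weighted least squares fit over coalition indicators under the Shapley
kernel with the efficiency constraint imposed.  On small feature counts the
two agree to numerical precision, which the test suite exploits.

Also here: volcano-plot tables from the univariate screen, the hierarchical
radiomics heatmap report (cophenetic correlation, adjusted Rand index of the
2-cluster case partition against outcome labels) and PCA projections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

MAX_EXACT_FEATURES = 15


@dataclass
class ShapExplanation:
    """Per-case, per-feature Shapley attributions for one model."""

    base_value: float  # expected model output over the background set
    values: np.ndarray  # (n_cases, n_features)
    feature_names: list
    predictions: np.ndarray  # model output per explained case
    mode: str = "exact"

    def global_importance(self) -> pd.Series:
        imp = np.abs(self.values).mean(axis=0)
        return pd.Series(imp, index=self.feature_names).sort_values(ascending=False)


def _coalition_values(predict_fn, x: np.ndarray, background: np.ndarray, masks: np.ndarray):
    """Model expectation for each coalition mask, marginalizing absent features.

    ``masks`` is (n_coalitions, d) boolean; present features take the
    explained case's value, absent ones are averaged over the background.
    """
    m, d = background.shape
    n_c = masks.shape[0]
    tiled = np.repeat(background[None, :, :], n_c, axis=0)  # (n_c, m, d)
    tiled[:, :, :] = np.where(masks[:, None, :], x[None, None, :], tiled)
    flat = tiled.reshape(n_c * m, d)
    preds = np.asarray(predict_fn(flat), dtype=np.float64).reshape(n_c, m)
    return preds.mean(axis=1)


def shapley_values_exact(
    predict_fn, X: np.ndarray, background: np.ndarray, feature_names=None
) -> ShapExplanation:
    """Exact Shapley attribution by enumeration over all 2^d coalitions.

    Satisfies the efficiency, symmetry and dummy axioms by construction:
    phi_i = sum over S not containing i of |S|!(d-|S|-1)!/d! *
    (v(S + i) - v(S)), with v(S) the background-marginalized expectation.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.size == 0:
        raise ValueError("empty background set")
    d = X.shape[1]
    if d > MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_FEATURES} features")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    n_sub = 1 << d
    masks = (np.arange(n_sub)[:, None] >> np.arange(d)[None, :]) & 1
    masks = masks.astype(bool)
    sizes = masks.sum(axis=1)
    w = np.array(
        [math.factorial(s) * math.factorial(d - s - 1) / math.factorial(d) for s in range(d)]
    )
    values = np.zeros((X.shape[0], d))
    preds = np.zeros(X.shape[0])
    base = None
    for ci, x in enumerate(X):
        v = _coalition_values(predict_fn, x, background, masks)
        if base is None:
            base = float(v[0])  # empty coalition; identical for every case
        preds[ci] = v[-1]  # full coalition
        for i in range(d):
            has_i = masks[:, i]
            s_without = np.flatnonzero(~has_i)
            partners = s_without | (1 << i)
            values[ci, i] = np.sum(w[sizes[s_without]] * (v[partners] - v[s_without]))
    return ShapExplanation(base, values, list(feature_names), preds, mode="exact")


def shapley_values_kernel(
    predict_fn,
    X: np.ndarray,
    background: np.ndarray,
    feature_names=None,
    n_samples: int | None = None,
    seed: int = 0,
) -> ShapExplanation:
    """KernelSHAP: weighted least squares over coalition indicators.

    Uses all 2^d - 2 proper coalitions when feasible (exact kernel solution),
    or ``n_samples`` kernel-weighted draws otherwise.  The efficiency
    constraint (attributions sum to prediction minus base) is imposed by
    eliminating the last coefficient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.size == 0:
        raise ValueError("empty background set")
    d = X.shape[1]
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(d)]
    full = (1 << d) - 2
    if n_samples is None or n_samples >= full:
        codes = np.arange(1, (1 << d) - 1)
    else:
        rng = np.random.default_rng(seed)
        sizes = np.arange(1, d)
        size_w = (d - 1) / (sizes * (d - sizes))
        size_w /= size_w.sum()
        codes = []
        for _ in range(n_samples):
            s = rng.choice(sizes, p=size_w)
            idx = rng.choice(d, size=s, replace=False)
            codes.append(int(np.sum(1 << idx)))
        codes = np.asarray(codes)
    Z = ((codes[:, None] >> np.arange(d)[None, :]) & 1).astype(bool)
    sizes = Z.sum(axis=1)
    kw = (d - 1) / (np.array([comb(d, s) for s in sizes]) * sizes * (d - sizes))

    empty_full = np.vstack([np.zeros(d, bool), np.ones(d, bool)])
    values = np.zeros((X.shape[0], d))
    preds = np.zeros(X.shape[0])
    base = None
    for ci, x in enumerate(X):
        v_ef = _coalition_values(predict_fn, x, background, empty_full)
        if base is None:
            base = float(v_ef[0])
        fx = float(v_ef[1])
        preds[ci] = fx
        v = _coalition_values(predict_fn, x, background, Z)
        # eliminate phi_{d-1} via the efficiency constraint
        y = v - base - Z[:, -1] * (fx - base)
        A = Z[:, :-1].astype(np.float64) - Z[:, -1:].astype(np.float64)
        Aw = A * kw[:, None]
        phi_rest, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
        phi_last = (fx - base) - phi_rest.sum()
        values[ci] = np.concatenate([phi_rest, [phi_last]])
    return ShapExplanation(base, values, list(feature_names), preds, mode="kernel")


def shapley_values(
    model_predict, X, background, feature_names=None, mode: str = "auto", **kw
) -> ShapExplanation:
    """Dispatch to exact enumeration (d <= 15) or the kernel estimator."""
    d = np.atleast_2d(X).shape[1]
    if mode == "exact" or (mode == "auto" and d <= MAX_EXACT_FEATURES):
        return shapley_values_exact(model_predict, X, background, feature_names)
    return shapley_values_kernel(model_predict, X, background, feature_names, **kw)


def summary_and_force_data(expl: ShapExplanation) -> dict:
    """Plot-ready tables: global importance ranking and per-case force data.

    Force entries are signed contributions sorted by magnitude; their sum
    plus the base value reproduces each case's prediction (efficiency).
    Contributions pushing the output below the base value point toward the
    benefit prediction under the cohort's sign convention.
    """
    importance = expl.global_importance()
    force = []
    for ci in range(expl.values.shape[0]):
        order = np.argsort(-np.abs(expl.values[ci]))
        force.append(
            pd.DataFrame(
                {
                    "feature": [expl.feature_names[i] for i in order],
                    "contribution": expl.values[ci][order],
                }
            ).assign(case=ci, base_value=expl.base_value, prediction=expl.predictions[ci])
        )
    return {"importance": importance, "force": pd.concat(force, ignore_index=True)}


# ---------------------------------------------------------------------------
# descriptive analytics
# ---------------------------------------------------------------------------


def volcano_data(
    screen: pd.DataFrame, handcrafted_names: set | None = None, effect: str = "smd"
) -> pd.DataFrame:
    """One volcano point per screened feature: effect size vs -log10 P.

    ``effect`` is the signed standardized mean difference (default) or
    ``"auc"`` for AUC - 0.5.  The family flag separates handcrafted from
    deep (D-map) features; by default deep features are those named like
    ``D<k>_...``.
    """
    import re

    eff = screen["smd"] if effect == "smd" else screen["auc"] - 0.5
    if handcrafted_names is not None:
        family = ["handcrafted" if f in handcrafted_names else "deep" for f in screen.index]
    else:
        family = [
            "deep" if re.match(r"^D\d+_", f) else "handcrafted" for f in screen.index
        ]
    return pd.DataFrame(
        {
            "feature": screen.index,
            "effect": np.asarray(eff, dtype=np.float64),
            "neg_log10_p": -np.log10(np.clip(screen["p"].to_numpy(), 1e-300, None)),
            "family": family,
            "significant": screen["significant"].to_numpy(),
        }
    ).reset_index(drop=True)


@dataclass
class ClusterReport:
    case_linkage: np.ndarray
    feature_linkage: np.ndarray
    cophenetic_correlation: float
    ari: float
    case_partition: np.ndarray


def heatmap_cluster(table: pd.DataFrame, labels: np.ndarray, k: int = 2) -> ClusterReport:
    """Average-linkage hierarchical clustering of cases and features.

    Distance is correlation distance (1 - Pearson).  Reports the cophenetic
    correlation of the case tree against the input distances and the
    adjusted Rand index of the k=2 case partition versus outcome labels.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 cases")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    dcases = pdist(table.to_numpy(dtype=np.float64), metric="correlation")
    dfeats = pdist(table.to_numpy(dtype=np.float64).T, metric="correlation")
    # correlation distance can dip microscopically below 0 in floating point
    dcases = np.clip(dcases, 0, None)
    dfeats = np.clip(dfeats, 0, None)
    zc = hierarchy.linkage(dcases, method="average")
    zf = hierarchy.linkage(dfeats, method="average")
    coph, _ = hierarchy.cophenet(zc, dcases)
    part = hierarchy.fcluster(zc, t=k, criterion="maxclust")
    return ClusterReport(
        case_linkage=zc,
        feature_linkage=zf,
        cophenetic_correlation=float(coph),
        ari=float(adjusted_rand_score(np.asarray(labels), part)),
        case_partition=part,
    )


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_components, n_features), orthonormal rows
    scores: np.ndarray  # (n_cases, n_components)
    explained_variance_ratio: np.ndarray


def pca_project(table: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Centered PCA projection of a (z-scored) feature table."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    p = PCA(n_components=min(n_components, min(table.shape) - 1))
    scores = p.fit_transform(table.to_numpy(dtype=np.float64))
    return PCAResult(
        loadings=p.components_,
        scores=scores,
        explained_variance_ratio=p.explained_variance_ratio_,
    )
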