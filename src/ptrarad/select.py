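"""Feature screening, consensus clustering and LASSO shrinkage.

The selection funnel mirrors standard radiomics practice on small cohorts:
z-score normalization; a univariate screen routed by per-class Shapiro-Wilk
normality (t-test if both classes are normal, Mann-Whitney U otherwise) with
a permissive P < 0.1 retention gate; consensus clustering of the retained
features with partitioning-around-medoids (PAM) on 1 - |Spearman rho|
distances, resampling features at a 50% rate 500 times to score how stably
each feature co-clusters with its subset ("consensus value"); the number of
subsets k grows from 2 until every feature correlates with its subset medoid
at |rho| > 0.6; and finally an L1-penalized logistic path whose strength is
chosen by stratified 10-fold cross-validated AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

SHAPIRO_ALPHA = 0.05
RETAIN_P = 0.1
SIGNIF_P = 0.05
MEDOID_RHO = 0.6


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def zscore(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scoring (population SD); zero-variance columns are dropped.

    'Zero variance' uses a relative tolerance: a column whose SD is at
    floating-point-noise level relative to its magnitude is constant in any
    meaningful sense and would otherwise poison rank statistics downstream.
    """
    sd = table.std(ddof=0)
    scale = table.abs().max().clip(lower=1.0)
    dead = sd[sd <= 1e-10 * scale].index.tolist()
    if len(dead) == len(table.columns):
        raise ValueError("all columns are constant; nothing to normalize")
    if dead:
        warnings.warn(f"dropping {len(dead)} zero-variance columns: {dead[:5]}...")
        table = table.drop(columns=dead)
        sd = sd.drop(dead)
    return (table - table.mean()) / sd


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------


def feature_pvalue(a: np.ndarray, b: np.ndarray, force: str | None = None) -> tuple[str, float]:
    """Two-sided group-difference P value with Shapiro-Wilk routing.

    Both classes normal at alpha 0.05 -> independent-samples t-test;
    otherwise (or with any class smaller than 3, where normality is
    undefined) -> Mann-Whitney U.  ``force`` overrides the routing.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    test = force
    if test is None:
        if len(a) < 3 or len(b) < 3:
            test = "mannwhitney"
        else:
            try:
                normal = stats.shapiro(a).pvalue > SHAPIRO_ALPHA and (
                    stats.shapiro(b).pvalue > SHAPIRO_ALPHA
                )
            except ValueError:
                normal = False
            test = "t" if normal else "mannwhitney"
    if test == "t":
        p = stats.ttest_ind(a, b).pvalue
    else:
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return test, float(p)


def bootstrap_auc_ci(
    values: np.ndarray, labels: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI of the rank AUC (vectorized midranks).

    Case resampling; resamples missing a class are dropped.  AUC per
    resample uses the Mann-Whitney identity with average ranks, so ties
    count 1/2 exactly as in the point estimate.
    """
    values = np.asarray(values, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    n = len(values)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, (n_boot, n))
    ys = y[idx]
    ranks = stats.rankdata(values[idx], method="average", axis=1)
    n1 = ys.sum(axis=1)
    n0 = n - n1
    ok = (n1 > 0) & (n0 > 0)
    aucs = ((ranks * ys).sum(axis=1)[ok] - n1[ok] * (n1[ok] + 1) / 2) / (n1[ok] * n0[ok])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def feature_auc(
    values: np.ndarray, labels: np.ndarray, n_boot: int = 2000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Rank-based AUC (ties count 1/2) with a percentile-bootstrap 95% CI."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, values))
    return auc, bootstrap_auc_ci(values, labels, n_boot=n_boot, seed=seed)


def univariate_screen(
    table: pd.DataFrame,
    labels: np.ndarray,
    compute_auc: bool = True,
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature group comparison; retain P < 0.1, flag significance at 0.05.

    Returns a frame indexed by feature with columns: test, p, smd (signed
    standardized mean difference, positive when the benefit class is higher),
    auc (and CI bounds when ``compute_auc``), retained, significant.
    """
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be non-empty")
    rows = []
    for j, name in enumerate(table.columns):
        v = table[name].to_numpy(dtype=np.float64)
        a, b = v[pos], v[~pos]
        test, p = feature_pvalue(a, b)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        smd = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        row = {
            "feature": name,
            "test": test,
            "p": p,
            "smd": float(smd),
            "retained": p < RETAIN_P,
            "significant": p < SIGNIF_P,
        }
        if compute_auc:
            auc, (lo, hi) = feature_auc(v, labels, n_boot=n_boot, seed=seed + j)
            row.update({"auc": auc, "auc_lo": lo, "auc_hi": hi})
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# PAM and consensus clustering
# ---------------------------------------------------------------------------


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    Greedy BUILD then steepest-descent SWAP; deterministic, ties toward the
    lower index.  Returns ``(medoid_indices, assignment)``.
    """
    dist = np.asarray(dist, dtype=np.float64)
    m = dist.shape[0]
    if not 1 <= k <= m:
        raise ValueError("need 1 <= k <= number of items")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        nearest = dist[medoids].min(axis=0)
        totals = np.minimum(nearest[None, :], dist).sum(axis=1)
        totals[medoids] = np.inf
        medoids.append(int(np.argmin(totals)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        dmed = dist[medoids]  # (k, m)
        order = np.argsort(dmed, axis=0)
        near_pos = order[0]
        d1 = dmed[near_pos, np.arange(m)]
        d2 = dmed[order[1], np.arange(m)] if k > 1 else np.full(m, np.inf)
        best_delta, best_swap = -1e-12, None
        non_med = np.setdiff1d(np.arange(m), medoids)
        if len(non_med) == 0:
            break
        dh = dist[non_med]  # (n_h, m)
        for pos in range(k):
            mine = near_pos == pos
            new_d = np.where(mine[None, :], np.minimum(d2[None, :], dh), np.minimum(d1[None, :], dh))
            deltas = new_d.sum(axis=1) - d1.sum()
            h_best = int(np.argmin(deltas))
            if deltas[h_best] < best_delta:
                best_delta = float(deltas[h_best])
                best_swap = (pos, non_med[h_best])
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        medoids = np.sort(medoids)
    assignment = np.argmin(dist[medoids], axis=0)
    assignment[medoids] = np.arange(k)  # medoids belong to their own cluster
    return medoids, assignment


def _pam_collapsed(dist: np.ndarray, k: int) -> np.ndarray:
    """PAM assignment that never splits zero-distance (indistinguishable) items.

    Items at distance 0 are collapsed to one representative before
    clustering; k is capped at the number of distinguishable items.  With
    real-valued distances this reduces to plain PAM.
    """
    from scipy.sparse.csgraph import connected_components

    adj = dist <= 1e-12
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp == dist.shape[0]:
        _, assign = pam(dist, min(k, dist.shape[0]))
        return assign
    reps = np.array([np.flatnonzero(comp == c)[0] for c in range(n_comp)])
    _, rep_assign = pam(dist[np.ix_(reps, reps)], min(k, n_comp))
    return rep_assign[comp]


def spearman_distance(table: pd.DataFrame) -> np.ndarray:
    """1 - |Spearman rho| between feature columns (redundancy is sign-agnostic)."""
    if table.shape[1] == 1:
        return np.zeros((1, 1))
    rho = stats.spearmanr(table.to_numpy()).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    d = 1.0 - np.abs(rho)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


@dataclass
class ConsensusResult:
    """Feature-subset assignment with per-feature consensus values and medoids."""

    k: int
    features: list
    assignment: dict = field(default_factory=dict)  # feature -> subset index
    consensus: dict = field(default_factory=dict)  # feature -> co-clustering probability
    medoids: list = field(default_factory=list)  # one feature name per subset
    resamples: int = 0
    rate: float = 0.5

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [self.assignment[f] for f in self.features],
                "consensus": [self.consensus[f] for f in self.features],
                "is_medoid": [f in self.medoids for f in self.features],
            },
            index=self.features,
        )


def consensus_cluster(
    table: pd.DataFrame,
    k: int,
    resamples: int = 500,
    rate: float = 0.5,
    seed: int = 0,
) -> ConsensusResult:
    """PAM consensus clustering of feature columns.

    The reference partition is full-data PAM at k.  Each resample draws
    ``rate`` of the features without replacement and re-clusters them; a
    feature's consensus value is the empirical probability of landing in the
    same cluster as its reference-subset peers, over the resamples containing
    both.  The subset medoid is its maximum-consensus feature (ties broken
    alphabetically); singleton subsets have consensus 1 by convention.
    """
    feats = list(table.columns)
    m = len(feats)
    if k > m:
        raise ValueError("k exceeds the number of features")
    dist = spearman_distance(table)
    assign = _pam_collapsed(dist, k)
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(np.ceil(rate * m)))
    co = np.zeros((m, m))
    cnt = np.zeros((m, m))
    for _ in range(resamples):
        idx = np.sort(rng.choice(m, size=n_sub, replace=False))
        sub_assign = _pam_collapsed(dist[np.ix_(idx, idx)], k)
        same = sub_assign[:, None] == sub_assign[None, :]
        cnt[np.ix_(idx, idx)] += 1.0
        co[np.ix_(idx, idx)] += same
    consensus = {}
    for i, f in enumerate(feats):
        peers = [j for j in range(m) if j != i and assign[j] == assign[i]]
        if not peers:
            consensus[f] = 1.0
            continue
        num = co[i, peers]
        den = cnt[i, peers]
        ok = den > 0
        consensus[f] = float((num[ok] / den[ok]).mean()) if ok.any() else 1.0
    medoids = []
    for c in range(k):
        members = sorted(
            (f for i, f in enumerate(feats) if assign[i] == c),
            key=lambda f: (-consensus[f], f),
        )
        if members:
            medoids.append(members[0])
    return ConsensusResult(
        k=k,
        features=feats,
        assignment={f: int(assign[i]) for i, f in enumerate(feats)},
        consensus=consensus,
        medoids=medoids,
        resamples=resamples,
        rate=rate,
    )


def choose_k_and_medoids(
    table: pd.DataFrame,
    resamples: int = 500,
    rate: float = 0.5,
    seed: int = 0,
    search_resamples: int | None = None,
    min_rho: float = MEDOID_RHO,
) -> ConsensusResult:
    """Smallest k >= 2 whose subsets all correlate with their medoid at |rho| > 0.6.

    ``search_resamples`` (default: ``resamples``) can lower the resampling
    effort during the k search; the accepted k is re-run at full effort.  If
    no k < m satisfies the criterion, every feature becomes its own singleton
    medoid (k = m) with a warning.
    """
    m = table.shape[1]
    if m < 2:
        raise ValueError("need at least 2 features")
    rho = 1.0 - spearman_distance(table)  # |Spearman| between feature columns
    feats = list(table.columns)
    sr = resamples if search_resamples is None else search_resamples
    for k in range(2, m):
        res = consensus_cluster(table, k, resamples=sr, rate=rate, seed=seed)
        ok = True
        for i, f in enumerate(feats):
            med = res.medoids[res.assignment[f]]
            if rho[i, feats.index(med)] <= min_rho:
                ok = False
                break
        if ok:
            if sr != resamples:
                res = consensus_cluster(table, k, resamples=resamples, rate=rate, seed=seed)
            return res
    warnings.warn("medoid-correlation criterion unreachable; returning all-singleton partition")
    return ConsensusResult(
        k=m,
        features=feats,
        assignment={f: i for i, f in enumerate(feats)},
        consensus={f: 1.0 for f in feats},
        medoids=feats,
        resamples=resamples,
        rate=rate,
    )


# ---------------------------------------------------------------------------
# LASSO-logistic selection
# ---------------------------------------------------------------------------


@dataclass
class LassoPath:
    strengths: np.ndarray  # inverse-regularization grid (sklearn C)
    coefs: np.ndarray  # (len(grid), n_features)
    cv_auc: np.ndarray
    chosen: float
    selected: list  # feature names, by descending |coefficient|
    coef_map: dict
    skipped: list = field(default_factory=list)


def lasso_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    c_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    seed: int = 0,
) -> LassoPath:
    """L1-penalized logistic path; strength chosen by stratified CV AUC.

    Ties in CV AUC break toward the stronger penalty (sparser model).  The
    final model is refit on all cases at the chosen strength; ``selected``
    lists its nonzero-coefficient features by descending |coefficient|.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    if c_grid is None:
        c_grid = np.logspace(-2, 2, 50)
    X = table.to_numpy(dtype=np.float64)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    cv_auc = np.full(len(c_grid), -np.inf)
    coefs = np.zeros((len(c_grid), X.shape[1]))
    skipped = []
    for gi, c in enumerate(c_grid):
        aucs = []
        try:
            for tr, te in splits:
                clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, max_iter=2000)
                clf.fit(X[tr], y[tr])
                prob = clf.predict_proba(X[te])[:, 1]
                if len(np.unique(y[te])) == 2:
                    aucs.append(roc_auc_score(y[te], prob))
            full = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c, max_iter=2000)
            full.fit(X, y)
            coefs[gi] = full.coef_[0]
            cv_auc[gi] = float(np.mean(aucs)) if aucs else -np.inf
        except Exception:  # noqa: BLE001 - non-convergence: flag and skip
            skipped.append(float(c))
    # ties break toward the stronger penalty (the grid is ascending in C)
    best = int(np.flatnonzero(cv_auc == cv_auc.max())[0])
    chosen = float(c_grid[best])
    coef = coefs[best]
    order = np.argsort(-np.abs(coef))
    selected = [table.columns[i] for i in order if abs(coef[i]) > 0]
    return LassoPath(
        strengths=np.asarray(c_grid),
        coefs=coefs,
        cv_auc=cv_auc,
        chosen=chosen,
        selected=selected,
        coef_map={table.columns[i]: float(coef[i]) for i in range(len(coef))},
        skipped=skipped,
    )
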