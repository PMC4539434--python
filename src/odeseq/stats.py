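"""Group comparisons on functional features.

Contains the two-sample Hotelling T^2 test on pooled FPCA scores of
response curves (chi-square reference with k degrees of freedom), an
L1-penalized logistic classifier fitted by iteratively reweighted
coordinate descent with an unpenalized intercept, cross-validated
classification metrics, and agglomerative clustering of feature rows with
Newick export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from scipy import stats as sps

from .fpca import FeatureMatrix, fit_fpca

__all__ = [
    "HotellingResult",
    "ClassifierModel",
    "ClassificationReport",
    "ClusterResult",
    "hotelling_response_test",
    "hotelling_from_scores",
    "lasso_logistic_fit",
    "kkt_residual",
    "classify_cv",
    "cluster_features",
]


# ---------------------------------------------------------------------------
# Hotelling T^2 on response-curve scores


@dataclass
class HotellingResult:
    t2: float
    k: int
    p_value: float
    mean_scores_1: np.ndarray
    mean_scores_2: np.ndarray
    pooled_cov: np.ndarray
    lam_matrix: np.ndarray
    pseudo_inverse_used: bool = False
    reference: str = "chi2"


def hotelling_response_test(
    responses_1: np.ndarray,
    responses_2: np.ndarray,
    t: np.ndarray,
    k: int = 3,
    reference: str = "chi2",
) -> HotellingResult:
    """Two-sample Hotelling T^2 test on pooled FPCA scores of curves.

    Both groups are expanded in eigenfunctions fitted on the pooled sample
    so they share one coordinate system; with group mean score vectors
    xi, eta, pooled covariance S and ``Lam = (1/N1 + 1/N2) S``::

        T2 = (xi - eta)^T Lam^{-1} (xi - eta)

    referred to a chi-square law with ``k`` degrees of freedom (the default
    reference; ``reference="f"`` uses the finite-sample Hotelling-F law
    instead).  A singular ``Lam`` falls back to a generalized inverse with a
    warning, since that inflates false positive rates.
    """
    R = np.atleast_2d(np.asarray(responses_1, dtype=float))
    S_curves = np.atleast_2d(np.asarray(responses_2, dtype=float))
    n1, n2 = R.shape[0], S_curves.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 response curves")
    if reference not in ("chi2", "f"):
        raise ValueError(f"unknown reference {reference!r}")
    pooled = np.vstack([R, S_curves])
    model = fit_fpca(pooled, t, n_components=k)
    return hotelling_from_scores(model.scores(R), model.scores(S_curves), reference)


def hotelling_from_scores(
    xi: np.ndarray, eta: np.ndarray, reference: str = "chi2"
) -> HotellingResult:
    """Hotelling T^2 from per-sample score vectors (n_i x k) directly."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    if xi.shape[1] != eta.shape[1]:
        raise ValueError("score dimensions differ between groups")
    n1, n2, k = xi.shape[0], eta.shape[0], xi.shape[1]
    xbar, ybar = xi.mean(axis=0), eta.mean(axis=0)
    Xc, Yc = xi - xbar, eta - ybar
    S = (Xc.T @ Xc + Yc.T @ Yc) / (n1 + n2 - 2)
    S = 0.5 * (S + S.T)
    Lam = (1.0 / n1 + 1.0 / n2) * S
    diff = xbar - ybar
    pinv_used = False
    try:
        cond = np.linalg.cond(Lam)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        sol = np.linalg.solve(Lam, diff)
    except np.linalg.LinAlgError:
        warnings.warn(
            "score covariance is singular; using a generalized inverse — "
            "this will inflate the false positive rates",
            RuntimeWarning,
        )
        sol = np.linalg.pinv(Lam) @ diff
        pinv_used = True
    t2 = float(diff @ sol)
    if t2 < 0:
        t2 = 0.0
    if reference == "chi2":
        p = float(sps.chi2.sf(t2, df=k))
    else:
        df2 = n1 + n2 - 1 - k
        if df2 < 1:
            raise ValueError("too few samples for the F reference")
        f_stat = t2 * df2 / (k * (n1 + n2 - 2))
        p = float(sps.f.sf(f_stat, k, df2))
    return HotellingResult(
        t2=t2,
        k=k,
        p_value=p,
        mean_scores_1=xbar,
        mean_scores_2=ybar,
        pooled_cov=S,
        lam_matrix=Lam,
        pseudo_inverse_used=pinv_used,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# L1-penalized logistic regression


@dataclass
class ClassifierModel:
    intercept: float
    coef: np.ndarray  # on the standardized feature scale
    lam: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    converged: bool = True

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self.feature_mean) / self.feature_scale
        return self.intercept + Xs @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def lasso_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> ClassifierModel:
    """Maximize the log-likelihood minus ``lam * ||beta||_1``.

    Features are standardized internally and the intercept is never
    penalized.  Fitting alternates a local quadratic (IRLS) approximation
    with coordinate descent, stopping when the stationarity conditions

        |x_j^T (y - pi)| <= lam          for beta_j = 0
        x_j^T (y - pi) = lam sign(beta_j) for beta_j != 0

    hold within ``tol`` (checked on the standardized design).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y disagree on sample count")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])) or classes.size != 2:
        raise ValueError("y must contain both classes, coded 0/1")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    beta = np.zeros(p)
    beta0 = float(np.log(y.mean() / (1.0 - y.mean())))
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = beta0 + Xs @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        if kkt_residual_raw(Xs, y, pi, beta, lam) < tol:
            converged = True
            break
        w = np.clip(pi * (1.0 - pi), 1e-6, None)
        z = eta + (y - pi) / w
        # one full cycle of coordinate descent on the weighted LS problem
        r = z - beta0 - Xs @ beta
        for j in range(p):
            r += Xs[:, j] * beta[j]
            num = float((w * Xs[:, j]) @ r)
            den = float(w @ (Xs[:, j] ** 2))
            beta[j] = _soft_threshold(num, lam) / den
            r -= Xs[:, j] * beta[j]
        beta0 += float(w @ r) / float(w.sum())
        r = z - beta0 - Xs @ beta  # refresh after intercept move
        if np.max(np.abs(beta)) > 40.0 or abs(beta0) > 40.0:
            separated = True
            break
    if separated:
        warnings.warn(
            "coefficients diverging (data may be separable at this lam); "
            "returning the capped iterate",
            RuntimeWarning,
        )
    elif not converged:
        warnings.warn(
            f"lasso_logistic_fit: stationarity not reached in {max_iter} "
            "iterations",
            RuntimeWarning,
        )
    return ClassifierModel(
        intercept=beta0,
        coef=beta,
        lam=lam,
        feature_mean=mu,
        feature_scale=sd,
        converged=converged,
    )


def kkt_residual_raw(
    Xs: np.ndarray, y: np.ndarray, pi: np.ndarray, beta: np.ndarray, lam: float
) -> float:
    g = Xs.T @ (y - pi)
    res = 0.0
    for j in range(beta.size):
        if beta[j] == 0.0:
            res = max(res, max(0.0, abs(g[j]) - lam))
        else:
            res = max(res, abs(g[j] - lam * np.sign(beta[j])))
    # intercept is unpenalized: its score must vanish
    res = max(res, abs(float(np.sum(y - pi))))
    return res


def kkt_residual(model: ClassifierModel, X: np.ndarray, y: np.ndarray) -> float:
    """Stationarity residual of a fitted model on its own standardized design."""
    Xs = (np.atleast_2d(X) - model.feature_mean) / model.feature_scale
    pi = model.predict_proba(X)
    return kkt_residual_raw(Xs, np.asarray(y, dtype=float), pi, model.coef, model.lam)


# ---------------------------------------------------------------------------
# cross-validated classification


@dataclass
class ClassificationReport:
    tp: int
    fn: int
    tn: int
    fp: int
    fold_lambdas: list[float] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fn + self.tn + self.fp
        return (self.tp + self.tn) / total if total else float("nan")


def _stratified_fold_ids(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold_of = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} samples, fewer than {k} folds"
            )
        order = rng.permutation(idx.size)
        for pos, j in enumerate(order):
            fold_of[idx[j]] = pos % k
    return fold_of


def classify_cv(
    Z: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    lambda_grid: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0),
    seed: int = 0,
    inner_folds: int = 3,
    threshold: float = 0.5,
) -> ClassificationReport:
    """Stratified k-fold classification of binary labels from features.

    Per outer fold the penalty is chosen by inner stratified CV accuracy
    (ties broken toward the larger, sparser penalty); test samples are
    classified at the given probability threshold and confusion counts are
    aggregated over folds.  Sensitivity is the fraction of class-1 samples
    recovered, specificity the fraction of class-0 samples.  Deterministic
    given ``seed``.
    """
    X = Z.Z if isinstance(Z, FeatureMatrix) else np.atleast_2d(np.asarray(Z, float))
    y = np.asarray(y, dtype=int).ravel()
    rng = np.random.default_rng(seed)
    fold_of = _stratified_fold_ids(y, k_folds, rng)
    grid = sorted(lambda_grid)
    tp = fn = tn = fp = 0
    chosen = []
    for f in range(k_folds):
        tr, te = fold_of != f, fold_of == f
        Xtr, ytr = X[tr], y[tr]
        if len(grid) == 1:
            lam_star = grid[0]
        else:
            inner = _stratified_fold_ids(ytr, inner_folds, rng)
            best_acc, lam_star = -1.0, grid[-1]
            for lam in grid:
                correct = 0
                for g in range(inner_folds):
                    m = lasso_logistic_fit(Xtr[inner != g], ytr[inner != g], lam)
                    correct += int(
                        np.sum(m.predict(Xtr[inner == g], threshold) == ytr[inner == g])
                    )
                acc = correct / ytr.size
                if acc >= best_acc:  # ties favor larger lam (grid is ascending)
                    best_acc, lam_star = acc, lam
        chosen.append(lam_star)
        model = lasso_logistic_fit(Xtr, ytr, lam_star)
        pred = model.predict(X[te], threshold)
        truth = y[te]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp, fold_lambdas=chosen)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass
class ClusterResult:
    labels: pd.Series  # cluster id per row, indexed by id
    linkage_matrix: np.ndarray
    newick: str


def _tree_to_newick(node, ids: list[str]) -> str:
    if node.is_leaf():
        return ids[node.id]
    parts = []
    for child in (node.get_left(), node.get_right()):
        length = max(node.dist - child.dist, 0.0)
        parts.append(f"{_tree_to_newick(child, ids)}:{length:.17g}")
    return f"({','.join(parts)})"


def cluster_features(
    Z: FeatureMatrix | np.ndarray,
    n_groups: int,
    metric: str = "euclidean",
    linkage_method: str = "average",
    ids: list[str] | None = None,
) -> ClusterResult:
    """Agglomerative clustering of feature rows, cut into ``n_groups``.

    Supports Euclidean and correlation distances; the dendrogram is exported
    as a Newick string.  Rows with zero variance are rejected under the
    correlation metric (their correlation distance is undefined), naming the
    offending id.
    """
    if isinstance(Z, FeatureMatrix):
        X = Z.Z
        if ids is None:
            ids = Z.sample_ids
    else:
        X = np.atleast_2d(np.asarray(Z, dtype=float))
    n = X.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    if n < n_groups:
        raise ValueError(f"cannot cut {n} rows into {n_groups} groups")
    if metric == "correlation":
        flat = np.flatnonzero(X.std(axis=1) == 0)
        if flat.size:
            raise ValueError(
                f"constant feature row(s) under the correlation metric: "
                f"{[ids[i] for i in flat]}"
            )
    D = pdist(X, metric=metric)
    Lk = linkage(D, method=linkage_method)
    labels = fcluster(Lk, t=n_groups, criterion="maxclust")
    tree = to_tree(Lk)
    newick = _tree_to_newick(tree, list(ids)) + ";"
    return ClusterResult(
        labels=pd.Series(labels, index=list(ids), name="cluster"),
        linkage_matrix=Lk,
        newick=newick,
    )
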