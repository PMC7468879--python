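"""Multivariate chemometrics for repeated-measures metabolomics.

Implements the discrimination workflow used on normalized NMR bucket
matrices: a multilevel (within-subject) variance split for repeated
measures, Wold-style orthogonal signal correction (OSC), mean-centering
with Pareto or unit-variance scaling, PCA, NIPALS PLS-DA and its sparse
variant (soft-thresholded X-weights, keepX variables per component), VIP
scores, Q2 by grouped cross-validation, label-permutation tests, and
Kruskal–Wallis screening with Benjamini–Hochberg FDR control.

All weight/loading vectors follow one sign convention: the element of
largest magnitude is made positive, so fits are reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, KFold
from statsmodels.stats.multitest import multipletests

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 1000


class ChemometricsError(ValueError):
    """Invalid input to a chemometrics operation."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge within its iteration budget."""


def _orient(w: np.ndarray) -> float:
    """Sign that makes the largest-magnitude element of ``w`` positive."""
    j = int(np.argmax(np.abs(w)))
    return 1.0 if w[j] >= 0 else -1.0


# ---------------------------------------------------------------------------
# Multilevel split
# ---------------------------------------------------------------------------

@dataclass
class MultilevelSplit:
    """Between/within-subject decomposition of a repeated-measures matrix.

    ``X = grand_mean + between + within`` row-wise; within-subject rows sum
    to zero inside each subject, so the within part isolates the paired
    (within-animal) variation that repeated-measures discrimination should
    model.
    """

    between: np.ndarray
    within: np.ndarray
    subject_ids: np.ndarray
    grand_mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.grand_mean[None, :] + self.between + self.within


def multilevel_split(X: np.ndarray, subjects) -> MultilevelSplit:
    """Split X into between-subject and within-subject parts.

    within = X − subject mean; between = subject mean − grand mean. Every
    subject needs at least two rows for the within part to be meaningful.
    """
    X = np.asarray(X, dtype=float)
    subjects = np.asarray(subjects)
    if len(subjects) != X.shape[0]:
        raise ChemometricsError("subjects length must match rows of X")
    grand = X.mean(axis=0)
    within = np.empty_like(X)
    between = np.empty_like(X)
    for s in np.unique(subjects):
        idx = subjects == s
        if idx.sum() < 2:
            raise ChemometricsError(f"subject {s!r} has a single row; cannot split")
        mu = X[idx].mean(axis=0)
        within[idx] = X[idx] - mu
        between[idx] = mu - grand
    return MultilevelSplit(between=between, within=within, subject_ids=subjects, grand_mean=grand)


# ---------------------------------------------------------------------------
# OSC
# ---------------------------------------------------------------------------

def _one_hot(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def osc_filter(
    X: np.ndarray,
    Y: np.ndarray,
    n_osc: int = 1,
    tol: float = 1e-10,
    max_iter: int = NIPALS_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray]:
    """Wold-style orthogonal signal correction.

    Iteratively finds score vectors t of X that are orthogonalized against
    the (centered) class-dummy matrix Y, then deflates X by t·pᵀ. Removes
    exactly the X-variation unrelated to class membership; each removed
    score has cosine < 1e-6 with every centered Y column.

    Returns (X_filtered, removed_scores) with one score column per OSC
    component.
    """
    X = np.asarray(X, dtype=float).copy()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if n_osc < 1:
        raise ChemometricsError("n_osc must be ≥ 1")
    Yc = Y - Y.mean(axis=0)
    # orthogonal projector onto the complement of span(Yc)
    q_basis, _ = np.linalg.qr(Yc)

    def anti_project(t: np.ndarray) -> np.ndarray:
        return t - q_basis @ (q_basis.T @ t)

    removed = []
    for _ in range(n_osc):
        # initialize from the dominant principal score
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        t = X @ vt[0]
        converged = False
        resid = np.inf
        for _ in range(max_iter):
            t_star = anti_project(t)
            w = X.T @ t_star
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError("OSC weight vector collapsed to zero")
            w /= nw
            t_new = X @ w
            resid = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-300)
            t = t_new
            if resid < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"OSC did not converge; last relative change {resid:.3e}")
        t = anti_project(t)  # exact orthogonality of the removed score
        p = X.T @ t / (t @ t)
        X -= np.outer(t, p)
        removed.append(t)
    return X, np.column_stack(removed)


# ---------------------------------------------------------------------------
# Scaling and PCA
# ---------------------------------------------------------------------------

def _center_scale(X: np.ndarray, sd_power: float) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s) before scaling",
            stacklevel=3,
        )
    return (X[:, keep] - mean[keep]) / sd[keep] ** sd_power


def pareto_scale(X: np.ndarray) -> np.ndarray:
    """Mean-center and divide each column by sqrt(its sample SD, n−1).

    Down-weights dominant peaks less aggressively than unit-variance
    scaling, the usual compromise for NMR intensity data. Zero-variance
    columns are dropped with a warning.
    """
    return _center_scale(X, 0.5)


def autoscale(X: np.ndarray) -> np.ndarray:
    """Mean-center and scale each column to unit sample SD (n−1)."""
    return _center_scale(X, 1.0)


@dataclass
class PCAResult:
    scores: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """PCA by SVD of the centered matrix; deterministic sign convention."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = rank
    ev_all = s**2 / max(X.shape[0] - 1, 1)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    for j in range(n_components):
        sign = _orient(loadings[:, j])
        loadings[:, j] *= sign
        scores[:, j] *= sign
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance=ev_all[:n_components],
        explained_variance_ratio=ev_all[:n_components] / ev_all.sum(),
    )


# ---------------------------------------------------------------------------
# NIPALS (sparse) PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted (sparse) PLS-DA model against one-hot class membership."""

    n_components: int
    scores: np.ndarray  # T (n, a)
    weights: np.ndarray  # W (p, a)
    loadings: np.ndarray  # P (p, a)
    y_loadings: np.ndarray  # Q (c, a)
    r2y: float
    classes: np.ndarray
    class_labels: np.ndarray
    keepX: list[int]
    x_mean: np.ndarray
    y_mean: np.ndarray
    vip: np.ndarray | None = None
    q2: float | None = None

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predicted (uncentered) class-membership matrix Ŷ for new X."""
        X = np.asarray(X, dtype=float)
        B = self.weights @ np.linalg.solve(self.loadings.T @ self.weights,
                                           self.y_loadings.T)
        return (X - self.x_mean) @ B + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        yhat = self.predict_scores(X)
        return self.classes[np.argmax(yhat, axis=1)]


def _soft_threshold(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so that exactly ``keep`` entries stay nonzero."""
    if keep >= w.size:
        return w
    mags = np.abs(w)
    lam = np.partition(mags, w.size - keep - 1)[w.size - keep - 1]
    return np.sign(w) * np.maximum(mags - lam, 0.0)


def _nipals_pls2(
    Xc: np.ndarray,
    Yc: np.ndarray,
    n_components: int,
    keepX: list[int],
    tol: float = NIPALS_TOL,
    max_iter: int = NIPALS_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n, p = Xc.shape
    c = Yc.shape[1]
    T = np.zeros((n, n_components))
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((c, n_components))
    X, Y = Xc.copy(), Yc.copy()
    for a in range(n_components):
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        if np.linalg.norm(u) == 0:
            raise ConvergenceError("Y residual exhausted before requested components")
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = X.T @ u / (u @ u)
            w = _soft_threshold(w, keepX[a])
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ConvergenceError("all X-weights thresholded to zero")
            w /= nw
            t = X @ w
            q = Y.T @ t / (t @ t)
            u = Y @ q / (q @ q)
            if np.linalg.norm(t - t_old) / max(np.linalg.norm(t), 1e-300) < tol:
                break
            t_old = t
        else:
            raise ConvergenceError(f"NIPALS did not converge on component {a + 1}")
        sign = _orient(w)
        w, t, q = sign * w, sign * t, sign * q
        pvec = X.T @ t / (t @ t)
        X = X - np.outer(t, pvec)
        Y = Y - np.outer(t, q)
        T[:, a], W[:, a], P[:, a], Q[:, a] = t, w, pvec, q
    return T, W, P, Q


def _fit_pls(X, y, n_components, keepX) -> PLSModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Y, classes = _one_hot(y)
    if len(classes) < 2:
        raise ChemometricsError("PLS-DA needs at least two classes")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = int(rank)
    if isinstance(keepX, int):
        keepX = [keepX] * n_components
    keepX = list(keepX)[:n_components]
    if len(keepX) < n_components:
        keepX = keepX + [keepX[-1]] * (n_components - len(keepX))
    if any(k <= 0 for k in keepX):
        raise ChemometricsError("keepX entries must be ≥ 1")
    keepX = [min(k, X.shape[1]) for k in keepX]
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - x_mean, Y - y_mean
    T, W, P, Q = _nipals_pls2(Xc, Yc, n_components, keepX)
    y_hat = T @ Q.T
    tss = float(np.sum(Yc**2))
    r2y = 1.0 - float(np.sum((Yc - y_hat) ** 2)) / tss if tss > 0 else 0.0
    model = PLSModel(
        n_components=n_components,
        scores=T,
        weights=W,
        loadings=P,
        y_loadings=Q,
        r2y=r2y,
        classes=classes,
        class_labels=y,
        keepX=keepX,
        x_mean=x_mean,
        y_mean=y_mean,
    )
    model.vip = vip(model)
    return model


def plsda_fit(X: np.ndarray, y, n_components: int = 2) -> PLSModel:
    """Dense PLS-DA via NIPALS PLS2 against one-hot class membership.

    R2Y is the fraction of centered-Y variance explained by the fitted
    components; class prediction is the argmax over predicted membership.
    """
    X = np.asarray(X, dtype=float)
    return _fit_pls(X, y, n_components, keepX=X.shape[1])


def splsda_fit(X: np.ndarray, y, n_components: int = 2, keepX=None) -> PLSModel:
    """Sparse PLS-DA: per-component X-weights soft-thresholded to keepX
    nonzero variables (Lê Cao-style L1 selection). keepX = p reproduces the
    dense fit exactly."""
    X = np.asarray(X, dtype=float)
    if keepX is None:
        keepX = X.shape[1]
    return _fit_pls(X, y, n_components, keepX=keepX)


def vip(model: PLSModel) -> np.ndarray:
    """Variable Importance in the Projection.

    VIP_j = sqrt( p * Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ), with SS_a the
    Y-variance explained by component a (‖t_a‖²·‖q_a‖²). For dense fits the
    mean of squared VIP is exactly 1 (Σ VIP² = p).
    """
    T, W, Q = model.scores, model.weights, model.y_loadings
    p = W.shape[0]
    ss = np.sum(T**2, axis=0) * np.sum(Q**2, axis=0)
    total = ss.sum()
    if total <= 0:
        raise ChemometricsError("model explains no Y variance; VIP undefined")
    wnorm2 = W**2 / np.maximum(np.sum(W**2, axis=0), 1e-300)
    return np.sqrt(p * (wnorm2 @ ss) / total)


# ---------------------------------------------------------------------------
# Cross-validation: Q2 and classification AUC
# ---------------------------------------------------------------------------

def _cv_splits(n: int, y, folds: int, groups, seed: int):
    if folds > n:
        raise ChemometricsError(f"folds={folds} exceeds {n} samples")
    idx = np.arange(n)
    if groups is not None:
        groups = np.asarray(groups)
        n_groups = len(np.unique(groups))
        folds = min(folds, n_groups)
        return list(GroupKFold(n_splits=folds).split(idx, y, groups))
    return list(KFold(n_splits=folds, shuffle=True, random_state=seed).split(idx))


@dataclass
class CVResult:
    q2: dict[int, float]
    chosen_n_components: int
    folds: int


def cv_q2(
    X: np.ndarray,
    y,
    folds: int = 7,
    n_components_grid=(1, 2, 3),
    groups=None,
    seed: int = 0,
    keepX=None,
) -> CVResult:
    """Cross-validated predictive ability Q2 over a component grid.

    Q2 = 1 − PRESS/TSS pooled over folds, with PRESS the squared prediction
    error of the one-hot class matrix and TSS measured against each training
    fold's class means. When ``groups`` (e.g. animal ids) are given, folds
    never split a group — repeated measures of one subject stay together —
    and the fold count is capped at the number of groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    Y, classes = _one_hot(y)
    splits = _cv_splits(X.shape[0], y, folds, groups, seed)
    q2 = {}
    for ncomp in n_components_grid:
        press = tss = 0.0
        ok = True
        for train, test in splits:
            if len(np.unique(y[train])) < 2:
                ok = False
                break
            kx = keepX if keepX is not None else X.shape[1]
            model = _fit_pls(X[train], y[train], ncomp, keepX=kx)
            yhat = model.predict_scores(X[test])
            # align predicted columns with the global class order
            col = {c: j for j, c in enumerate(model.classes)}
            pred = np.zeros((len(test), len(classes)))
            for j, c in enumerate(classes):
                if c in col:
                    pred[:, j] = yhat[:, col[c]]
            press += float(np.sum((Y[test] - pred) ** 2))
            ybar = Y[train].mean(axis=0)
            tss += float(np.sum((Y[test] - ybar) ** 2))
        q2[ncomp] = 1.0 - press / tss if ok and tss > 0 else float("-inf")
    chosen = max(q2, key=lambda k: q2[k])
    return CVResult(q2=q2, chosen_n_components=chosen, folds=len(splits))


def cv_auc(
    X: np.ndarray,
    y,
    n_components: int = 2,
    keepX=None,
    folds: int = 7,
    groups=None,
    seed: int = 0,
) -> float:
    """Cross-validated two-class ROC AUC of a (sparse) PLS-DA model.

    Decision value = predicted membership of the second class; predictions
    are pooled over folds before the ROC is computed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ChemometricsError("cv_auc is defined for two classes")
    splits = _cv_splits(X.shape[0], y, folds, groups, seed)
    scores = np.empty(X.shape[0])
    for train, test in splits:
        kx = keepX if keepX is not None else X.shape[1]
        model = _fit_pls(X[train], y[train], n_components, keepX=kx)
        yhat = model.predict_scores(X[test])
        j = int(np.where(model.classes == classes[1])[0][0])
        scores[test] = yhat[:, j]
    return float(roc_auc_score((y == classes[1]).astype(int), scores))


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int


def permutation_test(
    X: np.ndarray,
    y,
    fit_stat,
    n_perm: int = 200,
    seed: int = 0,
    within_subject=None,
) -> PermutationResult:
    """Label-permutation test of a model statistic (e.g. cross-validated Q2).

    ``fit_stat(X, y) -> float``; larger = stronger model. Labels are shuffled
    globally, or within subject blocks when ``within_subject`` labels are
    given (preserving each subject's label multiset). p uses the +1-corrected
    estimator p = (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ChemometricsError("constant labels cannot be permuted meaningfully")
    if n_perm < 1:
        raise ChemometricsError("n_perm must be ≥ 1")
    rng = np.random.default_rng(seed)
    observed = float(fit_stat(X, y))
    nulls = np.empty(n_perm)
    for b in range(n_perm):
        yp = y.copy()
        if within_subject is not None:
            blocks = np.asarray(within_subject)
            for s in np.unique(blocks):
                idx = np.flatnonzero(blocks == s)
                yp[idx] = yp[rng.permutation(idx)]
        else:
            yp = y[rng.permutation(len(y))]
        nulls[b] = fit_stat(X, yp)
    p = (1.0 + float(np.sum(nulls >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed_stat=observed, null_stats=nulls, p_value=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Univariate screening
# ---------------------------------------------------------------------------

def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis_fdr(X: np.ndarray, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable Kruskal–Wallis H test across groups with BH-FDR.

    H uses mid-ranks with the tie-correction factor and the chi-square
    upper-tail approximation (scipy). Variables with all values identical
    get H = 0, p = 1 by convention. Returns a frame with columns
    variable, H, p, q, significant (q < alpha).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ChemometricsError("Kruskal–Wallis needs ≥ 2 groups")
    samples_idx = [np.flatnonzero(groups == g) for g in labels]
    if any(len(ix) == 0 for ix in samples_idx):
        raise ChemometricsError("every group must be non-empty")
    H = np.empty(X.shape[1])
    p = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            H[j], p[j] = 0.0, 1.0
            continue
        H[j], p[j] = stats.kruskal(*(col[ix] for ix in samples_idx))
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "variable": np.arange(X.shape[1]),
            "H": H,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
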