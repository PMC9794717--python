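"""Predictive canonical correlation analysis with permutation model selection.

The inference core links PCA scores of disconnection features (X) to the
residualized behavioral scores (Y) through the *first* canonical pair.  As
the number of PCA components grows the in-sample canonical correlation
climbs toward 1 (overfitting), so the headline statistic T is instead the
leave-one-out cross-validated correlation: for each held-out patient the
pair of canonical weights is learned on the rest and the patient's
predicted canonical variates are pooled; T is the Pearson correlation of
the pooled pairs.  Significance per model order comes from permuting the
rows of X, recomputing the cross-validated statistic for each surrogate,
and counting surrogates that beat the observed value; the p-value error bar
is sqrt(p (1 - p) / n_perm) and the smallest resolvable p is 1 / n_perm.
The selected order (#Comp) is the smallest significant order achieving the
maximum T; its weights are back-projected through the PCA loadings to a
voxel map, z-scored and thresholded at |Z| > 2.

The canonical pair is computed in closed form: whiten the within-set
covariances by Cholesky factors, take the leading singular pair of the
whitened cross-covariance, and map the singular vectors back.  A small
ridge (1e-8 x mean diagonal) keeps near-degenerate covariances factorable.
Leave-one-out folds reuse the full-data Gram matrices through rank-one
downdates and run as one batched linear-algebra pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .features import FeatureSet, PCAFeatures
from .volumes import Volume

__all__ = [
    "CCAFit",
    "CCASelection",
    "BrainWeightMap",
    "CanonicalCorrelation",
    "IterativeCCA",
    "fit_cca",
    "loocv_cca",
    "permutation_pvalue",
    "scan_components",
    "backproject",
    "behavioral_weights",
]

DEFAULT_RIDGE = 1e-8


# ---------------------------------------------------------------------------
# closed-form first canonical pair
# ---------------------------------------------------------------------------

def _covariances(X: np.ndarray, Y: np.ndarray, ridge: float):
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Cxx = Xc.T @ Xc / (n - 1)
    Cyy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    Cxx += np.eye(Cxx.shape[0]) * (ridge * np.trace(Cxx) / Cxx.shape[0] + 1e-300)
    Cyy += np.eye(Cyy.shape[0]) * (ridge * np.trace(Cyy) / Cyy.shape[0] + 1e-300)
    return Cxx, Cxy, Cyy


def _first_pair(Cxx, Cxy, Cyy):
    """Leading canonical pair from covariance blocks (Cholesky + SVD)."""
    Lx = np.linalg.cholesky(Cxx)
    Ly = np.linalg.cholesky(Cyy)
    K = np.linalg.solve(Lx, Cxy)
    K = np.linalg.solve(Ly, K.swapaxes(-1, -2)).swapaxes(-1, -2)
    U, s, Vt = np.linalg.svd(K)
    a = np.linalg.solve(Lx.swapaxes(-1, -2), U[..., :, 0:1])[..., 0]
    b = np.linalg.solve(Ly.swapaxes(-1, -2), Vt.swapaxes(-1, -2)[..., :, 0:1])[..., 0]
    a = a / np.linalg.norm(a, axis=-1, keepdims=True)
    b = b / np.linalg.norm(b, axis=-1, keepdims=True)
    r = np.clip(s[..., 0], 0.0, 1.0)
    return a, b, r


def _apply_sign_convention(a: np.ndarray, b: np.ndarray):
    """Flip (a, b) jointly so the largest-|entry| of b is positive."""
    dom = np.argmax(np.abs(b))
    if b[dom] < 0:
        return -a, -b
    return a, b


@dataclass
class CCAFit:
    """First canonical pair: unit-norm weights and the training correlation."""

    x_weights: np.ndarray
    y_weights: np.ndarray
    train_corr: float


class CanonicalCorrelation(BaseEstimator):
    """First-canonical-pair CCA estimator.

    Parameters
    ----------
    ridge : float
        Relative ridge added to the within-set covariance diagonals.

    Attributes
    ----------
    x_weights_, y_weights_ : unit-norm weight vectors of the first pair,
        signed so the behavioral weight of largest magnitude is positive.
    train_corr_ : first canonical correlation, in [0, 1].
    """

    def __init__(self, ridge: float = DEFAULT_RIDGE):
        self.ridge = ridge

    def fit(self, X: np.ndarray, Y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must be 2D with matching rows")
        n = X.shape[0]
        if n <= 2:
            raise ValueError("need more than 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("X and Y must be finite")
        Cxx, Cxy, Cyy = _covariances(X, Y, self.ridge)
        try:
            a, b, r = _first_pair(Cxx, Cxy, Cyy)
        except np.linalg.LinAlgError:
            # degenerate covariance: retry with a much stronger ridge
            Cxx, Cxy, Cyy = _covariances(X, Y, max(self.ridge, 1e-4))
            a, b, r = _first_pair(Cxx, Cxy, Cyy)
        a, b = _apply_sign_convention(a, b)
        self.x_weights_, self.y_weights_, self.train_corr_ = a, b, float(r)
        self.x_mean_, self.y_mean_ = X.mean(axis=0), Y.mean(axis=0)
        return self

    def transform(self, X: np.ndarray, Y: np.ndarray | None = None):
        """Canonical variates u = (X - mean) a (and v if Y is given)."""
        u = (np.atleast_2d(X) - self.x_mean_) @ self.x_weights_
        if Y is None:
            return u
        v = (np.atleast_2d(Y) - self.y_mean_) @ self.y_weights_
        return u, v


def fit_cca(X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> CCAFit:
    """Functional wrapper over :class:`CanonicalCorrelation`."""
    est = CanonicalCorrelation(ridge=ridge).fit(X, Y)
    return CCAFit(est.x_weights_, est.y_weights_, est.train_corr_)


# ---------------------------------------------------------------------------
# leave-one-out predictive correlation (batched over folds)
# ---------------------------------------------------------------------------

def _loocv_variates(X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE):
    """Pooled held-out canonical variates (u, v), one pair per patient.

    All n leave-one-out folds are solved in one batched pass: the full-data
    Gram matrices are downdated by the held-out row, whitened by batched
    Cholesky factors, and the leading singular pair extracted per fold.
    Fold signs are aligned by flipping (a, b) jointly so that b matches the
    full-data y-weights (b_ref . b >= 0); the training canonical correlation
    is non-negative by construction.
    """
    n, k = X.shape
    q = Y.shape[1]
    b_ref = fit_cca(X, Y, ridge).y_weights

    Sx, Sy = X.sum(axis=0), Y.sum(axis=0)
    Gxx, Gxy, Gyy = X.T @ X, X.T @ Y, Y.T @ Y

    m = n - 1
    mx = (Sx[None, :] - X) / m  # per-fold training means
    my = (Sy[None, :] - Y) / m
    Gxx_i = Gxx[None] - np.einsum("ni,nj->nij", X, X)
    Gyy_i = Gyy[None] - np.einsum("ni,nj->nij", Y, Y)
    Gxy_i = Gxy[None] - np.einsum("ni,nj->nij", X, Y)
    Cxx = (Gxx_i - m * np.einsum("ni,nj->nij", mx, mx)) / (m - 1)
    Cyy = (Gyy_i - m * np.einsum("ni,nj->nij", my, my)) / (m - 1)
    Cxy = (Gxy_i - m * np.einsum("ni,nj->nij", mx, my)) / (m - 1)
    tr_x = np.einsum("nii->n", Cxx) / k
    tr_y = np.einsum("nii->n", Cyy) / q
    Cxx = Cxx + np.eye(k)[None] * (ridge * tr_x + 1e-300)[:, None, None]
    Cyy = Cyy + np.eye(q)[None] * (ridge * tr_y + 1e-300)[:, None, None]

    a, b, _ = _first_pair(Cxx, Cxy, Cyy)
    flip = np.sign(b @ b_ref)
    flip[flip == 0] = 1.0
    a *= flip[:, None]
    b *= flip[:, None]

    u = np.einsum("ni,ni->n", X - mx, a)
    v = np.einsum("ni,ni->n", Y - my, b)
    return u, v


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return 0.0
    return float(np.clip(np.corrcoef(u, v)[0, 1], -1.0, 1.0))


def loocv_cca(X: np.ndarray, Y: np.ndarray, ridge: float = DEFAULT_RIDGE) -> float:
    """Cross-validated canonical correlation T_cv over pooled held-out pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = X.shape[0]
    if n < 6:
        raise ValueError("leave-one-out CCA needs at least 6 samples")
    try:
        u, v = _loocv_variates(X, Y, ridge)
    except np.linalg.LinAlgError:
        # rare degenerate folds: redo fold-by-fold, skipping failures
        us, vs, skipped = [], [], 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            try:
                est = CanonicalCorrelation(ridge=max(ridge, 1e-6)).fit(X[mask], Y[mask])
                b_ref = fit_cca(X, Y, max(ridge, 1e-6)).y_weights
                sgn = 1.0 if est.y_weights_ @ b_ref >= 0 else -1.0
                us.append(sgn * float((X[i] - est.x_mean_) @ est.x_weights_))
                vs.append(sgn * float((Y[i] - est.y_mean_) @ est.y_weights_))
            except np.linalg.LinAlgError:
                skipped += 1
        if skipped > 0.1 * n:
            raise ValueError(f"{skipped}/{n} leave-one-out folds failed")
        u, v = np.asarray(us), np.asarray(vs)
    return _pearson(u, v)


# ---------------------------------------------------------------------------
# permutation inference and model-order scan
# ---------------------------------------------------------------------------

def permutation_pvalue(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    *,
    statistic: str = "loocv",
    ridge: float = DEFAULT_RIDGE,
    observed: float | None = None,
    permutations: np.ndarray | None = None,
) -> tuple[float, float, dict]:
    """Permutation p-value for the (cross-validated) canonical correlation.

    Rows of X are permuted ``n_perm`` times (Y fixed) and the statistic is
    recomputed for each surrogate; ``p`` is the fraction of surrogates
    strictly greater than the observed value — no +1 correction — with
    error bar sqrt(p (1 - p) / n_perm).  A zero count is reported as
    ``p_floor = 1 / n_perm`` ("p < 1/n_perm") alongside the raw p = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat = {"loocv": loocv_cca, "insample": lambda x, y, r=ridge: fit_cca(x, y, r).train_corr}[
        statistic
    ]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if observed is None:
        observed = stat(X, Y, ridge) if statistic == "loocv" else stat(X, Y)
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = np.stack(
            [rng.permutation(X.shape[0]) for _ in range(n_perm)]
        )
    surrogates = np.empty(len(permutations))
    for j, perm in enumerate(permutations):
        Xp = X[perm]
        surrogates[j] = stat(Xp, Y, ridge) if statistic == "loocv" else stat(Xp, Y)
    count = int(np.sum(surrogates > observed))
    p = count / len(permutations)
    p_err = float(np.sqrt(p * (1 - p) / len(permutations)))
    info = {
        "count": count,
        "observed": float(observed),
        "p_floor": max(p, 1.0 / len(permutations)),
        "surrogates": surrogates,
    }
    return p, p_err, info


@dataclass
class CCASelection:
    """Model-order scan results and the selected best model."""

    scan: pd.DataFrame  # columns: k, t_train, t_cv, p, p_err, count
    n_components: int | None  # selected order (#Comp); None if nothing significant
    t: float | None  # T_cv at the selected order
    ve: float | None  # cumulative PCA explained-variance ratio at #Comp
    x_weights: np.ndarray | None
    y_weights: np.ndarray | None
    alpha: float = 0.05
    n_perm: int = 1000
    p_selection: float | None = None  # scan-level (max-over-orders) p-value
    p_selection_err: float | None = None

    @property
    def significant(self) -> bool:
        return self.n_components is not None


class IterativeCCA(BaseEstimator):
    """Model-order scan: LOOCV-CCA at every order with permutation inference.

    For k = 1 .. k_max the estimator records the in-sample canonical
    correlation, the cross-validated correlation T_cv, and a marginal
    permutation p-value with its error bar.  One permutation set (drawn
    from ``random_state``) is shared across orders, which makes the scan's
    family-wise test free: the scan-level significance gate compares the
    observed maximum of T_cv over orders against each surrogate's maximum
    over the same orders, so scanning many orders does not inflate the
    type-I error.  When that gate passes at ``alpha``, the selected order
    (#Comp) is the smallest order achieving the maximum T_cv.

    Parameters
    ----------
    k_max : int or None
        Highest model order to scan (None: all available columns).
    n_perm : int
        Permutations per order.
    alpha : float
        Significance level for the selection rule.
    statistic : {"loocv", "insample"}
        Statistic recomputed per surrogate.
    """

    def __init__(
        self,
        k_max: int | None = None,
        n_perm: int = 1000,
        alpha: float = 0.05,
        statistic: str = "loocv",
        ridge: float = DEFAULT_RIDGE,
        random_state: int = 0,
        t_cv_tol: float = 0.01,
    ):
        self.k_max = k_max
        self.n_perm = n_perm
        self.alpha = alpha
        self.statistic = statistic
        self.ridge = ridge
        self.random_state = random_state
        self.t_cv_tol = t_cv_tol

    def fit(self, X: np.ndarray, Y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n, k_avail = X.shape
        k_max = min(self.k_max or k_avail, k_avail)
        if k_max < 1:
            raise ValueError("k_max must be >= 1")
        rng = np.random.default_rng(self.random_state)
        perms = np.stack([rng.permutation(n) for _ in range(self.n_perm)])

        rows = []
        weights = {}
        surrogate_stats = np.empty((self.n_perm, k_max))
        for k in range(1, k_max + 1):
            Xk = X[:, :k]
            full = fit_cca(Xk, Y, self.ridge)
            t_cv = loocv_cca(Xk, Y, self.ridge)
            p, p_err, info = permutation_pvalue(
                Xk,
                Y,
                seed=0,
                statistic=self.statistic,
                ridge=self.ridge,
                observed=t_cv if self.statistic == "loocv" else full.train_corr,
                permutations=perms,
            )
            surrogate_stats[:, k - 1] = info["surrogates"]
            weights[k] = full
            rows.append(
                {
                    "k": k,
                    "t_train": full.train_corr,
                    "t_cv": t_cv,
                    "p": p,
                    "p_err": p_err,
                    "count": info["count"],
                    "p_floor": info["p_floor"],
                }
            )
        scan = pd.DataFrame(rows)
        self.scan_ = scan

        # family-wise gate: max over orders, observed vs surrogate
        t_col = "t_cv" if self.statistic == "loocv" else "t_train"
        observed_max = float(scan[t_col].max())
        surrogate_max = surrogate_stats.max(axis=1)
        p_sel = float(np.sum(surrogate_max > observed_max)) / self.n_perm
        self.p_selection_ = p_sel
        self.p_selection_err_ = float(np.sqrt(p_sel * (1 - p_sel) / self.n_perm))

        if p_sel < self.alpha:
            # parsimony: orders whose T_cv sits within t_cv_tol of the
            # maximum are ties (differences that small are LOOCV noise)
            best_t = scan["t_cv"].max()
            k_sel = int(scan[scan["t_cv"] >= best_t - self.t_cv_tol]["k"].min())
            self.n_components_ = k_sel
            self.t_cv_ = float(scan.loc[scan["k"] == k_sel, "t_cv"].iloc[0])
            self.p_value_ = float(scan.loc[scan["k"] == k_sel, "p"].iloc[0])
            self.p_error_ = float(scan.loc[scan["k"] == k_sel, "p_err"].iloc[0])
            self.x_weights_ = weights[k_sel].x_weights
            self.y_weights_ = weights[k_sel].y_weights
        else:
            self.n_components_ = None
            self.t_cv_ = self.p_value_ = self.p_error_ = None
            self.x_weights_ = self.y_weights_ = None
        return self

    def selection(self, pca: PCAFeatures | None = None) -> CCASelection:
        ve = None
        if pca is not None and self.n_components_ is not None:
            ve = pca.cumulative_ve(self.n_components_)
        return CCASelection(
            scan=self.scan_,
            n_components=self.n_components_,
            t=self.t_cv_,
            ve=ve,
            x_weights=self.x_weights_,
            y_weights=self.y_weights_,
            alpha=self.alpha,
            n_perm=self.n_perm,
            p_selection=self.p_selection_,
            p_selection_err=self.p_selection_err_,
        )


def scan_components(
    pca: PCAFeatures,
    Y: np.ndarray,
    k_max: int | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "loocv",
) -> CCASelection:
    """Functional wrapper over :class:`IterativeCCA` on PCA scores."""
    est = IterativeCCA(
        k_max=k_max, n_perm=n_perm, alpha=alpha, statistic=statistic, random_state=seed
    ).fit(pca.scores, Y)
    return est.selection(pca)


# ---------------------------------------------------------------------------
# back-projection to brain space
# ---------------------------------------------------------------------------

@dataclass
class BrainWeightMap:
    """Voxel map of canonical weights: raw, z-scored, and |Z|>2 thresholded."""

    raw: Volume
    zscored: Volume
    thresholded: Volume
    modality: str
    median_weight: float
    mask: Volume


def _weights_to_map(
    weights_vox: np.ndarray, mask: Volume, modality: str, z_threshold: float,
    two_sided: bool,
) -> BrainWeightMap:
    m = np.asarray(mask.data, dtype=bool)
    raw = np.zeros(mask.grid.shape)
    raw[m] = weights_vox
    z_in = (weights_vox - weights_vox.mean()) / weights_vox.std()
    z = np.zeros(mask.grid.shape)
    z[m] = z_in
    supra = np.abs(z_in) > z_threshold if two_sided else z_in > z_threshold
    thr = np.zeros(mask.grid.shape)
    thr[m] = np.where(supra, z_in, 0.0)
    return BrainWeightMap(
        raw=Volume(raw, mask.grid),
        zscored=Volume(z, mask.grid),
        thresholded=Volume(thr, mask.grid),
        modality=modality,
        median_weight=float(np.median(weights_vox)),
        mask=mask,
    )


def backproject(
    x_weights: np.ndarray,
    pca: PCAFeatures,
    feature_set: FeatureSet | None = None,
    *,
    z_threshold: float = 2.0,
    two_sided: bool = True,
) -> BrainWeightMap | tuple[BrainWeightMap, BrainWeightMap]:
    """Map canonical weights through the PCA loadings into brain space.

    The voxel weight vector is ``loadings[:k].T @ x_weights``, z-scored over
    the union mask and thresholded at |Z| > ``z_threshold`` (two-sided by
    default; signed values are preserved).  A concatenated SC+FC feature set
    is split at its recorded column boundary into one map per modality, each
    reporting its median raw weight.
    """
    x_weights = np.asarray(x_weights, dtype=float)
    k = x_weights.size
    if k > pca.loadings.shape[0]:
        raise ValueError("weight length exceeds the number of PCA components")
    fs = feature_set if feature_set is not None else pca.feature_set
    if fs is None:
        raise ValueError("a FeatureSet is required to place weights in the mask")
    w_vox = pca.loadings[:k].T @ x_weights

    if fs.modality == "SC+FC":
        if fs.boundary is None:
            raise ValueError("concatenated feature set lacks a modality boundary")
        sc = _weights_to_map(w_vox[: fs.boundary], fs.union_mask, "SC", z_threshold, two_sided)
        fc = _weights_to_map(w_vox[fs.boundary :], fs.second_mask, "FC", z_threshold, two_sided)
        return sc, fc
    return _weights_to_map(w_vox, fs.union_mask, fs.modality, z_threshold, two_sided)


def behavioral_weights(selection: CCASelection, score_names=None) -> pd.Series:
    """Unit-norm y-weights over the four scores at the selected order."""
    if selection.y_weights is None:
        raise ValueError("no significant model was selected")
    from .synthetic import SCORE_COLUMNS

    names = score_names or SCORE_COLUMNS
    return pd.Series(selection.y_weights, index=list(names), name="behavioral_weight")
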