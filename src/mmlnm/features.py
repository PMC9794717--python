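"""Patients x voxels feature matrices, PCA reduction and behavior preparation.

The association stage needs (i) per-modality feature matrices over a union
mask of voxels that are non-zero in at least one patient's map, with the
structural maps log-transformed and, for multimodal fusion, each modality
column-standardized before spatial concatenation; (ii) PCA scores as the
imaging variables; (iii) behavior with missing scores imputed by chained
randomized-tree regression and confounds (age, days since stroke, lesion
size) regressed out, residuals z-scored.

Lesion symptom mapping (LSM) uses raw binary lesion maps as the per-patient
maps; everything downstream is the identical code path (``modality`` only
labels the map source).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .synthetic import CONFOUND_COLUMNS, SCORE_COLUMNS
from .volumes import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "PCAFeatures",
    "PreparedBehavior",
    "build_union_mask",
    "assemble_matrix",
    "concat_modalities",
    "pca_features",
    "impute_behavior",
    "regress_confounds",
    "ConfoundRegressor",
]

LOG_EPS = 1e-6  # offset in log(x + eps) for structural zeros


@dataclass
class FeatureSet:
    """Patients x in-mask voxels matrix for one modality (or a fusion).

    ``boundary`` is the column index splitting SC from FC columns when the
    set is a concatenation; ``standardized`` records whether columns were
    scaled to mean 0 / sd 1 (required before fusion).
    """

    matrix: np.ndarray
    union_mask: Volume
    modality: str  # "SC", "FC", "LESION" or "SC+FC"
    boundary: int | None = None
    standardized: bool = False
    constant_columns: np.ndarray | None = None
    second_mask: Volume | None = None  # FC union mask of a concatenation

    def __post_init__(self) -> None:
        n_mask = int(np.count_nonzero(self.union_mask.data))
        if self.modality == "SC+FC":
            if self.second_mask is None or self.boundary is None:
                raise ValueError("a concatenated set needs boundary and second_mask")
            expected = n_mask + int(np.count_nonzero(self.second_mask.data))
        else:
            expected = n_mask
        if self.matrix.shape[1] != expected:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but the mask(s) "
                f"cover {expected} voxels"
            )

    @property
    def n_patients(self) -> int:
        return self.matrix.shape[0]


def build_union_mask(maps: Sequence[Volume], modality: str = "") -> Volume:
    """Voxels non-zero in at least one patient's map."""
    if len(maps) == 0:
        raise ValueError("need at least one map")
    grid = maps[0].grid
    union = np.zeros(grid.shape, dtype=bool)
    for m in maps:
        if m.grid != grid:
            raise ValueError("maps must share a grid")
        union |= np.asarray(m.data) != 0
    if not union.any():
        raise ValueError(f"union mask is empty for modality {modality!r}")
    return Volume(union.astype(np.uint8), grid)


def assemble_matrix(
    maps: Sequence[Volume],
    union_mask: Volume,
    modality: str,
    *,
    standardize: bool | None = None,
    log_eps: float = LOG_EPS,
) -> FeatureSet:
    """Stack per-patient maps into a patients x in-mask-voxels matrix.

    SC values are log-transformed as ``log(x + log_eps)``; LESION maps are
    taken as binary; FC maps (T-values) as-is.  When ``standardize`` is true
    (the default only for matrices destined for fusion is set by the
    caller), each column is scaled to mean 0 / sd 1 and zero-variance
    columns are set to 0 and flagged.
    """
    if standardize is None:
        standardize = False
    mask = np.asarray(union_mask.data, dtype=bool)
    rows = []
    for i, m in enumerate(maps):
        if m.grid != union_mask.grid:
            raise ValueError("maps must share the union mask's grid")
        vals = np.asarray(m.data, dtype=float)[mask]
        if np.any(np.isnan(vals)):
            bad = np.flatnonzero(np.isnan(vals))[:5]
            raise ValueError(
                f"NaN values in patient map {i} at in-mask voxel indices {bad.tolist()}"
            )
        rows.append(vals)
    X = np.vstack(rows)
    if modality.upper() == "SC":
        X = np.log(X + log_eps)
    elif modality.upper() == "LESION":
        X = (X != 0).astype(float)
    constant = np.zeros(X.shape[1], dtype=bool)
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd == 0
        if constant.any():
            logger.info("%d constant columns standardized to zero", int(constant.sum()))
        X = np.where(constant[None, :], 0.0, (X - mu) / np.where(constant, 1.0, sd))
    return FeatureSet(
        matrix=X,
        union_mask=union_mask,
        modality=modality.upper(),
        standardized=standardize,
        constant_columns=constant,
    )


def concat_modalities(sc: FeatureSet, fc: FeatureSet) -> FeatureSet:
    """Spatially concatenate standardized SC and FC matrices (SC first)."""
    if sc.n_patients != fc.n_patients:
        raise ValueError("SC and FC matrices cover different patient rosters")
    if not (sc.standardized and fc.standardized):
        raise ValueError("both modalities must be column-standardized before fusion")
    boundary = sc.matrix.shape[1]
    return FeatureSet(
        matrix=np.hstack([sc.matrix, fc.matrix]),
        union_mask=sc.union_mask,
        modality="SC+FC",
        boundary=boundary,
        standardized=True,
        second_mask=fc.union_mask,
    )


@dataclass
class PCAFeatures:
    """Centered PCA of a feature matrix.

    ``loadings`` rows are orthonormal principal axes over voxels (or
    concatenated voxel columns); ``scores`` are the patients' projections;
    ``explained_variance_ratio`` is per component, non-increasing.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    column_means: np.ndarray
    feature_set: FeatureSet | None = None

    def cumulative_ve(self, k: int) -> float:
        """Cumulative explained-variance ratio of the first k components."""
        return float(self.explained_variance_ratio[:k].sum())

    def reconstruct(self, k: int | None = None) -> np.ndarray:
        """Back-project the first k components to the feature space."""
        k = k or self.loadings.shape[0]
        return self.scores[:, :k] @ self.loadings[:k] + self.column_means


def pca_features(X: FeatureSet, k_max: int | None = None) -> PCAFeatures:
    """Centered PCA via SVD, keeping up to ``k_max`` components."""
    n, p = X.matrix.shape
    limit = min(n - 1, p)
    if k_max is None:
        k_max = limit
    if not (1 <= k_max <= limit):
        raise ValueError(f"k_max must be in [1, {limit}] for a {n}x{p} matrix")
    pca = PCA(n_components=k_max, svd_solver="full")
    scores = pca.fit_transform(X.matrix)
    return PCAFeatures(
        scores=scores,
        loadings=pca.components_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        column_means=pca.mean_,
        feature_set=X,
    )


# ---------------------------------------------------------------------------
# behavior preparation
# ---------------------------------------------------------------------------

def impute_behavior(
    table: pd.DataFrame,
    seed: int = 0,
    *,
    max_iter: int = 10,
    tol: float = 1e-3,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing score cells by iterative chained tree-ensemble regression.

    Each incomplete score column is round-robin regressed on the other
    scores with an extra-trees ensemble until the imputed cells move less
    than ``tol`` or ``max_iter`` rounds pass.  Observed cells are never
    modified; confound columns are never imputed.  Returns the completed
    table and a log of (row, column) cells filled.  Deterministic per seed.
    """
    scores = table[list(SCORE_COLUMNS)]
    missing = scores.isna()
    if missing.all(axis=0).any():
        empty = [c for c in SCORE_COLUMNS if missing[c].all()]
        raise ValueError(f"cannot impute entirely missing column(s) {empty}")
    log = pd.DataFrame(
        [(int(i), c) for c in SCORE_COLUMNS for i in np.flatnonzero(missing[c].to_numpy())],
        columns=["row", "score"],
    )
    if not missing.to_numpy().any():
        return table.copy(), log
    imputer = IterativeImputer(
        estimator=ExtraTreesRegressor(n_estimators=n_estimators, random_state=seed),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = imputer.fit_transform(scores.to_numpy(dtype=float))
    out = table.copy()
    out[list(SCORE_COLUMNS)] = filled
    return out, log


@dataclass
class PreparedBehavior:
    """Residualized, z-scored behavior ready for the CCA."""

    Y: np.ndarray  # patients x 4, mean 0 / sd 1 per column
    confounds: np.ndarray
    score_names: tuple[str, ...] = SCORE_COLUMNS
    imputation_log: pd.DataFrame | None = None
    zero_variance: np.ndarray | None = None


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Remove confound effects from score columns by per-column OLS.

    Fits ordinary least squares of each score on the confounds (with
    intercept), keeps the residuals, and z-scores them.  Collinear confound
    designs fall back to the pseudo-inverse with a warning.  Residual
    columns with zero variance are flagged and left at zero.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, Y: np.ndarray, C: np.ndarray):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        C = np.atleast_2d(np.asarray(C, dtype=float))
        if np.any(np.isnan(C)):
            raise ValueError("confounds must be complete (no NaN)")
        n = Y.shape[0]
        if n <= C.shape[1] + 1:
            raise ValueError("need more patients than confounds + intercept")
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            logger.warning("collinear confounds; using pseudo-inverse")
        self.design_ = design
        self.beta_, *_ = np.linalg.lstsq(design, Y, rcond=None)
        return self

    def transform(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        resid = Y - self.design_ @ self.beta_
        sd = resid.std(axis=0, ddof=self.ddof)
        # residual variance at numerical-noise level counts as zero
        scale = np.maximum(Y.std(axis=0), 1.0)
        self.zero_variance_ = sd <= 1e-8 * scale
        if self.zero_variance_.any():
            logger.warning(
                "zero-variance residual column(s) %s; left at zero",
                np.flatnonzero(self.zero_variance_).tolist(),
            )
        resid = resid - resid.mean(axis=0)
        return resid / np.where(self.zero_variance_, 1.0, sd)


def regress_confounds(
    table: pd.DataFrame, imputation_log: pd.DataFrame | None = None
) -> PreparedBehavior:
    """Residualize the four scores on (age, TBSAA, lesion size), z-score."""
    Y = table[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    if np.any(np.isnan(Y)):
        raise ValueError("scores contain missing values; impute first")
    C = table[list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    reg = ConfoundRegressor()
    Yr = reg.fit(Y, C).transform(Y)
    return PreparedBehavior(
        Y=Yr,
        confounds=C,
        imputation_log=imputation_log,
        zero_variance=reg.zero_variance_,
    )
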