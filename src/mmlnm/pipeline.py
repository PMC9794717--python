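"""High-level association pipeline shared by LSM and LNM analyses.

One code path covers all four analyses — LSM (raw lesion maps), unimodal SC,
unimodal FC and multimodal SC+FC: build the union mask(s), assemble the
feature matrix (log-transforming SC; standardizing both modalities before
concatenation), reduce with PCA, prepare behavior (imputation + confound
regression), run the iterative LOOCV-CCA with permutation selection, and
back-project the best solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cca import BrainWeightMap, CCASelection, IterativeCCA, backproject
from .features import (
    FeatureSet,
    PCAFeatures,
    assemble_matrix,
    build_union_mask,
    concat_modalities,
    impute_behavior,
    pca_features,
    regress_confounds,
)
from .volumes import Volume

__all__ = ["AssociationResult", "build_features", "run_association"]


@dataclass
class AssociationResult:
    """Everything the association stage produces for one analysis."""

    selection: CCASelection
    pca: PCAFeatures
    features: FeatureSet
    behavior: "np.ndarray"
    maps: BrainWeightMap | tuple[BrainWeightMap, BrainWeightMap] | None
    imputation_log: pd.DataFrame | None = None

    @property
    def summary(self) -> dict:
        sel = self.selection
        out = {
            "n_components": sel.n_components,
            "T": sel.t,
            "Ve": sel.ve,
            "significant": sel.significant,
        }
        if sel.significant:
            row = sel.scan[sel.scan["k"] == sel.n_components].iloc[0]
            out.update(p=float(row["p"]), p_err=float(row["p_err"]))
        return out


def build_features(
    maps: Sequence[Volume] | dict[str, Sequence[Volume]],
    modality: str,
) -> FeatureSet:
    """Assemble the feature matrix for one analysis.

    ``modality`` is one of ``lesion``, ``sc``, ``fc`` or ``sc+fc``; for the
    multimodal case ``maps`` must be a dict with keys ``sc`` and ``fc`` and
    both matrices are column-standardized before concatenation.
    """
    modality = modality.lower()
    if modality == "sc+fc":
        if not isinstance(maps, dict):
            raise ValueError("multimodal analysis needs {'sc': [...], 'fc': [...]}")
        sc_mask = build_union_mask(maps["sc"], "SC")
        fc_mask = build_union_mask(maps["fc"], "FC")
        sc = assemble_matrix(maps["sc"], sc_mask, "SC", standardize=True)
        fc = assemble_matrix(maps["fc"], fc_mask, "FC", standardize=True)
        return concat_modalities(sc, fc)
    if isinstance(maps, dict):
        maps = maps[modality]
    name = {"lesion": "LESION", "sc": "SC", "fc": "FC"}[modality]
    mask = build_union_mask(maps, name)
    return assemble_matrix(maps, mask, name)


def run_association(
    maps: Sequence[Volume] | dict[str, Sequence[Volume]],
    behavior: pd.DataFrame,
    modality: str = "lesion",
    *,
    k_max: int | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    z_threshold: float = 2.0,
) -> AssociationResult:
    """Run the full association pipeline for one analysis mode."""
    features = build_features(maps, modality)
    imputed, log = impute_behavior(behavior, seed=seed)
    prepared = regress_confounds(imputed, log)
    pca = pca_features(features, k_max=k_max)
    est = IterativeCCA(
        k_max=k_max, n_perm=n_perm, alpha=alpha, random_state=seed
    ).fit(pca.scores, prepared.Y)
    selection = est.selection(pca)
    maps_out = None
    if selection.significant:
        maps_out = backproject(
            selection.x_weights, pca, features, z_threshold=z_threshold
        )
    return AssociationResult(
        selection=selection,
        pca=pca,
        features=features,
        behavior=prepared.Y,
        maps=maps_out,
        imputation_log=log,
    )
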