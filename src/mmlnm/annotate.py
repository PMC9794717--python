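"""Atlas annotation, hemispheric lateralization tests and cohort summaries."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CONFOUND_COLUMNS, SCORE_COLUMNS
from .volumes import Volume

__all__ = [
    "atlas_overlap",
    "hemisphere_counts",
    "lr_proportion_test",
    "cohort_report",
]


def _hemisphere_of(indices: np.ndarray, axis_len: int) -> np.ndarray:
    """L / R / M per voxel index along the midline axis (lower index = L).

    Voxels exactly on the central plane (odd axis length) are midline and
    excluded from left/right totals.
    """
    mid = (axis_len - 1) / 2.0
    out = np.where(indices < mid, "L", "R")
    out[indices == mid] = "M"
    return out


def atlas_overlap(
    thresholded: Volume,
    labels: Volume,
    label_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Count supra-threshold voxels per atlas label, split by hemisphere.

    ``labels`` is an integer label volume (0 = background).  Returns one row
    per non-background label with columns (label, name, n_voxels, n_left,
    n_right, hemisphere) where hemisphere is the label's dominant side.
    """
    if thresholded.grid != labels.grid:
        raise ValueError("map and label volume must share a grid")
    lab = np.asarray(labels.data).astype(int)
    if lab.min() < 0:
        raise ValueError("labels must be non-negative integers")
    supra = np.asarray(thresholded.data) != 0
    axis = thresholded.grid.midline_axis
    axis_len = thresholded.grid.shape[axis]

    rows = []
    for lid in np.unique(lab):
        if lid == 0:
            continue
        sel = (lab == lid) & supra
        idx = np.argwhere(sel)
        hemis = _hemisphere_of(idx[:, axis], axis_len) if len(idx) else np.array([])
        n_l = int(np.sum(hemis == "L"))
        n_r = int(np.sum(hemis == "R"))
        dominant = "L" if n_l > n_r else ("R" if n_r > n_l else "M")
        rows.append(
            {
                "label": int(lid),
                "name": (label_names or {}).get(int(lid), f"label-{lid}"),
                "n_voxels": int(sel.sum()),
                "n_left": n_l,
                "n_right": n_r,
                "hemisphere": dominant,
            }
        )
    return pd.DataFrame(rows, columns=["label", "name", "n_voxels", "n_left", "n_right", "hemisphere"])


def hemisphere_counts(thresholded: Volume) -> tuple[int, int]:
    """(left, right) supra-threshold voxel counts; midline voxels excluded."""
    supra = np.asarray(thresholded.data) != 0
    axis = thresholded.grid.midline_axis
    idx = np.argwhere(supra)
    hemis = _hemisphere_of(idx[:, axis], thresholded.grid.shape[axis])
    return int(np.sum(hemis == "L")), int(np.sum(hemis == "R"))


def lr_proportion_test(
    counts_a: tuple[int, int], counts_b: tuple[int, int], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square comparing L/R voxel proportions of two analyses.

    Uncorrected by default (no Yates continuity correction); 1 degree of
    freedom.  Returns (chi2, p).
    """
    table = np.asarray([counts_a, counts_b], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("chi-square undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def cohort_report(
    behavior: pd.DataFrame, lesions: Sequence[Volume] | None = None
) -> dict:
    """Cohort summary: L/R score comparisons, score and confound correlations.

    Per-score Kruskal-Wallis tests (reported as a chi-square statistic)
    compare patients with left- versus right-hemisphere lesions (hemisphere
    from the lesion center of mass); pairwise Pearson correlations are given
    among the four scores and between scores and confounds, plus the lesion
    size distribution.
    """
    out: dict = {}
    scores = behavior[list(SCORE_COLUMNS)]

    if lesions is not None:
        sides = []
        for mk in lesions:
            axis = mk.grid.midline_axis
            idx = np.argwhere(np.asarray(mk.data) > 0)
            com = idx[:, axis].mean()
            sides.append("L" if com < (mk.grid.shape[axis] - 1) / 2 else "R")
        sides = np.asarray(sides)
        kw_rows = []
        for col in SCORE_COLUMNS:
            vals = scores[col].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            left = vals[ok & (sides == "L")]
            right = vals[ok & (sides == "R")]
            if len(left) < 2 or len(right) < 2:
                kw_rows.append({"score": col, "chi2": np.nan, "p": np.nan,
                                "note": "a group has < 2 patients; skipped"})
                continue
            chi2, p = stats.kruskal(left, right)
            kw_rows.append({"score": col, "chi2": float(chi2), "p": float(p), "note": ""})
        out["left_right_comparison"] = pd.DataFrame(kw_rows)
        out["hemisphere"] = sides

    pair_rows = []
    cols = list(SCORE_COLUMNS)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = scores[cols[i]].to_numpy(dtype=float)
            b = scores[cols[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(a) | np.isnan(b))
            r, p = stats.pearsonr(a[ok], b[ok])
            pair_rows.append({"score_a": cols[i], "score_b": cols[j], "r": float(r), "p": float(p)})
    out["score_correlations"] = pd.DataFrame(pair_rows)

    conf_rows = []
    for conf in CONFOUND_COLUMNS:
        if conf not in behavior.columns:
            continue
        c = behavior[conf].to_numpy(dtype=float)
        for col in SCORE_COLUMNS:
            v = scores[col].to_numpy(dtype=float)
            ok = ~np.isnan(v)
            r, p = stats.pearsonr(c[ok], v[ok])
            conf_rows.append({"confound": conf, "score": col, "r": float(r), "p": float(p)})
    out["confound_correlations"] = pd.DataFrame(conf_rows)

    if "lesion_size" in behavior.columns:
        ls = behavior["lesion_size"].to_numpy(dtype=float)
        out["lesion_size"] = {
            "mean": float(ls.mean()),
            "sd": float(ls.std(ddof=1)) if len(ls) > 1 else 0.0,
            "min": float(ls.min()),
            "max": float(ls.max()),
        }
    return out
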