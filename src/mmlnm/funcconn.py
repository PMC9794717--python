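"""Functional disconnection mapping from a normative cohort.

Per normative subject: motion/DVARS volume censoring, simultaneous nuisance
regression + band-pass, spatial smoothing, lesion-seeded correlation with
Fisher z-transform.  Per patient: a one-sample T-map of the z-maps across
the cohort — the functional disconnection map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter

from .synthetic import NormativeSubject
from .volumes import GridSpec, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "CensorParams",
    "SBCMap",
    "FCDisconnectionMap",
    "censor_volumes",
    "regress_nuisance",
    "smooth_gaussian",
    "seed_series",
    "sbc_fisher",
    "group_t_map",
    "patient_fc_map",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
R_CLIP = 1.0 - 1e-7  # |r| clip before artanh, avoids infinities


@dataclass(frozen=True)
class CensorParams:
    """Volume-censoring thresholds and segmentation rule.

    A volume is censored when frame-wise displacement exceeds
    ``fd_threshold`` (mm) or the backward difference of the DVARS series
    exceeds ``dvars_threshold`` (percent).  ``n_before`` preceding and
    ``n_after`` following volumes are censored too; the series is then split
    into consecutive segments of ``segment_length`` volumes, any segment
    containing a censored volume is dropped, and so is the first segment.
    """

    fd_threshold: float = 0.2
    dvars_threshold: float = 0.75
    n_before: int = 1
    n_after: int = 2
    segment_length: int = 5

    def __post_init__(self) -> None:
        if self.fd_threshold <= 0 or self.dvars_threshold <= 0:
            raise ValueError("censoring thresholds must be positive")
        if self.segment_length < 1:
            raise ValueError("segment_length must be >= 1")


def censor_volumes(
    fd: np.ndarray, dvars: np.ndarray, params: CensorParams = CensorParams()
) -> np.ndarray:
    """Return a boolean keep-mask over volumes after motion scrubbing.

    The DVARS rule fires on the backward difference, so the first volume can
    only be censored by the FD rule or by proximity expansion.  Segmentation
    treats a trailing partial block as a segment (kept if uncontaminated).
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError(f"fd ({fd.shape}) and dvars ({dvars.shape}) length mismatch")
    T = fd.size
    if T < params.segment_length:
        raise ValueError("series shorter than one segment")

    censored = fd > params.fd_threshold
    d_dvars = np.zeros(T)
    d_dvars[1:] = np.diff(dvars)
    censored |= d_dvars > params.dvars_threshold

    expanded = censored.copy()
    for t in np.flatnonzero(censored):
        lo = max(t - params.n_before, 0)
        hi = min(t + params.n_after, T - 1)
        expanded[lo : hi + 1] = True

    keep = np.ones(T, dtype=bool)
    L = params.segment_length
    for s, start in enumerate(range(0, T, L)):
        seg = slice(start, min(start + L, T))
        if s == 0 or expanded[seg].any():
            keep[seg] = False
    return keep


def regress_nuisance(
    series: np.ndarray,
    nuisance: np.ndarray | None,
    band: tuple[float, float] = (0.01, 0.08),
    tr: float = 0.72,
    order: int = 4,
) -> np.ndarray:
    """Simultaneous nuisance regression and band-pass filtering.

    ``series`` is timepoints x voxels.  Both data and nuisance regressors
    are band-pass filtered with the same zero-phase Butterworth filter, then
    the filtered nuisance set (plus intercept) is projected out by ordinary
    least squares — equivalent to the one-step band-limited projection.
    Rank-deficient designs fall back to the pseudo-inverse with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be timepoints x voxels")
    T = series.shape[0]
    nyq = 0.5 / tr
    lo, hi = band
    if not (0 < lo < hi < nyq):
        raise ValueError(f"band {band} invalid for tr={tr} (nyquist {nyq:.3f} Hz)")
    sos = sp_signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    # even-reflection padding keeps filtfilt edge transients (the dominant
    # stop-band leakage on series this short) well under 1% of input power
    padlen = min(T - 1, max(3 * (2 * order + 1), int(1.0 / (lo * tr))))
    filt = lambda x: sp_signal.sosfiltfilt(
        sos, x, axis=0, padtype="even", padlen=padlen
    )

    data_f = filt(series)
    if nuisance is None or np.size(nuisance) == 0:
        return data_f
    nuis = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuis.shape[0] != T:
        raise ValueError("nuisance rows must match series timepoints")
    design = np.column_stack([np.ones(T), filt(nuis)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("rank-deficient nuisance design; using pseudo-inverse")
    beta, *_ = np.linalg.lstsq(design, data_f, rcond=None)
    return data_f - design @ beta


def smooth_gaussian(volume: Volume, fwhm: float) -> Volume:
    """Spatial Gaussian smoothing with a kernel of ``fwhm`` mm (0 = identity).

    Sigma per axis is ``fwhm * FWHM_TO_SIGMA / voxel_size``; a 4D volume is
    smoothed within each 3D frame only.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return Volume(np.array(volume.data, dtype=float), volume.grid, volume.affine)
    sigma = tuple(fwhm * FWHM_TO_SIGMA / v for v in volume.grid.voxel_size)
    if volume.data.ndim == 4:
        sigma = sigma + (0.0,)
    return Volume(
        gaussian_filter(np.asarray(volume.data, dtype=float), sigma=sigma),
        volume.grid,
        volume.affine,
    )


def seed_series(
    series: Volume,
    lesion: Volume,
    gm: Volume | None = None,
    *,
    fallback_whole_lesion: bool = True,
) -> np.ndarray:
    """Mean time series over the lesion voxels (restricted to gray matter).

    With an empty lesion-gray-matter intersection, falls back to whole-lesion
    averaging with a logged warning (or raises if ``fallback_whole_lesion``
    is False).
    """
    mask = np.asarray(lesion.data, dtype=bool)
    if gm is not None:
        inter = mask & np.asarray(gm.data, dtype=bool)
        if inter.sum() == 0:
            if not fallback_whole_lesion:
                raise ValueError("lesion does not intersect the gray-matter mask")
            logger.warning(
                "lesion/gray-matter intersection empty; averaging the whole lesion"
            )
        else:
            mask = inter
    if mask.sum() == 0:
        raise ValueError("empty lesion mask")
    return np.asarray(series.data, dtype=float)[mask].mean(axis=0)


@dataclass
class SBCMap:
    """Seed-based connectivity map: Pearson r and its Fisher z per voxel."""

    r: Volume
    z: Volume
    seed_mask: Volume
    subject_id: str = ""
    zero_variance: np.ndarray | None = None  # flagged voxels (constant series)


def sbc_fisher(series: Volume, seed_ts: np.ndarray, seed_mask: Volume | None = None,
               subject_id: str = "") -> SBCMap:
    """Voxelwise Pearson correlation with the seed, Fisher z = artanh(r).

    |r| is clipped to 1 - 1e-7 before artanh; voxels with zero temporal
    variance get z = 0 and are flagged.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    if seed_ts.std() == 0:
        raise ValueError("seed time series is constant")
    data = np.asarray(series.data, dtype=float)
    T = data.shape[-1]
    if seed_ts.size != T:
        raise ValueError("seed series length must match the 4D series")
    dm = data - data.mean(axis=-1, keepdims=True)
    sm = seed_ts - seed_ts.mean()
    denom = np.sqrt((dm**2).sum(axis=-1)) * np.sqrt((sm**2).sum())
    zero_var = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dm @ sm) / np.where(zero_var, 1.0, denom)
    r[zero_var] = 0.0
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    grid = series.grid
    return SBCMap(
        r=Volume(r, grid),
        z=Volume(z, grid),
        seed_mask=seed_mask if seed_mask is not None else Volume(np.zeros(grid.shape, np.uint8), grid),
        subject_id=subject_id,
        zero_variance=zero_var,
    )


@dataclass
class FCDisconnectionMap:
    """One-sample T-map of Fisher z maps across the normative cohort."""

    t: Volume
    n_subjects: int
    degenerate: np.ndarray | None = None  # voxels with zero across-subject sd


def group_t_map(z_maps: list[Volume], t_max: float = 100.0) -> FCDisconnectionMap:
    """Per-voxel one-sample t = mean / (sd / sqrt(n)) against zero.

    Voxels with zero across-subject variance get t = 0 when the mean is 0
    and a signed sentinel (+/- ``t_max``) otherwise; both are flagged.
    """
    if len(z_maps) < 2:
        raise ValueError("need at least 2 subjects for a T-map")
    grid = z_maps[0].grid
    if any(zm.grid != grid for zm in z_maps):
        raise ValueError("all z-maps must share a grid")
    stack = np.stack([np.asarray(zm.data, dtype=float) for zm in z_maps])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[degenerate] = np.sign(mean[degenerate]) * t_max
    return FCDisconnectionMap(t=Volume(t, grid), n_subjects=n, degenerate=degenerate)


def patient_fc_map(
    lesion: Volume,
    cohort: list[NormativeSubject],
    *,
    censor: CensorParams | None = CensorParams(),
    band: tuple[float, float] = (0.01, 0.08),
    fwhm: float = 6.0,
    max_minutes: float | None = 6.0,
    nuisance: dict[str, np.ndarray] | None = None,
) -> FCDisconnectionMap:
    """Full functional disconnection pipeline for one patient.

    For each normative subject: censor volumes by the subject's FD/DVARS
    traces, truncate to the first ``max_minutes`` of kept data, band-pass +
    regress nuisance (if provided per subject), smooth, seed with the lesion
    (gray-matter restricted) and Fisher-transform; then pool z-maps into the
    one-sample T-map.
    """
    if np.count_nonzero(lesion.data) == 0:
        raise ValueError("empty lesion mask")
    z_maps = []
    for sub in cohort:
        data = np.asarray(sub.series.data, dtype=float)
        T = data.shape[-1]
        if censor is not None and sub.fd is not None and sub.dvars is not None:
            keep = censor_volumes(sub.fd[:T], sub.dvars[:T], censor)
            data = data[..., keep]
        if max_minutes is not None:
            n_keep = int(round(max_minutes * 60.0 / sub.tr))
            data = data[..., :n_keep]
        if data.shape[-1] < 10:
            raise ValueError(f"subject {sub.subject_id}: too few volumes after censoring")
        flat = data.reshape(-1, data.shape[-1]).T  # time x voxels
        nuis = None if nuisance is None else nuisance.get(sub.subject_id)
        cleaned = regress_nuisance(flat, nuis, band=band, tr=sub.tr)
        vol = Volume(cleaned.T.reshape(data.shape), sub.series.grid)
        vol = smooth_gaussian(vol, fwhm)
        ts = seed_series(vol, lesion, sub.gm_mask)
        z_maps.append(sbc_fisher(vol, ts, seed_mask=lesion, subject_id=sub.subject_id).z)
    return group_t_map(z_maps)
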