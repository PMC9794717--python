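"""Synthetic normative cohort, lesions and behavior with known ground truth.

Real lesion network mapping rests on two datasets that cannot ship with a
package: a normative cohort (resting-state series plus a diffusion principal
direction / FA field per subject) and a patient cohort (lesion masks plus
bounded sensorimotor scores).  This module generates stand-ins for both on a
small common grid, with every source of randomness seeded, so that each
downstream stage — seed-based connectivity, deterministic tracking, the
predictive CCA — can be exercised against designed ground truth.

What is emulated
----------------
* 4D functional series: zero-mean Gaussian noise, optionally smoothed in
  space (kernel width parameterizes the spatial correlation structure) and
  optionally carrying shared "network" time courses over designated voxel
  sets so that co-fluctuation with a lesion site is a designed property.
* Direction/FA fields: polyline "tracts" rasterized with a radius; in-tract
  voxels carry the local unit tangent and a high FA, background voxels a low
  FA and a random unit vector.
* Patient lesions: binary balls on the grid.
* Behavior: four bounded instruments — ARAT (0-57), FMA-UE (0-66), Em-NSA
  (0-40) and PTT (mA, censored at 11) — produced from a linear map of
  disconnection features plus confound effects (age, days since stroke,
  lesion size) and Gaussian noise, then discretized by the instrument
  scoring rules, with completely-at-random missingness on scores only.

None of this models hemodynamics, physiological noise, diffusion signal
formation or realistic lesion shapes; it provides controllable statistical
structure, not biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volumes import GridSpec, Volume

__all__ = [
    "TractSpec",
    "NormativeSubject",
    "BehaviorGenSpec",
    "make_tract_field",
    "make_normative_subject",
    "make_lesion",
    "score_instruments",
    "make_behavior",
    "make_confounds",
    "make_cohort",
    "make_association_fixture",
]

#: Instrument ceilings: ARAT 19 items x 0-3 = 57; FMA-UE 33 items x 0-2 = 66
#: (the item decomposition is a documented stand-in; only the 0-66 range is
#: prescribed); Em-NSA 5 modalities x 0-8 = 40; PTT in mA, ceiling 10 with 11
#: assigned when nothing is felt at maximal stimulation.
SCORE_COLUMNS = ("ARAT", "FMA_UE", "EM_NSA", "PTT")
CONFOUND_COLUMNS = ("age", "tbsaa", "lesion_size")
SCORE_MAX = {"ARAT": 57, "FMA_UE": 66, "EM_NSA": 40, "PTT": 11.0}


@dataclass(frozen=True)
class TractSpec:
    """A designed white-matter "tract": a polyline with a tubular radius.

    ``polyline`` is an ordered list of continuous voxel-index coordinates;
    ``radius`` is in mm.  Voxels within the radius carry ``fa_inside`` and
    the local tangent; everything else carries ``fa_outside``.
    """

    polyline: tuple[tuple[float, float, float], ...]
    radius: float = 2.0
    fa_inside: float = 0.6
    fa_outside: float = 0.05

    def __post_init__(self) -> None:
        pl = tuple(tuple(float(c) for c in p) for p in self.polyline)
        if len(pl) < 2:
            raise ValueError("tract polyline needs at least 2 points")
        if not (0 < self.fa_inside <= 1):
            raise ValueError("fa_inside must be in (0, 1]")
        if not (0 <= self.fa_outside < 1):
            raise ValueError("fa_outside must be in [0, 1)")
        if self.fa_inside <= self.fa_outside:
            raise ValueError("fa_inside must exceed fa_outside")
        object.__setattr__(self, "polyline", pl)


@dataclass
class NormativeSubject:
    """One synthetic control: functional series + masks + diffusion fields."""

    subject_id: str
    series: Volume  # 4D (x, y, z, t)
    gm_mask: Volume  # uint8
    directions: Volume  # 4D (x, y, z, 3), unit vectors
    fa: Volume  # 3D in [0, 1]
    tr: float = 0.72  # seconds per volume
    fd: np.ndarray | None = None  # frame-wise displacement trace (mm)
    dvars: np.ndarray | None = None  # percent signal-change trace


def make_tract_field(
    grid: GridSpec,
    tracts: Sequence[TractSpec],
    seed: int,
) -> tuple[Volume, Volume]:
    """Rasterize tract polylines into a (direction field, FA volume) pair.

    In-tract voxels (within ``radius`` mm of the densely sampled polyline)
    take the unit tangent of the nearest polyline sample and ``fa_inside``;
    background voxels take ``fa_outside`` (of the first tract, or 0 with no
    tracts) and a seeded random unit vector.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    shape = grid.shape
    vs = np.asarray(grid.voxel_size)

    # background: random unit directions, low FA
    dirs = rng.standard_normal(shape + (3,))
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
    fa_bg = tracts[0].fa_outside if len(tracts) else 0.0
    fa = np.full(shape, fa_bg, dtype=float)

    for tract in tracts:
        pts = np.asarray(tract.polyline, dtype=float)
        if np.any(pts < -0.5) or np.any(pts > np.asarray(shape) - 0.5):
            raise ValueError(
                f"tract polyline leaves the grid: extent {pts.min(0)}..{pts.max(0)} "
                f"vs shape {shape}"
            )
        samples, tangents = _sample_polyline(pts, vs)
        r_vox = np.ceil(tract.radius / vs).astype(int)
        seen: dict[tuple[int, int, int], float] = {}
        for p, t in zip(samples, tangents):
            lo = np.maximum(np.round(p).astype(int) - r_vox, 0)
            hi = np.minimum(np.round(p).astype(int) + r_vox, np.asarray(shape) - 1)
            xs, ys, zs = (np.arange(lo[k], hi[k] + 1) for k in range(3))
            gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
            d2 = (
                ((gx - p[0]) * vs[0]) ** 2
                + ((gy - p[1]) * vs[1]) ** 2
                + ((gz - p[2]) * vs[2]) ** 2
            )
            inside = d2 <= tract.radius**2
            for ix, iy, iz, dd in zip(
                gx[inside], gy[inside], gz[inside], d2[inside]
            ):
                key = (int(ix), int(iy), int(iz))
                if key not in seen or dd < seen[key]:
                    seen[key] = dd
                    dirs[key] = t
                    fa[key] = tract.fa_inside
    return Volume(dirs, grid), Volume(fa, grid)


def _sample_polyline(
    pts: np.ndarray, voxel_size: np.ndarray, step: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Densely sample a polyline (voxel coords) and its unit tangents."""
    samples, tangents = [], []
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = float(np.linalg.norm(seg * voxel_size))
        if length == 0:
            continue
        tangent = seg / np.linalg.norm(seg)
        n = max(int(np.ceil(length / (step * voxel_size.min()))), 1)
        for frac in np.linspace(0.0, 1.0, n + 1):
            samples.append(a + frac * seg)
            tangents.append(tangent)
    return np.asarray(samples), np.asarray(tangents)


def make_normative_subject(
    grid: GridSpec,
    n_timepoints: int,
    spatial_corr: float,
    tracts: Sequence[TractSpec],
    seed: int,
    *,
    tr: float = 0.72,
    gm_margin: int = 1,
    networks: Sequence[np.ndarray] = (),
    network_amplitude: float = 1.0,
    subject_id: str | None = None,
) -> NormativeSubject:
    """Generate one synthetic control subject.

    Parameters
    ----------
    spatial_corr : float
        Gaussian kernel width (sigma, mm) applied to each timepoint of the
        white-noise series; 0 leaves voxels independent.
    networks : sequence of boolean arrays
        Optional voxel sets that each share an additional common time course
        of standard deviation ``network_amplitude`` — designed functional
        co-fluctuation for end-to-end tests.
    gm_margin : int
        The gray-matter mask covers the grid interior, excluding a margin of
        this many voxels at each face.
    """
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")
    rng = np.random.default_rng(seed)
    shape = grid.shape
    series = rng.standard_normal(shape + (n_timepoints,))
    if spatial_corr > 0:
        sigma_vox = tuple(spatial_corr / v for v in grid.voxel_size) + (0.0,)
        series = gaussian_filter(series, sigma=sigma_vox)
        # restore unit marginal variance so amplitudes stay comparable
        series /= max(series.std(), 1e-12)
    for net in networks:
        net = np.asarray(net, dtype=bool)
        tc = rng.standard_normal(n_timepoints) * network_amplitude
        series[net] += tc

    gm = np.zeros(shape, dtype=np.uint8)
    m = gm_margin
    gm[m : shape[0] - m, m : shape[1] - m, m : shape[2] - m] = 1

    dirs, fa = make_tract_field(grid, tracts, seed=seed + 1)
    return NormativeSubject(
        subject_id=subject_id or f"sub-{seed:05d}",
        series=Volume(series.astype(np.float32), grid),
        gm_mask=Volume(gm, grid),
        directions=dirs,
        fa=fa,
        tr=tr,
        fd=np.zeros(n_timepoints),
        dvars=np.zeros(n_timepoints),
    )


def make_lesion(
    grid: GridSpec, center: Sequence[float], radius: float
) -> Volume:
    """Binary ball lesion: voxel centers within ``radius`` mm of ``center``.

    ``center`` is a continuous voxel-index coordinate.  Lesion size in cm^3
    is exactly voxel count x voxel volume.
    """
    center = np.asarray(center, dtype=float)
    if not grid.contains(center):
        raise ValueError(f"lesion center {center} outside grid {grid.shape}")
    vs = np.asarray(grid.voxel_size)
    idx = np.indices(grid.shape)
    d2 = sum(((idx[k] - center[k]) * vs[k]) ** 2 for k in range(3))
    mask = (d2 <= radius**2).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError(
            f"radius {radius} mm covers no voxel centers (min voxel edge "
            f"{vs.min()} mm); lesion would be empty"
        )
    return Volume(mask, grid)


def lesion_size_cm3(mask: Volume) -> float:
    """Lesion size = voxel count x voxel volume (cm^3)."""
    return float(np.count_nonzero(mask.data)) * mask.grid.voxel_volume_cm3


# ---------------------------------------------------------------------------
# behavioral instruments
# ---------------------------------------------------------------------------

def score_instruments(
    arat_latent: np.ndarray,
    fma_latent: np.ndarray,
    emnsa_latent: np.ndarray,
    ptt_latent: np.ndarray,
) -> pd.DataFrame:
    """Discretize latent impairment values through the instrument rules.

    ARAT: 19 items in {0,1,2,3} filled cumulatively from the latent total,
    so the sum equals the latent clipped to [0, 57].  FMA-UE: 33 items in
    {0,1,2} summing to the latent clipped to [0, 66].  Em-NSA: 5 modalities
    of 4 contact points graded 0/1/2 (0-8 per modality), summing to the
    latent clipped to [0, 40].  PTT: perceptual threshold of touch in mA,
    clipped to (0, 10]; a latent threshold above 10 mA (nothing felt at
    maximal stimulation) is awarded 11.  Higher PTT = worse somatosensation.
    """
    arat_latent, fma_latent, emnsa_latent, ptt_latent = (
        np.atleast_1d(np.asarray(v, dtype=float))
        for v in (arat_latent, fma_latent, emnsa_latent, ptt_latent)
    )
    if not all(
        np.all(np.isfinite(v))
        for v in (arat_latent, fma_latent, emnsa_latent, ptt_latent)
    ):
        raise ValueError("latent impairment values must be finite")

    def _sum_of_items(latent, n_items, item_max):
        # cumulative (Guttman-style) filling: item i scores
        # clip(total - item_max*i, 0, item_max); the sum is the clipped,
        # rounded total, and every item respects its own range.
        total = np.clip(np.round(latent), 0, n_items * item_max)
        items = np.clip(
            total[:, None] - item_max * np.arange(n_items)[None, :], 0, item_max
        )
        return items.sum(axis=1).astype(int)

    arat = _sum_of_items(arat_latent, 19, 3)
    fma = _sum_of_items(fma_latent, 33, 2)
    emnsa = _sum_of_items(emnsa_latent, 20, 2)  # 5 modalities x 4 points x 0/1/2
    ptt = np.where(ptt_latent > 10.0, 11.0, np.clip(ptt_latent, 0.1, 10.0))
    return pd.DataFrame(
        {"ARAT": arat, "FMA_UE": fma, "EM_NSA": emnsa, "PTT": np.round(ptt, 2)}
    )


@dataclass
class BehaviorGenSpec:
    """Generative model for the behavior table.

    ``weights`` has one column per score over the disconnection features;
    ``confound_effects`` maps (age years, TBSAA days, lesion size cm^3) to
    latent score units; ``noise_sd`` is per-score Gaussian noise in score
    units; ``missing_rate`` applies completely at random to scores only.

    Defaults place the cohort at the observed means of a moderately impaired
    stroke sample (ARAT ~15, FMA-UE ~26, Em-NSA ~29, PTT ~6.7) and give the
    confounds effect sizes that reproduce the reported sign and rough
    magnitude of their score correlations (days-since-stroke raises Em-NSA,
    lesion size lowers Em-NSA and raises PTT).
    """

    weights: np.ndarray | None = None  # (n_features, 4)
    intercepts: tuple[float, float, float, float] = (15.2, 26.2, 28.6, 6.7)
    confound_effects: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # ARAT    FMA_UE   EM_NSA   PTT     per unit of:
                [0.00, 0.00, 0.00, 0.000],  # age (years)
                [0.00, 0.00, 0.22, 0.000],  # TBSAA (days)
                [0.00, 0.00, -0.11, 0.021],  # lesion size (cm^3)
            ]
        )
    )
    noise_sd: tuple[float, float, float, float] = (9.0, 10.0, 5.0, 1.2)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be >= 0")


def make_confounds(n: int, seed: int) -> pd.DataFrame:
    """Draw (age, TBSAA) confounds matching the cohort's demographics.

    Age ~ N(68.8, 14.0) clipped to [28, 92] years; TBSAA ~ N(25.6, 20.3)
    clipped to [4, 64] days.  Lesion size is supplied separately (it comes
    from the generated masks).
    """
    rng = np.random.default_rng(seed)
    age = np.clip(rng.normal(68.78, 13.98, n), 28, 92)
    tbsaa = np.clip(rng.normal(25.61, 20.32, n), 4, 64)
    return pd.DataFrame({"age": np.round(age, 1), "tbsaa": np.round(tbsaa, 1)})


def make_behavior(
    features: np.ndarray,
    spec: BehaviorGenSpec,
    confounds: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Generate the behavior table from disconnection features.

    ``features`` is patients x features (row-aligned with ``confounds``,
    which must contain age, tbsaa and lesion_size columns).  Latent scores
    are ``intercepts + features @ weights + confounds @ confound_effects +
    noise``, discretized by :func:`score_instruments`; missingness is then
    applied at ``missing_rate`` to score cells only.  Returns the table
    (scores + confounds) and a ground-truth dict for recovery tests.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = features.shape[0]
    if len(confounds) != n:
        raise ValueError(
            f"features rows ({n}) and confounds rows ({len(confounds)}) differ"
        )
    missing_cols = [c for c in CONFOUND_COLUMNS if c not in confounds.columns]
    if missing_cols:
        raise ValueError(f"confounds table lacks columns {missing_cols}")
    rng = np.random.default_rng(spec.seed)
    weights = (
        np.zeros((features.shape[1], 4))
        if spec.weights is None
        else np.asarray(spec.weights, dtype=float)
    )
    if weights.shape[0] != features.shape[1]:
        raise ValueError("weights rows must match feature columns")

    conf = confounds[list(CONFOUND_COLUMNS)].to_numpy(dtype=float)
    latent = (
        np.asarray(spec.intercepts)[None, :]
        + features @ weights
        + (conf - conf.mean(axis=0)) @ np.asarray(spec.confound_effects)
        + rng.standard_normal((n, 4)) * np.asarray(spec.noise_sd)[None, :]
    )
    scores = score_instruments(latent[:, 0], latent[:, 1], latent[:, 2], latent[:, 3])

    if spec.missing_rate > 0:
        miss = rng.random((n, 4)) < spec.missing_rate
        svals = scores.to_numpy(dtype=float)
        svals[miss] = np.nan
        scores = pd.DataFrame(svals, columns=scores.columns)

    table = pd.concat([scores, confounds[list(CONFOUND_COLUMNS)]], axis=1)
    truth = {
        "weights": weights,
        "latent": latent,
        "intercepts": np.asarray(spec.intercepts),
        "confound_effects": np.asarray(spec.confound_effects),
    }
    return table, truth


# ---------------------------------------------------------------------------
# cohort-level convenience generators
# ---------------------------------------------------------------------------

def make_cohort(
    grid: GridSpec,
    n_controls: int,
    n_patients: int,
    seed: int,
    *,
    n_timepoints: int = 120,
    spatial_corr: float = 2.0,
    tracts: Sequence[TractSpec] | None = None,
    lesion_radius_mm: tuple[float, float] = (3.0, 8.0),
    tr: float = 0.72,
    networks: Sequence[np.ndarray] = (),
    network_amplitude: float = 1.0,
) -> tuple[list[NormativeSubject], list[Volume], pd.DataFrame]:
    """Generate a normative cohort, patient lesions and confounds.

    Lesion centers are drawn uniformly over the grid interior, alternating
    hemispheres so left/right groups stay balanced; radii are uniform in
    ``lesion_radius_mm``.  Returns (controls, lesion masks, confounds with
    lesion_size filled in).
    """
    rng = np.random.default_rng(seed)
    if tracts is None:
        tracts = default_tracts(grid)
    controls = [
        make_normative_subject(
            grid,
            n_timepoints,
            spatial_corr,
            tracts,
            seed=int(rng.integers(2**31 - 1)),
            tr=tr,
            networks=networks,
            network_amplitude=network_amplitude,
            subject_id=f"ctl-{i:04d}",
        )
        for i in range(n_controls)
    ]
    shape = np.asarray(grid.shape)
    mid_ax = grid.midline_axis
    lesions = []
    for i in range(n_patients):
        center = 1.5 + rng.random(3) * (shape - 4.0)
        half = shape[mid_ax] / 2
        # alternate hemispheres for balanced left/right groups
        if (i % 2 == 0) == (center[mid_ax] >= half):
            center[mid_ax] = shape[mid_ax] - 1 - center[mid_ax]
        radius = rng.uniform(*lesion_radius_mm)
        lesions.append(make_lesion(grid, center, radius))
    confounds = make_confounds(n_patients, seed=int(rng.integers(2**31 - 1)))
    confounds["lesion_size"] = [round(lesion_size_cm3(m), 3) for m in lesions]
    return controls, lesions, confounds


def default_tracts(grid: GridSpec) -> list[TractSpec]:
    """Three designed tracts spanning the grid (one per axis, offset)."""
    nx, ny, nz = grid.shape
    r = 1.1 * min(grid.voxel_size)
    return [
        TractSpec(((1.0, ny * 0.35, nz * 0.5), (nx - 2.0, ny * 0.35, nz * 0.5)), radius=r),
        TractSpec(((nx * 0.65, 1.0, nz * 0.4), (nx * 0.65, ny - 2.0, nz * 0.4)), radius=r),
        TractSpec(((nx * 0.3, ny * 0.65, 1.0), (nx * 0.3, ny * 0.65, nz - 2.0)), radius=r),
    ]


def make_association_fixture(
    n_patients: int = 60,
    grid: GridSpec | None = None,
    seed: int = 0,
    *,
    n_patterns: int = 5,
    signal_sd: float = 1.0,
    voxel_noise_sd: float = 0.6,
    score_loadings: tuple[float, float, float, float] = (-10.0, -11.0, -7.0, 2.6),
    noise_sd: tuple[float, float, float, float] = (9.0, 10.0, 7.0, 1.2),
    missing_rate: float = 0.0,
) -> dict:
    """Patient disconnection-feature maps + behavior from a known voxel map.

    Each patient's map is a random combination of ``n_patterns`` smooth
    spatial patterns plus voxel noise; the patient's loading on the *first*
    pattern is the latent disconnection burden that drives behavior through
    ``score_loadings`` (score units per SD of burden: more disconnection
    lowers ARAT/FMA-UE/Em-NSA and raises the PTT touch threshold).  The
    default loadings and noise make PTT clearly dominant on the
    standardized scale (|loading|/noise ~2.2 vs <= 1.1 for the others), so
    the generative dominant score is unambiguous and weight-rank recovery
    is a well-posed check.  The generative voxel map to recover is the
    first pattern.

    Returns a dict with ``maps`` (list of Volume), ``behavior`` (table with
    confounds), ``truth`` (generative voxel map volume, burden, loadings)
    and ``grid``.
    """
    if grid is None:
        grid = GridSpec((14, 14, 12), (2.0, 2.0, 2.0))
    rng = np.random.default_rng(seed)
    shape = grid.shape
    nvox = int(np.prod(shape))

    patterns = rng.standard_normal((n_patterns,) + shape)
    patterns = np.stack([gaussian_filter(p, sigma=1.5) for p in patterns])
    patterns /= patterns.reshape(n_patterns, -1).std(axis=1)[:, None, None, None]

    loadings = rng.standard_normal((n_patients, n_patterns)) * signal_sd
    maps_arr = (
        np.tensordot(loadings, patterns, axes=(1, 0))
        + rng.standard_normal((n_patients,) + shape) * voxel_noise_sd
    )
    maps = [Volume(maps_arr[i].astype(np.float32), grid) for i in range(n_patients)]

    burden = loadings[:, 0]  # SD ~ signal_sd by construction
    confounds = make_confounds(n_patients, seed=seed + 1)
    confounds["lesion_size"] = np.round(
        np.clip(rng.lognormal(mean=2.9, sigma=1.1, size=n_patients), 0.3, 256.0), 3
    )
    spec = BehaviorGenSpec(
        weights=np.asarray(score_loadings)[None, :] / max(signal_sd, 1e-12),
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed + 2,
    )
    behavior, truth_b = make_behavior(burden[:, None], spec, confounds)
    truth = {
        "map": Volume(patterns[0], grid),
        "burden": burden,
        "score_loadings": np.asarray(score_loadings),
        "weights": truth_b["weights"],
        "n_voxels": nvox,
    }
    return {"maps": maps, "behavior": behavior, "truth": truth, "grid": grid}
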