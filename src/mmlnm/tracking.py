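"""Structural disconnection via FACT-style deterministic streamline tracking.

Streamlines are propagated bidirectionally from every lesion voxel through a
normative subject's principal-direction field, terminating on a fractional
anisotropy threshold, a maximum turning angle, the volume boundary or a step
cap.  Per subject the visited voxels are binarized; the patient's structural
disconnection map is the across-subject mean of these binary maps, so a
voxel reads 1 when the lesion is connected to it in every normative subject
and 0 when it is connected in none.

The stepping rule is the voxel-hop variant of fiber assignment by
continuous tracking: the direction is re-read from the voxel currently
occupied and one voxel-edge step is taken along it, landing on the nearest
voxel.  Principal diffusion directions are sign-ambiguous, so each step the
field vector's sign is chosen to maximize alignment with the incoming
direction, and the very first step goes both ways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import NormativeSubject
from .volumes import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "TrackParams",
    "SCDisconnectionMap",
    "fact_track",
    "visitation_map",
    "sc_disconnection_map",
    "patient_sc_map",
]


@dataclass(frozen=True)
class TrackParams:
    """Termination criteria for deterministic tracking.

    ``fa_threshold`` stops propagation in low-anisotropy tissue; ``max_angle``
    (degrees) bounds the turn between successive step directions; ``step`` is
    the step length in voxel-edge units; ``max_steps`` caps each direction
    (default, set at track time, is twice the grid diagonal in voxels).
    """

    fa_threshold: float = 0.15
    max_angle: float = 60.0
    step: float = 1.0
    max_steps: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fa_threshold < 1):
            raise ValueError("fa_threshold must be in (0, 1)")
        if not (0 < self.max_angle < 180):
            raise ValueError("max_angle must be in (0, 180) degrees")
        if self.max_steps is not None and self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


def fact_track(
    directions: Volume,
    fa: Volume,
    seed: tuple[int, int, int],
    params: TrackParams = TrackParams(),
) -> list[tuple[int, int, int]]:
    """Track one bidirectional streamline from a seed voxel.

    Returns the ordered list of visited voxels (backward leg reversed, seed
    once).  A step is accepted only if the landing voxel is inside the grid,
    passes the FA threshold, and its (sign-aligned) direction turns by at
    most ``max_angle`` from the incoming direction; the offending landing
    voxel is excluded.  A seed below the FA threshold yields an empty
    streamline.
    """
    dir_field = np.asarray(directions.data, dtype=float)
    fa_field = np.asarray(fa.data, dtype=float)
    shape = np.asarray(fa_field.shape)
    seed = tuple(int(s) for s in seed)
    if np.any(np.asarray(seed) < 0) or np.any(np.asarray(seed) >= shape):
        raise ValueError(f"seed {seed} outside grid {tuple(shape)}")
    if fa_field[seed] < params.fa_threshold:
        return []
    max_steps = params.max_steps
    if max_steps is None:
        max_steps = int(2 * np.ceil(np.linalg.norm(shape)))
    cos_max = np.cos(np.deg2rad(params.max_angle))

    def march(sign: float) -> list[tuple[int, int, int]]:
        visited: list[tuple[int, int, int]] = []
        pos = np.asarray(seed, dtype=float)
        voxel = seed
        direction = sign * dir_field[voxel]
        for _ in range(max_steps):
            pos = pos + params.step * direction
            nxt = tuple(np.round(pos).astype(int))
            if np.any(np.asarray(nxt) < 0) or np.any(np.asarray(nxt) >= shape):
                break
            if fa_field[nxt] < params.fa_threshold:
                break
            new_dir = dir_field[nxt]
            if new_dir @ direction < 0:  # diffusion axes are sign-ambiguous
                new_dir = -new_dir
            if new_dir @ direction < cos_max:
                break  # turn exceeds max_angle: exclude the landing voxel
            if nxt != voxel:
                visited.append(nxt)
            voxel = nxt
            direction = new_dir
        return visited

    forward = march(+1.0)
    backward = march(-1.0)
    return backward[::-1] + [seed] + forward


def visitation_map(streamlines: list[list[tuple[int, int, int]]], grid) -> Volume:
    """Binary volume: 1 iff a voxel is visited by at least one streamline."""
    vol = np.zeros(grid.shape, dtype=np.uint8)
    for sl in streamlines:
        for vx in sl:
            vol[vx] = 1
    return Volume(vol, grid)


def sc_disconnection_map(subject_maps: list[Volume]) -> "SCDisconnectionMap":
    """Voxelwise mean of per-subject binary visitation maps."""
    if len(subject_maps) == 0:
        raise ValueError("need at least one subject map")
    grid = subject_maps[0].grid
    stack = []
    for sm in subject_maps:
        if sm.grid != grid:
            raise ValueError("subject maps must share a grid")
        data = np.asarray(sm.data)
        if not np.all(np.isin(np.unique(data), (0, 1))):
            raise ValueError("subject maps must be binary (0/1)")
        stack.append(data.astype(float))
    return SCDisconnectionMap(
        fraction=Volume(np.mean(stack, axis=0), grid), n_subjects=len(stack)
    )


@dataclass
class SCDisconnectionMap:
    """Across-subject connection fraction in [0, 1] per voxel."""

    fraction: Volume
    n_subjects: int

    def __post_init__(self) -> None:
        vals = np.asarray(self.fraction.data)
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("fraction values must lie in [0, 1]")


def patient_sc_map(
    lesion: Volume,
    cohort: list[NormativeSubject],
    params: TrackParams = TrackParams(),
) -> SCDisconnectionMap:
    """Structural disconnection map for one patient.

    For each normative subject, every lesion voxel seeds a streamline
    through that subject's direction/FA field; the visited voxels (always
    including the lesion voxels themselves — a lesion is trivially connected
    to itself) are binarized, and the cohort mean is returned.  Seeds below
    the FA threshold produce no streamline; their count is logged.
    """
    seeds = [tuple(int(v) for v in vx) for vx in np.argwhere(np.asarray(lesion.data) > 0)]
    if not seeds:
        raise ValueError("empty lesion mask")
    subject_maps = []
    for sub in cohort:
        streamlines = []
        n_skipped = 0
        for seed in seeds:
            sl = fact_track(sub.directions, sub.fa, seed, params)
            if sl:
                streamlines.append(sl)
            else:
                n_skipped += 1
        if n_skipped:
            logger.info(
                "subject %s: %d/%d lesion seeds below FA threshold",
                sub.subject_id, n_skipped, len(seeds),
            )
        streamlines.append(seeds)  # lesion voxels count as visited
        subject_maps.append(visitation_map(streamlines, lesion.grid))
    return sc_disconnection_map(subject_maps)
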