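"""Motion artefact synthesis by k-space merging across motion states.

The simulation inverts the reconstruction: go back into k-space, swap
readouts between the k-spaces of the subject at different positions,
and reconstruct the now inconsistent ("joint") k-space.  Two motion
models are provided:

* **Bulk motion** -- a sudden rigid repositioning (6 degrees of
  freedom) lasting for a contiguous block of the acquisition, described
  by the *fraction* of readouts exchanged and the *offset* into the
  scan at which the movement starts.  Five steps: rigidly transform the
  volume, extract the central slice of both volumes, forward-transform
  both slices, merge the two k-spaces readout-wise, reconstruct.
* **Respiratory motion** -- a sinusoidal superior-inferior translation
  of the heart (up to 7 mm by default, after reported craniocaudal
  heart displacements of 3-7 mm over the breathing cycle), quantized to
  a small number of displacement states; successive readouts come from
  the volume at successive positions in the breathing cycle.

Acquisition ordering is linear: readout index equals acquisition time,
so for Cartesian sampling a movement "after half of the scan" affects
the central phase-encoding lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .kspace import (
    KSpaceData,
    Trajectory,
    adjoint_reconstruct,
    density_weights,
    forward_transform,
)
from .phantoms import HeartMask, Image2D, Volume3D, central_slice

__all__ = [
    "RigidTransform",
    "MotionSchedule",
    "RespiratoryModel",
    "rigid_transform_volume",
    "sample_bulk_transform",
    "bulk_schedule",
    "respiratory_schedule",
    "translate_heart",
    "merge_kspace",
    "simulate_bulk_artefact",
    "simulate_respiratory_artefact",
]

MAX_TRANSLATION_MM = 3.64  # default bulk translation bound
MAX_ROTATION_DEG = 5.0  # heuristic default; the natural-looking range


@dataclass(frozen=True)
class RigidTransform:
    """Rigid 6-DOF motion: rotations (deg, about x/y/z through the
    volume center) followed by a translation (mm)."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.rotation_deg)) or not all(np.isfinite(self.translation_mm)):
            raise ValueError("rigid transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return not any(self.rotation_deg) and not any(self.translation_mm)


@dataclass(frozen=True)
class MotionSchedule:
    """Assignment of each readout (in acquisition order) to a motion
    state; state 0 is rest."""

    assignment: np.ndarray
    n_states: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=np.int64)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("assignment must be a 1D sequence of state indices")
        if a.min() < 0 or a.max() >= self.n_states:
            raise ValueError("state indices must lie in [0, n_states)")
        object.__setattr__(self, "assignment", a)

    @property
    def n_readouts(self) -> int:
        return self.assignment.size


@dataclass(frozen=True)
class RespiratoryModel:
    """Sinusoidal breathing: ``n_cycles`` breathing cycles per
    acquisition, peak superior heart displacement ``max_displacement_mm``
    (default 7), quantized to ``n_states`` displacement levels."""

    n_cycles: float = 4.0
    max_displacement_mm: float = 7.0
    n_states: int = 8

    def __post_init__(self) -> None:
        if self.n_cycles < 0 or self.max_displacement_mm < 0 or self.n_states < 1:
            raise ValueError("invalid respiratory model parameters")


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rigid_transform_volume(volume: Volume3D, transform: RigidTransform) -> Volume3D:
    """Resample a volume under a rigid map (rotation about the volume
    center, then translation), with linear interpolation and zero fill
    outside the field of view."""
    if transform.is_identity:
        return Volume3D(volume.data.copy(), volume.spacing, volume.axes)
    R = _rotation_matrix(transform.rotation_deg)
    spacing = np.asarray(volume.spacing)
    t_vox = np.asarray(transform.translation_mm) / spacing
    center = (np.asarray(volume.shape) - 1) / 2.0
    # output voxel o maps back to input voxel R^-1 (o - center - t) + center
    Rinv = R.T
    offset = center - Rinv @ (center + t_vox)
    data = ndimage.affine_transform(
        volume.data, Rinv, offset=offset, order=1, mode="constant", cval=0.0
    )
    return Volume3D(data, volume.spacing, volume.axes)


def sample_bulk_transform(
    seed: int,
    max_translation_mm: float = MAX_TRANSLATION_MM,
    max_rotation_deg: float = MAX_ROTATION_DEG,
) -> RigidTransform:
    """Draw a random bulk-motion transform.

    Translation components are uniform in ``[-b, b]`` with the vector
    rescaled onto the sphere of radius ``max_translation_mm`` if its
    norm exceeds it; rotation angles are uniform in
    ``[-max_rotation_deg, max_rotation_deg]``.  Deterministic per seed.
    """
    if max_translation_mm < 0 or max_rotation_deg < 0:
        raise ValueError("motion bounds must be non-negative")
    rng = np.random.default_rng(seed)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    norm = np.linalg.norm(t)
    if norm > max_translation_mm > 0:
        t *= max_translation_mm / norm
    r = rng.uniform(-max_rotation_deg, max_rotation_deg, size=3)
    return RigidTransform(tuple(r), tuple(t))


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def bulk_schedule(n_readouts: int, offset_fraction: float, exchange_fraction: float) -> MotionSchedule:
    """Rectangular-pulse schedule for sudden bulk motion.

    Readouts in ``[round(offset*n), round(offset*n) + round(exchange*n))``
    are assigned to the moved state 1; rounding is half-away-from-zero
    so that a fraction 2/256 of a 256-readout scan at offset 0.5 affects
    exactly the two central readouts.
    """
    if not (0 <= offset_fraction <= 1 and 0 <= exchange_fraction <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if offset_fraction + exchange_fraction > 1 + 1e-12:
        raise ValueError("offset_fraction + exchange_fraction must not exceed 1")
    start = _round_half_away(offset_fraction * n_readouts)
    length = _round_half_away(exchange_fraction * n_readouts)
    a = np.zeros(n_readouts, dtype=np.int64)
    a[start : start + length] = 1
    return MotionSchedule(a, 2)


def respiratory_schedule(
    n_readouts: int, model: RespiratoryModel
) -> tuple[MotionSchedule, np.ndarray]:
    """Quantized sinusoidal breathing schedule.

    The continuous superior displacement is
    ``d(t) = max * (1 - cos(2*pi*n_cycles*t/n_readouts)) / 2`` for
    readout index t, ranging over [0, max] (the bottom of the curve is
    full inhale, the top full exhale).  Displacements are quantized to
    ``n_states`` equispaced levels; returns the schedule plus the per-
    state displacements in mm (state 0 = 0 mm = rest).
    """
    if n_readouts < 1:
        raise ValueError("n_readouts must be >= 1")
    t = np.arange(n_readouts)
    d = model.max_displacement_mm * (1 - np.cos(2 * np.pi * model.n_cycles * t / n_readouts)) / 2
    if model.n_states == 1 or model.max_displacement_mm == 0 or model.n_cycles == 0:
        return MotionSchedule(np.zeros(n_readouts, dtype=np.int64), max(model.n_states, 1)), np.zeros(
            max(model.n_states, 1)
        )
    levels = np.linspace(0.0, model.max_displacement_mm, model.n_states)
    states = np.rint(d / model.max_displacement_mm * (model.n_states - 1)).astype(np.int64)
    return MotionSchedule(states, model.n_states), levels


def translate_heart(volume: Volume3D, mask: HeartMask, displacement_mm: float) -> Volume3D:
    """Translate the heart region superiorly, leaving the rest in place.

    Within a dilated mask (dilation radius = ceil(displacement in
    voxels) + 2) the content is resampled from the position shifted
    inferiorly by the displacement, so the heart appears moved
    superiorly (+z); a linear feather across the dilation band blends
    moved and static content so no seam appears.  Voxels outside the
    dilated mask are untouched.
    """
    if displacement_mm < 0:
        raise ValueError("displacement must be non-negative")
    if mask.data.shape != volume.data.shape:
        raise ValueError("mask shape does not match volume shape")
    if displacement_mm == 0:
        return Volume3D(volume.data.copy(), volume.spacing, volume.axes)
    dz_vox = displacement_mm / volume.spacing[2]
    radius = int(np.ceil(dz_vox)) + 2
    # Euclidean distance from the mask gives an exact linear feather
    dist = ndimage.distance_transform_edt(~mask.data, sampling=(1, 1, 1))
    w = np.clip(1.0 - dist / radius, 0.0, 1.0)
    shifted = ndimage.shift(volume.data, (0.0, 0.0, dz_vox), order=1, mode="constant", cval=0.0)
    data = w * shifted + (1.0 - w) * volume.data
    return Volume3D(data, volume.spacing, volume.axes)


def merge_kspace(states: list[KSpaceData], schedule: MotionSchedule) -> KSpaceData:
    """Build the joint k-space: readout r is copied whole (line, spoke
    or interleave) from ``states[schedule(r)]``."""
    if not states:
        raise ValueError("need at least one k-space state")
    ref = states[0].trajectory
    fp = ref.fingerprint()
    if any(s.trajectory.fingerprint() != fp for s in states[1:]):
        raise ValueError("all k-space states must share one trajectory")
    if schedule.n_readouts != ref.n_readouts:
        raise ValueError("schedule length does not match trajectory readout count")
    if schedule.assignment.max() >= len(states):
        raise ValueError("schedule references a missing motion state")
    stack = np.stack([s.samples for s in states])
    merged = stack[schedule.assignment, np.arange(ref.n_readouts), :]
    return KSpaceData(merged, ref)


def _reconstruct_magnitude(kdata: KSpaceData) -> Image2D:
    img = adjoint_reconstruct(kdata, density_weights(kdata.trajectory))
    return Image2D(np.abs(img.data), img.spacing)


def simulate_bulk_artefact(
    volume: Volume3D,
    transform: RigidTransform,
    trajectory: Trajectory,
    offset_fraction: float,
    exchange_fraction: float,
) -> tuple[Image2D, Image2D]:
    """Full bulk-motion pipeline on the central slice.

    Rigidly transform the volume; extract the central slice of both
    volumes; forward-transform both slices along the trajectory; merge
    the k-spaces per the rectangular-pulse schedule; reconstruct.
    Returns ``(clean, corrupted)`` magnitude images, both passed through
    the identical reconstruction so that with no exchange (or an
    identity transform) they agree exactly.
    """
    moved = rigid_transform_volume(volume, transform)
    k_clean = forward_transform(central_slice(volume), trajectory)
    k_moved = forward_transform(central_slice(moved), trajectory)
    schedule = bulk_schedule(trajectory.n_readouts, offset_fraction, exchange_fraction)
    joint = merge_kspace([k_clean, k_moved], schedule)
    return _reconstruct_magnitude(k_clean), _reconstruct_magnitude(joint)


def simulate_respiratory_artefact(
    volume: Volume3D,
    mask: HeartMask,
    trajectory: Trajectory,
    model: RespiratoryModel,
) -> tuple[Image2D, Image2D]:
    """Full respiratory pipeline on the central slice.

    One translated volume is built per quantized displacement state;
    successive readouts are taken from the k-space of the state the
    breathing curve occupies at that time.  Returns
    ``(clean, corrupted)`` magnitude images.
    """
    schedule, displacements = respiratory_schedule(trajectory.n_readouts, model)
    used = np.unique(schedule.assignment)
    k_states: list[KSpaceData] = []
    k_clean = forward_transform(central_slice(volume), trajectory)
    for s, d in enumerate(displacements):
        if s == 0 or s not in used:
            k_states.append(k_clean)  # state 0 is rest; unused states never read
            continue
        moved = translate_heart(volume, mask, float(d))
        k_states.append(forward_transform(central_slice(moved), trajectory))
    joint = merge_kspace(k_states, schedule)
    return _reconstruct_magnitude(k_clean), _reconstruct_magnitude(joint)
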