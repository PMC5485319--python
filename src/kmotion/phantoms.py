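"""Synthetic 3D test objects and NIfTI volume I/O.

Two phantom families are provided so the whole artefact-synthesis and
detection pipeline can be exercised without access to clinical data:

* a *brain-like* phantom -- a bright head-shaped ellipsoid containing
  several internal structures of distinct intensity (including a small
  dark blob), surrounded by background of almost no intensity, the
  regime in which motion artefacts spread into visibly empty space;
* a *cardiac-like* phantom -- a textured torso containing a two-chamber
  heart (two myocardial rings around brighter blood pools) together with
  a binary heart mask, the regime in which respiratory heart motion is
  simulated.

All generators are pure functions of ``(seed, shape)``: the same seed
always yields the bit-identical volume, and distinct seeds jitter the
anatomy (position, size, orientation, texture) so that no two subjects
are identical.

Axis convention: ``data[ix, iy, iz]`` with x = left-right,
y = anterior-posterior, z = inferior-superior; the superior direction is
+z and the central axial slice is ``data[:, :, depth // 2]``.
Intensities live in ``[0, 1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "Image2D",
    "HeartMask",
    "VolumeFormatError",
    "make_brain_phantom",
    "make_cardiac_phantom",
    "read_volume",
    "write_volume",
    "write_mask",
    "central_slice",
    "export_png",
]

AXES_CONVENTION = "x=left-right, y=anterior-posterior, z=inferior-superior"


class VolumeFormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3D volume."""


@dataclass(frozen=True)
class Volume3D:
    """A 3D intensity volume with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axes: str = AXES_CONVENTION

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if min(self.data.shape) < 8:
            raise ValueError(f"all dimensions must be >= 8, got {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Image2D:
    """A 2D image (real magnitude or complex) with pixel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError(f"expected 2D data, got {self.data.ndim}D")
        if min(self.data.shape) < 8:
            raise ValueError(f"all dimensions must be >= 8, got {self.data.shape}")
        if not np.iscomplexobj(self.data) and np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")


@dataclass(frozen=True)
class HeartMask:
    """Binary mask congruent with its parent volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.data.dtype != bool:
            object.__setattr__(self, "data", self.data.astype(bool))
        if not self.data.any():
            raise ValueError("mask must be non-empty")


def _coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    return np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")


def _ellipsoid(
    grids: tuple[np.ndarray, ...],
    center: np.ndarray,
    semiaxes: np.ndarray,
    angle_z: float = 0.0,
) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipsoid, optionally rotated about z."""
    dx = grids[0] - center[0]
    dy = grids[1] - center[1]
    dz = grids[2] - center[2]
    if angle_z != 0.0:
        c, s = np.cos(angle_z), np.sin(angle_z)
        dx, dy = c * dx + s * dy, -s * dx + c * dy
    return (dx / semiaxes[0]) ** 2 + (dy / semiaxes[1]) ** 2 + (dz / semiaxes[2]) ** 2 <= 1.0


def _check_shape(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError(f"phantom shape dims must be >= 32, got {shape}")
    return shape


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude smooth random field (phantom texture)."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = n.std()
    return n / s if s > 0 else n


def make_brain_phantom(
    seed: int,
    shape: tuple[int, int, int] = (256, 256, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Volume3D:
    """Generate a brain-like volume: bright head over near-zero background.

    The head is an ellipsoid with per-seed jitter of position, size and
    orientation; inside it sit a brighter cortical shell, two bright
    ventricle-like lobes, a mid-intensity deep structure and a small dark
    blob, plus smooth random texture.  The exterior carries only
    low-amplitude noise so that artefact energy spilling outwards is
    visible against an almost empty background.
    """
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    dims = np.array(shape, dtype=float)
    g = _coords(shape)

    jitter = lambda lo, hi: rng.uniform(lo, hi)  # noqa: E731
    center = dims / 2 + rng.uniform(-0.02, 0.02, size=3) * dims
    head_ax = np.array([0.36, 0.42, 0.40]) * dims * (1 + rng.uniform(-0.05, 0.05, size=3))
    tilt = jitter(-0.12, 0.12)

    head = _ellipsoid(g, center, head_ax, tilt)
    vol = np.zeros(shape)
    vol[head] = 0.65

    # cortical shell: slightly brighter rim just inside the head boundary
    inner = _ellipsoid(g, center, head_ax * 0.88, tilt)
    vol[head & ~inner] = 0.78

    # two bright ventricle-like lobes near the center (bright on T2)
    for side in (-1.0, 1.0):
        off = np.array([side * jitter(0.08, 0.12), jitter(-0.04, 0.04), jitter(-0.05, 0.05)]) * dims
        ax = np.array([0.05, 0.12, 0.10]) * dims * (1 + jitter(-0.1, 0.1))
        vol[_ellipsoid(g, center + off, ax, tilt)] = 0.95

    # mid-intensity deep structure
    off = np.array([jitter(-0.03, 0.03), jitter(0.10, 0.16), jitter(-0.04, 0.04)]) * dims
    ax = np.array([0.10, 0.07, 0.08]) * dims
    vol[_ellipsoid(g, center + off, ax, tilt)] = 0.45

    # small dark blob (a sharp detail structure that motion blurs away)
    off = np.array([jitter(-0.12, -0.06), jitter(-0.16, -0.10), jitter(-0.03, 0.03)]) * dims
    ax = np.full(3, 0.025) * dims.min()
    vol[_ellipsoid(g, center + off, ax)] = 0.10

    # smooth per-seed texture inside the head only
    vol[inner] += jitter(0.03, 0.05) * _smooth_noise(rng, shape, sigma=3.0)[inner]

    # faint magnitude-like background noise; its level varies between
    # subjects, as scanner SNR does between acquisitions
    bg = ~head
    sigma_bg = jitter(0.002, 0.008)
    vol[bg] = np.abs(rng.normal(0.0, sigma_bg, size=int(bg.sum())))

    return Volume3D(np.clip(vol, 0.0, 1.0), spacing)


def make_cardiac_phantom(
    seed: int,
    shape: tuple[int, int, int] = (256, 256, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[Volume3D, HeartMask]:
    """Generate a cardiac-like volume plus binary heart mask.

    A textured torso (non-zero everywhere inside, faint noise outside)
    contains a two-chamber heart: a left-ventricular ring (bright blood
    pool inside darker myocardium) and a smaller right-ventricular ring
    beside it.  Heart position and orientation are jittered per seed
    within bounds that keep the heart inside the torso.  The mask covers
    the heart structure (both rings including their blood pools).
    """
    shape = _check_shape(shape)
    rng = np.random.default_rng(seed)
    dims = np.array(shape, dtype=float)
    g = _coords(shape)

    torso_ax = np.array([0.46, 0.42, 0.55]) * dims
    torso = _ellipsoid(g, dims / 2, torso_ax)
    # noise/texture amplitudes vary between subjects, like scanner SNR
    vol = np.full(shape, rng.uniform(0.03, 0.05))
    vol += rng.uniform(0.01, 0.02) * np.abs(_smooth_noise(rng, shape, sigma=2.0))
    vol[torso] = 0.35 + rng.uniform(0.04, 0.08) * _smooth_noise(rng, shape, sigma=4.0)[torso]

    # dark lung-like regions flanking the heart
    for side in (-1.0, 1.0):
        off = np.array([side * 0.24, -0.05, 0.0]) * dims
        ax = np.array([0.13, 0.20, 0.35]) * dims
        lung = _ellipsoid(g, dims / 2 + off, ax)
        vol[lung & torso] = 0.12

    # heart placement: jittered position and in-plane orientation
    hc = dims * (np.array([0.5, 0.48, 0.5]) + rng.uniform(-0.03, 0.03, size=3))
    theta = rng.uniform(-0.5, 0.5)
    n = dims[:2].min()  # in-plane scale; depth scales only the z extent
    z_ax = 0.34 * shape[2]

    def ring(center, r_in, r_out, pool_val, myo_val):
        outer = _ellipsoid(g, center, np.array([r_out, r_out, z_ax]), theta)
        pool = _ellipsoid(g, center, np.array([r_in, r_in, z_ax * 0.85]), theta)
        vol[outer] = myo_val
        vol[pool] = pool_val
        return outer

    r_lv = n * rng.uniform(0.075, 0.088)
    lv = ring(hc, r_lv, 1.55 * r_lv, 0.92, 0.50)
    rv_off = 2.1 * r_lv * np.array([np.cos(theta + 2.4), np.sin(theta + 2.4), 0.0])
    rv = ring(hc + rv_off, 0.75 * r_lv, 1.25 * r_lv, 0.88, 0.50)

    mask = lv | rv
    vol[torso] = np.clip(vol[torso], 0.02, 1.0)
    return Volume3D(np.clip(vol, 0.0, 1.0), spacing), HeartMask(mask)


def central_slice(volume: Volume3D) -> Image2D:
    """Central axial slice of a volume (the 2D plane all simulation uses)."""
    z = volume.shape[2] // 2
    return Image2D(np.ascontiguousarray(volume.data[:, :, z]), volume.spacing[:2])


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (float32 data, spacing in the affine)."""
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: HeartMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI-1 volume; raises :class:`VolumeFormatError` otherwise."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / not NIfTI
        raise VolumeFormatError(f"cannot read volume from {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path!r}: expected a 3D volume, got {data.ndim}D data")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(np.asarray(data, dtype=np.float64), spacing)


def read_mask(path) -> HeartMask:
    vol = read_volume(path)
    return HeartMask(vol.data > 0.5)


def export_png(image, path) -> None:
    """8-bit min-max scaled PNG export, for visual inspection only."""
    from PIL import Image as PILImage

    data = np.abs(image.data if isinstance(image, Image2D) else image)
    lo, hi = float(data.min()), float(data.max())
    scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    PILImage.fromarray((scaled * 255).astype(np.uint8).T).save(str(path))
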