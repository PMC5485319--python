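"""Intensity-based image features for artefact detection.

Four families of features are extracted inside a rectangular region of
interest (ROI), from a frozen, randomly parameterized specification set
applied identically to every image:

* **box** -- mean and variance inside a patch of random size/position;
* **line** -- standard deviation and max-min range along a line profile
  of random start, angle and length (bilinear interpolation);
* **histogram** -- mean, variance, skewness, kurtosis, entropy and
  energy of an intensity histogram with a random number of bins,
  computed either over the whole ROI (rotation invariant) or inside a
  random patch (not rotation invariant);
* **texture** -- the 13 classical Haralick statistics of the gray-level
  co-occurrence matrix at distance 1, averaged over the four 2D
  adjacency directions for rotation invariance.

Blurring and ghosting smear structure into formerly empty regions,
raising local variance and histogram entropy while lowering contrast;
these features give a decision forest purchase on exactly that.

Every image is min-max normalized to [0, 1] over the ROI before
extraction, so features cannot key on global intensity scale introduced
by the reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import graycomatrix

from .phantoms import HeartMask, Image2D

__all__ = [
    "ROI",
    "FeatureSpec",
    "FeatureSpecSet",
    "FeatureMatrix",
    "compute_roi",
    "sample_feature_specs",
    "box_features",
    "line_features",
    "histogram_features",
    "haralick_features",
    "extract_feature_matrix",
]

KINDS = ("box", "line", "histogram_global", "histogram_patch", "texture")

DEFAULT_COUNTS = {
    "box": 200,
    "line": 100,
    "histogram_global": 25,
    "histogram_patch": 25,
    "texture": 1,
}
DEFAULT_BIN_RANGE = (8, 64)
GLCM_LEVELS = 64


@dataclass(frozen=True)
class ROI:
    """Rectangle (0-based, half-open) in image pixel coordinates."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height * self.width < 16:
            raise ValueError("ROI area must be at least 16 pixels")
        if self.row < 0 or self.col < 0 or self.height < 1 or self.width < 1:
            raise ValueError("ROI must have positive size and non-negative origin")

    def contains(self, row: float, col: float) -> bool:
        return self.row <= row < self.row + self.height and self.col <= col < self.col + self.width

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)


@dataclass(frozen=True)
class FeatureSpec:
    """A single randomly parameterized feature definition.

    ``geometry`` is a patch ``(row, col, height, width)`` for box and
    patch-histogram kinds, ``(row0, col0, angle_rad, length)`` for
    lines, and ``None`` for whole-ROI kinds.
    """

    kind: str
    geometry: tuple | None = None
    n_bins: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind.startswith("histogram") and (self.n_bins is None or self.n_bins < 2):
            raise ValueError("histogram features need n_bins >= 2")
        if self.kind == "line" and (self.geometry is None or self.geometry[3] < 2):
            raise ValueError("line features need length >= 2 pixels")

    @property
    def n_values(self) -> int:
        return {"box": 2, "line": 2, "histogram_global": 6, "histogram_patch": 6, "texture": 13}[
            self.kind
        ]


@dataclass(frozen=True)
class FeatureSpecSet:
    """Frozen ordered collection of feature specs; order defines the
    feature-column order of every extracted matrix."""

    specs: tuple[FeatureSpec, ...]
    seed: int
    roi: ROI

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("feature spec set must be non-empty")

    @property
    def n_features(self) -> int:
        return sum(s.n_values for s in self.specs)

    def column_names(self) -> list[str]:
        names = []
        parts = {
            "box": ("mean", "var"),
            "line": ("std", "range"),
            "histogram_global": ("mean", "var", "skew", "kurt", "entropy", "energy"),
            "histogram_patch": ("mean", "var", "skew", "kurt", "entropy", "energy"),
            "texture": tuple(f"h{i + 1}" for i in range(13)),
        }
        for i, s in enumerate(self.specs):
            names += [f"{s.kind}_{i}_{p}" for p in parts[s.kind]]
        return names

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "roi": [self.roi.row, self.roi.col, self.roi.height, self.roi.width],
            "specs": [
                {"kind": s.kind, "geometry": s.geometry, "n_bins": s.n_bins} for s in self.specs
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass(frozen=True)
class FeatureMatrix:
    """Images x features table with labels and subject ids."""

    values: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must not contain missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")
        if len(set(self.subject_ids.tolist())) != len(self.subject_ids):
            raise ValueError("each subject may appear only once")
        if not (len(self.values) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("rows, labels and subject ids must align")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.columns))
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df


# ---------------------------------------------------------------------------
# ROI


def compute_roi(masks, image_shape: tuple[int, int], margin: float = 0.10) -> ROI:
    """Common rectangular ROI for a cohort.

    With heart masks: take each subject's central-slice bounding box,
    the maximum width and height over subjects, enlarge each by
    ``margin`` in total (half per side), center the box on the pooled
    mask centroid and clip to the image.  Without masks (brain case) the
    ROI is the full image.
    """
    h_img, w_img = image_shape
    if not masks:
        return ROI(0, 0, h_img, w_img)
    heights, widths, centroids = [], [], []
    for m in masks:
        data = m.data if isinstance(m, HeartMask) else np.asarray(m, dtype=bool)
        sl = data[:, :, data.shape[2] // 2] if data.ndim == 3 else data
        if not sl.any():
            raise ValueError("mask has an empty central slice")
        rows, cols = np.nonzero(sl)
        heights.append(rows.max() - rows.min() + 1)
        widths.append(cols.max() - cols.min() + 1)
        centroids.append((rows.mean(), cols.mean()))
    h = int(round(max(heights) * (1 + margin)))
    w = int(round(max(widths) * (1 + margin)))
    h, w = min(h, h_img), min(w, w_img)
    cr, cc = np.mean([c[0] for c in centroids]), np.mean([c[1] for c in centroids])
    row = int(np.clip(round(cr - h / 2), 0, h_img - h))
    col = int(np.clip(round(cc - w / 2), 0, w_img - w))
    return ROI(row, col, h, w)


# ---------------------------------------------------------------------------
# spec sampling


def sample_feature_specs(
    seed: int,
    roi: ROI,
    counts: dict[str, int] | None = None,
    bin_range: tuple[int, int] = DEFAULT_BIN_RANGE,
    edge_range: tuple[int, int] | None = None,
    max_line_radius: int | None = None,
) -> FeatureSpecSet:
    """Draw a frozen feature specification set, uniform within the ROI.

    One set serves an entire experiment: every image is measured with
    exactly the same random patches, lines and bin counts.
    """
    counts = dict(DEFAULT_COUNTS if counts is None else counts)
    if any(c < 0 for c in counts.values()) or sum(counts.values()) <= 0:
        raise ValueError("counts must be non-negative with at least one kind > 0")
    if edge_range is None:
        edge_range = (4, max(4, min(roi.height, roi.width) // 2))
    if edge_range[0] > min(roi.height, roi.width):
        raise ValueError("patch edge range exceeds ROI size")
    if max_line_radius is None:
        max_line_radius = max(2, min(roi.height, roi.width) // 2)
    rng = np.random.default_rng(seed)

    def draw_patch():
        h = int(rng.integers(edge_range[0], min(edge_range[1], roi.height) + 1))
        w = int(rng.integers(edge_range[0], min(edge_range[1], roi.width) + 1))
        r = int(rng.integers(roi.row, roi.row + roi.height - h + 1))
        c = int(rng.integers(roi.col, roi.col + roi.width - w + 1))
        return (r, c, h, w)

    def draw_line():
        # rejection-sample until the whole profile stays inside the ROI
        while True:
            length = int(rng.integers(2, max_line_radius + 1))
            angle = float(rng.uniform(0, 2 * np.pi))
            r0 = float(rng.uniform(roi.row, roi.row + roi.height - 1))
            c0 = float(rng.uniform(roi.col, roi.col + roi.width - 1))
            r1 = r0 + (length - 1) * np.cos(angle)
            c1 = c0 + (length - 1) * np.sin(angle)
            # closed bounds: every profile point must be interpolable
            if (
                roi.row <= r1 <= roi.row + roi.height - 1
                and roi.col <= c1 <= roi.col + roi.width - 1
            ):
                return (r0, c0, angle, length)

    specs: list[FeatureSpec] = []
    for _ in range(counts.get("box", 0)):
        specs.append(FeatureSpec("box", draw_patch()))
    for _ in range(counts.get("line", 0)):
        specs.append(FeatureSpec("line", draw_line()))
    for _ in range(counts.get("histogram_global", 0)):
        specs.append(FeatureSpec("histogram_global", None, int(rng.integers(bin_range[0], bin_range[1] + 1))))
    for _ in range(counts.get("histogram_patch", 0)):
        specs.append(
            FeatureSpec("histogram_patch", draw_patch(), int(rng.integers(bin_range[0], bin_range[1] + 1)))
        )
    for _ in range(counts.get("texture", 0)):
        specs.append(FeatureSpec("texture"))
    return FeatureSpecSet(tuple(specs), seed, roi)


# ---------------------------------------------------------------------------
# individual feature families


def _image_data(image) -> np.ndarray:
    data = image.data if isinstance(image, Image2D) else np.asarray(image)
    return np.abs(data) if np.iscomplexobj(data) else data


def box_features(image, spec: FeatureSpec) -> tuple[float, float]:
    """Population mean and variance inside the spec's patch."""
    if spec.kind != "box":
        raise ValueError("spec is not a box feature")
    r, c, h, w = spec.geometry
    patch = _image_data(image)[r : r + h, c : c + w]
    return float(patch.mean()), float(patch.var())


def line_features(image, spec: FeatureSpec) -> tuple[float, float]:
    """Population std and max-min range of a bilinear line profile
    sampled at unit-pixel steps."""
    if spec.kind != "line":
        raise ValueError("spec is not a line feature")
    r0, c0, angle, length = spec.geometry
    t = np.arange(length, dtype=float)
    rows = r0 + t * np.cos(angle)
    cols = c0 + t * np.sin(angle)
    data = _image_data(image)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > data.shape[0] - 1
        or cols.max() > data.shape[1] - 1
    ):
        raise ValueError("line profile exits the image")
    profile = ndimage.map_coordinates(data, np.vstack([rows, cols]), order=1)
    return float(profile.std()), float(profile.max() - profile.min())


def histogram_features(values, n_bins: int) -> tuple[float, float, float, float, float, float]:
    """Six scalars of an intensity histogram: mean, variance, skewness,
    kurtosis (excess), entropy (bits) and energy.

    Moments are computed from the bin centers weighted by normalized
    counts, so the number of bins genuinely matters.  Degenerate
    conventions: a constant input puts all mass in one bin (entropy 0,
    energy 1) and zero-variance skewness/kurtosis are defined as 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("histogram features need at least one value")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        p = np.zeros(n_bins)
        p[0] = 1.0
        centers = np.full(n_bins, lo)
    else:
        counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
        p = counts / counts.sum()
        centers = (edges[:-1] + edges[1:]) / 2
    mean = float(p @ centers)
    var = float(p @ (centers - mean) ** 2)
    sigma = np.sqrt(var)
    if sigma > 0:
        skew = float(p @ (centers - mean) ** 3 / sigma**3)
        kurt = float(p @ (centers - mean) ** 4 / sigma**4 - 3.0)
    else:
        skew = kurt = 0.0
    nz = p[p > 0]
    entropy = float(-(nz @ np.log2(nz)))
    energy = float(p @ p)
    return mean, var, skew, kurt, entropy, energy


def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence statistics of one normalized,
    symmetric GLCM.  Zero-variance and zero-entropy denominators follow
    the degenerate conventions (correlation and the information
    measures of correlation are 0 there)."""
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(px @ i)
    var = float(px @ (i - mu) ** 2)

    asm = float((P**2).sum())
    contrast = float((P * (I - J) ** 2).sum())
    correlation = float(((I - mu) * (J - mu) * P).sum() / var) if var > 0 else 0.0
    sum_sq_variance = float((P * (I - mu) ** 2).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())

    # distributions of i+j and |i-j|
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (I + J).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(I - J).astype(int).ravel(), P.ravel())
    ks = np.arange(2 * L - 1, dtype=float)
    kd = np.arange(L, dtype=float)

    sum_average = float(psum @ ks)
    sum_variance = float(psum @ (ks - sum_average) ** 2)
    nzs = psum[psum > 0]
    sum_entropy = float(-(nzs @ np.log2(nzs)))
    nzp = P[P > 0]
    entropy = float(-(nzp @ np.log2(nzp)))
    diff_average = float(pdiff @ kd)
    diff_variance = float(pdiff @ (kd - diff_average) ** 2)
    nzd = pdiff[pdiff > 0]
    diff_entropy = float(-(nzd @ np.log2(nzd)))

    nzx = px[px > 0]
    hx = float(-(nzx @ np.log2(nzx)))
    # symmetric GLCM: marginals coincide, HX == HY
    q = np.outer(px, px)
    mask = q > 0
    logq = np.zeros_like(q)
    np.log2(q, where=mask, out=logq)
    hxy1 = float(-(P[mask] @ logq[mask]))
    hxy2 = float(-(q[mask] @ logq[mask]))
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return np.array(
        [
            asm,
            contrast,
            correlation,
            sum_sq_variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            diff_variance,
            diff_entropy,
            imc1,
            imc2,
        ]
    )


def haralick_features(image, roi: ROI | None = None, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Direction-averaged 13-vector of Haralick texture statistics.

    The ROI is quantized to ``levels`` gray levels by min-max scaling;
    symmetric normalized GLCMs at distance 1 are built for the four 2D
    adjacency directions (horizontal, vertical and both diagonals) and
    the 13 statistics are averaged element-wise over the directions,
    which makes the vector exactly invariant under quarter-turn image
    rotations.
    """
    data = _image_data(image)
    if roi is not None:
        data = data[roi.slices()]
    if data.size < 4:
        raise ValueError("ROI too small for texture features")
    lo, hi = float(data.min()), float(data.max())
    if hi == lo:
        q = np.zeros(data.shape, dtype=np.uint8)
    else:
        q = np.minimum((levels * (data - lo) / (hi - lo)).astype(np.int64), levels - 1).astype(
            np.uint8
        )
    glcms = graycomatrix(
        q,
        distances=[1],
        angles=[0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    stats = [_haralick_from_glcm(glcms[:, :, 0, a]) for a in range(4)]
    return np.mean(stats, axis=0)


# ---------------------------------------------------------------------------
# matrix assembly


def _normalize_roi(image, roi: ROI) -> np.ndarray:
    data = _image_data(image).astype(float)
    sub = data[roi.slices()]
    lo, hi = float(sub.min()), float(sub.max())
    return np.zeros_like(data) if hi == lo else np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def extract_features(image, specs: FeatureSpecSet) -> np.ndarray:
    """Feature vector of one image under a frozen spec set (the image is
    min-max normalized over the ROI first)."""
    norm = _normalize_roi(image, specs.roi)
    out: list[float] = []
    for spec in specs.specs:
        if spec.kind == "box":
            out.extend(box_features(norm, spec))
        elif spec.kind == "line":
            out.extend(line_features(norm, spec))
        elif spec.kind == "histogram_global":
            out.extend(histogram_features(norm[specs.roi.slices()], spec.n_bins))
        elif spec.kind == "histogram_patch":
            r, c, h, w = spec.geometry
            out.extend(histogram_features(norm[r : r + h, c : c + w], spec.n_bins))
        else:
            out.extend(haralick_features(norm, specs.roi))
    return np.asarray(out)


def extract_feature_matrix(images, labels, subject_ids, specs: FeatureSpecSet) -> FeatureMatrix:
    """Assemble the images x features table used for classification."""
    if not (len(images) == len(labels) == len(subject_ids)):
        raise ValueError("images, labels and subject_ids must have equal length")
    rows = np.vstack([extract_features(img, specs) for img in images])
    return FeatureMatrix(
        rows,
        np.asarray(labels, dtype=np.int64),
        np.asarray(subject_ids),
        tuple(specs.column_names()),
    )
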