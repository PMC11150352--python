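"""Bone texture quantification: first-order variance and GLCM features.

The feature mathematics are implemented directly (not delegated to a
radiomics package): images are min–max normalized to [0, 1] over the whole
stack, quantized into equal-width bins (default 200), and a gray-level
co-occurrence matrix (GLCM) is accumulated inside a circular region of
interest for each of the four unique distance-1 in-plane directions with
symmetric pair counting.  Features — joint energy, joint entropy and inverse
difference (homogeneity) — are computed per offset matrix and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizationError",
    "EmptyROIError",
    "ROISpec",
    "GLCM",
    "TextureFeatures",
    "DEFAULT_OFFSETS",
    "normalize_stack",
    "quantize",
    "first_order_variance",
    "circular_roi_mask",
    "compute_glcm",
    "glcm_features",
    "texture_features",
]

DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))
DEFAULT_BINS = 200


class NormalizationError(ValueError):
    """The stack is constant and cannot be min-max normalized."""


class EmptyROIError(ValueError):
    """The ROI contains no voxels or no valid neighbor pairs."""


@dataclass(frozen=True)
class ROISpec:
    """Circular in-slice region of interest (voxel coordinates, pixel diameter)."""

    center: tuple[float, float]  # (row, col)
    diameter_px: float = 40.0
    slice_index: int = 0

    def __post_init__(self):
        if self.diameter_px <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass
class GLCM:
    """Normalized co-occurrence matrices, one per offset."""

    matrices: list[np.ndarray]
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    n_levels: int
    normalized: bool


@dataclass
class TextureFeatures:
    variance: float
    joint_energy: float
    joint_entropy: float
    inverse_difference: float
    bin_occupancy: int


def normalize_stack(values: np.ndarray) -> np.ndarray:
    """Linear min–max rescale of a whole image stack to [0, 1]."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        raise NormalizationError("constant stack cannot be normalized")
    return (values - vmin) / (vmax - vmin)


def quantize(values: np.ndarray, n_bins: int = DEFAULT_BINS) -> tuple[np.ndarray, int]:
    """Quantize [0, 1] values into equal-width bins.

    Level ``k = min(floor(v * n_bins), n_bins - 1)``.  Returns the integer
    levels and the occupancy count of distinct levels.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("values must lie in [0, 1]; normalize first")
    levels = np.minimum(np.floor(values * n_bins).astype(np.int64), n_bins - 1)
    return levels, int(np.unique(levels).size)


def first_order_variance(values: np.ndarray) -> float:
    """Population variance of the (normalized) intensities within the ROI."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("variance needs at least two values")
    return float(np.var(values))


def circular_roi_mask(shape: tuple[int, int], roi: ROISpec) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the ROI circle."""
    rows, cols = np.indices(shape)
    d2 = (rows - roi.center[0]) ** 2 + (cols - roi.center[1]) ** 2
    mask = d2 <= (roi.diameter_px / 2.0) ** 2
    rr, cc = np.nonzero(mask)
    if mask.any() and (
        rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]
    ):  # pragma: no cover - indices cannot exceed shape
        raise ValueError("ROI extends outside the image")
    return mask


def compute_glcm(
    levels: np.ndarray,
    roi_mask: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    n_levels: int | None = None,
) -> GLCM:
    """Accumulate co-occurrence matrices over an ROI.

    Both voxels of a pair must lie inside the ROI; with ``symmetric`` each
    pair contributes in both orders.  Each offset matrix is normalized to
    sum 1.
    """
    levels = np.asarray(levels)
    if levels.ndim != 2 or roi_mask.shape != levels.shape:
        raise ValueError("levels and ROI mask must be matching 2D arrays")
    if not roi_mask.any():
        raise EmptyROIError("ROI contains no voxels")
    if n_levels is None:
        n_levels = int(levels[roi_mask].max()) + 1
    matrices = []
    any_pairs = False
    for dy, dx in offsets:
        # pair (i, j) -> (i + dy, j + dx), both inside the ROI and image
        h, w = levels.shape
        ys, xs = np.nonzero(roi_mask)
        ok = (ys + dy >= 0) & (ys + dy < h) & (xs + dx >= 0) & (xs + dx < w)
        ys, xs = ys[ok], xs[ok]
        ok2 = roi_mask[ys + dy, xs + dx]
        ys, xs = ys[ok2], xs[ok2]
        mat = np.zeros((n_levels, n_levels), dtype=float)
        if ys.size:
            a = levels[ys, xs]
            b = levels[ys + dy, xs + dx]
            np.add.at(mat, (a, b), 1.0)
            if symmetric:
                np.add.at(mat, (b, a), 1.0)
            any_pairs = True
            mat /= mat.sum()
        matrices.append(mat)
    if not any_pairs:
        raise EmptyROIError("ROI has no valid neighbor pairs")
    return GLCM(matrices, tuple(offsets), symmetric, n_levels, normalized=True)


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Joint energy, joint entropy (bits) and inverse difference.

    Computed per offset matrix and averaged across offsets.  The entropy sum
    carries a machine-epsilon guard inside the logarithm and is clipped at 0.
    """
    if not glcm.normalized:
        raise ValueError("GLCM must be normalized before feature extraction")
    eps = np.finfo(float).eps
    energies, entropies, invdiffs = [], [], []
    for mat in glcm.matrices:
        if mat.sum() == 0:
            continue
        energies.append(float(np.sum(mat**2)))
        entropies.append(max(0.0, float(-np.sum(mat * np.log2(mat + eps)))))
        i, j = np.indices(mat.shape)
        invdiffs.append(float(np.sum(mat / (1.0 + np.abs(i - j)))))
    return {
        "joint_energy": float(np.mean(energies)),
        "joint_entropy": float(np.mean(entropies)),
        "inverse_difference": float(np.mean(invdiffs)),
    }


def texture_features(
    normalized_image: np.ndarray,
    roi: ROISpec,
    n_bins: int = DEFAULT_BINS,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> TextureFeatures:
    """All texture features of one ROI on an already-normalized 2D image."""
    mask = circular_roi_mask(normalized_image.shape, roi)
    levels, _ = quantize(normalized_image, n_bins)
    _, occupancy = quantize(np.asarray(normalized_image)[mask], n_bins)
    glcm = compute_glcm(levels, mask, offsets=offsets, n_levels=n_bins)
    feats = glcm_features(glcm)
    return TextureFeatures(
        variance=first_order_variance(np.asarray(normalized_image)[mask]),
        joint_energy=feats["joint_energy"],
        joint_entropy=feats["joint_entropy"],
        inverse_difference=feats["inverse_difference"],
        bin_occupancy=occupancy,
    )
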