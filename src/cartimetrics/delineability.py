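"""Defect delineability from signal-intensity line profiles.

A line profile is placed through a fluid-filled cartilage defect and the
adjacent cartilage, normalized to a maximum of 1, and summarized by two
sharpness surrogates:

* **FWHM** — the width of the defect peak at half maximum, where "half" is
  midway between the cartilage background level and the maximum, with
  crossings localized by linear interpolation between samples.
* **Edge width (EW)** — the mean 10–90% transition width of the two defect
  shoulders.  The thresholds are, by default, absolute fractions of the
  normalized maximum; a ``relative`` mode measures them across the
  background-to-maximum range instead, which is required whenever the
  background exceeds 10% of the maximum (the usual situation for cartilage
  flanking a bright defect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "NoDefectError",
    "ThresholdUnreachableError",
    "LineProfile",
    "DelineabilityResult",
    "extract_profile",
    "normalize_profile",
    "estimate_background",
    "compute_fwhm",
    "compute_edge_width",
    "analyze_profile",
]


class GeometryError(ValueError):
    """Line endpoints fall outside the image."""


class NoDefectError(ValueError):
    """The profile has no enclosed peak crossing the half-maximum level."""


class ThresholdUnreachableError(ValueError):
    """The 10% threshold lies below the background and is never crossed."""


@dataclass
class LineProfile:
    """Uniformly sampled signal intensities along a world-space segment."""

    positions_mm: np.ndarray
    intensities: np.ndarray
    p0_mm: tuple[float, float]
    p1_mm: tuple[float, float]
    step_mm: float

    def __post_init__(self):
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_mm.size != self.intensities.size:
            raise ValueError("positions and intensities must match")
        if self.positions_mm.size < 10:
            raise ValueError("a profile needs at least 10 samples")
        d = np.diff(self.positions_mm)
        if np.any(d <= 0) or not np.allclose(d, self.step_mm, rtol=1e-6):
            raise ValueError("positions must increase uniformly by step_mm")


@dataclass
class DelineabilityResult:
    fwhm_mm: float
    ew_mm: float
    shoulder_widths_mm: tuple[float, float]
    background: float
    half_level: float
    crossings_mm: tuple[float, float]


def extract_profile(image, p0_mm, p1_mm, spacing_mm, step_mm=None) -> LineProfile:
    """Sample an image along a segment by bilinear interpolation.

    ``image`` is a 2D array; endpoints are world coordinates in mm with the
    convention world = voxel index * spacing.  The default sampling step is
    a quarter of the in-plane spacing; the number of samples is
    ``floor(L / step) + 1``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a single 2D slice")
    if step_mm is None:
        step_mm = 0.25 * spacing_mm
    if step_mm <= 0:
        raise ValueError("step must be positive")
    p0 = np.asarray(p0_mm, dtype=float)
    p1 = np.asarray(p1_mm, dtype=float)
    for p in (p0, p1):
        vox = p / spacing_mm
        if np.any(vox < 0) or np.any(vox > np.asarray(image.shape) - 1):
            raise GeometryError(f"endpoint {tuple(p)} mm outside image bounds")
    length = float(np.linalg.norm(p1 - p0))
    n = int(np.floor(length / step_mm)) + 1
    pos = np.arange(n) * step_mm
    direction = (p1 - p0) / length
    pts = p0[None, :] + pos[:, None] * direction[None, :]
    coords = (pts / spacing_mm).T  # (2, n) in voxel units
    vals = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    return LineProfile(pos, vals, tuple(p0), tuple(p1), step_mm)


def normalize_profile(profile: LineProfile) -> LineProfile:
    """Scale intensities so the profile maximum is exactly 1."""
    peak = float(np.max(profile.intensities))
    if peak <= 0:
        raise ValueError("cannot normalize a profile with non-positive maximum")
    return LineProfile(
        profile.positions_mm,
        profile.intensities / peak,
        profile.p0_mm,
        profile.p1_mm,
        profile.step_mm,
    )


def estimate_background(profile: LineProfile, flank_fraction: float = 0.2) -> float:
    """Cartilage background level: mean of the two profile flanks.

    Each flank is the first/last ``flank_fraction`` of the samples; the
    background is the arithmetic mean of the two flank means.
    """
    if not 0 < flank_fraction <= 0.4:
        raise ValueError("flank_fraction must be in (0, 0.4]")
    n = profile.intensities.size
    k = max(1, int(round(flank_fraction * n)))
    left = float(np.mean(profile.intensities[:k]))
    right = float(np.mean(profile.intensities[-k:]))
    return 0.5 * (left + right)


def _cross_down(pos, val, level, start, stop, step):
    """First interpolated crossing of ``level`` scanning from ``start`` toward
    ``stop`` (exclusive), moving away from the peak; returns position or None."""
    i = start
    while i != stop:
        j = i + step
        a, b = val[i], val[j]
        if (a - level) * (b - level) <= 0 and a != b:
            t = (level - a) / (b - a)
            return float(pos[i] + t * (pos[j] - pos[i]))
        if a == level == b:
            return float(pos[i])
        i = j
    return None


def compute_fwhm(profile: LineProfile, background: float) -> tuple[float, tuple[float, float]]:
    """Full width at half maximum of the defect peak.

    The half level is midway between the background and the (normalized)
    maximum; the width runs between the crossings nearest the global maximum
    on its left and right, localized by linear interpolation.
    """
    val = profile.intensities
    pos = profile.positions_mm
    vmax = float(np.max(val))
    if background >= vmax:
        raise ValueError("background must lie below the profile maximum")
    half = background + 0.5 * (vmax - background)
    i_max = int(np.argmax(val))
    left = _cross_down(pos, val, half, i_max, -1, -1) if i_max > 0 else None
    right = _cross_down(pos, val, half, i_max, val.size - 1, 1) if i_max < val.size - 1 else None
    if left is None or right is None:
        raise NoDefectError("profile never crosses the half-maximum level on both sides")
    return right - left, (left, right)


def compute_edge_width(
    profile: LineProfile,
    background: float,
    mode: str = "absolute",
    lo: float = 0.10,
    hi: float = 0.90,
) -> tuple[float, tuple[float, float]]:
    """Mean 10–90% shoulder width of the defect edges.

    ``mode='absolute'`` takes the thresholds as fractions of the normalized
    maximum; ``mode='relative'`` spans the background-to-maximum range.  In
    absolute mode a background at or above the lower threshold makes that
    level unreachable and raises :class:`ThresholdUnreachableError`.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError("mode must be 'absolute' or 'relative'")
    val = profile.intensities
    pos = profile.positions_mm
    vmax = float(np.max(val))
    if mode == "absolute":
        t_lo, t_hi = lo * vmax, hi * vmax
        if background >= t_lo:
            raise ThresholdUnreachableError(
                "background exceeds the 10% level; use mode='relative'"
            )
    else:
        t_lo = background + lo * (vmax - background)
        t_hi = background + hi * (vmax - background)
    i_max = int(np.argmax(val))
    widths = []
    for stop, step in ((-1, -1), (val.size - 1, 1)):
        x_hi = _cross_down(pos, val, t_hi, i_max, stop, step)
        x_lo = _cross_down(pos, val, t_lo, i_max, stop, step)
        if x_hi is None or x_lo is None:
            raise ThresholdUnreachableError(
                "shoulder never crosses the 10%/90% levels"
            )
        widths.append(abs(x_hi - x_lo))
    ew = float(np.mean(widths))
    return ew, (widths[0], widths[1])


def analyze_profile(
    profile: LineProfile,
    flank_fraction: float = 0.2,
    ew_mode: str = "absolute",
) -> DelineabilityResult:
    """Normalize a profile and compute both delineability surrogates."""
    prof = normalize_profile(profile)
    bg = estimate_background(prof, flank_fraction)
    fwhm, crossings = compute_fwhm(prof, bg)
    ew, shoulders = compute_edge_width(prof, bg, mode=ew_mode)
    half = bg + 0.5 * (1.0 - bg)
    return DelineabilityResult(fwhm, ew, shoulders, bg, half, crossings)
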