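"""Voxel-wise mono-exponential T2 / T1rho mapping from prep-weighted stacks.

The signal model is ``S(tau) = S0 * exp(-tau / T)`` where ``tau`` is the
preparation duration (TE-prep for T2, spin-lock duration for T1rho).  Fitting
is log-linear least squares on ``ln S = ln S0 - tau / T`` — exact on
noise-free data and identical to the two-point closed form
``T = dtau / ln(S1/S2)`` for two echoes.  Voxels whose signals fall below the
noise floor, fail to decay, or fit to a nonphysical relaxation time are
flagged invalid and encoded as NaN with an accompanying validity mask.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "InvalidVoxelError",
    "RelaxationMap",
    "fit_monoexp",
    "map_relaxation",
]

DEFAULT_CAP_MS = 500.0


class InvalidVoxelError(ValueError):
    """Signals cannot support a physical mono-exponential fit."""


@dataclass
class RelaxationMap:
    """Relaxation-time image (ms) with validity mask and fitted S0."""

    values_ms: np.ndarray  # NaN where invalid
    mask: np.ndarray  # bool
    s0: np.ndarray
    contrast_family: str
    spacing_mm: float = 1.0

    def __post_init__(self):
        if self.mask.shape != self.values_ms.shape or self.s0.shape != self.values_ms.shape:
            raise ValueError("map, mask and S0 must share one shape")
        valid = self.values_ms[self.mask]
        if valid.size and (np.any(~np.isfinite(valid)) or np.any(valid <= 0)):
            raise ValueError("masked-in values must be finite and positive")

    def save(self, path: str, mask_path: str | None = None) -> None:
        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        arr = np.transpose(np.atleast_3d(self.values_ms), (2, 1, 0))
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine), path)
        if mask_path:
            m = np.transpose(np.atleast_3d(self.mask.astype(np.uint8)), (2, 1, 0))
            nib.save(nib.Nifti1Image(m, affine), mask_path)
        meta = {"contrast_family": self.contrast_family, "spacing_mm": self.spacing_mm}
        sidecar = os.path.splitext(path)[0]
        if sidecar.endswith(".nii"):
            sidecar = os.path.splitext(sidecar)[0]
        with open(sidecar + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


def fit_monoexp(signals, taus) -> tuple[float, float]:
    """Fit ``S(tau) = S0 exp(-tau/T)`` to one voxel's signals.

    Returns ``(S0, T_ms)``.  Raises :class:`InvalidVoxelError` for
    non-positive or non-decaying signals — in map fitting these propagate to
    a False validity mask rather than an exception.
    """
    s = np.asarray(signals, dtype=float)
    t = np.asarray(taus, dtype=float)
    if s.size < 2 or s.size != t.size:
        raise ValueError("need matching signals and taus, at least two each")
    if np.any(np.diff(t) <= 0):
        raise ValueError("taus must be strictly increasing")
    if np.any(s <= 0):
        raise InvalidVoxelError("non-positive signal")
    if s[-1] >= s[0]:
        raise InvalidVoxelError("signal does not decay")
    if s.size == 2:
        big_t = (t[1] - t[0]) / np.log(s[0] / s[1])
        return float(s[0] * np.exp(t[0] / big_t)), float(big_t)
    ln_s = np.log(s)
    slope, intercept = np.polyfit(t, ln_s, 1)
    if slope >= 0:
        raise InvalidVoxelError("non-decaying fit")
    return float(np.exp(intercept)), float(-1.0 / slope)


def map_relaxation(
    stack,
    mask: np.ndarray | None = None,
    floor: float = 0.0,
    cap: float = DEFAULT_CAP_MS,
) -> RelaxationMap:
    """Apply the mono-exponential fit voxel-wise over a contrast stack.

    ``floor`` excludes voxels whose signal at any echo is at or below the
    noise floor (a sensible default with Rician noise of level sigma is
    ``3 * sigma``); ``cap`` marks implausibly long relaxation times invalid.
    The returned map is NaN outside the validity mask.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    if cap <= 0:
        raise ValueError("cap must be positive")
    taus = np.asarray(stack.taus_ms, dtype=float)
    sig = np.stack([np.asarray(im, dtype=float) for im in stack.images], axis=0)
    shape = sig.shape[1:]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    elif mask.shape != shape:
        raise ValueError("mask geometry does not match the stack")

    valid = mask & np.all(sig > max(floor, 0.0), axis=0) & np.all(sig > 0, axis=0)
    valid &= sig[-1] < sig[0]

    ln_s = np.where(sig > 0, np.log(np.where(sig > 0, sig, 1.0)), 0.0)
    t_c = taus - taus.mean()
    denom = float(np.sum(t_c**2))
    slope = np.tensordot(t_c, ln_s, axes=(0, 0)) / denom
    intercept = ln_s.mean(axis=0) - slope * taus.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        big_t = -1.0 / slope
    s0 = np.exp(intercept)

    valid &= np.isfinite(big_t) & (big_t > 0) & (big_t <= cap)
    values = np.where(valid, big_t, np.nan)
    s0 = np.where(valid, s0, np.nan)
    return RelaxationMap(
        values_ms=values,
        mask=valid,
        s0=s0,
        contrast_family=stack.contrast_family,
        spacing_mm=getattr(stack, "spacing_mm", 1.0),
    )
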