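"""Synthetic digital knee phantom and prep-module-weighted acquisition simulation.

The phantom emulates a sagittal slice through the lateral femorotibial
compartment: a circular femoral condyle (cortical shell around textured fatty
marrow) carrying a curved cartilage band of ~3 mm thickness, facing a flat
tibial plateau with its own cartilage layer, separated by synovial fluid.
Full-thickness cartilage defects of configurable nominal diameters (default
3, 5, 8 mm) are cut perpendicular to the bone contour and filled with fluid,
ordered anterior to posterior.

Image formation models only the magnetization-preparation dimension: each
echo is ``S(x, tau) = PD(x) * exp(-tau / Tc(x)) * f(x)`` where ``Tc`` is T2
for T2-preparation or T1rho for spin-lock preparation and ``f`` is a scalar
fat-suppression factor on fat-flagged voxels.  The echo train, TR/T1
saturation and coil/k-space effects are absorbed into the proton-density map.
Sequence-specific sharpness is modeled by a Gaussian point-spread blur and
measurement noise by the Rician magnitude law.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "TISSUE_CLASSES",
    "REGION_CLASSES",
    "TissueParams",
    "DEFAULT_TISSUE_TABLE",
    "PhantomSpec",
    "TissueModel",
    "SequenceParams",
    "ContrastStack",
    "DefectPlacementError",
    "build_phantom",
    "simulate_stack",
    "add_rician_noise",
    "defect_profile_endpoints",
    "texture_roi_center",
    "thickness_site",
    "t2prep_params",
    "spinlock_params",
]

# integer tissue labels used throughout
TISSUE_CLASSES = {
    "background": 0,
    "muscle": 1,
    "bone": 2,
    "marrow": 3,
    "cartilage": 4,
    "fluid": 5,
}

# cartilage subregions: anterior/central/posterior femur and tibia
REGION_CLASSES = {"none": 0, "aF": 1, "cF": 2, "pF": 3, "T": 4}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue signal model parameters.

    proton_density is in arbitrary units; t2 and t1rho in ms; fat marks
    tissue attenuated by spectral fat suppression.
    """

    proton_density: float
    t2: float
    t1rho: float
    fat: bool = False


# Relaxation times for cartilage default to the mid-range of the femoral
# values; they are overridden region-wise by PhantomSpec.regional_t2/t1rho.
DEFAULT_TISSUE_TABLE: dict[str, TissueParams] = {
    "background": TissueParams(0.0, 1.0, 1.0),
    "muscle": TissueParams(350.0, 30.0, 35.0),
    "bone": TissueParams(120.0, 5.0, 6.0),
    "marrow": TissueParams(900.0, 60.0, 65.0, fat=True),
    "cartilage": TissueParams(400.0, 50.0, 40.0),
    "fluid": TissueParams(1000.0, 200.0, 150.0),
}


class DefectPlacementError(ValueError):
    """A defect cannot be placed on the cartilage band without overlap."""

    def __init__(self, diameter_mm: float, message: str | None = None):
        self.diameter_mm = diameter_mm
        super().__init__(
            message or f"cannot place {diameter_mm} mm defect without overlap"
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue parameters and simulation settings of one phantom.

    The defaults reproduce the study conditions: 0.27 mm in-plane voxels,
    defects of 3, 5 and 8 mm diameter, a ~3 mm femoral cartilage band, and
    regional cartilage relaxation times matching the pre-defect study values.
    """

    shape: tuple[int, int] = (192, 192)  # (rows, cols) of one sagittal slice
    n_slices: int = 1
    spacing_mm: float = 0.27
    defect_diameters_mm: tuple[float, ...] = (3.0, 5.0, 8.0)
    defects_enabled: bool = True
    cartilage_thickness_mm: float = 3.0
    thickness_shift_mm: float = 0.0  # additive change, e.g. post-defect swelling
    tissue_table: dict[str, TissueParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE)
    )
    # region-wise cartilage relaxation times (ms); keys aF, cF, pF, T
    regional_t2: dict[str, float] = field(
        default_factory=lambda: {"aF": 48.0, "cF": 51.0, "pF": 64.0, "T": 41.0}
    )
    regional_t1rho: dict[str, float] = field(
        default_factory=lambda: {"aF": 43.0, "cF": 41.0, "pF": 34.0, "T": 36.0}
    )
    t2_shift: dict[str, float] = field(default_factory=dict)  # additive, ms
    t1rho_shift: dict[str, float] = field(default_factory=dict)
    # condyle geometry
    condyle_center_mm: tuple[float, float] | None = None  # (y, x); default from shape
    bone_radius_mm: float = 16.0
    cartilage_arc_deg: float = 150.0
    # trabecular marrow texture: multiplicative smoothed-noise field on marrow PD
    marrow_texture_amplitude: float = 0.05
    marrow_texture_scale_mm: float = 0.5
    # per-sequence PSF blur (mm) and global noise level, used by the pipeline
    blur_sigma_mm: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(d <= 0 for d in self.defect_diameters_mm):
            raise ValueError("defect diameters must be positive")
        if self.spacing_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.cartilage_thickness_mm + self.thickness_shift_mm <= 0:
            raise ValueError("cartilage thickness must be positive")
        for name, tp in self.tissue_table.items():
            if tp.t2 <= 0 or tp.t1rho <= 0:
                raise ValueError(f"relaxation times must be positive ({name})")
            if tp.proton_density < 0:
                raise ValueError(f"proton density must be non-negative ({name})")
        for table in (self.regional_t2, self.regional_t1rho):
            if any(v <= 0 for v in table.values()):
                raise ValueError("regional relaxation times must be positive")

    @property
    def center_mm(self) -> tuple[float, float]:
        if self.condyle_center_mm is not None:
            return self.condyle_center_mm
        ny, nx = self.shape
        return (0.33 * ny * self.spacing_mm, 0.5 * nx * self.spacing_mm)

    def without_defects(self) -> "PhantomSpec":
        """Paired pre-defect spec: identical geometry and seed, no defects."""
        return dataclasses.replace(self, defects_enabled=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tissue_table"] = {
            k: dataclasses.asdict(v) for k, v in self.tissue_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "tissue_table" in d:
            d["tissue_table"] = {
                k: TissueParams(**v) for k, v in d["tissue_table"].items()
            }
        for key in ("shape", "defect_diameters_mm", "condyle_center_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TissueModel:
    """Voxel grid of tissue labels with ground-truth parameter maps.

    Arrays are (slices, rows, cols).  ``region_labels`` carries the cartilage
    subregions (aF/cF/pF/T) used by the regional statistics module.
    """

    labels: np.ndarray  # uint8 tissue class
    region_labels: np.ndarray  # uint8 cartilage region
    proton_density: np.ndarray
    t2: np.ndarray
    t1rho: np.ndarray
    fat: np.ndarray  # bool
    spacing_mm: float
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spec: PhantomSpec | None = None

    def __post_init__(self):
        for arr in (self.region_labels, self.proton_density, self.t2,
                    self.t1rho, self.fat):
            if arr.shape != self.labels.shape:
                raise ValueError("parameter maps must share the label volume shape")
        if np.any(self.proton_density < 0):
            raise ValueError("proton density must be non-negative")
        nonbg = self.labels != TISSUE_CLASSES["background"]
        if np.any(self.t2[nonbg] <= 0) or np.any(self.t1rho[nonbg] <= 0):
            raise ValueError("relaxation maps must be positive on tissue voxels")

    @property
    def mid_slice(self) -> int:
        return self.labels.shape[0] // 2

    def tissue_mask(self, name: str) -> np.ndarray:
        return self.labels == TISSUE_CLASSES[name]

    def save(self, out_dir: str, prefix: str = "phantom") -> None:
        """Write label volume and parameter maps as NIfTI plus a JSON sidecar."""
        os.makedirs(out_dir, exist_ok=True)
        affine = np.diag([self.spacing_mm, self.spacing_mm, self.spacing_mm, 1.0])
        for name, arr in [
            ("labels", self.labels.astype(np.uint8)),
            ("regions", self.region_labels.astype(np.uint8)),
            ("pd", self.proton_density.astype(np.float32)),
            ("t2", self.t2.astype(np.float32)),
            ("t1rho", self.t1rho.astype(np.float32)),
        ]:
            img = nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine)
            nib.save(img, os.path.join(out_dir, f"{prefix}_{name}.nii.gz"))
        sidecar = {"spacing_mm": self.spacing_mm, "origin_mm": list(self.origin_mm)}
        if self.spec is not None:
            sidecar["spec"] = self.spec.to_dict()
        with open(os.path.join(out_dir, f"{prefix}.json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)


@dataclass(frozen=True)
class SequenceParams:
    """Acquisition parameters of one simulated prep-weighted sequence.

    ``contrast_family`` selects which relaxation time the preparation module
    probes: 'T2prep-PDFS' (T2 preparation; proton-density fat-sat baseline)
    or 'SLprep-T1w' (spin-lock preparation on a T1-weighted baseline).
    """

    contrast_family: str
    taus_ms: tuple[float, ...]
    fat_suppressed: tuple[bool, ...]
    blur_sigma_mm: float = 0.0
    spin_lock_hz: float = 500.0  # metadata only

    def __post_init__(self):
        if self.contrast_family not in ("T2prep-PDFS", "SLprep-T1w"):
            raise ValueError(f"unknown contrast family {self.contrast_family!r}")
        taus = self.taus_ms
        if len(taus) < 2:
            raise ValueError("at least two preparation durations required")
        if taus[0] != 0:
            raise ValueError("first preparation duration must be 0")
        if any(b >= a for a, b in zip(taus[1:], taus[:-1])):
            raise ValueError("preparation durations must be strictly increasing")
        if len(self.fat_suppressed) != len(taus):
            raise ValueError("need one fat-suppression flag per echo")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur sigma must be non-negative")


def t2prep_params(blur_sigma_mm: float = 0.0) -> SequenceParams:
    """The T2-preparation acquisition: PD-weighted FS plus a 50 ms prep echo."""
    return SequenceParams("T2prep-PDFS", (0.0, 50.0), (True, True), blur_sigma_mm)


def spinlock_params(blur_sigma_mm: float = 0.0) -> SequenceParams:
    """The spin-lock acquisition: T1-weighted plus 25/50 ms spin-lock echoes."""
    return SequenceParams(
        "SLprep-T1w", (0.0, 25.0, 50.0), (False, True, True), blur_sigma_mm
    )


@dataclass
class ContrastStack:
    """Co-registered echoes of one sequence, tagged with preparation duration."""

    images: list[np.ndarray]
    taus_ms: tuple[float, ...]
    fat_suppressed: tuple[bool, ...]
    contrast_family: str
    spacing_mm: float

    def __post_init__(self):
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all echoes must share one shape")
        if len(set(self.taus_ms)) != len(self.taus_ms):
            raise ValueError("preparation durations must be unique")

    def __len__(self) -> int:
        return len(self.images)

    def echo(self, tau_ms: float) -> np.ndarray:
        return self.images[self.taus_ms.index(tau_ms)]

    def save(self, out_dir: str, prefix: str = "stack") -> None:
        os.makedirs(out_dir, exist_ok=True)
        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        for i, im in enumerate(self.images):
            img = nib.Nifti1Image(
                np.transpose(im, (2, 1, 0)).astype(np.float32), affine
            )
            nib.save(img, os.path.join(out_dir, f"{prefix}_echo{i}.nii.gz"))
        meta = {
            "contrast_family": self.contrast_family,
            "taus_ms": list(self.taus_ms),
            "fat_suppressed": list(self.fat_suppressed),
            "spacing_mm": self.spacing_mm,
        }
        with open(os.path.join(out_dir, f"{prefix}.json"), "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, in_dir: str, prefix: str = "stack") -> "ContrastStack":
        with open(os.path.join(in_dir, f"{prefix}.json")) as fh:
            meta = json.load(fh)
        images = []
        for i in range(len(meta["taus_ms"])):
            img = nib.load(os.path.join(in_dir, f"{prefix}_echo{i}.nii.gz"))
            images.append(np.transpose(np.asarray(img.dataobj), (2, 1, 0)))
        return cls(
            images=images,
            taus_ms=tuple(meta["taus_ms"]),
            fat_suppressed=tuple(meta["fat_suppressed"]),
            contrast_family=meta["contrast_family"],
            spacing_mm=meta["spacing_mm"],
        )


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def _defect_angles(spec: PhantomSpec) -> list[float]:
    """Angular positions (rad, 0 = inferior apex, + = posterior) of each defect.

    Three defects sit at -38/0/+38 degrees; other counts are spread evenly
    over the central +/-45 degrees of the band.  Raises DefectPlacementError
    when adjacent defects would overlap or a defect would run off the band.
    """
    diams = spec.defect_diameters_mm
    k = len(diams)
    if k == 0:
        return []
    if k == 3:
        angles = [math.radians(a) for a in (-38.0, 0.0, 38.0)]
    elif k == 1:
        angles = [0.0]
    else:
        angles = list(np.linspace(math.radians(-45), math.radians(45), k))
    r_mid = spec.bone_radius_mm + 0.5 * (
        spec.cartilage_thickness_mm + spec.thickness_shift_mm
    )
    half_arc = math.radians(spec.cartilage_arc_deg / 2.0)
    margin = 0.5  # mm clearance between defects and to the band edge
    for d, a in zip(diams, angles):
        if r_mid * (half_arc - abs(a)) < d / 2 + margin:
            raise DefectPlacementError(d, f"{d} mm defect runs off the cartilage band")
    for (d1, a1), (d2, a2) in zip(zip(diams, angles), zip(diams[1:], angles[1:])):
        if r_mid * abs(a2 - a1) < (d1 + d2) / 2 + margin:
            raise DefectPlacementError(d2)
    return angles


def build_phantom(spec: PhantomSpec) -> TissueModel:
    """Construct the tissue model for one phantom specification.

    Deterministic given ``spec.seed``; a paired pre-defect model is obtained
    from ``spec.without_defects()`` (identical geometry, marrow texture and
    seed, no fluid-filled gaps).
    """
    ny, nx = spec.shape
    sp = spec.spacing_mm
    cy, cx = spec.center_mm
    tc = spec.cartilage_thickness_mm + spec.thickness_shift_mm
    rb = spec.bone_radius_mm

    ys, xs = np.meshgrid(
        np.arange(ny) * sp, np.arange(nx) * sp, indexing="ij"
    )
    dy = ys - cy
    dx = xs - cx
    r = np.hypot(dy, dx)
    # polar angle measured from the inferior (downward) apex; + toward posterior
    phi = np.arctan2(dx, dy)
    half_arc = math.radians(spec.cartilage_arc_deg / 2.0)

    labels = np.full((ny, nx), TISSUE_CLASSES["muscle"], dtype=np.uint8)
    regions = np.zeros((ny, nx), dtype=np.uint8)

    # femoral condyle: 1 mm cortical shell around trabecular marrow
    labels[r <= rb] = TISSUE_CLASSES["bone"]
    labels[r <= rb - 1.0] = TISSUE_CLASSES["marrow"]

    # femoral cartilage band on the inferior arc
    band = (r > rb) & (r <= rb + tc) & (np.abs(phi) <= half_arc)
    labels[band] = TISSUE_CLASSES["cartilage"]
    third = half_arc * 2 / 3
    regions[band & (phi < -half_arc + third)] = REGION_CLASSES["aF"]
    regions[band & (phi >= -half_arc + third) & (phi <= half_arc - third)] = (
        REGION_CLASSES["cF"]
    )
    regions[band & (phi > half_arc - third)] = REGION_CLASSES["pF"]

    # tibial plateau below the joint space (geometry independent of swelling)
    tib_top = cy + rb + spec.cartilage_thickness_mm + 1.5
    tib_cart = (ys > tib_top) & (ys <= tib_top + 2.5) & (np.abs(dx) <= 15.0)
    labels[tib_cart] = TISSUE_CLASSES["cartilage"]
    regions[tib_cart] = REGION_CLASSES["T"]
    tib_bone = ys > tib_top + 2.5
    labels[tib_bone] = TISSUE_CLASSES["bone"]
    labels[ys > tib_top + 3.5] = TISSUE_CLASSES["marrow"]

    # synovial fluid fills the joint space around the cartilage surfaces
    fluid = (
        (r > rb + tc)
        & (ys <= tib_top)
        & (ys > cy)
        & (np.abs(dx) <= 16.0)
        & (labels == TISSUE_CLASSES["muscle"])
    )
    labels[fluid] = TISSUE_CLASSES["fluid"]

    # full-thickness defects: slots of width d cut along the surface normal
    if spec.defects_enabled and spec.defect_diameters_mm:
        for d, a in zip(spec.defect_diameters_mm, _defect_angles(spec)):
            uy, ux = math.cos(a), math.sin(a)
            along = dy * uy + dx * ux
            perp = np.abs(dx * uy - dy * ux)
            cut = band & (perp < d / 2.0) & (along > 0)
            labels[cut] = TISSUE_CLASSES["fluid"]
            regions[cut] = REGION_CLASSES["none"]

    # parameter maps from the tissue table, cartilage overridden region-wise
    pd_map = np.zeros((ny, nx))
    t2_map = np.ones((ny, nx))
    t1r_map = np.ones((ny, nx))
    fat_map = np.zeros((ny, nx), dtype=bool)
    for name, code in TISSUE_CLASSES.items():
        tp = spec.tissue_table[name]
        m = labels == code
        pd_map[m] = tp.proton_density
        t2_map[m] = tp.t2
        t1r_map[m] = tp.t1rho
        fat_map[m] = tp.fat
    for reg, code in REGION_CLASSES.items():
        if reg == "none":
            continue
        m = (regions == code) & (labels == TISSUE_CLASSES["cartilage"])
        t2_map[m] = spec.regional_t2[reg] + spec.t2_shift.get(reg, 0.0)
        t1r_map[m] = spec.regional_t1rho[reg] + spec.t1rho_shift.get(reg, 0.0)

    # stack slices and add seeded trabecular texture to marrow proton density
    nz = spec.n_slices
    labels3 = np.broadcast_to(labels, (nz, ny, nx)).copy()
    regions3 = np.broadcast_to(regions, (nz, ny, nx)).copy()
    pd3 = np.broadcast_to(pd_map, (nz, ny, nx)).copy()
    t2_3 = np.broadcast_to(t2_map, (nz, ny, nx)).copy()
    t1r3 = np.broadcast_to(t1r_map, (nz, ny, nx)).copy()
    fat3 = np.broadcast_to(fat_map, (nz, ny, nx)).copy()

    if spec.marrow_texture_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal((nz, ny, nx))
        sigma_px = spec.marrow_texture_scale_mm / sp
        fieldv = ndimage.gaussian_filter(
            noise, sigma=(0, sigma_px, sigma_px), mode="reflect"
        )
        fieldv /= max(fieldv.std(), 1e-12)
        marrow = labels3 == TISSUE_CLASSES["marrow"]
        pd3[marrow] *= np.clip(
            1.0 + spec.marrow_texture_amplitude * fieldv[marrow], 0.05, None
        )

    return TissueModel(
        labels=labels3,
        region_labels=regions3,
        proton_density=pd3,
        t2=t2_3,
        t1rho=t1r3,
        fat=fat3,
        spacing_mm=sp,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# annotation helpers tied to the phantom geometry
# ---------------------------------------------------------------------------

def defect_profile_endpoints(
    spec: PhantomSpec, diameter_mm: float, flank_mm: float = 3.0
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints (mm, (y, x)) of a line through a defect and adjacent cartilage.

    The line runs tangentially through the defect center at the cartilage
    mid-surface, extending ``flank_mm`` of cartilage beyond each shoulder —
    the programmatic analogue of the study's manually placed line profiles.
    """
    diams = spec.defect_diameters_mm
    if diameter_mm not in diams:
        raise ValueError(f"no {diameter_mm} mm defect in this phantom")
    a = _defect_angles(spec)[diams.index(diameter_mm)]
    cy, cx = spec.center_mm
    r_mid = spec.bone_radius_mm + 0.5 * (
        spec.cartilage_thickness_mm + spec.thickness_shift_mm
    )
    center = (cy + r_mid * math.cos(a), cx + r_mid * math.sin(a))
    tangent = (-math.sin(a), math.cos(a))  # anterior -> posterior
    half = diameter_mm / 2.0 + flank_mm
    p0 = (center[0] - half * tangent[0], center[1] - half * tangent[1])
    p1 = (center[0] + half * tangent[0], center[1] + half * tangent[1])
    return p0, p1


def texture_roi_center(
    spec: PhantomSpec, depth_mm: float = 9.0, diameter_mm: float = 5.0
) -> tuple[float, float]:
    """Voxel-coordinate (row, col) center of the subchondral bone texture ROI.

    Placed in the marrow along the axis of the given defect (default the 5 mm
    defect), ``depth_mm`` beneath the cartilage-bone interface.
    """
    diams = spec.defect_diameters_mm
    a = _defect_angles(spec)[diams.index(diameter_mm)] if diameter_mm in diams else 0.0
    cy, cx = spec.center_mm
    r_roi = spec.bone_radius_mm - depth_mm
    y = cy + r_roi * math.cos(a)
    x = cx + r_roi * math.sin(a)
    return (y / spec.spacing_mm, x / spec.spacing_mm)


def thickness_site(
    spec: PhantomSpec, diameter_mm: float = 8.0, offset_mm: float = 1.5
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Caliper site adjacent to a defect: (location voxel, outward normal).

    The location sits at the cartilage mid-surface, ``offset_mm`` beyond the
    defect rim (anterior side); the direction is the local surface normal.
    """
    diams = spec.defect_diameters_mm
    a0 = _defect_angles(spec)[diams.index(diameter_mm)] if diameter_mm in diams else 0.0
    r_mid = spec.bone_radius_mm + 0.5 * (
        spec.cartilage_thickness_mm + spec.thickness_shift_mm
    )
    a = a0 - (diameter_mm / 2.0 + offset_mm) / r_mid
    cy, cx = spec.center_mm
    loc = (
        (cy + r_mid * math.cos(a)) / spec.spacing_mm,
        (cx + r_mid * math.sin(a)) / spec.spacing_mm,
    )
    return loc, (math.cos(a), math.sin(a))


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def add_rician_noise(image: np.ndarray, sigma: float, seed: int | None = None):
    """Corrupt an image with Rician (magnitude) noise.

    Output is ``sqrt((I + n1)^2 + n2^2)`` with independent ``n1, n2 ~
    N(0, sigma^2)``.  ``sigma == 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, image.shape)
    n2 = rng.normal(0.0, sigma, image.shape)
    return np.sqrt((image + n1) ** 2 + n2**2)


def simulate_stack(
    model: TissueModel,
    seq: SequenceParams,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    fat_suppression_factor: float = 0.05,
) -> ContrastStack:
    """Simulate the echoes of one prep-weighted sequence on a tissue model.

    Each echo is the ideal prep-decayed signal, optionally fat-attenuated,
    then blurred with the sequence's Gaussian PSF (reflective boundary,
    kernel truncated at 4 sigma) and corrupted with Rician noise.  With zero
    blur and zero noise the ideal signal is reproduced exactly.
    """
    if noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    tc = model.t2 if seq.contrast_family == "T2prep-PDFS" else model.t1rho
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    echo_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(seq.taus_ms))]
    sigma_px = seq.blur_sigma_mm / model.spacing_mm
    images = []
    for tau, fs, eseed in zip(seq.taus_ms, seq.fat_suppressed, echo_seeds):
        s = model.proton_density * np.exp(-tau / tc)
        if fs:
            s = np.where(model.fat, s * fat_suppression_factor, s)
        if sigma_px > 0:
            s = ndimage.gaussian_filter(
                s, sigma=(0, sigma_px, sigma_px), mode="reflect", truncate=4.0
            )
        if noise_sigma > 0:
            s = add_rician_noise(s, noise_sigma, seed=eseed)
        images.append(s)
    return ContrastStack(
        images=images,
        taus_ms=seq.taus_ms,
        fat_suppressed=seq.fat_suppressed,
        contrast_family=seq.contrast_family,
        spacing_mm=model.spacing_mm,
    )
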