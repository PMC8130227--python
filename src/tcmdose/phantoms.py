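"""Synthetic thorax phantoms and CT-volume handling.

The generator builds a supine, elliptical thorax in Hounsfield units: an
AP-flattened soft-tissue body, two low-density lungs, a posterior vertebral
column and, for female phantoms, two breast mounds whose glandular cores can
be displaced laterally so that tissue falls outside the anterior 120 degree
fluence-reduction sector of an organ-based modulation scheme.  The body
outline is solved by bisection so the water-equivalent diameter of the
central slice lands on a requested target.

HU volumes are converted to transport phantoms by a fixed threshold table
(air / lung / fat / water / muscle / bone) with a linear HU -> mass-density
ramp quantized to 17 discrete levels per material family.

Axis convention: arrays are indexed (z, y, x); z is the table direction,
anterior is -y, patient-left is +x.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from . import physics
from .tcm import Topogram

__all__ = [
    "SyntheticCT",
    "VoxelPhantom",
    "PatientRecord",
    "generate_thorax_phantom",
    "build_voxel_model",
    "compute_dw",
    "synthesize_topogram",
    "save_nifti",
    "load_nifti",
]

HU_MIN, HU_MAX = -1024.0, 3000.0

# HU thresholds of the material families (upper edges, air below -930)
_FAMILY_EDGES = {
    "air": (-np.inf, -930.0),
    "lung": (-930.0, -250.0),
    "fat": (-250.0, -20.0),
    "water": (-20.0, 20.0),
    "muscle": (20.0, 100.0),
    "bone": (100.0, np.inf),
}
_N_DENSITY_LEVELS = 17
AIR_DENSITY = 0.0012  # g/cm^3 floor
_BONE_DENSITY_MAX = 2.2


@dataclass(frozen=True)
class SyntheticCT:
    """Synthetic CT volume in HU with organ masks."""

    volume: np.ndarray  # (z, y, x) HU
    voxel_size: tuple  # (dz, dy, dx) cm
    organ_masks: dict  # name -> bool array, same shape
    sex: str
    meta: dict = field(default_factory=dict)

    def content_hash(self) -> str:
        h = hashlib.sha256(np.ascontiguousarray(self.volume).tobytes())
        for name in sorted(self.organ_masks):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.organ_masks[name]).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class VoxelPhantom:
    """Voxelized transport medium: material family codes + mass density."""

    material_id: np.ndarray  # uint8, physics material codes
    density: np.ndarray  # g/cm^3
    voxel_size: tuple  # (dz, dy, dx) cm
    organ_masks: dict = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


@dataclass
class PatientRecord:
    """One patient's size, scanner output and normalized-dose comparison."""

    id: str
    sex: str
    scanner: str
    dw_cm: float
    ctdivol_obtcm: float
    ctdivol_atcm: float
    nd_obtcm: float
    nd_atcm: float
    delta_nd_pct: float


def compute_dw(slice_hu: np.ndarray, roi_mask: np.ndarray, pixel_area: float) -> float:
    """Water-equivalent diameter (cm) of a 2-D HU slice.

    D_w = 2 * sqrt(A_w / pi) with the water-equivalent area
    A_w = sum over the ROI of (HU/1000 + 1) * pixel_area  (AAPM 220).
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    a_w = float(np.sum((np.asarray(slice_hu, float)[roi_mask] / 1000.0 + 1.0)) * pixel_area)
    return 2.0 * np.sqrt(max(a_w, 0.0) / np.pi)


def _thorax_slice(
    nx: int,
    ny: int,
    pixel_cm: float,
    a_lat: float,
    a_ap: float,
    taper: float,
    noise: np.ndarray,
    sex: str,
    breast_lateral_offset: float,
    in_breast_band: bool,
    z_breast_frac: float,
):
    """One axial HU slice plus masks.  Deterministic given the noise field."""
    yc, xc = (ny - 1) / 2.0, (nx - 1) / 2.0
    x = (np.arange(nx) - xc) * pixel_cm
    y = (np.arange(ny) - yc) * pixel_cm
    xx, yy = np.meshgrid(x, y)

    al, aa = a_lat * taper, a_ap * taper
    body = (xx / al) ** 2 + (yy / aa) ** 2 <= 1.0

    hu = np.full((ny, nx), -1000.0)
    hu[body] = 35.0 + 15.0 * noise[body]

    # lungs: two posteriorly-shifted ellipses
    lung = np.zeros_like(body)
    for k in (-1.0, 1.0):
        lx, ly = k * 0.36 * al, 0.06 * aa
        lung |= ((xx - lx) / (0.27 * al)) ** 2 + ((yy - ly) / (0.55 * aa)) ** 2 <= 1.0
    lung &= body
    hu[lung] = -750.0 + 30.0 * noise[lung]

    # vertebral column, posterior midline
    spine_r = max(1.3, 0.09 * al)
    spine = (xx**2 + (yy - 0.70 * aa) ** 2 <= spine_r**2) & body
    hu[spine] = 700.0

    breast_glandular = np.zeros_like(body)
    if sex == "female" and in_breast_band:
        theta_c = np.radians(min(20.0 + 9.0 * breast_lateral_offset, 80.0))
        # longitudinal envelope of the mound, 1 at band center
        env = np.sqrt(max(1.0 - z_breast_frac**2, 0.0))
        rbx, rby = 0.24 * al * env, 0.20 * aa * env
        if rbx > pixel_cm and rby > pixel_cm:
            for k in (-1.0, 1.0):
                bx = k * 0.92 * al * np.sin(theta_c)
                by = -0.92 * aa * np.cos(theta_c)
                mound = ((xx - bx) / rbx) ** 2 + ((yy - by) / rby) ** 2 <= 1.0
                core = ((xx - bx) / (0.6 * rbx)) ** 2 + ((yy - by) / (0.6 * rby)) ** 2 <= 1.0
                new = mound & ~body
                hu[new] = -80.0 + 15.0 * noise[new]
                hu[core] = 30.0 + 15.0 * noise[core]
                body |= mound
                breast_glandular |= core
    return hu, body, lung, breast_glandular


def generate_thorax_phantom(
    sex: str,
    target_dw: float,
    breast_lateral_offset: float = 0.0,
    n_slices: int = 32,
    seed: int = 0,
    grid_size: int = 112,
    pixel_cm: float = 0.5,
    slice_thickness_cm: float = 1.0,
) -> SyntheticCT:
    """Generate a supine thorax CT volume with a target water-equivalent
    diameter (cm) at the central slice.

    ``breast_lateral_offset`` (cm) displaces the breast mounds laterally; at
    ~3 cm the glandular cores straddle the +/-60 degree anterior sector, at 0
    they sit fully inside it.
    """
    if sex not in ("female", "male"):
        raise ValueError(f"sex must be 'female' or 'male', got {sex!r}")
    if not 15.0 <= target_dw <= 40.0:
        raise ValueError("target_dw must lie in [15, 40] cm")
    if n_slices < 8:
        raise ValueError("n_slices must be >= 8")

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_slices, grid_size, grid_size))
    nz = n_slices
    zc = nz // 2  # central-slice convention
    pixel_area = pixel_cm**2

    band_lo, band_hi = int(0.25 * nz), int(0.75 * nz)

    def central_dw(a_lat: float) -> float:
        zf = 0.0 if band_hi == band_lo else (2.0 * (zc - band_lo) / (band_hi - band_lo) - 1.0)
        hu, body, _, _ = _thorax_slice(
            grid_size, grid_size, pixel_cm, a_lat, 0.72 * a_lat, 1.0,
            noise[zc], sex, breast_lateral_offset,
            band_lo <= zc < band_hi, zf,
        )
        return compute_dw(hu, body, pixel_area)

    lo, hi = 0.30 * target_dw, 1.05 * target_dw
    if central_dw(hi) < target_dw:
        raise ValueError("target_dw too large for the phantom grid")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if central_dw(mid) < target_dw:
            lo = mid
        else:
            hi = mid
    a_lat = 0.5 * (lo + hi)
    a_ap = 0.72 * a_lat
    if a_lat * 1.05 > grid_size * pixel_cm / 2.0:
        raise ValueError("phantom exceeds the grid field of view; enlarge grid_size")

    volume = np.empty((nz, grid_size, grid_size))
    body_m = np.zeros((nz, grid_size, grid_size), bool)
    lung_m = np.zeros_like(body_m)
    breast_m = np.zeros_like(body_m)
    for iz in range(nz):
        zeta = iz / (nz - 1)
        taper = 0.92 + 0.08 * np.sin(np.pi * zeta)
        zf = 0.0 if band_hi == band_lo else (2.0 * (iz - band_lo) / (band_hi - band_lo) - 1.0)
        hu, body, lung, gland = _thorax_slice(
            grid_size, grid_size, pixel_cm, a_lat, a_ap, taper,
            noise[iz], sex, breast_lateral_offset,
            band_lo <= iz < band_hi, zf,
        )
        volume[iz], body_m[iz], lung_m[iz], breast_m[iz] = hu, body, lung, gland

    volume = np.clip(volume, HU_MIN, HU_MAX)
    masks = {"body": body_m, "lung": lung_m}
    if sex == "female":
        masks["breast_glandular"] = breast_m
    meta = {
        "sex": sex,
        "target_dw_cm": target_dw,
        "breast_lateral_offset_cm": breast_lateral_offset,
        "n_slices": n_slices,
        "seed": seed,
        "grid_size": grid_size,
        "pixel_cm": pixel_cm,
        "slice_thickness_cm": slice_thickness_cm,
        "a_lat_cm": a_lat,
        "achieved_dw_cm": compute_dw(volume[zc], body_m[zc], pixel_area),
    }
    return SyntheticCT(
        volume=volume,
        voxel_size=(slice_thickness_cm, pixel_cm, pixel_cm),
        organ_masks=masks,
        sex=sex,
        meta=meta,
    )


def _family_levels(lo_hu: float, hi_hu: float) -> np.ndarray:
    lo = 1.0 + lo_hu / 1000.0
    hi = 1.0 + hi_hu / 1000.0
    return np.linspace(lo, hi, _N_DENSITY_LEVELS)


_LEVELS = {
    physics.LUNG: _family_levels(-930.0, -250.0),
    physics.FAT: _family_levels(-250.0, -20.0),
    physics.WATER: _family_levels(-20.0, 20.0),
    physics.MUSCLE: _family_levels(20.0, 100.0),
    physics.BONE: np.linspace(1.10, _BONE_DENSITY_MAX, _N_DENSITY_LEVELS),
}


def material_of_hu(hu: np.ndarray) -> np.ndarray:
    """Material family code for each HU value (threshold table)."""
    hu = np.asarray(hu, float)
    mat = np.full(hu.shape, physics.BONE, dtype=np.uint8)
    mat[hu < 100.0] = physics.MUSCLE
    mat[hu < 20.0] = physics.WATER
    mat[hu < -20.0] = physics.FAT
    mat[hu < -250.0] = physics.LUNG
    mat[hu < -930.0] = physics.AIR
    return mat


def quantize_density(hu: np.ndarray, material: np.ndarray) -> np.ndarray:
    """Linear HU->density ramp snapped to 17 levels within each family."""
    rho_raw = 1.0 + np.asarray(hu, float) / 1000.0
    rho = np.full(rho_raw.shape, AIR_DENSITY)
    for fam, levels in _LEVELS.items():
        sel = material == fam
        if not np.any(sel):
            continue
        r = np.clip(rho_raw[sel], levels[0], levels[-1])
        idx = np.rint((r - levels[0]) / (levels[1] - levels[0])).astype(int)
        rho[sel] = levels[np.clip(idx, 0, _N_DENSITY_LEVELS - 1)]
    return rho


def build_voxel_model(ct, voxel_size=None) -> VoxelPhantom:
    """Convert a SyntheticCT (or raw HU volume + voxel_size) into a
    transport phantom of (material, density) voxels."""
    if isinstance(ct, SyntheticCT):
        hu, voxel_size, masks = ct.volume, ct.voxel_size, dict(ct.organ_masks)
    else:
        if voxel_size is None:
            raise ValueError("voxel_size required when passing a raw HU volume")
        hu, masks = np.asarray(ct, float), {}
    if not np.all(np.isfinite(hu)):
        idx = tuple(
            int(i) for i in np.unravel_index(int(np.flatnonzero(~np.isfinite(hu))[0]), hu.shape)
        )
        raise ValueError(f"non-finite HU at voxel {idx}")
    mat = material_of_hu(hu)
    rho = quantize_density(hu, mat)
    return VoxelPhantom(material_id=mat, density=rho, voxel_size=tuple(voxel_size), organ_masks=masks)


def synthesize_topogram(phantom: VoxelPhantom, design_energy_kev: float = 66.0) -> Topogram:
    """Scatter-free AP and LAT water-equivalent dimensions per table position.

    Each value is the maximum, over parallel detector rays, of the
    water-equivalent path length integral(mu / mu_water) dl at the design
    energy (~66 keV, where mu_water ~ 0.2/cm, the topogram convention for a
    120 kVp beam).
    """
    if phantom.material_id.size == 0:
        raise ValueError("empty phantom")
    mu_w = float(physics.mu_water(design_energy_kev))
    mu_rho = np.array(
        [float(physics.mu_rho_total(m, design_energy_kev)) for m in range(physics.N_MATERIALS)]
    )
    ratio = phantom.density * mu_rho[phantom.material_id] / mu_w
    dz, dy, dx = phantom.voxel_size
    ap = (ratio.sum(axis=1) * dy).max(axis=1)  # integrate along y, max over x
    lat = (ratio.sum(axis=2) * dx).max(axis=1)  # integrate along x, max over y
    z = (np.arange(phantom.material_id.shape[0]) + 0.5) * dz
    return Topogram(table_positions=z, ap=ap, lat=lat)


def save_nifti(ct: SyntheticCT, path) -> None:
    """Write the HU volume (+ masks and JSON sidecar) as NIfTI-1.

    Voxel sizes are stored in cm in the header zooms; array order (z, y, x).
    """
    path = str(path)
    affine = np.diag([ct.voxel_size[2], ct.voxel_size[1], ct.voxel_size[0], 1.0])
    img = nib.Nifti1Image(np.asarray(ct.volume, np.float32).T, affine)
    nib.save(img, path)
    base = path.removesuffix(".gz").removesuffix(".nii")
    for name, mask in ct.organ_masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8).T, affine), f"{base}_{name}.nii.gz")
    with open(base + ".json", "w") as fh:
        json.dump(ct.meta | {"sex": ct.sex, "voxel_size_cm": list(ct.voxel_size)}, fh, indent=2)


def load_nifti(path) -> SyntheticCT:
    path = str(path)
    img = nib.load(path)
    vol = np.asarray(img.get_fdata(), float).T
    zooms = img.header.get_zooms()
    base = path.removesuffix(".gz").removesuffix(".nii")
    try:
        with open(base + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {}
    sex = meta.get("sex", "female")
    masks = {}
    import glob as _glob

    for mpath in _glob.glob(base + "_*.nii.gz"):
        name = mpath[len(base) + 1 : -len(".nii.gz")]
        masks[name] = np.asarray(nib.load(mpath).get_fdata()).T.astype(bool)
    return SyntheticCT(
        volume=vol,
        voxel_size=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        organ_masks=masks,
        sex=sex,
        meta=meta,
    )
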