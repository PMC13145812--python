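"""Voxel phantoms, radiological ray tracing and the dual-resolution grid.

Grids are axis-aligned with 0-based indices; voxel (0,0,0) occupies the
half-open box [origin, origin + spacing).  World coordinates are in mm.
Radiological path length is geometric length scaled by the local relative
electron density, which equalises all media to water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .materials import AIR, BONE, WATER, Material

__all__ = [
    "VoxelGrid",
    "RayTraceResult",
    "Phantom",
    "trace_ray",
    "adaptive_mask",
    "coarsen_grid",
    "upsample_to_fine",
    "make_phantom",
    "save_phantom",
    "load_phantom",
    "save_volume",
]


@dataclass
class VoxelGrid:
    """Axis-aligned voxel grid with per-voxel (rho, rho_e, rho_c)."""

    shape: tuple[int, int, int]
    spacing: np.ndarray      # (3,) mm
    origin: np.ndarray       # (3,) mm, corner of voxel (0,0,0)
    rho: np.ndarray          # g cm^-3
    rho_e: np.ndarray        # relative electron density
    rho_c: np.ndarray        # relative atomic-core density

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive")
        for name in ("rho", "rho_e", "rho_c"):
            arr = getattr(self, name)
            if arr.shape != tuple(self.shape):
                raise ValueError(f"{name} has shape {arr.shape}, expected {self.shape}")

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int, int],
        spacing: float | np.ndarray = 1.0,
        origin: np.ndarray | None = None,
        material: Material = WATER,
    ) -> "VoxelGrid":
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,)).copy()
        if origin is None:
            origin = np.zeros(3)
        full = lambda v: np.full(shape, v, dtype=np.float32)  # noqa: E731
        return cls(tuple(shape), spacing, np.asarray(origin, float),
                   full(material.rho), full(material.rho_e), full(material.rho_c))

    def fill(self, mask: np.ndarray, material: Material) -> None:
        self.rho[mask] = material.rho
        self.rho_e[mask] = material.rho_e
        self.rho_c[mask] = material.rho_c

    @property
    def extent(self) -> np.ndarray:
        """Upper corner of the grid box in mm."""
        return self.origin + self.spacing * np.asarray(self.shape)

    def centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(self.centers(0), self.centers(1), self.centers(2),
                           indexing="ij")


@dataclass
class RayTraceResult:
    """Ordered voxel traversal of one ray."""

    indices: np.ndarray       # (N, 3) int voxel indices
    lengths: np.ndarray       # (N,) geometric segment lengths, mm
    rad_lengths: np.ndarray   # (N,) radiological segment lengths, mm
    entry_t: float = 0.0      # distance from ray origin to grid entry, mm

    def __len__(self) -> int:
        return len(self.lengths)

    @property
    def cum_geom(self) -> np.ndarray:
        return np.cumsum(self.lengths)

    @property
    def cum_rad(self) -> np.ndarray:
        return np.cumsum(self.rad_lengths)


def trace_ray(grid: VoxelGrid, origin: np.ndarray, direction: np.ndarray) -> RayTraceResult:
    """Siddon-style exact voxel traversal of a ray through the grid.

    ``origin`` is a point on the ray (mm), ``direction`` a unit vector.  A
    ray that misses the grid returns an empty result.  Boundary-coincident
    crossings advance along the axis with the largest direction cosine
    first, which makes the traversal deterministic.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")

    lo = grid.origin
    hi = grid.extent
    t0, t1 = 0.0, np.inf
    for ax in range(3):
        d = direction[ax]
        if abs(d) < 1e-14:
            if not (lo[ax] <= origin[ax] < hi[ax]):
                return RayTraceResult(np.empty((0, 3), int), np.empty(0), np.empty(0))
            continue
        ta = (lo[ax] - origin[ax]) / d
        tb = (hi[ax] - origin[ax]) / d
        t0 = max(t0, min(ta, tb))
        t1 = min(t1, max(ta, tb))
    if t1 <= t0 + 1e-12:
        return RayTraceResult(np.empty((0, 3), int), np.empty(0), np.empty(0))

    eps = 1e-9
    p = origin + (t0 + eps) * direction
    idx = np.floor((p - lo) / grid.spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)

    step = np.where(direction > 0, 1, -1)
    # parametric distance to the next boundary along each axis
    t_next = np.full(3, np.inf)
    dt = np.full(3, np.inf)
    for ax in range(3):
        d = direction[ax]
        if abs(d) < 1e-14:
            continue
        next_bound = lo[ax] + (idx[ax] + (1 if d > 0 else 0)) * grid.spacing[ax]
        t_next[ax] = (next_bound - origin[ax]) / d
        dt[ax] = grid.spacing[ax] / abs(d)

    dominant = np.argsort(-np.abs(direction))  # tie-break priority
    indices, lengths = [], []
    t = t0
    shape = np.asarray(grid.shape)
    while t < t1 - 1e-12:
        ax = min(range(3), key=lambda a: (t_next[a], list(dominant).index(a)))
        t_hit = min(t_next[ax], t1)
        seg = t_hit - t
        if seg > 1e-12:
            indices.append(idx.copy())
            lengths.append(seg)
        t = t_hit
        idx[ax] += step[ax]
        t_next[ax] += dt[ax]
        if idx[ax] < 0 or idx[ax] >= shape[ax]:
            break

    if not indices:
        return RayTraceResult(np.empty((0, 3), int), np.empty(0), np.empty(0))
    indices = np.array(indices)
    lengths = np.array(lengths)
    rho_e = grid.rho_e[indices[:, 0], indices[:, 1], indices[:, 2]]
    return RayTraceResult(indices, lengths, lengths * rho_e, entry_t=t0)


def adaptive_mask(grid: VoxelGrid, footprint: np.ndarray, threshold: float = 1e-3) -> np.ndarray:
    """Fine-resolution mask from an incident classical-fluence footprint.

    Voxels where the footprint exceeds ``threshold`` times its maximum are
    resolved at the native (fine) spacing; the rest of the grid is handled
    on 4x aggregated coarse blocks.  Returns a boolean array, True = fine.
    """
    footprint = np.asarray(footprint)
    if footprint.shape != tuple(grid.shape):
        raise ValueError("footprint must be defined on the full grid")
    peak = footprint.max()
    if peak <= 0:
        return np.zeros(grid.shape, dtype=bool)
    return footprint > threshold * peak


def coarsen_grid(grid: VoxelGrid, factor: int = 4) -> VoxelGrid:
    """Aggregate fine voxels into factor^3 blocks with volume-averaged densities."""
    cs = tuple(-(-n // factor) for n in grid.shape)

    def block_mean(a: np.ndarray) -> np.ndarray:
        pad = [(0, c * factor - n) for n, c in zip(a.shape, cs)]
        a = np.pad(a, pad, mode="edge")
        return a.reshape(cs[0], factor, cs[1], factor, cs[2], factor).mean(axis=(1, 3, 5))

    return VoxelGrid(cs, grid.spacing * factor, grid.origin.copy(),
                     block_mean(grid.rho).astype(np.float32),
                     block_mean(grid.rho_e).astype(np.float32),
                     block_mean(grid.rho_c).astype(np.float32))


def upsample_to_fine(coarse: np.ndarray, fine_shape: tuple[int, int, int],
                     factor: int = 4) -> np.ndarray:
    """Block-replicate a coarse-grid field onto the fine grid."""
    out = coarse.repeat(factor, 0).repeat(factor, 1).repeat(factor, 2)
    return out[: fine_shape[0], : fine_shape[1], : fine_shape[2]]


@dataclass
class Phantom:
    grid: VoxelGrid
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _sphere_mask(grid: VoxelGrid, center: np.ndarray, radius: float) -> np.ndarray:
    X, Y, Z = grid.center_mesh()
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2 <= radius**2


def make_phantom(preset: str, **params) -> Phantom:
    """Build a synthetic phantom fixture.

    Presets
    -------
    watertank : homogeneous water tank; the 12 mm water-equivalent entry
        wall is uniform water so the volume is homogeneous.
    slab : water with slabs of air or bone perpendicular to the z axis;
        ``slabs=[(z0_mm, thickness_mm, "bone"), ...]``.
    sinus : water containing an air/bone checkerboard pocket emulating a
        frontal-sinus heterogeneity.
    head : ellipsoidal water head with a 5 mm skin shell, a bone shell
        beneath it, and a superficial spherical GTV (diameter ``gtv_diameter``
        mm at centre depth ``gtv_depth`` mm below the +x surface).
    """
    shape = tuple(params.pop("shape", (100, 100, 100)))
    spacing = params.pop("spacing", 1.0)

    if preset == "watertank":
        grid = VoxelGrid.uniform(shape, spacing, material=WATER)
        return Phantom(grid, meta={"preset": preset, "entry_equivalent_mm": 12.0})

    if preset == "slab":
        slabs = params.pop("slabs", [])
        grid = VoxelGrid.uniform(shape, spacing, material=WATER)
        z = grid.centers(2)
        mats = {"air": AIR, "bone": BONE, "water": WATER}
        for z0, thick, mat_name in slabs:
            sel = (z >= z0) & (z < z0 + thick)
            grid.rho[:, :, sel] = mats[mat_name].rho
            grid.rho_e[:, :, sel] = mats[mat_name].rho_e
            grid.rho_c[:, :, sel] = mats[mat_name].rho_c
        return Phantom(grid, meta={"preset": preset, "slabs": slabs})

    if preset == "sinus":
        grid = VoxelGrid.uniform(shape, spacing, material=WATER)
        pocket = params.pop("pocket_mm", (20.0, 60.0))  # along z
        period = int(round(params.pop("cell_mm", 4.0) / grid.spacing[2]))
        z = grid.centers(2)
        sel = (z >= pocket[0]) & (z < pocket[1])
        I, J, K = np.indices(shape)
        checker = ((I // period) + (J // period) + (K // period)) % 2 == 0
        air_m = sel[None, None, :] & checker
        bone_m = sel[None, None, :] & ~checker
        grid.fill(air_m, AIR)
        grid.fill(bone_m, BONE)
        return Phantom(grid, meta={"preset": preset})

    if preset == "head":
        shape = tuple(params.pop("head_shape", (110, 110, 110))) if shape == (100, 100, 100) else shape
        gtv_depth = params.pop("gtv_depth", 15.0)
        gtv_diameter = params.pop("gtv_diameter", 14.0)
        skin_mm = params.pop("skin_mm", 5.0)
        bone_mm = params.pop("bone_mm", 5.0)
        grid = VoxelGrid.uniform(shape, spacing, material=AIR)
        center = (grid.origin + grid.extent) / 2.0
        semi = np.asarray(params.pop("semi_axes", None)
                          if params.get("semi_axes") is not None
                          else (np.asarray(shape) * grid.spacing) / 2.0 - 3.0, float)
        if gtv_depth >= semi[0]:
            raise ValueError("GTV deeper than head radius")
        if gtv_depth >= 36.0:
            raise ValueError("GTV depth must be < 36 mm for this treatment geometry")
        X, Y, Z = grid.center_mesh()

        def ellipsoid(scale_mm: float) -> np.ndarray:
            s = semi - scale_mm
            return ((X - center[0]) / s[0]) ** 2 + ((Y - center[1]) / s[1]) ** 2 \
                + ((Z - center[2]) / s[2]) ** 2 <= 1.0

        head = ellipsoid(0.0)
        inner_skin = ellipsoid(skin_mm)
        inner_bone = ellipsoid(skin_mm + bone_mm)
        grid.fill(head, WATER)
        grid.fill(inner_skin & ~inner_bone, BONE)
        gtv_center = np.array([center[0] + semi[0] - gtv_depth, center[1], center[2]])
        gtv = _sphere_mask(grid, gtv_center, gtv_diameter / 2.0)
        grid.fill(gtv, WATER)  # tumour is soft tissue
        masks = {
            "gtv": gtv,
            "skin": head & ~inner_skin,
            "brain": inner_bone & ~gtv,
        }
        return Phantom(grid, masks, meta={"preset": preset, "gtv_center": gtv_center.tolist(),
                                          "gtv_diameter": gtv_diameter})

    raise ValueError(f"unknown phantom preset: {preset!r}")


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin + grid.spacing / 2.0
    return aff


def save_phantom(phantom: Phantom, path: str) -> None:
    """Write the density volume as NIfTI with a YAML sidecar and label maps."""
    grid = phantom.grid
    nib.save(nib.Nifti1Image(grid.rho.astype(np.float32), _affine(grid)), path)
    base = path.removesuffix(".gz").removesuffix(".nii")
    sidecar = {
        "density_to_material": {"air": "rho <= 0.05", "bone": "rho >= 1.2",
                                "water": "otherwise"},
        "meta": {k: v for k, v in phantom.meta.items()},
        "spacing_mm": grid.spacing.tolist(),
        "origin_mm": grid.origin.tolist(),
    }
    with open(base + ".yaml", "w") as fh:
        yaml.safe_dump(sidecar, fh)
    for name, mask in phantom.masks.items():
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(grid)),
                 f"{base}_{name}.nii.gz")


def load_phantom(path: str) -> Phantom:
    img = nib.load(path)
    rho = np.asarray(img.dataobj, dtype=np.float32)
    base = path.removesuffix(".gz").removesuffix(".nii")
    with open(base + ".yaml") as fh:
        sidecar = yaml.safe_load(fh)
    spacing = np.asarray(sidecar["spacing_mm"], float)
    origin = np.asarray(sidecar["origin_mm"], float)
    rho_e = np.empty_like(rho)
    rho_c = np.empty_like(rho)
    for mat, sel in ((AIR, rho <= 0.05), (BONE, rho >= 1.2),
                     (WATER, (rho > 0.05) & (rho < 1.2))):
        scale = rho[sel] / mat.rho if mat.rho > 0 else 1.0
        rho_e[sel] = mat.rho_e * scale
        rho_c[sel] = mat.rho_c * scale
    grid = VoxelGrid(tuple(rho.shape), spacing, origin, rho, rho_e, rho_c)
    masks = {}
    import glob
    import os
    for mpath in glob.glob(base + "_*.nii.gz"):
        name = os.path.basename(mpath)[len(os.path.basename(base)) + 1:].removesuffix(".nii.gz")
        masks[name] = np.asarray(nib.load(mpath).dataobj) > 0
    return Phantom(grid, masks, meta=sidecar.get("meta", {}))


def save_volume(arr: np.ndarray, grid: VoxelGrid, path: str) -> None:
    """Write a scalar field aligned to the phantom grid as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(grid)), path)
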