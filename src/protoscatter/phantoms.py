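"""Voxel HU phantoms and target volumes.

The synthetic phantoms emulate the composition extremes seen across
passive-scattering treatment sites: a homogeneous water box, a lung-like
phantom with a controllable air fraction in the beam's-eye view (BEV), a
pelvis-like phantom with a controllable dense-bone fraction, and arbitrary
axis-aligned slab stacks used as ray-tracing oracles.

Conventions
-----------
* The beam axis is +z; phantoms are generated so that their heterogeneity
  pattern is constant within full-cross-section z-bands, which makes the
  BEV composition exactly controllable and independent of beam angle.
* Voxel indexing is 0-based with array axes (x, y, z); the world
  coordinate of a voxel centre is ``origin + (index + 0.5) * spacing``
  (half-voxel convention).
* Default grids are 2 mm isotropic over a 30 cm cube.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .errors import InvalidInputError
from .materials import HU_MAX, HU_MIN

DEFAULT_SHAPE = (150, 150, 150)
DEFAULT_SPACING = (2.0, 2.0, 2.0)

#: Default radius (mm) of the central BEV cylinder used when a generator
#: targets a composition fraction; matches the default 5 cm field radius.
DEFAULT_BEV_RADIUS_MM = 50.0

HU_AIR_POCKET = -800
HU_BONE_SHELL = 300
HU_DENSE_BONE = 700


@dataclass
class HUGrid:
    """A voxelised CT-like phantom in Hounsfield units.

    values
        int16 array with axes (x, y, z).
    spacing, origin
        millimetres; origin is the world coordinate of the grid corner
        (the corner of voxel (0,0,0), not its centre).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InvalidInputError("HU grid must be 3-D with all dims >= 1")
        if self.values.dtype != np.int16:
            if self.values.min() < HU_MIN or self.values.max() > HU_MAX:
                raise InvalidInputError("HU values outside [-1024, 3000]")
            self.values = self.values.astype(np.int16)
        if self.values.min() < HU_MIN or self.values.max() > HU_MAX:
            raise InvalidInputError("HU values outside [-1024, 3000]")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if min(self.spacing) <= 0:
            raise InvalidInputError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def world_center(self) -> np.ndarray:
        return np.asarray(self.origin) + self.extent_mm / 2.0


@dataclass
class TargetSpec:
    """A target volume: boolean mask congruent with an HUGrid plus its
    centroid in world millimetres (the isocentre surrogate)."""

    mask: np.ndarray
    centroid: np.ndarray = field(default=None)
    _grid: HUGrid = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise InvalidInputError("target mask is empty")
        if self.centroid is None:
            if self._grid is None:
                raise InvalidInputError("centroid or grid required")
            idx = np.argwhere(self.mask)
            c = idx.mean(axis=0) + 0.5
            self.centroid = np.asarray(self._grid.origin) + c * np.asarray(
                self._grid.spacing
            )
        self.centroid = np.asarray(self.centroid, dtype=float)


def _validate_shape(shape) -> tuple[int, int, int]:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 10:
        raise InvalidInputError(f"degenerate phantom shape {shape}; need >= (10,10,10)")
    return shape


def _central_cube_mask(shape, frac: float = 0.2) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    sl = []
    for n in shape:
        w = max(1, int(round(n * frac)))
        lo = (n - w) // 2
        sl.append(slice(lo, lo + w))
    mask[tuple(sl)] = True
    return mask


def bev_cylinder_mask(grid: HUGrid, radius_mm: float = DEFAULT_BEV_RADIUS_MM,
                      center_xy_mm=None) -> np.ndarray:
    """Boolean mask of the central cylinder along the beam (+z) axis used
    as the beam's-eye-view composition region."""
    if radius_mm <= 0:
        raise InvalidInputError("BEV radius must be positive")
    cx, cy = (grid.world_center()[:2] if center_xy_mm is None else center_xy_mm)
    x = grid.voxel_centers_axis(0)
    y = grid.voxel_centers_axis(1)
    r2 = (x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2
    disc = r2 <= radius_mm**2
    return np.repeat(disc[:, :, None], grid.shape[2], axis=2)


def make_water_box(shape=(50, 50, 50), spacing=DEFAULT_SPACING,
                   origin=(0.0, 0.0, 0.0)) -> tuple[HUGrid, TargetSpec]:
    """Homogeneous water phantom (HU 0 everywhere) with a central cubic
    target spanning one fifth of each dimension."""
    shape = _validate_shape(shape)
    grid = HUGrid(np.zeros(shape, dtype=np.int16), spacing, origin)
    target = TargetSpec(_central_cube_mask(shape), _grid=grid)
    return grid, target


def make_slab_phantom(layers, lateral_shape=(50, 50), spacing=DEFAULT_SPACING,
                      origin=(0.0, 0.0, 0.0)) -> tuple[HUGrid, TargetSpec]:
    """Stack axis-aligned slabs along the beam (+z) axis.

    ``layers`` is a list of ``(thickness_mm, hu)`` pairs; each slab is
    rasterised to whole voxels (thickness rounded to the nearest voxel,
    minimum one).
    """
    if not layers:
        raise InvalidInputError("need at least one slab layer")
    sz = spacing[2]
    counts = []
    for thickness, hu in layers:
        if thickness <= 0:
            raise InvalidInputError("slab thicknesses must be positive")
        counts.append(max(1, int(round(thickness / sz))))
    nz = sum(counts)
    nx, ny = lateral_shape
    vals = np.zeros((nx, ny, nz), dtype=np.int16)
    z0 = 0
    for (thickness, hu), n in zip(layers, counts):
        vals[:, :, z0 : z0 + n] = int(hu)
        z0 += n
    grid = HUGrid(vals, spacing, origin)
    mask = np.zeros_like(vals, dtype=bool)
    mask[nx // 4 : -nx // 4 or None, ny // 4 : -ny // 4 or None, nz // 3 : 2 * nz // 3] = True
    target = TargetSpec(mask, _grid=grid)
    return grid, target


def make_lung_phantom(air_fraction: float, seed: int, shape=DEFAULT_SHAPE,
                      spacing=DEFAULT_SPACING, bev_radius_mm=DEFAULT_BEV_RADIUS_MM,
                      surface_gap_mm: float = 0.0) -> tuple[HUGrid, TargetSpec]:
    """Lung-like phantom: soft-tissue body with low-density (HU -800) air
    bands filling the requested fraction of the BEV region.

    The air pockets are full-cross-section z-bands chosen with the seeded
    generator from the interior slice set (excluding an entrance/exit
    chest-wall shell and the target block), so the achieved BEV air
    fraction equals the request to within one slice (< 0.5 percentage
    points) and every beamlet traverses the same air path.

    ``surface_gap_mm`` optionally inserts a true-air (HU -1000) gap at the
    entrance surface, emulating a gap between an immobilisation device and
    the patient surface; it is not counted toward ``air_fraction``.
    """
    if not (0.0 <= air_fraction <= 0.6):
        raise InvalidInputError("air_fraction must be within [0, 0.6]")
    shape = _validate_shape(shape)
    nx, ny, nz = shape
    rng = np.random.default_rng(int(seed))
    vals = np.zeros(shape, dtype=np.int16)

    shell = max(2, int(round(20.0 / spacing[2])))  # ~2 cm chest wall each side
    gap_slices = int(round(surface_gap_mm / spacing[2]))
    if gap_slices:
        vals[:, :, :gap_slices] = -1000
        shell_lo = gap_slices + shell
    else:
        shell_lo = shell

    target_mask = _central_cube_mask(shape, frac=0.2)
    zt = np.where(target_mask.any(axis=(0, 1)))[0]
    margin = max(1, int(round(4.0 / spacing[2])))
    forbidden = set(range(0, shell_lo)) | set(range(nz - shell, nz))
    forbidden |= set(range(max(0, zt[0] - margin), min(nz, zt[-1] + margin + 1)))
    available = np.array(sorted(set(range(nz)) - forbidden))

    n_band = int(round(air_fraction * nz))
    if n_band > len(available):
        raise InvalidInputError(
            f"air_fraction {air_fraction} needs {n_band} slices but only "
            f"{len(available)} are outside the shell and target"
        )
    if n_band:
        chosen = rng.choice(available, size=n_band, replace=False)
        vals[:, :, np.sort(chosen)] = HU_AIR_POCKET

    grid = HUGrid(vals, spacing)
    target = TargetSpec(target_mask, _grid=grid)
    return grid, target


def make_pelvis_phantom(dense_bone_fraction: float, seed: int, shape=DEFAULT_SHAPE,
                        spacing=DEFAULT_SPACING,
                        bev_radius_mm=DEFAULT_BEV_RADIUS_MM) -> tuple[HUGrid, TargetSpec]:
    """Pelvis-like phantom: soft-tissue body with a femoral-head-like bone
    crossing upstream of the target — an HU 700 dense core wrapped in HU
    300 cortical shell slices — as a lateral prostate field traverses.

    Like the lung generator, the bone is laid down as full-cross-section
    z-bands so the BEV composition is exact: the dense core occupies
    ``round(dense_bone_fraction * nz)`` slices (well within the +-1
    percentage point tolerance), placed with the seeded generator between
    the entrance shell and the target.
    """
    if not (0.0 <= dense_bone_fraction <= 0.10):
        raise InvalidInputError("dense_bone_fraction must be within [0, 0.10]")
    shape = _validate_shape(shape)
    nx, ny, nz = shape
    rng = np.random.default_rng(int(seed))
    vals = np.zeros(shape, dtype=np.int16)
    target_mask = _central_cube_mask(shape, frac=0.2)

    k = int(round(dense_bone_fraction * nz))
    if k:
        shell_px = 2  # cortical HU 300 slices each side of the dense core
        entry = max(2, int(round(15.0 / spacing[2])))
        zt = np.where(target_mask.any(axis=(0, 1)))[0]
        margin = max(1, int(round(4.0 / spacing[2])))
        lo_limit = entry + shell_px
        hi_limit = zt[0] - margin - shell_px - k
        if hi_limit < lo_limit:
            raise InvalidInputError(
                f"dense_bone_fraction {dense_bone_fraction} does not fit "
                "between entrance shell and target; enlarge the grid"
            )
        z_lo = int(rng.integers(lo_limit, hi_limit + 1))
        vals[:, :, z_lo - shell_px : z_lo + k + shell_px] = HU_BONE_SHELL
        vals[:, :, z_lo : z_lo + k] = HU_DENSE_BONE
    grid = HUGrid(vals, spacing)
    target = TargetSpec(target_mask, _grid=grid)
    return grid, target


# ---------------------------------------------------------------------------
# MetaImage I/O

def write_mha(grid_or_mask, path) -> None:
    """Write an HUGrid (int16) or boolean mask (uint8 0/1) as MetaImage."""
    if isinstance(grid_or_mask, HUGrid):
        arr = grid_or_mask.values
        spacing = grid_or_mask.spacing
        origin = grid_or_mask.origin
    else:
        arr = np.asarray(grid_or_mask).astype(np.uint8)
        spacing = DEFAULT_SPACING
        origin = (0.0, 0.0, 0.0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    # SimpleITK's origin is the centre of voxel (0,0,0).
    img.SetOrigin(tuple(float(o) + 0.5 * float(s) for o, s in zip(origin, spacing)))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_mha(path) -> HUGrid:
    """Read a MetaImage written by :func:`write_mha` back into an HUGrid."""
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = img.GetSpacing()
    origin = tuple(o - 0.5 * s for o, s in zip(img.GetOrigin(), spacing))
    return HUGrid(arr.astype(np.int16), spacing, origin)


def read_mask_mha(path) -> np.ndarray:
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(bool)
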