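"""Synthetic voxelized breast phantoms.

A phantom is a labeled voxel grid standing in for a patient-specific
breast model: a hemisphere of soft tissue attached to a flat chest wall,
imaged in the prone (pendant) position.  World coordinates are in meters,
the chest-wall plane is ``z = 0`` and the ``z`` axis points from chest
wall to nipple.  Voxel membership is decided by the voxel *center*.

Tissue classes
--------------
========  =====  ==========================================
label     name   role
========  =====  ==========================================
0         air    outside the body
1         fat    adipose tissue
2         gland  fibro-glandular tissue
3         tumor  embedded spherical lesion
4         chest  chest wall (fixed core temperature)
5         skin   optional thin cutaneous shell
========  =====  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
import yaml

AIR, FAT, GLAND, TUMOR, CHEST, SKIN = 0, 1, 2, 3, 4, 5

#: labels that count as breast (soft, perfused) tissue
BREAST_LABELS = (FAT, GLAND, TUMOR, SKIN)

#: voxel budget guard against accidentally huge grids
MAX_VOXELS = 4_000_000


class PhantomError(ValueError):
    """Invalid phantom geometry or parameters."""


class TumorPlacementError(PhantomError):
    """Tumor sphere captures no breast voxel (outside breast / sub-voxel)."""


@dataclass(frozen=True)
class TumorParams:
    """Spherical tumor: center (m, world coordinates) and diameter (m)."""

    center: tuple[float, float, float]
    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise PhantomError(f"tumor diameter must be > 0, got {self.diameter}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    def as_array(self) -> np.ndarray:
        return np.array([*self.center, self.diameter], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "TumorParams":
        x, y, z, d = (float(v) for v in theta)
        return cls(center=(x, y, z), diameter=d)


@dataclass(frozen=True)
class ClassProperties:
    """Thermal properties of one tissue class."""

    k: float  # thermal conductivity, W m^-1 K^-1
    omega_b: float  # blood perfusion rate, s^-1
    q_m: float  # metabolic volumetric heat, W m^-3

    def __post_init__(self):
        if not self.k > 0:
            raise PhantomError(f"conductivity must be > 0, got {self.k}")
        if self.omega_b < 0 or self.q_m < 0:
            raise PhantomError("perfusion and metabolic heat must be >= 0")


@dataclass(frozen=True)
class TissueProperties:
    """Per-class thermal properties plus shared blood parameters.

    ``rho_b``/``c_b`` are blood density (kg m^-3) and specific heat
    (J kg^-1 K^-1); ``T_a`` is arterial temperature (degC).  The
    perfusion term of the bioheat equation is
    ``omega_b * rho_b * c_b * (T_a - T)``.
    """

    classes: dict[int, ClassProperties]
    rho_b: float = 1060.0
    c_b: float = 3770.0
    T_a: float = 37.0

    def __post_init__(self):
        if not (30.0 < self.T_a < 45.0):
            raise PhantomError(f"arterial temperature {self.T_a} degC implausible")

    def for_label(self, label: int) -> ClassProperties:
        return self.classes[label]

    def override(self, label: int, **kwargs) -> "TissueProperties":
        """Return a copy with one class's properties partially replaced."""
        classes = dict(self.classes)
        classes[label] = replace(classes[label], **kwargs)
        return replace(self, classes=classes)


def default_tissue_properties() -> TissueProperties:
    """Package default property table (breast bioheat literature values).

    The tumor class carries the same background conductivity and perfusion
    as gland; its thermal contrast comes from the size-dependent volumetric
    heat source (see :func:`thermoscreen.bioheat.tumor_heat_generation`),
    which is applied on top of ``q_m``.
    """
    return TissueProperties(
        classes={
            FAT: ClassProperties(k=0.21, omega_b=0.00022, q_m=400.0),
            GLAND: ClassProperties(k=0.48, omega_b=0.00054, q_m=700.0),
            TUMOR: ClassProperties(k=0.48, omega_b=0.00054, q_m=700.0),
            SKIN: ClassProperties(k=0.37, omega_b=0.00020, q_m=368.0),
        }
    )


@dataclass(frozen=True)
class AmbientConditions:
    """Room and boundary-condition parameters.

    Skin loses heat by convection (coefficient ``h``) and thermal
    radiation (emissivity ``epsilon``, Stefan-Boltzmann constant
    ``sigma_SB``); the chest wall is held at the core temperature.
    """

    T_inf: float = 21.0  # degC
    h: float = 5.0  # W m^-2 K^-1
    epsilon: float = 0.98
    sigma_SB: float = 5.670374419e-8  # W m^-2 K^-4
    T_core: float = 37.0  # degC

    def __post_init__(self):
        if not (0.0 <= self.epsilon <= 1.0):
            raise PhantomError(f"emissivity {self.epsilon} outside [0, 1]")
        if self.h < 0:
            raise PhantomError("convective coefficient must be >= 0")
        if not self.T_inf < self.T_core:
            raise PhantomError("ambient must be cooler than core")


@dataclass
class BreastPhantom:
    """Labeled voxel grid of a hemispherical breast on a chest wall."""

    label_grid: np.ndarray  # 3D int8, labels above
    voxel_size: float  # m, cubic voxels
    origin: np.ndarray  # world coordinate of the grid corner (m)
    breast_radius: float  # hemisphere radius (m)

    def __post_init__(self):
        self.label_grid = np.asarray(self.label_grid, dtype=np.int8)
        self.origin = np.asarray(self.origin, dtype=float)
        if not self.voxel_size > 0:
            raise PhantomError("voxel_size must be > 0")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.label_grid.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def center_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (nx,1,1), (1,ny,1), (1,1,nz) center coordinates."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    @property
    def breast_mask(self) -> np.ndarray:
        return np.isin(self.label_grid, BREAST_LABELS)

    def world_to_index(self, point) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point, float) - self.origin) / self.voxel_size)
        return tuple(int(i) for i in idx)

    def label_at(self, point) -> int:
        """Tissue label at a world point; AIR if outside the grid."""
        i, j, k = self.world_to_index(point)
        if not all(0 <= v < n for v, n in zip((i, j, k), self.shape)):
            return AIR
        return int(self.label_grid[i, j, k])

    def breast_centroid(self) -> np.ndarray:
        idx = np.argwhere(self.breast_mask)
        if idx.size == 0:
            raise PhantomError("phantom contains no breast voxels")
        return self.origin + (idx.mean(axis=0) + 0.5) * self.voxel_size

    def copy(self) -> "BreastPhantom":
        return BreastPhantom(
            self.label_grid.copy(), self.voxel_size, self.origin.copy(), self.breast_radius
        )

    def mirrored(self) -> "BreastPhantom":
        """Mirror across the mid-sagittal plane x = 0."""
        out = self.copy()
        out.label_grid = out.label_grid[::-1].copy()
        # grid is symmetric about x = 0 by construction, origin unchanged
        return out


def build_hemisphere_phantom(
    breast_radius: float,
    voxel_size: float,
    gland_fraction: float = 0.5,
    skin_thickness: float = 0.0,
) -> BreastPhantom:
    """Build a hemispherical breast phantom on a chest-wall base.

    The breast occupies ``x^2 + y^2 + z^2 <= r^2`` with ``z > 0``; an inner
    concentric hemisphere of relative radius ``gland_fraction`` is labeled
    gland, the remainder fat.  With ``skin_thickness > 0`` the outermost
    shell (within that distance of the curved surface) is labeled skin.
    The grid is laterally centered (odd-sized in x and y) so mirroring
    across ``x = 0`` maps voxel centers onto voxel centers, and padded with
    air so the hemisphere never touches a lateral grid face.

    Deterministic for fixed arguments.
    """
    if not (breast_radius > 0 and voxel_size > 0):
        raise PhantomError("radius and voxel_size must be > 0")
    if breast_radius < 5 * voxel_size:
        raise PhantomError("breast_radius must be at least 5 voxels")
    if not (0.0 <= gland_fraction <= 1.0):
        raise PhantomError(f"gland_fraction {gland_fraction} outside [0, 1]")

    half = int(np.ceil(breast_radius / voxel_size)) + 2
    nx = ny = 2 * half + 1
    nz = 1 + int(np.ceil(breast_radius / voxel_size)) + 2  # chest layer + dome + air
    if nx * ny * nz > MAX_VOXELS:
        raise PhantomError(f"grid {nx}x{ny}x{nz} exceeds voxel budget {MAX_VOXELS}")

    # origin so that voxel centers are at ((i - half) +- 0.5 symmetric) and the
    # chest layer (k = 0) sits just below the z = 0 interface plane
    origin = np.array(
        [-(half + 0.5) * voxel_size, -(half + 0.5) * voxel_size, -voxel_size]
    )
    grid = np.zeros((nx, ny, nz), dtype=np.int8)
    ph = BreastPhantom(grid, voxel_size, origin, breast_radius)
    x, y, z = ph.center_grids()
    r2 = x * x + y * y + z * z
    inside = (r2 <= breast_radius**2) & (z > 0)

    grid[inside] = FAT
    if gland_fraction > 0:
        grid[inside & (r2 <= (gland_fraction * breast_radius) ** 2)] = GLAND
    if skin_thickness > 0:
        shell = inside & (r2 > (breast_radius - skin_thickness) ** 2)
        grid[shell] = SKIN
    grid[:, :, 0] = CHEST
    ph.label_grid = grid
    return ph


def embed_tumor(phantom: BreastPhantom, tumor: TumorParams) -> BreastPhantom:
    """Return a copy of ``phantom`` with breast voxels inside the tumor
    sphere relabeled ``TUMOR``.

    A voxel is captured when its center lies within ``diameter / 2`` of the
    tumor center and it is currently breast tissue.  Raises
    :class:`TumorPlacementError` when no voxel is captured (sphere outside
    the breast, or diameter below the grid resolution) — this signal is what
    the detection rule consumes to call a tumor "absent".
    """
    out = phantom.copy()
    x, y, z = out.center_grids()
    cx, cy, cz = tumor.center
    d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    captured = (d2 <= tumor.radius**2) & np.isin(out.label_grid, (FAT, GLAND, SKIN))
    already = (d2 <= tumor.radius**2) & (out.label_grid == TUMOR)
    if not captured.any() and not already.any():
        raise TumorPlacementError(
            f"tumor sphere (center {tumor.center}, D={tumor.diameter}) captures "
            "no breast voxel"
        )
    out.label_grid[captured] = TUMOR
    return out


# -- I/O -------------------------------------------------------------------


def save_phantom(phantom: BreastPhantom, path) -> None:
    """Write the label grid as NIfTI; voxel size and origin go in the affine."""
    affine = np.diag([phantom.voxel_size] * 3 + [1.0])
    affine[:3, 3] = phantom.origin + 0.5 * phantom.voxel_size
    img = nib.Nifti1Image(phantom.label_grid.astype(np.int16), affine)
    img.header["descrip"] = f"breast_radius={phantom.breast_radius:.6g}".encode()
    nib.save(img, str(path))


def load_phantom(path) -> BreastPhantom:
    img = nib.load(str(path))
    affine = img.affine
    voxel = float(affine[0, 0])
    origin = affine[:3, 3] - 0.5 * voxel
    descrip = img.header["descrip"].tobytes().decode(errors="ignore").strip("\x00")
    radius = 0.0
    for part in descrip.split(","):
        if part.startswith("breast_radius="):
            radius = float(part.split("=")[1])
    return BreastPhantom(
        np.asarray(img.dataobj).astype(np.int8), voxel, origin, radius
    )


def properties_to_yaml(props: TissueProperties, ambient: AmbientConditions, path) -> None:
    doc = {
        "tissue": {
            str(lbl): {"k": c.k, "omega_b": c.omega_b, "q_m": c.q_m}
            for lbl, c in props.classes.items()
        },
        "blood": {"rho_b": props.rho_b, "c_b": props.c_b, "T_a": props.T_a},
        "ambient": {
            "T_inf": ambient.T_inf,
            "h": ambient.h,
            "epsilon": ambient.epsilon,
            "T_core": ambient.T_core,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def properties_from_yaml(path) -> tuple[TissueProperties, AmbientConditions]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    classes = {
        int(lbl): ClassProperties(**vals) for lbl, vals in doc["tissue"].items()
    }
    props = TissueProperties(classes=classes, **doc["blood"])
    ambient = AmbientConditions(**doc["ambient"])
    return props, ambient
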