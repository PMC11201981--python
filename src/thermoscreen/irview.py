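"""Surface temperature extraction, multi-view IR rendering, camera noise.

The skin surface of a voxel phantom is the set of breast-voxel faces
adjacent to air; each face contributes one node carrying the adjacent
cell temperature.  Eight orthographic views at 45-degree azimuth steps
around the pendant breast emulate a multi-view infrared acquisition; a
small downward camera elevation keeps the nipple cap visible.  Camera
noise is additive i.i.d. Gaussian with standard deviation equal to the
camera's thermal sensitivity (NETD).

The inverse problem fits in node space: on synthetic phantoms the
simulated and "observed" surfaces share the same node set by
construction, so the rendered views are a faithful presentation and
noise layer, not the fitting domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .bioheat import TemperatureField
from .phantom import AIR, BREAST_LABELS, BreastPhantom

__all__ = [
    "SurfaceMap",
    "IRViewSet",
    "NoiseModel",
    "extract_surface",
    "render_views",
    "add_camera_noise",
    "surface_residual",
    "save_surface_csv",
    "load_surface_csv",
    "save_views",
]

_FACE_NORMALS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
)


@dataclass
class SurfaceMap:
    """Skin-surface nodes: positions (m), outward unit normals, temperatures (degC)."""

    positions: np.ndarray  # (N, 3)
    normals: np.ndarray  # (N, 3)
    T: np.ndarray  # (N,)
    cell_rows: np.ndarray  # flat grid index of the adjacent cell, for provenance
    provenance: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.T.size

    def with_temperatures(self, T: np.ndarray, **prov) -> "SurfaceMap":
        return SurfaceMap(
            self.positions, self.normals, np.asarray(T, float),
            self.cell_rows, {**self.provenance, **prov},
        )


@dataclass
class IRViewSet:
    """Rendered multi-view IR images (degC; NaN background)."""

    images: list  # of 2D arrays, v (rows) x u (cols)
    node_maps: list  # per-view int arrays, winning node index or -1
    azimuths_deg: np.ndarray
    pixel_pitch: float
    elevation_deg: float

    @property
    def n_views(self) -> int:
        return len(self.images)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian camera noise: sd ``sigma_cam`` (degC), seeded."""

    sigma_cam: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.sigma_cam < 0:
            raise ValueError("sigma_cam must be >= 0")


def surface_indices(phantom: BreastPhantom):
    """Deterministic enumeration of breast faces adjacent to air.

    Returns (cell index array (N,3), normal direction index (N,)) ordered
    by direction then grid index.  Chest-wall base faces adjoin chest
    voxels, not air, and are therefore excluded by construction.
    """
    lab = phantom.label_grid
    breast = phantom.breast_mask
    cells, dirs = [], []
    for d, nvec in enumerate(_FACE_NORMALS):
        ax = d // 2
        shifted = np.full(lab.shape, AIR, dtype=lab.dtype)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if d % 2 == 0:  # +axis neighbor
            dst[ax], src[ax] = slice(None, -1), slice(1, None)
        else:
            dst[ax], src[ax] = slice(1, None), slice(None, -1)
        shifted[tuple(dst)] = lab[tuple(src)]
        m = breast & (shifted == AIR)
        ijk = np.argwhere(m)
        cells.append(ijk)
        dirs.append(np.full(len(ijk), d, dtype=np.int8))
    return np.concatenate(cells), np.concatenate(dirs)


def extract_surface(phantom: BreastPhantom, fld: TemperatureField) -> SurfaceMap:
    """Build the skin :class:`SurfaceMap` from a solved temperature field."""
    if fld.phantom.shape != phantom.shape or fld.phantom.voxel_size != phantom.voxel_size:
        raise ValueError("temperature field was not solved on this phantom")
    cells, dirs = surface_indices(phantom)
    dx = phantom.voxel_size
    centers = phantom.origin + (cells + 0.5) * dx
    normals = _FACE_NORMALS[dirs]
    positions = centers + 0.5 * dx * normals
    T = fld.T_grid[cells[:, 0], cells[:, 1], cells[:, 2]]
    if np.isnan(T).any():
        raise ValueError("temperature undefined on some surface cells")
    rows = np.ravel_multi_index((cells[:, 0], cells[:, 1], cells[:, 2]), phantom.shape)
    return SurfaceMap(positions, normals, T.astype(float), rows, {"phantom": "inline"})


def render_views(
    surface: SurfaceMap,
    n_views: int = 8,
    pixel_pitch: float | None = None,
    elevation_deg: float = 20.0,
) -> IRViewSet:
    """Orthographic nearest-node rendering of the surface at ``n_views``
    equally spaced azimuths.

    View rays point from the camera toward the breast axis, tilted
    ``elevation_deg`` toward the chest wall so the dome cap is seen.
    Front-facing nodes (``normal . ray <= 0``) compete per pixel; the node
    closest to the camera wins (z-buffer).  Each pixel stores the winning
    node's temperature unmodified, so view-averaging a node's pixels
    returns its temperature exactly.
    """
    if surface.n_nodes == 0:
        raise ValueError("empty surface map")
    if pixel_pitch is None:
        # node spacing: voxel size inferred from position lattice
        pixel_pitch = float(
            np.min(np.diff(np.unique(np.round(surface.positions[:, 2], 12)))) or 1e-3
        )
    e = np.deg2rad(elevation_deg)
    azimuths = np.arange(n_views) * (360.0 / n_views)
    images, node_maps = [], []
    P = surface.positions
    for az in np.deg2rad(azimuths):
        ray = np.array(
            [-np.cos(e) * np.cos(az), -np.cos(e) * np.sin(az), -np.sin(e)]
        )
        u_axis = np.array([-np.sin(az), np.cos(az), 0.0])
        v_axis = np.cross(u_axis, ray)
        front = (surface.normals @ ray) <= 1e-12
        idx = np.flatnonzero(front)
        u = P[idx] @ u_axis
        v = P[idx] @ v_axis
        depth = P[idx] @ ray
        iu = np.floor((u - u.min()) / pixel_pitch).astype(int)
        iv = np.floor((v - v.min()) / pixel_pitch).astype(int)
        img = np.full((iv.max() + 1, iu.max() + 1), np.nan)
        nmap = np.full(img.shape, -1, dtype=np.int64)
        order = np.argsort(depth)[::-1]  # nearest (smallest depth) painted last
        img[iv[order], iu[order]] = surface.T[idx[order]]
        nmap[iv[order], iu[order]] = idx[order]
        images.append(img)
        node_maps.append(nmap)
    return IRViewSet(images, node_maps, azimuths, float(pixel_pitch), elevation_deg)


def add_camera_noise(obj, model: NoiseModel):
    """Add i.i.d. Gaussian camera noise; reproducible from ``model.seed``."""
    rng = np.random.default_rng(model.seed)
    if isinstance(obj, SurfaceMap):
        noise = rng.normal(0.0, model.sigma_cam, obj.n_nodes) if model.sigma_cam else 0.0
        return obj.with_temperatures(obj.T + noise, noise_sigma=model.sigma_cam, noise_seed=model.seed)
    if isinstance(obj, IRViewSet):
        images = []
        for img in obj.images:
            if model.sigma_cam:
                img = img + rng.normal(0.0, model.sigma_cam, img.shape)
            else:
                img = img.copy()
            images.append(img)
        return replace(obj, images=images)
    raise TypeError(f"cannot add camera noise to {type(obj).__name__}")


def surface_residual(sim: SurfaceMap, obs: SurfaceMap):
    """Node-wise residual ``T_sim - T_obs`` and its RMS (degC).

    The two maps must share the same node set (guaranteed by construction
    on synthetic phantoms)."""
    if sim.n_nodes != obs.n_nodes or not np.allclose(sim.positions, obs.positions):
        raise ValueError("surface maps are defined on different node sets")
    r = sim.T - obs.T
    return r, float(np.sqrt(np.mean(r**2)))


# -- I/O -------------------------------------------------------------------


def save_surface_csv(surface: SurfaceMap, path) -> None:
    data = np.column_stack([surface.positions, surface.normals, surface.T])
    np.savetxt(
        path, data, delimiter=",", header="x,y,z,nx,ny,nz,T", comments="", fmt="%.9g"
    )


def load_surface_csv(path) -> SurfaceMap:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return SurfaceMap(
        positions=data[:, 0:3],
        normals=data[:, 3:6],
        T=data[:, 6],
        cell_rows=np.arange(len(data)),
        provenance={"source": str(path)},
    )


def save_views(views: IRViewSet, outdir) -> None:
    """Write each view as 16-bit PNG with a JSON sidecar giving the degC
    scale, plus a raw CSV."""
    import imageio.v3 as iio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (img, az) in enumerate(zip(views.images, views.azimuths_deg)):
        finite = np.isfinite(img)
        lo = float(np.nanmin(img)) if finite.any() else 0.0
        hi = float(np.nanmax(img)) if finite.any() else 1.0
        span = hi - lo if hi > lo else 1.0
        scaled = np.zeros(img.shape, dtype=np.uint16)
        scaled[finite] = ((img[finite] - lo) / span * 65534 + 1).astype(np.uint16)
        iio.imwrite(outdir / f"view_{i}.png", scaled)
        with open(outdir / f"view_{i}.json", "w") as fh:
            json.dump(
                {
                    "azimuth_deg": float(az),
                    "elevation_deg": views.elevation_deg,
                    "pixel_pitch_m": views.pixel_pitch,
                    "T_min_C": lo,
                    "T_max_C": hi,
                    "background_value": 0,
                },
                fh,
                indent=1,
            )
        np.savetxt(outdir / f"view_{i}.csv", img, delimiter=",", fmt="%.6g")
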