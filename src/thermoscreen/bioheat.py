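"""Steady-state Pennes bioheat solver on voxel phantoms.

The temperature field obeys

    div(k grad T) + omega_b rho_b c_b (T_a - T) + q_m + q_t = 0

with a convective + radiative (Stefan-Boltzmann, linearized) boundary on
the skin, the chest wall held at core temperature, and a tumor source
``q_t`` that depends on tumor diameter through an empirical
growth-rate relation.

Discretization is a cell-centered finite volume scheme on the phantom's
voxel grid: 6-neighbor stencil, harmonic-mean face conductivities, the
chest-wall temperature imposed at the chest/breast interface faces, and
half-cell series resistance to the skin film.  The scheme is conservative,
so the discrete energy balance (total boundary flux = total volumetric
source) holds to solver precision; :func:`energy_balance` checks it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import (
    AIR,
    BREAST_LABELS,
    CHEST,
    TUMOR,
    AmbientConditions,
    BreastPhantom,
    TissueProperties,
    TumorParams,
)

__all__ = [
    "tumor_heat_generation",
    "min_active_diameter",
    "tumor_occupancy",
    "assemble_system",
    "solve_bioheat",
    "energy_balance",
    "slab_oracle",
    "build_slab_phantom",
    "DiscreteSystem",
    "TemperatureField",
    "HeatSourceDomainError",
    "ConvergenceError",
]


class HeatSourceDomainError(ValueError):
    """Tumor diameter outside the domain of the heat-generation relation."""


class ConvergenceError(RuntimeError):
    """Linear solver failed to reach the requested residual."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        self.tol = tol
        super().__init__(f"solver residual {residual:.3e} above tolerance {tol:.3e}")


# -- tumor heat source -----------------------------------------------------

#: defaults of the adopted size-dependent source relation
#: q_t(D) = C1 / (C2 * ln(100 D) + C3), D in meters, q_t in W m^-3.
#: The denominator is the tumor volume-doubling time in days as an
#: empirical function of diameter; C1 is the metabolic-heat/doubling-time
#: product.  Faster-growing (smaller) tumors run hotter per unit volume.
Q_C1 = 3.27e6
Q_C2 = 468.5
Q_C3 = 50.0


def min_active_diameter(C2: float = Q_C2, C3: float = Q_C3) -> float:
    """Smallest diameter (m) for which the source relation is defined
    (positive doubling time)."""
    return math.exp(-C3 / C2) / 100.0


def power_stationary_diameter(C2: float = Q_C2, C3: float = Q_C3) -> float:
    """Diameter (m) at which total tumor power ``q_t(D) (pi/6) D^3`` is
    stationary (~12.5 mm under defaults).

    Below it, smaller tumors emit *more* total heat (their doubling-time
    denominator collapses faster than the volume shrinks); above it, power
    grows with volume.  Two diameters on opposite sides can therefore
    produce nearly identical surface signatures for a deep tumor — the
    size ambiguity the inverse solver's branch restart probes.
    """
    return math.exp(1.0 / 3.0 - C3 / C2) / 100.0


def tumor_heat_generation(
    diameter: float, C1: float = Q_C1, C2: float = Q_C2, C3: float = Q_C3
) -> float:
    """Volumetric heat generation rate (W m^-3) of a tumor of given
    diameter (m).

    Strictly decreasing in diameter over the relation's domain.  Raises
    :class:`HeatSourceDomainError` where the doubling-time denominator is
    non-positive (diameter <= ~9 mm under defaults).  ``C1 = 0`` turns the
    source off for every diameter.
    """
    if not diameter > 0:
        raise HeatSourceDomainError(f"diameter must be > 0, got {diameter}")
    if C1 == 0.0:
        return 0.0
    denom = C2 * math.log(100.0 * diameter) + C3
    if denom <= 0.0:
        raise HeatSourceDomainError(
            f"doubling-time denominator non-positive at D={diameter:.4g} m "
            f"(valid for D > {min_active_diameter(C2, C3):.4g} m)"
        )
    return C1 / denom


def tumor_occupancy(phantom: BreastPhantom, tumor: TumorParams) -> np.ndarray:
    """Fractional occupancy of the tumor sphere per voxel, restricted to
    breast tissue.

    Uses a half-voxel linear ramp across the sphere surface
    (``clip(0.5 + (R - dist)/voxel, 0, 1)``), which makes the voxelized
    source — and hence the forward surface-temperature map — continuous in
    the tumor center and diameter.  That continuity is what lets a
    derivative-based inverse solver move the source by sub-voxel steps.
    """
    x, y, z = phantom.center_grids()
    cx, cy, cz = tumor.center
    dist = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
    frac = np.clip(0.5 + (tumor.radius - dist) / phantom.voxel_size, 0.0, 1.0)
    frac[~phantom.breast_mask] = 0.0
    return frac


# -- discrete system -------------------------------------------------------


@dataclass
class TemperatureField:
    """Steady-state solution on the phantom grid.

    ``T_grid`` holds temperatures in degC: NaN outside the body, the core
    temperature on chest-wall voxels.
    """

    T_grid: np.ndarray
    phantom: BreastPhantom
    vector: np.ndarray  # unknowns only, system row order
    info: dict


@dataclass
class DiscreteSystem:
    """Assembled sparse linear system ``A T = b`` (one row per breast voxel)."""

    A: sp.csr_matrix
    b: np.ndarray
    idx_grid: np.ndarray  # 3D int32, row index per voxel, -1 elsewhere
    rows_ijk: np.ndarray  # (N, 3) grid index of each row
    phantom: BreastPhantom
    props: TissueProperties
    ambient: AmbientConditions
    h_eff: float
    skin_rows: np.ndarray  # rows with a skin face
    skin_coeff: np.ndarray  # W/K per skin face
    chest_rows: np.ndarray
    chest_coeff: np.ndarray
    perf_coeff: np.ndarray  # omega rho c V per row, W/K
    source: np.ndarray  # (q_m + q_t) V per row, W

    @property
    def n(self) -> int:
        return self.b.size


def radiative_coefficient(ambient: AmbientConditions, T_lin: float = 33.0) -> float:
    """Linearized radiation film coefficient about a skin reference
    temperature (degC): ``eps sigma (Tr^2 + Too^2)(Tr + Too)`` in Kelvin."""
    Tr = T_lin + 273.15
    Too = ambient.T_inf + 273.15
    return ambient.epsilon * ambient.sigma_SB * (Tr**2 + Too**2) * (Tr + Too)


def assemble_system(
    phantom: BreastPhantom,
    props: TissueProperties,
    ambient: AmbientConditions,
    tumor: TumorParams | None = None,
    *,
    radiative: bool = True,
    T_lin: float = 33.0,
) -> DiscreteSystem:
    """Assemble the finite-volume system for one phantom.

    If ``tumor`` is given and the phantom carries tumor-labeled voxels, the
    source ``q_t(D)`` is applied uniformly over those voxels; if the
    phantom has no tumor labels, the source is distributed by fractional
    sphere occupancy (:func:`tumor_occupancy`).  Grid-boundary faces are
    insulated, which the hemisphere never exposes laterally but slab
    configurations use to realize one-dimensional conduction.
    """
    lab = phantom.label_grid
    unk = phantom.breast_mask
    n = int(unk.sum())
    if n == 0:
        raise ValueError("phantom has no breast voxels")

    dx = phantom.voxel_size
    area, vol = dx * dx, dx**3

    idx_grid = np.full(lab.shape, -1, dtype=np.int32)
    rows_ijk = np.argwhere(unk)
    idx_grid[unk] = np.arange(n, dtype=np.int32)

    kc = np.zeros(lab.shape)
    pc = np.zeros(lab.shape)  # omega rho c
    qm = np.zeros(lab.shape)
    for lbl in BREAST_LABELS:
        m = lab == lbl
        if not m.any():
            continue
        cp = props.for_label(lbl)
        kc[m] = cp.k
        pc[m] = cp.omega_b * props.rho_b * props.c_b
        qm[m] = cp.q_m

    h_eff = ambient.h + (radiative_coefficient(ambient, T_lin) if radiative else 0.0)

    diag = pc[unk] * vol
    b = pc[unk] * vol * props.T_a + qm[unk] * vol
    coo_i: list[np.ndarray] = []
    coo_j: list[np.ndarray] = []
    coo_v: list[np.ndarray] = []
    skin_rows, skin_coeff = [], []
    chest_rows, chest_coeff = [], []

    def lo(a):  # slices for neighbor pairs along axis a
        s = [slice(None)] * 3
        s[a] = slice(None, -1)
        return tuple(s)

    def hi(a):
        s = [slice(None)] * 3
        s[a] = slice(1, None)
        return tuple(s)

    for a in range(3):
        il, ih = idx_grid[lo(a)], idx_grid[hi(a)]
        ll, lh = lab[lo(a)], lab[hi(a)]
        kl, kh = kc[lo(a)], kc[hi(a)]
        ul, uh = il >= 0, ih >= 0

        # interior faces between two breast cells: harmonic-mean conductance
        m = ul & uh
        if m.any():
            g = dx * 2.0 * kl[m] * kh[m] / (kl[m] + kh[m])
            i, j = il[m], ih[m]
            np.add.at(diag, i, g)
            np.add.at(diag, j, g)
            coo_i += [i, j]
            coo_j += [j, i]
            coo_v += [-g, -g]

        # breast/chest faces: temperature pinned at the interface face
        for mi, ki, rows in (((ul & (lh == CHEST)), kl, il), ((uh & (ll == CHEST)), kh, ih)):
            if mi.any():
                g = 2.0 * ki[mi] * dx
                r = rows[mi]
                np.add.at(diag, r, g)
                np.add.at(b, r, g * ambient.T_core)
                chest_rows.append(r)
                chest_coeff.append(g)

        # breast/air faces: convective + linearized radiative film with
        # half-cell conduction in series
        for mi, ki, rows in (((ul & (lh == AIR)), kl, il), ((uh & (ll == AIR)), kh, ih)):
            if mi.any() and h_eff > 0:
                u = area / (dx / (2.0 * ki[mi]) + 1.0 / h_eff)
                r = rows[mi]
                np.add.at(diag, r, u)
                np.add.at(b, r, u * ambient.T_inf)
                skin_rows.append(r)
                skin_coeff.append(u)

    source = qm[unk] * vol
    if tumor is not None:
        if (lab == TUMOR).any():
            qt = tumor_heat_generation(tumor.diameter)
            rows = idx_grid[lab == TUMOR]
            b[rows] += qt * vol
            source[rows] += qt * vol
        else:
            qt = tumor_heat_generation(tumor.diameter)
            frac = tumor_occupancy(phantom, tumor)
            add = qt * vol * frac[unk]
            b += add
            source += add

    i = np.concatenate(coo_i) if coo_i else np.empty(0, np.int32)
    j = np.concatenate(coo_j) if coo_j else np.empty(0, np.int32)
    v = np.concatenate(coo_v) if coo_v else np.empty(0)
    A = sp.coo_matrix(
        (np.concatenate([v, diag]), (np.concatenate([i, np.arange(n)]), np.concatenate([j, np.arange(n)]))),
        shape=(n, n),
    ).tocsr()

    cat = lambda parts: np.concatenate(parts) if parts else np.empty(0)
    return DiscreteSystem(
        A=A,
        b=b,
        idx_grid=idx_grid,
        rows_ijk=rows_ijk,
        phantom=phantom,
        props=props,
        ambient=ambient,
        h_eff=h_eff,
        skin_rows=cat(skin_rows).astype(np.int64) if skin_rows else np.empty(0, np.int64),
        skin_coeff=cat(skin_coeff),
        chest_rows=cat(chest_rows).astype(np.int64) if chest_rows else np.empty(0, np.int64),
        chest_coeff=cat(chest_coeff),
        perf_coeff=pc[unk] * vol,
        source=source,
    )


def solve_bioheat(
    system: DiscreteSystem,
    *,
    rtol: float = 1e-9,
    b: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    method: str = "auto",
    maxiter: int = 20000,
) -> TemperatureField:
    """Solve the assembled system.

    Default path is conjugate gradients with a Jacobi (diagonal)
    preconditioner — the operator is symmetric positive definite — with an
    optional warm start ``x0``; small systems go through a sparse direct
    solve.  Raises :class:`ConvergenceError` if the requested relative
    residual is not reached.
    """
    rhs = system.b if b is None else b
    n = system.n
    if method == "auto":
        method = "direct" if n < 3000 else "cg"

    if method == "direct":
        x = spla.spsolve(system.A.tocsc(), rhs)
        iters = 1
    elif method == "cg":
        d = system.A.diagonal()
        M = spla.LinearOperator((n, n), lambda v: v / d)
        count = [0]
        x, info = spla.cg(
            system.A,
            rhs,
            x0=x0,
            rtol=rtol,
            atol=0.0,
            M=M,
            maxiter=maxiter,
            callback=lambda _: count.__setitem__(0, count[0] + 1),
        )
        iters = count[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    res = float(np.linalg.norm(system.A @ x - rhs) / np.linalg.norm(rhs))
    if res > max(rtol * 10, 1e-12) and method != "direct":
        raise ConvergenceError(res, rtol)

    T_grid = np.full(system.phantom.shape, np.nan)
    T_grid[system.phantom.label_grid == CHEST] = system.ambient.T_core
    T_grid[system.phantom.breast_mask] = x
    return TemperatureField(
        T_grid=T_grid,
        phantom=system.phantom,
        vector=x,
        info={"method": method, "iterations": iters, "residual": res},
    )


def energy_balance(system: DiscreteSystem, fld: TemperatureField) -> dict:
    """Discrete energy balance at the solution.

    Total volumetric source (metabolic + tumor + net perfusion) must equal
    the total flux leaving through skin and chest-wall faces; the scheme is
    conservative so the relative imbalance is at solver precision.
    """
    x = fld.vector
    source = float(
        system.source.sum() + (system.perf_coeff * (system.props.T_a - x)).sum()
    )
    skin = float((system.skin_coeff * (x[system.skin_rows] - system.ambient.T_inf)).sum())
    chest = float(
        (system.chest_coeff * (x[system.chest_rows] - system.ambient.T_core)).sum()
    )
    out = skin + chest
    denom = max(abs(source), 1e-30)
    return {
        "total_source_W": source,
        "skin_flux_W": skin,
        "chest_flux_W": chest,
        "relative_imbalance": abs(source - out) / denom,
    }


# -- analytic slab oracle --------------------------------------------------


def build_slab_phantom(
    thickness: float,
    voxel_size: float,
    *,
    label: int = 2,
    nx: int = 1,
    ny: int = 1,
) -> BreastPhantom:
    """Homogeneous tissue slab: chest wall at ``z = 0``, skin film at
    ``z = thickness``, laterally insulated (grid-boundary faces carry no
    flux), realizing 1-D conduction for the analytic oracle."""
    nz = int(round(thickness / voxel_size))
    if abs(nz * voxel_size - thickness) > 1e-9:
        raise ValueError("thickness must be a whole number of voxels")
    grid = np.zeros((nx, ny, nz + 2), dtype=np.int8)
    grid[:, :, 1 : nz + 1] = label
    grid[:, :, 0] = CHEST
    origin = np.array([0.0, 0.0, -voxel_size])
    return BreastPhantom(grid, voxel_size, origin, breast_radius=thickness)


class SlabSolution:
    """Closed-form 1-D steady profile of the perfused slab.

    Chest side fixed at ``T_core`` at ``x = 0``; skin side at ``x = L``
    exchanging with ambient through a film coefficient ``h`` (radiation
    off).  With perfusion ``P = omega_b rho_b c_b > 0`` and total source
    ``Q = q_m + q``:

        T(x) = T_p + A e^{m x} + B e^{-m x},  T_p = T_a + Q/P,  m = sqrt(P/k)

    and for ``P = 0`` the pure-conduction quadratic profile.
    """

    def __init__(self, thickness, props: TissueProperties, ambient: AmbientConditions, q=0.0, label=2):
        cp = props.for_label(label)
        self.L = float(thickness)
        self.k = cp.k
        self.h = ambient.h
        self.T0 = ambient.T_core
        self.T_inf = ambient.T_inf
        self.P = cp.omega_b * props.rho_b * props.c_b
        self.Q = cp.q_m + q
        self.T_a = props.T_a
        k, h, L, Q = self.k, self.h, self.L, self.Q
        if self.P > 0:
            m = math.sqrt(self.P / k)
            Tp = self.T_a + Q / self.P
            ep, en = math.exp(m * L), math.exp(-m * L)
            # A + B = T0 - Tp ;  -k m (A ep - B en) = h (Tp + A ep + B en - T_inf)
            M = np.array(
                [[1.0, 1.0], [-k * m * ep - h * ep, k * m * en - h * en]]
            )
            rhs = np.array([self.T0 - Tp, h * (Tp - self.T_inf)])
            A, B = np.linalg.solve(M, rhs)
            self.m, self.Tp, self.A, self.B = m, Tp, A, B
        else:
            C = -Q * L**2 / (2 * k) + self.T0 - self.T_inf
            a = (Q * L - h * C) / (k + h * L)
            self.a = a

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.P > 0:
            return self.Tp + self.A * np.exp(self.m * x) + self.B * np.exp(-self.m * x)
        return self.T0 + self.a * x - self.Q * x**2 / (2 * self.k)

    def ode_residual(self, x):
        """k T'' + P (T_a - T) + Q, evaluated analytically (zero up to
        round-off for a correct solution)."""
        x = np.asarray(x, dtype=float)
        if self.P > 0:
            T = self(x)
            Tpp = self.m**2 * (self.A * np.exp(self.m * x) + self.B * np.exp(-self.m * x))
            return self.k * Tpp + self.P * (self.T_a - T) + self.Q
        return np.full_like(x, self.k * (-self.Q / self.k) + self.Q)


def slab_oracle(
    thickness: float,
    props: TissueProperties,
    ambient: AmbientConditions,
    q: float = 0.0,
    label: int = 2,
) -> SlabSolution:
    """Closed-form 1-D slab profile used as an independent check of the
    finite-volume solver (see :class:`SlabSolution`)."""
    return SlabSolution(thickness, props, ambient, q=q, label=label)
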