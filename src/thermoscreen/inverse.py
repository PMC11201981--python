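"""Levenberg-Marquardt inverse estimation of tumor presence, size and location.

The inverse problem fits the four-vector theta = (x_c, y_c, z_c, D) — tumor
center and diameter — by minimizing the node-wise misfit between simulated
and observed skin-surface temperatures.  The tumor enters the forward model
purely as a volumetric heat source whose magnitude is coupled to the
diameter through the growth-rate relation, so size and strength are a
single degree of freedom.

Absence is a *mechanism*, not a special case: the center coordinates are
unconstrained, so when the data carry no tumor signature the optimizer is
free to park the source where it cannot influence the surface — outside
the breast, at the chest wall, or at a thermally silent size.  The
classifier turns the fitted parameters plus the achieved misfit reduction
into a present/absent call.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .bioheat import (
    HeatSourceDomainError,
    assemble_system,
    min_active_diameter,
    power_stationary_diameter,
    solve_bioheat,
    tumor_heat_generation,
    tumor_occupancy,
)
from .irview import SurfaceMap, extract_surface, surface_residual
from .phantom import (
    AIR,
    CHEST,
    AmbientConditions,
    BreastPhantom,
    TissueProperties,
    TumorParams,
)

__all__ = [
    "InverseResult",
    "LMConfig",
    "DetectionConfig",
    "ForwardOperator",
    "initial_guess",
    "forward_model",
    "jacobian_fd",
    "levenberg_marquardt",
    "lma_fit",
    "classify_detection",
]

#: initial tumor diameter for the inverse solve (m): 1.8 cm sphere placed
#: centrally in the breast
INIT_DIAMETER = 0.018


@dataclass
class LMConfig:
    """Levenberg-Marquardt schedule and stopping rules."""

    lam0: float = 1e-2
    lam_factor: float = 3.0  # divide on accept, multiply on reject
    ftol: float = 1e-4  # relative residual-RMS change
    xtol: float = 1e-4  # step norm relative to parameter scale
    max_iter: int = 50
    max_rejects: int = 8  # consecutive rejected steps before giving up
    rho_min: float = 1e-3  # minimum gain ratio (actual/predicted reduction)
    max_step: float = 1.0  # trust region: max step norm in units of x_scale
    fd_coord_step_voxels: float = 1.0
    fd_diameter_rel_step: float = 0.10
    branch_restart: bool = True  # probe the other size branch of the
    # non-monotone power curve when the primary fit found a real source


@dataclass
class DetectionConfig:
    """Presence/absence decision thresholds (explicit package choices).

    ``chest_margin_voxels``: fitted centers within this many voxels of the
    chest-wall plane are called absent.  ``min_f_ratio``: the fitted source
    must reduce the sum of squared residuals, relative to the tumor-free
    model, by more than noise alone plausibly would — a nested-model
    F-ratio on 4 parameters.  With noiseless data any genuine improvement
    passes; with camera noise the chance level of the statistic is ~1, so
    the default keeps a wide margin on both sides.
    """

    chest_margin_voxels: float = 1.0
    min_f_ratio: float = 10.0
    n_params: int = 4


@dataclass
class InverseResult:
    """Outcome of one inverse fit."""

    theta_hat: TumorParams
    residual_rms: float
    baseline_rms: float  # tumor-free model vs the same observation
    n_nodes: int
    iterations: int
    converged: bool
    stop_reason: str
    trajectory: list  # per accepted/rejected step: dict(theta, rms, lam, accepted)
    detected: bool | None = None
    decision_reason: str | None = None
    seed: int | None = None
    config_hash: str | None = None

    def to_json(self, path=None) -> str:
        doc = {
            "theta_hat": {
                "center_m": list(self.theta_hat.center),
                "diameter_m": self.theta_hat.diameter,
            },
            "residual_rms_C": self.residual_rms,
            "baseline_rms_C": self.baseline_rms,
            "n_nodes": self.n_nodes,
            "iterations": self.iterations,
            "converged": self.converged,
            "stop_reason": self.stop_reason,
            "detected": self.detected,
            "decision_reason": self.decision_reason,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "trajectory": self.trajectory,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def initial_guess(phantom: BreastPhantom) -> TumorParams:
    """Standard initialization: 1.8 cm diameter, centered at the centroid
    of the breast tissue."""
    c = phantom.breast_centroid()
    return TumorParams(center=tuple(c), diameter=INIT_DIAMETER)


class ForwardOperator:
    """Cached forward map theta -> skin SurfaceMap for one phantom.

    The system matrix does not depend on theta (the tumor is a pure heat
    source on a fixed background), so it is assembled once; each
    evaluation rebuilds only the right-hand side from the smooth sphere
    occupancy and re-solves with a warm start from the previous solution.
    A diameter below the source relation's domain, or a sphere that does
    not overlap breast tissue, contributes nothing — the forward map then
    equals the tumor-free solve.
    """

    def __init__(
        self,
        phantom: BreastPhantom,
        props: TissueProperties,
        ambient: AmbientConditions,
        *,
        rtol: float = 1e-9,
    ):
        self.phantom = phantom
        self.props = props
        self.ambient = ambient
        self.rtol = rtol
        self.system = assemble_system(phantom, props, ambient, tumor=None)
        self.base_field = solve_bioheat(self.system, rtol=rtol)
        self.base_surface = extract_surface(phantom, self.base_field)
        # map surface nodes to system rows for fast temperature gather
        flat_idx = self.system.idx_grid.ravel()[self.base_surface.cell_rows]
        self._surf_rows = flat_idx
        self._unk = phantom.breast_mask
        self._vol = phantom.voxel_size**3
        self._x_last = self.base_field.vector.copy()
        self.n_solves = 0

    def surface(self, theta: TumorParams | None) -> SurfaceMap:
        if theta is None:
            return self.base_surface
        try:
            qt = tumor_heat_generation(theta.diameter)
        except HeatSourceDomainError:
            qt = 0.0
        if qt == 0.0:
            return self.base_surface
        frac = tumor_occupancy(self.phantom, theta)[self._unk]
        if not frac.any():
            return self.base_surface
        b = self.system.b + qt * self._vol * frac
        fld = solve_bioheat(self.system, rtol=self.rtol, b=b, x0=self._x_last)
        self._x_last = fld.vector
        self.n_solves += 1
        return self.base_surface.with_temperatures(fld.vector[self._surf_rows])

    def field(self, theta: TumorParams | None):
        """Full temperature field (used by the CLI / plotting, not the fit)."""
        if theta is None:
            return self.base_field
        try:
            qt = tumor_heat_generation(theta.diameter)
        except HeatSourceDomainError:
            qt = 0.0
        frac = tumor_occupancy(self.phantom, theta)[self._unk]
        b = self.system.b + qt * self._vol * frac
        return solve_bioheat(self.system, rtol=self.rtol, b=b, x0=self._x_last)


def forward_model(
    theta: TumorParams | None,
    phantom: BreastPhantom,
    props: TissueProperties,
    ambient: AmbientConditions,
    operator: ForwardOperator | None = None,
) -> SurfaceMap:
    """Simulate skin-surface temperatures for tumor parameters ``theta``
    (``None`` = tumor-free).  Pass an existing :class:`ForwardOperator` to
    reuse its assembled system."""
    op = operator or ForwardOperator(phantom, props, ambient)
    return op.surface(theta)


def jacobian_fd(
    theta: TumorParams,
    op: ForwardOperator,
    *,
    coord_step: float | None = None,
    diameter_rel_step: float = 0.10,
    one_sided: bool = False,
) -> np.ndarray:
    """Finite-difference sensitivity of surface temperatures to theta.

    Columns (x_c, y_c, z_c, D); central differences by default with steps
    of one voxel for the coordinates and 10% for the diameter.
    """
    dx = coord_step if coord_step is not None else op.phantom.voxel_size
    t0 = theta.as_array()
    steps = np.array([dx, dx, dx, max(diameter_rel_step * theta.diameter, 1e-5)])
    base = op.surface(theta).T
    J = np.zeros((base.size, 4))
    for p in range(4):
        tp = t0.copy()
        tp[p] += steps[p]
        Tp = op.surface(TumorParams.from_array(tp)).T
        if one_sided:
            J[:, p] = (Tp - base) / steps[p]
        else:
            tm = t0.copy()
            tm[p] -= steps[p]
            Tm = op.surface(TumorParams.from_array(tm)).T
            J[:, p] = (Tp - Tm) / (2 * steps[p])
    return J


def levenberg_marquardt(
    residual_fn,
    x0: np.ndarray,
    jacobian_fn,
    *,
    x_scale: np.ndarray,
    config: LMConfig | None = None,
):
    """Generic damped Gauss-Newton (Levenberg-Marquardt) least squares.

    ``residual_fn(x)`` returns the residual vector; ``jacobian_fn(x)`` its
    Jacobian.  Steps solve ``(J^T J + lam diag(J^T J)) delta = -J^T r``;
    a step is accepted when it lowers the residual RMS *and* its gain
    ratio (actual over linearized predicted reduction) exceeds
    ``rho_min`` — the standard trust-region safeguard that rejects long
    steps whose improvement is accidental.  Accepted steps divide ``lam``
    by the schedule factor, rejections multiply it.  The Jacobian is
    refreshed only after accepted steps.  Returns
    ``(x, trajectory, stop_reason)`` with the full step history; residual
    RMS is non-increasing along the accepted steps.
    """
    cfg = config or LMConfig()
    x = np.asarray(x0, dtype=float).copy()
    r = residual_fn(x)
    rms = float(np.sqrt(np.mean(r**2)))
    lam = cfg.lam0
    trajectory = [
        {"theta": x.tolist(), "rms": rms, "lam": lam, "accepted": True, "iteration": 0}
    ]
    if rms < 1e-12:  # already at the data: nothing to fit
        return x, trajectory, "zero_residual"
    stop = "max_iter"
    J = None
    rejects = 0
    for it in range(1, cfg.max_iter + 1):
        if J is None:
            J = jacobian_fn(x)
        JtJ = J.T @ J
        g = J.T @ r
        d = np.diag(JtJ).copy()
        d[d <= 0] = max(d.max(), 1e-300) * 1e-12  # insensitive parameter guard
        accepted = False
        for _ in range(30):
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(d), -g)
            except np.linalg.LinAlgError:
                lam *= cfg.lam_factor
                continue
            if np.linalg.norm(delta / x_scale) > cfg.max_step:
                # trust region: damp harder rather than leap beyond the
                # scale on which the linearization can be trusted
                lam *= cfg.lam_factor
                continue
            x_try = x + delta
            r_try = residual_fn(x_try)
            rms_try = float(np.sqrt(np.mean(r_try**2)))
            predicted = -(2.0 * g @ delta + delta @ JtJ @ delta)
            actual = float(r @ r - r_try @ r_try)
            rho = actual / predicted if predicted > 0 else -1.0
            if rms_try < rms and rho >= cfg.rho_min:
                accepted = True
                break
            lam *= cfg.lam_factor
            rejects += 1
            trajectory.append(
                {"theta": x_try.tolist(), "rms": rms_try, "lam": lam,
                 "accepted": False, "iteration": it}
            )
            if rejects >= cfg.max_rejects:
                break
        if not accepted:
            stop = "no_improvement"
            break
        rejects = 0
        rel_drop = (rms - rms_try) / max(rms, 1e-300)
        step_rel = float(np.linalg.norm(delta / x_scale))
        x, r, rms = x_try, r_try, rms_try
        lam = max(lam / cfg.lam_factor, 1e-12)
        J = None
        trajectory.append(
            {"theta": x.tolist(), "rms": rms, "lam": lam, "accepted": True,
             "iteration": it}
        )
        if rel_drop < cfg.ftol:
            stop = "ftol"
            break
        if step_rel < cfg.xtol:
            stop = "xtol"
            break
    return x, trajectory, stop


def improvement_f_ratio(n: int, baseline_rms: float, rms: float, p: int = 4) -> float:
    """Nested-model F-ratio of the fitted source against the tumor-free
    model: how much better than chance the source explains the surface."""
    ss0 = n * baseline_rms**2
    ss1 = n * rms**2
    if ss1 <= 0.0:
        return np.inf if ss0 > 0 else 0.0
    return ((ss0 - ss1) / p) / (ss1 / max(n - p, 1))


def quadrant_starts(phantom: BreastPhantom) -> list[TumorParams]:
    """Five starting points: the central initial guess plus one per breast
    quadrant at half the breast radius (multi-start insurance for misfit
    surfaces with local minima)."""
    c = phantom.breast_centroid()
    r = 0.5 * phantom.breast_radius
    starts = [TumorParams(center=tuple(c), diameter=INIT_DIAMETER)]
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        starts.append(
            TumorParams(
                center=(c[0] + sx * r / np.sqrt(2), c[1] + sy * r / np.sqrt(2), c[2]),
                diameter=INIT_DIAMETER,
            )
        )
    return starts


def lma_fit(
    observed: SurfaceMap,
    phantom: BreastPhantom,
    props: TissueProperties,
    ambient: AmbientConditions,
    init: TumorParams | None = None,
    *,
    config: LMConfig | None = None,
    operator: ForwardOperator | None = None,
    multi_start: bool = False,
    _allow_branch_restart: bool = True,
) -> InverseResult:
    """Fit tumor parameters to an observed skin-surface temperature map.

    The diameter is floored at a tenth of a voxel inside the forward
    wrapper, keeping the parameterization unbounded while preventing
    degenerate negative sizes.  With ``multi_start`` the fit is repeated
    from :func:`quadrant_starts` and the lowest-residual solution kept
    (off by default; the single central start is the standard protocol).
    Non-convergence is reported through ``converged``/``stop_reason``,
    never raised.
    """
    cfg = config or LMConfig()
    op = operator or ForwardOperator(phantom, props, ambient)
    if multi_start and init is None:
        results = [
            lma_fit(observed, phantom, props, ambient, init=s, config=cfg, operator=op)
            for s in quadrant_starts(phantom)
        ]
        return min(results, key=lambda r: r.residual_rms)
    theta0 = init or initial_guess(phantom)
    d_floor = 0.1 * phantom.voxel_size

    def clip(x):
        x = x.copy()
        x[3] = max(x[3], d_floor)
        return x

    def residual_fn(x):
        r, _ = surface_residual(op.surface(TumorParams.from_array(clip(x))), observed)
        return r

    def jacobian_fn(x):
        return jacobian_fd(
            TumorParams.from_array(clip(x)),
            op,
            coord_step=cfg.fd_coord_step_voxels * phantom.voxel_size,
            diameter_rel_step=cfg.fd_diameter_rel_step,
        )

    _, base_rms = surface_residual(op.surface(None), observed)
    scale = np.array(
        [phantom.breast_radius, phantom.breast_radius, phantom.breast_radius, INIT_DIAMETER]
    )
    x_hat, trajectory, stop = levenberg_marquardt(
        residual_fn, theta0.as_array(), jacobian_fn, x_scale=scale, config=cfg
    )
    x_hat = clip(x_hat)
    accepted = [t for t in trajectory if t["accepted"]]

    # Size-branch disambiguation.  Total source power is non-monotonic in
    # diameter (see bioheat.power_stationary_diameter), so the misfit
    # surface can hold one minimum on each side of the stationary size;
    # when the primary fit found a genuine source, refit from the opposite
    # branch and keep the lower-residual solution (plain global
    # optimization of the same least-squares objective).
    if cfg.branch_restart and _allow_branch_restart:
        rms_hat = accepted[-1]["rms"]
        if improvement_f_ratio(observed.n_nodes, base_rms, rms_hat) >= 10.0:
            d_star = power_stationary_diameter()
            d_alt = 0.8 * d_star if x_hat[3] > d_star else 1.6 * d_star
            alt_init = TumorParams(
                center=(x_hat[0], x_hat[1], max(x_hat[2], 2 * phantom.voxel_size)),
                diameter=d_alt,
            )
            alt = lma_fit(
                observed, phantom, props, ambient, init=alt_init,
                config=cfg, operator=op, _allow_branch_restart=False,
            )
            if alt.residual_rms < rms_hat:
                return alt

    return InverseResult(
        theta_hat=TumorParams.from_array(x_hat),
        residual_rms=float(accepted[-1]["rms"]),
        baseline_rms=float(base_rms),
        n_nodes=observed.n_nodes,
        iterations=accepted[-1]["iteration"],
        converged=stop in ("ftol", "xtol", "zero_residual"),
        stop_reason=stop,
        trajectory=trajectory,
        config_hash=hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:12],
    )


def classify_detection(
    result: InverseResult,
    phantom: BreastPhantom,
    config: DetectionConfig | None = None,
) -> InverseResult:
    """Turn a fitted result into a present/absent call.

    The governing principle is that absence means the optimizer parked
    the source where it *minimally impacts surface temperature*.  The
    primary evidence is therefore the misfit reduction itself: a nested-
    model F-ratio of the fitted source against the tumor-free model.  A
    source failing the F-test is absent, with the positional reason —
    (a) center outside breast tissue, (b) center within the chest-wall
    margin, (c) thermally silent diameter (below the source relation's
    domain or the sub-voxel floor) — or "no-improvement" when it sits in
    the breast but explains nothing.  A source passing the F-test is a
    genuine heat source and is called present even when the optimizer's
    positional estimate has drifted to the margins of the breast.  Fills
    ``detected``/``decision_reason`` in place and returns the result.
    """
    cfg = config or DetectionConfig()
    th = result.theta_hat
    dx = phantom.voxel_size

    n, p = result.n_nodes, cfg.n_params
    ss0 = n * result.baseline_rms**2
    ss1 = n * result.residual_rms**2
    if ss1 <= 0.0:
        f_ratio = np.inf if ss0 > 0 else 0.0
    else:
        f_ratio = ((ss0 - ss1) / p) / (ss1 / max(n - p, 1))
    significant = f_ratio >= cfg.min_f_ratio

    silent_size = th.diameter <= max(min_active_diameter(), 0.5 * dx)
    outside = phantom.label_at(th.center) in (AIR, CHEST)
    at_wall = th.center[2] < cfg.chest_margin_voxels * dx

    if significant and not silent_size:
        result.detected, result.decision_reason = True, "in-breast"
        return result
    result.detected = False
    if outside:
        result.decision_reason = "outside-breast"
    elif at_wall:
        result.decision_reason = "chest-wall"
    elif silent_size:
        result.decision_reason = "sub-voxel-size"
    else:
        result.decision_reason = "no-improvement"
    return result
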