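# Methods

## Physical model

Tissue temperature in the breast is modeled by the steady-state Pennes
bioheat equation,

    div(k grad T) + omega_b rho_b c_b (T_a - T) + q_m + q_t = 0,

with thermal conductivity `k`, blood perfusion rate `omega_b`, blood
density and specific heat `rho_b`, `c_b`, arterial temperature `T_a`,
metabolic heat `q_m`, and a tumor source `q_t`.  Perfusion acts as a
distributed heat exchanger pulling tissue toward arterial temperature;
its screening length sqrt(k / (omega_b rho_b c_b)) is ~1.5 cm in gland,
which is what makes deep sources faint at the skin.

Boundary conditions: the chest-wall plane is held at core temperature
(37 °C); skin faces lose heat by convection, `h (T - T_inf)`, and thermal
radiation per the Stefan–Boltzmann law, `eps sigma (T^4 - T_inf^4)`,
linearized about a 33 °C skin reference (one-shot linearization; skin
temperatures span a narrow band so the film-coefficient error is well
below the camera noise).

The tumor is modeled purely as a volumetric heat source on an unchanged
tissue background — its conductivity and perfusion default to gland
values — with magnitude from the empirical growth-rate relation

    q_t(D) = C1 / (C2 ln(100 D) + C3),
    C1 = 3.27e6 W m^-3, C2 = 468.5, C3 = 50  (D in meters),

whose denominator is the tumor volume-doubling time in days: smaller,
faster-growing tumors run hotter per unit volume.  The relation is
undefined below D ≈ 9 mm (doubling time → 0), so the package treats such
diameters as thermally silent, and the synthetic batch samples diameters
from 10 mm up.

**Power non-monotonicity.** Total emitted power P(D) = q_t(D) (π/6) D³ is
*stationary* at D\* = e^(1/3 − C3/C2)/100 ≈ 12.5 mm: below D\* the
collapsing doubling time outweighs the shrinking volume.  Two diameters on
opposite sides of D\* can therefore emit the same power, and for a deep
tumor — whose surface signature is essentially that of a point source —
they produce nearly indistinguishable skin maps.  This is an intrinsic
ambiguity of the source relation, not of the solver; it drives both the
branch-restart strategy and the known limitation below.

## Discretization and solver

Cell-centered finite volumes on the phantom's voxel grid (6-neighbor
stencil): harmonic-mean face conductivities across tissue interfaces, the
chest-wall temperature imposed at the chest/breast interface faces, and
half-cell series resistance to the combined convective + radiative skin
film.  Grid-boundary faces are insulated (the hemisphere never exposes a
lateral face; slab configurations use this to realize 1-D conduction).
The scheme is conservative: at the solution, total boundary flux equals
total volumetric source to solver precision, and `energy_balance` checks
this to 1e-6 relative.

The linear system (symmetric positive definite, one row per breast voxel,
~5e4 unknowns at 2.5 mm) is solved by conjugate gradients with a Jacobi
preconditioner to a relative residual of 1e-9, warm-started from the
previous solution across the inverse loop's many right-hand sides; small
systems use a sparse direct solve.  An analytic perfused-slab solution
(`slab_oracle`) verifies the scheme: agreement within 0.05 °C at 2.5 mm
voxels with the error shrinking ~4x at 1.25 mm (nominal order 2).

The spherical source is voxelized with a half-voxel linear occupancy ramp,
making the forward map continuous (and a.e. differentiable) in the tumor
center and diameter — the property that lets a derivative-based optimizer
take sub-voxel steps on a discrete grid.

## Multi-view acquisition model

The skin surface is the set of breast-voxel faces adjacent to air; each
face contributes one node carrying the adjacent cell temperature (no
interpolation).  Eight orthographic views at 45° azimuth steps, tilted 20°
toward the chest wall so the nipple cap is seen, render the nodes with
nearest-node z-buffering.  Camera noise is additive i.i.d. Gaussian with
sd equal to the camera's thermal sensitivity (default 0.02 °C), seeded.
On synthetic phantoms the simulated and observed surfaces share one node
set by construction, so the inverse problem fits in node space and the
views are a faithful presentation/noise layer; registering real
photographs to a patient mesh is out of scope.

## Inverse method

Levenberg–Marquardt on theta = (x_c, y_c, z_c, D), residual = node-wise
temperature difference.  Sensitivities by central finite differences
(steps: 1 voxel for coordinates, 10 % for the diameter) through the cached
forward operator; the Jacobian is refreshed only after accepted steps.
Schedule and stopping: lambda_0 = 1e-2, /3 on accept, x3 on reject; stop
on relative residual change < 1e-4, scaled step norm < 1e-4, 50
iterations, or 8 consecutive rejections.  Two standard safeguards beyond
the plain accept-on-decrease rule:

- **gain ratio**: a step must achieve at least 1e-3 of its linearized
  predicted reduction (rejects long steps whose improvement is
  accidental);
- **trust region**: step norm capped at one unit of the parameter scale
  (breast radius for coordinates, 18 mm for diameter) — the linearization
  cannot be trusted over moves larger than the organ.

Initialization follows the standard protocol: D = 1.8 cm at the centroid
of the breast tissue.  The diameter is floored at a tenth of a voxel; the
center is unconstrained, because pushing the source out of the breast is
the mechanism by which the fit expresses "no tumor".  After a significant
primary fit, one restart probes the opposite side of the power-stationary
diameter D\* and the lower-residual solution is kept — plain global
optimization of the same least-squares objective over its known two-branch
structure.  A 5-point quadrant-seeded multi-start is available but off by
default.  On a 1-D two-parameter toy problem the optimizer's optimum
matches an exhaustive grid search of the misfit surface within grid
resolution (tested).

## Detection rule

Absence means the fitted source *minimally impacts the surface
temperature*.  The primary evidence is a nested-model F-ratio comparing
the fitted source against the tumor-free model on the same observation,

    F = ((SS_0 - SS_1)/4) / (SS_1/(n - 4)),

with threshold 10: far above the ~1 chance level of fitting 4 parameters
to noise, far below the values (> 100) produced by genuine sources, and
reducing to "any improvement" as noise → 0.  Non-significant fits are
absent, with the positional reason recorded: center outside breast tissue,
center within one voxel of the chest wall, thermally silent diameter, or
in-breast with no improvement.  A significant source is a detection even
when its positional estimate has drifted to the margins of the breast —
position alone is a proxy, and overriding a strong source on positional
grounds would manufacture false negatives.

## Synthetic validation batch

The default batch (the package's standard study conditions) is 10
tumor-bearing plus 10 tumor-free hemispherical phantoms at 2.5 mm voxels:
breast radius uniform on 60–75 mm, gland fraction 0.4–0.7, tumor diameter
uniform on 10–25 mm and center depth 10–40 mm below the skin along a
random admissible direction, camera noise 0.02 °C; every random draw
descends from one run-level seed recorded in the outputs.  These spans
mirror the clinical cohort's actual sizes (0.5–2.7 cm) and MRI depths
(0.95–5.45 cm) at desk scale, except that sub-centimeter diameters are
excluded by the source relation's domain (above).

What the generator emulates: pendant-breast geometry against a warm chest
wall, fat/gland property contrast, size-coupled source strength, camera
noise at hardware sensitivity.  What it does not: real breast shape and
its MRI segmentation, skin microvasculature and ambient convection
inhomogeneity, registration error between camera views and the model, and
inter-patient property variability.  Passing the synthetic recovery tests
therefore demonstrates the correctness and conditioning of the
forward/inverse machinery under the stated noise — not clinical
performance on real patients.

## Parameter defaults

| parameter | value | units | rationale |
|---|---|---|---|
| k (fat / gland / tumor / skin) | 0.21 / 0.48 / 0.48 / 0.37 | W m⁻¹ K⁻¹ | breast bioheat literature |
| omega_b (fat / gland / tumor / skin) | 2.2e-4 / 5.4e-4 / 5.4e-4 / 2.0e-4 | s⁻¹ | idem |
| q_m (fat / gland / tumor / skin) | 400 / 700 / 700 / 368 | W m⁻³ | idem (tumor *excess* heat comes from q_t) |
| rho_b, c_b | 1060, 3770 | kg m⁻³, J kg⁻¹ K⁻¹ | blood |
| T_a = T_core | 37 | °C | steady state, acclimated subject |
| T_inf | 21 | °C | typical imaging room |
| h | 5 | W m⁻² K⁻¹ | natural convection |
| epsilon | 0.98 | — | human skin emissivity |
| sigma_cam | 0.02 | °C | camera thermal sensitivity |
| voxel | 2.5 (fine preset 1.25) | mm | desk-scale solves with demonstrated grid convergence |

All of these are explicit configuration (`TissueProperties.override`,
`AmbientConditions`, YAML round-trip via `RunConfig`).

## Known limitations

- **Deep-tumor size ambiguity.** For tumors deeper than ~35 mm with
  diameters near D\* ≈ 12.5 mm, the two power-branches differ at the skin
  by far less than the camera noise, so the global least-squares minimum
  can sit on the wrong branch, mis-sizing the tumor by ~10 mm and
  displacing the fitted center by several mm — while detection itself
  (the F-test) remains unambiguous.  No estimator can resolve this from a
  single noisy acquisition; it would take lower noise (frame averaging),
  a prior on size, or a source relation without a power-stationary point.
- The radiative boundary is linearized once, not iterated; adequate for
  skin temperature bands of a few °C.
- Tumor conductivity/perfusion contrast is ignored (source-only tumor);
  solid, uniformly heated spheres only; one tumor per breast.
- The hemisphere-on-plane geometry preserves the depth/surface
  relationship the method exploits but none of the shape detail of a real
  pendant breast.
- Cohort statistics are per tumor row, not per patient: the printed table
  does not link rows of the one bilateral case to a patient identity.
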