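# thermoscreen

Steady-state breast thermography simulation and inverse-model tumor
detection.

Malignant breast tumors are metabolically hyperactive and hyper-perfused:
they act as volumetric heat sources inside the breast and perturb the skin
surface temperature by tenths of a degree — within reach of modern thermal
cameras (NETD ≈ 0.02 °C) imaging the pendant breast in the prone position.
`thermoscreen` implements the physics-based detection pipeline behind this
idea end-to-end on synthetic phantoms:

1. **Phantom** — a voxelized hemispherical breast (fat/gland, chest wall,
   optional skin shell) standing in for an MRI-derived patient model, with
   an embedded spherical tumor.
2. **Forward model** — the steady-state Pennes bioheat equation

   ∇·(k∇T) + ω_b ρ_b c_b (T_a − T) + q_m + q_t = 0

   discretized with a conservative cell-centered finite-volume scheme;
   convective + radiative (Stefan–Boltzmann, linearized) skin boundary,
   chest wall at core temperature.  The tumor source q_t(D) follows an
   empirical growth-rate relation, q_t = C₁ / (C₂ ln(100 D) + C₃), coupling
   heat generation to diameter.
3. **Multi-view IR acquisition** — skin-surface extraction, 8 orthographic
   views at 45° azimuth steps, additive Gaussian camera noise.
4. **Inverse model** — Levenberg–Marquardt estimation of θ = (x_c, y_c,
   z_c, D) from the surface temperatures, with finite-difference
   sensitivities through the PDE solver.  The center is unconstrained:
   when the data carry no tumor signature, the optimizer parks the source
   where it cannot heat the skin (outside the breast, at the chest wall,
   or at a thermally silent size), and the classifier reads that — plus a
   nested-model F-test on the misfit reduction — as "absent".
5. **Validation** — a packaged 25-tumor clinical cohort table (ages,
   densities, histologies, actual vs thermally estimated sizes, MRI
   depths) and batch scoring of sensitivity, specificity, and size /
   location errors on synthetic cases.

## Worked example

Simulate a 5 cm breast with a 14 mm tumor 2.5 cm off the chest wall, then
recover it from the surface temperatures alone:

```bash
$ thermoscreen simulate --radius 0.05 --tumor 0.0 0.01 0.025 0.014 \
      --outdir demo --views
surface nodes: 3749, T range 27.091..35.478 degC

$ thermoscreen invert demo/surface.csv demo/phantom.nii.gz --out demo/result.json
wrote demo/result.json
detected=True reason=in-breast
```

The fitted parameters in `demo/result.json` read back the truth to within
a fraction of a voxel: diameter 14.0 mm, center (−0.0, 10.0, 25.0) mm.
The surface temperatures span 27.1–35.5 °C: coolest at the pendant tip
(farthest from the 37 °C chest wall), warmest at the chest-wall rim, with
the tumor adding a localized ≈ 0.2 °C excess above the site at
(0, 10) mm.

The packaged cohort table and its summary statistics:

```bash
$ thermoscreen cohort-stats
{
 "n_records": 25,
 "age_median": 67.0,
 "age_min": 42,
 "age_max": 72,
 ...
}
```

25 tumor records, median age 67 (range 42–72), 5 heterogeneously-dense and
1 extremely-dense breast, actual sizes 0.5–2.7 cm, and a maximum gap of
0.5 cm between actual and thermally estimated size.

A full synthetic validation batch (10 tumor-bearing + 10 tumor-free
phantoms, 0.02 °C camera noise):

```bash
thermoscreen run-batch --seed 1 --outdir runs/batch1
```

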