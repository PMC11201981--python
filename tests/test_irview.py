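"""Surface extraction, multi-view rendering, camera noise, residuals."""

import numpy as np
import pytest

from thermoscreen.bioheat import TemperatureField
from thermoscreen.irview import (
    NoiseModel,
    add_camera_noise,
    extract_surface,
    load_surface_csv,
    render_views,
    save_surface_csv,
    surface_residual,
    surface_indices,
)
from thermoscreen.phantom import AIR, TumorParams, build_hemisphere_phantom


def isothermal_field(phantom, T=37.0):
    grid = np.full(phantom.shape, np.nan)
    grid[phantom.label_grid > 0] = T
    vec = np.full(int(phantom.breast_mask.sum()), T)
    return TemperatureField(grid, phantom, vec, {})


class TestExtractSurface:
    def test_isothermal_surface_is_isothermal(self, small_phantom):
        surf = extract_surface(small_phantom, isothermal_field(small_phantom))
        assert np.allclose(surf.T, 37.0)
        assert np.allclose(np.linalg.norm(surf.normals, axis=1), 1.0)

    def test_node_count_matches_brute_force_enumeration(self, small_phantom):
        cells, dirs = surface_indices(small_phantom)
        lab = small_phantom.label_grid
        brute = 0
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        for i in range(lab.shape[0]):
            for j in range(lab.shape[1]):
                for k in range(lab.shape[2]):
                    if not small_phantom.breast_mask[i, j, k]:
                        continue
                    for di, dj, dk in offsets:
                        ii, jj, kk = i + di, j + dj, k + dk
                        inside = (
                            0 <= ii < lab.shape[0]
                            and 0 <= jj < lab.shape[1]
                            and 0 <= kk < lab.shape[2]
                        )
                        if inside and lab[ii, jj, kk] == AIR:
                            brute += 1
        assert len(cells) == brute
        # staircase surface area exceeds the smooth hemisphere area by the
        # lattice (L1-projection) factor of 1.5
        smooth = 2 * np.pi * small_phantom.breast_radius**2 / small_phantom.voxel_size**2
        assert len(cells) / smooth == pytest.approx(1.5, rel=0.07)

    def test_mirrored_phantom_gives_mirrored_surface(self, small_phantom):
        surf = extract_surface(small_phantom, isothermal_field(small_phantom))
        msurf = extract_surface(
            small_phantom.mirrored(), isothermal_field(small_phantom.mirrored())
        )
        key = lambda P: set(map(tuple, np.round(P, 9)))
        mirrored = surf.positions.copy()
        mirrored[:, 0] *= -1
        assert key(mirrored) == key(msurf.positions)

    def test_mismatched_pair_rejected(self, small_phantom):
        other = build_hemisphere_phantom(0.04, 0.0025)
        with pytest.raises(ValueError):
            extract_surface(small_phantom, isothermal_field(other))


class TestRenderViews:
    def test_eight_views_isothermal_foreground(self, small_phantom):
        surf = extract_surface(small_phantom, isothermal_field(small_phantom))
        views = render_views(surf, pixel_pitch=small_phantom.voxel_size)
        assert views.n_views == 8
        assert np.allclose(np.diff(views.azimuths_deg), 45.0)
        for img in views.images:
            fg = img[np.isfinite(img)]
            assert fg.size > 0 and np.allclose(fg, 37.0)

    def test_view_average_reproduces_node_temperature(self, small_operator):
        surf = small_operator.base_surface
        views = render_views(surf, pixel_pitch=surf.provenance.get("pitch", 0.0025))
        sums = np.zeros(surf.n_nodes)
        counts = np.zeros(surf.n_nodes)
        for img, nmap in zip(views.images, views.node_maps):
            hit = nmap >= 0
            np.add.at(sums, nmap[hit], img[hit])
            np.add.at(counts, nmap[hit], 1.0)
        seen = counts > 0
        assert np.allclose(sums[seen] / counts[seen], surf.T[seen])

    def test_every_node_front_facing_somewhere_and_rendered_at_fine_pitch(
        self, small_phantom
    ):
        surf = extract_surface(small_phantom, isothermal_field(small_phantom))
        views = render_views(surf, pixel_pitch=small_phantom.voxel_size / 2)
        e = np.deg2rad(views.elevation_deg)
        front = np.zeros(surf.n_nodes, bool)
        for az in np.deg2rad(views.azimuths_deg):
            ray = np.array([-np.cos(e) * np.cos(az), -np.cos(e) * np.sin(az), -np.sin(e)])
            front |= (surf.normals @ ray) <= 1e-12
        assert front.all()
        seen = np.zeros(surf.n_nodes, bool)
        for nmap in views.node_maps:
            seen[nmap[nmap >= 0]] = True
        assert seen.all()

    def test_tumor_azimuth_rotation_rotates_view_signature(self, small_operator):
        """Advancing the tumor azimuth by 45 degrees rotates the per-view
        excess-signal vector by exactly one view."""
        op = small_operator
        base = op.base_surface

        def view_signal(az_deg):
            az = np.deg2rad(az_deg)
            t = TumorParams(
                center=(0.03 * np.cos(az), 0.03 * np.sin(az), 0.018), diameter=0.014
            )
            s = op.surface(t)
            views = render_views(
                base.with_temperatures(s.T - base.T), pixel_pitch=0.0025
            )
            return np.array([np.nansum(img) for img in views.images])

        s1 = view_signal(22.5)
        s2 = view_signal(67.5)
        assert np.allclose(s2, np.roll(s1, 1), rtol=0.12)
        # and the strongest views face the tumor
        assert int(np.argmax(s1)) in (0, 1)
        assert int(np.argmax(s2)) in (1, 2)


class TestCameraNoise:
    def test_zero_sigma_is_identity(self, small_operator):
        surf = small_operator.base_surface
        out = add_camera_noise(surf, NoiseModel(sigma_cam=0.0, seed=3))
        assert np.array_equal(out.T, surf.T)

    def test_noise_sd_matches_sensitivity(self):
        rng = np.random.default_rng(0)
        n = 20000
        surf_T = np.full(n, 33.0)
        from thermoscreen.irview import SurfaceMap

        surf = SurfaceMap(
            positions=rng.random((n, 3)),
            normals=np.tile([0.0, 0.0, 1.0], (n, 1)),
            T=surf_T,
            cell_rows=np.arange(n),
        )
        noisy = add_camera_noise(surf, NoiseModel(sigma_cam=0.02, seed=5))
        sd = np.std(noisy.T - surf.T)
        assert 0.018 <= sd <= 0.022

    def test_same_seed_reproduces(self, small_operator):
        surf = small_operator.base_surface
        a = add_camera_noise(surf, NoiseModel(0.02, seed=9))
        b = add_camera_noise(surf, NoiseModel(0.02, seed=9))
        c = add_camera_noise(surf, NoiseModel(0.02, seed=10))
        assert np.array_equal(a.T, b.T)
        assert not np.array_equal(a.T, c.T)

    def test_views_noise(self, small_operator):
        views = render_views(small_operator.base_surface, pixel_pitch=0.0025)
        noisy = add_camera_noise(views, NoiseModel(0.02, seed=1))
        diff = np.concatenate(
            [
                (n - c)[np.isfinite(c)]
                for n, c in zip(noisy.images, views.images)
            ]
        )
        assert 0.015 <= diff.std() <= 0.025


class TestSurfaceResidual:
    def test_identity_and_shift(self, small_operator):
        surf = small_operator.base_surface
        r, rms = surface_residual(surf, surf)
        assert rms == 0.0 and np.allclose(r, 0.0)
        shifted = surf.with_temperatures(surf.T + 0.1)
        _, rms = surface_residual(shifted, surf)
        assert rms == pytest.approx(0.1)

    def test_permutation_invariance(self, small_operator):
        surf = small_operator.base_surface
        rng = np.random.default_rng(2)
        perm = rng.permutation(surf.n_nodes)
        from thermoscreen.irview import SurfaceMap

        sp = SurfaceMap(surf.positions[perm], surf.normals[perm], surf.T[perm],
                        surf.cell_rows[perm])
        op = SurfaceMap(surf.positions[perm], surf.normals[perm],
                        surf.T[perm] + 0.05, surf.cell_rows[perm])
        _, rms_p = surface_residual(sp, op)
        _, rms_0 = surface_residual(surf, surf.with_temperatures(surf.T + 0.05))
        assert rms_p == pytest.approx(rms_0)

    def test_mismatched_node_sets_rejected(self, small_operator):
        surf = small_operator.base_surface
        from thermoscreen.irview import SurfaceMap

        other = SurfaceMap(surf.positions[:-1], surf.normals[:-1], surf.T[:-1],
                           surf.cell_rows[:-1])
        with pytest.raises(ValueError):
            surface_residual(surf, other)


def test_surface_csv_round_trip(tmp_path, small_operator):
    surf = small_operator.base_surface
    path = tmp_path / "surface.csv"
    save_surface_csv(surf, path)
    back = load_surface_csv(path)
    assert np.allclose(back.positions, surf.positions)
    assert np.allclose(back.T, surf.T)
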