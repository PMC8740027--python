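import numpy as np
import pytest

from divmap.fields import (
    EvalGrid,
    VectorField,
    divergence_field,
    make_grid,
    median_speed,
    velocity_field,
)
from divmap.rbf import MultisiteRecording, fit_interpolant

from conftest import random_recording


def radial_recording(c=0.546, source=(0.0, 0.0), seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-12, 12, size=(15, 2))
    t = np.hypot(pts[:, 0] - source[0], pts[:, 1] - source[1]) / c
    return MultisiteRecording(pts, t, 150.0)


class TestGrid:
    def test_hull_mask_contains_sites(self, patch_layout):
        grid = make_grid(patch_layout, resolution=100, mask_mode="hull")
        # interior points of the layout must be masked valid
        xx, yy = np.meshgrid(grid.x, grid.y)
        for p in patch_layout.points * 0.9:  # shrink toward centroid: interior
            i = np.argmin(np.abs(grid.y - p[1]))
            j = np.argmin(np.abs(grid.x - p[0]))
            assert grid.mask[i, j]

    def test_box_mask_all_true(self, patch_layout):
        grid = make_grid(patch_layout, resolution=50, mask_mode="box")
        assert grid.mask.all()

    def test_uniform_spacing(self, patch_layout):
        grid = make_grid(patch_layout, resolution=64)
        assert np.allclose(np.diff(grid.x), grid.spacing)
        assert np.allclose(np.diff(grid.y), grid.spacing)

    def test_degenerate_bounds(self):
        with pytest.raises(ValueError):
            make_grid(((0.0, 0.0), (0.0, 1.0)), resolution=16, mask_mode="box")

    def test_resolution_floor(self, patch_layout):
        with pytest.raises(ValueError):
            make_grid(patch_layout, resolution=4)


class TestVelocityField:
    def test_plane_wave_speed_and_direction(self, patch_layout):
        pts = patch_layout.points
        c = 0.604  # mm/ms = 60.4 cm/s
        rec = MultisiteRecording(pts, pts[:, 0] / c, 150.0)
        vf = velocity_field(fit_interpolant(rec), make_grid(patch_layout, resolution=60))
        assert np.allclose(vf.speed[vf.valid], 60.4, rtol=1e-9)
        assert np.allclose(vf.unit_vx[vf.valid], 1.0, atol=1e-9)
        assert np.allclose(vf.unit_vy[vf.valid], 0.0, atol=1e-9)

    def test_radial_unit_vectors_point_outward(self):
        rec = radial_recording(source=(1.0, -2.0))
        grid = make_grid(rec, resolution=60)
        vf = velocity_field(fit_interpolant(rec), grid)
        xx, yy = np.meshgrid(grid.x, grid.y)
        r = np.hypot(xx - 1.0, yy + 2.0)
        sel = vf.valid & (r > 3.0)
        dot = (vf.unit_vx * (xx - 1.0) + vf.unit_vy * (yy + 2.0)) / np.where(r > 0, r, 1)
        assert np.all(dot[sel] > 0.9)

    def test_speed_gradient_identity(self, random_models):
        """Eq of motion consistency: speed * ||grad f|| = 1 after unit conversion."""
        for m in random_models[:5]:
            grid = make_grid(type("L", (), {"points": m.centers})(), resolution=40)
            vf = velocity_field(m, grid)
            g = m.gradient(grid.points()).reshape(grid.shape + (2,))
            norm = np.hypot(g[..., 0], g[..., 1])
            prod = vf.speed[vf.valid] / 100.0 * norm[vf.valid]
            assert np.allclose(prod, 1.0, rtol=1e-9)

    def test_unit_norm(self, random_models):
        grid = make_grid(type("L", (), {"points": random_models[0].centers})(), resolution=30)
        vf = velocity_field(random_models[0], grid)
        n = np.hypot(vf.unit_vx[vf.valid], vf.unit_vy[vf.valid])
        assert np.allclose(n, 1.0, atol=1e-9)

    def test_median_speed_of_known_values(self):
        grid = EvalGrid(np.arange(3.0), np.arange(3.0), np.ones((3, 3), bool))
        speeds = np.array([40.0, 50.0, 60.0] * 3).reshape(3, 3)
        vf = VectorField(grid, speeds, np.zeros_like(speeds),
                         np.ones_like(speeds), np.zeros_like(speeds),
                         np.ones((3, 3), bool))
        assert median_speed(vf) == 50.0

    def test_median_speed_requires_valid_nodes(self):
        grid = EvalGrid(np.arange(3.0), np.arange(3.0), np.ones((3, 3), bool))
        vf = VectorField(grid, np.ones((3, 3)), np.ones((3, 3)),
                         np.ones((3, 3)), np.ones((3, 3)), np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            median_speed(vf)


class TestDivergence:
    def test_plane_wave_divergence_zero(self, patch_layout):
        pts = patch_layout.points
        rec = MultisiteRecording(pts, pts[:, 0] / 0.604, 150.0)
        d = divergence_field(fit_interpolant(rec), make_grid(patch_layout, resolution=60))
        assert np.nanmax(np.abs(d.values[d.valid])) < 1e-9

    def test_matches_finite_difference_oracle(self, random_models):
        """Analytic divergence vs central differences of the sampled unit field."""
        for m in random_models[:6]:
            grid = make_grid(type("L", (), {"points": m.centers})(),
                             resolution=50, mask_mode="box")
            d = divergence_field(m, grid)
            vf = velocity_field(m, grid)
            h = grid.spacing
            fd = np.full(grid.shape, np.nan)
            ux, uy = vf.unit_vx, vf.unit_vy
            fd[1:-1, 1:-1] = (ux[1:-1, 2:] - ux[1:-1, :-2]) / (2 * h) + (
                uy[2:, 1:-1] - uy[:-2, 1:-1]
            ) / (2 * h)
            ok = d.valid & np.isfinite(fd)
            # away from degenerate spots the FD of the unit field converges to D
            ok[1:-1, 1:-1] &= (
                vf.valid[:-2, 1:-1] & vf.valid[2:, 1:-1] & vf.valid[1:-1, :-2] & vf.valid[1:-1, 2:]
            )
            diff = np.abs(d.values - fd)[ok]
            assert np.median(diff) < 1e-3

    def test_rotation_equivariance(self):
        rec = radial_recording(seed=5)
        th = 0.6
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rec_r = MultisiteRecording(rec.positions @ rot.T, rec.times, 150.0)
        grid = EvalGrid(np.linspace(-6, 6, 40), np.linspace(-6, 6, 40), np.ones((40, 40), bool))
        m, mr = fit_interpolant(rec), fit_interpolant(rec_r)
        pts = grid.points()
        d = divergence_field(m, grid)
        # evaluate rotated model at rotated points: divergence is a scalar
        from divmap.fields import ScalarField  # noqa: F401

        g = mr.gradient(pts @ rot.T)
        h = mr.hessian(pts @ rot.T)
        norm = np.hypot(g[:, 0], g[:, 1])
        dv = (h[:, 0, 0] + h[:, 1, 1]) / norm - np.einsum("ni,nij,nj->n", g, h, g) / norm**3
        assert np.allclose(d.values.ravel(), dv, atol=1e-6)

    def test_time_rescaling_invariance(self):
        rec = radial_recording(seed=6)
        rec2 = MultisiteRecording(rec.positions, 3.7 * rec.times, 150.0)
        grid = EvalGrid(np.linspace(-6, 6, 30), np.linspace(-6, 6, 30), np.ones((30, 30), bool))
        d1 = divergence_field(fit_interpolant(rec), grid)
        d2 = divergence_field(fit_interpolant(rec2), grid)
        assert np.allclose(d1.values[d1.valid & d2.valid], d2.values[d1.valid & d2.valid], atol=1e-9)

    def test_focal_source_positive_collision_negative(self, patch_layout):
        pts = patch_layout.points
        # focal: max D near center; collision: negative band at the midline
        rec_f = MultisiteRecording(pts, np.hypot(*pts.T) / 0.55, 150.0)
        grid = make_grid(patch_layout, resolution=80)
        df = divergence_field(fit_interpolant(rec_f), grid)
        xx, yy = np.meshgrid(grid.x, grid.y)
        r = np.hypot(xx, yy)
        assert np.nanmedian(df.values[df.valid & (r < 5)]) > 0

        t_coll = np.minimum(pts[:, 0] - (-13), 13 - pts[:, 0]) / 0.55
        dc = divergence_field(fit_interpolant(MultisiteRecording(pts, t_coll, 150.0)), grid)
        band = dc.valid & (np.abs(xx) < 1.5)
        assert np.nanmedian(dc.values[band]) < 0
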