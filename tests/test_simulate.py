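import numpy as np
import pytest

from divmap.eikonal import fast_march
from divmap.simulate import (
    HeterogeneityConfig,
    PatternConfig,
    add_jitter,
    remove_sites,
    sample_multisite,
    simulate_activation_field,
    _sector_speed_map,
)


class TestPatternFields:
    def test_plane_exact_median_speed(self, plane_field):
        assert np.median(plane_field.true_speed) == pytest.approx(60.4)
        assert plane_field.grid_times.min() >= 0

    def test_focal_exact_median_speed(self, focal_field):
        s = focal_field.true_speed
        assert np.median(s[s > 0]) == pytest.approx(54.6)

    def test_collision_continuous_times_discontinuous_gradient(self):
        f = simulate_activation_field(PatternConfig(pattern="collision", time_quantum=0.0))
        t = f.grid_times
        # continuity: neighboring cells differ by at most one cell-crossing
        c = 55.8 / 100.0
        assert np.max(np.abs(np.diff(t, axis=1))) <= f.spacing / c + 1e-9
        # velocity flips sign across the midline
        mid = t.shape[1] // 2
        assert np.all(f.true_vx[:, : mid - 1] > 0)
        assert np.all(f.true_vx[:, mid + 1 :] < 0)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            PatternConfig(pattern="spiral")

    def test_source_outside_patch_rejected(self):
        with pytest.raises(ValueError, match="inside the patch"):
            PatternConfig(pattern="focal_homogeneous", source_position=(45.0, 5.0))

    def test_heterogeneous_realized_statistics(self):
        """Sector speeds emulate the reported ~59.9 +/- 12.5 cm/s tissue."""
        xx, yy = np.meshgrid((np.arange(200) + 0.5) * 0.2, (np.arange(200) + 0.5) * 0.2)
        means, sds = [], []
        for s in range(30):
            sp = _sector_speed_map(PatternConfig(pattern="focal_heterogeneous", seed=s), xx, yy)
            means.append(sp.mean())
            sds.append(sp.std())
        assert np.mean(means) == pytest.approx(59.9, abs=1.0)
        assert np.mean(sds) == pytest.approx(12.5, abs=2.0)

    def test_heterogeneous_reproducible(self):
        cfg = PatternConfig(pattern="focal_heterogeneous", grid_n=100, seed=7)
        a = simulate_activation_field(cfg)
        b = simulate_activation_field(cfg)
        assert np.array_equal(a.grid_times, b.grid_times)

    def test_quantization_bounded_change(self):
        q = 2.0
        cfg0 = PatternConfig(pattern="focal_homogeneous", time_quantum=0.0, grid_n=100)
        cfgq = PatternConfig(pattern="focal_homogeneous", time_quantum=q, grid_n=100)
        t0 = simulate_activation_field(cfg0).grid_times
        tq = simulate_activation_field(cfgq).grid_times
        assert np.max(np.abs(t0 - tq)) <= q / 2 + 1e-12


class TestEikonal:
    def test_uniform_speed_matches_radial_field(self):
        n, h = 120, 0.25
        x = (np.arange(n) + 0.5) * h
        speed = np.full((n, n), 0.6)
        src = (x[n // 2], x[n // 2])
        t = fast_march(speed, h, x, x, src)
        xx, yy = np.meshgrid(x, x)
        r = np.hypot(xx - src[0], yy - src[1])
        exact = r / 0.6
        sel = r >= 5 * h
        assert np.max(np.abs(t[sel] - exact[sel]) / exact[sel]) < 0.01

    def test_slow_region_delays_arrival(self):
        n, h = 80, 0.5
        x = (np.arange(n) + 0.5) * h
        speed = np.full((n, n), 0.6)
        speed[:, n // 2 :] = 0.2  # slow right half
        src = (x[n // 4], x[n // 2])
        t = fast_march(speed, h, x, x, src)
        # symmetric probes left/right of the source: slow side arrives later
        j = n // 2
        assert t[n // 4, j + 20] > t[n // 4, j - 20]

    def test_positive_speed_required(self):
        with pytest.raises(ValueError):
            fast_march(np.zeros((10, 10)), 1.0, np.arange(10.0), np.arange(10.0), (5, 5))


class TestSampling:
    def test_beat_columns_offset_by_cycle_length(self, plane_field, patch_layout):
        rec = sample_multisite(plane_field, patch_layout, n_beats=2)
        assert np.allclose(rec.times[:, 1] - rec.times[:, 0], 150.0)

    def test_focal_inner_bipoles_activate_first(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout)
        t = dict(zip(rec.site_labels, rec.times[:, 0]))
        for s in "ABCDE":
            assert t[f"{s}_34"] < t[f"{s}_23"] < t[f"{s}_12"]

    def test_grid_node_sampled_exactly(self, focal_field):
        import divmap.catheter as cat

        node = np.array([focal_field.x[60], focal_field.y[90]])
        pts = np.array([node, node + [3.0, 0.0], node + [0.0, 3.0]])
        lay = cat.CatheterLayout(pts - node, ("p0", "p1", "p2"), swept_radius=5.0)
        rec = sample_multisite(focal_field, lay, center=node)
        assert rec.times[0, 0] == pytest.approx(focal_field.grid_times[90, 60], abs=1e-12)

    def test_outside_patch_rejected(self, focal_field, patch_layout):
        with pytest.raises(ValueError, match="outside the patch"):
            sample_multisite(focal_field, patch_layout, center=(2.0, 2.0))


class TestCorruption:
    def test_zero_jitter_identity(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout)
        assert np.array_equal(add_jitter(rec, 0.0, 1).times, rec.times)

    def test_jitter_amplitude_and_moments(self, focal_field, patch_layout):
        """eps is the full distribution width: |jitter| <= eps/2, SD = eps/(2*sqrt(3))."""
        rec = sample_multisite(focal_field, patch_layout, n_beats=7000)
        jit = add_jitter(rec, 0.10, 42).times - rec.times
        assert np.max(np.abs(jit)) <= 7.5
        assert np.std(jit) == pytest.approx(7.5 / np.sqrt(3), rel=0.02)

    def test_jitter_reproducible(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout, n_beats=3)
        assert np.array_equal(add_jitter(rec, 0.1, 7).times, add_jitter(rec, 0.1, 7).times)

    def test_jitter_fraction_bounds(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout)
        with pytest.raises(ValueError):
            add_jitter(rec, 0.6, 0)

    def test_remove_zero_identity(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout)
        assert remove_sites(rec, 0, 0) is rec

    def test_remove_six_leaves_nine(self, focal_field, patch_layout):
        rec = remove_sites(sample_multisite(focal_field, patch_layout), 6, 3)
        assert rec.n_sites == 9
        assert len(rec.site_labels) == 9

    def test_remove_too_many(self, focal_field, patch_layout):
        with pytest.raises(ValueError):
            remove_sites(sample_multisite(focal_field, patch_layout), 13, 0)

    def test_remove_reproducible(self, focal_field, patch_layout):
        rec = sample_multisite(focal_field, patch_layout)
        a, b = remove_sites(rec, 5, 11), remove_sites(rec, 5, 11)
        assert a.site_labels == b.site_labels
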