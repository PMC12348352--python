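"""String mechanics: initialization, projection update, reparameterization,
smoothing, and convergence to the minimum free-energy path."""

import numpy as np
import pytest

from fieldstring.constants import DEG
from fieldstring.geometry import OPPoint, wrap_deg
from fieldstring.sampler import SamplerConfig
from fieldstring.string_fts import (FTSConfig, StringState, _tangents,
                                    initialize_string, reparameterize,
                                    run_fts, smooth_string, unwrap_chain,
                                    update_images)


def straight_string(n=6, spacing=10.0):
    imgs = np.column_stack([spacing * np.arange(n), np.zeros(n)])
    return StringState(images=imgs)


class TestInitialize:
    def test_linear_interpolation_per_coordinate(self):
        s = initialize_string(OPPoint(0, 0), OPPoint(168.5, 153.0), 20)
        assert s.n_images == 20
        np.testing.assert_allclose(s.images[1], [168.5 / 19, 153.0 / 19],
                                   atol=1e-12)
        np.testing.assert_allclose(s.images[0], [0, 0], atol=0)
        np.testing.assert_allclose(s.images[-1], [168.5, 153.0], atol=1e-12)

    def test_shortest_arc_crosses_the_period_boundary(self):
        s = initialize_string(OPPoint(-170, 0), OPPoint(170, 0), 5)
        # shortest path goes through +-180, so image 2 sits at the wrap point
        assert s.images[2, 0] == pytest.approx(-180.0)
        assert abs(wrap_deg(s.images[1, 0] - (-175.0))) < 1e-9

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            initialize_string(OPPoint(10, 10), OPPoint(10 - 360, 10), 5)


class TestUpdate:
    def test_tangential_force_produces_no_motion(self):
        s = straight_string()
        forces = np.tile([3.0, 0.0], (6, 1))      # parallel to the string
        new = update_images(s, forces, [np.eye(2)] * 6, step=5.0)
        np.testing.assert_allclose(new.images, s.images, atol=1e-12)

    def test_perpendicular_force_moves_by_step_times_force(self):
        s = straight_string()
        f_perp = 0.5 / DEG                        # 0.5 kJ/mol/deg in rad units
        forces = np.tile([0.0, f_perp], (6, 1))
        new = update_images(s, forces, [np.eye(2)] * 6, step=2.0)
        np.testing.assert_allclose(new.images[1:-1, 1], -2.0 * 0.5, atol=1e-9)
        np.testing.assert_allclose(new.images[[0, -1]], s.images[[0, -1]])

    def test_metric_tensor_scales_displacement_linearly(self):
        s = straight_string()
        forces = np.tile([0.0, 0.1 / DEG], (6, 1))
        one = update_images(s, forces, [np.eye(2)] * 6, step=2.0)
        two = update_images(s, forces, [2 * np.eye(2)] * 6, step=2.0)
        d1 = two.images[1:-1, 1] - s.images[1:-1, 1]
        d0 = one.images[1:-1, 1] - s.images[1:-1, 1]
        np.testing.assert_allclose(d1, 2 * d0, atol=1e-9)

    def test_displacement_cap(self):
        s = straight_string()
        forces = np.tile([0.0, 100.0], (6, 1))
        new = update_images(s, forces, [np.eye(2)] * 6, step=50.0,
                            max_displacement=3.0)
        assert np.abs(new.images[1:-1, 1]).max() == pytest.approx(3.0)

    def test_projection_operator_identities(self):
        """P = I - t t^T is idempotent and annihilates the tangent."""
        rng = np.random.default_rng(0)
        imgs = np.cumsum(rng.uniform(2, 8, size=(8, 2)), axis=0)
        tang = _tangents(unwrap_chain(StringState(images=imgs).images))
        for t in tang:
            p = np.eye(2) - np.outer(t, t)
            np.testing.assert_allclose(p @ p, p, atol=1e-12)
            np.testing.assert_allclose(p @ t, 0, atol=1e-12)


class TestReparameterize:
    def test_uniform_straight_string_is_fixed_point(self):
        s = straight_string()
        r = reparameterize(s)
        np.testing.assert_allclose(r.images, s.images, atol=1e-12)
        assert abs(r.arc_lengths()[-1] - s.arc_lengths()[-1]) < 1e-9

    def test_nonuniform_straight_string_redistributed(self):
        imgs = np.array([[0.0, 0], [1.0, 0], [3.0, 0], [30.0, 0]])
        r = reparameterize(StringState(images=imgs))
        seg = np.diff(r.images[:, 0])
        np.testing.assert_allclose(seg, 10.0, atol=1e-5)
        # total length preserved on a straight string
        assert r.arc_lengths()[-1] == pytest.approx(30.0, abs=1e-9)

    def test_segments_equal_after_call(self):
        rng = np.random.default_rng(3)
        imgs = np.cumsum(rng.uniform(2, 15, size=(10, 2)), axis=0)
        r = reparameterize(StringState(images=imgs))
        seg = np.linalg.norm(np.diff(unwrap_chain(r.images), axis=0), axis=1)
        assert np.max(np.abs(seg - seg.mean())) <= 1e-6 * seg.mean() * 1.001

    def test_elbow_keeps_corner_image(self):
        """A right-angle elbow with equal arms: the interior images already
        sit at equal arc positions, including the corner itself."""
        imgs = np.array([[0.0, 0.0], [0.0, 10.0], [10.0, 10.0], [20.0, 10.0]])
        r = reparameterize(StringState(images=imgs))
        seg = np.linalg.norm(np.diff(r.images, axis=0), axis=1)
        np.testing.assert_allclose(seg, 10.0, atol=1e-6)
        np.testing.assert_allclose(r.images[[0, -1]], imgs[[0, -1]], atol=0)


class TestSmoothing:
    def test_zero_lambda_is_identity(self):
        s = straight_string()
        np.testing.assert_array_equal(smooth_string(s, 0.0).images, s.images)

    def test_collinear_string_is_fixed_point(self):
        s = straight_string()
        np.testing.assert_allclose(smooth_string(s, 0.3).images, s.images,
                                   atol=1e-12)

    def test_zigzag_amplitude_reduced_by_lambda(self):
        h = 4.0
        imgs = np.array([[0.0, 0], [10.0, h], [20.0, 0], [30.0, h], [40.0, 0]])
        sm = smooth_string(StringState(images=imgs), 0.1)
        assert sm.images[1, 1] == pytest.approx(0.9 * h, abs=1e-12)
        assert sm.images[2, 1] == pytest.approx(0.1 * h, abs=1e-12)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            smooth_string(straight_string(), 1.0)


class TestRunFTS:
    def test_quadratic_valley_converges_to_straight_mfep(self):
        """Two wells joined by a straight harmonic valley: the converged
        string lies on the straight line between the minima."""
        a_t = 0.05   # transverse stiffness, kJ/mol/deg^2

        def grad(pts):
            pts = np.atleast_2d(pts)
            g = np.empty_like(pts)
            # double well in phi with minima at +-60, harmonic valley in psi
            g[:, 0] = 4 * 1e-5 * pts[:, 0] * (pts[:, 0] ** 2 - 60.0 ** 2) / 60.0
            g[:, 1] = a_t * pts[:, 1]
            return g

        cfg = FTSConfig(n_images=12, max_iterations=80, string_step=10.0,
                        sampler=SamplerConfig(n_steps=8000, time_step=5e-4))
        res = run_fts(grad, None, cfg, seed=4,
                      endpoints=(OPPoint(-60, 0), OPPoint(60, 0)))
        assert res.converged
        rms = np.sqrt(np.mean(res.string.images[:, 1] ** 2))
        assert rms < 1.0

    def test_zero_noise_limit_recovers_reference_path(self, default_landscape):
        """With exact gradients as mean forces the string converges onto the
        built-in path within 1 degree RMS transverse distance."""
        cfg = FTSConfig(force_mode="exact")
        res = run_fts(default_landscape, None, cfg, seed=0)
        assert res.converged
        _, d2 = default_landscape.project(res.string.images)
        assert np.sqrt(d2.mean()) < 1.0

    def test_default_run_converges_near_saddle(self, fts_runs):
        """Sampled default runs: converged within the iteration budget and
        the equal-arc invariant holds for the final string."""
        for seed, (res, prof) in fts_runs.items():
            assert res.converged
            assert res.iterations_run <= 100
            seg = np.linalg.norm(
                np.diff(unwrap_chain(res.string.images), axis=0), axis=1)
            assert np.max(np.abs(seg - seg.mean())) <= 2e-6 * seg.mean()

    def test_displacement_shrinks_between_early_and_late_iterations(self, fts_runs):
        for seed, (res, _) in fts_runs.items():
            hist = np.asarray(res.displacement_history)
            assert np.median(hist[-5:]) < np.median(hist[:5])

    def test_same_seed_reproduces_run(self, default_landscape):
        cfg = FTSConfig(force_mode="exact", max_iterations=10)
        a = run_fts(default_landscape, None, cfg, seed=9)
        b = run_fts(default_landscape, None, cfg, seed=9)
        np.testing.assert_array_equal(a.string.images, b.string.images)
        assert a.displacement_history == b.displacement_history
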