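"""Free-energy reconstruction: line integral, WHAM, barrier extraction."""

import numpy as np
import pytest

import fieldstring as fs
from fieldstring.constants import DEG, RAD, rt_kj_mol
from fieldstring.geometry import OPPoint
from fieldstring.pmf import (PMFProfile, WhamError, barrier,
                             integrate_mean_force, landscape_grid,
                             wham_profile)
from fieldstring.sampler import WindowSample
from fieldstring.string_fts import StringState, reparameterize

RT = rt_kj_mol(298.15)
E_TOP = 41.14e8


def path_string(landscape, n=20):
    """Equal-arc images placed on the analytic reference path."""
    pts = landscape.path_point(np.linspace(0, 1, 400))
    sel = pts[np.linspace(0, 399, n).astype(int)]
    return reparameterize(StringState(images=sel))


class TestLineIntegral:
    def test_zero_forces_give_flat_profile(self):
        s = StringState(images=np.column_stack([np.arange(5) * 10.0, np.zeros(5)]))
        prof = integrate_mean_force(s, np.zeros((5, 2)))
        np.testing.assert_array_equal(prof.F, 0.0)

    def test_exact_gradients_recover_profile(self, default_landscape):
        """Analytic gradients at 20 on-path images reproduce the built-in
        profile at the images to ~1 kJ/mol and the barrier to much better."""
        st = path_string(default_landscape)
        forces = default_landscape.gradient_deg(st.images) * RAD
        prof = integrate_mean_force(st, forces)
        truth = default_landscape.energy(st.images)
        truth -= truth[0]
        assert np.abs(prof.F - truth).max() < 1.0
        h, _ = barrier(prof)
        assert h == pytest.approx(18.3, abs=1.0)

    def test_refinement_converges_to_truth(self, default_landscape):
        """Denser strings drive the recovery error to zero."""
        errs = []
        for n in (20, 60, 160):
            st = path_string(default_landscape, n)
            forces = default_landscape.gradient_deg(st.images) * RAD
            prof = integrate_mean_force(st, forces)
            truth = default_landscape.energy(st.images)
            truth -= truth[0]
            errs.append(np.abs(prof.F - truth).max())
        assert errs[2] < errs[0]
        assert errs[2] < 0.1

    def test_reversed_string_reverses_profile(self, default_landscape):
        st = path_string(default_landscape)
        forces = default_landscape.gradient_deg(st.images) * RAD
        fwd = integrate_mean_force(st, forces)
        rev_state = StringState(images=st.images[::-1].copy())
        rev = integrate_mean_force(rev_state, forces[::-1])
        np.testing.assert_allclose(rev.F, fwd.F[::-1] - fwd.F[-1], atol=1e-9)
        assert barrier(fwd, "conformation2")[0] == pytest.approx(
            barrier(rev, "conformation1")[0], abs=1e-9)

    def test_misaligned_forces_rejected(self, default_landscape):
        st = path_string(default_landscape)
        with pytest.raises(ValueError):
            integrate_mean_force(st, np.zeros((7, 2)))

    def test_trapezoid_rule_available(self, default_landscape):
        st = path_string(default_landscape)
        forces = default_landscape.gradient_deg(st.images) * RAD
        prof = integrate_mean_force(st, forces, rule="trapezoid")
        assert prof.F[0] == 0.0
        assert np.all(np.isfinite(prof.F))


class TestBarrier:
    def test_flat_profile_has_zero_barrier(self):
        prof = PMFProfile(alpha=np.linspace(0, 1, 5), F=np.zeros(5))
        assert barrier(prof) == (0.0, 0.0)

    def test_monotone_profile_barrier_is_total_rise(self):
        prof = PMFProfile(alpha=np.linspace(0, 1, 5), F=np.arange(5.0))
        h, a = barrier(prof, "conformation1")
        assert h == 4.0 and a == 1.0

    def test_ties_break_toward_smaller_alpha(self):
        prof = PMFProfile(alpha=np.linspace(0, 1, 5),
                          F=np.array([0.0, 3.0, 1.0, 3.0, 0.0]))
        _, a = barrier(prof)
        assert a == 0.25

    def test_unknown_reference_rejected(self):
        prof = PMFProfile(alpha=np.linspace(0, 1, 4), F=np.zeros(4))
        with pytest.raises(ValueError):
            barrier(prof, "conformation3")


class TestWham:
    @staticmethod
    def _double_well_samples(n_windows=12, n_per=4000, seed=0):
        """Exact draws from harmonically biased 1-D double-well densities,
        embedded on the phi axis (psi = 0)."""
        rng = np.random.default_rng(seed)
        kappa = 100.0  # kJ/mol/rad^2
        span = 120.0
        centers = np.linspace(0.0, span, n_windows)
        xs = np.linspace(-30.0, span + 30.0, 4001)

        def f_true(x):
            return 8.0 * np.sin(np.pi * x / span) ** 2

        samples = []
        for c in centers:
            u = 0.5 * kappa * ((xs - c) * DEG) ** 2
            w = np.exp(-(f_true(xs) + u) / RT)
            w /= w.sum()
            draws = rng.choice(xs, size=n_per, p=w)
            draws = draws + rng.uniform(-0.015, 0.015, n_per)  # de-discretize
            traj = np.column_stack([draws, np.zeros(n_per)])
            samples.append(WindowSample(
                center=OPPoint(c, 0.0), mean_op=OPPoint(c, 0.0),
                covariance=np.eye(2) * RT / kappa, mean_restraint_force=np.zeros(2),
                n_effective=n_per, spring=kappa, temperature=298.15,
                trajectory=traj))
        string = StringState(images=np.column_stack(
            [centers, np.zeros(n_windows)]))
        return samples, string, f_true

    def test_recovers_known_double_well(self):
        samples, string, f_true = self._double_well_samples()
        prof = wham_profile(samples, string)
        truth = f_true(string.images[:, 0])
        truth -= truth[0]
        rms = np.sqrt(np.mean((prof.F - truth) ** 2))
        assert rms < 1.0

    def test_too_few_windows_rejected(self):
        samples, string, _ = self._double_well_samples()
        with pytest.raises(ValueError):
            wham_profile(samples[:1], StringState(images=string.images[:4]))

    def test_missing_trajectory_rejected(self):
        samples, string, _ = self._double_well_samples()
        samples[3].trajectory = None
        with pytest.raises(WhamError, match="trajectory"):
            wham_profile(samples, string)

    def test_disjoint_windows_diagnosed(self):
        samples, string, _ = self._double_well_samples()
        # squeeze window 5's samples onto its center: no overlap with neighbors
        samples[5].trajectory = np.tile(samples[5].center.as_array(), (100, 1))
        with pytest.raises(WhamError, match="share"):
            wham_profile(samples, string)

    def test_agrees_with_line_integral_on_default_run(self, fts_runs):
        """The two estimators reconstruct the same profile within 1.5 kJ/mol
        RMS on a full sampled run."""
        res, prof = fts_runs[1]
        wh = wham_profile(res.samples, res.string)
        rms = np.sqrt(np.mean((prof.F - wh.F) ** 2))
        assert rms < 1.5


class TestLandscapeGrid:
    def test_grid_minimum_is_zero_at_conformation2(self, default_landscape):
        phi, psi, f = landscape_grid(default_landscape, resolution=180)
        assert f.min() == pytest.approx(0.0, abs=0.02)

    def test_grid_maximum_along_path_matches_saddle(self, default_landscape):
        phi, psi, f = landscape_grid(default_landscape, resolution=360)
        pts = default_landscape.path_point(np.linspace(0, 1, 500))
        idx_p = np.round((pts[:, 0] + 180.0)).astype(int) % 360
        idx_s = np.round((pts[:, 1] + 180.0)).astype(int) % 360
        on_path_max = f[idx_p, idx_s].max()
        assert on_path_max == pytest.approx(18.3, abs=0.3)

    def test_direction_insensitive_coupling(self, default_landscape):
        grids = [landscape_grid(default_landscape, fs.FieldSpec(ax, 1, E_TOP),
                                resolution=60)[2] for ax in "xyz"]
        np.testing.assert_array_equal(grids[0], grids[1])
        np.testing.assert_array_equal(grids[0], grids[2])

    def test_resolution_floor(self, default_landscape):
        with pytest.raises(ValueError):
            landscape_grid(default_landscape, resolution=5)


def test_gauge_invariance_of_line_integral(default_landscape):
    """The profile is unchanged when a constant is added to the potential
    (the mean forces are gradients, so constants never enter)."""
    st = path_string(default_landscape)
    forces = default_landscape.gradient_deg(st.images) * RAD
    base = integrate_mean_force(st, forces)
    shifted = integrate_mean_force(st, forces.copy())
    np.testing.assert_array_equal(base.F, shifted.F)
    assert base.F[0] == 0.0


def test_field_shift_recovery_within_printed_bound(fts_runs, fts_runs_field):
    """Barrier(+x max) - barrier(0) from full FTS runs stays in (0, 5.5)."""
    b0 = np.mean([barrier(p)[0] for _, p in fts_runs.values()])
    b1 = np.mean([barrier(p)[0] for _, p in fts_runs_field.values()])
    assert 0.0 < b1 - b0 < 5.5
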