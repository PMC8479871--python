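"""Contact-angle geometry, shape descriptors, domain tracking, velocity
decomposition, and population fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import bisect

from memwave.kinematics import (
    DomainTrack,
    FitError,
    area_ratio,
    area_ratio_exact,
    contact_angle,
    contact_angle_closed_form,
    decompose_velocity,
    population_fits,
    shape_descriptors,
    track_domain,
)
from memwave.reconstruction import SignalField
from memwave.synthetic_cell import SceneSpec, make_geometry, make_signal


class TestAreaRatio:
    def test_zero_contact(self):
        assert area_ratio(0.0) == 0.0

    def test_hemisphere_is_one_third(self):
        assert area_ratio(np.pi / 2) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_pi_over_6_symbolic(self):
        expect = 0.25 / (4.0 - (1.0 - np.sqrt(3) / 2))
        assert area_ratio(np.pi / 6) == pytest.approx(expect, abs=1e-12)

    def test_strictly_increasing(self):
        om = np.linspace(0, np.pi / 2, 200)
        r = area_ratio(om)
        assert np.all(np.diff(r) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            area_ratio(2.0)


class TestContactAngle:
    def test_endpoints(self):
        assert contact_angle(0.0) == 0.0
        assert contact_angle(1.0 / 3.0) == pytest.approx(np.pi / 2, abs=1e-9)

    def test_bisection_oracle_at_0p1(self):
        oracle = bisect(lambda om: area_ratio(om) - 0.1, 0.0, np.pi / 2, xtol=1e-12)
        assert contact_angle(0.1) == pytest.approx(oracle, abs=1e-9)

    def test_round_trip_identity(self):
        for om in np.linspace(0.0, np.pi / 2, 91):
            assert contact_angle(area_ratio(om)) == pytest.approx(om, abs=1e-8)

    def test_closed_form_matches_inversion(self):
        for ra in np.linspace(0.0, 1.0 / 3.0, 50):
            assert contact_angle_closed_form(ra) == pytest.approx(contact_angle(ra),
                                                                  abs=1e-8)

    def test_beyond_model_range_rejected(self):
        with pytest.raises(ValueError):
            contact_angle(0.4)

    def test_model_vs_exact_geometry_discrepancy_documented(self):
        # the model ratio and the exact truncated-sphere ratio agree at the
        # endpoints and differ by a bounded amount in between
        assert area_ratio_exact(0.0) == 0.0
        assert area_ratio_exact(np.pi / 2) == pytest.approx(1.0 / 3.0, abs=1e-12)
        om = np.linspace(0.1, np.pi / 2 - 0.1, 100)
        rel = np.abs(area_ratio(om) / area_ratio_exact(om) - 1)
        assert 0.0 < rel.max() < 0.15


class TestShapeDescriptors:
    def test_sphere_volume_closed_form(self):
        m = make_geometry(SceneSpec(radius=3.05, contact_angle=0.0, pattern="quiet"))
        g = shape_descriptors(m)
        assert g.volume_pl == pytest.approx(4 * np.pi * 3.05**3 / 3 / 1000, rel=0.01)
        assert g.omega == 0.0
        assert np.isnan(g.kappa_max)

    def test_synthetic_omega_recovered_within_5_degrees(self):
        m = make_geometry(SceneSpec(radius=2.0, contact_angle=np.pi / 3,
                                    pattern="quiet"))
        g = shape_descriptors(m)
        assert abs(np.degrees(g.omega) - 60.0) < 5.0

    def test_rim_curvature_exceeds_sphere_curvature(self, trunc_mesh):
        g = shape_descriptors(trunc_mesh)
        assert g.kappa_max > 1.0 / 2.5


class TestTrackDomain:
    def test_stationary_blob_stays_put(self, sphere_mesh):
        u = sphere_mesh.nodes / np.linalg.norm(sphere_mesh.nodes, axis=1)[:, None]
        c = u[0]
        act = np.exp(-0.5 * (np.arccos(np.clip(u @ c, -1, 1)) / 0.5) ** 2)
        sig = SignalField(values=np.tile(act[:, None], (1, 10)), dt=10.0)
        tr = track_domain(sig, sphere_mesh)
        assert tr.valid.all()
        spread = np.linalg.norm(tr.positions - tr.positions.mean(axis=0), axis=1)
        assert spread.max() < 1e-9

    @pytest.mark.parametrize("T", [120.0, 200.0, 300.0])
    def test_rotation_speed_recovered_within_5_percent(self, sphere_mesh, T):
        # closed form: circumference of the latitude band over the period
        theta_band = 0.3
        spec = SceneSpec(radius=3.0, pattern="horizontal_wave", period=T,
                         theta_band=theta_band, noise_sd=0.0, duration=2 * T)
        sig, _ = make_signal(sphere_mesh, spec)
        v = decompose_velocity(track_domain(sig, sphere_mesh), sphere_mesh)
        expect = 2 * np.pi * 3.0 * np.cos(theta_band) / (T / 60.0)
        assert abs(v.v_mean / expect - 1) < 0.05

    def test_antipodal_tie_flagged_ambiguous(self, sphere_mesh):
        u = sphere_mesh.nodes / np.linalg.norm(sphere_mesh.nodes, axis=1)[:, None]
        c = u[0]
        act = (np.exp(-0.5 * (np.arccos(np.clip(u @ c, -1, 1)) / 0.4) ** 2)
               + np.exp(-0.5 * (np.arccos(np.clip(-u @ c, -1, 1)) / 0.4) ** 2))
        sig = SignalField(values=np.tile(act[:, None], (1, 6)), dt=10.0)
        tr = track_domain(sig, sphere_mesh)
        assert tr.ambiguous[tr.valid].all()

    def test_flat_signal_yields_empty_track(self, sphere_mesh):
        sig = SignalField(values=np.ones((sphere_mesh.n_nodes, 8)), dt=10.0)
        tr = track_domain(sig, sphere_mesh)
        assert tr.n_valid == 0


class TestDecomposeVelocity:
    @staticmethod
    def _circle_track(lat=0.4, R=3.0, n=12, meridional=False):
        ang = np.linspace(0, 1.2, n)
        if meridional:
            pos = R * np.column_stack([np.cos(ang), np.zeros(n), np.sin(ang)])
        else:
            pos = R * np.column_stack([np.cos(lat) * np.cos(ang),
                                       np.cos(lat) * np.sin(ang),
                                       np.full(n, np.sin(lat))])
        return DomainTrack(times=10.0 * np.arange(n), positions=pos,
                           valid=np.ones(n, bool), ambiguous=np.zeros(n, bool),
                           dt=10.0)

    def test_purely_azimuthal_rotation_flagged(self, sphere_mesh):
        v = decompose_velocity(self._circle_track(), sphere_mesh)
        assert v.v_a_flagged
        assert v.v_a == np.inf
        assert v.v_theta == pytest.approx(0.0, abs=1e-9)

    def test_purely_meridional_rotation(self, sphere_mesh):
        v = decompose_velocity(self._circle_track(meridional=True), sphere_mesh)
        assert not v.v_a_flagged
        assert v.v_a == pytest.approx(0.0, abs=1e-9)

    def test_speed_bounds_components(self, sphere_mesh):
        spec = SceneSpec(radius=3.0, pattern="isotropic_domain", period=200.0,
                         noise_sd=0.0, duration=400.0, seed=33)
        sig, _ = make_signal(sphere_mesh, spec)
        v = decompose_velocity(track_domain(sig, sphere_mesh), sphere_mesh)
        assert v.v_theta <= v.v_mean + 1e-9
        assert v.v_phi <= v.v_mean + 1e-9

    def test_isotropic_rotations_give_unit_ratio(self, sphere_mesh):
        vas = []
        for seed in range(30):
            spec = SceneSpec(radius=3.0, pattern="isotropic_domain", period=200.0,
                             noise_sd=0.0, duration=600.0, seed=seed)
            sig, _ = make_signal(sphere_mesh, spec)
            v = decompose_velocity(track_domain(sig, sphere_mesh), sphere_mesh)
            vas.append(v.v_a)
        assert np.mean(vas) == pytest.approx(1.0, abs=0.15)

    def test_too_few_steps_rejected(self, sphere_mesh):
        tr = self._circle_track(n=4)
        with pytest.raises(ValueError):
            decompose_velocity(tr, sphere_mesh)


class TestPopulationFits:
    def test_exact_linear_composition_recovered(self):
        # v_a and r_a both exactly linear in delta_alpha: eliminating
        # delta_alpha must return the exact composition
        rng = np.random.default_rng(17)
        da = rng.uniform(-0.5, 0.5, 40)
        table = pd.DataFrame({"delta_alpha": da,
                              "r_a": 0.3 * da + 0.12,
                              "v_a": -2.0 * da + 1.5})
        fit = population_fits(table)
        # v_a = m r_a + n0 with m = -2/0.3, n0 = 1.5 + 2*0.12/0.3... composed:
        m_true = -2.0 / 0.3
        n0_true = 1.5 - m_true * 0.12
        assert fit.slope == pytest.approx(m_true, abs=1e-6)
        assert fit.intercept == pytest.approx(n0_true, abs=1e-6)

    def test_intercept_near_unity_for_spherical_cells(self, sphere_mesh):
        # simulated population whose adhesion vanishes: the intercept of
        # v_a = m r_a + n0 at r_a = 0 recovers the isotropic ratio ~1
        rows = []
        for seed in range(16):
            spec = SceneSpec(radius=3.0, pattern="isotropic_domain", period=200.0,
                             noise_sd=0.0, duration=600.0, seed=100 + seed)
            sig, _ = make_signal(sphere_mesh, spec)
            v = decompose_velocity(track_domain(sig, sphere_mesh), sphere_mesh)
            # nearly-spherical cells: r_a ~ 0 with a small spread, and a
            # delta_alpha spread uncorrelated with v_a
            ra = 0.002 * (seed % 4)
            rows.append({"delta_alpha": 0.05 * (seed % 8) - 0.2 + 0.1 * ra,
                         "r_a": ra, "v_a": v.v_a})
        fit = population_fits(pd.DataFrame(rows))
        assert fit.intercept == pytest.approx(1.0, abs=0.25)

    def test_single_bin_population_rejected(self):
        table = pd.DataFrame({"delta_alpha": np.zeros(10),
                              "r_a": np.full(10, 0.1),
                              "v_a": np.ones(10)})
        with pytest.raises(FitError):
            population_fits(table)

    def test_too_few_cells_rejected(self):
        table = pd.DataFrame({"delta_alpha": [0.1, 0.2], "r_a": [0.1, 0.2],
                              "v_a": [1.0, 1.1]})
        with pytest.raises(FitError):
            population_fits(table)
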