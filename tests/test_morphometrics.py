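import numpy as np
import pytest

from nucleophase.dynamics import FieldState, Trajectory
from nucleophase.free_energy import FreeEnergyParams
from nucleophase.morphometrics import (centroid_eccentricity, classify,
                                       flow_metrics, interface_bands,
                                       morphology_report, segment_dense,
                                       total_R_eff, vacuole_radius)

import pandas as pd


def disk_field(domain, center, radius, phi_in=0.63, phi_out=0.13):
    r = np.hypot(domain.x - center[0], domain.y - center[1])
    return np.where(r < radius, phi_in, phi_out)


def annulus_field(domain, r_in, r_out, phi_in=0.63, phi_out=0.13):
    r = np.hypot(domain.x, domain.y)
    return np.where((r > r_in) & (r < r_out), phi_in, phi_out)


class TestSegmentDense:
    def test_threshold_is_binodal_midpoint(self, fe_default):
        assert fe_default.threshold == pytest.approx(0.4)

    def test_uniform_dilute_has_no_components(self, domain_test,
                                              fe_default):
        phi = np.full(domain_test.n_cells, 0.13)
        _, regions = segment_dense(phi, domain_test, fe_default)
        assert regions == []
        assert total_R_eff(phi, domain_test, fe_default) == 0.0

    def test_ideal_disk_radius_recovered(self, domain_test, fe_default):
        phi = disk_field(domain_test, (0.0, 0.0), 4.0)
        _, regions = segment_dense(phi, domain_test, fe_default)
        assert len(regions) == 1
        assert regions[0]["R_eff"] == pytest.approx(4.0,
                                                    abs=domain_test.dx)

    def test_two_disks_two_components(self, domain_test, fe_default):
        phi = np.maximum(disk_field(domain_test, (-6.0, 0.0), 2.0),
                         disk_field(domain_test, (6.0, 0.0), 3.0))
        _, regions = segment_dense(phi, domain_test, fe_default)
        assert len(regions) == 2
        # sorted by area: larger disk first, centroids recovered
        assert regions[0]["centroid"][0] == pytest.approx(6.0, abs=0.2)
        assert regions[1]["centroid"][0] == pytest.approx(-6.0, abs=0.2)


class TestVacuoleRadius:
    def test_solid_disk_has_no_vacuole(self, domain_test, fe_default):
        phi = disk_field(domain_test, (0.0, 0.0), 4.0)
        assert vacuole_radius(phi, domain_test, fe_default) is None

    def test_annulus_inner_radius_recovered(self, domain_test,
                                            fe_default):
        phi = annulus_field(domain_test, 3.0, 6.0)
        v = vacuole_radius(phi, domain_test, fe_default)
        assert v == pytest.approx(3.0, abs=domain_test.dx)

    def test_fully_dilute_field_has_no_vacuole(self, domain_test,
                                               fe_default):
        phi = np.full(domain_test.n_cells, 0.1)
        assert vacuole_radius(phi, domain_test, fe_default) is None

    def test_open_crescent_is_not_a_vacuole(self, domain_test,
                                            fe_default):
        # a dilute bay connected to the outside must not count
        phi = annulus_field(domain_test, 3.0, 6.0)
        channel = (np.abs(domain_test.y) < 1.0) & (domain_test.x > 0)
        phi[channel] = 0.13
        assert vacuole_radius(phi, domain_test, fe_default) is None


class TestInterfaceBands:
    def test_uniform_stable_field_zero_bands(self, domain_test,
                                             fe_default):
        phi_P = np.full(domain_test.n_cells, 0.13)
        phi_R = np.zeros(domain_test.n_cells)
        assert interface_bands(phi_P, phi_R, fe_default,
                               domain_test) == 0

    def test_sharp_droplet_single_band(self, domain_test, fe_default):
        # step profile traverses the spinodal once on the way out
        phi_P = disk_field(domain_test, (0.0, 0.0), 4.0)
        phi_R = np.zeros(domain_test.n_cells)
        assert interface_bands(phi_P, phi_R, fe_default,
                               domain_test) == 1

    def test_annulus_dual_bands(self, domain_test, fe_default):
        phi_P = annulus_field(domain_test, 3.0, 6.0)
        phi_R = np.zeros(domain_test.n_cells)
        assert interface_bands(phi_P, phi_R, fe_default,
                               domain_test) == 2


class TestCentroidEccentricity:
    def test_radially_symmetric_profile_zero_ecc(self, domain_test,
                                                 fe_default):
        phi = disk_field(domain_test, (0.0, 0.0), 4.0)
        (cx, cy), e = centroid_eccentricity(phi, domain_test, fe_default)
        assert abs(cx) < 1e-10 and abs(cy) < 1e-10
        assert e == pytest.approx(0.0, abs=1e-20)

    def test_moment_arithmetic_on_anisotropic_gaussian(self, domain_test):
        # I_xx = 3, I_yy = 1, I_xy = 0  ->  e = (2/4)^2 = 0.25
        w = np.exp(-domain_test.x ** 2 / (2 * 3.0)
                   - domain_test.y ** 2 / (2 * 1.0))
        (_, _), e = centroid_eccentricity(w, domain_test, mass="raw")
        assert e == pytest.approx(0.25, rel=1e-3)

    def test_translation_moves_centroid_not_ecc(self, domain_test,
                                                fe_default):
        a = disk_field(domain_test, (0.0, 0.0), 3.0)
        b = disk_field(domain_test, (4.0, -2.0), 3.0)
        (ca, _), ea = centroid_eccentricity(a, domain_test, fe_default)
        (cb, cyb), eb = centroid_eccentricity(b, domain_test, fe_default)
        assert cb == pytest.approx(4.0, abs=0.1)
        assert cyb == pytest.approx(-2.0, abs=0.1)
        assert eb == pytest.approx(ea, abs=1e-3)

    def test_rotation_invariance_of_default_form(self, domain_test):
        rng = np.random.default_rng(7)
        grid = domain_test.to_grid(
            rng.random(domain_test.n_cells), fill=0.0)
        rotated = np.rot90(grid)
        _, e0 = centroid_eccentricity(grid[domain_test.mask],
                                      domain_test, mass="raw")
        _, e90 = centroid_eccentricity(rotated[domain_test.mask],
                                       domain_test, mass="raw")
        assert e90 == pytest.approx(e0, rel=1e-10)

    def test_literal_formula_agrees_when_cross_moment_zero(self,
                                                           domain_test):
        w = np.exp(-domain_test.x ** 2 / 6.0 - domain_test.y ** 2 / 2.0)
        _, e_inv = centroid_eccentricity(w, domain_test, mass="raw")
        _, e_lit = centroid_eccentricity(w, domain_test, mass="raw",
                                         formula="literal")
        assert e_lit == pytest.approx(e_inv, abs=1e-6)

    def test_zero_mass_rejected(self, domain_test, fe_default):
        with pytest.raises(ValueError):
            centroid_eccentricity(np.zeros(domain_test.n_cells),
                                  domain_test, fe_default)


def synthetic_moving_trajectory(domain, speed, n_snaps=6, dt_snap=10.0,
                                R=3.0):
    """Disk translating at constant speed along +x (synthetic stand-in
    for a flow trajectory)."""
    snaps = []
    for i in range(n_snaps):
        t = i * dt_snap
        x0 = -8.0 + speed * t
        snaps.append(FieldState(t, disk_field(domain, (x0, 0.0), R),
                                np.zeros(domain.n_cells)))
    return Trajectory(snapshots=snaps, scalars=pd.DataFrame())


class TestFlowMetrics:
    def test_stationary_droplet_zero_velocity(self, domain_test,
                                              fe_default, kin_default):
        traj = synthetic_moving_trajectory(domain_test, 0.0)
        fm = flow_metrics(traj, fe_default, kin_default, domain_test,
                          R_c=4.0)
        assert fm["peak_dimensionless_velocity"] == pytest.approx(0.0,
                                                                  abs=1e-6)

    def test_dimensionless_velocity_arithmetic(self, domain_test,
                                               fe_default, kin_default):
        # speed 0.39, R_c = 4, D_p = 1.56  ->  v R_c / D_p = 1.0
        traj = synthetic_moving_trajectory(domain_test, 0.039,
                                           dt_snap=10.0)
        fm = flow_metrics(traj, fe_default, kin_default, domain_test,
                          R_c=4.0)
        assert fm["D_p"] == pytest.approx(1.56, rel=1e-12)
        assert fm["peak_dimensionless_velocity"] == pytest.approx(
            0.1, rel=0.15)

    def test_dissolved_condensate_truncates_series(self, domain_test,
                                                   fe_default,
                                                   kin_default):
        traj = synthetic_moving_trajectory(domain_test, 0.0, n_snaps=4)
        traj.snapshots[2].phi_P = np.full(domain_test.n_cells, 0.13)
        traj.snapshots[3].phi_P = np.full(domain_test.n_cells, 0.13)
        fm = flow_metrics(traj, fe_default, kin_default, domain_test)
        assert fm["lost"]
        assert len(fm["t"]) == 2


class TestClassify:
    def test_static_droplet_at_site(self, domain_test, fe_default,
                                    kin_default):
        from nucleophase.geometry import GeneCluster
        traj = synthetic_moving_trajectory(domain_test, 0.0)
        cl = [GeneCluster((-8.0, 0.0), 2.0, 1.0)]
        morphology, dynamics = classify(traj, cl, fe_default,
                                        kin_default, domain_test,
                                        R_c=4.0)
        assert morphology == "spherical"
        assert dynamics == "at_site"

    def test_moving_droplet_flows_to_cluster(self, domain_test,
                                             fe_default, kin_default):
        from nucleophase.geometry import GeneCluster
        traj = synthetic_moving_trajectory(domain_test, 0.2)
        cl = [GeneCluster((4.0, 0.0), 2.0, 1.0)]
        _, dynamics = classify(traj, cl, fe_default, kin_default,
                               domain_test, R_c=3.0)
        assert dynamics == "flow"

    def test_dissolved_final_state(self, domain_test, fe_default,
                                   kin_default):
        from nucleophase.geometry import GeneCluster
        traj = synthetic_moving_trajectory(domain_test, 0.0, n_snaps=3)
        for s in traj.snapshots:
            s.phi_P = np.full(domain_test.n_cells, 0.13)
        morphology, _ = classify(traj, [GeneCluster((0.0, 0.0), 2.0,
                                                    1.0)],
                                 fe_default, kin_default, domain_test)
        assert morphology == "dissolved"

    def test_annulus_classified_as_vacuole(self, domain_test, fe_default,
                                           kin_default):
        from nucleophase.geometry import GeneCluster
        snaps = [FieldState(float(t), annulus_field(domain_test, 3.0,
                                                    6.0),
                            np.zeros(domain_test.n_cells))
                 for t in (0.0, 10.0, 20.0)]
        traj = Trajectory(snapshots=snaps, scalars=pd.DataFrame())
        morphology, _ = classify(traj, [GeneCluster((0.0, 0.0), 4.0,
                                                    1.0)],
                                 fe_default, kin_default, domain_test)
        assert morphology == "vacuole"




class TestMorphologyReport:
    def test_empty_field_report(self, domain_test, fe_default):
        state = FieldState(0.0, np.full(domain_test.n_cells, 0.1),
                           np.zeros(domain_test.n_cells))
        rep = morphology_report(state, domain_test, fe_default)
        assert rep.R_eff == 0.0
        assert rep.n_components == 0
        assert rep.centroid is None

    def test_droplet_report(self, domain_test, fe_default):
        state = FieldState(0.0, disk_field(domain_test, (0.0, 0.0), 4.0),
                           np.zeros(domain_test.n_cells))
        rep = morphology_report(state, domain_test, fe_default)
        assert rep.R_eff == pytest.approx(4.0, abs=0.2)
        assert rep.vacuole_radius is None
        assert rep.n_interfaces == 1
        assert rep.n_components == 1
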