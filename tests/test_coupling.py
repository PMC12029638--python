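import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibflow.coupling import (Particle, Simulation, advect_nodes, delta3,
                             hat_phi, interpolate_velocity, place_particles,
                             spread_forces)
from ibflow.geometry import straight_vessel
from ibflow.lbm import DistributionField
from ibflow.membrane import MembraneParams, icosphere
from ibflow.units import ConfigError

PARAMS = MembraneParams(ks=1e-3, kalpha=1e-3, kB=0.0, kA=1e-3, kV=1e-3)


class TestKernel:
    @given(st.floats(-3, 3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_hat_partition_of_unity(self, x):
        lo = np.floor(x)
        assert hat_phi(x - lo) + hat_phi(x - lo - 1) == pytest.approx(1.0)

    def test_hat_support_and_positivity(self):
        r = np.linspace(-2, 2, 41)
        phi = hat_phi(r)
        assert np.all(phi >= 0)
        assert np.all(phi[np.abs(r) >= 1] == 0)

    def test_delta_is_tensor_product(self, rng):
        off = rng.uniform(-1, 1, size=(5, 3))
        assert np.allclose(delta3(off),
                           hat_phi(off[:, 0]) * hat_phi(off[:, 1]) * hat_phi(off[:, 2]))


class TestSpreadInterp:
    def test_on_site_node_spreads_to_one_site(self):
        fld = DistributionField((6, 6, 6))
        spread_forces(np.array([[2.0, 3.0, 4.0]]), np.array([[1.0, -2.0, 0.5]]), fld)
        assert fld.Fx[2, 3, 4] == pytest.approx(1.0)
        assert fld.Fy[2, 3, 4] == pytest.approx(-2.0)
        assert fld.Fx.sum() == pytest.approx(1.0)
        assert np.count_nonzero(fld.Fx) == 1

    def test_cell_center_node_spreads_eighths(self):
        fld = DistributionField((6, 6, 6))
        spread_forces(np.array([[2.5, 2.5, 2.5]]), np.array([[8.0, 0.0, 0.0]]), fld)
        assert np.allclose(fld.Fx[2:4, 2:4, 2:4], 1.0)
        assert fld.Fx.sum() == pytest.approx(8.0)

    def test_total_force_conserved_random_cloud(self, rng):
        fld = DistributionField((8, 7, 9))
        pos = rng.uniform(0, [8, 7, 9], size=(40, 3))
        frc = rng.standard_normal((40, 3))
        spread_forces(pos, frc, fld)
        total = np.array([fld.Fx.sum(), fld.Fy.sum(), fld.Fz.sum()])
        assert np.allclose(total, frc.sum(axis=0), atol=1e-12)

    def test_uniform_flow_interpolates_exactly(self, rng):
        u = np.broadcast_to(np.array([0.01, -0.02, 0.03]), (6, 6, 6, 3)).copy()
        pos = rng.uniform(1, 5, size=(10, 3))
        v = interpolate_velocity(u, pos)
        assert np.allclose(v, [0.01, -0.02, 0.03], atol=1e-14)

    def test_linear_shear_field_reproduced(self, rng):
        # hat kernel reproduces linear fields: u_x = gamma * y exactly
        gamma = 0.01
        y = np.arange(8)
        u = np.zeros((6, 8, 6, 3))
        u[..., 0] = gamma * y[None, :, None]
        pos = rng.uniform([1, 1, 1], [5, 6, 5], size=(20, 3))
        v = interpolate_velocity(u, pos)
        assert np.allclose(v[:, 0], gamma * pos[:, 1], atol=1e-14)
        assert np.allclose(v[:, 1:], 0.0, atol=1e-14)

    def test_spread_interp_adjointness(self, rng):
        # <spread(F), u>_grid = <F, interp(u)>_nodes
        shape = (7, 6, 8)
        fld = DistributionField(shape)
        pos = rng.uniform(0, [7, 6, 8], size=(25, 3))
        frc = rng.standard_normal((25, 3))
        u = rng.standard_normal(shape + (3,))
        spread_forces(pos, frc, fld)
        lhs = (fld.Fx * u[..., 0] + fld.Fy * u[..., 1] + fld.Fz * u[..., 2]).sum()
        rhs = (frc * interpolate_velocity(u, pos)).sum()
        assert lhs == pytest.approx(rhs, rel=1e-12)

    @pytest.mark.parametrize("kernel", ["cosine"])
    def test_cosine_kernel_also_conserves(self, rng, kernel):
        fld = DistributionField((9, 9, 9))
        pos = rng.uniform(2, 7, size=(15, 3))
        frc = rng.standard_normal((15, 3))
        spread_forces(pos, frc, fld, kernel=kernel)
        total = np.array([fld.Fx.sum(), fld.Fy.sum(), fld.Fz.sum()])
        assert np.allclose(total, frc.sum(axis=0), atol=1e-12)


class TestAdvect:
    def test_zero_velocity_fixed(self):
        pos = np.array([[1.0, 2.0, 3.0]])
        assert np.array_equal(advect_nodes(pos, np.zeros((1, 3))), pos)

    def test_uniform_velocity_displacement(self):
        pos = np.zeros((1, 3))
        u = np.array([[0.1, 0.0, -0.2]])
        for _ in range(5):
            pos = advect_nodes(pos, u)
        assert np.allclose(pos, [[0.5, 0.0, -1.0]])

    def test_periodic_wrap_in_x(self):
        pos = advect_nodes(np.array([[19.5, 1.0, 1.0]]),
                           np.array([[1.0, 0.0, 0.0]]), wrap_x=20.0)
        assert pos[0, 0] == pytest.approx(0.5)


class TestPlacement:
    GEO = straight_vessel(30, 20, (30, 24, 24))
    SPECS = [
        {"kind": "dc", "radius": 2.0, "faces": 120, "params": PARAMS},
        {"kind": "rbc", "radius": 4.0, "faces": 120, "params": PARAMS},
        {"kind": "dc", "radius": 2.0, "faces": 120, "params": PARAMS},
    ]

    def test_deterministic_given_seed(self):
        a = place_particles(self.GEO, self.SPECS, seed=42)
        b = place_particles(self.GEO, self.SPECS, seed=42)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.mesh.vertices, pb.mesh.vertices)
        c = place_particles(self.GEO, self.SPECS, seed=43)
        assert not np.allclose(a[0].mesh.vertices, c[0].mesh.vertices)

    def test_wall_clearance(self):
        for p, spec in zip(place_particles(self.GEO, self.SPECS, seed=7),
                           self.SPECS):
            c = p.mesh.centroid()
            assert self.GEO.radial_distance(c) <= \
                self.GEO.radius - spec["radius"] - 1.0 + 1e-6

    def test_no_overlap_at_release(self):
        parts = place_particles(self.GEO, self.SPECS, seed=11)
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                dist = np.linalg.norm(parts[i].mesh.centroid()
                                      - parts[j].mesh.centroid())
                assert dist > parts[i].radius + parts[j].radius

    def test_impossible_placement_raises(self):
        with pytest.raises(ConfigError):
            place_particles(self.GEO, [{"kind": "dc", "radius": 12.0,
                                        "faces": 120, "params": PARAMS}], seed=1)


class TestCoupledStep:
    def test_no_particles_reduces_to_bare_lbm(self):
        shape = (8, 8, 8)
        a = DistributionField(shape)
        b = DistributionField(shape)
        sim = Simulation(a, tau=0.8, body_accel=(1e-5, 0, 0), guard_every=0)
        for _ in range(10):
            sim.coupled_step()
        for _ in range(10):
            b.clear_forces()
            b.add_body_force(1e-5)
            b.step(0.8)
        assert np.array_equal(a.f, b.f)

    def test_momentum_audit(self):
        # periodic box: per-step change of bare fluid momentum equals the
        # total applied impulse (body force + spread membrane forces)
        shape = (16, 16, 16)
        fld = DistributionField(shape)
        mesh = icosphere(3.0, 80).translate((8.0, 8.0, 8.0))
        mesh.vertices *= np.array([1.15, 0.9, 1.0])          # pre-strained
        mesh_params = MembraneParams(0.05, 0.05, 0.0, 0.01, 0.01)
        ax = 2e-6
        sim = Simulation(fld, tau=0.9, particles=[Particle(mesh, mesh_params)],
                         body_accel=(ax, 0.0, 0.0), guard_every=0)
        for _ in range(20):
            p_before = fld.total_momentum()
            sim.coupled_step()
            impulse = np.array([fld.Fx.sum(), fld.Fy.sum(), fld.Fz.sum()])
            p_after = fld.total_momentum()
            err = np.linalg.norm(p_after - p_before - impulse)
            assert err <= 1e-8 * max(np.linalg.norm(impulse), 1e-12)

    def test_centered_capsule_in_symmetric_shear_stays_centered(self):
        # stiff capsule at the center plane of a symmetric Couette flow:
        # symmetry admits no lateral drift
        n = 24
        solid = np.zeros((n, n, n), dtype=bool)
        solid[:, 0, :] = True
        solid[:, -1, :] = True
        fld = DistributionField((n, n, n), solid=solid)
        fld.wall_ux[:, 0, :] = -0.02
        fld.wall_ux[:, -1, :] = 0.02
        center = ((n - 1) / 2,) * 3
        mesh = icosphere(4.0, 320).translate(center)
        stiff = MembraneParams(0.5, 0.5, 0.0, 0.1, 0.5)
        sim = Simulation(fld, tau=1.0, particles=[Particle(mesh, stiff)],
                         guard_every=0)
        for _ in range(1000):
            sim.coupled_step()
        drift = mesh.centroid() - np.array(center)
        assert np.abs(drift[1:]).max() < 1e-3     # no cross-flow drift
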