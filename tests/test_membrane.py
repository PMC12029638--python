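import numpy as np
import pytest

from conftest import fd_membrane_force
from ibflow.membrane import (BiconcaveSpec, MembraneParams, MeshDegenerateError,
                             TriMesh, area_volume_energy, bending_energy,
                             biconcave_mesh, icosphere, membrane_forces,
                             skalak_energy, strain_invariants, total_energy)


class TestIcosphere:
    @pytest.mark.parametrize("nf,n_expected", [(20, 12), (80, 42), (120, 62),
                                               (320, 162), (480, 242)])
    def test_closed_mesh_counts(self, nf, n_expected):
        # Euler's formula for a closed triangulated sphere: 2N = Nf + 4
        mesh = icosphere(1.0, nf)
        assert mesh.n_faces == nf
        assert mesh.n_vertices == n_expected
        assert 2 * mesh.n_vertices == mesh.n_faces + 4
        assert 2 * len(mesh.edges) == 3 * mesh.n_faces

    def test_area_and_volume_approach_sphere(self):
        # inscribed polyhedra: area/volume below the sphere's, converging
        # from ~5% low at Nf=120 to ~1% low at Nf=480
        a120 = icosphere(2.0, 120)
        a480 = icosphere(2.0, 480)
        sphere_area = 4 * np.pi * 4.0
        assert a120.area() == pytest.approx(sphere_area, rel=0.06)
        assert a480.area() == pytest.approx(sphere_area, rel=0.02)
        assert abs(a480.area() - sphere_area) < abs(a120.area() - sphere_area)
        assert a480.volume() == pytest.approx(4 * np.pi / 3 * 8.0, rel=0.03)

    def test_outward_orientation(self):
        assert icosphere(1.0, 320).volume() > 0


class TestBiconcave:
    def test_rim_and_dimple(self):
        spec = BiconcaveSpec(R=3.5)
        mesh = biconcave_mesh(spec, 480)
        v = mesh.vertices
        r = np.hypot(v[:, 0], v[:, 2])
        assert r.max() == pytest.approx(3.5, rel=1e-6)     # disk radius = R
        # near the poles the half-thickness is R*C0/2
        pole = np.argmin(r)
        assert abs(v[pole, 1]) == pytest.approx(3.5 * 0.207 / 2, rel=0.05)
        # rim vertices (r = R) lie on the midplane
        rim = np.isclose(r, 3.5, atol=1e-9)
        assert np.allclose(v[rim, 1], 0.0, atol=1e-12)

    def test_mirror_symmetry_and_euler(self):
        mesh = biconcave_mesh(BiconcaveSpec(R=3.0), 120)
        assert 2 * mesh.n_vertices == mesh.n_faces + 4
        mirrored = mesh.vertices * np.array([1.0, -1.0, 1.0])
        # every vertex has a mirror partner
        d = np.linalg.norm(mirrored[:, None, :] - mesh.vertices[None, :, :],
                           axis=-1).min(axis=1)
        assert d.max() < 1e-9

    def test_thinner_than_sphere(self):
        mesh = biconcave_mesh(BiconcaveSpec(R=3.5), 480)
        assert mesh.volume() < 4 * np.pi / 3 * 3.5**3 * 0.5


class TestSkalakEnergy:
    def test_undeformed_zero(self, small_sphere, generic_params):
        E, (I1, I2) = skalak_energy(small_sphere, generic_params)
        assert E == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(I1, 0.0, atol=1e-12)
        assert np.allclose(I2, 0.0, atol=1e-12)

    def test_uniform_stretch_invariants(self, small_sphere):
        # isotropic stretch of all vertices: l1 = l2 = 1.1 on every face
        lam = 1.1
        small_sphere.vertices = small_sphere.vertices * lam
        I1, I2 = strain_invariants(small_sphere)
        assert np.allclose(I1, 2 * lam**2 - 2, rtol=1e-12)     # 0.42
        assert np.allclose(I2, lam**4 - 1, rtol=1e-12)         # 0.4641
        ks, ka = 2.0, 3.0
        E, _ = skalak_energy(small_sphere, MembraneParams(ks, ka, 0, 0, 0))
        eps = ks / 12 * (0.42**2 + 2 * 0.42 - 2 * 0.4641) + ka / 12 * 0.4641**2
        assert E == pytest.approx(eps * small_sphere.A0, rel=1e-10)

    def test_area_preserving_shear_has_zero_I2(self, small_sphere):
        # act with an in-plane (l, 1/l) map on one face's plane
        mesh = small_sphere
        f0 = mesh.faces[0]
        v0, v1, v2 = mesh.vertices[f0]
        e1 = v1 - v0
        e1 /= np.linalg.norm(e1)
        n = np.cross(v1 - v0, v2 - v0)
        n /= np.linalg.norm(n)
        e2 = np.cross(n, e1)
        lam = 1.3
        M = (lam * np.outer(e1, e1) + (1 / lam) * np.outer(e2, e2)
             + np.outer(n, n))
        mesh.vertices = mesh.vertices @ M.T
        I1, I2 = strain_invariants(mesh)
        assert I2[0] == pytest.approx(0.0, abs=1e-10)
        assert I1[0] == pytest.approx(lam**2 + lam**-2 - 2, rel=1e-10)

    def test_degenerate_face_named(self, small_sphere):
        tri = small_sphere.faces[3]
        small_sphere.vertices[tri[1]] = small_sphere.vertices[tri[0]]
        small_sphere.vertices[tri[2]] = small_sphere.vertices[tri[0]]
        with pytest.raises(MeshDegenerateError, match=r"face \d+"):
            skalak_energy(small_sphere, MembraneParams(1, 1, 0, 0, 0))


class TestBendingEnergy:
    def test_reference_zero(self, small_sphere):
        assert bending_energy(small_sphere, 1.0) == pytest.approx(0.0, abs=1e-16)

    def test_dihedral_tracks_rotation_about_edge(self, small_sphere):
        # rotate the mesh "cap" vertex about one edge axis: that edge's
        # dihedral changes by exactly the rotation angle
        mesh = small_sphere
        e = mesh.edges[0]
        p0, p1, p3 = mesh.vertices[e[0]], mesh.vertices[e[1]], mesh.vertices[e[3]]
        axis = (p1 - p0) / np.linalg.norm(p1 - p0)
        phi = 0.4
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rot = np.eye(3) + np.sin(phi) * K + (1 - np.cos(phi)) * K @ K
        before = mesh.dihedral_angles()[0]
        mesh.vertices[e[3]] = p0 + Rot @ (p3 - p0)
        after = mesh.dihedral_angles()[0]
        assert abs(abs(after - before) - phi) < 1e-12

    def test_energy_matches_angle_sum(self, small_sphere, rng):
        mesh = small_sphere
        mesh.vertices = mesh.vertices * (1 + 0.05 * rng.standard_normal(
            mesh.vertices.shape))
        dth = mesh.dihedral_angles() - mesh.theta0
        kB = 0.7
        assert bending_energy(mesh, kB) == pytest.approx(
            0.5 * kB * (np.tan(dth / 2) ** 2).sum(), rel=1e-12)
        assert bending_energy(mesh, kB, "quadratic") == pytest.approx(
            0.5 * kB * (dth**2).sum(), rel=1e-12)

    def test_rigid_rotation_invariance(self, small_sphere, rng):
        mesh = small_sphere
        mesh.vertices = mesh.vertices * (1 + 0.05 * rng.standard_normal(
            mesh.vertices.shape))
        e_before = bending_energy(mesh, 1.0)
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        mesh.vertices = mesh.vertices @ R.T
        assert bending_energy(mesh, 1.0) == pytest.approx(e_before, rel=1e-12)


class TestAreaVolumeEnergy:
    def test_reference_zero(self, small_sphere, generic_params):
        EA, EV = area_volume_energy(small_sphere, generic_params)
        assert EA == pytest.approx(0.0, abs=1e-16)
        assert EV == pytest.approx(0.0, abs=1e-16)

    def test_ten_percent_area_excess(self, small_sphere):
        # uniform scaling by sqrt(1.1) gives A = 1.1 A0 exactly
        params = MembraneParams(0, 0, 0, kA=3.0, kV=0.0)
        mesh = small_sphere
        mesh.vertices = mesh.vertices * np.sqrt(1.1)
        EA, _ = area_volume_energy(mesh, params)
        assert EA == pytest.approx(0.005 * 3.0, rel=1e-10)

    def test_volume_energy_quadratic(self, small_sphere):
        params = MembraneParams(0, 0, 0, 0, kV=2.0)
        v = small_sphere.vertices.copy()
        small_sphere.vertices = v * 1.01
        _, EV1 = area_volume_energy(small_sphere, params)
        small_sphere.vertices = v * (1 + 0.02 * (1.01**3 - 1) / (3 * 0.01)) \
            if False else v * ((2 * (1.01**3 - 1) + 1) ** (1 / 3))
        _, EV2 = area_volume_energy(small_sphere, params)
        assert EV2 == pytest.approx(4 * EV1, rel=1e-6)


class TestMembraneForces:
    def test_reference_configuration_force_free(self, small_sphere, generic_params):
        F = membrane_forces(small_sphere, generic_params)
        assert np.abs(F).max() < 1e-14

    @pytest.mark.parametrize("nf", [20, 80])
    @pytest.mark.parametrize("term", ["skalak", "bending", "bending_quad",
                                      "areavol", "combined"])
    def test_matches_finite_difference_oracle(self, nf, term, rng):
        params = {
            "skalak": MembraneParams(1.0, 0.7, 0, 0, 0),
            "bending": MembraneParams(0, 0, 0.3, 0, 0),
            "bending_quad": MembraneParams(0, 0, 0.3, 0, 0,
                                           bending_model="quadratic"),
            "areavol": MembraneParams(0, 0, 0, 2.0, 1.5),
            "combined": MembraneParams(1.0, 0.7, 0.3, 2.0, 1.5),
        }[term]
        mesh = icosphere(1.0, nf)
        mesh.vertices = mesh.vertices * (
            1 + 0.08 * rng.standard_normal(mesh.vertices.shape))
        Fa = membrane_forces(mesh, params)
        Ff = fd_membrane_force(mesh, params)
        assert np.abs(Fa - Ff).max() / np.abs(Ff).max() < 1e-5

    def test_zero_net_force_and_torque_per_term(self, rng):
        mesh = icosphere(1.0, 80)
        mesh.vertices = mesh.vertices * (
            1 + 0.1 * rng.standard_normal(mesh.vertices.shape))
        for p in (MembraneParams(1, 0.5, 0, 0, 0),
                  MembraneParams(0, 0, 1.0, 0, 0),
                  MembraneParams(0, 0, 0, 1.0, 0),
                  MembraneParams(0, 0, 0, 0, 1.0)):
            F = membrane_forces(mesh, p)
            scale = np.abs(F).max()
            assert np.abs(F.sum(axis=0)).max() < 1e-12 * max(scale, 1e-30)
            torque = np.cross(mesh.vertices, F).sum(axis=0)
            assert np.abs(torque).max() < 1e-12 * max(scale, 1e-30)

    def test_inflated_sphere_pulled_inward(self):
        mesh = icosphere(1.0, 80)
        mesh.vertices = mesh.vertices * 1.05
        F = membrane_forces(mesh, MembraneParams(0, 0, 0, 0, kV=1.0))
        radial = np.einsum("ij,ij->i", F, mesh.vertices)
        assert np.all(radial < 0)

    def test_overdamped_relaxation_decreases_energy(self, rng):
        mesh = icosphere(1.0, 80)
        params = MembraneParams(1.0, 1.0, 0.05, 1.0, 1.0)
        mesh.vertices = mesh.vertices * (
            1 + 0.05 * rng.standard_normal(mesh.vertices.shape))
        energies = [total_energy(mesh, params)]
        eta = 5e-3
        for _ in range(40):
            mesh.vertices = mesh.vertices + eta * membrane_forces(mesh, params)
            energies.append(total_energy(mesh, params))
        assert all(b < a for a, b in zip(energies, energies[1:]))
        assert energies[-1] < 0.5 * energies[0]
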