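import numpy as np
import pytest

from ibflow.membrane import MembraneParams, icosphere


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def small_sphere():
    """Icosahedral Nf=20 sphere mesh, radius 1."""
    return icosphere(1.0, 20)


@pytest.fixture()
def generic_params():
    """O(1) moduli exercising every energy term."""
    return MembraneParams(ks=1.0, kalpha=0.7, kB=0.3, kA=2.0, kV=1.5)


def fd_membrane_force(mesh, params, h=1e-6):
    """Central-finite-difference force oracle, -dE/dx over all coordinates."""
    from ibflow.membrane import total_energy

    F = np.zeros_like(mesh.vertices)
    base = mesh.vertices.copy()
    for n in range(mesh.n_vertices):
        for c in range(3):
            mesh.vertices = base.copy()
            mesh.vertices[n, c] += h
            e_plus = total_energy(mesh, params)
            mesh.vertices = base.copy()
            mesh.vertices[n, c] -= h
            e_minus = total_energy(mesh, params)
            F[n, c] = -(e_plus - e_minus) / (2.0 * h)
    mesh.vertices = base
    return F
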