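"""Immersed-boundary transfer between fluid grid and membranes, and the
coupled time loop.

Lagrangian membrane nodes talk to the Eulerian lattice through a tensor-
product discrete delta kernel.  The default is the two-point hat kernel
phi(r) = 1 - |r| for |r| < 1 (two-point interpolation); the common four-point
cosine kernel is available by configuration.  Spreading and interpolation
use the same weights, so they are exact adjoints, and the hat kernel is a
partition of unity, so the total spread force equals the total nodal force
to round-off.

One coupled step runs: membrane forces -> force spreading -> LBM collide/
stream (with bounce-back walls) -> macroscopic moments -> velocity
interpolation -> forward-Euler node advection.  Membranes are advected with
unwrapped coordinates; when a particle's centroid leaves the periodic axial
extent the whole mesh is shifted by one period, so mesh geometry never sees
the wrap.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from numba import njit

from .lbm import DistributionField
from .membrane import (BiconcaveSpec, MembraneParams, TriMesh, biconcave_mesh,
                       icosphere, membrane_forces)
from .units import ConfigError

log = logging.getLogger(__name__)


def hat_phi(r):
    """Two-point hat kernel phi(r) = 1 - |r| on |r| < 1."""
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r < 1.0, 1.0 - r, 0.0)


def cosine_phi(r):
    """Four-point cosine kernel, support |r| < 2."""
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r < 2.0, 0.25 * (1.0 + np.cos(0.5 * np.pi * r)), 0.0)


def delta3(offset, kernel: str = "hat"):
    """Tensor-product delta weight for a 3-vector offset."""
    phi = hat_phi if kernel == "hat" else cosine_phi
    off = np.asarray(offset, dtype=float)
    return np.prod(phi(off), axis=-1)


@njit(cache=True, fastmath=True)
def _spread_hat(pos, frc, Fx, Fy, Fz):  # pragma: no cover
    nx, ny, nz = Fx.shape
    for n in range(pos.shape[0]):
        x = pos[n, 0]
        y = pos[n, 1]
        z = pos[n, 2]
        x0 = int(math.floor(x))
        y0 = int(math.floor(y))
        z0 = int(math.floor(z))
        tx = x - x0
        ty = y - y0
        tz = z - z0
        for dx in range(2):
            wx = tx if dx == 1 else 1.0 - tx
            xi = (x0 + dx) % nx
            for dy in range(2):
                wy = ty if dy == 1 else 1.0 - ty
                yi = (y0 + dy) % ny
                wxy = wx * wy
                for dz in range(2):
                    wz = tz if dz == 1 else 1.0 - tz
                    zi = (z0 + dz) % nz
                    w = wxy * wz
                    Fx[xi, yi, zi] += w * frc[n, 0]
                    Fy[xi, yi, zi] += w * frc[n, 1]
                    Fz[xi, yi, zi] += w * frc[n, 2]


@njit(cache=True, fastmath=True)
def _interp_hat(pos, ux, uy, uz, out):  # pragma: no cover
    nx, ny, nz = ux.shape
    for n in range(pos.shape[0]):
        x = pos[n, 0]
        y = pos[n, 1]
        z = pos[n, 2]
        x0 = int(math.floor(x))
        y0 = int(math.floor(y))
        z0 = int(math.floor(z))
        tx = x - x0
        ty = y - y0
        tz = z - z0
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for dx in range(2):
            wx = tx if dx == 1 else 1.0 - tx
            xi = (x0 + dx) % nx
            for dy in range(2):
                wy = ty if dy == 1 else 1.0 - ty
                yi = (y0 + dy) % ny
                wxy = wx * wy
                for dz in range(2):
                    wz = tz if dz == 1 else 1.0 - tz
                    zi = (z0 + dz) % nz
                    w = wxy * wz
                    vx += w * ux[xi, yi, zi]
                    vy += w * uy[xi, yi, zi]
                    vz += w * uz[xi, yi, zi]
        out[n, 0] = vx
        out[n, 1] = vy
        out[n, 2] = vz


@njit(cache=True, fastmath=True)
def _spread_cos(pos, frc, Fx, Fy, Fz):  # pragma: no cover
    nx, ny, nz = Fx.shape
    for n in range(pos.shape[0]):
        x = pos[n, 0]
        y = pos[n, 1]
        z = pos[n, 2]
        x0 = int(math.floor(x)) - 1
        y0 = int(math.floor(y)) - 1
        z0 = int(math.floor(z)) - 1
        for dx in range(4):
            rx = abs(x - (x0 + dx))
            wx = 0.25 * (1.0 + math.cos(0.5 * math.pi * rx)) if rx < 2.0 else 0.0
            xi = (x0 + dx) % nx
            for dy in range(4):
                ry = abs(y - (y0 + dy))
                wy = 0.25 * (1.0 + math.cos(0.5 * math.pi * ry)) if ry < 2.0 else 0.0
                yi = (y0 + dy) % ny
                wxy = wx * wy
                for dz in range(4):
                    rz = abs(z - (z0 + dz))
                    wz = 0.25 * (1.0 + math.cos(0.5 * math.pi * rz)) if rz < 2.0 else 0.0
                    zi = (z0 + dz) % nz
                    w = wxy * wz
                    Fx[xi, yi, zi] += w * frc[n, 0]
                    Fy[xi, yi, zi] += w * frc[n, 1]
                    Fz[xi, yi, zi] += w * frc[n, 2]


@njit(cache=True, fastmath=True)
def _interp_cos(pos, ux, uy, uz, out):  # pragma: no cover
    nx, ny, nz = ux.shape
    for n in range(pos.shape[0]):
        x = pos[n, 0]
        y = pos[n, 1]
        z = pos[n, 2]
        x0 = int(math.floor(x)) - 1
        y0 = int(math.floor(y)) - 1
        z0 = int(math.floor(z)) - 1
        vx = 0.0
        vy = 0.0
        vz = 0.0
        for dx in range(4):
            rx = abs(x - (x0 + dx))
            wx = 0.25 * (1.0 + math.cos(0.5 * math.pi * rx)) if rx < 2.0 else 0.0
            xi = (x0 + dx) % nx
            for dy in range(4):
                ry = abs(y - (y0 + dy))
                wy = 0.25 * (1.0 + math.cos(0.5 * math.pi * ry)) if ry < 2.0 else 0.0
                yi = (y0 + dy) % ny
                wxy = wx * wy
                for dz in range(4):
                    rz = abs(z - (z0 + dz))
                    wz = 0.25 * (1.0 + math.cos(0.5 * math.pi * rz)) if rz < 2.0 else 0.0
                    zi = (z0 + dz) % nz
                    vx += wxy * wz * ux[xi, yi, zi]
                    vy += wxy * wz * uy[xi, yi, zi]
                    vz += wxy * wz * uz[xi, yi, zi]
        out[n, 0] = vx
        out[n, 1] = vy
        out[n, 2] = vz


def spread_forces(positions, forces, field: DistributionField,
                  kernel: str = "hat") -> None:
    """Distribute nodal forces onto the fluid force field (accumulating)."""
    pos = np.ascontiguousarray(positions, dtype=float)
    frc = np.ascontiguousarray(forces, dtype=float)
    if kernel == "hat":
        _spread_hat(pos, frc, field.Fx, field.Fy, field.Fz)
    elif kernel == "cosine":
        _spread_cos(pos, frc, field.Fx, field.Fy, field.Fz)
    else:
        raise ConfigError(f"unknown coupling kernel {kernel!r}")


def interpolate_velocity(u: np.ndarray, positions, kernel: str = "hat") -> np.ndarray:
    """Kernel-weighted interpolation of a grid velocity field at node positions."""
    pos = np.ascontiguousarray(positions, dtype=float)
    out = np.empty_like(pos)
    ux = np.ascontiguousarray(u[..., 0])
    uy = np.ascontiguousarray(u[..., 1])
    uz = np.ascontiguousarray(u[..., 2])
    if kernel == "hat":
        _interp_hat(pos, ux, uy, uz, out)
    elif kernel == "cosine":
        _interp_cos(pos, ux, uy, uz, out)
    else:
        raise ConfigError(f"unknown coupling kernel {kernel!r}")
    return out


def interpolate_scalar(field3d: np.ndarray, positions, kernel: str = "hat") -> np.ndarray:
    """Interpolate a scalar grid field (e.g. density) at node positions."""
    z = np.zeros_like(field3d)
    u = np.stack([field3d, z, z], axis=-1)
    return interpolate_velocity(u, positions, kernel)[:, 0]


def advect_nodes(positions, velocities, dt: float = 1.0,
                 wrap_x: float | None = None) -> np.ndarray:
    """Forward-Euler node update x(t+dt) = x(t) + u dt, optional periodic x."""
    out = np.asarray(positions, dtype=float) + dt * np.asarray(velocities, dtype=float)
    if wrap_x is not None:
        out[..., 0] %= wrap_x
    return out


# ---------------------------------------------------------------------------
# Particles and placement
# ---------------------------------------------------------------------------

class Particle:
    """A membrane mesh plus its moduli and bookkeeping for the coupled loop."""

    def __init__(self, mesh: TriMesh, params: MembraneParams, label: str = ""):
        self.mesh = mesh
        self.params = params
        self.label = label
        self.node_velocities = np.zeros_like(mesh.vertices)
        self.radius = float(
            np.linalg.norm(mesh.vertices - mesh.vertices.mean(axis=0), axis=1).max()
        )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (from a random unit quaternion)."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def place_particles(geometry, specs, seed: int, wall_clearance: float = 1.0,
                    max_trials: int = 10_000, mode: str = "random",
                    d0: float | None = None) -> list:
    """Seeded random, non-overlapping particle placement inside a vessel.

    Each spec is a dict with keys ``kind`` ("rbc" | "dc"), ``radius``
    (lattice units), ``faces`` and ``params`` (a :class:`MembraneParams`).
    Particle centers keep ``radius + wall_clearance`` away from the wall and
    particles never overlap at release; orientation is uniformly random.

    ``mode="random"`` draws centers uniformly over the admissible
    cross-section (the free release of the migration study);
    ``mode="ring"`` fixes every center at radial distance ``d0`` from the
    centerline (random angle and axial position), which starts all species
    from the same distance so differential migration can be read directly.
    """
    if mode not in ("random", "ring"):
        raise ConfigError(f"unknown placement mode {mode!r}")
    if mode == "ring" and d0 is None:
        raise ConfigError("ring placement requires d0")
    rng = np.random.default_rng(seed)
    placed = []
    centers = []
    radii = []
    for k, spec in enumerate(specs):
        r_p = float(spec["radius"])
        if r_p >= geometry.radius:
            raise ConfigError(f"particle radius {r_p} exceeds vessel radius")
        r_max = geometry.radius - r_p - wall_clearance
        if r_max <= 0:
            raise ConfigError(
                f"no room for particle of radius {r_p} in vessel D={geometry.D}")
        for _ in range(max_trials):
            x = rng.uniform(0.0, geometry.L)
            # ring radius (per-spec override allowed) is clamped to the
            # particle's own wall clearance
            ring_r = float(spec.get("d0", d0)) if mode == "ring" else 0.0
            rad = min(ring_r, r_max) if mode == "ring" else r_max * np.sqrt(rng.uniform())
            ang = rng.uniform(0.0, 2.0 * np.pi)
            ycl, zcl = geometry.centerline(x)
            center = np.array([x, float(ycl) + rad * np.cos(ang),
                               float(zcl) + rad * np.sin(ang)])
            ok = all(
                np.linalg.norm(center - c) > r_p + r0 + 1.0
                for c, r0 in zip(centers, radii)
            )
            if ok:
                break
        else:
            raise ConfigError(
                f"could not place particle {k} after {max_trials} trials")
        if spec["kind"] == "rbc":
            mesh = biconcave_mesh(BiconcaveSpec(R=r_p), spec.get("faces", 480))
        else:
            mesh = icosphere(r_p, spec.get("faces", 120))
        mesh.vertices = mesh.vertices @ _random_rotation(rng).T + center
        centers.append(center)
        radii.append(r_p)
        placed.append(Particle(mesh, spec["params"],
                               label=spec.get("label", f"{spec['kind']}{k}")))
    return placed


# ---------------------------------------------------------------------------
# Coupled simulation
# ---------------------------------------------------------------------------

class Simulation:
    """Coupled IB-LBM time loop over one fluid field and a set of particles."""

    def __init__(self, field: DistributionField, tau: float, particles=(),
                 body_accel=(0.0, 0.0, 0.0), kernel: str = "hat",
                 geometry=None, membrane_substeps: int = 1,
                 guard_every: int = 200):
        self.field = field
        self.tau = float(tau)
        self.particles = list(particles)
        self.body_accel = np.asarray(body_accel, dtype=float)
        self.kernel = kernel
        self.geometry = geometry
        self.membrane_substeps = int(membrane_substeps)
        self.guard_every = int(guard_every)
        self.rho = None
        self.u = None

    @property
    def t(self) -> int:
        return self.field.t

    def _nodal_forces(self, p: Particle) -> np.ndarray:
        m = self.membrane_substeps
        if m <= 1:
            return membrane_forces(p.mesh, p.params)
        # stiff-membrane stabilizer: average the elastic force along the
        # frozen-velocity node path across m sub-evaluations
        base = p.mesh.vertices.copy()
        acc = np.zeros_like(base)
        for k in range(m):
            p.mesh.vertices = base + (k / m) * p.node_velocities
            acc += membrane_forces(p.mesh, p.params)
        p.mesh.vertices = base
        return acc / m

    def coupled_step(self) -> None:
        """Advance fluid and membranes by one time step."""
        fld = self.field
        fld.clear_forces()
        if np.any(self.body_accel != 0.0):
            fld.add_body_force(self.body_accel)
        for p in self.particles:
            spread_forces(p.mesh.vertices, self._nodal_forces(p), fld, self.kernel)
        fld.step(self.tau)
        self.rho, self.u = fld.macroscopic()
        for p in self.particles:
            p.node_velocities = interpolate_velocity(self.u, p.mesh.vertices,
                                                     self.kernel)
            p.mesh.vertices = p.mesh.vertices + p.node_velocities
            self._rewrap(p)
        if self.geometry is not None:
            self._wall_guard()
        if self.guard_every and fld.t % self.guard_every == 0:
            fld.check_divergence()

    def run(self, n_steps: int, callback=None, callback_every: int = 1) -> None:
        for _ in range(n_steps):
            self.coupled_step()
            if callback is not None and self.t % callback_every == 0:
                callback(self)

    def _rewrap(self, p: Particle) -> None:
        """Shift a whole mesh by one axial period when its centroid leaves it."""
        L = self.field.shape[0]
        cx = p.mesh.vertices[:, 0].mean()
        if cx >= L:
            p.mesh.vertices[:, 0] -= L
        elif cx < 0.0:
            p.mesh.vertices[:, 0] += L

    def _wall_guard(self) -> None:
        """Penetration monitor: clamp nodes radially back to the wall clearance."""
        limit = self.geometry.radius - 0.55
        for p in self.particles:
            v = p.mesh.vertices
            ycl, zcl = self.geometry.centerline(v[:, 0])
            dy = v[:, 1] - ycl
            dz = v[:, 2] - zcl
            r = np.hypot(dy, dz)
            bad = r > limit
            if np.any(bad):
                log.warning("step %d: %d nodes of %s at wall, clamped",
                            self.t, int(bad.sum()), p.label)
                scale = limit / r[bad]
                v[bad, 1] = ycl[bad] + dy[bad] * scale
                v[bad, 2] = zcl[bad] + dz[bad] * scale

    def total_fluid_momentum(self) -> np.ndarray:
        return self.field.total_momentum()
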