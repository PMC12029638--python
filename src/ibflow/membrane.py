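"""Triangulated capsule membranes: meshes, energies and nodal forces.

A particle membrane is a closed, consistently oriented triangle mesh.  Its
elastic state is measured against a stored reference (undeformed)
configuration and penalized by four energies:

* in-plane Skalak strain energy, per face, from the invariants
  I1 = l1^2 + l2^2 - 2 and I2 = l1^2 l2^2 - 1 of the reference->current
  mapping (l1, l2 the principal in-plane stretches):
  eps_s = ks/12 (I1^2 + 2 I1 - 2 I2) + kalpha/12 I2^2, summed with the
  reference face areas as weights;
* bending energy over adjacent face pairs, (kB/2) sum tan^2((theta-theta0)/2)
  with theta the signed dihedral between face normals (a plain quadratic
  (kB/2) sum (theta-theta0)^2 is available as an alternative);
* global area and volume penalties (kA/2)((A-A0)/A0)^2, (kV/2)((V-V0)/V0)^2.

Nodal forces are the exact analytic negative gradients of these energies.
The in-plane invariants are evaluated from the face edge metrics
g = [[a.a, a.b], [a.b, b.b]] (current) against the stored inverse reference
metric, which makes both the energy and its gradient rotation-invariant by
construction.  All gradients are validated against central finite
differences in the test suite.

Everything here is in lattice units; :class:`MembraneParams` converts the
physical moduli tables through a :class:`~ibflow.units.UnitSystem`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .units import UnitSystem


class MeshDegenerateError(RuntimeError):
    """A face of the membrane mesh collapsed to zero area."""


class MembraneDivergedError(RuntimeError):
    """A dihedral angle approached the tan singularity (fold by ~pi)."""


@dataclass(frozen=True)
class MembraneParams:
    """The five membrane moduli of one particle species, in lattice units."""

    ks: float          # elastic shear modulus
    kalpha: float      # area dilation modulus
    kB: float          # bending modulus
    kA: float          # global surface-area modulus
    kV: float          # global volume modulus
    bending_model: str = "tan_half"   # "tan_half" | "quadratic"

    def __post_init__(self):
        for name in ("ks", "kalpha", "kB", "kA", "kV"):
            if getattr(self, name) < 0:
                raise ValueError(f"MembraneParams.{name} must be >= 0")
        if self.bending_model not in ("tan_half", "quadratic"):
            raise ValueError(f"unknown bending model {self.bending_model!r}")

    @classmethod
    def from_physical(cls, table: dict, us: UnitSystem, **kw) -> "MembraneParams":
        """Convert a physical parameter table (N/m, N m, N/m^2) to lattice units."""
        return cls(
            ks=us.to_lattice_shear_modulus(table["ks"]),
            kalpha=us.to_lattice_shear_modulus(table["kalpha"]),
            kB=us.to_lattice_bending_modulus(table["kB"]),
            kA=us.to_lattice_shear_modulus(table["kA"]),
            kV=us.to_lattice_volume_modulus(table["kV"]),
            **kw,
        )

    def scaled(self, factor: float) -> "MembraneParams":
        return replace(self, ks=self.ks * factor, kalpha=self.kalpha * factor,
                       kB=self.kB * factor, kA=self.kA * factor,
                       kV=self.kV * factor)


@dataclass(frozen=True)
class BiconcaveSpec:
    """Scale and shape constants of the biconcave discocyte profile."""

    R: float = 3.5
    C0: float = 0.207
    C1: float = 2.003
    C2: float = -1.123

    def __post_init__(self):
        if self.C0 <= 0:
            raise ValueError("BiconcaveSpec.C0 must be positive")


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------

class TriMesh:
    """Closed oriented triangle mesh with a stored reference configuration.

    Vertices are mutable (the membrane advects); faces and the reference data
    are fixed at construction (or when :meth:`set_reference` is called).
    """

    def __init__(self, vertices, faces, set_reference: bool = True):
        self.vertices = np.array(vertices, dtype=float)
        self.faces = np.array(faces, dtype=np.int64)
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (Nf, 3) vertex-index triples")
        self.n_vertices = len(self.vertices)
        self.n_faces = len(self.faces)
        self._build_edges()
        if set_reference:
            self.set_reference()

    # -- topology ----------------------------------------------------------
    def _build_edges(self) -> None:
        """Collect interior-edge stencils (p0, p1, p2, p3).

        p0->p1 is the directed edge as it appears in the 'left' face (whose
        third vertex is p2); the 'right' face holds p1->p0 and third vertex
        p3.  In a closed consistently-oriented mesh every undirected edge
        appears exactly once in each direction.
        """
        half = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for p0, p1, p2 in ((a, b, c), (b, c, a), (c, a, b)):
                key = (int(p0), int(p1))
                if key in half:
                    raise ValueError(f"duplicated directed edge {key} (face {fi})")
                half[key] = int(p2)
        stencils = []
        for (p0, p1), p2 in half.items():
            if p0 < p1:
                if (p1, p0) not in half:
                    raise ValueError(f"mesh is not closed at edge ({p0},{p1})")
                stencils.append((p0, p1, p2, half[(p1, p0)]))
        self.edges = np.array(stencils, dtype=np.int64)
        if 2 * len(self.edges) != 3 * self.n_faces:
            raise ValueError("edge/face count mismatch; mesh is not closed")

    # -- geometry ----------------------------------------------------------
    def face_corners(self, vertices=None):
        v = self.vertices if vertices is None else vertices
        tri = v[self.faces]
        return tri[:, 0], tri[:, 1], tri[:, 2]

    def face_normals_areas(self):
        v0, v1, v2 = self.face_corners()
        n = np.cross(v1 - v0, v2 - v0)
        nn = np.linalg.norm(n, axis=1)
        if np.any(nn < 1e-12):
            bad = int(np.argmin(nn))
            raise MeshDegenerateError(f"face {bad} has (near-)zero area")
        return n, nn / 2.0

    def area(self) -> float:
        _, areas = self.face_normals_areas()
        return float(areas.sum())

    def volume(self) -> float:
        """Signed enclosed volume by the divergence theorem (positive when
        the orientation is outward)."""
        v0, v1, v2 = self.face_corners()
        return float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)

    def centroid(self) -> np.ndarray:
        """Centroid of the enclosed solid (not the vertex mean)."""
        v0, v1, v2 = self.face_corners()
        vt = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0
        c = (v0 + v1 + v2) / 4.0            # tetra centroid, 4th vertex at origin
        return (vt[:, None] * c).sum(axis=0) / vt.sum()

    def dihedral_angles(self, vertices=None) -> np.ndarray:
        """Signed angle between face normals across every interior edge."""
        v = self.vertices if vertices is None else vertices
        p0 = v[self.edges[:, 0]]
        p1 = v[self.edges[:, 1]]
        p2 = v[self.edges[:, 2]]
        p3 = v[self.edges[:, 3]]
        e = p1 - p0
        n1 = np.cross(e, p2 - p0)
        n2 = np.cross(p0 - p1, p3 - p1)
        n1n = np.linalg.norm(n1, axis=1)
        n2n = np.linalg.norm(n2, axis=1)
        en = np.linalg.norm(e, axis=1)
        cos = np.einsum("ij,ij->i", n1, n2) / (n1n * n2n)
        sin = np.einsum("ij,ij->i", np.cross(n1, n2), e) / (n1n * n2n * en)
        return np.arctan2(sin, cos)

    # -- reference state -----------------------------------------------------
    def set_reference(self) -> None:
        """Freeze the current configuration as the stress-free reference."""
        v0, v1, v2 = self.face_corners()
        a = v1 - v0
        b = v2 - v0
        g11 = np.einsum("ij,ij->i", a, a)
        g12 = np.einsum("ij,ij->i", a, b)
        g22 = np.einsum("ij,ij->i", b, b)
        det = g11 * g22 - g12**2
        if np.any(det < 1e-20):
            bad = int(np.argmin(det))
            raise MeshDegenerateError(f"reference face {bad} is degenerate")
        self.ref_det = det                       # det g0
        self.ref_h11 = g22 / det                 # inverse reference metric
        self.ref_h12 = -g12 / det
        self.ref_h22 = g11 / det
        self.ref_face_area = np.sqrt(det) / 2.0  # A_i^0
        self.A0 = float(self.ref_face_area.sum())
        self.V0 = self.volume()
        if self.V0 <= 0:
            raise ValueError("mesh orientation is inward (signed volume <= 0)")
        self.theta0 = self.dihedral_angles()

    def copy(self) -> "TriMesh":
        out = TriMesh.__new__(TriMesh)
        out.__dict__.update(
            {k: (v.copy() if isinstance(v, np.ndarray) else v)
             for k, v in self.__dict__.items()}
        )
        return out

    def translate(self, shift) -> "TriMesh":
        self.vertices = self.vertices + np.asarray(shift, dtype=float)
        return self


# ---------------------------------------------------------------------------
# Sphere and biconcave mesh generation
# ---------------------------------------------------------------------------

def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def _subdivide4(verts, faces):
    """One 4:1 refinement: split every edge at its midpoint."""
    verts = list(map(np.asarray, verts))
    cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = len(verts)
            verts.append((verts[i] + verts[j]) / 2.0)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
    return np.array(verts), np.array(out, dtype=np.int64)


def _barycentric_subdivide(verts, faces):
    """Split every face into 6 around its centroid and edge midpoints (3x faces)."""
    verts = list(map(np.asarray, verts))
    cache = {}

    def midpoint(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = len(verts)
            verts.append((verts[i] + verts[j]) / 2.0)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        g = len(verts)
        verts.append((verts[a] + verts[b] + verts[c]) / 3.0)
        out.extend([(a, ab, g), (ab, b, g), (b, bc, g),
                    (bc, c, g), (c, ca, g), (ca, a, g)])
    return np.array(verts), np.array(out, dtype=np.int64)


def _face_count_plan(target_faces: int):
    """Choose the subdivision sequence whose face count is nearest the target.

    Reachable counts are 20*4^k (icosahedral refinement) and 120*4^k (one
    barycentric split first, giving the 120-face disdyakis pattern and its
    refinements, e.g. 480)."""
    best = None
    for bary in (False, True):
        base = 120 if bary else 20
        for k in range(0, 8):
            nf = base * 4**k
            score = (abs(nf - target_faces), nf)
            if best is None or score < best[0]:
                best = (score, bary, k)
    return best[1], best[2]


def icosphere(radius: float, target_faces: int = 320) -> TriMesh:
    """Unit-refinement sphere mesh with ~``target_faces`` triangles.

    Vertices are re-projected to the sphere after every subdivision, so face
    shapes stay nearly uniform; the result is closed and outward oriented
    (2N = Nf + 4 by Euler's formula).
    """
    verts, faces = _icosahedron()
    bary, k = _face_count_plan(target_faces)
    if bary:
        verts, faces = _barycentric_subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(k):
        verts, faces = _subdivide4(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriMesh(verts * radius, faces)


def biconcave_mesh(spec: BiconcaveSpec, target_faces: int = 480) -> TriMesh:
    """Biconcave discocyte (red-cell rest shape) by projecting a unit sphere.

    Each unit-sphere vertex (x, y, z) maps to (R x, y', R z) with
    y' = (R/2) (1 - r^2)^(1/2) (C0 + C1 r^2 + C2 r^4) carrying the sign of y
    and r^2 = x^2 + z^2.  On the unit sphere (1 - r^2)^(1/2) = |y|, so the
    map is smooth through the equator.  The disk radius (max extent in the
    x-z plane) equals R; the mesh volume defines the equilibrium volume V0.
    """
    sphere = icosphere(1.0, target_faces)
    v = sphere.vertices
    r2 = v[:, 0] ** 2 + v[:, 2] ** 2
    shape = spec.C0 + spec.C1 * r2 + spec.C2 * r2**2
    mapped = np.column_stack([
        spec.R * v[:, 0],
        0.5 * spec.R * v[:, 1] * shape,
        spec.R * v[:, 2],
    ])
    return TriMesh(mapped, sphere.faces)


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def _current_metric(mesh: TriMesh):
    v0, v1, v2 = mesh.face_corners()
    a = v1 - v0
    b = v2 - v0
    g11 = np.einsum("ij,ij->i", a, a)
    g12 = np.einsum("ij,ij->i", a, b)
    g22 = np.einsum("ij,ij->i", b, b)
    det = g11 * g22 - g12**2
    if np.any(det < 1e-20):
        bad = int(np.argmin(det))
        raise MeshDegenerateError(f"face {bad} is degenerate")
    return a, b, g11, g12, g22, det


def strain_invariants(mesh: TriMesh):
    """Per-face Skalak invariants (I1, I2) of the current configuration."""
    _, _, g11, g12, g22, det = _current_metric(mesh)
    I1 = (mesh.ref_h11 * g11 + 2.0 * mesh.ref_h12 * g12
          + mesh.ref_h22 * g22) - 2.0
    I2 = det / mesh.ref_det - 1.0
    return I1, I2


def skalak_energy(mesh: TriMesh, params: MembraneParams):
    """In-plane strain energy; returns ``(E_S, (I1, I2))`` per face."""
    I1, I2 = strain_invariants(mesh)
    eps = (params.ks / 12.0) * (I1**2 + 2.0 * I1 - 2.0 * I2) \
        + (params.kalpha / 12.0) * I2**2
    return float((eps * mesh.ref_face_area).sum()), (I1, I2)


def bending_energy(mesh: TriMesh, kB: float, model: str = "tan_half") -> float:
    """Dihedral bending energy over all adjacent face pairs."""
    dtheta = mesh.dihedral_angles() - mesh.theta0
    if model == "tan_half":
        if np.any(np.abs(dtheta) > 3.0):
            raise MembraneDivergedError(
                "dihedral angle deviation approaching pi (tan singularity)")
        return float(0.5 * kB * (np.tan(0.5 * dtheta) ** 2).sum())
    if model == "quadratic":
        return float(0.5 * kB * (dtheta**2).sum())
    raise ValueError(f"unknown bending model {model!r}")


def area_volume_energy(mesh: TriMesh, params: MembraneParams):
    """Global penalties ``(E_A, E_V)`` on total area and enclosed volume."""
    A = mesh.area()
    V = mesh.volume()
    EA = 0.5 * params.kA * ((A - mesh.A0) / mesh.A0) ** 2
    EV = 0.5 * params.kV * ((V - mesh.V0) / mesh.V0) ** 2
    return float(EA), float(EV)


def total_energy(mesh: TriMesh, params: MembraneParams) -> float:
    ES, _ = skalak_energy(mesh, params)
    EB = bending_energy(mesh, params.kB, params.bending_model)
    EA, EV = area_volume_energy(mesh, params)
    return ES + EB + EA + EV


# ---------------------------------------------------------------------------
# Analytic nodal forces F(x_n) = -dE/dx_n
# ---------------------------------------------------------------------------

def _accumulate(n_vertices, idx, contrib):
    """Sum per-element vector contributions onto vertices (bincount per axis)."""
    out = np.empty((n_vertices, 3))
    flat = idx.ravel()
    for c in range(3):
        out[:, c] = np.bincount(flat, weights=contrib[..., c].ravel(),
                                minlength=n_vertices)
    return out


def _skalak_gradient(mesh: TriMesh, params: MembraneParams):
    a, b, g11, g12, g22, det = _current_metric(mesh)
    I1 = (mesh.ref_h11 * g11 + 2.0 * mesh.ref_h12 * g12
          + mesh.ref_h22 * g22) - 2.0
    I2 = det / mesh.ref_det - 1.0
    dI1 = (params.ks / 12.0) * (2.0 * I1 + 2.0)
    dI2 = (params.kalpha * I2 - params.ks) / 6.0
    w = mesh.ref_face_area
    # dE/dg components (per face)
    P = w * (dI1 * mesh.ref_h11 + dI2 * g22 / mesh.ref_det)        # dE/dg11
    Q = w * (dI1 * 2.0 * mesh.ref_h12 - dI2 * 2.0 * g12 / mesh.ref_det)
    R = w * (dI1 * mesh.ref_h22 + dI2 * g11 / mesh.ref_det)        # dE/dg22
    gv1 = 2.0 * P[:, None] * a + Q[:, None] * b
    gv2 = 2.0 * R[:, None] * b + Q[:, None] * a
    gv0 = -(gv1 + gv2)
    grads = np.stack([gv0, gv1, gv2], axis=1)                      # (Nf, 3, 3)
    return _accumulate(mesh.n_vertices, mesh.faces, grads)


def _area_volume_gradient(mesh: TriMesh, params: MembraneParams):
    v0, v1, v2 = mesh.face_corners()
    a = v1 - v0
    b = v2 - v0
    n = np.cross(a, b)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(nn < 1e-12):
        raise MeshDegenerateError(f"face {int(np.argmin(nn))} has zero area")
    nhat = n / nn
    A = float(nn.sum()) / 2.0
    V = float(np.einsum("ij,ij->", v0, np.cross(v1, v2)) / 6.0)
    cA = params.kA * (A - mesh.A0) / mesh.A0**2
    cV = params.kV * (V - mesh.V0) / mesh.V0**2
    # area gradient per face corner
    dA1 = 0.5 * np.cross(b, nhat)
    dA2 = 0.5 * np.cross(nhat, a)
    dA0 = -(dA1 + dA2)
    # volume gradient per face corner
    dV0 = np.cross(v1, v2) / 6.0
    dV1 = np.cross(v2, v0) / 6.0
    dV2 = np.cross(v0, v1) / 6.0
    grads = cA * np.stack([dA0, dA1, dA2], axis=1) \
        + cV * np.stack([dV0, dV1, dV2], axis=1)
    return _accumulate(mesh.n_vertices, mesh.faces, grads)


def _bending_gradient(mesh: TriMesh, kB: float, model: str):
    v = mesh.vertices
    p0 = v[mesh.edges[:, 0]]
    p1 = v[mesh.edges[:, 1]]
    p2 = v[mesh.edges[:, 2]]
    p3 = v[mesh.edges[:, 3]]
    e = p1 - p0
    n1 = np.cross(e, p2 - p0)
    n2 = np.cross(p0 - p1, p3 - p1)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    en = np.linalg.norm(e, axis=1)
    theta = mesh.dihedral_angles()
    dtheta = theta - mesh.theta0
    if model == "tan_half":
        if np.any(np.abs(dtheta) > 3.0):
            raise MembraneDivergedError(
                "dihedral angle deviation approaching pi (tan singularity)")
        t = np.tan(0.5 * dtheta)
        dEdth = 0.5 * kB * t * (1.0 + t**2)
    elif model == "quadratic":
        dEdth = kB * dtheta
    else:
        raise ValueError(f"unknown bending model {model!r}")
    # dihedral-angle gradients (standard hinge formulas)
    a1 = en / n1sq
    a2 = en / n2sq
    g2 = -a1[:, None] * n1
    g3 = -a2[:, None] * n2
    c01 = np.einsum("ij,ij->i", p2 - p1, e) / en**2
    c02 = np.einsum("ij,ij->i", p3 - p1, e) / en**2
    c11 = np.einsum("ij,ij->i", p2 - p0, e) / en**2
    c12 = np.einsum("ij,ij->i", p3 - p0, e) / en**2
    g0 = -(c01 * a1)[:, None] * n1 - (c02 * a2)[:, None] * n2
    g1 = (c11 * a1)[:, None] * n1 + (c12 * a2)[:, None] * n2
    grads = dEdth[:, None, None] * np.stack([g0, g1, g2, g3], axis=1)
    return _accumulate(mesh.n_vertices, mesh.edges, grads)


@njit(cache=True, fastmath=True)
def _face_kernel(v, faces, h11, h12, h22, dets, w0, ks, ka, kA, kV,
                 A0, V0, grad):  # pragma: no cover
    """Fused per-face pass: Skalak + global area/volume gradients.

    Accumulates dE/dx into ``grad`` and returns (A, V) of the current mesh.
    The area/volume penalty gradients need the totals first, so the loop
    runs twice; both passes are cheap compared with the allocation-heavy
    vectorized route.
    """
    nf = faces.shape[0]
    A = 0.0
    V = 0.0
    for i in range(nf):
        i0, i1, i2 = faces[i, 0], faces[i, 1], faces[i, 2]
        ax = v[i1, 0] - v[i0, 0]
        ay = v[i1, 1] - v[i0, 1]
        az = v[i1, 2] - v[i0, 2]
        bx = v[i2, 0] - v[i0, 0]
        by = v[i2, 1] - v[i0, 1]
        bz = v[i2, 2] - v[i0, 2]
        nx = ay * bz - az * by
        ny = az * bx - ax * bz
        nz = ax * by - ay * bx
        A += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
        V += (v[i0, 0] * (v[i1, 1] * v[i2, 2] - v[i1, 2] * v[i2, 1])
              + v[i0, 1] * (v[i1, 2] * v[i2, 0] - v[i1, 0] * v[i2, 2])
              + v[i0, 2] * (v[i1, 0] * v[i2, 1] - v[i1, 1] * v[i2, 0])) / 6.0
    cA = kA * (A - A0) / (A0 * A0)
    cV = kV * (V - V0) / (V0 * V0)
    for i in range(nf):
        i0, i1, i2 = faces[i, 0], faces[i, 1], faces[i, 2]
        ax = v[i1, 0] - v[i0, 0]
        ay = v[i1, 1] - v[i0, 1]
        az = v[i1, 2] - v[i0, 2]
        bx = v[i2, 0] - v[i0, 0]
        by = v[i2, 1] - v[i0, 1]
        bz = v[i2, 2] - v[i0, 2]
        # Skalak: invariants from the metric against the reference inverse
        g11 = ax * ax + ay * ay + az * az
        g12 = ax * bx + ay * by + az * bz
        g22 = bx * bx + by * by + bz * bz
        det = g11 * g22 - g12 * g12
        I1 = h11[i] * g11 + 2.0 * h12[i] * g12 + h22[i] * g22 - 2.0
        I2 = det / dets[i] - 1.0
        dI1 = (ks / 12.0) * (2.0 * I1 + 2.0)
        dI2 = (ka * I2 - ks) / 6.0
        P = w0[i] * (dI1 * h11[i] + dI2 * g22 / dets[i])
        Q = w0[i] * (dI1 * 2.0 * h12[i] - dI2 * 2.0 * g12 / dets[i])
        R = w0[i] * (dI1 * h22[i] + dI2 * g11 / dets[i])
        g1x = 2.0 * P * ax + Q * bx
        g1y = 2.0 * P * ay + Q * by
        g1z = 2.0 * P * az + Q * bz
        g2x = 2.0 * R * bx + Q * ax
        g2y = 2.0 * R * by + Q * ay
        g2z = 2.0 * R * bz + Q * az
        # area + volume penalties
        nx = ay * bz - az * by
        ny = az * bx - ax * bz
        nz = ax * by - ay * bx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        hx = nx / nn
        hy = ny / nn
        hz = nz / nn
        dA1x = 0.5 * (by * hz - bz * hy)
        dA1y = 0.5 * (bz * hx - bx * hz)
        dA1z = 0.5 * (bx * hy - by * hx)
        dA2x = 0.5 * (hy * az - hz * ay)
        dA2y = 0.5 * (hz * ax - hx * az)
        dA2z = 0.5 * (hx * ay - hy * ax)
        g1x += cA * dA1x
        g1y += cA * dA1y
        g1z += cA * dA1z
        g2x += cA * dA2x
        g2y += cA * dA2y
        g2z += cA * dA2z
        # translation invariance of the in-plane and area terms
        g0x = -(g1x + g2x)
        g0y = -(g1y + g2y)
        g0z = -(g1z + g2z)
        # volume gradient (cyclic cross products; not translation-local)
        c0x = (v[i1, 1] * v[i2, 2] - v[i1, 2] * v[i2, 1]) / 6.0
        c0y = (v[i1, 2] * v[i2, 0] - v[i1, 0] * v[i2, 2]) / 6.0
        c0z = (v[i1, 0] * v[i2, 1] - v[i1, 1] * v[i2, 0]) / 6.0
        c1x = (v[i2, 1] * v[i0, 2] - v[i2, 2] * v[i0, 1]) / 6.0
        c1y = (v[i2, 2] * v[i0, 0] - v[i2, 0] * v[i0, 2]) / 6.0
        c1z = (v[i2, 0] * v[i0, 1] - v[i2, 1] * v[i0, 0]) / 6.0
        c2x = (v[i0, 1] * v[i1, 2] - v[i0, 2] * v[i1, 1]) / 6.0
        c2y = (v[i0, 2] * v[i1, 0] - v[i0, 0] * v[i1, 2]) / 6.0
        c2z = (v[i0, 0] * v[i1, 1] - v[i0, 1] * v[i1, 0]) / 6.0
        grad[i0, 0] += g0x + cV * c0x
        grad[i0, 1] += g0y + cV * c0y
        grad[i0, 2] += g0z + cV * c0z
        grad[i1, 0] += g1x + cV * c1x
        grad[i1, 1] += g1y + cV * c1y
        grad[i1, 2] += g1z + cV * c1z
        grad[i2, 0] += g2x + cV * c2x
        grad[i2, 1] += g2y + cV * c2y
        grad[i2, 2] += g2z + cV * c2z
    return A, V


@njit(cache=True, fastmath=True)
def _edge_kernel(v, edges, theta0, kB, tan_half, grad):  # pragma: no cover
    """Per-hinge bending-gradient pass.  Returns the worst |theta - theta0|
    (the caller raises on approach to the tan singularity)."""
    ne = edges.shape[0]
    worst = 0.0
    for i in range(ne):
        e0, e1, e2, e3 = edges[i, 0], edges[i, 1], edges[i, 2], edges[i, 3]
        ex = v[e1, 0] - v[e0, 0]
        ey = v[e1, 1] - v[e0, 1]
        ez = v[e1, 2] - v[e0, 2]
        ax = v[e2, 0] - v[e0, 0]
        ay = v[e2, 1] - v[e0, 1]
        az = v[e2, 2] - v[e0, 2]
        bx = v[e3, 0] - v[e1, 0]
        by = v[e3, 1] - v[e1, 1]
        bz = v[e3, 2] - v[e1, 2]
        # n1 = e x a ; n2 = (-e) x b
        n1x = ey * az - ez * ay
        n1y = ez * ax - ex * az
        n1z = ex * ay - ey * ax
        n2x = -(ey * bz - ez * by)
        n2y = -(ez * bx - ex * bz)
        n2z = -(ex * by - ey * bx)
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        en = np.sqrt(ex * ex + ey * ey + ez * ez)
        cx = n1y * n2z - n1z * n2y
        cy = n1z * n2x - n1x * n2z
        cz = n1x * n2y - n1y * n2x
        sin_t = (cx * ex + cy * ey + cz * ez) / (np.sqrt(n1sq * n2sq) * en)
        cos_t = (n1x * n2x + n1y * n2y + n1z * n2z) / np.sqrt(n1sq * n2sq)
        dth = np.arctan2(sin_t, cos_t) - theta0[i]
        adth = abs(dth)
        if adth > worst:
            worst = adth
        if tan_half:
            t = np.tan(0.5 * dth)
            dE = 0.5 * kB * t * (1.0 + t * t)
        else:
            dE = kB * dth
        a1 = en / n1sq
        a2 = en / n2sq
        # opposite vertices
        grad[e2, 0] += dE * (-a1 * n1x)
        grad[e2, 1] += dE * (-a1 * n1y)
        grad[e2, 2] += dE * (-a1 * n1z)
        grad[e3, 0] += dE * (-a2 * n2x)
        grad[e3, 1] += dE * (-a2 * n2y)
        grad[e3, 2] += dE * (-a2 * n2z)
        # edge vertices
        en2 = en * en
        c01 = ((v[e2, 0] - v[e1, 0]) * ex + (v[e2, 1] - v[e1, 1]) * ey
               + (v[e2, 2] - v[e1, 2]) * ez) / en2
        c02 = ((v[e3, 0] - v[e1, 0]) * ex + (v[e3, 1] - v[e1, 1]) * ey
               + (v[e3, 2] - v[e1, 2]) * ez) / en2
        c11 = ((v[e2, 0] - v[e0, 0]) * ex + (v[e2, 1] - v[e0, 1]) * ey
               + (v[e2, 2] - v[e0, 2]) * ez) / en2
        c12 = ((v[e3, 0] - v[e0, 0]) * ex + (v[e3, 1] - v[e0, 1]) * ey
               + (v[e3, 2] - v[e0, 2]) * ez) / en2
        grad[e0, 0] += dE * (-(c01 * a1) * n1x - (c02 * a2) * n2x)
        grad[e0, 1] += dE * (-(c01 * a1) * n1y - (c02 * a2) * n2y)
        grad[e0, 2] += dE * (-(c01 * a1) * n1z - (c02 * a2) * n2z)
        grad[e1, 0] += dE * ((c11 * a1) * n1x + (c12 * a2) * n2x)
        grad[e1, 1] += dE * ((c11 * a1) * n1y + (c12 * a2) * n2y)
        grad[e1, 2] += dE * ((c11 * a1) * n1z + (c12 * a2) * n2z)
    return worst


def membrane_forces(mesh: TriMesh, params: MembraneParams) -> np.ndarray:
    """Per-vertex elastic force, the analytic -dE/dx_n of all four energies.

    Translation and rotation invariance of the energies imply zero net force
    and zero net torque, up to floating-point round-off.  The hot path runs
    in two numba kernels (a face pass for the in-plane and area/volume
    terms, an edge pass for bending); the separate vectorized gradient
    helpers remain the readable reference and agree to round-off.
    """
    grad = np.zeros_like(mesh.vertices)
    A, V = _face_kernel(mesh.vertices, mesh.faces,
                        mesh.ref_h11, mesh.ref_h12, mesh.ref_h22,
                        mesh.ref_det, mesh.ref_face_area,
                        params.ks, params.kalpha, params.kA, params.kV,
                        mesh.A0, mesh.V0, grad)
    if not np.isfinite(A) or A <= 0.0:
        _, _ = mesh.face_normals_areas()    # raises naming the bad face
    if params.kB != 0.0:
        worst = _edge_kernel(mesh.vertices, mesh.edges, mesh.theta0,
                             params.kB, params.bending_model == "tan_half",
                             grad)
        if params.bending_model == "tan_half" and worst > 3.0:
            raise MembraneDivergedError(
                "dihedral angle deviation approaching pi (tan singularity)")
    return -grad
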