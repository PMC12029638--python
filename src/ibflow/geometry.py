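"""Vessel solid masks (straight and curved tubes) and analytic reference flows.

A vessel is a constant-diameter circular tube aligned with x, periodic in x.
The curved variant bends the centerline along a single-period sinusoid in the
x-y plane, y(x) = yc + A sin(2 pi x / L), which keeps the tube x-periodic and
the cross-section circular at every axial station.  Walls are voxelized
(staircase) and handled by halfway bounce-back in the solver, so a site is
fluid iff its perpendicular distance from the local centerline is < D/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ConfigError


@dataclass
class VesselGeometry:
    """Voxelized vessel: mask plus centerline description (lattice units)."""

    L: int                    # axial length (periodic)
    D: float                  # inner diameter
    shape: tuple              # full grid (Nx, Ny, Nz)
    amplitude: float = 0.0    # centerline bend amplitude
    yc: float = 0.0           # centerline y at amplitude 0
    zc: float = 0.0
    solid_mask: np.ndarray = field(default=None, repr=False)

    def centerline(self, x):
        """(y, z) of the centerline at axial position x (periodic in L)."""
        x = np.asarray(x, dtype=float)
        y = self.yc + self.amplitude * np.sin(2.0 * np.pi * x / self.L)
        return y, np.broadcast_to(np.asarray(self.zc), y.shape)

    @property
    def radius(self) -> float:
        return self.D / 2.0

    def radial_distance(self, points) -> np.ndarray:
        """Perpendicular distance of points (..., 3) from the local centerline."""
        pts = np.asarray(points, dtype=float)
        ycl, zcl = self.centerline(pts[..., 0])
        d = np.hypot(pts[..., 1] - ycl, pts[..., 2] - zcl)
        return float(d) if np.ndim(d) == 0 else d


def _tube_mask(L, D, shape, amplitude, yc, zc):
    nx, ny, nz = shape
    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    ycl = yc + amplitude * np.sin(2.0 * np.pi * x / L)
    r2 = (y - ycl) ** 2 + (z - zc) ** 2
    return r2 >= (D / 2.0) ** 2


def straight_vessel(L: int, D: float, grid: tuple) -> VesselGeometry:
    """Circular cylinder of diameter D along x on an (L, Ny, Nz) grid."""
    nx, ny, nz = grid
    if nx != L:
        raise ConfigError(f"grid x-extent {nx} must equal vessel length {L}")
    if D > min(ny, nz) - 1:
        raise ConfigError(f"diameter {D} does not fit the {ny}x{nz} cross-section")
    yc, zc = (ny - 1) / 2.0, (nz - 1) / 2.0
    mask = _tube_mask(L, D, grid, 0.0, yc, zc)
    return VesselGeometry(L=L, D=D, shape=grid, amplitude=0.0,
                          yc=yc, zc=zc, solid_mask=mask)


def curved_vessel(L: int, D: float, amplitude: float, grid: tuple) -> VesselGeometry:
    """Constant-diameter tube around the periodic centerline y(x) = A sin(2 pi x/L).

    ``amplitude=0`` reduces exactly to :func:`straight_vessel`.
    """
    nx, ny, nz = grid
    if nx != L:
        raise ConfigError(f"grid x-extent {nx} must equal vessel length {L}")
    yc, zc = (ny - 1) / 2.0, (nz - 1) / 2.0
    if amplitude + D / 2.0 > min(yc, ny - 1 - yc) + 0.5 or D > nz - 1:
        raise ConfigError(
            f"curved tube (amplitude {amplitude}, D {D}) clips the {ny}x{nz} "
            "grid cross-section"
        )
    mask = _tube_mask(L, D, grid, amplitude, yc, zc)
    return VesselGeometry(L=L, D=D, shape=grid, amplitude=amplitude,
                          yc=yc, zc=zc, solid_mask=mask)


def poiseuille_profile(a: float, nu: float, D: float, y) -> np.ndarray:
    """Pipe Poiseuille profile along a diametral line, u = a/(4 nu) y (D - y).

    With y measured across the diameter (walls at y = 0 and y = D) this is
    identical to the cylindrical form a/(4 nu)(R^2 - r^2), since
    R^2 - (y - R)^2 = y (D - y).  Note it is *not* the solution of the
    plane slit of width D, which carries a/(2 nu) instead (the slit loses
    the transverse curvature term); use :func:`poiseuille_profile_slit`
    for flat-plate channels.
    """
    y = np.asarray(y, dtype=float)
    return a / (4.0 * nu) * y * (D - y)


def poiseuille_profile_slit(a: float, nu: float, D: float, y) -> np.ndarray:
    """Plane-slit Poiseuille profile u(y) = a/(2 nu) y (D - y),
    walls at y = 0 and y = D."""
    y = np.asarray(y, dtype=float)
    return a / (2.0 * nu) * y * (D - y)


def poiseuille_profile_cylindrical(a: float, nu: float, R: float, r) -> np.ndarray:
    """Pipe Poiseuille profile u(r) = a/(4 nu) * (R^2 - r^2).

    The steady solution for a body-force-driven circular pipe of radius R;
    the correct reference for the 3-D cylindrical vessel validation.
    """
    r = np.asarray(r, dtype=float)
    return a / (4.0 * nu) * (R**2 - r**2)
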