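"""Shape and position diagnostics, equilibration detection, and the
validation / migration experiment drivers.

Shape is measured through the inertia ellipsoid of the solid enclosed by the
membrane: the second-moment tensor of the enclosed volume is computed
exactly from the triangulation (divergence theorem over tetrahedra), and the
equivalent-ellipsoid semi-axes follow from the solid-ellipsoid relation
S = diag(a^2, b^2, c^2)/5.  For an affinely deformed sphere mesh this
recovers the ellipsoid axes exactly, because the icosahedral reference mesh
has an exactly isotropic second moment.

The Taylor parameter D = (A - B)/(A + B) uses the major/minor semi-axes in
the shear (velocity-gradient) plane; the normalized time-dependent variant
rescales the current axes by their undeformed values, so it vanishes for an
undeformed particle of any shape and lies in (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .coupling import (Particle, Simulation, interpolate_scalar, place_particles)
from .geometry import poiseuille_profile_cylindrical, straight_vessel, curved_vessel
from .lbm import DistributionField
from .membrane import MembraneParams, TriMesh, icosphere, membrane_forces
from .units import (CS2, UnitSystem, mean_velocity_from_acceleration,
                    poiseuille_acceleration, unit_system_from_config,
                    ConfigError, RBC_PARAMS, DC_PARAMS)


# ---------------------------------------------------------------------------
# Shape diagnostics
# ---------------------------------------------------------------------------

def inertia_tensor(mesh: TriMesh):
    """Volume, centroid and exact second-moment tensor of the enclosed solid."""
    v0, v1, v2 = mesh.face_corners()
    vt = np.einsum("ij,ij->i", v0, np.cross(v1, v2)) / 6.0   # signed tetra volumes
    V = vt.sum()
    c = (vt[:, None] * (v0 + v1 + v2) / 4.0).sum(axis=0) / V
    s = v0 + v1 + v2
    outer = (
        np.einsum("i,ij,ik->jk", vt, v0, v0)
        + np.einsum("i,ij,ik->jk", vt, v1, v1)
        + np.einsum("i,ij,ik->jk", vt, v2, v2)
        + np.einsum("i,ij,ik->jk", vt, s, s)
    ) / 20.0
    S = outer / V - np.outer(c, c)      # covariance of the enclosed solid
    return float(V), c, S


def ellipsoid_semiaxes(mesh: TriMesh):
    """Equivalent-ellipsoid semi-axes (descending) and their directions."""
    _, _, S = inertia_tensor(mesh)
    evals, evecs = np.linalg.eigh(S)
    axes = np.sqrt(5.0 * np.clip(evals, 0.0, None))
    order = np.argsort(axes)[::-1]
    return axes[order], evecs[:, order]


def taylor_parameter(mesh: TriMesh, vorticity_axis: int = 2) -> float:
    """Taylor shape parameter D = (A - B)/(A + B) in the shear plane.

    The equivalent-ellipsoid axis most aligned with ``vorticity_axis`` is
    excluded; A and B are the larger/smaller of the remaining two.  Exactly
    zero for a sphere.  This shear-plane version is tied to the flow axes by
    construction and is therefore not invariant under arbitrary rigid
    rotations of the mesh (the normalized variant below is the one that
    vanishes for any undeformed shape).
    """
    axes, vecs = ellipsoid_semiaxes(mesh)
    k = int(np.argmax(np.abs(vecs[vorticity_axis, :])))
    inplane = [axes[i] for i in range(3) if i != k]
    A, B = max(inplane), min(inplane)
    return (A - B) / (A + B)


def taylor_radii(mesh: TriMesh):
    """Overall major and minor equivalent-ellipsoid semi-axes (a, b)."""
    axes, _ = ellipsoid_semiaxes(mesh)
    return float(axes[0]), float(axes[2])


def taylor_parameter_normalized(mesh: TriMesh, a0: float, b0: float) -> float:
    """Deformation tracker D(t) = (a^ - b^)/(a^ + b^), a^ = a/a0, b^ = b/b0.

    Zero when the particle keeps its undeformed axis ratio; always in (-1, 1).
    """
    if a0 <= 0 or b0 <= 0:
        raise ValueError("undeformed radii must be positive")
    a, b = taylor_radii(mesh)
    ah, bh = a / a0, b / b0
    return (ah - bh) / (ah + bh)


def capillary_number(mu: float, gamma: float, r_p: float, ks: float) -> float:
    """Ca = mu gamma r_p / ks (consistent units)."""
    if min(mu, gamma, r_p, ks) <= 0:
        raise ValueError("capillary_number needs positive arguments")
    return mu * gamma * r_p / ks


def distance_d(mesh: TriMesh, geometry) -> float:
    """Cross-sectional distance of the particle center from the centerline."""
    c = mesh.centroid()
    c = np.array([c[0] % geometry.L, c[1], c[2]])
    return float(geometry.radial_distance(c))


def equilibration_time(times, values, tol: float, window_frac: float = 0.2):
    """First time after which the trailing-window mean stays within ``tol``
    of its final value through the end of the series.

    Returns ``None`` ("not reached") when only the final window qualifies.
    """
    t = np.asarray(times, dtype=float)
    d = np.asarray(values, dtype=float)
    n = len(d)
    w = max(2, int(np.ceil(window_frac * n)))
    if n <= w:
        raise ValueError("series shorter than the detection window")
    kernel = np.ones(w) / w
    means = np.convolve(d, kernel, mode="valid")        # means[j] over d[j:j+w]
    final = means[-1]
    ok = np.abs(means - final) < tol
    # earliest window index from which every later window stays in band
    idx = len(ok)
    for j in range(len(ok) - 1, -1, -1):
        if not ok[j]:
            break
        idx = j
    # require the plateau to span at least one full window before the end,
    # otherwise a slowly drifting series would always "equilibrate" at its tail
    if idx > len(ok) - 1 - w:
        return None
    return float(t[idx])


# ---------------------------------------------------------------------------
# Experiment: body-force-driven pipe flow validation
# ---------------------------------------------------------------------------

@dataclass
class PoiseuilleResult:
    y: np.ndarray               # diametral line positions (lattice)
    r: np.ndarray               # radial coordinate
    u_sim: np.ndarray           # axial velocity, lattice units
    u_ana: np.ndarray           # analytic pipe profile
    l2_error: float
    steps: int
    ax: float
    nu: float
    Re: float


def run_poiseuille_validation(D: int = 20, L: int | None = None,
                              tau: float | None = None,
                              us: UnitSystem | None = None,
                              u_max: float = 0.05,
                              steady_tol: float = 1e-7,
                              max_steps: int = 60_000) -> PoiseuilleResult:
    """Drive a straight cylindrical vessel to steady state with a body force
    and compare the radial profile against the analytic pipe solution.

    ``tau`` defaults to the relaxation time of the unit system (the
    viscosity-relaxation relation); the body force is sized for a target
    centerline velocity ``u_max`` (lattice units, kept well below cs).
    """
    us = us or UnitSystem()
    tau = tau if tau is not None else us.tau
    nu = (tau - 0.5) * CS2
    L = L or D
    # even cross-section puts the axis at a cell center, which de-biases the
    # staircase wall: the halfway bounce-back surface then straddles the
    # nominal radius symmetrically instead of hitting lattice-aligned rings
    n_cross = D + 4 if D % 2 == 0 else D + 3
    geo = straight_vessel(L, D, (L, n_cross, n_cross))
    R = D / 2.0
    ax = 4.0 * nu * u_max / R**2
    fld = DistributionField(geo.solid_mask.shape, solid=geo.solid_mask)
    u_prev = None
    check = 250
    while fld.t < max_steps:
        fld.clear_forces()
        fld.add_body_force(ax)
        for _ in range(check):
            fld.step(tau)
        _, u = fld.macroscopic()
        if u_prev is not None:
            diff = np.abs(u - u_prev).max()
            if diff < steady_tol * max(np.abs(u).max(), 1e-30):
                break
        u_prev = u
    _, u = fld.macroscopic()
    yc, zc = geo.yc, geo.zc
    iz = int(np.floor(zc))          # sampling line nearest the axis
    iy = np.arange(fld.shape[1])
    line_fluid = ~geo.solid_mask[0, :, iz]
    y = iy[line_fluid].astype(float)
    r = np.hypot(y - yc, iz - zc)
    u_sim = u[0, line_fluid, iz, 0]
    u_ana = poiseuille_profile_cylindrical(ax, nu, R, r)
    denom = float((u_ana**2).sum())
    l2 = float(np.sqrt(((u_sim - u_ana) ** 2).sum() / denom)) if denom else 0.0
    Um = u_sim.mean()
    return PoiseuilleResult(y=y, r=r, u_sim=u_sim, u_ana=u_ana, l2_error=l2,
                            steps=fld.t, ax=ax, nu=nu, Re=Um * D / nu)


# ---------------------------------------------------------------------------
# Experiment: capsule in wall-driven shear
# ---------------------------------------------------------------------------

@dataclass
class ShearCapsuleResult:
    times: np.ndarray
    D_series: np.ndarray
    D_steady: float
    Ca: float
    D_over_Ca: float
    gamma: float
    ks_lat: float
    steps: int


def run_shear_capsule(Ca: float = 0.03, n: int = 30, radius: float = 5.0,
                      faces: int = 1280, tau: float = 1.0,
                      wall_speed: float = 0.02, kalpha_ratio: float = 1.0,
                      steady_rtol: float = 1e-3, steady_window: int = 1000,
                      max_steps: int = 40_000,
                      record_every: int = 50) -> ShearCapsuleResult:
    """Deform an initially spherical capsule between counter-moving plates.

    The cubic n^3 domain has plates at the y-extremes moving at +-wall_speed
    along x (velocity bounce-back), periodic x and z.  The shear rate is
    gamma = 2 wall_speed / H with H the wall-to-wall gap; the capsule shear
    modulus is sized from the target capillary number, Ca = mu gamma r / ks.
    The run stops when the Taylor parameter changes by less than
    ``steady_rtol`` (relative) over ``steady_window`` steps.
    """
    if not 0 < Ca < 1:
        raise ConfigError("Ca must be in (0, 1)")
    solid = np.zeros((n, n, n), dtype=bool)
    solid[:, 0, :] = True
    solid[:, -1, :] = True
    H = n - 2                     # halfway walls at y = 0.5 and n - 1.5
    gamma = 2.0 * wall_speed / H
    mu = (tau - 0.5) * CS2        # rho_lat = 1
    ks = mu * gamma * radius / Ca
    params = MembraneParams(ks=ks, kalpha=kalpha_ratio * ks,
                            kB=0.0, kA=0.0, kV=0.0)
    fld = DistributionField((n, n, n), solid=solid)
    fld.wall_ux[:, 0, :] = -wall_speed
    fld.wall_ux[:, -1, :] = wall_speed
    center = ((n - 1) / 2.0, (n - 1) / 2.0, (n - 1) / 2.0)
    mesh = icosphere(radius, faces).translate(center)
    sim = Simulation(fld, tau, [Particle(mesh, params, "capsule")])
    times, series = [], []
    D_prev, t_prev = None, 0
    while sim.t < max_steps:
        sim.coupled_step()
        if sim.t % record_every == 0:
            Dnow = taylor_parameter(mesh)
            times.append(sim.t)
            series.append(Dnow)
            if D_prev is not None and sim.t - t_prev >= steady_window:
                if abs(Dnow - D_prev) < steady_rtol * max(abs(Dnow), 1e-12):
                    break
                D_prev, t_prev = Dnow, sim.t
            elif D_prev is None:
                D_prev, t_prev = Dnow, sim.t
    D_steady = series[-1]
    return ShearCapsuleResult(times=np.asarray(times), D_series=np.asarray(series),
                              D_steady=float(D_steady), Ca=Ca,
                              D_over_Ca=float(D_steady / Ca), gamma=gamma,
                              ks_lat=ks, steps=sim.t)


def shear_capsule_limit(ca_points=(0.01, 0.03), **kw):
    """Estimate the Ca -> 0 limit of D/Ca by linear extrapolation in Ca.

    Runs the shear-capsule case at each given capillary number and fits
    D/Ca = p0 + p1 Ca; returns ``(p0, results)``.
    """
    results = [run_shear_capsule(Ca=ca, **kw) for ca in ca_points]
    cas = np.array([r.Ca for r in results])
    ratios = np.array([r.D_over_Ca for r in results])
    p1, p0 = np.polyfit(cas, ratios, 1)
    return float(p0), results


# ---------------------------------------------------------------------------
# Experiment: particle migration in a vessel
# ---------------------------------------------------------------------------

@dataclass
class MigrationRecord:
    """Per-particle time series of the migration diagnostics (lattice units,
    except ``d_phys`` and ``t_ms``)."""

    label: str
    t: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    d: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    D: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    fmax: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    vmean: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    pressure: np.ndarray = dfield(default_factory=lambda: np.empty(0))
    t_eq: float | None = None


@dataclass
class MigrationResult:
    records: list
    geometry: object
    us: UnitSystem
    Re: float
    steps: int

    def record(self, label: str) -> MigrationRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(label)


#: full-scale reference for dynamic-similarity scaling: vessel diameter and
#: peak velocity (lattice units) of the physical-scale migration problem
FULL_SCALE = {"D": 50.0, "u_max": 0.0012, "rbc_radius": 3.5, "dc_radius": 1.5}


def _similarity_scale(params: MembraneParams, r_full: float, r_scaled: float,
                      gamma_full: float, gamma_scaled: float) -> MembraneParams:
    """Rescale membrane moduli so a scaled-down particle keeps the full-scale
    dimensionless elasticity.

    Preserved groups: the capillary number Ca = mu gamma r / ks (so
    ks' = ks (gamma' r')/(gamma r)), the modulus ratios kalpha/ks, kA/ks,
    the reduced bending stiffness kB/(ks r^2) and reduced volume stiffness
    kV r / ks.  Raw physical moduli at a shrunken radius and slower shear
    would otherwise overstate deformability (the capillary number of the
    scaled run would be several times the physical one).
    """
    s = (gamma_scaled * r_scaled) / (gamma_full * r_full)
    return MembraneParams(
        ks=params.ks * s,
        kalpha=params.kalpha * s,
        kB=params.kB * s * (r_scaled / r_full) ** 2,
        kA=params.kA * s,
        kV=params.kV * s * (r_full / r_scaled),
        bending_model=params.bending_model,
    )


def run_vessel_migration(cfg: dict) -> MigrationResult:
    """Full coupled simulation of RBC/DC migration in a (scaled-down) vessel.

    The configuration follows :data:`ibflow.units.DEFAULT_CONFIG`; the body
    force is sized from the target Reynolds number through the mean-velocity
    relation Um = ax D^2/(32 nu), Re = Um D/nu.  Membrane moduli are, by
    default, rescaled for dynamic similarity with the full-scale problem
    (see :func:`_similarity_scale`); set ``run.moduli_scaling: direct`` to
    use the raw converted tables instead.  With no particles the run reduces
    to the bare Poiseuille problem.
    """
    us = unit_system_from_config(cfg)
    tau = us.tau
    nu = us.nu_lat
    geo_cfg = cfg["geometry"]
    grid = (geo_cfg["L"], geo_cfg["ny"], geo_cfg["nz"])
    if geo_cfg["type"] == "curved" and geo_cfg.get("amplitude", 0.0) > 0:
        geo = curved_vessel(geo_cfg["L"], geo_cfg["D"], geo_cfg["amplitude"], grid)
    else:
        geo = straight_vessel(geo_cfg["L"], geo_cfg["D"], grid)
    run = cfg["run"]
    ax = poiseuille_acceleration(run["Re"], nu, geo.D)
    bending = run.get("bending_model", "tan_half")
    pc = cfg["particles"]
    rbc_params = MembraneParams.from_physical(RBC_PARAMS, us, bending_model=bending)
    dc_table = dict(DC_PARAMS)
    dc_table.update(cfg.get("dc_moduli", {}))
    dc_params = MembraneParams.from_physical(dc_table, us, bending_model=bending)
    if run.get("moduli_scaling", "similarity") == "similarity":
        u_max = 2.0 * mean_velocity_from_acceleration(ax, geo.D, nu)
        gamma_scaled = 4.0 * u_max / geo.D
        gamma_full = 4.0 * FULL_SCALE["u_max"] / FULL_SCALE["D"]
        rbc_params = _similarity_scale(rbc_params, FULL_SCALE["rbc_radius"],
                                       pc["rbc_radius"], gamma_full, gamma_scaled)
        dc_params = _similarity_scale(dc_params, FULL_SCALE["dc_radius"],
                                      pc["dc_radius"], gamma_full, gamma_scaled)
    rbc_d0 = pc.get("rbc_d0_frac", pc.get("d0_frac", 0.6)) * geo.radius
    dc_d0 = pc.get("dc_d0_frac", pc.get("d0_frac", 0.6)) * geo.radius
    specs = [
        {"kind": "rbc", "radius": pc["rbc_radius"], "faces": pc["rbc_faces"],
         "params": rbc_params, "label": f"rbc{i}", "d0": rbc_d0}
        for i in range(pc["n_rbc"])
    ] + [
        {"kind": "dc", "radius": pc["dc_radius"], "faces": pc["dc_faces"],
         "params": dc_params, "label": f"dc{i}", "d0": dc_d0}
        for i in range(pc["n_dc"])
    ]
    mode = pc.get("placement", "random")
    d0 = pc.get("d0_frac", 0.6) * geo.radius if mode == "ring" else None
    particles = place_particles(geo, specs, seed=cfg["seed"], mode=mode, d0=d0)
    fld = DistributionField(geo.solid_mask.shape, solid=geo.solid_mask)
    sim = Simulation(fld, tau, particles, body_accel=(ax, 0.0, 0.0),
                     geometry=geo,
                     membrane_substeps=run.get("membrane_substeps", 1))
    records = {p.label: MigrationRecord(label=p.label) for p in particles}
    series = {p.label: {"t": [], "d": [], "D": [], "fmax": [], "vmean": [],
                        "p": []} for p in particles}
    radii0 = {p.label: taylor_radii(p.mesh) for p in particles}

    every = run.get("record_every", 200)
    snap_every = int(run.get("snapshot_every", 0) or 0)
    snap_dir = run.get("snapshot_dir")

    def snapshot(s: Simulation) -> None:
        from pathlib import Path
        from .io import write_polydata_vtk, write_structured_vtk
        path = Path(snap_dir)
        path.mkdir(parents=True, exist_ok=True)
        write_structured_vtk(
            path / f"field_{s.t:08d}.vtk",
            {"rho": s.rho,
             "u": s.u,
             "F": np.stack([s.field.Fx, s.field.Fy, s.field.Fz], axis=-1)})
        for p in s.particles:
            write_polydata_vtk(path / f"{p.label}_{s.t:08d}.vtk", p.mesh)

    def recorder(s: Simulation) -> None:
        if snap_every and snap_dir and s.t % snap_every == 0:
            snapshot(s)
        for p in s.particles:
            a0, b0 = radii0[p.label]
            ser = series[p.label]
            ser["t"].append(s.t)
            ser["d"].append(distance_d(p.mesh, geo))
            ser["D"].append(taylor_parameter_normalized(p.mesh, a0, b0))
            fr = membrane_forces(p.mesh, p.params)
            ser["fmax"].append(float(np.linalg.norm(fr, axis=1).max()))
            ser["vmean"].append(
                float(np.linalg.norm(p.node_velocities, axis=1).mean()))
            c = p.mesh.centroid()
            c[0] %= geo.L
            ser["p"].append(float(CS2 * interpolate_scalar(s.rho, c[None, :])[0]))

    sim.run(run["steps"], callback=recorder, callback_every=every)

    for p in sim.particles:
        ser = series[p.label]
        rec = records[p.label]
        rec.t = np.asarray(ser["t"], dtype=float)
        rec.d = np.asarray(ser["d"])
        rec.D = np.asarray(ser["D"])
        rec.fmax = np.asarray(ser["fmax"])
        rec.vmean = np.asarray(ser["vmean"])
        rec.pressure = np.asarray(ser["p"])
        tol = 0.02 * geo.radius
        try:
            rec.t_eq = equilibration_time(rec.t, rec.d, tol=tol)
        except ValueError:
            rec.t_eq = None
    return MigrationResult(records=list(records.values()), geometry=geo,
                           us=us, Re=run["Re"], steps=sim.t)
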