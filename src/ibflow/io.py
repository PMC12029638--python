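"""Plain-text writers (legacy VTK, OFF, CSV) and HDF5 checkpointing.

The VTK writers emit the legacy ASCII format (STRUCTURED_POINTS for Eulerian
fields, POLYDATA for membrane meshes), which every ParaView/VTK build reads;
only the small subset needed for field and mesh snapshots is implemented.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np


def write_structured_vtk(path, fields: dict, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write grid fields to a legacy ASCII VTK STRUCTURED_POINTS file.

    ``fields`` maps names to arrays of shape (Nx, Ny, Nz) (scalars) or
    (Nx, Ny, Nz, 3) (vectors); all must share the same grid.
    """
    arrays = {k: np.asarray(v) for k, v in fields.items()}
    shapes = {v.shape[:3] for v in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nibflow field snapshot\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in arrays.items():
            flat = arr.transpose((2, 1, 0) + tuple(range(3, arr.ndim)))
            if arr.ndim == 3:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, flat.reshape(-1, 1), fmt="%.9g")
            elif arr.ndim == 4 and arr.shape[3] == 3:
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, flat.reshape(-1, 3), fmt="%.9g")
            else:
                raise ValueError(f"field {name!r} has unsupported shape {arr.shape}")


def write_polydata_vtk(path, mesh, point_data: dict | None = None) -> None:
    """Write a membrane mesh (and optional per-vertex data) as VTK POLYDATA."""
    v = mesh.vertices
    f = mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nibflow membrane\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        np.savetxt(fh, v, fmt="%.9g")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {len(v)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    np.savetxt(fh, arr, fmt="%.9g")


def write_off(path, mesh) -> None:
    """Write a membrane mesh in the OFF polygon format."""
    v = mesh.vertices
    f = mesh.faces
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(v)} {len(f)} {3 * len(f) // 2}\n")
        np.savetxt(fh, v, fmt="%.9g")
        np.savetxt(fh, np.column_stack([np.full(len(f), 3), f]), fmt="%d")


def write_timeseries_csv(path, record) -> None:
    """Write a MigrationRecord (t, d, D, force/velocity/pressure) as CSV."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["t", "d", "D", "fmax", "vmean", "pressure"])
        for row in zip(record.t, record.d, record.D, record.fmax,
                       record.vmean, record.pressure):
            wr.writerow([f"{x:.9g}" for x in row])


def save_checkpoint(path, sim) -> None:
    """Store the full coupled state (populations, forces, meshes, clock)."""
    with h5py.File(path, "w") as h5:
        h5.attrs["t"] = sim.t
        h5.attrs["tau"] = sim.tau
        h5.attrs["kernel"] = sim.kernel
        h5.create_dataset("f", data=sim.field.f, compression="gzip")
        h5.create_dataset("solid", data=sim.field.solid)
        h5.create_dataset("wall_ux", data=sim.field.wall_ux)
        h5.create_dataset("body_accel", data=sim.body_accel)
        for k, p in enumerate(sim.particles):
            grp = h5.create_group(f"particle{k}")
            grp.attrs["label"] = p.label
            for name in ("ks", "kalpha", "kB", "kA", "kV"):
                grp.attrs[name] = getattr(p.params, name)
            grp.attrs["bending_model"] = p.params.bending_model
            grp.create_dataset("vertices", data=p.mesh.vertices)
            grp.create_dataset("faces", data=p.mesh.faces)
            grp.create_dataset("node_velocities", data=p.node_velocities)
            ref = grp.create_group("reference")
            for name in ("ref_det", "ref_h11", "ref_h12", "ref_h22",
                         "ref_face_area", "theta0"):
                ref.create_dataset(name, data=getattr(p.mesh, name))
            ref.attrs["A0"] = p.mesh.A0
            ref.attrs["V0"] = p.mesh.V0


def load_checkpoint(path, geometry=None):
    """Restore a :class:`~ibflow.coupling.Simulation` from a checkpoint."""
    from .coupling import Particle, Simulation
    from .lbm import DistributionField
    from .membrane import MembraneParams, TriMesh

    with h5py.File(path, "r") as h5:
        solid = h5["solid"][...]
        fld = DistributionField(solid.shape, solid=solid)
        fld.f = np.ascontiguousarray(h5["f"][...])
        fld._fbuf = fld.f.copy()
        fld.wall_ux = h5["wall_ux"][...]
        fld.t = int(h5.attrs["t"])
        particles = []
        k = 0
        while f"particle{k}" in h5:
            grp = h5[f"particle{k}"]
            mesh = TriMesh(grp["vertices"][...], grp["faces"][...],
                           set_reference=False)
            ref = grp["reference"]
            for name in ("ref_det", "ref_h11", "ref_h12", "ref_h22",
                         "ref_face_area", "theta0"):
                setattr(mesh, name, ref[name][...])
            mesh.A0 = float(ref.attrs["A0"])
            mesh.V0 = float(ref.attrs["V0"])
            params = MembraneParams(
                ks=float(grp.attrs["ks"]), kalpha=float(grp.attrs["kalpha"]),
                kB=float(grp.attrs["kB"]), kA=float(grp.attrs["kA"]),
                kV=float(grp.attrs["kV"]),
                bending_model=str(grp.attrs["bending_model"]),
            )
            p = Particle(mesh, params, label=str(grp.attrs["label"]))
            p.node_velocities = grp["node_velocities"][...]
            particles.append(p)
            k += 1
        sim = Simulation(fld, float(h5.attrs["tau"]), particles,
                         body_accel=h5["body_accel"][...],
                         kernel=str(h5.attrs["kernel"]), geometry=geometry)
    return sim
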