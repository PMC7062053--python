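"""File I/O: CSV centerlines/waveforms, ASCII STL/VTK meshes, field containers.

Legacy ASCII VTK writers/readers are implemented here directly (polydata for
wall surfaces with per-vertex scalar arrays, structured points for voxel
velocity frames); the HDF5 single-file layout uses h5py. Binary formats are
deliberately not supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .fields import FlowWaveform, VelocityField4D

__all__ = [
    "write_centerline_csv",
    "read_centerline_csv",
    "write_waveform_csv",
    "read_waveform_csv",
    "write_stl",
    "write_vtk_polydata",
    "read_vtk_polydata",
    "write_field_hdf5",
    "read_field_hdf5",
    "write_field_vtk_series",
    "read_field_vtk_series",
]


# ---------------------------------------------------------------------------
# CSV

def write_centerline_csv(path, centerline, radius, thickness) -> None:
    """Write a centerline as CSV with columns x,y,z,radius,thickness (mm)."""
    pts = np.asarray(centerline, dtype=float)
    n = len(pts)
    df = pd.DataFrame(
        {
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "radius": np.broadcast_to(np.asarray(radius, float), (n,)),
            "thickness": np.broadcast_to(np.asarray(thickness, float), (n,)),
        }
    )
    df.to_csv(path, index=False)


def read_centerline_csv(path):
    """Return (points (n,3), radius (n,), thickness (n,)) in mm."""
    df = pd.read_csv(path)
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return pts, df["radius"].to_numpy(dtype=float), df["thickness"].to_numpy(dtype=float)


def write_waveform_csv(path, waveform: FlowWaveform) -> None:
    """Write a flow waveform as CSV with a unit-bearing header."""
    pd.DataFrame({"time_ms": waveform.times_ms, "flow_mL_s": waveform.flow_ml_s}).to_csv(
        path, index=False
    )


def read_waveform_csv(path, plane: str = "") -> FlowWaveform:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns or "flow_mL_s" not in df.columns:
        raise ValueError("waveform CSV must have columns time_ms, flow_mL_s")
    return FlowWaveform(
        times_ms=df["time_ms"].to_numpy(float),
        flow_ml_s=df["flow_mL_s"].to_numpy(float),
        plane=plane,
    )


# ---------------------------------------------------------------------------
# STL (ASCII, geometry only)

def write_stl(path, vertices, faces, name: str = "vessel") -> None:
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    with open(path, "w") as f:
        f.write(f"solid {name}\n")
        for tri in faces:
            a, b, c = vertices[tri]
            n = np.cross(b - a, c - a)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            f.write(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}\n")
            f.write("    outer loop\n")
            for v in (a, b, c):
                f.write(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            f.write("    endloop\n")
            f.write("  endfacet\n")
        f.write(f"endsolid {name}\n")


# ---------------------------------------------------------------------------
# Legacy ASCII VTK polydata (surface + per-vertex scalars)

def write_vtk_polydata(path, vertices, faces, point_data: dict | None = None) -> None:
    """Write a triangulated surface with optional per-vertex scalar arrays.

    ``point_data`` maps array names to 1D numeric arrays (one value per
    vertex). String label arrays should be integer-coded by the caller.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    lines = ["# vtk DataFile Version 3.0", "aortassr surface", "ASCII", "DATASET POLYDATA"]
    lines.append(f"POINTS {len(vertices)} float")
    lines.extend(" ".join(f"{x:.9g}" for x in v) for v in vertices)
    lines.append(f"POLYGONS {len(faces)} {4 * len(faces)}")
    lines.extend("3 " + " ".join(str(i) for i in tri) for tri in faces)
    if point_data:
        lines.append(f"POINT_DATA {len(vertices)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.shape != (len(vertices),):
                raise ValueError(f"point data {name!r} must be 1D with one value per vertex")
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
            lines.append(f"SCALARS {name} {kind} 1")
            lines.append("LOOKUP_TABLE default")
            fmt = "{:d}" if kind == "int" else "{:.9g}"
            lines.extend(fmt.format(v) for v in arr.tolist())
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_polydata(path):
    """Read back a surface written by :func:`write_vtk_polydata`.

    Returns (vertices, faces, point_data dict).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    vertices = faces = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    line = next(it, None)
    while line is not None:
        parts = line.split()
        if parts[:1] == ["POINTS"]:
            n_points = int(parts[1])
            vals = []
            while len(vals) < 3 * n_points:
                vals.extend(float(x) for x in next(it).split())
            vertices = np.array(vals).reshape(n_points, 3)
        elif parts[:1] == ["POLYGONS"]:
            n_faces = int(parts[1])
            out = []
            for _ in range(n_faces):
                row = [int(x) for x in next(it).split()]
                if row[0] != 3:
                    raise ValueError("only triangle polygons are supported")
                out.append(row[1:])
            faces = np.array(out, dtype=int)
        elif parts[:1] == ["SCALARS"]:
            name, kind = parts[1], parts[2]
            next(it)  # LOOKUP_TABLE line
            vals = []
            while len(vals) < n_points:
                vals.extend(next(it).split())
            dtype = int if kind == "int" else float
            point_data[name] = np.array([dtype(v) for v in vals])
        line = next(it, None)
    if vertices is None or faces is None:
        raise ValueError(f"{path} is not a supported VTK polydata file")
    return vertices, faces, point_data


# ---------------------------------------------------------------------------
# VelocityField4D containers

def write_field_hdf5(path, field: VelocityField4D) -> None:
    """Single-file HDF5 layout: datasets velocities, mask, times, spacing, origin."""
    with h5py.File(path, "w") as f:
        f.create_dataset("velocities", data=field.velocities, compression="gzip")
        f.create_dataset("mask", data=field.lumen_mask.astype(np.uint8), compression="gzip")
        f.create_dataset("times", data=field.frame_times_ms)
        f.create_dataset("spacing", data=field.spacing)
        f.create_dataset("origin", data=field.origin)
        f.attrs["units_velocity"] = "m/s"
        f.attrs["units_length"] = "mm"
        f.attrs["units_time"] = "ms"


def read_field_hdf5(path) -> VelocityField4D:
    with h5py.File(path, "r") as f:
        return VelocityField4D(
            origin=f["origin"][()],
            spacing=f["spacing"][()],
            frame_times_ms=f["times"][()],
            velocities=f["velocities"][()],
            lumen_mask=f["mask"][()].astype(bool),
        )


def _write_structured_points(path, field: VelocityField4D, frame: int) -> None:
    nx, ny, nz = field.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"aortassr velocity frame t={field.frame_times_ms[frame]:.6g} ms",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {field.origin[0]:.9g} {field.origin[1]:.9g} {field.origin[2]:.9g}",
        f"SPACING {field.spacing[0]:.9g} {field.spacing[1]:.9g} {field.spacing[2]:.9g}",
        f"POINT_DATA {nx * ny * nz}",
        "VECTORS velocity float",
    ]
    # VTK structured points iterate x fastest
    v = np.transpose(field.velocities[frame], (2, 1, 0, 3)).reshape(-1, 3)
    lines.extend(" ".join(f"{x:.7g}" for x in row) for row in v)
    lines.append("SCALARS lumen_mask int 1")
    lines.append("LOOKUP_TABLE default")
    m = np.transpose(field.lumen_mask, (2, 1, 0)).reshape(-1).astype(int)
    lines.extend(str(x) for x in m.tolist())
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_vtk_series(directory, field: VelocityField4D, basename: str = "frame") -> None:
    """One legacy ASCII VTK structured-points file per frame + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for k in range(field.n_frames):
        name = f"{basename}_{k:04d}.vtk"
        _write_structured_points(directory / name, field, k)
        names.append(name)
    manifest = {
        "files": names,
        "frame_times_ms": field.frame_times_ms.tolist(),
        "origin_mm": field.origin.tolist(),
        "spacing_mm": field.spacing.tolist(),
        "dimensions": list(field.shape),
        "units_velocity": "m/s",
    }
    (directory / f"{basename}_manifest.json").write_text(json.dumps(manifest, indent=1))


def read_field_vtk_series(directory, basename: str = "frame") -> VelocityField4D:
    directory = Path(directory)
    manifest = json.loads((directory / f"{basename}_manifest.json").read_text())
    nx, ny, nz = manifest["dimensions"]
    frames = []
    mask = None
    for name in manifest["files"]:
        lines = (directory / name).read_text().split("\n")
        i = lines.index("VECTORS velocity float")
        vals = []
        j = i + 1
        while len(vals) < 3 * nx * ny * nz:
            vals.extend(float(x) for x in lines[j].split())
            j += 1
        v = np.array(vals).reshape(nz, ny, nx, 3).transpose(2, 1, 0, 3)
        frames.append(v)
        k = next(idx for idx, ln in enumerate(lines) if ln.startswith("SCALARS lumen_mask"))
        mvals: list[int] = []
        j = k + 2
        while len(mvals) < nx * ny * nz:
            mvals.extend(int(x) for x in lines[j].split())
            j += 1
        mask = np.array(mvals).reshape(nz, ny, nx).transpose(2, 1, 0).astype(bool)
    return VelocityField4D(
        origin=np.array(manifest["origin_mm"]),
        spacing=np.array(manifest["spacing_mm"]),
        frame_times_ms=np.array(manifest["frame_times_ms"]),
        velocities=np.stack(frames),
        lumen_mask=mask,
    )
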