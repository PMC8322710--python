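"""Plain-text geometry and field output: legacy-ASCII VTK polydata and PLY.

The legacy VTK writer covers exactly what this package needs — triangle
polydata with integer/scalar/vector point-data arrays — and keeps the output
greppable.  PLY export delegates to trimesh.
"""

from __future__ import annotations

import os

import numpy as np

from .geometry import EyeGeometry
from .sheardyn import TractionSeries


def write_vtk_polydata(path, vertices: np.ndarray, faces: np.ndarray, point_data: dict | None = None) -> None:
    """Write triangle polydata with optional per-vertex arrays.

    ``point_data`` maps names to (n,) int/float arrays or (n, 3) float arrays.
    """
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        "oculotamp surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [" ".join(f"{c:.8g}" for c in p) for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in f]
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, arr in point_data.items():
            a = np.asarray(arr)
            if a.ndim == 2 and a.shape[1] == 3:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{c:.8g}" for c in row) for row in a]
            else:
                kind = "int" if np.issubdtype(a.dtype, np.integer) or a.dtype == bool else "float"
                lines.append(f"SCALARS {name} {kind} 1")
                lines.append("LOOKUP_TABLE default")
                if kind == "int":
                    lines += [str(int(x)) for x in a]
                else:
                    lines += [f"{float(x):.8g}" for x in a]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_geometry(path_vtk, geom: EyeGeometry, extra_point_data: dict | None = None) -> None:
    """Labeled chamber mesh as VTK polydata (arrays ``region``, ``hemisphere``)."""
    data = {}
    if geom.vertex_region is not None:
        data["region"] = geom.vertex_region.astype(np.int32)
        data["hemisphere"] = geom.vertex_hemisphere.astype(np.int32)
    if extra_point_data:
        data.update(extra_point_data)
    write_vtk_polydata(path_vtk, geom.vertices, geom.triangles, data)


def write_ply(path, geom: EyeGeometry) -> None:
    geom.mesh.export(path, file_type="ply", encoding="ascii")


def write_traction_series(directory, prefix: str, series: TractionSeries, geom: EyeGeometry, stride: int = 10) -> list[str]:
    """One VTK polydata file per ``stride``-th sample with a ``traction_Pa``
    vector array; returns the written paths."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i in range(0, len(series.times), stride):
        p = os.path.join(directory, f"{prefix}_{i:04d}.vtk")
        write_vtk_polydata(
            p,
            geom.vertices,
            geom.triangles,
            {"traction_Pa": series.vectors(i)},
        )
        paths.append(p)
    return paths


def read_vtk_point_data(path) -> dict:
    """Minimal reader for the arrays this package writes (round-trip checks)."""
    out: dict = {}
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    n_points = 0
    while i < len(tokens):
        line = tokens[i].split()
        if line[:1] == ["POINTS"]:
            n_points = int(line[1])
            out["points"] = np.array(
                [[float(x) for x in tokens[i + 1 + k].split()] for k in range(n_points)]
            )
            i += n_points
        elif line[:1] == ["SCALARS"]:
            name, kind = line[1], line[2]
            vals = tokens[i + 2 : i + 2 + n_points]
            out[name] = np.array([int(v) if kind == "int" else float(v) for v in vals])
            i += n_points + 1
        elif line[:1] == ["VECTORS"]:
            out[line[1]] = np.array(
                [[float(x) for x in tokens[i + 1 + k].split()] for k in range(n_points)]
            )
            i += n_points
        i += 1
    return out
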