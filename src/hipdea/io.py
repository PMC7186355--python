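"""File formats: meshes, per-vertex fields, thickness maps, solutions, configs.

Triangle meshes go through trimesh (STL/PLY/OBJ, both directions).  Two
small writers cover visualization formats trimesh does not expose directly:
ASCII PLY with arbitrary per-vertex scalar properties, and legacy ASCII VTK
polydata with point data.  Thickness maps and summaries are JSON,
population manifests YAML, nodal tables CSV (comma separator, '.' decimal,
header row).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .cartilage import ThicknessMap
from .mesh import SurfaceMesh

__all__ = [
    "load_mesh",
    "save_mesh",
    "save_ply_with_scalars",
    "save_vtk",
    "save_thickness_map",
    "load_thickness_map",
    "solution_table",
    "save_solution_csv",
    "save_json",
    "load_yaml",
    "config_hash",
]


def load_mesh(path) -> SurfaceMesh:
    """Read an STL/PLY/OBJ file into a SurfaceMesh.

    Vertices and their order are kept untouched for indexed formats
    (PLY/OBJ).  STL stores bare triangles, so duplicated corners are merged
    back into shared vertices on load; the triangle set round-trips, vertex
    numbering does not.
    """
    tm = trimesh.load_mesh(str(path), process=False)
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise ValueError(f"{path}: not a triangle mesh")
    if str(path).lower().endswith(".stl"):
        tm.merge_vertices()
    return SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def save_mesh(mesh: SurfaceMesh, path) -> None:
    """Write a SurfaceMesh as STL/PLY/OBJ (format from the extension).

    PLY goes through the package's ASCII writer at full double precision;
    the other formats go through trimesh.
    """
    if str(path).lower().endswith(".ply"):
        save_ply_with_scalars(mesh, path, {})
        return
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def save_ply_with_scalars(mesh: SurfaceMesh, path, scalars: dict) -> None:
    """ASCII PLY with one float property per named per-vertex scalar field."""
    for name, values in scalars.items():
        if len(values) != mesh.n_vertices:
            raise ValueError(f"scalar field {name!r} length mismatch")
    names = list(scalars)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        for name in names:
            fh.write(f"property double {name}\n")
        fh.write(f"element face {mesh.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = np.column_stack([mesh.vertices] + [np.asarray(scalars[n], float) for n in names])
        for row in cols:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def save_vtk(mesh: SurfaceMesh, path, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK polydata with optional per-vertex scalar fields."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhipdea surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]!r} {v[1]!r} {v[2]!r}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                if len(values) != mesh.n_vertices:
                    raise ValueError(f"point data {name!r} length mismatch")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in values:
                    fh.write(f"{x!r}\n")


def save_thickness_map(tmap: ThicknessMap, path) -> None:
    payload = {
        "side": tmap.side,
        "n_subjects": tmap.n_subjects,
        "normalized_thickness": tmap.normalized_thickness.tolist(),
    }
    if tmap.head_radii is not None:
        payload["head_radii"] = np.asarray(tmap.head_radii).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def load_thickness_map(path) -> ThicknessMap:
    data = json.loads(Path(path).read_text())
    radii = data.get("head_radii")
    return ThicknessMap(
        normalized_thickness=np.asarray(data["normalized_thickness"], dtype=float),
        side=data["side"],
        n_subjects=int(data["n_subjects"]),
        head_radii=None if radii is None else np.asarray(radii, dtype=float),
    )


def solution_table(solution, springs) -> pd.DataFrame:
    """Per-node solution table: node, x, y, z, stress (MPa), contact flag."""
    return pd.DataFrame(
        {
            "node": springs.nodes,
            "x": springs.anchors[:, 0],
            "y": springs.anchors[:, 1],
            "z": springs.anchors[:, 2],
            "stress": solution.stress,
            "contact": solution.contact.astype(int),
        }
    )


def save_solution_csv(solution, springs, path) -> None:
    solution_table(solution, springs).to_csv(path, index=False)


def save_json(payload: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=1, default=_default))


def load_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration, for provenance logs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
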