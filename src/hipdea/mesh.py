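"""Triangulated-surface data model and geometric primitives.

Everything downstream (cartilage layers, springs, contact stress) lives on
triangulated surfaces of articulating bone.  Units are fixed package-wide:
lengths in mm, areas in mm^2, forces in N, stresses in N/mm^2 = MPa.

The key primitives are

* :class:`SurfaceMesh` -- vertices, faces and oriented per-vertex normals;
* :func:`fit_sphere` -- algebraic least-squares sphere fit, used to obtain
  the acetabular and femoral radii ``R_a``/``R_f`` that drive the cartilage
  thickness predictors;
* :func:`vertex_tributary_area` -- the one-third barycentric lumping of
  triangle areas onto vertices, the ``S_i`` carried by each contact spring;
* :func:`make_ball_socket` -- concentric spherical-cap meshes sharing one
  template triangulation, the geometry of the verification benchmark and of
  every synthetic joint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "SurfaceMesh",
    "SphereFit",
    "fit_sphere",
    "vertex_normals",
    "vertex_tributary_area",
    "make_spherical_cap",
    "make_ball_socket",
]

_DEGENERATE_AREA = 1e-12


def _face_cross(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Cross products of face edge vectors; |.|/2 is the face area."""
    p0 = vertices[faces[:, 0]]
    p1 = vertices[faces[:, 1]]
    p2 = vertices[faces[:, 2]]
    return np.cross(p1 - p0, p2 - p0)


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Each vertex normal is the normalized sum of the (area-scaled) normals of
    its incident faces, so the orientation follows the face winding.  A
    vertex with no incident face has no normal and raises.
    """
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.intp)
    cross = _face_cross(vertices, faces)  # = 2 * area * face normal
    acc = np.zeros_like(vertices)
    for col in range(3):
        np.add.at(acc, faces[:, col], cross)
    norms = np.linalg.norm(acc, axis=1)
    incident = np.zeros(len(vertices), dtype=bool)
    incident[faces.ravel()] = True
    if not incident.all():
        raise DegenerateGeometryError(
            f"{int((~incident).sum())} isolated vertices have no incident face"
        )
    if np.any(norms <= 0):
        raise DegenerateGeometryError("vertex with vanishing accumulated normal")
    return acc / norms[:, None]


@dataclass
class SurfaceMesh:
    """Triangulated articulating surface.

    Attributes
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array
        Consistently wound so face normals agree with vertex normals.
    normals : (n, 3) float array
        Per-vertex unit normals oriented away from the underlying bone
        (recomputed from the winding when not supplied).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DegenerateGeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise DegenerateGeometryError("faces must be an (m, 3) array")
        if self.validate:
            if self.faces.size and (
                self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
            ):
                raise DegenerateGeometryError("face references an invalid vertex index")
            areas = self.face_areas()
            if np.any(areas < _DEGENERATE_AREA):
                raise DegenerateGeometryError(
                    f"{int((areas < _DEGENERATE_AREA).sum())} degenerate faces"
                )
        if self.normals is None:
            self.normals = vertex_normals(self.vertices, self.faces)
        else:
            self.normals = np.ascontiguousarray(self.normals, dtype=float)
            if self.normals.shape != self.vertices.shape:
                raise DegenerateGeometryError("normals must match vertices in shape")

    # -- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(_face_cross(self.vertices, self.faces), axis=1)

    def face_normals(self) -> np.ndarray:
        cross = _face_cross(self.vertices, self.faces)
        return cross / np.linalg.norm(cross, axis=1)[:, None]

    def area(self) -> float:
        """Total surface area in mm^2."""
        return float(self.face_areas().sum())

    def translated(self, t) -> "SurfaceMesh":
        """Rigidly translated copy (normals unchanged)."""
        return SurfaceMesh(
            self.vertices + np.asarray(t, dtype=float),
            self.faces.copy(),
            normals=self.normals.copy(),
            validate=False,
        )

    def flipped(self) -> "SurfaceMesh":
        """Copy with reversed winding and hence reversed normals."""
        return SurfaceMesh(self.vertices.copy(), self.faces[:, ::-1].copy())

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(), self.faces.copy(), self.normals.copy(), validate=False
        )


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center (mm), radius (mm), RMS radial residual (mm)."""

    center: np.ndarray
    radius: float
    rms_residual: float


def fit_sphere(points) -> SphereFit:
    """Algebraic least-squares sphere through a point cloud.

    Linearizes ``|p - c|^2 = r^2`` into the normal equations
    ``2 p . c + (r^2 - |c|^2) = |p|^2`` and solves them in one shot; the
    residual reported is the RMS of radial distances about the fitted
    radius.  Needs at least four points in general position — coplanar or
    collinear clouds make the system singular.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
        raise DegenerateGeometryError("sphere fit needs >= 4 three-dimensional points")
    # coplanarity check on the centered cloud
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    scale = max(sv[0], 1.0)
    if sv[-1] < 1e-9 * scale:
        raise DegenerateGeometryError("points are coplanar or collinear; sphere fit is singular")
    a = np.column_stack([2.0 * points, np.ones(len(points))])
    b = np.einsum("ij,ij->i", points, points)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("singular normal equations in sphere fit")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateGeometryError("sphere fit produced non-positive radius")
    radius = float(np.sqrt(r2))
    dist = np.linalg.norm(points - center, axis=1)
    rms = float(np.sqrt(np.mean((dist - radius) ** 2)))
    return SphereFit(center=center, radius=radius, rms_residual=rms)


def vertex_tributary_area(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex tributary area S_i (mm^2) by the one-third rule.

    Each triangle contributes one third of its area to each of its three
    vertices, so the vertex areas partition the total surface area exactly.
    Vertices without incident faces get zero area and trigger a warning.
    """
    areas = mesh.face_areas()
    s = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(s, mesh.faces[:, col], areas / 3.0)
    if np.any(s == 0.0):
        warnings.warn(
            f"{int((s == 0.0).sum())} vertices have no incident face; tributary area 0",
            stacklevel=2,
        )
    return s


# ---------------------------------------------------------------------------
# parametric spherical caps
# ---------------------------------------------------------------------------


def _unit_cap(target_edge_angle: float, cap_angle_rad: float):
    """Near-isometric triangulation of a unit spherical cap about +z.

    Rings of latitude at uniform polar spacing, with per-ring azimuthal
    counts chosen to keep edges near the requested angular length; adjacent
    rings are stitched by merging their angle sequences.  The pole is a
    single vertex, so theta = 0 is always sampled exactly.
    """
    n_rings = max(2, int(round(cap_angle_rad / target_edge_angle)))
    dtheta = cap_angle_rad / n_rings
    ring_thetas = dtheta * np.arange(n_rings + 1)

    verts = [np.array([0.0, 0.0, 1.0])]
    ring_index: list[np.ndarray] = [np.array([0])]
    ring_phis: list[np.ndarray] = [np.array([0.0])]
    for j in range(1, n_rings + 1):
        theta = ring_thetas[j]
        n_phi = max(3, int(round(2.0 * np.pi * np.sin(theta) / target_edge_angle)))
        # stagger alternate rings for better-shaped triangles
        phi = 2.0 * np.pi * np.arange(n_phi) / n_phi + (0.5 * np.pi / n_phi) * (j % 2)
        idx = len(verts) + np.arange(n_phi)
        st, ct = np.sin(theta), np.cos(theta)
        verts.extend(np.column_stack([st * np.cos(phi), st * np.sin(phi), np.full(n_phi, ct)]))
        ring_index.append(idx)
        ring_phis.append(phi)

    faces = []
    # pole fan
    first = ring_index[1]
    for i in range(len(first)):
        faces.append((0, first[i], first[(i + 1) % len(first)]))
    # stitch consecutive rings by merged angular order
    for j in range(1, n_rings):
        ia, ib = ring_index[j], ring_index[j + 1]
        pa, pb = ring_phis[j], ring_phis[j + 1]
        na, nb = len(ia), len(ib)
        i = k = 0
        while i < na or k < nb:
            next_a = pa[(i + 1) % na] + (2 * np.pi if i + 1 >= na else 0.0)
            next_b = pb[(k + 1) % nb] + (2 * np.pi if k + 1 >= nb else 0.0)
            if k >= nb or (i < na and next_a <= next_b):
                faces.append((ia[i % na], ib[k % nb], ia[(i + 1) % na]))
                i += 1
            else:
                faces.append((ia[i % na], ib[k % nb], ib[(k + 1) % nb]))
                k += 1
    return np.array(verts), np.asarray(faces, dtype=np.intp)


def make_spherical_cap(
    radius: float,
    target_edge: float = 1.5,
    cap_angle: float = 90.0,
    axis=(0.0, 0.0, -1.0),
    inward: bool = False,
    sizing_radius: float | None = None,
) -> SurfaceMesh:
    """Spherical-cap mesh of the given radius about the origin.

    ``axis`` is the pole direction (theta = 0).  ``inward=True`` winds the
    faces so normals point toward the center, the convention for the socket
    (bone lies outside the surface).  ``sizing_radius`` lets several
    concentric caps share one template triangulation: edge lengths are set
    at that radius, so caps generated with the same ``sizing_radius`` and
    ``target_edge`` are in exact vertex correspondence.
    """
    if radius <= 0:
        raise DegenerateGeometryError("radius must be positive")
    if not 0 < cap_angle <= 90.0:
        raise DegenerateGeometryError("cap_angle must lie in (0, 90] degrees")
    r_size = radius if sizing_radius is None else sizing_radius
    cap_rad = np.deg2rad(cap_angle)
    edge_angle = target_edge / r_size
    if edge_angle >= cap_rad:
        raise DegenerateGeometryError("target_edge larger than the cap itself")
    verts, faces = _unit_cap(edge_angle, cap_rad)

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # rotate +z onto axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(z @ axis)
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    verts = verts @ rot.T * radius
    if inward:
        faces = faces[:, ::-1]
    # the parametric sphere has exact radial normals; using them avoids the
    # free-boundary bias of discretely estimated vertex normals
    normals = verts / radius
    if inward:
        normals = -normals
    return SurfaceMesh(verts, faces, normals=normals)


def make_ball_socket(
    r_ball: float,
    r_shell: float,
    target_edge: float = 1.5,
    cap_angle: float = 90.0,
    axis=(0.0, 0.0, -1.0),
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Concentric ball and shell caps in template correspondence.

    The ball (femoral analogue, normals outward) and shell (acetabular
    analogue, normals inward, toward the ball) share one cap triangulation
    sized at the mean radius, so vertex ``i`` of one mesh articulates with
    vertex ``i`` of the other along the common radial direction.  Both have
    a vertex exactly at the pole.
    """
    if not 0 < r_ball < r_shell:
        raise DegenerateGeometryError("need 0 < r_ball < r_shell")
    r_size = 0.5 * (r_ball + r_shell)
    ball = make_spherical_cap(
        r_ball, target_edge, cap_angle, axis, inward=False, sizing_radius=r_size
    )
    shell = make_spherical_cap(
        r_shell, target_edge, cap_angle, axis, inward=True, sizing_radius=r_size
    )
    return ball, shell
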