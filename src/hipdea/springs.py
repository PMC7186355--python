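"""Compressive spring bed between two cartilage layers.

Cartilage is modelled as an array of independent springs normal to the
acetabular articular surface.  Each spring i carries

    F_i = k * eps_i * S_i * n_i            (linear law)
    F_i = H_A0 * (1 - eps_i + 1.5*(1+4*beta) * eps_i^2) * eps_i * S_i * n_i

with strain eps_i = dd_i / h_i, where dd_i is the interpenetration of the
two articular surfaces along the spring direction n_i, h_i the combined
thickness of both cartilage layers at that node and S_i the tributary area.
The series-spring partition underlies the strain definition: with equal
moduli in the two layers, a total approach dd splits in proportion to layer
thickness (each layer compresses by dd * l/h), so both layers carry the
same strain dd/h and transmit the same force.  Springs resist compression
only; a spring whose gap is open transmits nothing.

The constrained (aggregate) modulus plays the role of the linear spring
stiffness:

    k = E * (1 - v) / ((1 - 2v) * (1 + v))

which for the literature values E = 11.85 MPa, v = 0.45 gives
k = 44.948 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cartilage import CartilageLayer
from .errors import CorrespondenceError, FullCompressionError
from .mesh import vertex_tributary_area

__all__ = [
    "LinearMaterial",
    "NonlinearMaterial",
    "spring_stiffness",
    "strain",
    "linear_force",
    "nonlinear_force",
    "SpringSet",
    "build_springs",
    "ray_surface_gap",
]

#: reject Poisson ratios this close to the incompressible pole of Eq.-3-type
#: stiffness, where k diverges
_POISSON_MAX = 0.499

#: default hard cap on spring strain; the foundation model is nonphysical
#: approaching full compression of the layer
STRAIN_CLAMP = 0.95


def spring_stiffness(e: float, v: float) -> float:
    """Constrained modulus k = E(1-v) / ((1-2v)(1+v)) in MPa."""
    if e <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= v < _POISSON_MAX:
        raise ValueError(
            f"Poisson ratio {v} outside [0, {_POISSON_MAX}); the constrained "
            "modulus diverges at v = 0.5"
        )
    return e * (1.0 - v) / ((1.0 - 2.0 * v) * (1.0 + v))


@dataclass(frozen=True)
class LinearMaterial:
    """Linear cartilage spring: Young's modulus E (MPa), Poisson ratio v."""

    e: float = 11.85
    v: float = 0.45

    def __post_init__(self):
        spring_stiffness(self.e, self.v)  # validates

    @property
    def k(self) -> float:
        """Constrained spring stiffness in MPa."""
        return spring_stiffness(self.e, self.v)

    def stress(self, eps: np.ndarray) -> np.ndarray:
        """Spring stress (MPa) at strain eps."""
        return self.k * np.asarray(eps, dtype=float)


@dataclass(frozen=True)
class NonlinearMaterial:
    """Strain-stiffening cartilage spring.

    H_A0 is the aggregate modulus at zero strain (MPa), beta the
    dimensionless stiffening parameter; stress is
    H_A0 * (1 - eps + 1.5*(1+4*beta)*eps^2) * eps.  The defaults come from
    experimental human/bovine stress-strain data.
    """

    h_a0: float = 0.40
    beta: float = 0.35

    def __post_init__(self):
        if self.h_a0 <= 0:
            raise ValueError("H_A0 must be positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")

    @property
    def quadratic_coefficient(self) -> float:
        return 1.5 * (1.0 + 4.0 * self.beta)

    def stress(self, eps: np.ndarray) -> np.ndarray:
        eps = np.asarray(eps, dtype=float)
        return self.h_a0 * (1.0 - eps + self.quadratic_coefficient * eps**2) * eps


def strain(delta_d: float, h: float, clamp: float = STRAIN_CLAMP) -> float:
    """Spring strain eps = dd / h for approach dd of layers of combined thickness h."""
    if h <= 0:
        raise ValueError("combined thickness must be positive")
    if delta_d < 0:
        raise ValueError("compression distance must be non-negative")
    eps = delta_d / h
    if eps >= clamp:
        raise FullCompressionError(
            f"strain {eps:.4f} exceeds the clamp {clamp}; layer nearly fully compressed"
        )
    return eps


def _force(eps, n, s, material) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("spring direction must be a unit vector")
    if s <= 0:
        raise ValueError("tributary area must be positive")
    if eps < 0:
        raise ValueError("strain must be non-negative")
    return float(material.stress(eps)) * s * n


def linear_force(eps: float, n, s: float, material: LinearMaterial) -> np.ndarray:
    """Linear spring force vector (N): k * eps * S * n."""
    return _force(eps, n, s, material)


def nonlinear_force(eps: float, n, s: float, material: NonlinearMaterial) -> np.ndarray:
    """Non-linear spring force vector (N)."""
    return _force(eps, n, s, material)


# ---------------------------------------------------------------------------
# gap computation
# ---------------------------------------------------------------------------


def _moller_trumbore(origins, dirs, tri0, tri1, tri2, eps=1e-12):
    """Ray/triangle intersection for paired rays and triangles.

    Returns (t, u, v, hit): line parameter t (can be negative — the ray is
    treated as a full line so overlap shows up as t < 0) and barycentric
    coordinates of the hit.
    """
    e1 = tri1 - tri0
    e2 = tri2 - tri0
    p = np.cross(dirs, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > eps
    inv = np.where(ok, det, 1.0)
    tvec = origins - tri0
    u = np.einsum("ij,ij->i", tvec, p) / inv
    q = np.cross(tvec, e1)
    v = np.einsum("ij,ij->i", dirs, q) / inv
    t = np.einsum("ij,ij->i", e2, q) / inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1.0 + tol)
    return t, u, v, hit


def ray_surface_gap(mesh, origins, dirs, k_candidates: int = 32):
    """Signed distance from each origin to ``mesh`` along its ray direction.

    Positive means the surface lies ahead of the origin along the ray
    (separation), negative behind it (overlap).  Candidate triangles come
    from a KD-tree on face centroids; rays whose candidates all miss fall
    back to an exhaustive test.  Returns (gap, face_index, bary) with NaN
    gap / index -1 for true misses.
    """
    verts, faces = mesh.vertices, mesh.faces
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    centroids = verts[faces].mean(axis=1)
    k = min(k_candidates, len(faces))
    tree = cKDTree(centroids)
    _, cand = tree.query(origins, k=k)
    cand = np.atleast_2d(cand)

    n_rays = len(origins)
    gap = np.full(n_rays, np.nan)
    face_idx = np.full(n_rays, -1, dtype=np.intp)
    bary = np.zeros((n_rays, 3))

    def _resolve(ray_ids, cand_matrix):
        nc = cand_matrix.shape[1]
        ro = np.repeat(origins[ray_ids], nc, axis=0)
        rd = np.repeat(dirs[ray_ids], nc, axis=0)
        f = faces[cand_matrix.ravel()]
        t, u, v, hit = _moller_trumbore(ro, rd, verts[f[:, 0]], verts[f[:, 1]], verts[f[:, 2]])
        t = np.where(hit, t, np.inf)
        t = t.reshape(len(ray_ids), nc)
        best = np.argmin(np.abs(t), axis=1)
        tb = t[np.arange(len(ray_ids)), best]
        found = np.isfinite(tb)
        ids = ray_ids[found]
        gap[ids] = tb[found]
        fsel = cand_matrix[np.arange(len(ray_ids)), best][found]
        face_idx[ids] = fsel
        ub = u.reshape(len(ray_ids), nc)[np.arange(len(ray_ids)), best][found]
        vb = v.reshape(len(ray_ids), nc)[np.arange(len(ray_ids)), best][found]
        bary[ids] = np.column_stack([1.0 - ub - vb, ub, vb])
        return ray_ids[~found]

    missed = _resolve(np.arange(n_rays), cand)
    if len(missed) and k < len(faces):
        # exhaustive fallback in chunks
        all_faces = np.arange(len(faces), dtype=np.intp)
        for start in range(0, len(missed), 64):
            chunk = missed[start : start + 64]
            _resolve(chunk, np.tile(all_faces, (len(chunk), 1)))
    return gap, face_idx, bary


@dataclass
class SpringSet:
    """Spring bed anchored at the acetabular articular vertices.

    ``gap0`` is the signed separation to the femoral articular surface along
    each spring direction in the reference pose; under a rigid femoral
    translation t the gap is ``gap0 + t . n`` and the compression
    ``dd = max(0, -(gap0 + t . n))``.  ``usable`` marks springs whose
    opposing surface exists (peripheral rays that miss are permanently
    inactive).
    """

    nodes: np.ndarray  # acetabular articular vertex indices
    dirs: np.ndarray  # unit directions n_i, acetabular -> femoral side
    l_own: np.ndarray  # own-layer (acetabular) thickness, mm
    h_combined: np.ndarray  # combined thickness of both layers, mm
    areas: np.ndarray  # tributary areas S_i, mm^2
    gap0: np.ndarray  # reference-pose signed gaps, mm
    usable: np.ndarray  # bool: spring has an opposing surface
    anchors: np.ndarray = field(repr=False)  # anchor coordinates, mm
    pairing: str = "nodal"

    def __len__(self) -> int:
        return len(self.nodes)

    def gaps(self, translation) -> np.ndarray:
        """Signed gaps after a rigid femoral translation (mm)."""
        return self.gap0 + self.dirs @ np.asarray(translation, dtype=float)

    def compressions(self, translation) -> np.ndarray:
        """Non-negative spring compressions dd_i (mm); unusable springs are 0."""
        dd = np.maximum(0.0, -self.gaps(translation))
        dd[~self.usable] = 0.0
        return dd


def build_springs(
    acet: CartilageLayer,
    fem: CartilageLayer,
    pairing: str = "auto",
    correspondence: np.ndarray | None = None,
) -> SpringSet:
    """Assemble one spring per acetabular articular vertex.

    With ``pairing='nodal'`` (or 'auto' when both layers share a template)
    the opposing point of vertex i is the corresponding femoral articular
    vertex, the natural choice when both surfaces come from one
    correspondence model; gaps are then exact for rigid translations.
    ``pairing='raycast'`` instead shoots each spring direction at the
    femoral articular surface and interpolates the opposing thickness
    barycentrically at the hit — the fallback for surfaces without shared
    connectivity.  An explicit ``correspondence`` array (femoral vertex
    index per acetabular vertex, -1 for none) overrides both.
    """
    if acet.side != "acetabular" or fem.side != "femoral":
        raise CorrespondenceError("build_springs expects (acetabular, femoral) layers")
    surf = acet.articular_surface
    anchors = surf.vertices
    dirs = surf.normals
    areas = vertex_tributary_area(surf)
    n = len(anchors)
    fem_verts = fem.articular_surface.vertices

    if correspondence is not None:
        corr = np.asarray(correspondence, dtype=np.intp)
        if corr.shape != (n,):
            raise CorrespondenceError("correspondence must give one femoral index per spring")
        usable = corr >= 0
        gap0 = np.zeros(n)
        h = acet.thickness.copy()
        safe = np.where(usable, corr, 0)
        gap0[:] = np.einsum("ij,ij->i", fem_verts[safe] - anchors, dirs)
        h += np.where(usable, fem.thickness[safe], 0.0)
        gap0[~usable] = np.nan
        pairing_used = "correspondence"
    else:
        if pairing == "auto":
            pairing = "nodal" if fem.n_vertices == n else "raycast"
        if pairing == "nodal":
            if fem.n_vertices != n:
                raise CorrespondenceError(
                    "nodal pairing needs equal vertex counts on both articular surfaces"
                )
            gap0 = np.einsum("ij,ij->i", fem_verts - anchors, dirs)
            h = acet.thickness + fem.thickness
            usable = np.ones(n, dtype=bool)
        elif pairing == "raycast":
            gap0, face_idx, bary = ray_surface_gap(fem.articular_surface, anchors, dirs)
            usable = face_idx >= 0
            h = acet.thickness.copy()
            tf = fem.thickness[fem.articular_surface.faces[np.where(usable, face_idx, 0)]]
            h += np.where(usable, np.einsum("ij,ij->i", bary, tf), 0.0)
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        pairing_used = pairing

    if np.any(h[usable] <= 0):
        raise ValueError("combined thickness must be positive at usable springs")
    return SpringSet(
        nodes=np.arange(n, dtype=np.intp),
        dirs=dirs.copy(),
        l_own=acet.thickness.copy(),
        h_combined=h,
        areas=areas,
        gap0=gap0,
        usable=usable,
        anchors=anchors.copy(),
        pairing=pairing_used,
    )
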