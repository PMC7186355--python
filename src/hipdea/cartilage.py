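"""Cartilage layer construction and thickness prediction.

A :class:`CartilageLayer` is a bone surface, a per-vertex thickness field
and the articular surface obtained by extruding each bone vertex along its
normal.  Three predictors build layers from bony anatomy alone:

* spherical — fit spheres to both bones, place a single congruent joint
  surface at the mean radius R = (R_a + R_f)/2 and measure each side's
  thickness radially back to its own bone (Eq.-5-style construction);
* constant — extrude both bones by the uniform thickness d = (R_a - R_f)/2;
* population-averaged map — per-node thickness normalized by the femoral
  head radius, averaged over a corresponded population, and rescaled to a
  new subject's head radius.

The map workflow requires meshes in template correspondence (vertex k means
the same anatomical location in every subject), which the synthetic
population generator provides and which statistical shape models provide
for real anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import CorrespondenceError, DegenerateGeometryError
from .mesh import SurfaceMesh, fit_sphere

__all__ = [
    "CartilageLayer",
    "ThicknessMap",
    "project_cartilage",
    "predict_spherical",
    "predict_constant",
    "build_thickness_map",
    "apply_thickness_map",
    "thickness_error",
    "loo_validate",
]

SIDES = ("acetabular", "femoral")


@dataclass
class CartilageLayer:
    """One side's cartilage: bone surface, nodal thickness, articular surface."""

    bone_surface: SurfaceMesh
    thickness: np.ndarray
    articular_surface: SurfaceMesh
    side: str

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.thickness = np.asarray(self.thickness, dtype=float)
        if self.thickness.shape != (self.bone_surface.n_vertices,):
            raise CorrespondenceError("thickness length must match bone vertex count")

    @property
    def n_vertices(self) -> int:
        return self.bone_surface.n_vertices


def project_cartilage(bone: SurfaceMesh, thickness, side: str) -> CartilageLayer:
    """Extrude each bone vertex along its normal by its nodal thickness.

    The articular surface keeps the bone connectivity.  Negative thickness
    is an error; an extrusion that inverts triangles (local
    self-intersection) only warns, since peripheral nodes of real anatomy
    occasionally do this and the springs there are inactive anyway.
    """
    thickness = np.asarray(thickness, dtype=float)
    if thickness.ndim == 0:
        thickness = np.full(bone.n_vertices, float(thickness))
    if thickness.shape != (bone.n_vertices,):
        raise CorrespondenceError("thickness length must match bone vertex count")
    if np.any(thickness < 0):
        raise ValueError("negative cartilage thickness")
    verts = bone.vertices + thickness[:, None] * bone.normals
    articular = SurfaceMesh(verts, bone.faces.copy(), validate=False)
    # orientation guard: extrusion must not flip the winding
    flipped = np.einsum("ij,ij->i", articular.face_normals(), bone.face_normals()) <= 0
    if flipped.any():
        warnings.warn(
            f"extrusion inverted {int(flipped.sum())} faces (self-intersecting layer)",
            stacklevel=2,
        )
    return CartilageLayer(bone, thickness, articular, side)


def _clamped(thickness: np.ndarray, what: str) -> np.ndarray:
    if np.any(thickness < 0):
        warnings.warn(
            f"{what}: {int((thickness < 0).sum())} nodes cross the joint sphere; "
            "thickness clamped to 0",
            stacklevel=3,
        )
        thickness = np.maximum(thickness, 0.0)
    return thickness


def predict_spherical(
    acet_bone: SurfaceMesh, fem_bone: SurfaceMesh
) -> tuple[CartilageLayer, CartilageLayer]:
    """Spherical-fit cartilage prediction with a congruent joint interface.

    Both articular surfaces lie on the sphere of radius R = (R_a + R_f)/2;
    thickness at each bone vertex is its radial distance to that sphere
    (about the respective fit center), clamped at zero where bone already
    crosses it.
    """
    fa = fit_sphere(acet_bone.vertices)
    ff = fit_sphere(fem_bone.vertices)
    if ff.radius >= fa.radius:
        raise DegenerateGeometryError(
            f"no joint space: R_f={ff.radius:.3f} >= R_a={fa.radius:.3f}"
        )
    r_joint = 0.5 * (fa.radius + ff.radius)
    t_acet = np.linalg.norm(acet_bone.vertices - fa.center, axis=1) - r_joint
    t_fem = r_joint - np.linalg.norm(fem_bone.vertices - ff.center, axis=1)
    acet = project_cartilage(acet_bone, _clamped(t_acet, "acetabular"), "acetabular")
    fem = project_cartilage(fem_bone, _clamped(t_fem, "femoral"), "femoral")
    return acet, fem


def predict_constant(
    acet_bone: SurfaceMesh, fem_bone: SurfaceMesh
) -> tuple[CartilageLayer, CartilageLayer]:
    """Uniform-thickness prediction d = (R_a - R_f)/2 on both bones."""
    fa = fit_sphere(acet_bone.vertices)
    ff = fit_sphere(fem_bone.vertices)
    d = 0.5 * (fa.radius - ff.radius)
    if d <= 0:
        raise DegenerateGeometryError(f"non-positive constant thickness d={d:.3f}")
    acet = project_cartilage(acet_bone, np.full(acet_bone.n_vertices, d), "acetabular")
    fem = project_cartilage(fem_bone, np.full(fem_bone.n_vertices, d), "femoral")
    return acet, fem


@dataclass
class ThicknessMap:
    """Population-averaged nodal thickness, normalized by femoral head radius.

    ``normalized_thickness[k]`` is dimensionless (mm of cartilage per mm of
    head radius) on a fixed template correspondence.
    """

    normalized_thickness: np.ndarray
    side: str
    n_subjects: int
    head_radii: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        self.normalized_thickness = np.asarray(self.normalized_thickness, dtype=float)
        if np.any(self.normalized_thickness < 0):
            raise ValueError("normalized thickness must be non-negative")


def build_thickness_map(layers, head_radii) -> ThicknessMap:
    """Average radius-normalized nodal thickness over corresponded subjects.

    Every layer's thickness is divided by that subject's femoral head
    radius before averaging, removing overall joint scale from the map.
    """
    layers = list(layers)
    head_radii = np.asarray(head_radii, dtype=float)
    if len(layers) == 0 or len(layers) != len(head_radii):
        raise CorrespondenceError("need one head radius per layer")
    if np.any(head_radii <= 0):
        raise ValueError("head radii must be positive")
    n = layers[0].n_vertices
    side = layers[0].side
    for lay in layers:
        if lay.n_vertices != n:
            raise CorrespondenceError("layers are not on a common template")
        if lay.side != side:
            raise CorrespondenceError("layers mix acetabular and femoral sides")
    stacked = np.stack([lay.thickness / r for lay, r in zip(layers, head_radii)])
    return ThicknessMap(stacked.mean(axis=0), side, len(layers), head_radii.copy())


def apply_thickness_map(
    tmap: ThicknessMap, bone: SurfaceMesh, head_radius: float
) -> CartilageLayer:
    """Rescale the map by a subject's head radius and extrude their bone."""
    if head_radius <= 0:
        raise ValueError("head radius must be positive")
    if len(tmap.normalized_thickness) != bone.n_vertices:
        raise CorrespondenceError("bone is not in the map's template correspondence")
    return project_cartilage(bone, tmap.normalized_thickness * head_radius, tmap.side)


def thickness_error(
    predicted: CartilageLayer,
    reference: CartilageLayer,
    correspondence: np.ndarray | None = None,
) -> tuple[float, float]:
    """RMS and maximum distance from predicted articular nodes to the reference.

    With no explicit ``correspondence`` the layers must share a template and
    node ``i`` is compared with node ``i``; a nearest-neighbour map (see
    :func:`hipdea.metrics.nearest_correspondence`) covers the general case.
    """
    if predicted.n_vertices == 0 or reference.n_vertices == 0:
        raise DegenerateGeometryError("empty layer")
    pv = predicted.articular_surface.vertices
    rv = reference.articular_surface.vertices
    if correspondence is None:
        if len(pv) != len(rv):
            raise CorrespondenceError(
                "layers differ in vertex count; supply a correspondence map"
            )
        target = rv
    else:
        target = rv[np.asarray(correspondence, dtype=np.intp)]
    dist = np.linalg.norm(pv - target, axis=1)
    return float(np.sqrt(np.mean(dist**2))), float(dist.max())


def loo_validate(layers, head_radii):
    """Leave-one-out accuracy of the population-averaged map (k = n folds).

    For each subject the map is rebuilt from the other n-1 subjects,
    applied to that subject's bone and head radius, and scored against the
    subject's own layer.  Returns a list of (rmse, max_error) in mm.
    """
    layers = list(layers)
    head_radii = np.asarray(head_radii, dtype=float)
    if len(layers) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    scores = []
    for i, (lay, r) in enumerate(zip(layers, head_radii)):
        rest = [lay_j for j, lay_j in enumerate(layers) if j != i]
        rest_r = np.delete(head_radii, i)
        tmap = build_thickness_map(rest, rest_r)
        pred = apply_thickness_map(tmap, lay.bone_surface, r)
        scores.append(thickness_error(pred, lay))
    return scores
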