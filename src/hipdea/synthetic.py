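"""Synthetic joints and corresponded populations with known ground truth.

Real workflows obtain corresponded bone meshes and segmented cartilage from
imaging plus a statistical shape model; neither is needed to exercise the
mechanics.  This module builds geometric analogues: spherical-cap "hips"
whose bone meshes share one template triangulation across all subjects
(vertex k is the same location in every subject), with smooth ground-truth
thickness fields composed of low-order polar harmonics — enough spatial
structure to distinguish the three thickness predictors, and nothing finer
than the mesh can carry.

The generator is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cartilage import CartilageLayer, project_cartilage
from .mesh import SurfaceMesh, make_spherical_cap, vertex_tributary_area

__all__ = ["SyntheticSubject", "synth_population", "synth_edge_case"]

_AXIS = np.array([0.0, 0.0, -1.0])  # pole direction shared by all fixtures


@dataclass
class SyntheticSubject:
    """One synthetic hip: bone meshes, ground-truth thickness, provenance."""

    acet_bone: SurfaceMesh
    fem_bone: SurfaceMesh
    acet_thickness: np.ndarray
    fem_thickness: np.ndarray
    head_radius: float
    provenance: dict = field(default_factory=dict)
    correspondence: np.ndarray | None = None  # acet vertex -> fem vertex, if unequal meshes

    def femoral_layer(self) -> CartilageLayer:
        return project_cartilage(self.fem_bone, self.fem_thickness, "femoral")

    def acetabular_layer(self) -> CartilageLayer:
        return project_cartilage(self.acet_bone, self.acet_thickness, "acetabular")


def _angular_basis(mesh: SurfaceMesh, axis=_AXIS) -> np.ndarray:
    """Low-order (<= 4) polar-harmonic basis evaluated at mesh vertices."""
    v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
    ct = np.clip(v @ axis, -1.0, 1.0)
    theta = np.arccos(ct)
    # azimuth about the pole axis
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.cross(axis, e1)
    phi = np.arctan2(v @ e2, v @ e1)
    st = np.sin(theta)
    return np.column_stack(
        [
            np.cos(theta),
            np.cos(2 * theta),
            np.cos(3 * theta),
            np.cos(4 * theta),
            st * np.cos(phi),
            st * np.sin(phi),
            st**2 * np.cos(2 * phi),
            st**2 * np.sin(2 * phi),
        ]
    )


def _smooth_field(basis, weights, rng, rms):
    """Random smooth field with the requested area-weighted RMS."""
    raw = basis @ rng.standard_normal(basis.shape[1])
    raw -= np.average(raw, weights=weights)
    scale = np.sqrt(np.average(raw**2, weights=weights))
    if scale == 0 or rms == 0:
        return np.zeros(len(raw))
    return raw * (rms / scale)


def synth_population(
    n: int = 10,
    seed: int = 0,
    mean_head_radius: float = 25.0,
    radius_sd: float = 1.5,
    base_thickness: float = 2.0,
    field_amplitude: float = 0.3,
    perturbation_sd: float = 0.1,
    cap_angle: float = 90.0,
    target_edge: float = 1.5,
    min_thickness: float = 0.2,
) -> list[SyntheticSubject]:
    """Corresponded population of spherical-cap hips.

    Every subject shares one template triangulation (sized at the mean
    head radius) scaled to its own head radius R_f ~ N(mean, sd^2).  The
    ground-truth femoral/acetabular thickness is a population-shared smooth
    field that scales with R_f — mean ``base_thickness`` and spatial RMS
    ``field_amplitude`` (mm, at the mean radius) — plus a subject-specific
    smooth perturbation of RMS ``perturbation_sd`` mm.  The acetabular bone
    is the concentric sphere leaving exactly the subject's mean combined
    thickness of joint space, so the sphere-fit radii R_a, R_f used by the
    predictors are exact.  Fields are floored at ``min_thickness`` to keep
    the articulating region strictly positive.
    """
    if n < 1:
        raise ValueError("need at least one subject")
    if min(mean_head_radius, base_thickness) <= 0 or min(radius_sd, perturbation_sd) < 0:
        raise ValueError("degenerate population parameters")
    rng = np.random.default_rng(seed)
    template = make_spherical_cap(
        1.0, target_edge, cap_angle, _AXIS, sizing_radius=mean_head_radius
    )
    weights = vertex_tributary_area(template)
    basis = _angular_basis(template)
    shared = {
        side: _smooth_field(basis, weights, rng, field_amplitude / mean_head_radius)
        + base_thickness / mean_head_radius
        for side in ("femoral", "acetabular")
    }
    radii = mean_head_radius + radius_sd * rng.standard_normal(n)

    subjects = []
    for i in range(n):
        r_f = float(radii[i])
        if r_f <= 0:
            raise ValueError("sampled non-positive head radius; reduce radius_sd")
        t_fem = np.maximum(
            r_f * shared["femoral"] + _smooth_field(basis, weights, rng, perturbation_sd),
            min_thickness,
        )
        t_acet = np.maximum(
            r_f * shared["acetabular"] + _smooth_field(basis, weights, rng, perturbation_sd),
            min_thickness,
        )
        joint_space = float(np.average(t_fem + t_acet, weights=weights))
        r_a = r_f + joint_space
        fem_bone = SurfaceMesh(
            template.vertices * r_f, template.faces.copy(), template.normals.copy(), validate=False
        )
        acet_bone = SurfaceMesh(
            template.vertices * r_a,
            template.faces[:, ::-1].copy(),
            -template.normals.copy(),
            validate=False,
        )
        subjects.append(
            SyntheticSubject(
                acet_bone=acet_bone,
                fem_bone=fem_bone,
                acet_thickness=t_acet,
                fem_thickness=t_fem,
                head_radius=r_f,
                provenance={
                    "generator": "synth_population",
                    "seed": seed,
                    "index": i,
                    "mean_head_radius": mean_head_radius,
                    "radius_sd": radius_sd,
                    "base_thickness": base_thickness,
                    "field_amplitude": field_amplitude,
                    "perturbation_sd": perturbation_sd,
                    "cap_angle": cap_angle,
                    "target_edge": target_edge,
                },
            )
        )
    return subjects


def synth_edge_case(
    coverage_angle: float = 50.0,
    tilt: float = 20.0,
    r_ball: float = 20.0,
    r_shell: float = 24.0,
    cartilage_thickness: float = 2.0,
    target_edge: float = 1.5,
) -> SyntheticSubject:
    """Reduced-coverage (dysplasia-like) socket with a tilted load axis.

    The femoral cap spans the full hemisphere while the socket is truncated
    at ``coverage_angle`` degrees from the pole, so a load tilted by
    ``tilt`` degrees drives the contact patch against the acetabular rim.
    Both meshes come from one template, and the retained socket vertices
    keep their template indices in ``correspondence``.  The suggested load
    direction is stored in ``provenance['load_direction']`` (unit vector of
    the joint reaction on the femur).
    """
    if not 0 < coverage_angle <= 90:
        raise ValueError("coverage_angle must lie in (0, 90] degrees")
    r_size = 0.5 * (r_ball + r_shell)
    ball = make_spherical_cap(r_ball, target_edge, 90.0, _AXIS, sizing_radius=r_size)
    shell_full = make_spherical_cap(r_shell, target_edge, 90.0, _AXIS, inward=True, sizing_radius=r_size)

    ct = np.clip(shell_full.vertices @ _AXIS / r_shell, -1.0, 1.0)
    theta = np.degrees(np.arccos(ct))
    keep = theta <= coverage_angle + 1e-9
    kept_idx = np.flatnonzero(keep)
    remap = -np.ones(shell_full.n_vertices, dtype=np.intp)
    remap[kept_idx] = np.arange(len(kept_idx))
    face_keep = keep[shell_full.faces].all(axis=1)
    faces = remap[shell_full.faces[face_keep]]
    shell = SurfaceMesh(
        shell_full.vertices[kept_idx], faces, shell_full.normals[kept_idx], validate=False
    )

    tilt_rad = np.deg2rad(tilt)
    load_dir = -(
        np.cos(tilt_rad) * _AXIS + np.sin(tilt_rad) * np.array([1.0, 0.0, 0.0])
    )  # reaction on the femur, opposite the tilted compression axis
    return SyntheticSubject(
        acet_bone=shell,
        fem_bone=ball,
        acet_thickness=np.full(shell.n_vertices, cartilage_thickness),
        fem_thickness=np.full(ball.n_vertices, cartilage_thickness),
        head_radius=r_ball,
        provenance={
            "generator": "synth_edge_case",
            "coverage_angle": coverage_angle,
            "tilt_deg": tilt,
            "r_ball": r_ball,
            "r_shell": r_shell,
            "cartilage_thickness": cartilage_thickness,
            "target_edge": target_edge,
            "load_direction": load_dir,
        },
        correspondence=kept_idx,  # acet vertex j corresponds to fem vertex kept_idx[j]
    )
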