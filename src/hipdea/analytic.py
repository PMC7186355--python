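"""Closed-form elastic-foundation solution and the verification benchmark.

For a thin elastic layer of thickness h and constrained modulus k between
conformal rigid spheres, with displacement allowed only radially, a rigid
central approach delta0 compresses the layer by delta0*cos(theta) at polar
angle theta from the load axis, so the contact pressure is

    p(theta) = k * delta0 * cos(theta) / h         for theta within contact

and vertical equilibrium over a cap of half-angle theta_c gives

    W = integral p cos(theta) dA
      = p0 * 2 pi R^2 * (1 - cos^3(theta_c)) / 3,

hence for the full hemisphere p0 = 3 W / (2 pi R^2) and
delta0 = h * p0 / k.

The verification benchmark is a rigid 20 mm ball in a rigid 24 mm shell
with a 4 mm elastic layer under 2000 N: the one-layer configuration slides
at the ball surface (contact radius 20 mm), the two-layer configuration
(2 + 2 mm) slides at the mid interface (22 mm).  Because peak pressure
scales as 1/R^2, the continuum one-layer peak exceeds the two-layer peak by
(22/20)^2 - 1 = 21 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cartilage import project_cartilage
from .errors import HipDeaError
from .mesh import make_ball_socket
from .solver import DEASolution, SolverConfig, solve_equilibrium
from .springs import LinearMaterial, build_springs

__all__ = ["AnalyticProfile", "analytic_layer_solution", "run_verification", "VerificationReport"]


@dataclass
class AnalyticProfile:
    """Elastic-foundation pressure profile p(theta)."""

    theta: np.ndarray  # degrees from vertical
    pressure: np.ndarray  # MPa
    delta0: float  # central approach, mm
    p0: float  # peak pressure, MPa
    contact_half_angle: float  # degrees

    def at(self, theta_deg) -> np.ndarray:
        """Pressure at arbitrary angles (degrees)."""
        theta_deg = np.asarray(theta_deg, dtype=float)
        p = self.p0 * np.cos(np.deg2rad(theta_deg))
        return np.where(theta_deg <= self.contact_half_angle, np.maximum(p, 0.0), 0.0)


def analytic_layer_solution(
    r_contact: float,
    h: float,
    k: float,
    w: float,
    cap_angle: float = 90.0,
    n_theta: int = 181,
) -> AnalyticProfile:
    """Closed-form conformal-layer contact solution.

    Parameters are the contact-interface radius (mm), layer thickness (mm),
    constrained modulus (MPa), total compressive load (N) and the cap
    half-angle limiting the contact (degrees; pressure support never
    exceeds 90 degrees).
    """
    if min(r_contact, h, k) <= 0 or w < 0:
        raise ValueError("r_contact, h, k must be positive and w non-negative")
    theta_c = min(cap_angle, 90.0)
    tc = np.deg2rad(theta_c)
    p0 = 3.0 * w / (2.0 * np.pi * r_contact**2 * (1.0 - np.cos(tc) ** 3))
    delta0 = h * p0 / k
    if delta0 >= h:
        raise HipDeaError(
            f"layer bottoms out: central approach {delta0:.3f} mm >= thickness {h} mm"
        )
    theta = np.linspace(0.0, theta_c, n_theta)
    return AnalyticProfile(
        theta=theta,
        pressure=p0 * np.cos(np.deg2rad(theta)),
        delta0=delta0,
        p0=p0,
        contact_half_angle=theta_c,
    )


@dataclass
class VerificationReport:
    """One- vs two-layer DEA against the analytic layer solution."""

    theta_1layer: np.ndarray
    stress_1layer: np.ndarray
    theta_2layer: np.ndarray
    stress_2layer: np.ndarray
    analytic_1layer: AnalyticProfile
    analytic_2layer: AnalyticProfile
    rmse_1layer_vs_analytic: float
    rmse_2layer_vs_analytic: float
    peak_1layer: float
    peak_2layer: float
    peak_excess_percent: float
    solution_1layer: DEASolution = field(repr=False, default=None)
    solution_2layer: DEASolution = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "rmse_1layer_vs_analytic": self.rmse_1layer_vs_analytic,
            "rmse_2layer_vs_analytic": self.rmse_2layer_vs_analytic,
            "peak_1layer": self.peak_1layer,
            "peak_2layer": self.peak_2layer,
            "peak_analytic": self.analytic_1layer.p0,
            "delta0_analytic": self.analytic_1layer.delta0,
            "peak_excess_percent": self.peak_excess_percent,
        }


def _solve_config(acet_layer, fem_layer, load, material, cfg, axis):
    springs = build_springs(acet_layer, fem_layer)
    sol = solve_equilibrium(springs, load, material, config=cfg)
    verts = acet_layer.articular_surface.vertices
    radii = np.linalg.norm(verts, axis=1)
    cos_t = np.clip((verts @ axis) / radii, -1.0, 1.0)
    theta = np.degrees(np.arccos(cos_t))
    return sol, theta


def run_verification(
    r_ball: float = 20.0,
    r_shell: float = 24.0,
    layer_thickness: float = 4.0,
    e: float = 11.85,
    v: float = 0.45,
    load_magnitude: float = 2000.0,
    target_edge: float = 1.0,
    cap_angle: float = 90.0,
    theta_max: float = 85.0,
    rel_tol: float = 1e-6,
) -> VerificationReport:
    """Run the ball-and-socket verification benchmark.

    Builds the one-layer model (all ``layer_thickness`` mm of cartilage on
    the shell, sliding contact at the ball surface) and the two-layer model
    (half on each side, contact at the mid interface), solves both under a
    vertical compressive load with linear springs, and compares the
    one-layer nodal stresses with the analytic profile over nodes with
    theta <= ``theta_max`` (the boundary ring is excluded).  The benchmark
    is deterministic, so a tight force tolerance costs little and is used
    by default.
    """
    if layer_thickness != r_shell - r_ball:
        raise ValueError("layer must fill the shell-ball gap exactly (conformal benchmark)")
    axis = np.array([0.0, 0.0, -1.0])  # pole direction; load axis is -z on the ball
    ball, shell = make_ball_socket(r_ball, r_shell, target_edge, cap_angle, axis)
    material = LinearMaterial(e, v)
    load = -load_magnitude * axis  # joint reaction on the femoral side
    cfg = SolverConfig(rel_tol=rel_tol)

    # one layer: whole thickness on the shell, contact at the ball surface
    acet1 = project_cartilage(shell, layer_thickness, "acetabular")
    fem1 = project_cartilage(ball, 0.0, "femoral")
    sol1, theta1 = _solve_config(acet1, fem1, load, material, cfg, axis)

    # two layers: split thickness, contact at the mid interface
    half = 0.5 * layer_thickness
    acet2 = project_cartilage(shell, half, "acetabular")
    fem2 = project_cartilage(ball, half, "femoral")
    sol2, theta2 = _solve_config(acet2, fem2, load, material, cfg, axis)

    ana1 = analytic_layer_solution(r_ball, layer_thickness, material.k, load_magnitude, cap_angle)
    ana2 = analytic_layer_solution(
        r_ball + half, layer_thickness, material.k, load_magnitude, cap_angle
    )

    def _rmse(theta, sol, ana):
        sel = (theta <= theta_max) & sol.contact
        return float(np.sqrt(np.mean((sol.stress[sel] - ana.at(theta[sel])) ** 2)))

    peak1 = float(sol1.stress.max())
    peak2 = float(sol2.stress.max())
    return VerificationReport(
        theta_1layer=theta1,
        stress_1layer=sol1.stress,
        theta_2layer=theta2,
        stress_2layer=sol2.stress,
        analytic_1layer=ana1,
        analytic_2layer=ana2,
        rmse_1layer_vs_analytic=_rmse(theta1, sol1, ana1),
        rmse_2layer_vs_analytic=_rmse(theta2, sol2, ana2),
        peak_1layer=peak1,
        peak_2layer=peak2,
        peak_excess_percent=100.0 * (peak1 / peak2 - 1.0),
        solution_1layer=sol1,
        solution_2layer=sol2,
    )
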