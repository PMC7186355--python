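"""Rigid-body translational equilibrium of the spring bed.

The femoral side is free to translate (3 DOF, no rotation).  The solver
finds the translation t at which the vector sum of compressive spring
forces balances the joint reaction ``load`` transmitted through the
cartilage, by gradient descent on the residual

    f(t) = || sum_i F_i(t) - load ||            (N)

by descent on f with central finite-difference derivatives and a
backtracking line search.  Each iteration first tries the Gauss-Newton
step (exact wherever the contact active set does not change, since spring
forces are piecewise linear in t there) and falls back to steepest descent
when that step does not reduce f.  The initial iterate approaches along
the load axis until first contact.  Convergence is declared when
f <= rel_tol * ||load||.

Contact stress is reported per acetabular articular node as
sigma_i = |F_i| / S_i = material stress at strain eps_i; nodes out of
contact carry zero stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, DislocationError, FullCompressionError
from .springs import STRAIN_CLAMP, LinearMaterial, NonlinearMaterial, SpringSet

__all__ = ["SolverConfig", "DEASolution", "solve_equilibrium"]


@dataclass(frozen=True)
class SolverConfig:
    """Tunable solver parameters.

    rel_tol — force-imbalance tolerance relative to ||load||;
    fd_step — central-difference step for the residual gradient, mm;
    strain_clamp — hard strain cap (nonphysical near full compression);
    armijo, step_shrink, min_step — line-search constants.
    """

    rel_tol: float = 1e-3
    max_iter: int = 500
    fd_step: float = 1e-4
    strain_clamp: float = STRAIN_CLAMP
    armijo: float = 1e-4
    step_shrink: float = 0.5
    min_step: float = 1e-10

    def __post_init__(self):
        if not (0 < self.rel_tol < 1 and self.fd_step > 0 and 0 < self.strain_clamp <= 1):
            raise ValueError("invalid solver configuration")


@dataclass
class DEASolution:
    """Equilibrium state of a DEA contact model."""

    translation: np.ndarray  # mm, rigid femoral translation
    stress: np.ndarray  # MPa per acetabular articular node
    contact: np.ndarray  # bool per node
    residual: float  # N, force imbalance at the solution
    iterations: int
    converged: bool
    strains: np.ndarray = field(repr=False, default=None)
    forces: np.ndarray = field(repr=False, default=None)  # (n, 3) N

    @property
    def n_contact(self) -> int:
        return int(self.contact.sum())


def _total_force(springs: SpringSet, material, t, clamp):
    """(sum of forces, per-spring stress, strains) at translation t.

    Returns None when any strain violates the clamp, so the line search can
    reject the step.
    """
    dd = springs.compressions(t)
    eps = np.zeros(len(springs))
    use = springs.usable
    eps[use] = dd[use] / springs.h_combined[use]
    if np.any(eps >= clamp):
        return None
    sigma = material.stress(eps)
    total = (sigma * springs.areas) @ springs.dirs
    return total, sigma, eps


def _first_contact_step(springs: SpringSet, direction: np.ndarray) -> float:
    """Smallest femoral advance along ``direction`` that closes some gap."""
    rate = springs.dirs @ direction  # gap change per unit step
    closing = springs.usable & (rate < -1e-12)
    if not closing.any():
        raise DislocationError("no spring can activate along the load direction")
    g0 = springs.gap0[closing]
    if np.any(g0 <= 0):
        return 0.0
    return float(np.min(g0 / -rate[closing]))


def solve_equilibrium(
    springs: SpringSet,
    load,
    material: LinearMaterial | NonlinearMaterial = LinearMaterial(),
    law: str | None = None,
    config: SolverConfig | None = None,
) -> DEASolution:
    """Find the femoral translation balancing ``load`` through the spring bed.

    ``load`` is the joint reaction force vector on the femoral side (N):
    the vector the spring forces must sum to at equilibrium.  ``law``
    optionally cross-checks the material type ('linear'/'nonlinear').
    """
    cfg = config or SolverConfig()
    load = np.asarray(load, dtype=float)
    load_norm = float(np.linalg.norm(load))
    if load_norm <= 0:
        raise ValueError("load magnitude must be positive")
    if law is not None:
        expected = LinearMaterial if law == "linear" else NonlinearMaterial
        if law not in ("linear", "nonlinear") or not isinstance(material, expected):
            raise ValueError(f"material {type(material).__name__} does not match law {law!r}")

    def residual_vector(t):
        out = _total_force(springs, material, t, cfg.strain_clamp)
        if out is None:
            return None
        return out[0] - load

    def residual(t):
        r = residual_vector(t)
        return np.inf if r is None else float(np.linalg.norm(r))

    # initial approach: advance along the load axis until first contact,
    # then a cheap 1-D bracket toward force balance along that axis
    approach = -load / load_norm  # femur moves opposite the reaction it receives
    a = _first_contact_step(springs, approach)
    t = a * approach
    f = residual(t)
    step = max(1e-3, 1e-3 * float(np.median(springs.h_combined[springs.usable])))
    while True:
        f_next = residual(t + step * approach)
        if f_next >= f or not np.isfinite(f_next):
            break
        t = t + step * approach
        f = f_next
        step *= 2.0

    tol = cfg.rel_tol * load_norm
    n_iter = 0
    converged = f <= tol
    while not converged and n_iter < cfg.max_iter:
        n_iter += 1
        r = residual_vector(t)
        if r is None:
            break
        # central finite-difference Jacobian of the 3-vector imbalance
        jac = np.empty((3, 3))
        for axis in range(3):
            dt = np.zeros(3)
            dt[axis] = cfg.fd_step
            rp, rm = residual_vector(t + dt), residual_vector(t - dt)
            if rp is not None and rm is not None:
                jac[:, axis] = (rp - rm) / (2.0 * cfg.fd_step)
            elif rm is not None:  # forward step hits the strain clamp
                jac[:, axis] = (r - rm) / cfg.fd_step
            elif rp is not None:
                jac[:, axis] = (rp - r) / cfg.fd_step
            else:
                jac[:, axis] = 0.0

        def _try(direction, slope):
            nonlocal t, f
            alpha = 1.0
            while alpha >= cfg.min_step:
                f_new = residual(t + alpha * direction)
                if f_new <= f - cfg.armijo * alpha * slope:
                    t = t + alpha * direction
                    f = f_new
                    return True
                alpha *= cfg.step_shrink
            return False

        improved = False
        # Gauss-Newton step: exact within the current contact active set
        dt_gn = np.linalg.lstsq(jac, -r, rcond=None)[0]
        if np.all(np.isfinite(dt_gn)) and np.linalg.norm(dt_gn) > 0:
            improved = _try(dt_gn, f)
        if not improved:
            # steepest descent on f = ||r||; step sized to the first-order
            # zero crossing f / ||grad f||
            grad = (jac.T @ r) / f
            gnorm = float(np.linalg.norm(grad))
            if gnorm == 0.0 or not np.isfinite(gnorm):
                break
            direction = -(grad / gnorm) * (f / gnorm)
            improved = _try(direction, f)
        if not improved:
            break  # stuck at a kink of the piecewise-smooth residual
        converged = f <= tol

    if not converged:
        raise ConvergenceError(
            f"no equilibrium within {n_iter} iterations (residual {f:.4g} N, "
            f"tolerance {tol:.4g} N)",
            translation=t,
            residual=f,
            iterations=n_iter,
        )

    out = _total_force(springs, material, t, cfg.strain_clamp)
    if out is None:
        raise FullCompressionError("solution violates the strain clamp")
    total, sigma, eps = out
    contact = (eps > 0) & springs.usable
    if not contact.any():
        raise DislocationError("all springs inactive at the optimum")
    sigma = np.where(contact, sigma, 0.0)
    forces = (sigma * springs.areas)[:, None] * springs.dirs
    return DEASolution(
        translation=t,
        stress=sigma,
        contact=contact,
        residual=float(np.linalg.norm(total - load)),
        iterations=n_iter,
        converged=True,
        strains=eps,
        forces=forces,
    )
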