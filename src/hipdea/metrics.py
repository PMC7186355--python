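"""Contact summaries, node-wise comparison and Bland-Altman agreement.

These are the evaluation tools used to compare contact solutions between
models (e.g. DEA vs a reference solution, or two cartilage-geometry
methods): peak/average contact stress and contact area, node-by-node
stress differences over a correspondence, and (regression-based)
Bland-Altman limits of agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh
from .solver import DEASolution
from .springs import SpringSet

__all__ = [
    "ContactSummary",
    "AgreementStats",
    "contact_summary",
    "nearest_correspondence",
    "nodewise_difference",
    "bland_altman",
]


@dataclass(frozen=True)
class ContactSummary:
    """Peak stress (MPa), average stress over contacting nodes (MPa),
    contact area (mm^2) and the number of contacting nodes."""

    peak_stress: float
    average_stress: float
    contact_area: float
    n_contact_nodes: int


def contact_summary(
    solution: DEASolution, springs: SpringSet, area_weighted: bool = True
) -> ContactSummary:
    """Summary statistics over the contacting nodes of a solved model.

    Contact area is the sum of tributary areas S_i of contacting nodes,
    consistent with the stress normalization (sigma_i = |F_i| / S_i), so
    total transmitted force equals average stress times contact area when
    ``area_weighted`` is on.  Non-contacting regions are excluded from the
    average.  ``area_weighted=False`` gives the plain nodal mean instead.
    """
    mask = solution.contact
    if not mask.any():
        warnings.warn("no contacting nodes; summary is all zero", stacklevel=2)
        return ContactSummary(0.0, 0.0, 0.0, 0)
    s = springs.areas[mask]
    sigma = solution.stress[mask]
    avg = float((sigma * s).sum() / s.sum()) if area_weighted else float(sigma.mean())
    return ContactSummary(
        peak_stress=float(sigma.max()),
        average_stress=avg,
        contact_area=float(s.sum()),
        n_contact_nodes=int(mask.sum()),
    )


def nearest_correspondence(source: SurfaceMesh, target: SurfaceMesh):
    """Nearest-target-vertex index and distance for every source vertex.

    Ties in distance break deterministically toward the lowest target
    index.  Allows node-to-node comparison of fields living on meshes
    without shared connectivity.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("meshes must be non-empty")
    tree = cKDTree(target.vertices)
    dist, idx = tree.query(source.vertices)
    # deterministic tie-break: lowest index among equidistant targets
    for i in np.flatnonzero(dist >= 0):
        ties = tree.query_ball_point(source.vertices[i], dist[i] * (1 + 1e-12) + 1e-300)
        if len(ties) > 1:
            idx[i] = min(ties)
    return idx.astype(np.intp), dist


def nodewise_difference(a, b, index_map=None):
    """(rmse, mean absolute, max absolute) difference of two nodal fields.

    ``index_map`` aligns a to b (``a[i]`` compared with ``b[index_map[i]]``);
    without it the fields must already be aligned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if index_map is not None:
        b = b[np.asarray(index_map, dtype=np.intp)]
    if a.shape != b.shape:
        raise ValueError("field lengths differ; supply an index map")
    d = a - b
    return (
        float(np.sqrt(np.mean(d**2))),
        float(np.mean(np.abs(d))),
        float(np.max(np.abs(d))),
    )


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between paired measurements.

    ``bias`` is the mean difference a - b, ``loa_low``/``loa_high`` the 95 %
    limits of agreement (bias -/+ 1.96 sd).  The regression-based variant
    fits the difference against the pair mean by ordinary least squares;
    slope/intercept confidence bounds use the t distribution with n - 2
    degrees of freedom (None when fewer than 3 pairs).
    """

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    slope: float | None = None
    intercept: float | None = None
    slope_ci: tuple[float, float] | None = None
    intercept_ci: tuple[float, float] | None = None


def bland_altman(pairs) -> AgreementStats:
    """Classic and regression-based Bland-Altman statistics for (a, b) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least 2 (a, b) pairs")
    a, b = arr[:, 0], arr[:, 1]
    diff = a - b
    mean = 0.5 * (a + b)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    out = dict(bias=bias, sd_diff=sd, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)
    if len(arr) >= 3:
        sxx = float(((mean - mean.mean()) ** 2).sum())
        if sxx < 1e-30:  # all pair means identical; regression undefined -> flat line
            out.update(slope=0.0, intercept=bias, slope_ci=(0.0, 0.0), intercept_ci=(bias, bias))
        else:
            res = stats.linregress(mean, diff)
            tcrit = stats.t.ppf(0.975, len(arr) - 2)
            out.update(
                slope=float(res.slope),
                intercept=float(res.intercept),
                slope_ci=(
                    float(res.slope - tcrit * res.stderr),
                    float(res.slope + tcrit * res.stderr),
                ),
                intercept_ci=(
                    float(res.intercept - tcrit * res.intercept_stderr),
                    float(res.intercept + tcrit * res.intercept_stderr),
                ),
            )
    return AgreementStats(**out)
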