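"""Morphometric proxies and vertex-wise cohort statistics.

Provides simplified, phantom-scale counterparts of the standard surface
morphometrics — thickness as corresponding-vertex distance, a local
gyrification index against a convex-hull outer surface, geodesic-Gaussian
smoothing — plus the statistical stage applied to cohorts: vertex-wise
Pearson correlation with Student-t p-values, Benjamini-Hochberg FDR
control, and polynomial (linear/quadratic) trend fits of global metrics
against age.

Inter-subject vertex correspondence is assumed given (phantom cohorts share
one topology); no spherical registration is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.spatial import ConvexHull, QhullError, cKDTree
from statsmodels.stats.multitest import multipletests

from .emod import EphapticParams, SupportSpec, VARIANTS, emod_local
from .phantoms import CohortSubject
from .surface import (
    SurfaceMesh,
    compute_vertex_frame,
    geodesic_distance_matrix,
    neighbors_within,
)

__all__ = [
    "CorrelationMap",
    "TrendFit",
    "vertex_thickness",
    "gyrification_proxy",
    "smooth_map",
    "pearson_map",
    "bh_fdr",
    "fit_trend",
    "cohort_metrics",
]


@dataclass(frozen=True)
class CorrelationMap:
    """Vertex-wise Pearson r, two-sided p and BH rejection mask."""

    r: np.ndarray
    p: np.ndarray
    q_mask: np.ndarray
    valid: np.ndarray  # vertices where r is defined


@dataclass(frozen=True)
class TrendFit:
    """Polynomial trend of a global metric against a covariate."""

    order: int
    coefficients: np.ndarray  # ascending powers: c0 + c1 x (+ c2 x^2)
    r_squared: float
    p_value: float  # overall F-test

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


def vertex_thickness(white: SurfaceMesh, pial: SurfaceMesh) -> np.ndarray:
    """Per-vertex Euclidean distance between corresponding white/pial
    vertices (mm) — a simplified stand-in for the symmetric surface-to-
    surface definition used by full MRI pipelines."""
    if white.n_vertices != pial.n_vertices:
        raise ValueError(
            f"vertex count mismatch: white {white.n_vertices} vs pial {pial.n_vertices}"
        )
    return np.linalg.norm(pial.vertices - white.vertices, axis=1)


def gyrification_proxy(mesh: SurfaceMesh, radius: float) -> np.ndarray:
    """Local gyrification: pial area within ``radius`` of each vertex over
    outer-surface area within the same radius of the nearest outer point.

    The outer surface is the convex hull of the mesh, subdivided so its
    vertex areas sample area at a scale finer than the radius. On folded
    surfaces the ratio exceeds 1; on convex or flat surfaces it is ~1.
    A (near-)planar mesh has no 3D hull and is its own outer surface.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    frame = compute_vertex_frame(mesh, orientation="as_is")
    tree = cKDTree(mesh.vertices)

    hull_mesh: Optional[SurfaceMesh] = None
    try:
        hull = ConvexHull(mesh.vertices)
        if hull.volume > 1e-9 * radius**3:
            import trimesh as _tm

            tm = _tm.convex.convex_hull(mesh.vertices)
            # resample the hull at the mesh's own edge scale so the two
            # area-in-ball sums share boundary-sampling statistics
            edges = mesh.vertices[mesh.faces[:, [0, 1]]]
            target = float(np.max(np.linalg.norm(edges[:, 0] - edges[:, 1], axis=1)))
            v, f = _tm.remesh.subdivide_to_size(tm.vertices, tm.faces, max_edge=target)
            hull_mesh = SurfaceMesh(v, f, name="hull")
    except QhullError:
        hull_mesh = None

    pial_area_sum = np.array(
        [frame.areas[idx].sum() for idx in tree.query_ball_point(mesh.vertices, r=radius)]
    )
    if hull_mesh is None:
        # planar/degenerate: the surface is its own outer wrap
        return np.ones(mesh.n_vertices)

    hull_frame = compute_vertex_frame(hull_mesh, orientation="as_is")
    hull_tree = cKDTree(hull_mesh.vertices)
    _, nearest = hull_tree.query(mesh.vertices)
    hull_balls = hull_tree.query_ball_point(hull_mesh.vertices[nearest], r=radius)
    hull_area_sum = np.array([hull_frame.areas[idx].sum() for idx in hull_balls])
    if np.any(hull_area_sum <= 0):
        raise ValueError("degenerate hull: zero outer area in a query ball")
    return pial_area_sum / hull_area_sum


def smooth_map(mesh: SurfaceMesh, values: np.ndarray, fwhm: float) -> np.ndarray:
    """Geodesic-Gaussian surface smoothing.

    Kernel sigma = fwhm / 2.355 (mm), truncated at 3 sigma along mesh-edge
    geodesics; weights are normalized per vertex so constants are preserved.
    ``fwhm = 0`` is the identity.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mesh.n_vertices:
        raise ValueError("map length does not match vertex count")
    if fwhm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm == 0:
        return values.copy()
    sigma = fwhm / 2.355
    dist = geodesic_distance_matrix(mesh, max_dist=3.0 * sigma)
    with np.errstate(over="ignore"):
        w = np.where(np.isfinite(dist), np.exp(-0.5 * (dist / sigma) ** 2), 0.0)
    norm = w.sum(axis=1)
    return (w @ values) / norm


def pearson_map(
    subject_maps: np.ndarray, covariate: np.ndarray, q: float = 0.05
) -> CorrelationMap:
    """Vertex-wise Pearson correlation of per-subject maps with a covariate.

    ``subject_maps`` is (n_subjects, n_vertices). p-values are two-sided
    from t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; vertices
    with zero variance are masked. The BH mask is computed at level ``q``
    over the valid vertices.
    """
    X = np.asarray(subject_maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if cov.shape[0] != n:
        raise ValueError("covariate length does not match subject count")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant")
    xc = cov - cov.mean()
    Yc = X - X.mean(axis=0)
    sy = np.sqrt((Yc**2).sum(axis=0))
    sx = np.sqrt((xc**2).sum())
    valid = sy > 0
    r = np.full(X.shape[1], np.nan)
    r[valid] = (xc @ Yc[:, valid]) / (sx * sy[valid])
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r[valid] * np.sqrt((n - 2) / np.maximum(1.0 - r[valid] ** 2, 1e-300))
    p[valid] = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    q_mask = np.zeros(X.shape[1], dtype=bool)
    if valid.any():
        rej, _ = bh_fdr(p[valid], q=q)
        q_mask[valid] = rej
    return CorrelationMap(r=r, p=p, q_mask=q_mask, valid=valid)


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject mask, adjusted p-values): reject all p(i) (sorted
    ascending) with i <= max{i : p(i) <= (i/m) q}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def fit_trend(x, y, order: int = 1) -> TrendFit:
    """OLS polynomial fit of a global metric against a covariate.

    Returns coefficients in ascending powers, R-squared and the overall
    F-test p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if x.size <= order + 1:
        raise ValueError("need more points than parameters")
    design = np.vander(x, N=order + 1, increasing=True)
    if np.linalg.matrix_rank(design) < order + 1:
        raise ValueError("rank-deficient design (constant covariate?)")
    model = sm.OLS(y, design).fit()
    return TrendFit(
        order=order,
        coefficients=np.asarray(model.params),
        r_squared=float(model.rsquared),
        p_value=float(model.f_pvalue),
    )


def cohort_metrics(
    subjects: Sequence[CohortSubject],
    params: EphapticParams = EphapticParams(),
    spec: SupportSpec = VARIANTS["emod1"],
    use_area: bool = False,
    gyrification_radius: Optional[float] = None,
) -> pd.DataFrame:
    """Per-subject global metrics: EMOD1, mean thickness, total pial area
    and (optionally) mean local gyrification.

    One row per subject, carrying age alongside the metrics, ready for
    trend fits and correlation analyses.
    """
    rows = []
    for sub in subjects:
        frame = compute_vertex_frame(sub.pial, orientation="as_is")
        pairs = neighbors_within(sub.pial, params.l0)
        res = emod_local(sub.pial, frame, pairs, params, spec, use_area)
        row = {
            "subject": sub.subject,
            "age": sub.age,
            "emod1": res.global_index,
            "mean_thickness": float(vertex_thickness(sub.white, sub.pial).mean()),
            "total_area": sub.pial.total_area(),
        }
        if gyrification_radius is not None:
            row["mean_gyrification"] = float(
                gyrification_proxy(sub.pial, gyrification_radius).mean()
            )
        rows.append(row)
    return pd.DataFrame(rows)
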