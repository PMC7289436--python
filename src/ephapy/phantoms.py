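"""Synthetic folded-surface phantoms and an age-parameterized cohort.

Real cortical meshes require an MRI pipeline; these phantoms reproduce the
geometric features the ephaptic index responds to — opposing sulcal walls at
a controllable wall-to-wall width, a curved fundus, optional gyral crowns —
with exactly known geometry, so every pipeline stage is testable against
closed forms. Null geometries (flat sheet, sphere, parallel plates) bracket
the index: convex or flat surfaces give identically zero gated index, and
the parallel-plate limit has an analytic value.

The synthetic cohort emulates age-related sulcal widening (and cortical
thinning) via a linear width model with Gaussian noise; all subjects share
one mesh topology so vertex correspondence holds across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import trimesh

from .surface import SurfaceMesh, VertexFrame, compute_vertex_frame

__all__ = [
    "SulcusSpec",
    "CohortSpec",
    "CohortSubject",
    "make_sulcus_phantom",
    "make_parallel_plates",
    "make_flat_sheet",
    "make_sphere",
    "make_synthetic_cohort",
]


@dataclass(frozen=True)
class SulcusSpec:
    """Geometry of a single synthetic sulcus.

    width   : wall-to-wall separation, mm (the "sulcal width").
    depth   : top-of-wall to fundus bottom, mm; must exceed width.
    length  : extrusion length along the sulcus, mm.
    gyral_cap : add outward-curving crowns at the top of the outer walls.
    spacing : target edge length, mm; must be < width/2.
    n_folds : number of parallel sulci; adjacent folds share a gyral crown
              (a corrugated sheet emulating repeated cortical folding).
    """

    width: float = 2.0
    depth: float = 10.0
    length: float = 10.0
    gyral_cap: bool = True
    spacing: float = 0.5
    n_folds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.spacing >= self.width / 2:
            raise ValueError("spacing must be < width/2 to resolve the gap")
        if self.depth <= self.width:
            raise ValueError("depth must exceed width")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")


@dataclass(frozen=True)
class CohortSpec:
    """Age-parameterized synthetic cohort.

    Sulcal width follows w(age) = w_base + slope * age + N(0, noise_sd) mm,
    emulating reported age-related widening; thickness follows
    t(age) = t_base + t_slope * age + N(0, t_noise_sd) mm (thinning for
    negative slope). Widths are floored at 2.05 * spacing so every subject's
    gap stays resolvable. Generation is a pure function of the spec.
    """

    n_subjects: int = 40
    age_range: tuple[float, float] = (16.0, 83.0)
    w_base: float = 0.8
    slope: float = 0.03
    noise_sd: float = 0.15
    t_base: float = 2.8
    t_slope: float = -0.01
    t_noise_sd: float = 0.1
    depth: float = 8.0
    length: float = 6.0
    spacing: float = 0.4
    gyral_cap: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")


@dataclass(frozen=True)
class CohortSubject:
    subject: str
    age: float
    width_mm: float
    thickness_mm: float
    pial: SurfaceMesh
    white: SurfaceMesh


# ---------------------------------------------------------------------------
# Extrusion helpers
# ---------------------------------------------------------------------------


def _extrude_profile(profile_xz: np.ndarray, y_vals: np.ndarray, name: str) -> SurfaceMesh:
    """Extrude an (x, z) polyline along y into a triangle strip grid.

    With the profile ordered so successive points advance and y increasing,
    face winding gives normals along (profile tangent) x (+y).
    """
    nk = profile_xz.shape[0]
    ny = y_vals.shape[0]
    verts = np.empty((nk * ny, 3))
    verts[:, 0] = np.repeat(profile_xz[:, 0], ny)
    verts[:, 1] = np.tile(y_vals, nk)
    verts[:, 2] = np.repeat(profile_xz[:, 1], ny)
    idx = np.arange(nk * ny).reshape(nk, ny)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], axis=1), np.stack([a, c, d], axis=1)])
    return SurfaceMesh(verts, faces, name=name)


def _arc(center, radius, a0, a1, n_seg):
    ang = np.linspace(a0, a1, n_seg + 1)
    return np.stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1)


def _profile_counts(width: float, depth: float, spacing: float, gyral_cap: bool) -> dict:
    """Per-piece segment counts; fixing these fixes the mesh topology."""
    wall_len = depth - width / 2.0
    counts = {
        "wall": max(2, int(np.ceil(wall_len / spacing))),
        "fundus": max(3, int(np.ceil((np.pi * width / 2.0) / spacing))),
        "crown": max(3, int(np.ceil((np.pi * width / 2.0) / spacing))),
    }
    if gyral_cap:
        counts["cap"] = max(2, int(np.ceil((np.pi * width / 4.0) / spacing)))
    return counts


def _sulcus_profile(width: float, depth: float, gyral_cap: bool, counts: dict,
                    n_folds: int = 1):
    """Cross-section polyline in (x, z) with per-point piece labels.

    Folds sit at period 2 * width; adjacent folds share a semicircular gyral
    crown. Traversal order (cap_a, [wall_a, fundus, wall_b, crown]*, cap_b)
    makes the extruded normals point into the sulcal gaps on all walls.
    """
    w2 = width / 2.0
    z_top = 0.0
    z_wall_bottom = -(depth - w2)
    pieces: list[tuple[str, np.ndarray]] = []

    def wall(x, z0, z1):
        return np.stack(
            [np.full(counts["wall"] + 1, x), np.linspace(z0, z1, counts["wall"] + 1)], axis=1
        )

    x_first = -(n_folds - 1) * width - w2  # wall_a of the first fold
    if gyral_cap:
        pieces.append(("cap_a", _arc((x_first - w2, z_top), w2, np.pi / 2.0, 0.0, counts["cap"])))
    for f in range(n_folds):
        xc = (2.0 * f - (n_folds - 1)) * width
        pieces.append(("wall_a", wall(xc - w2, z_top, z_wall_bottom)))
        pieces.append(("fundus", _arc((xc, z_wall_bottom), w2, np.pi, 2.0 * np.pi, counts["fundus"])))
        pieces.append(("wall_b", wall(xc + w2, z_wall_bottom, z_top)))
        if f < n_folds - 1:
            pieces.append(("crown", _arc((xc + width, z_top), w2, np.pi, 0.0, counts["crown"])))
    if gyral_cap:
        x_last = (n_folds - 1) * width + w2
        pieces.append(("cap_b", _arc((x_last + w2, z_top), w2, np.pi, np.pi / 2.0, counts["cap"])))
    points = [pieces[0][1]]
    labels = [np.full(pieces[0][1].shape[0], pieces[0][0], dtype=object)]
    for name, arr in pieces[1:]:
        points.append(arr[1:])  # drop shared joint point
        labels.append(np.full(arr.shape[0] - 1, name, dtype=object))
    return np.concatenate(points), np.concatenate(labels)


# ---------------------------------------------------------------------------
# Phantom constructors
# ---------------------------------------------------------------------------


def make_sulcus_phantom(
    spec: SulcusSpec, counts: Optional[dict] = None
) -> tuple[SurfaceMesh, VertexFrame, np.ndarray]:
    """Open sulcus surface: two opposing walls joined by a semicylindrical
    fundus, optionally capped by gyral crowns.

    Returns the mesh, its vertex frame (normals point into the sulcal gap on
    the walls, so facing wall vertices have n_x . n_y = -1), and a per-vertex
    label array (cap_a, wall_a, fundus, wall_b, cap_b). Passing ``counts``
    (from a reference geometry) fixes the topology across varying widths.
    """
    if counts is None:
        counts = _profile_counts(spec.width, spec.depth, spec.spacing, spec.gyral_cap)
    profile, plabels = _sulcus_profile(spec.width, spec.depth, spec.gyral_cap, counts,
                                       n_folds=spec.n_folds)
    ny = max(2, int(np.ceil(spec.length / spec.spacing))) + 1
    y_vals = np.linspace(0.0, spec.length, ny)
    mesh = _extrude_profile(profile, y_vals, name=f"sulcus_w{spec.width:g}")
    labels = np.repeat(plabels, ny)
    frame = compute_vertex_frame(mesh, orientation="as_is")
    return mesh, frame, labels


def make_parallel_plates(separation: float, side: float, spacing: float) -> SurfaceMesh:
    """Two square sheets at z = 0 and z = separation with inward-facing
    normals — the idealized limit of opposing sulcal walls."""
    if separation <= 0 or side <= 0 or spacing <= 0:
        raise ValueError("separation, side and spacing must be positive")
    n = int(np.round(side / spacing)) + 1
    x = np.linspace(-side / 2.0, side / 2.0, n)
    bottom = np.stack([x, np.zeros(n)], axis=1)  # z = 0, normal +z
    top = np.stack([x[::-1], np.full(n, separation)], axis=1)  # reversed -> normal -z
    mb = _extrude_profile(bottom, x, name="plate_bottom")
    mt = _extrude_profile(top, x, name="plate_top")
    verts = np.concatenate([mb.vertices, mt.vertices])
    faces = np.concatenate([mb.faces, mt.faces + mb.n_vertices])
    return SurfaceMesh(verts, faces, name=f"plates_d{separation:g}")


def make_flat_sheet(side: float, spacing: float) -> SurfaceMesh:
    """Square sheet in the z = 0 plane (normals +z); gated-index null case."""
    n = int(np.round(side / spacing)) + 1
    x = np.linspace(-side / 2.0, side / 2.0, n)
    profile = np.stack([x, np.zeros(n)], axis=1)
    mesh = _extrude_profile(profile, x, name="flat_sheet")
    return mesh


def make_sphere(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    """Icosphere (closed, outward winding); convex null case for the gated
    index whenever radius > l0 / sqrt(2)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces), name=f"sphere_r{radius:g}")


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


def make_synthetic_cohort(spec: CohortSpec) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Generate an age-parameterized cohort of sulcus phantoms.

    Each subject gets a pial sulcus surface whose width follows the age
    model, and a white surface offset inward by the subject's thickness
    (so pial-white vertex distances equal the thickness exactly). All
    subjects share one topology: profile counts come from the width model
    evaluated at the mid-range age.
    """
    rng = np.random.default_rng(spec.seed)
    ages = np.sort(rng.uniform(spec.age_range[0], spec.age_range[1], spec.n_subjects))
    widths = spec.w_base + spec.slope * ages + rng.normal(0.0, spec.noise_sd, spec.n_subjects)
    widths = np.maximum(widths, 2.05 * spec.spacing)
    thicknesses = spec.t_base + spec.t_slope * ages + rng.normal(0.0, spec.t_noise_sd, spec.n_subjects)
    thicknesses = np.maximum(thicknesses, 0.5)

    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    ref_width = max(spec.w_base + spec.slope * mid_age, 2.05 * spec.spacing)
    counts = _profile_counts(ref_width, spec.depth, spec.spacing, spec.gyral_cap)

    subjects: list[CohortSubject] = []
    rows = []
    for k in range(spec.n_subjects):
        sub_id = f"sub-{k:03d}"
        s = SulcusSpec(
            width=float(widths[k]),
            depth=spec.depth,
            length=spec.length,
            gyral_cap=spec.gyral_cap,
            spacing=min(spec.spacing, widths[k] / 2.05),
            seed=spec.seed,
        )
        pial, frame, _ = make_sulcus_phantom(s, counts=counts)
        white = SurfaceMesh(
            pial.vertices - thicknesses[k] * frame.normals, pial.faces,
            name=pial.name + "_white",
        )
        subjects.append(
            CohortSubject(
                subject=sub_id,
                age=float(ages[k]),
                width_mm=float(widths[k]),
                thickness_mm=float(thicknesses[k]),
                pial=pial,
                white=white,
            )
        )
        rows.append(
            {
                "subject": sub_id,
                "age": float(ages[k]),
                "width_mm": float(widths[k]),
                "thickness_mm": float(thicknesses[k]),
            }
        )
    return subjects, pd.DataFrame(rows)
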