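"""Quasi-static current-dipole electrostatics in a homogeneous medium.

The endogenous fields of interest oscillate below ~100 Hz, where the
quasi-static approximation holds: a current dipole **p** at the origin of an
infinite medium of conductivity sigma produces

    Phi(x) = p . rhat / (4 pi sigma r^2)
    E(x)   = -grad Phi = (3 (p . rhat) rhat - p) / (4 pi sigma r^3)
           = p / (4 pi sigma r^3) (2 cos(theta) rhat + sin(theta) thetahat)

with r the source-observer distance and theta the angle from the dipole
axis. This analytic surrogate replaces finite-element tissue models: it
reproduces the r^-3 single-source decay regime while remaining closed-form.

Units at the API boundary: positions mm, moments nA.m, conductivity S/m;
fields are returned in V/m and potentials in microvolts. SI is used
internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .emod import EphapticParams

__all__ = [
    "Medium",
    "DipoleSet",
    "FieldSample",
    "DecayFit",
    "dipole_field",
    "dipole_potential",
    "make_grid_patch",
    "patch_field",
    "lambda_e",
    "pairwise_impact",
    "fit_power_decay",
    "TISSUE_CONDUCTIVITY",
]

#: Low-frequency tissue conductivities (S/m); only the homogeneous scalar is
#: used in computation, the table is reference data.
TISSUE_CONDUCTIVITY = {"scalp": 0.33, "skull": 0.008, "csf": 1.79, "gm": 0.40, "wm": 0.15}

_MM = 1e-3  # mm -> m
_NAM = 1e-9  # nA.m -> A.m
_V_TO_UV = 1e6
_R_SINGULAR_M = 1e-9  # observer closer than this (m) to a source is singular


@dataclass(frozen=True)
class Medium:
    """Homogeneous volume conductor of conductivity sigma (S/m)."""

    sigma: float = TISSUE_CONDUCTIVITY["gm"]
    tissue_table: dict = field(default_factory=lambda: dict(TISSUE_CONDUCTIVITY))

    def __post_init__(self) -> None:
        if self.sigma <= 0 or any(v <= 0 for v in self.tissue_table.values()):
            raise ValueError("conductivities must be positive")


@dataclass(frozen=True)
class DipoleSet:
    """Point current dipoles: positions (mm), moments (nA.m), nominal
    surface density p0 (nA.m/mm^2)."""

    positions: np.ndarray  # (n, 3) mm
    moments: np.ndarray  # (n, 3) nA.m
    density: float = 0.0

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        mom = np.atleast_2d(np.asarray(self.moments, dtype=np.float64))
        if pos.shape != mom.shape or pos.shape[1] != 3:
            raise ValueError("positions and moments must both be (n, 3)")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "moments", mom)

    @property
    def n_dipoles(self) -> int:
        return int(self.positions.shape[0])


@dataclass(frozen=True)
class FieldSample:
    """Field/potential evaluated at observation points.

    ``r`` and ``theta`` are per (point, source): distance in mm and polar
    angle (rad) from each source's moment axis.
    """

    points: np.ndarray  # (m, 3) mm
    E: np.ndarray  # (m, 3) V/m
    phi: np.ndarray  # (m,) microvolts
    r: np.ndarray  # (m, n_sources) mm
    theta: np.ndarray  # (m, n_sources) rad

    def to_frame(self):
        """Tabular export (pandas DataFrame) for plotting/CSV."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "y_mm": self.points[:, 1],
                "z_mm": self.points[:, 2],
                "Ex_V_per_m": self.E[:, 0],
                "Ey_V_per_m": self.E[:, 1],
                "Ez_V_per_m": self.E[:, 2],
                "Emag_V_per_m": np.linalg.norm(self.E, axis=1),
                "phi_uV": self.phi,
            }
        )


@dataclass(frozen=True)
class DecayFit:
    """Power-law fit v ~ r^exponent from OLS on (log10 r, log10 |v|)."""

    exponent: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("decay fit needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of [0, 1]")


# ---------------------------------------------------------------------------
# Point-dipole formulas
# ---------------------------------------------------------------------------


def _displacements_m(sources_mm: np.ndarray, obs_mm: np.ndarray) -> np.ndarray:
    return (np.atleast_2d(obs_mm)[:, None, :] - np.atleast_2d(sources_mm)[None, :, :]) * _MM


def dipole_field(moment, source, obs, sigma: float = TISSUE_CONDUCTIVITY["gm"]) -> np.ndarray:
    """Electric field (V/m) of one current dipole at an observation point.

    Cartesian form (3 (p.rhat) rhat - p) / (4 pi sigma r^3); for a moment
    along z this equals the polar form p/(4 pi sigma r^3)
    (2 cos(theta) rhat + sin(theta) thetahat).
    """
    d = (np.asarray(obs, dtype=float) - np.asarray(source, dtype=float)) * _MM
    r = np.linalg.norm(d)
    if r < _R_SINGULAR_M:
        raise ValueError(f"observation point within {_R_SINGULAR_M} m of the source")
    p = np.asarray(moment, dtype=float) * _NAM
    rhat = d / r
    return (3.0 * (p @ rhat) * rhat - p) / (4.0 * np.pi * sigma * r**3)


def dipole_potential(moment, source, obs, sigma: float = TISSUE_CONDUCTIVITY["gm"]) -> float:
    """Electrostatic potential (microvolts): Phi = p.rhat / (4 pi sigma r^2)."""
    d = (np.asarray(obs, dtype=float) - np.asarray(source, dtype=float)) * _MM
    r = np.linalg.norm(d)
    if r < _R_SINGULAR_M:
        raise ValueError(f"observation point within {_R_SINGULAR_M} m of the source")
    p = np.asarray(moment, dtype=float) * _NAM
    return float((p @ d) / (4.0 * np.pi * sigma * r**3) * _V_TO_UV)


# ---------------------------------------------------------------------------
# Dipole patches
# ---------------------------------------------------------------------------


def make_grid_patch(
    extent: float,
    spacing: float = 1.0,
    n_dipoles: int = 77,
    density: float = 0.5,
    normal=(0.0, 0.0, 1.0),
    center=(0.0, 0.0, 0.0),
) -> DipoleSet:
    """Regular planar grid of identical dipoles emulating an active patch.

    Each dipole carries moment density * extent / n_dipoles along ``normal``
    (e.g. 60 mm^2 shared by 77 dipoles at 0.5 nA.m/mm^2 gives 0.39 nA.m
    each). The grid is the most square rows x cols factorization of
    ``n_dipoles``, spaced ``spacing`` mm in the plane orthogonal to
    ``normal`` and centred on ``center``.
    """
    if n_dipoles < 1:
        raise ValueError("n_dipoles must be >= 1")
    if extent <= 0:
        raise ValueError("extent must be positive")
    n_hat = np.asarray(normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    # in-plane orthonormal basis
    seed = np.array([1.0, 0.0, 0.0]) if abs(n_hat[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(n_hat, seed)
    u /= np.linalg.norm(u)
    v = np.cross(n_hat, u)
    rows = int(np.floor(np.sqrt(n_dipoles)))
    while n_dipoles % rows:
        rows -= 1
    cols = n_dipoles // rows
    iu = (np.arange(rows) - (rows - 1) / 2.0) * spacing
    iv = (np.arange(cols) - (cols - 1) / 2.0) * spacing
    uu, vv = np.meshgrid(iu, iv, indexing="ij")
    positions = np.asarray(center, dtype=float) + uu.ravel()[:, None] * u + vv.ravel()[:, None] * v
    strength = density * extent / n_dipoles
    moments = np.tile(strength * n_hat, (n_dipoles, 1))
    return DipoleSet(positions=positions, moments=moments, density=density)


def patch_field(dipoles: DipoleSet, points, sigma: float = TISSUE_CONDUCTIVITY["gm"]) -> FieldSample:
    """Linear superposition of all dipoles' fields and potentials at points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = _displacements_m(dipoles.positions, pts)  # (m, n, 3)
    r = np.linalg.norm(d, axis=2)
    if np.any(r < _R_SINGULAR_M):
        raise ValueError("an observation point coincides with a source")
    p = dipoles.moments * _NAM  # (n, 3)
    pdotd = np.einsum("mns,ns->mn", d, p)
    E = (3.0 * pdotd[..., None] * d / r[..., None] ** 2 - p[None, :, :]) / (
        4.0 * np.pi * sigma * r[..., None] ** 3
    )
    phi = pdotd / (4.0 * np.pi * sigma * r**3) * _V_TO_UV
    p_norm = np.linalg.norm(p, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(p_norm > 0, pdotd / (r * np.where(p_norm > 0, p_norm, 1.0)), 0.0)
    theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
    return FieldSample(points=pts, E=E.sum(axis=1), phi=phi.sum(axis=1), r=r / _MM, theta=theta)


# ---------------------------------------------------------------------------
# lambda-E coupling
# ---------------------------------------------------------------------------


def lambda_e(E, lambda_vec) -> float:
    """Membrane perturbation deltaPhi = lambda . E in microvolts.

    ``lambda_vec`` is the effective space-constant vector in mm, so
    mm x V/m = mV, returned as microvolts (x1000).
    """
    return float(np.dot(np.asarray(lambda_vec, float), np.asarray(E, float)) * 1e3)


def pairwise_impact(
    source_pos,
    source_normal,
    obs_pos,
    obs_normal,
    params: "EphapticParams",
    mode: str = "on_top",
    delta_area: float = 1.0,
) -> float:
    """Ephaptic impact (microvolts) of a unit-area dipole source on a receiver.

    The source carries moment p0 * delta_area along its surface normal; the
    receiver couples through lambda0 times its own normal. ``mode="full"``
    evaluates the exact dipole field; ``mode="on_top"`` uses the on-axis
    approximation 2 lambda0 p0 dA (n_x . n_y) / (4 pi sigma r^3), which the
    full form reduces to when the receiver sits on the dipole axis.
    """
    src = np.asarray(source_pos, float)
    obs = np.asarray(obs_pos, float)
    n_y = np.asarray(source_normal, float)
    n_x = np.asarray(obs_normal, float)
    if mode == "full":
        moment = params.p0 * delta_area * n_y  # nA.m
        E = dipole_field(moment, src, obs, params.sigma)
        return lambda_e(E, params.lambda0 * n_x)
    if mode == "on_top":
        r = np.linalg.norm(obs - src)
        if r * _MM < _R_SINGULAR_M:
            raise ValueError("source and receiver coincide")
        # kappa (uV.mm) * dA (mm^2) / r^3 (mm^3), with n_x.n_y orientation factor
        return float(params.kappa * delta_area * (n_x @ n_y) / r**3)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------


def fit_power_decay(distances, values, fit_range: tuple[float, float] | None = None) -> DecayFit:
    """OLS power-law fit: slope of log10 |v| against log10 r.

    ``fit_range`` restricts to distances in [lo, hi]. Values must be
    single-signed (zeros excluded); mixed signs indicate the quantity
    changes sign over the range and cannot be log-fit directly.
    """
    r = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    if r.shape != v.shape:
        raise ValueError("distances and values must have the same length")
    keep = r > 0
    if fit_range is not None:
        lo, hi = fit_range
        keep &= (r >= lo) & (r <= hi)
    r, v = r[keep], v[keep]
    nz = v != 0
    r, v = r[nz], v[nz]
    if v.size and np.any(v > 0) and np.any(v < 0):
        raise ValueError(
            "values change sign over the fit range; take magnitudes or restrict fit_range"
        )
    if r.size < 3:
        raise ValueError("need at least 3 positive (distance, value) pairs after filtering")
    x = np.log10(r)
    y = np.log10(np.abs(v))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - np.sum(resid**2) / ss_tot)
    return DecayFit(exponent=float(slope), intercept=float(intercept),
                    r_squared=float(min(r2, 1.0)), n_points=int(r.size))
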