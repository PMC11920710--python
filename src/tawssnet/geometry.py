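"""Idealized 3D left-coronary bifurcation surfaces and structured point clouds.

The geometry is the smooth union of three constant-diameter tubes: a straight
left main (LM) segment ending at the origin, and two daughter branches (LAD,
LCx) leaving the origin along in-plane circular arcs.  The bifurcation lies in
the z = 0 plane; the LM axis is +x.  The surface is the zero level set of a
smooth-min blend of the three tube signed-distance fields, sampled on a
structured (axial station x circumferential angle) grid of fixed size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .morphology import MorphologyParams

__all__ = [
    "GeometryError",
    "GeometryConfig",
    "Centerline",
    "SurfacePointCloud",
    "build_centerlines",
    "sample_surface",
    "blended_distance",
]

VESSELS = ("LM", "LAD", "LCX")
#: integer codes for per-point vessel labels (stored in PLY files)
VESSEL_CODES = {"LM": 0, "LAD": 1, "LCX": 2, "JUNCTION": 3}
VESSEL_NAMES = {v: k for k, v in VESSEL_CODES.items()}


class GeometryError(ValueError):
    """Raised for degenerate or self-folding geometric configurations."""


@dataclass(frozen=True)
class GeometryConfig:
    """Construction parameters for the idealized bifurcation.

    Lengths are expressed as multiples of vessel diameters so that the
    geometry scales with the morphology: LM length ``lm_len_factor * d_lm``,
    daughter lengths ``daughter_len_factor * max(d_lad, d_lcx)``.  Daughters
    follow circular arcs of radius ``arc_radius`` mm (``inf`` = straight
    rays).  ``blend_k_factor * d_lm`` is the smooth-min blending length at
    the junction.
    """

    lm_len_factor: float = 8.0
    daughter_len_factor: float = 10.0
    arc_radius: float = 20.0
    #: cap on the total heading change of a daughter arc; long daughters get a
    #: proportionally larger effective radius so they never hook back over the LM
    max_arc_turn_deg: float = 60.0
    centerline_samples: int = 64
    blend_k_factor: float = 0.4
    fold_threshold_deg: float = 30.0
    row_quota: tuple[float, float, float] = (0.25, 0.375, 0.375)
    check_self_intersection: bool = False
    self_intersection_tol: float = 0.05  # mm, for the optional global check


@dataclass
class Centerline:
    """Polyline centerline of one vessel with tangents and radius."""

    vessel: str
    points: np.ndarray  # (S, 3) mm
    tangents: np.ndarray  # (S, 3) unit
    arclength: np.ndarray  # (S,) mm, strictly increasing from 0
    radius: float  # tube radius, mm

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise GeometryError(f"{self.vessel}: centerline needs >= 2 points")
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError(f"{self.vessel}: tangents not unit-norm")
        if np.any(np.diff(self.arclength) <= 0):
            raise GeometryError(f"{self.vessel}: arclength not increasing")

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of the polyline at arclength ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self.arclength, self.points[:, k])
        return out

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        for k in range(3):
            out[:, k] = np.interp(s, self.arclength, self.tangents[:, k])
        n = np.linalg.norm(out, axis=1, keepdims=True)
        return out / n

    def distance(self, pts: np.ndarray) -> np.ndarray:
        """Exact distance from each point to the polyline (min over segments)."""
        a = self.points[:-1]  # (J, 3)
        ab = self.points[1:] - a  # (J, 3)
        denom = np.einsum("jk,jk->j", ab, ab)  # (J,)
        ap = pts[:, None, :] - a[None, :, :]  # (N, J, 3)
        t = np.einsum("njk,jk->nj", ap, ab) / denom
        np.clip(t, 0.0, 1.0, out=t)
        closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("njk->nj", (pts[:, None, :] - closest) ** 2)
        return np.sqrt(d2.min(axis=1))


@dataclass
class SurfacePointCloud:
    """Fixed-size structured surface sample of one bifurcation model."""

    coords: np.ndarray  # (N, 3) mm
    vessel_label: np.ndarray  # (N,) int codes per VESSEL_CODES
    station_index: np.ndarray  # (N,) axial row index
    circ_angle: np.ndarray  # (N,) radians in [0, 2*pi)
    model_id: str = ""
    rows: int = 0
    cols: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite surface coordinates")

    @property
    def n_points(self) -> int:
        return len(self.coords)


def _daughter_headings(params: MorphologyParams) -> tuple[float, float]:
    """In-plane heading angles (rad, CCW from +x) of the LAD and LCx."""
    theta_lad = math.radians(180.0 - params.gamma)  # deviation from straight
    phi_lad = -theta_lad  # LAD on the y < 0 side
    phi_lcx = phi_lad + math.radians(params.alpha)  # opens toward y > 0
    return phi_lad, phi_lcx


def _arc_polyline(
    phi0: float, length: float, radius: float, turn_sign: float, samples: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """In-plane (z=0) circular-arc polyline from the origin.

    Starts at the origin with heading ``phi0`` and constant curvature
    ``turn_sign / radius`` (``radius = inf`` gives a straight ray).
    """
    s = np.linspace(0.0, length, samples + 1)
    if not math.isfinite(radius):
        phi = np.full_like(s, phi0)
        x = s * math.cos(phi0)
        y = s * math.sin(phi0)
    else:
        phi = phi0 + turn_sign * s / radius
        # integral of (cos phi, sin phi) ds for constant curvature
        x = (np.sin(phi) - math.sin(phi0)) * radius * turn_sign
        y = -(np.cos(phi) - math.cos(phi0)) * radius * turn_sign
    pts = np.column_stack([x, y, np.zeros_like(s)])
    tans = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(s)])
    return pts, tans, s


def build_centerlines(
    params: MorphologyParams, cfg: GeometryConfig = GeometryConfig()
) -> dict[str, Centerline]:
    """Construct LM/LAD/LCx centerlines from one morphology.

    LM is a straight segment ending at the origin with tangent +x.  The LAD
    initial tangent makes an angle of (180 deg - gamma) with +x; the LCx
    initial tangent opens a further alpha degrees from the LAD, on the
    opposite side.  Daughters follow in-plane arcs of radius
    ``cfg.arc_radius`` bending away from each other.
    """
    phi_lad, phi_lcx = _daughter_headings(params)
    # angle between the LCx heading and the upstream (-x) direction
    included = 180.0 - abs(math.degrees(phi_lcx))
    if included < cfg.fold_threshold_deg:
        raise GeometryError(
            f"LCx heading {math.degrees(phi_lcx):.1f} deg folds back onto the LM "
            f"(included angle {included:.1f} < {cfg.fold_threshold_deg} deg)"
        )

    lm_len = cfg.lm_len_factor * params.d_lm
    d_len = cfg.daughter_len_factor * max(params.d_lad, params.d_lcx)
    m = cfg.centerline_samples

    lm_pts = np.array([[-lm_len, 0.0, 0.0], [0.0, 0.0, 0.0]])
    lm = Centerline(
        vessel="LM",
        points=lm_pts,
        tangents=np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        arclength=np.array([0.0, lm_len]),
        radius=params.d_lm / 2.0,
    )
    radius = cfg.arc_radius
    if math.isfinite(radius) and cfg.max_arc_turn_deg > 0:
        radius = max(radius, d_len / math.radians(cfg.max_arc_turn_deg))
    lad_pts, lad_tan, lad_s = _arc_polyline(phi_lad, d_len, radius, -1.0, m)
    lcx_pts, lcx_tan, lcx_s = _arc_polyline(phi_lcx, d_len, radius, +1.0, m)
    lad = Centerline("LAD", lad_pts, lad_tan, lad_s, params.d_lad / 2.0)
    lcx = Centerline("LCX", lcx_pts, lcx_tan, lcx_s, params.d_lcx / 2.0)
    return {"LM": lm, "LAD": lad, "LCX": lcx}


def blended_distance(
    pts: np.ndarray, centerlines: Mapping[str, Centerline], k: float
) -> np.ndarray:
    """Smooth-min union field F(p); F = 0 is the blended surface.

    F is the exponential smooth minimum of the three tube signed distances
    d_v(p) = dist(p, centerline_v) - r_v with blending length ``k``.
    """
    d = np.stack(
        [c.distance(pts) - c.radius for c in centerlines.values()], axis=0
    )  # (3, N)
    dmin = d.min(axis=0)
    # shift-stabilized logsumexp
    w = np.exp(-(d - dmin) / k)
    return dmin - k * np.log(w.sum(axis=0))


def _row_allocation(rows: int, quota: tuple[float, float, float]) -> tuple[int, int, int]:
    raw = np.array(quota) * rows
    alloc = np.floor(raw).astype(int)
    # distribute the remainder by largest fractional part
    for idx in np.argsort(raw - alloc)[::-1][: rows - alloc.sum()]:
        alloc[idx] += 1
    return int(alloc[0]), int(alloc[1]), int(alloc[2])


def sample_surface(
    centerlines: Mapping[str, Centerline],
    params: MorphologyParams,
    grid_rows: int = 64,
    grid_cols: int = 64,
    cfg: GeometryConfig = GeometryConfig(),
) -> SurfacePointCloud:
    """Sample the blended surface on a structured rows x cols grid.

    Rows are axial stations allocated across LM/LAD/LCx by ``cfg.row_quota``
    (station centers along each vessel's arclength); columns are equispaced
    circumferential angles measured from the bifurcation-plane normal (+z).
    Each grid point is obtained by radial projection from its centerline
    station onto the zero level set of the blended distance field, found by
    bisection to machine-level residual.
    """
    k = cfg.blend_k_factor * params.d_lm
    n_lm, n_lad, n_lcx = _row_allocation(grid_rows, cfg.row_quota)

    stations: list[tuple[str, np.ndarray, np.ndarray]] = []
    for vessel, n_rows in (("LM", n_lm), ("LAD", n_lad), ("LCX", n_lcx)):
        c = centerlines[vessel]
        total = c.arclength[-1]
        s = (np.arange(n_rows) + 0.5) / n_rows * total
        stations.append((vessel, c.point_at(s), c.tangent_at(s)))

    centers = np.concatenate([p for _, p, _ in stations], axis=0)  # (rows, 3)
    tangents = np.concatenate([t for _, _, t in stations], axis=0)
    radii = np.concatenate(
        [np.full(n, centerlines[v].radius) for (v, _, _), n in zip(stations, (n_lm, n_lad, n_lcx))]
    )

    phis = 2.0 * np.pi * np.arange(grid_cols) / grid_cols
    z_hat = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(np.broadcast_to(z_hat, tangents.shape), tangents)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)

    # radial directions: (rows, cols, 3)
    dirs = (
        np.cos(phis)[None, :, None] * z_hat[None, None, :]
        + np.sin(phis)[None, :, None] * e2[:, None, :]
    )
    origin = np.repeat(centers, grid_cols, axis=0)  # (N, 3)
    dirs_flat = dirs.reshape(-1, 3)
    n_pts = len(origin)

    lo = np.zeros(n_pts)
    hi = np.repeat(radii, grid_cols) + 6.0 * k
    for _ in range(12):  # expand until strictly outside
        f_hi = blended_distance(origin + hi[:, None] * dirs_flat, centerlines, k)
        inside = f_hi <= 0
        if not inside.any():
            break
        hi[inside] *= 1.5
    else:
        raise GeometryError("failed to bracket the surface along radial rays")

    for _ in range(52):
        mid = 0.5 * (lo + hi)
        f = blended_distance(origin + mid[:, None] * dirs_flat, centerlines, k)
        neg = f < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    rho = 0.5 * (lo + hi)
    coords = origin + rho[:, None] * dirs_flat

    # labels: own vessel, or JUNCTION inside the blend zone
    d = np.stack([c.distance(coords) - c.radius for c in centerlines.values()])
    order = np.sort(d, axis=0)
    own = np.argmin(d, axis=0)
    labels = np.array([VESSEL_CODES[v] for v in centerlines.keys()])[own]
    junction = (order[1] - order[0]) < 3.0 * k
    labels[junction] = VESSEL_CODES["JUNCTION"]

    station_index = np.repeat(np.arange(grid_rows), grid_cols)
    circ_angle = np.tile(phis, grid_rows)

    cloud = SurfacePointCloud(
        coords=coords,
        vessel_label=labels,
        station_index=station_index,
        circ_angle=circ_angle,
        model_id=params.model_id,
        rows=grid_rows,
        cols=grid_cols,
    )
    if cfg.check_self_intersection:
        _check_self_intersection(cloud, dirs_flat, cfg)
    return cloud


def _check_self_intersection(
    cloud: SurfacePointCloud, normals: np.ndarray, cfg: GeometryConfig
) -> None:
    """Flag pairs of near-coincident points with opposing outward normals."""
    tree = cKDTree(cloud.coords)
    pairs = tree.query_pairs(cfg.self_intersection_tol, output_type="ndarray")
    if len(pairs) == 0:
        return
    i, j = pairs[:, 0], pairs[:, 1]
    non_adjacent = np.abs(cloud.station_index[i] - cloud.station_index[j]) > 1
    opposing = np.einsum("nk,nk->n", normals[i], normals[j]) < -0.5
    bad = non_adjacent & opposing
    if bad.any():
        raise GeometryError(
            f"self-intersection: {bad.sum()} opposing-normal point pairs closer "
            f"than {cfg.self_intersection_tol} mm"
        )


def apply_pose(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Rigid motion p -> R p + t applied row-wise."""
    return coords @ np.asarray(rotation).T + np.asarray(translation)
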