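"""Analytic pulsatile wall-shear surrogate used to label the synthetic dataset.

This module stands in for a transient CFD solve.  Each surface point receives
an instantaneous wall shear stress built from the Poiseuille wall shear rate
of its owning vessel (gamma_dot = 32 Q / (pi D^3)), the Carreau-Yasuda
shear-thinning viscosity of blood, and smooth spatial modulators that emulate
the hemodynamic features of a bifurcation: elevated shear at the flow divider
(apex), reduced shear on the lateral walls, and a front/back circumferential
asymmetry.  Time averaging of |WSS| over one cardiac cycle yields TAWSS.

The field is a declared synthetic construct: it reproduces the magnitude and
spatial character of bifurcation TAWSS, not the solution of the Navier-Stokes
equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .geometry import (
    Centerline,
    GeometryConfig,
    SurfacePointCloud,
    _daughter_headings,
    build_centerlines,
    sample_surface,
    apply_pose,
)
from .morphology import MorphologyParams, SplitManifest
from .ply import write_cloud_ply

__all__ = [
    "ViscosityParams",
    "FlowState",
    "TawssField",
    "ModulatorConfig",
    "SurrogateConfig",
    "BLOOD_CARREAU_YASUDA",
    "carreau_yasuda_viscosity",
    "murray_flow_split",
    "two_lobe_waveform",
    "default_flow_state",
    "wall_shear_series",
    "tawss",
    "generate_dataset",
]


class DomainError(ValueError):
    """Raised for physically inadmissible inputs (negative shear, zero diameter...)."""


@dataclass(frozen=True)
class ViscosityParams:
    """Carreau-Yasuda constants: mu(gd) = (mu0-mu_inf)[1+(lambda*gd)^a]^((m-1)/a) + mu_inf."""

    mu_inf: float = 0.0035  # Pa.s, infinite-shear viscosity
    mu_0: float = 0.056  # Pa.s, zero-shear viscosity
    lambda_cy: float = 1.902  # s, relaxation time
    m: float = 0.22  # power-law index
    a: float = 1.25  # Yasuda exponent

    def __post_init__(self) -> None:
        if not self.mu_0 > self.mu_inf > 0:
            raise DomainError("require mu_0 > mu_inf > 0")
        if self.lambda_cy <= 0 or self.a <= 0:
            raise DomainError("lambda_cy and a must be positive")


#: Literature constants for healthy blood.
BLOOD_CARREAU_YASUDA = ViscosityParams()


def carreau_yasuda_viscosity(
    gamma_dot: float | np.ndarray, vp: ViscosityParams = BLOOD_CARREAU_YASUDA
) -> float | np.ndarray:
    """Shear-thinning dynamic viscosity (Pa.s) at shear rate ``gamma_dot`` (1/s)."""
    gd = np.asarray(gamma_dot, dtype=float)
    if np.any(gd < 0):
        raise DomainError("shear rate must be nonnegative")
    mu = (vp.mu_0 - vp.mu_inf) * (1.0 + (vp.lambda_cy * gd) ** vp.a) ** (
        (vp.m - 1.0) / vp.a
    ) + vp.mu_inf
    return float(mu) if np.isscalar(gamma_dot) else mu


def murray_flow_split(d_lad: float, d_lcx: float) -> dict[str, float]:
    """Cube-law (Murray) apportioning of the LM flow between the daughters."""
    if d_lad <= 0 or d_lcx <= 0:
        raise DomainError("daughter diameters must be positive")
    c3 = d_lad**3 + d_lcx**3
    return {"LAD": d_lad**3 / c3, "LCX": d_lcx**3 / c3}


def two_lobe_waveform(
    systole_frac: float = 0.35, systole_amp: float = 0.55
) -> Callable[[np.ndarray], np.ndarray]:
    """Normalized two-lobe raised-cosine coronary flow waveform, w(t/T).

    A smaller systolic lobe on [0, systole_frac) and a dominant diastolic
    lobe on [systole_frac, 1) (left-coronary flow is diastolic-dominant).
    The returned callable takes the cycle fraction t/T in [0, 1] and has
    exact cycle mean 1 (raised-cosine lobes integrate to half their support).
    """
    f, amp = systole_frac, systole_amp
    mean_raw = 0.5 * (amp * f + 1.0 * (1.0 - f))
    scale = 1.0 / mean_raw

    def w(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float) % 1.0
        sys_lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * u / f))
        dia_lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * (u - f) / (1.0 - f)))
        return scale * np.where(u < f, amp * sys_lobe, dia_lobe)

    return w


@dataclass
class FlowState:
    """Pulsatile inflow of one model: mean LM flow, waveform and branch split."""

    q_mean_lm: float  # mm^3/s
    period: float = 0.8  # s
    waveform: Callable[[np.ndarray], np.ndarray] = field(default_factory=two_lobe_waveform)
    q_fractions: dict[str, float] = field(default_factory=lambda: {"LAD": 0.5, "LCX": 0.5})

    def __post_init__(self) -> None:
        s = sum(self.q_fractions.values())
        if abs(s - 1.0) > 1e-12:
            raise DomainError(f"branch flow fractions sum to {s}, expected 1")
        if not all(0.0 < v < 1.0 for v in self.q_fractions.values()):
            raise DomainError("branch flow fractions must lie in (0, 1)")

    def q_of(self, vessel: str, t: np.ndarray) -> np.ndarray:
        """Instantaneous volumetric flow (mm^3/s) in ``vessel`` at times ``t`` (s)."""
        frac = 1.0 if vessel == "LM" else self.q_fractions[vessel]
        return self.q_mean_lm * frac * self.waveform(np.asarray(t) / self.period)


@dataclass
class TawssField:
    """Per-point time-averaged wall shear stress aligned to one cloud."""

    values: np.ndarray  # (N,) Pa
    model_id: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise DomainError("TAWSS values must be positive and finite")


@dataclass(frozen=True)
class ModulatorConfig:
    """Spatial modulation of the base Poiseuille shear.

    ``apex_amp``/``apex_sigma_factor``: Gaussian amplification around the
    flow divider (sigma = factor * d_lm).  ``lateral_amp``/``lateral_sigma_factor``:
    Gaussian reduction around the two lateral wall centers.
    ``front_back_ratio``: target ratio of mean front-half to mean back-half
    TAWSS on a pure tube; implemented as 1 + A_c cos(phi) with
    A_c = (pi/2) (r-1)/(r+1) so the half-circumference means realize the
    ratio exactly.  ``alpha_gain`` optionally scales the apex amplification
    linearly with the opening angle alpha (0 disables).
    """

    enabled: bool = True
    apex_amp: float = 1.0
    apex_sigma_factor: float = 0.5
    lateral_amp: float = 0.4
    lateral_sigma_factor: float = 1.0
    front_back_ratio: float = 1.25
    alpha_gain: float = 0.0

    @property
    def circ_amp(self) -> float:
        r = self.front_back_ratio
        return (math.pi / 2.0) * (r - 1.0) / (r + 1.0)


#: Default mean LM inlet velocity (mm/s), calibrated once so that pooled
#: surrogate TAWSS over the admissible morphology space spans physiological
#: coronary magnitudes: 5th-95th percentile within [2, 20] Pa, bulk around
#: 5-15 Pa (100-model calibration run; see docs/methods.md).
DEFAULT_MEAN_VELOCITY = 800.0


def default_flow_state(params: MorphologyParams, mean_velocity: float = DEFAULT_MEAN_VELOCITY) -> FlowState:
    """Flow state with Q_LM from a mean inlet velocity and a Murray branch split."""
    q_mean = mean_velocity * math.pi * params.d_lm**2 / 4.0
    return FlowState(q_mean_lm=q_mean, q_fractions=murray_flow_split(params.d_lad, params.d_lcx))


def _modulators(
    cloud: SurfacePointCloud,
    params: MorphologyParams,
    cfg: ModulatorConfig,
) -> np.ndarray:
    """Time-independent per-point modulation factor (canonical frame)."""
    if not cfg.enabled:
        return np.ones(cloud.n_points)
    p = cloud.coords
    # flow divider (carina): on the bisector of the daughter take-off
    # directions, one mean radius out from the centerline meeting point
    phi_lad, phi_lcx = _daughter_headings(params)
    bis = 0.5 * (phi_lad + phi_lcx)
    r_mean = 0.25 * (params.d_lad + params.d_lcx)
    apex = r_mean * np.array([math.cos(bis), math.sin(bis), 0.0])
    sigma_a = cfg.apex_sigma_factor * params.d_lm
    d_apex2 = np.einsum("nk,nk->n", p - apex, p - apex)
    apex_amp = cfg.apex_amp
    if cfg.alpha_gain != 0.0:
        # wider openings concentrate stagnation-point shear at the divider
        apex_amp = apex_amp * (1.0 + cfg.alpha_gain * (params.alpha - 15.0) / 115.0)
    mod = 1.0 + apex_amp * np.exp(-d_apex2 / (2.0 * sigma_a**2))

    # lateral (outer) walls: perpendicular to the carina bisector, in plane
    sigma_l = cfg.lateral_sigma_factor * params.d_lm
    perp = np.array([-math.sin(bis), math.cos(bis), 0.0])
    lat = 0.75 * params.d_lm * np.stack([perp, -perp])
    d_lat2 = np.minimum(
        np.einsum("nk,nk->n", p - lat[0], p - lat[0]),
        np.einsum("nk,nk->n", p - lat[1], p - lat[1]),
    )
    mod *= 1.0 - cfg.lateral_amp * np.exp(-d_lat2 / (2.0 * sigma_l**2))
    mod *= 1.0 + cfg.circ_amp * np.cos(cloud.circ_angle)
    return mod


def wall_shear_series(
    cloud: SurfacePointCloud,
    params: MorphologyParams,
    flow: FlowState,
    vp: ViscosityParams = BLOOD_CARREAU_YASUDA,
    mod_cfg: ModulatorConfig = ModulatorConfig(),
    t_grid: np.ndarray | None = None,
    centerlines: Mapping[str, Centerline] | None = None,
    geometry_cfg: GeometryConfig = GeometryConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous wall shear stress tau(p, t) (Pa) for every cloud point.

    The base stress of vessel v is mu(gd_v(t)) * gd_v(t) with the Poiseuille
    wall shear rate gd_v(t) = 32 Q_v(t) / (pi D_v^3).  Per-point values blend
    the three vessel stresses with soft weights exp(-|tube distance| / k)
    (continuous across the junction) and are scaled by the spatial
    modulators.  Returns ``(wss, t_grid)`` with ``wss`` shaped (N, len(t_grid)).
    """
    diam = {"LM": params.d_lm, "LAD": params.d_lad, "LCX": params.d_lcx}
    if min(diam.values()) <= 0:
        raise DomainError("vessel diameters must be positive")
    if t_grid is None:
        t_grid = np.linspace(0.0, flow.period, 64)
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) < 16 or abs(t_grid[0]) > 1e-12 or abs(t_grid[-1] - flow.period) > 1e-9:
        raise DomainError("t_grid must span exactly one period with >= 16 samples")

    tau_v = np.empty((3, len(t_grid)))
    for i, v in enumerate(("LM", "LAD", "LCX")):
        q = flow.q_of(v, t_grid)
        gd = 32.0 * q / (math.pi * diam[v] ** 3)
        tau_v[i] = carreau_yasuda_viscosity(gd, vp) * gd

    if centerlines is None:
        centerlines = build_centerlines(params, geometry_cfg)
    k = geometry_cfg.blend_k_factor * params.d_lm
    d = np.stack(
        [np.abs(centerlines[v].distance(cloud.coords) - centerlines[v].radius) for v in ("LM", "LAD", "LCX")]
    )  # (3, N)
    d -= d.min(axis=0, keepdims=True)
    w = np.exp(-np.minimum(d / k, 30.0))
    w[d / k > 12.0] = 0.0  # exact single-vessel stress far from the junction
    w /= w.sum(axis=0, keepdims=True)

    wss = w.T @ tau_v  # (N, Nt)
    wss *= _modulators(cloud, params, mod_cfg)[:, None]
    return wss, t_grid


def tawss(wss_series: np.ndarray, t_grid: np.ndarray, model_id: str = "") -> TawssField:
    """Time average of |WSS| over one cycle (trapezoidal rule)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2:
        raise DomainError("need at least 2 time samples")
    if np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing")
    period = t_grid[-1] - t_grid[0]
    vals = np.trapezoid(np.abs(wss_series), t_grid, axis=-1) / period
    return TawssField(values=vals, model_id=model_id)


@dataclass(frozen=True)
class SurrogateConfig:
    """End-to-end labeling configuration for dataset generation."""

    viscosity: ViscosityParams = BLOOD_CARREAU_YASUDA
    modulators: ModulatorConfig = ModulatorConfig()
    mean_velocity: float = DEFAULT_MEAN_VELOCITY  # mm/s
    period: float = 0.8  # s
    n_time_samples: int = 64
    #: store each model rotated by a random in-plane angle.  Independently
    #: constructed models share no in-plane orientation, but they do share
    #: the bifurcation plane; the front/back-asymmetric shear field makes
    #: the plane normal physically meaningful, so it is kept common.
    random_pose: bool = True


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Random in-plane rotation (about the bifurcation-plane normal)."""
    th = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def label_model(
    params: MorphologyParams,
    geometry_cfg: GeometryConfig = GeometryConfig(),
    surrogate_cfg: SurrogateConfig = SurrogateConfig(),
    grid_rows: int = 64,
    grid_cols: int = 64,
    pose: np.ndarray | None = None,
) -> tuple[SurfacePointCloud, TawssField]:
    """Build, sample and label one model; optionally re-pose the stored cloud."""
    centerlines = build_centerlines(params, geometry_cfg)
    cloud = sample_surface(centerlines, params, grid_rows, grid_cols, geometry_cfg)
    flow = default_flow_state(params, surrogate_cfg.mean_velocity)
    flow = replace(flow, period=surrogate_cfg.period)
    t_grid = np.linspace(0.0, flow.period, surrogate_cfg.n_time_samples)
    wss, t_grid = wall_shear_series(
        cloud,
        params,
        flow,
        surrogate_cfg.viscosity,
        surrogate_cfg.modulators,
        t_grid,
        centerlines=centerlines,
        geometry_cfg=geometry_cfg,
    )
    fld = tawss(wss, t_grid, model_id=params.model_id)
    if pose is not None:
        cloud.coords = apply_pose(cloud.coords, pose, np.zeros(3))
    return cloud, fld


def generate_dataset(
    manifest: SplitManifest,
    geometry_cfg: GeometryConfig = GeometryConfig(),
    surrogate_cfg: SurrogateConfig = SurrogateConfig(),
    out_dir: str | Path = "dataset",
    grid_rows: int = 64,
    grid_cols: int = 64,
    overwrite: bool = False,
) -> SplitManifest:
    """Label every manifest model and write PLY files plus the manifest.

    Updates ``manifest.tawss_global_max/min`` with the extremes over *all*
    generated points (the NAME normalization convention) and saves the
    manifest to ``out_dir/manifest.json``.
    """
    out = Path(out_dir)
    models_dir = out / "models"
    if models_dir.exists() and any(models_dir.iterdir()) and not overwrite:
        raise FileExistsError(f"{models_dir} exists and is non-empty; pass overwrite=True")
    models_dir.mkdir(parents=True, exist_ok=True)

    gmax, gmin = -np.inf, np.inf
    for i, model_id in enumerate(manifest.all_ids):
        params = manifest.morphology(model_id)
        pose = None
        if surrogate_cfg.random_pose:
            pose = _random_rotation(np.random.default_rng([manifest.seed % (2**31), i]))
        cloud, fld = label_model(
            params, geometry_cfg, surrogate_cfg, grid_rows, grid_cols, pose=pose
        )
        write_cloud_ply(models_dir / f"{model_id}.ply", cloud, fld.values)
        gmax = max(gmax, float(fld.values.max()))
        gmin = min(gmin, float(fld.values.min()))

    manifest.tawss_global_max = gmax
    manifest.tawss_global_min = gmin
    manifest.save(out / "manifest.json")
    return manifest
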