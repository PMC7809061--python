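"""Mechanical stimuli: oriented edges indented into or scanned across the skin.

An edge at orientation ``theta`` is a Gaussian ridge on the normalized mesh,

    edge(x, y) = exp(-(x sin(theta) + y cos(theta))^2 / (2 w^2)),

maximal on the line ``x sin(theta) + y cos(theta) = 0`` and falling off with
perpendicular distance; ``w`` (default 0.05 normalized units = 0.3 mm) is the
edge width.  Point indentations use an isotropic 2-D Gaussian force bump.

A trial is rendered as a :class:`StimulusMovie`: one force frame per time
step (dt = 0.1 ms).  Indented edges follow a trapezoidal depth profile
(50 ms on-ramp, 200 ms hold, 50 ms off-ramp); scanned edges ramp into
contact at the patch border and then translate at constant speed
(24 mm/s, 12 mm in 500 ms).  Trial-to-trial variability combines a scalar
depth jitter (1 mm +/- 0.5 mm SD) with a smooth multiplicative modulation of
the contact force ("indentation noise", Ornstein-Uhlenbeck, stated as a
fraction of the nominal amplitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .grid import MM_TO_NORM, MechanoreceptorGrid

#: force -> input-current calibration constant (arbitrary units); fixed once
#: so that on-edge SA-I afferents sustain ~20-60 Hz during the hold phase.
FORCE_AMPLITUDE = 100.0

#: default time step, ms (forward-Euler step used throughout the network)
DT_MS = 0.1


class StimulusError(ValueError):
    """Raised when a requested stimulus cannot be placed on the grid."""


# ---------------------------------------------------------------------------
# spatial templates
# ---------------------------------------------------------------------------


def _edge_values(
    grid: MechanoreceptorGrid,
    theta_deg: float,
    w: float,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    x, y = grid.mesh_norm()
    th = np.deg2rad(theta_deg)
    d = (x - center[0]) * np.sin(th) + (y - center[1]) * np.cos(th)
    return np.exp(-(d**2) / (2.0 * w**2))


@dataclass(frozen=True)
class EdgeTemplate:
    """Per-mechanoreceptor weights of an oriented Gaussian ridge."""

    theta_deg: float
    w: float
    grid: MechanoreceptorGrid
    center: tuple[float, float] = (0.0, 0.0)
    values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def shifted(self, center: tuple[float, float]) -> "EdgeTemplate":
        return edge_template(self.theta_deg, self.w, self.grid, center=center)


def edge_template(
    theta_deg: float,
    w: float = 0.05,
    grid: MechanoreceptorGrid | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> EdgeTemplate:
    """Oriented edge weights on the normalized mesh.

    Parameters
    ----------
    theta_deg:
        Edge orientation in degrees, ``0 <= theta < 180``.
    w:
        Edge width in normalized units (> 0).
    center:
        Normalized (x0, y0) through which the ridge line passes.
    """
    if not (0.0 <= theta_deg < 180.0):
        raise ValueError(f"theta must be in [0, 180); got {theta_deg}")
    if w <= 0:
        raise ValueError("edge width w must be positive")
    grid = grid or MechanoreceptorGrid()
    values = _edge_values(grid, theta_deg, w, center)
    return EdgeTemplate(theta_deg, w, grid, center, values)


@dataclass(frozen=True)
class ForceField:
    """Isotropic Gaussian pressure bump (point indentation)."""

    amplitude: float
    center: tuple[float, float]
    sigma_x: float
    sigma_y: float
    grid: MechanoreceptorGrid
    values: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def gaussian_force(
    amplitude: float,
    center: tuple[float, float] = (0.0, 0.0),
    grid: MechanoreceptorGrid | None = None,
    sigma_x: float = 0.05,
    sigma_y: float = 0.05,
) -> ForceField:
    """Force felt by each mechanoreceptor under a point press of amplitude F."""
    if amplitude < 0:
        raise ValueError("force amplitude must be non-negative")
    grid = grid or MechanoreceptorGrid()
    x, y = grid.mesh_norm()
    values = amplitude * np.exp(
        -(
            (x - center[0]) ** 2 / (2.0 * sigma_x**2)
            + (y - center[1]) ** 2 / (2.0 * sigma_y**2)
        )
    )
    return ForceField(amplitude, center, sigma_x, sigma_y, grid, values)


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndentProfile:
    """Trapezoidal indentation envelope (ms)."""

    ramp_on_ms: float = 50.0
    hold_ms: float = 200.0
    ramp_off_ms: float = 50.0
    depth_mm: float = 1.0

    @property
    def total_ms(self) -> float:
        return self.ramp_on_ms + self.hold_ms + self.ramp_off_ms

    def envelope(self, t_ms: np.ndarray) -> np.ndarray:
        """Piecewise-linear envelope in [0, 1] at times ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        env = np.zeros_like(t)
        if self.ramp_on_ms > 0:
            rising = t < self.ramp_on_ms
            env[rising] = t[rising] / self.ramp_on_ms
        t_off = self.ramp_on_ms + self.hold_ms
        env[(t >= self.ramp_on_ms) & (t < t_off)] = 1.0
        if self.ramp_off_ms > 0:
            falling = (t >= t_off) & (t < self.total_ms)
            env[falling] = 1.0 - (t[falling] - t_off) / self.ramp_off_ms
        return np.clip(env, 0.0, 1.0)


@dataclass(frozen=True)
class ScanTrajectory:
    """Constant-speed translation of the edge across the patch (+y)."""

    speed_mm_s: float = 24.0
    travel_mm: float = 12.0
    ramp_on_ms: float = 50.0  # stationary contact on-ramp before motion

    @property
    def scan_ms(self) -> float:
        return self.travel_mm / self.speed_mm_s * 1000.0

    @property
    def total_ms(self) -> float:
        return self.ramp_on_ms + self.scan_ms

    def offset_mm(self, t_ms: np.ndarray) -> np.ndarray:
        """Edge displacement from its start position, in mm, at times ``t_ms``."""
        t = np.asarray(t_ms, dtype=float)
        moved = np.clip(t - self.ramp_on_ms, 0.0, self.scan_ms)
        return moved * self.speed_mm_s / 1000.0


@dataclass(frozen=True)
class TrialNoiseSpec:
    """Trial-to-trial stimulus variability.

    ``depth_jitter_mean_mm`` / ``depth_jitter_sd_mm`` describe the indentation
    depth distribution (force scales linearly with depth relative to the
    nominal 1 mm).  ``indentation_noise_frac`` is the SD of a smooth
    multiplicative force modulation (OU process, correlation time
    ``noise_tau_ms``) emulating micro-variations in contact during the trial.
    """

    depth_jitter_mean_mm: float = 1.0
    depth_jitter_sd_mm: float = 0.5
    indentation_noise_frac: float = 0.0
    noise_tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.indentation_noise_frac < 0:
            raise ValueError("noise fraction must be >= 0")

    def depth_factor(self, rng: np.random.Generator, nominal_mm: float = 1.0) -> float:
        if self.depth_jitter_sd_mm == 0 and self.depth_jitter_mean_mm == nominal_mm:
            return 1.0
        depth = rng.normal(self.depth_jitter_mean_mm, self.depth_jitter_sd_mm)
        return max(depth, 0.1 * nominal_mm) / nominal_mm

    def amplitude_modulation(self, n_steps: int, dt: float, rng: np.random.Generator) -> np.ndarray:
        """Multiplicative gain trace (1 + OU noise), clipped at 0."""
        if self.indentation_noise_frac == 0:
            return np.ones(n_steps)
        sd = self.indentation_noise_frac
        tau = max(self.noise_tau_ms, dt)
        alpha = dt / tau
        eta = np.empty(n_steps)
        eta[0] = rng.normal(0.0, sd)
        innov = rng.normal(0.0, sd * np.sqrt(2.0 * alpha), size=n_steps - 1)
        decay = 1.0 - alpha
        for i in range(1, n_steps):
            eta[i] = eta[i - 1] * decay + innov[i - 1]
        return np.clip(1.0 + eta, 0.0, None)


#: noiseless trial (no depth jitter, no indentation noise)
NOISELESS = TrialNoiseSpec(depth_jitter_mean_mm=1.0, depth_jitter_sd_mm=0.0,
                           indentation_noise_frac=0.0)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


@dataclass
class StimulusMovie:
    """Per-time-step force on every mechanoreceptor.

    ``frames`` has shape (n_steps, n_sites), float32, all values >= 0.
    """

    dt_ms: float
    frames: np.ndarray
    grid: MechanoreceptorGrid
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt_ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt_ms


def _check_on_grid(values: np.ndarray) -> None:
    if float(values.max(initial=0.0)) < 1e-3:
        raise StimulusError("stimulus placed fully off the mechanoreceptor grid")


def make_indent_movie(
    template: EdgeTemplate,
    profile: IndentProfile = IndentProfile(),
    location_offset_mm: float | tuple[float, float] = 0.0,
    noise: TrialNoiseSpec = NOISELESS,
    dt_ms: float = DT_MS,
    amplitude: float = FORCE_AMPLITUDE,
    rng: np.random.Generator | int | None = None,
    duration_ms: float | None = None,
) -> StimulusMovie:
    """Render an edge indentation trial.

    ``location_offset_mm`` shifts the edge on the skin: a scalar is a y-axis
    offset in mm, a tuple gives (dx, dy).  Depth jitter and the indentation
    noise trace are drawn once per trial from ``rng``.  ``duration_ms`` caps
    the rendered length (analyses windowed to [0, T] only need the first
    T ms of frames).
    """
    rng = np.random.default_rng(rng)
    if np.isscalar(location_offset_mm):
        offset = (0.0, float(location_offset_mm))
    else:
        offset = tuple(location_offset_mm)  # type: ignore[assignment]
    center = (offset[0] * MM_TO_NORM, offset[1] * MM_TO_NORM)
    shifted = template.shifted(center) if center != (0.0, 0.0) else template
    _check_on_grid(shifted.values)

    total = profile.total_ms if duration_ms is None else min(duration_ms, profile.total_ms)
    n_steps = int(round(total / dt_ms))
    t = np.arange(n_steps) * dt_ms
    scale = amplitude * noise.depth_factor(rng, profile.depth_mm) * profile.envelope(t)
    scale = scale * noise.amplitude_modulation(n_steps, dt_ms, rng)
    frames = (scale[:, None] * shifted.values[None, :]).astype(np.float32)
    np.clip(frames, 0.0, None, out=frames)
    meta = {
        "kind": "indent",
        "theta_deg": template.theta_deg,
        "w": template.w,
        "offset_mm": offset,
        "profile": (profile.ramp_on_ms, profile.hold_ms, profile.ramp_off_ms),
        "amplitude": amplitude,
    }
    return StimulusMovie(dt_ms, frames, template.grid, meta)


def make_scan_movie(
    template: EdgeTemplate,
    traj: ScanTrajectory = ScanTrajectory(),
    noise: TrialNoiseSpec = NOISELESS,
    dt_ms: float = DT_MS,
    amplitude: float = FORCE_AMPLITUDE,
    rng: np.random.Generator | int | None = None,
) -> StimulusMovie:
    """Render a scanned-edge trial.

    The edge makes contact at the bottom border of the patch, force ramps up
    over ``traj.ramp_on_ms`` while the edge is stationary, then the edge
    translates in +y at ``traj.speed_mm_s`` until it has covered
    ``traj.travel_mm``.  Contact force is held constant during the scan.
    """
    rng = np.random.default_rng(rng)
    grid = template.grid
    x, y = grid.mesh_norm()
    th = np.deg2rad(template.theta_deg)
    if abs(np.cos(th)) < 1e-9:
        raise StimulusError("a vertical edge does not move under a +y scan")

    n_steps = int(round(traj.total_ms / dt_ms))
    t = np.arange(n_steps) * dt_ms
    # line passes through (0, c(t)): starts at the bottom border c=-1
    c = -1.0 + traj.offset_mm(t) * MM_TO_NORM
    d0 = x * np.sin(th) + y * np.cos(th)  # (n_sites,)
    arg = d0[None, :] - (c * np.cos(th))[:, None]
    frames = np.exp(-(arg.astype(np.float32) ** 2) / np.float32(2.0 * template.w**2))

    env = np.minimum(t / traj.ramp_on_ms, 1.0) if traj.ramp_on_ms > 0 else np.ones(n_steps)
    scale = amplitude * noise.depth_factor(rng) * env
    scale = scale * noise.amplitude_modulation(n_steps, dt_ms, rng)
    frames *= scale[:, None].astype(np.float32)
    np.clip(frames, 0.0, None, out=frames)
    meta = {
        "kind": "scan",
        "theta_deg": template.theta_deg,
        "w": template.w,
        "speed_mm_s": traj.speed_mm_s,
        "ramp_on_ms": traj.ramp_on_ms,
        "amplitude": amplitude,
    }
    return StimulusMovie(dt_ms, frames, grid, meta)
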