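"""Synthetic activation patterns on a square tissue patch.

Dense ground-truth first-activation fields for the four canonical
propagation patterns used to validate the mapping pipeline:

- ``plane``: a planar wavefront crossing the patch at constant speed;
- ``focal_homogeneous``: centrifugal activation from a point source in
  uniform tissue (radial cone, t = ||x - s|| / c);
- ``focal_heterogeneous``: centrifugal activation through 8 angular
  sectors around the source with independently drawn sector speeds,
  solved as a first-arrival (eikonal) problem;
- ``collision``: two opposing planar wavefronts meeting mid-patch
  (pointwise minimum of the two arrival times).

Defaults reproduce the reference study conditions: a 4 x 4 cm patch
down-sampled to a 200 x 200 grid (0.2 mm/cell), speeds of 60.4, 54.6
and 55.8 cm/s for the homogeneous patterns, sector speeds drawn from
Normal(60, 13) cm/s truncated at 20 cm/s so the realized heterogeneous
field has ~59.9 +/- 12.5 cm/s, and an activation cycle length of
150 ms.  Activation times are quantized to 1 ms by default, emulating
activation detection on 1 kHz-sampled electrograms; set
``time_quantum=0`` for ideal continuous fields.

The corruption models used by the robustness experiments live here
too: uniform activation-time jitter (its amplitude eps is the full
width of the distribution, expressed as a fraction of the cycle
length) and random removal of mapping sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import truncnorm

from .catheter import CatheterLayout, place_layout
from .eikonal import fast_march
from .fields import MM_PER_MS_TO_CM_PER_S
from .rbf import MultisiteRecording

__all__ = [
    "HeterogeneityConfig",
    "PatternConfig",
    "ActivationField",
    "PATTERNS",
    "simulate_activation_field",
    "sample_multisite",
    "add_jitter",
    "remove_sites",
]

PATTERNS = ("plane", "focal_homogeneous", "focal_heterogeneous", "collision")

#: reference speeds (cm/s) per pattern
DEFAULT_SPEEDS = {
    "plane": 60.4,
    "focal_homogeneous": 54.6,
    "focal_heterogeneous": 60.0,
    "collision": 55.8,
}


@dataclass(frozen=True)
class HeterogeneityConfig:
    """Sector-speed model for heterogeneous focal conduction.

    ``n_regions`` equal angular sectors around the source; per-sector
    speeds drawn from Normal(cv_mean, cv_sd) cm/s truncated below at
    cv_min (re-drawn, not clipped).
    """

    n_regions: int = 8
    cv_mean: float = 60.0
    cv_sd: float = 13.0
    cv_min: float = 20.0


@dataclass(frozen=True)
class PatternConfig:
    """Full specification of one synthetic activation pattern."""

    pattern: str
    patch_size: float = 40.0  # mm
    grid_n: int = 200
    speed: float | None = None  # cm/s; pattern default if None
    heterogeneity: HeterogeneityConfig = field(default_factory=HeterogeneityConfig)
    source_position: tuple[float, float] | None = None  # mm; patch center if None
    wave_direction: tuple[float, float] = (1.0, 0.0)
    cycle_length: float = 150.0  # ms
    time_quantum: float = 1.0  # ms; 0 -> ideal continuous times
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.grid_n < 50:
            raise ValueError("grid_n must be at least 50")
        if self.speed is not None and self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.time_quantum < 0:
            raise ValueError("time_quantum must be non-negative")
        src = self.resolved_source
        if self.pattern.startswith("focal"):
            if not (0 < src[0] < self.patch_size and 0 < src[1] < self.patch_size):
                raise ValueError("source must lie inside the patch")

    @property
    def resolved_speed(self) -> float:
        return DEFAULT_SPEEDS[self.pattern] if self.speed is None else self.speed

    @property
    def resolved_source(self) -> tuple[float, float]:
        if self.source_position is None:
            return (self.patch_size / 2, self.patch_size / 2)
        return tuple(float(v) for v in self.source_position)



@dataclass
class ActivationField:
    """Dense ground truth: activation times + true CV vectors on the grid.

    x, y : (grid_n,) cell-center coordinates, mm; grid_times : (ny, nx)
    first-activation times, ms; true_vx/true_vy : CV vectors, cm/s.
    """

    x: np.ndarray
    y: np.ndarray
    grid_times: np.ndarray
    true_vx: np.ndarray
    true_vy: np.ndarray
    true_source: tuple[float, float] | None
    config: PatternConfig

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def true_speed(self) -> np.ndarray:
        return np.hypot(self.true_vx, self.true_vy)


def _cell_centers(cfg: PatternConfig) -> tuple[np.ndarray, np.ndarray]:
    h = cfg.patch_size / cfg.grid_n
    c = (np.arange(cfg.grid_n) + 0.5) * h
    return c, c


def _sector_speed_map(cfg: PatternConfig, xx, yy) -> np.ndarray:
    het = cfg.heterogeneity
    rng = np.random.default_rng(cfg.seed)
    a, b = (het.cv_min - het.cv_mean) / het.cv_sd, np.inf
    speeds = truncnorm.rvs(a, b, loc=het.cv_mean, scale=het.cv_sd,
                           size=het.n_regions, random_state=rng)
    sx, sy = cfg.resolved_source
    theta = np.arctan2(yy - sy, xx - sx)  # (-pi, pi]
    sector = np.floor((theta + np.pi) / (2 * np.pi / het.n_regions)).astype(int)
    sector = np.clip(sector, 0, het.n_regions - 1)
    return speeds[sector]


def simulate_activation_field(config: PatternConfig) -> ActivationField:
    """Generate the dense ground-truth field for one pattern."""
    cfg = config
    x, y = _cell_centers(cfg)
    xx, yy = np.meshgrid(x, y)
    c = cfg.resolved_speed / MM_PER_MS_TO_CM_PER_S  # mm/ms
    source = None

    if cfg.pattern == "plane":
        d = np.asarray(cfg.wave_direction, dtype=float)
        d = d / np.hypot(*d)
        proj = d[0] * xx + d[1] * yy
        t = (proj - proj.min()) / c
        vx = np.full_like(t, d[0] * cfg.resolved_speed)
        vy = np.full_like(t, d[1] * cfg.resolved_speed)
    elif cfg.pattern == "focal_homogeneous":
        source = cfg.resolved_source
        r = np.hypot(xx - source[0], yy - source[1])
        t = r / c
        with np.errstate(invalid="ignore", divide="ignore"):
            ux, uy = (xx - source[0]) / r, (yy - source[1]) / r
        ux = np.where(r > 0, ux, 0.0)
        uy = np.where(r > 0, uy, 0.0)
        vx, vy = ux * cfg.resolved_speed, uy * cfg.resolved_speed
    elif cfg.pattern == "collision":
        # two opposing planar fronts entering from the left and right edges
        t1 = xx / c
        t2 = (cfg.patch_size - xx) / c
        t = np.minimum(t1, t2)
        sign = np.where(t1 <= t2, 1.0, -1.0)
        vx = sign * cfg.resolved_speed
        vy = np.zeros_like(vx)
    else:  # focal_heterogeneous
        source = cfg.resolved_source
        speed_cm = _sector_speed_map(cfg, xx, yy)
        speed_mm = speed_cm / MM_PER_MS_TO_CM_PER_S
        h = cfg.patch_size / cfg.grid_n
        t = fast_march(speed_mm, h, x, y, source)
        gy, gx = np.gradient(t, y, x)  # ms/mm
        gnorm2 = gx**2 + gy**2
        with np.errstate(invalid="ignore", divide="ignore"):
            vx = gx / gnorm2 * MM_PER_MS_TO_CM_PER_S
            vy = gy / gnorm2 * MM_PER_MS_TO_CM_PER_S
        vx = np.where(gnorm2 > 0, vx, 0.0)
        vy = np.where(gnorm2 > 0, vy, 0.0)

    q = cfg.time_quantum
    if q > 0:
        t = np.round(t / q) * q
    return ActivationField(x=x, y=y, grid_times=t, true_vx=vx, true_vy=vy,
                           true_source=source, config=cfg)


def sample_multisite(
    afield: ActivationField,
    layout: CatheterLayout,
    center: Sequence[float] | None = None,
    rotation: float = 0.0,
    n_beats: int = 1,
    cycle_length: float | None = None,
) -> MultisiteRecording:
    """Sample the dense field through a placed catheter over several beats.

    The layout is placed at ``center`` (defaults to the patch center)
    with the given rotation; grid times are interpolated bilinearly at
    the bipole positions, and beat b repeats the base time shifted by
    (b - 1) cycle lengths.
    """
    cfg = afield.config
    if center is None:
        center = (cfg.patch_size / 2, cfg.patch_size / 2)
    placed = place_layout(layout, center=np.asarray(center) - layout.center, rotation=rotation)
    pts = placed.points
    if (pts.min() < 0) or (pts.max() > cfg.patch_size):
        raise ValueError("placed catheter extends outside the patch")
    interp = RegularGridInterpolator(
        (afield.y, afield.x), afield.grid_times, method="linear",
        bounds_error=False, fill_value=None,
    )
    base = interp(pts[:, ::-1])  # (y, x) ordering
    cl = cfg.cycle_length if cycle_length is None else cycle_length
    times = base[:, None] + np.arange(n_beats)[None, :] * cl
    return MultisiteRecording(
        positions=pts, times=times, cycle_length=cl, site_labels=placed.labels
    )


def add_jitter(
    recording: MultisiteRecording,
    eps_fraction: float,
    seed: int | np.random.Generator = 0,
) -> MultisiteRecording:
    """Add uniform activation-time jitter of amplitude eps to every entry.

    ``eps_fraction`` expresses the jitter amplitude as a fraction of the
    cycle length.  The amplitude eps = eps_fraction * cycle_length is
    the full width of the uniform distribution: jitter is drawn
    independently per site and beat on [-eps/2, +eps/2].
    """
    if not 0 <= eps_fraction <= 0.5:
        raise ValueError("eps_fraction must be in [0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = 0.5 * eps_fraction * recording.cycle_length
    jitter = rng.uniform(-half, half, size=recording.times.shape) if half > 0 else 0.0
    return MultisiteRecording(
        positions=recording.positions,
        times=recording.times + jitter,
        cycle_length=recording.cycle_length,
        site_labels=recording.site_labels,
    )


def remove_sites(
    recording: MultisiteRecording,
    n_remove: int,
    seed: int | np.random.Generator = 0,
) -> MultisiteRecording:
    """Remove a uniform random subset of sites (all beats affected alike)."""
    n = recording.n_sites
    if n_remove < 0 or n - n_remove < 3:
        raise ValueError("cannot remove that many sites (fewer than 3 would remain)")
    if n_remove == 0:
        return recording
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=n - n_remove, replace=False))
    labels = None
    if recording.site_labels is not None:
        labels = tuple(recording.site_labels[i] for i in keep)
    return MultisiteRecording(
        positions=recording.positions[keep],
        times=recording.times[keep],
        cycle_length=recording.cycle_length,
        site_labels=labels,
    )
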