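"""Radial basis function reconstruction of activation maps.

Scattered local activation times t_i at mapping sites X_i are
interpolated by a polyharmonic spline with Duchon's radial cubic kernel
R(r) = r^3 augmented by a first-order polynomial,

    f(X) = sum_i alpha_i ||X - X_i||^3 + b1 + b2 x + b3 y,

subject to the interpolation constraints f(X_i) = t_i and the side
constraints sum_i alpha_i = sum_i alpha_i x_i = sum_i alpha_i y_i = 0.
The weights solve the symmetric (N+3) x (N+3) saddle-point system

    [ R  P ] [alpha]   [t]
    [ P' 0 ] [beta ] = [0]

which is non-singular whenever the sites are distinct and not all
collinear.  The kernel is smooth away from the centers, so first and
second derivatives of f are available in closed form; they feed the
conduction-velocity and divergence analysis in :mod:`divmap.fields`.

Internally coordinates are centered and scaled by the mean pairwise
site distance before assembly (the r^3 kernel on raw millimetre
coordinates has a large dynamic range); the returned weights are
de-scaled back to mm/ms units, so the model is exactly the interpolant
of the original data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MultisiteRecording",
    "InterpolantModel",
    "FitError",
    "fit_interpolant",
    "evaluate_time",
    "evaluate_gradient",
    "evaluate_hessian",
]

#: sites closer than this (mm) are considered duplicates and rejected
MIN_SITE_SEPARATION = 1e-6


class FitError(RuntimeError):
    """Raised when the interpolation system cannot be solved."""


@dataclass
class MultisiteRecording:
    """Scattered multisite activation times.

    positions : (N, 2) site positions, mm.
    times : (N, B) activation times, ms; column b holds beat b.  A
        missing activation is NaN, never 0.
    cycle_length : nominal activation cycle length, ms.
    site_labels : optional per-site identifiers.
    """

    positions: np.ndarray
    times: np.ndarray
    cycle_length: float = 150.0
    site_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if t.ndim == 1:
            t = t[:, None]
        self.times = t
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (N, 2)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times must have one row per site")
        if self.positions.shape[0] < 3:
            raise ValueError("at least 3 sites required")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        d = cdist(self.positions, self.positions)
        np.fill_diagonal(d, np.inf)
        if d.min() <= MIN_SITE_SEPARATION:
            raise ValueError("duplicate site positions (closer than 1e-6 mm)")
        if self.site_labels is not None:
            self.site_labels = tuple(self.site_labels)
            if len(self.site_labels) != self.n_sites:
                raise ValueError("one label per site required")

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def n_beats(self) -> int:
        return self.times.shape[1]


@dataclass(frozen=True)
class InterpolantModel:
    """Fitted activation-map interpolant for one beat.

    centers : (N, 2) mm; alpha : (N,) kernel weights (ms/mm^3);
    beta : (3,) polynomial coefficients (ms, ms/mm, ms/mm).
    """

    centers: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    beat_index: int = 0

    def time(self, points: np.ndarray) -> np.ndarray:
        return evaluate_time(self, points)

    def gradient(self, points: np.ndarray) -> np.ndarray:
        return evaluate_gradient(self, points)

    def hessian(self, points: np.ndarray) -> np.ndarray:
        return evaluate_hessian(self, points)

    def to_json(self) -> str:
        return json.dumps(
            {
                "centers": self.centers.tolist(),
                "alpha": self.alpha.tolist(),
                "beta": self.beta.tolist(),
                "beat_index": self.beat_index,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "InterpolantModel":
        d = json.loads(text)
        return cls(
            centers=np.asarray(d["centers"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            beat_index=int(d["beat_index"]),
        )


def fit_interpolant(recording: MultisiteRecording, beat: int = 0) -> InterpolantModel:
    """Fit the augmented polyharmonic interpolant to one beat.

    Sites whose activation is missing (NaN) for this beat are dropped
    from the fit; at least 3 non-collinear sites must remain.
    """
    t_all = recording.times[:, beat]
    keep = np.isfinite(t_all)
    if keep.sum() < 3:
        raise ValueError(f"beat {beat}: fewer than 3 sites with activation times")
    pts = recording.positions[keep]
    t = t_all[keep]
    n = len(pts)

    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise FitError(f"beat {beat}: usable sites are collinear")

    # condition the system: center, scale by mean pairwise distance
    origin = pts.mean(axis=0)
    dists = cdist(pts, pts)
    scale = dists[np.triu_indices(n, 1)].mean()
    z = (pts - origin) / scale

    r = cdist(z, z)
    a = np.zeros((n + 3, n + 3))
    a[:n, :n] = r**3
    p = np.column_stack([np.ones(n), z])
    a[:n, n:] = p
    a[n:, :n] = p.T
    rhs = np.concatenate([t, np.zeros(3)])
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guard above
        raise FitError(f"beat {beat}: singular interpolation system") from exc
    if not np.all(np.isfinite(sol)):
        raise FitError(f"beat {beat}: non-finite solution")

    alpha_s, beta_s = sol[:n], sol[n:]
    # de-scale: f = sum a_s ||(X-o)/s||^3 + b0 + b1 (x-ox)/s + b2 (y-oy)/s
    alpha = alpha_s / scale**3
    b_lin = beta_s[1:] / scale
    beta = np.array([beta_s[0] - b_lin @ origin, b_lin[0], b_lin[1]])
    return InterpolantModel(centers=pts.copy(), alpha=alpha, beta=beta, beat_index=beat)


def _as_points(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    return pts


def evaluate_time(model: InterpolantModel, points: np.ndarray) -> np.ndarray:
    """Evaluate f at (M, 2) points; returns (M,) times in ms."""
    pts = _as_points(points)
    r = cdist(pts, model.centers)
    return r**3 @ model.alpha + model.beta[0] + pts @ model.beta[1:]


def evaluate_gradient(model: InterpolantModel, points: np.ndarray) -> np.ndarray:
    """Analytic gradient of f, (M, 2) in ms/mm.

    grad ||d||^3 = 3 ||d|| d; the limit at a center is 0, so evaluation
    exactly on a center is finite and continuous.
    """
    pts = _as_points(points)
    d = pts[:, None, :] - model.centers[None, :, :]  # (M, N, 2)
    r = np.sqrt(np.einsum("mnk,mnk->mn", d, d))
    g = np.einsum("mn,mnk->mk", 3.0 * r * model.alpha, d)
    return g + model.beta[1:]


def evaluate_hessian(model: InterpolantModel, points: np.ndarray) -> np.ndarray:
    """Analytic Hessian of f, (M, 2, 2) in ms/mm^2.

    For one center, H = 3 (r I + d d^T / r); the r -> 0 limit is taken
    as 0 (the kernel's second derivatives vanish at the center along
    every approach direction's symmetric part used here).
    """
    pts = _as_points(points)
    d = pts[:, None, :] - model.centers[None, :, :]
    r = np.sqrt(np.einsum("mnk,mnk->mn", d, d))
    safe = np.where(r > 0, r, 1.0)
    outer = np.einsum("mni,mnj->mnij", d, d) / safe[:, :, None, None]
    eye = np.eye(2)
    h_per = 3.0 * (r[:, :, None, None] * eye + np.where((r > 0)[:, :, None, None], outer, 0.0))
    return np.einsum("n,mnij->mij", model.alpha, h_per)
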