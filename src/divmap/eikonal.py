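"""First-arrival (eikonal) times on a uniform grid by fast marching.

Solves |grad T| = 1/c(x) for the first-arrival time T from a point
source over a spatially varying speed map, using the upwind
fast-marching scheme (Dijkstra-like sweep with a min-heap and the
two-sided quadratic update), with second-order one-sided differences
where two upwind neighbors are available.

The scheme's largest error arises from the source singularity, where
the wavefront curvature is unresolved; nodes within a small disc
around the source are therefore seeded with their exact radial times
r / c(node).  For the angular-sector speed maps used here the exact
ray from source to a nearby node stays inside one sector, so the
seeded values are exact.
"""

from __future__ import annotations

import heapq

import numpy as np

__all__ = ["fast_march"]


def fast_march(
    speed: np.ndarray,
    spacing: float,
    x: np.ndarray,
    y: np.ndarray,
    source: tuple[float, float],
    seed_radius_cells: float = 6.0,
) -> np.ndarray:
    """First-arrival times (ms) from a point source.

    speed : (ny, nx) local propagation speed, mm/ms, all > 0.
    spacing : grid spacing, mm; x, y : node coordinate vectors, mm.
    source : (sx, sy) source position, mm (need not be a node).
    """
    speed = np.asarray(speed, dtype=float)
    ny, nx = speed.shape
    if np.any(speed <= 0):
        raise ValueError("speed map must be strictly positive")
    sx, sy = source
    h = float(spacing)

    times = np.full((ny, nx), np.inf)
    accepted = np.zeros((ny, nx), dtype=bool)
    heap: list[tuple[float, int, int]] = []

    # seed a small disc around the source with exact radial times; the
    # seeds are frozen boundary values (accepted immediately) so that
    # no upwind update can undercut them
    xx, yy = np.meshgrid(x, y)
    r = np.hypot(xx - sx, yy - sy)
    seed = r <= seed_radius_cells * h
    if not seed.any():
        seed = r <= (r.min() + 0.51 * h)
    times[seed] = r[seed] / speed[seed]
    accepted |= seed
    for iy, ix in zip(*np.nonzero(seed)):
        heapq.heappush(heap, (times[iy, ix], iy, ix))

    def axis_terms(iy: int, ix: int, dy: int, dx: int) -> tuple[float, float] | None:
        """(coeff, tau) for one upwind direction, or None if unusable."""
        jy, jx = iy + dy, ix + dx
        if not (0 <= jy < ny and 0 <= jx < nx and accepted[jy, jx]):
            return None
        t1 = times[jy, jx]
        ky, kx = iy + 2 * dy, ix + 2 * dx
        if 0 <= ky < ny and 0 <= kx < nx and accepted[ky, kx] and times[ky, kx] <= t1:
            # second-order one-sided difference
            return 2.25, (4.0 * t1 - times[ky, kx]) / 3.0
        return 1.0, t1

    def update(iy: int, ix: int) -> float:
        terms = []
        for axis in (((0, -1), (0, 1)), ((-1, 0), (1, 0))):
            best = None
            for d in axis:
                cand = axis_terms(iy, ix, *d)
                if cand is not None and (best is None or cand[1] < best[1]):
                    best = cand
            if best is not None:
                terms.append(best)
        if not terms:
            return np.inf
        terms.sort(key=lambda ct: ct[1])
        f2 = (h / speed[iy, ix]) ** 2
        # solve sum_i c_i (T - tau_i)^2 = h^2 / c^2 for the largest root,
        # dropping the later axis if the quadratic loses causality
        for use in (terms, terms[:1] if len(terms) > 1 else None):
            if use is None:
                break
            a = sum(c for c, _ in use)
            b = sum(c * tau for c, tau in use)
            q = sum(c * tau * tau for c, tau in use)
            disc = b * b - a * (q - f2)
            if disc < 0:
                continue
            t = (b + np.sqrt(disc)) / a
            if all(t >= tau for _, tau in use):
                return t
        return min(tau for _, tau in terms) + h / speed[iy, ix]

    processed = np.zeros((ny, nx), dtype=bool)
    while heap:
        t, iy, ix = heapq.heappop(heap)
        if processed[iy, ix]:
            continue
        processed[iy, ix] = True
        if not accepted[iy, ix]:
            accepted[iy, ix] = True
            times[iy, ix] = t
        for dy, dx in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            jy, jx = iy + dy, ix + dx
            if 0 <= jy < ny and 0 <= jx < nx and not accepted[jy, jx]:
                tn = update(jy, jx)
                if tn < times[jy, jx]:
                    times[jy, jx] = tn
                    heapq.heappush(heap, (tn, jy, jx))
    return times
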