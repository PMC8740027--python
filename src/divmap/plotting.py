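"""Optional rendering of activation, CV and divergence maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap, TwoSlopeNorm

from .fields import ScalarField, VectorField

__all__ = ["render_divergence_map", "render_vector_field"]

#: diverging palette: blue (sinks) - green (planar) - red (sources)
_DIV_CMAP = LinearSegmentedColormap.from_list(
    "divmap", ["#1f4fd8", "#2fa84f", "#d82f1f"]
)


def render_divergence_map(field: ScalarField, path: str | Path,
                          sites: np.ndarray | None = None,
                          vmax: float | None = None) -> None:
    """Write a PNG of a divergence map (red sources, blue sinks)."""
    vals = np.where(field.valid, field.values, np.nan)
    if vmax is None:
        finite = vals[np.isfinite(vals)]
        vmax = float(np.percentile(np.abs(finite), 99)) if finite.size else 1.0
        vmax = max(vmax, 1e-12)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    g = field.grid
    im = ax.pcolormesh(g.x, g.y, vals, cmap=_DIV_CMAP,
                       norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax))
    if sites is not None:
        ax.plot(sites[:, 0], sites[:, 1], "k.", ms=4)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.colorbar(im, ax=ax, label="divergence (mm$^{-1}$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_vector_field(field: VectorField, path: str | Path,
                        stride: int = 6) -> None:
    """Write a PNG of the CV field: speed map + normalized arrows."""
    g = field.grid
    speed = np.where(field.valid, field.speed, np.nan)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.pcolormesh(g.x, g.y, speed, cmap="viridis")
    s = slice(None, None, stride)
    ax.quiver(g.x[s], g.y[s], field.unit_vx[s, s], field.unit_vy[s, s],
              color="white", scale=30, width=3e-3)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.colorbar(im, ax=ax, label="CV (cm/s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
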