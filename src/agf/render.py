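"""Snapshot rendering: force-center disks, augmented Voronoi, stress maps.

Color convention of the stress mode: fill encodes the major virial
stress (tensile red, compressive blue, saturation by magnitude);
outlines mark inactive (gray), active (black) and constricted (yellow)
cells.  Colors are presentation only, not part of any data contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import EllipseCollection  # noqa: E402

from .stress import stress_field  # noqa: E402
from .system import InteractionModel, ParticleSystem  # noqa: E402
from .voronoi import shape_tensor_field, tessellate  # noqa: E402

__all__ = ["render_snapshot"]


def _outline_colors(system: ParticleSystem):
    colors = np.empty(system.n, dtype=object)
    colors[:] = "0.6"
    colors[system.active] = "black"
    colors[system.constricted] = "gold"
    return colors


def _stress_fill(major: np.ndarray):
    scale = np.percentile(np.abs(major), 95) or 1.0
    sat = np.clip(np.abs(major) / scale, 0, 1)
    rgb = np.ones((major.size, 3))
    tens = major >= 0
    rgb[tens, 1] = rgb[tens, 2] = 1 - sat[tens]      # tension -> red
    rgb[~tens, 0] = rgb[~tens, 1] = 1 - sat[~tens]   # compression -> blue
    return rgb


def render_snapshot(system: ParticleSystem, mode: str, path,
                    model: InteractionModel | None = None,
                    resolution: float = 8.0) -> Path:
    """Write a PNG of the snapshot in the requested mode.

    Modes: "circles" (force-center disks), "voronoi" (stress-augmented
    tessellation labels), "stress" (major-stress fill + outline codes).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lx, ly = system.box
    fig, ax = plt.subplots(figsize=(7, 7 * ly / lx))
    ax.set_xlim(0, lx)
    ax.set_ylim(0, ly)
    ax.set_aspect("equal")
    if mode == "circles":
        ec = EllipseCollection(system.diameters, system.diameters,
                               np.zeros(system.n), units="xy",
                               offsets=system.positions,
                               transOffset=ax.transData,
                               facecolors="none",
                               edgecolors=_outline_colors(system))
        ax.add_collection(ec)
    elif mode in ("voronoi", "stress"):
        sigma, S = stress_field(system, model)
        shapes = shape_tensor_field(system, S)
        if mode == "voronoi":
            raster = tessellate(system, shapes, resolution=resolution)
            ax.imshow(raster.labels % 17, origin="lower",
                      extent=(0, lx, 0, ly), cmap="tab20",
                      interpolation="nearest")
        else:
            vals = np.linalg.eigvalsh(S)
            major = np.where(np.abs(vals[:, 1]) >= np.abs(vals[:, 0]),
                             vals[:, 1], vals[:, 0])
            ec = EllipseCollection(system.diameters, system.diameters,
                                   np.zeros(system.n), units="xy",
                                   offsets=system.positions,
                                   transOffset=ax.transData,
                                   facecolors=_stress_fill(major),
                                   edgecolors=_outline_colors(system))
            ax.add_collection(ec)
    else:
        raise ValueError(f"unknown render mode {mode!r}")
    ax.set_xlabel("x (cell diameters)")
    ax.set_ylabel("y (cell diameters)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
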