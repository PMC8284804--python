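"""Stress-augmented anisotropic Voronoi tessellation.

A force-center configuration is rendered as a confluent cell layer by
assigning every pixel to the particle with the smallest *weighted*
distance.  The weight is the cellular shape tensor

    D_i = d_i (I + S_i / s0),

which inflates a cell's reach along directions of tensile stress: cells
in constriction chains come out elongated along the chain, as observed in
the embryo.  With all stresses zero the construction reduces to a
size-weighted (polydisperse) tessellation, and with D_i = I to the
standard Voronoi diagram.

The weighted distance from particle i to a trial point at offset rho is

    rho_bar_i = rho / (rho_hat . D_i . rho_hat),

i.e. the Euclidean distance divided by the directional extent of the
cell's representative ellipse.  (An alternative sqrt reading
rho / sqrt(rho_hat . D_i . rho_hat) is available via ``sqrt_form``.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .system import ParticleSystem

__all__ = ["ShapeTensorField", "TessellationRaster", "shape_tensor",
           "shape_tensor_field", "weighted_distance", "tessellate"]

DEFAULT_S0 = 2.1
#: relative floor for shape-tensor eigenvalues under strong compression
EIGENVALUE_CLAMP = 0.05


def shape_tensor(d_i: float, S_i: np.ndarray, s0: float = DEFAULT_S0,
                 clamp: bool = True) -> np.ndarray:
    """Shape tensor D_i = d_i (I + S_i/s0) of a single cell.

    Strong compression can push an eigenvalue of D_i below zero, which
    would invert the distance weight; eigenvalues are clamped at
    ``EIGENVALUE_CLAMP * d_i`` with a warning.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    S_i = np.asarray(S_i, dtype=float)
    D = d_i * (np.eye(2) + S_i / s0)
    D = 0.5 * (D + D.T)
    vals, vecs = np.linalg.eigh(D)
    floor = EIGENVALUE_CLAMP * d_i
    if clamp and np.any(vals < floor):
        warnings.warn("shape tensor has a non-positive/degenerate eigenvalue; "
                      "clamping", stacklevel=2)
        vals = np.maximum(vals, floor)
        D = (vecs * vals) @ vecs.T
    return D


@dataclass
class ShapeTensorField:
    """Per-particle shape tensors D_i (N, 2, 2) plus the stress scale s0."""

    D: np.ndarray
    s0: float = DEFAULT_S0


def shape_tensor_field(system: ParticleSystem, S: np.ndarray | None = None,
                       s0: float = DEFAULT_S0) -> ShapeTensorField:
    """Shape tensors for the whole system.

    ``S`` is the (N, 2, 2) virial stress field; None means stress-free
    (pure size weighting).  Pass ``s0=np.inf`` for the polydisperse
    stress-free limit explicitly.
    """
    n = system.n
    D = np.empty((n, 2, 2))
    for i in range(n):
        S_i = np.zeros((2, 2)) if S is None or not np.isfinite(s0) else S[i]
        D[i] = shape_tensor(system.diameters[i], S_i,
                            s0 if np.isfinite(s0) else 1.0)
    return ShapeTensorField(D=D, s0=s0)


def weighted_distance(point: np.ndarray, position: np.ndarray,
                      D_i: np.ndarray, sqrt_form: bool = False) -> float:
    """Weighted distance from a particle to a trial point (no periodicity).

    Reduces to rho/d for isotropic D = d I and to the Euclidean distance
    for D = I.  Returns 0 at the particle center.
    """
    rho_vec = np.asarray(point, dtype=float) - np.asarray(position, dtype=float)
    rho = float(np.hypot(*rho_vec))
    if rho == 0.0:
        return 0.0
    vals = np.linalg.eigvalsh(np.asarray(D_i, dtype=float))
    if np.any(vals <= 0):
        raise ValueError("shape tensor must be positive-definite")
    u = rho_vec / rho
    ext = float(u @ D_i @ u)
    return rho / np.sqrt(ext) if sqrt_form else rho / ext


@dataclass
class TessellationRaster:
    """Integer label raster: pixel -> particle id + 1 (0 = unassigned)."""

    labels: np.ndarray          # (ny, nx) int32
    resolution: float           # pixels per unit length
    box: tuple

    def save_tiff(self, path) -> None:
        """Write the labels as a 16-bit integer TIFF."""
        import tifffile

        if self.labels.max() > np.iinfo(np.uint16).max:
            raise ValueError("too many labels for a 16-bit TIFF")
        tifffile.imwrite(path, self.labels.astype(np.uint16))

    def pixel_sets(self) -> dict:
        """particle id -> (rows, cols) pixel index arrays."""
        out = {}
        flat = self.labels.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        bounds = np.searchsorted(sorted_labels,
                                 np.arange(1, self.labels.max() + 1))
        bounds = np.append(bounds, flat.size)
        ny, nx = self.labels.shape
        for lab in range(1, self.labels.max() + 1):
            sel = order[bounds[lab - 1]:bounds[lab]]
            out[lab - 1] = (sel // nx, sel % nx)
        return out


def tessellate(system: ParticleSystem, shapes: ShapeTensorField,
               resolution: float = 8.0,
               sqrt_form: bool = False) -> TessellationRaster:
    """Rasterize the weighted-Voronoi diagram of the system.

    Every pixel center inside the box is assigned to the arg-min particle
    under the periodic minimum-image weighted distance; ties go to the
    lowest particle id.  Each particle's own center pixel keeps its id.
    """
    lx, ly = system.box
    nx = max(1, int(round(lx * resolution)))
    ny = max(1, int(round(ly * resolution)))
    xs = (np.arange(nx) + 0.5) / resolution
    ys = (np.arange(ny) + 0.5) / resolution
    gx, gy = np.meshgrid(xs, ys)
    D = shapes.D
    labels = _kernels.tessellate_labels(
        gx.ravel(), gy.ravel(), system.positions,
        np.ascontiguousarray(D[:, 0, 0]), np.ascontiguousarray(D[:, 1, 1]),
        np.ascontiguousarray(D[:, 0, 1]), lx, ly, sqrt_form)
    labels = labels.reshape(ny, nx).astype(np.int32)
    # guarantee every particle labels its own center pixel
    col = np.clip((system.positions[:, 0] * resolution).astype(int), 0, nx - 1)
    row = np.clip((system.positions[:, 1] * resolution).astype(int), 0, ny - 1)
    labels[row, col] = np.arange(1, system.n + 1, dtype=np.int32)
    return TessellationRaster(labels=labels, resolution=resolution,
                              box=(lx, ly))


def region_aspect_ratios(raster: TessellationRaster) -> np.ndarray:
    """Major/minor second-moment aspect ratio of every cell's pixel set.

    Periodic wrap is handled by recentering each pixel set around its
    first pixel with minimum-image offsets.  Cells with fewer than 3
    pixels get NaN.
    """
    ny, nx = raster.labels.shape
    out = np.full(int(raster.labels.max()), np.nan)
    for pid, (rows, cols) in raster.pixel_sets().items():
        if rows.size < 3:
            continue
        dr = rows.astype(float) - rows[0]
        dc = cols.astype(float) - cols[0]
        dr -= ny * np.rint(dr / ny)
        dc -= nx * np.rint(dc / nx)
        dr -= dr.mean()
        dc -= dc.mean()
        cov = np.array([[np.mean(dc * dc), np.mean(dc * dr)],
                        [np.mean(dc * dr), np.mean(dr * dr)]])
        vals = np.linalg.eigvalsh(cov)
        if vals[0] <= 0:
            continue
        out[pid] = float(np.sqrt(vals[1] / vals[0]))
    return out
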