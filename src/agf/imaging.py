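"""Constriction metrics from segmented label-image time-lapses.

The input is the output of a segmentation/tracking pipeline: one integer
label raster per frame (0 = membrane/background, k >= 1 = tracked cell,
ids consistent across frames).  A cell's apical shape is summarized by
the eigenvalues of its second-moment (central scatter) matrix

    M_i = sum_j [ (px_j - rx)^2        (px_j - rx)(py_j - ry) ]
                [ (px_j - rx)(py_j-ry) (py_j - ry)^2          ],

from which the equivalent-ellipse minor axis length is
lambda = 4 sqrt(e_min / area).  A cell counts as constricted in a frame
when its minor-axis reduction r = lambda / lambda_ref falls to or below a
threshold r_c (lambda_ref is the pre-onset average of that cell's minor
axis).  Active cells are those whose minimum r over the movie reaches
0.85; the binned constricted fraction nu_avg profiles constriction
activity along the anteroposterior axis.

A synthetic movie generator (jittered-lattice weighted-Voronoi cells,
1-pixel membranes, prescribed constriction schedules) provides ground
truth for testing every metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SegmentedMovie", "second_moment_matrix", "minor_axis_length",
    "track_cells", "reference_minor_axis", "constriction_flags",
    "detect_time_zero", "pixel_neighbor_graph", "identify_active_cells",
    "nu_avg_profile", "generate_synthetic_movie",
]


@dataclass
class SegmentedMovie:
    """Label-raster time-lapse with tracking-consistent cell ids."""

    frames: list                    # list of 2D int arrays, same shape
    frame_interval: float = 15.0    # seconds
    pixel_size: float | None = None  # micrometers per pixel
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(np.concatenate([np.unique(f) for f in self.frames]))
        return ids[ids > 0]


def second_moment_matrix(pixels, centroid=None) -> np.ndarray:
    """Unnormalized central second-moment matrix of a pixel set.

    ``pixels`` is an (n, 2) array of (x, y) pixel indices; the centroid
    defaults to the pixel mean.  Requires at least 3 pixels.
    """
    pts = np.asarray(pixels, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise ValueError("degenerate shape: need at least 3 pixels")
    c = pts.mean(axis=0) if centroid is None else np.asarray(centroid, float)
    d = pts - c
    m_xx = float(np.sum(d[:, 0] ** 2))
    m_yy = float(np.sum(d[:, 1] ** 2))
    m_xy = float(np.sum(d[:, 0] * d[:, 1]))
    return np.array([[m_xx, m_xy], [m_xy, m_yy]])


def minor_axis_length(M: np.ndarray, area: int) -> float:
    """Equivalent-ellipse minor axis (full length, pixels): 4 sqrt(e_min/area)."""
    if area <= 0:
        raise ValueError("area must be positive")
    e_min = float(np.linalg.eigvalsh(np.asarray(M, float))[0])
    if e_min <= 0:
        warnings.warn("collinear pixel set; minor axis 0", stacklevel=2)
        return 0.0
    return 4.0 * np.sqrt(e_min / area)


def major_axis_length(M: np.ndarray, area: int) -> float:
    if area <= 0:
        raise ValueError("area must be positive")
    e_max = float(np.linalg.eigvalsh(np.asarray(M, float))[1])
    return 4.0 * np.sqrt(max(e_max, 0.0) / area)


def track_cells(movie: SegmentedMovie) -> pd.DataFrame:
    """Per-(frame, cell) geometry table.

    Columns: frame, cell, area, cx, cy, minor, major.  Cells lost by
    tracking in a frame simply have no row there.
    """
    rows = []
    for t, frame in enumerate(movie.frames):
        frame = np.asarray(frame)
        flat = frame.ravel()
        order = np.argsort(flat, kind="stable")
        sorted_lab = flat[order]
        labs, starts = np.unique(sorted_lab, return_index=True)
        starts = np.append(starts, flat.size)
        ny, nx = frame.shape
        for k, lab in enumerate(labs):
            if lab == 0:
                continue
            sel = order[starts[k]:starts[k + 1]]
            ys, xs = sel // nx, sel % nx
            pts = np.column_stack([xs, ys]).astype(float)
            area = pts.shape[0]
            c = pts.mean(axis=0)
            if area >= 3:
                M = second_moment_matrix(pts, c)
                minor = minor_axis_length(M, area)
                major = major_axis_length(M, area)
            else:
                minor = major = np.nan
            rows.append((t, int(lab), area, c[0], c[1], minor, major))
    return pd.DataFrame(rows, columns=["frame", "cell", "area", "cx", "cy",
                                       "minor", "major"])


def reference_minor_axis(track: pd.DataFrame, window: int = 20,
                         onset_frame: int | None = None) -> pd.Series:
    """Reference minor axis per cell: mean over ``window`` pre-onset frames.

    ``onset_frame`` marks where constrictions begin (frames < onset are
    pre-onset; default: use the first ``window`` frames of the movie).
    Cells lacking ``window`` pre-onset frames get NaN (flagged/excluded).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if onset_frame is None:
        onset_frame = window
    pre = track[track["frame"] < onset_frame]
    out = {}
    for cell, grp in pre.groupby("cell"):
        grp = grp.sort_values("frame").tail(window)
        out[cell] = grp["minor"].mean() if len(grp) >= window else np.nan
    return pd.Series(out, name="lambda_ref")


def constriction_flags(track: pd.DataFrame, lambda_ref: pd.Series,
                       r_c: float = 0.65) -> pd.DataFrame:
    """Boolean constricted flag per (frame, cell): lambda/lambda_ref <= r_c.

    The boundary is inclusive; flags may toggle over time (unratcheted
    pulses are permitted in data).  Cells without a reference are NaN.
    """
    t = track.copy()
    t["lambda_ref"] = t["cell"].map(lambda_ref)
    t["r"] = t["minor"] / t["lambda_ref"]
    t["constricted"] = t["r"] <= r_c
    t.loc[t["lambda_ref"].isna(), "constricted"] = False
    return t


def detect_time_zero(movie: SegmentedMovie, r_c: float = 0.65,
                     persistence: int = 3, ref_window: int = 5):
    """First frame with a cell constricted there and in the next
    ``persistence`` frames; returns (frame, cell) or (None, None).

    Uses a provisional lambda_ref from the earliest ``ref_window`` frames.
    """
    track = track_cells(movie)
    lref = reference_minor_axis(track, window=ref_window,
                                onset_frame=ref_window)
    flagged = constriction_flags(track, lref, r_c=r_c)
    piv = flagged.pivot_table(index="frame", columns="cell",
                              values="constricted", aggfunc="first")
    piv = piv.reindex(range(movie.n_frames)).fillna(False).astype(bool)
    arr = piv.to_numpy()
    for t in range(movie.n_frames - persistence):
        run = arr[t:t + persistence + 1].all(axis=0)
        if run.any():
            cell = piv.columns[int(np.argmax(run))]
            return t, int(cell)
    return None, None


def pixel_neighbor_graph(frame: np.ndarray, reach: int = 2) -> set:
    """Cell adjacency from pixel proximity (Chebyshev distance <= reach).

    Two cells are adjacent if any pixel of one lies within a
    (2*reach+1)^2 window of a pixel of the other, allowing membrane
    pixels between them.  Returns a set of (lo, hi) id pairs.
    """
    frame = np.asarray(frame)
    pairs = set()
    ny, nx = frame.shape
    for dy in range(-reach, reach + 1):
        for dx in range(-reach, reach + 1):
            if dy < 0 or (dy == 0 and dx <= 0):
                continue
            a = frame[max(0, -dy):ny - max(0, dy) or ny,
                      max(0, -dx):nx - max(0, dx) or nx]
            b = frame[max(0, dy):ny - max(0, -dy) or ny,
                      max(0, dx):nx - max(0, -dx) or nx]
            m = (a > 0) & (b > 0) & (a != b)
            if m.any():
                av, bv = a[m], b[m]
                lo = np.minimum(av, bv)
                hi = np.maximum(av, bv)
                pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def identify_active_cells(movie: SegmentedMovie, r_active: float = 0.85,
                          window: int = 20,
                          onset_frame: int | None = None) -> set:
    """Cells whose minimum minor-axis reduction over the movie is <= r_active.

    This set is the denominator N_a0 of %N_c and C_ave for image data.
    """
    track = track_cells(movie)
    lref = reference_minor_axis(track, window=window, onset_frame=onset_frame)
    flagged = constriction_flags(track, lref, r_c=r_active)
    rmin = flagged.dropna(subset=["r"]).groupby("cell")["r"].min()
    return set(int(c) for c, r in rmin.items() if r <= r_active)


def nu_avg_profile(movie: SegmentedMovie, frames, n_bins: int = 10,
                   minor_threshold_um: float | None = 1.3,
                   r_c: float | None = None, window: int = 20,
                   onset_frame: int | None = None) -> pd.DataFrame:
    """Binned constricted fraction vs fractional x-position.

    Cells are binned by centroid fractional position along x; per bin the
    constricted fraction (over all cells present) is averaged across the
    requested frames.  The constricted rule is either absolute (minor
    axis <= ``minor_threshold_um``; needs pixel_size) or relative
    (r <= ``r_c``).  Empty bins are NaN.
    """
    track = track_cells(movie)
    if r_c is not None:
        lref = reference_minor_axis(track, window=window,
                                    onset_frame=onset_frame)
        flagged = constriction_flags(track, lref, r_c=r_c)
    else:
        if movie.pixel_size is None:
            raise ValueError("absolute threshold requires pixel_size")
        flagged = track.copy()
        flagged["constricted"] = \
            flagged["minor"] * movie.pixel_size <= minor_threshold_um
    nx = np.asarray(movie.frames[0]).shape[1]
    flagged["bin"] = np.clip((flagged["cx"] / nx * n_bins).astype(int),
                             0, n_bins - 1)
    sub = flagged[flagged["frame"].isin(list(frames))]
    rows = []
    for b in range(n_bins):
        grp = sub[sub["bin"] == b]
        per_frame = grp.groupby("frame")["constricted"].mean()
        rows.append((b, (b + 0.5) / n_bins,
                     per_frame.mean() if len(per_frame) else np.nan,
                     per_frame.std(ddof=1) if len(per_frame) > 1 else np.nan,
                     len(grp)))
    return pd.DataFrame(rows, columns=["bin", "frac_x", "nu_avg", "sd",
                                       "n_cells"])


# ----------------------------------------------------------------------
def generate_synthetic_movie(n_cols: int = 16, n_rows: int = 12,
                             cell_px: int = 11, n_frames: int = 30,
                             schedule: str = "random",
                             n_constrict: int = 20,
                             onset_frame: int = 22,
                             active_rows: tuple | None = None,
                             constrict_factor: float = 0.5,
                             jitter: float = 0.25,
                             pixel_size: float = 0.2,
                             band_cols: tuple | None = None,
                             seed: int = 0) -> SegmentedMovie:
    """Synthetic segmented time-lapse emulating tracked apical cells.

    Cells are weighted-Voronoi regions of a jittered lattice with 1-pixel
    membrane gaps.  From ``onset_frame`` on, scheduled cells shrink their
    vertical (minor) axis weight by ``constrict_factor``; schedules:

    * "none"             no constrictions,
    * "random"           ``n_constrict`` active cells at random times,
    * "chain"            a horizontal run of laterally adjacent cells,
    * "band-disrupted"   random, but cells in ``band_cols`` never chosen.

    Ground truth (true adjacency on frame 0, true constriction frame per
    cell, true reference minor axis) is stored in ``ground_truth``.
    Deterministic from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_cells = n_cols * n_rows
    gx, gy = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    centers = np.column_stack([(gx.ravel() + 0.5) * cell_px,
                               (gy.ravel() + 0.5) * cell_px]).astype(float)
    centers += rng.uniform(-jitter * cell_px, jitter * cell_px,
                           size=centers.shape)
    width, height = n_cols * cell_px, n_rows * cell_px

    if active_rows is None:
        active_rows = (1, n_rows - 1)
    row_of = np.repeat(np.arange(n_rows), n_cols)
    col_of = np.tile(np.arange(n_cols), n_rows)
    active = (row_of >= active_rows[0]) & (row_of < active_rows[1])
    active_ids = np.flatnonzero(active)

    times = np.full(n_cells, -1)
    if schedule == "none":
        chosen = np.array([], dtype=int)
    elif schedule in ("random", "band-disrupted"):
        pool = active_ids
        if schedule == "band-disrupted":
            if band_cols is None:
                band_cols = (n_cols // 2 - 2, n_cols // 2 + 2)
            pool = pool[(col_of[pool] < band_cols[0])
                        | (col_of[pool] >= band_cols[1])]
        if n_constrict > pool.size:
            raise ValueError("schedule constricts more cells than exist")
        chosen = rng.choice(pool, size=n_constrict, replace=False)
        times[chosen] = rng.integers(onset_frame, n_frames,
                                     size=n_constrict)
    elif schedule == "chain":
        row = (active_rows[0] + active_rows[1]) // 2
        length = min(n_constrict, n_cols)
        chosen = row * n_cols + np.arange(length)
        span = max(1, n_frames - onset_frame)
        times[chosen] = onset_frame + (np.arange(length) * span // length)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")

    # per-cell anisotropic weights; shrinking sy shrinks the rendered cell
    # vertically (minor axis along y, the dorsoventral direction).  The
    # cell boundary is a weighted bisector, so a weight sy renders a
    # measured height reduction of about 2 sy/(1+sy); invert that so that
    # ``constrict_factor`` is the reduction the metrics should measure
    weight_factor = constrict_factor / (2.0 - constrict_factor)
    ys, xs = np.mgrid[0:height, 0:width]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    from scipy.spatial import cKDTree
    tree = cKDTree(centers)
    _, cand = tree.query(pts, k=min(8, n_cells))

    frames = []
    raw_labels = []
    for t in range(n_frames):
        sy = np.where((times >= 0) & (t >= times), weight_factor, 1.0)
        dx = pts[:, None, 0] - centers[cand, 0]
        dy = pts[:, None, 1] - centers[cand, 1]
        w = dx ** 2 + (dy / sy[cand]) ** 2
        lab = cand[np.arange(pts.shape[0]), np.argmin(w, axis=1)] + 1
        lab = lab.reshape(height, width).astype(np.int32)
        raw_labels.append(lab)
        memb = np.zeros_like(lab, dtype=bool)
        memb[:, :-1] |= lab[:, :-1] != lab[:, 1:]
        memb[:-1, :] |= lab[:-1, :] != lab[1:, :]
        out = lab.copy()
        out[memb] = 0
        frames.append(out)

    # ground-truth adjacency: 4-adjacent label pairs in the raw frame-0 field
    lab0 = raw_labels[0]
    adj = set()
    for a, b in ((lab0[:, :-1], lab0[:, 1:]), (lab0[:-1, :], lab0[1:, :])):
        m = a != b
        lo = np.minimum(a[m], b[m])
        hi = np.maximum(a[m], b[m])
        adj.update(zip(lo.tolist(), hi.tolist()))

    # ground-truth reference minor axis: measured on the static pre-onset
    # raster with an independent implementation (scikit-image)
    from skimage.measure import regionprops
    lam_ref = {}
    for prop in regionprops(frames[0]):
        lam_ref[int(prop.label)] = float(prop.axis_minor_length)

    movie = SegmentedMovie(frames=frames, pixel_size=pixel_size)
    movie.ground_truth = {
        "adjacency": adj,
        "constriction_frame": {int(c) + 1: int(times[c]) for c in chosen},
        "lambda_ref": lam_ref,
        "active_ids": set(int(i) + 1 for i in active_ids),
        "onset_frame": onset_frame,
    }
    return movie
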