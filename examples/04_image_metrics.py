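"""Constriction metrics on a synthetic segmented time-lapse.

Generates a label-image movie (jittered-lattice cells with 1-pixel
membranes, a chain of cells constricting after frame 20), then runs the
image pipeline: per-cell minor axes, reference values, constriction
flags, time zero, the pixel-adjacency graph, and cluster statistics.
"""

from agf.clusters import cluster_report, identify_clusters
from agf.imaging import (constriction_flags, detect_time_zero,
                         generate_synthetic_movie, identify_active_cells,
                         pixel_neighbor_graph, reference_minor_axis,
                         track_cells)

movie = generate_synthetic_movie(n_cols=14, n_rows=10, n_frames=30,
                                 schedule="chain", n_constrict=9,
                                 onset_frame=21, seed=5)
print(f"movie: {movie.n_frames} frames of {movie.frames[0].shape} px, "
      f"{len(movie.cell_ids)} tracked cells")

t0, first_cell = detect_time_zero(movie, r_c=0.65, persistence=3)
print(f"time zero: frame {t0} (cell {first_cell} stays constricted)")

track = track_cells(movie)
lref = reference_minor_axis(track, window=20, onset_frame=21)
flagged = constriction_flags(track, lref, r_c=0.65)
last = flagged[flagged["frame"] == movie.n_frames - 1]
constricted = set(last[last["constricted"]]["cell"].astype(int))
print(f"cells constricted in the last frame (r <= 0.65): "
      f"{sorted(constricted)}")

active = identify_active_cells(movie, r_active=0.85, window=20,
                               onset_frame=21)
pairs = list(pixel_neighbor_graph(movie.frames[-1]))
rpt = cluster_report(identify_clusters(constricted, pairs), len(active))
print(f"active cells N_a0 = {len(active)}, %N_c = {rpt.pct_nc:.2f}; "
      f"{rpt.n_clusters} cluster(s), eta_m = {rpt.eta_m:.2f}")
print("A chain schedule shows up as a single multiplet spanning the "
      "constricted cells, exactly\nwhat the cluster statistics report on "
      "segmented embryo movies.")
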