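"""Particle-system container and interaction parameters.

The epithelial monolayer is coarse-grained to soft disks: every apical
cell end is one force center with an effective diameter ``d_i`` (the range
of the repulsive branch of the pair potential).  Lengths are measured in
units of the mean large-particle diameter, energies in units of the
spring energy scale epsilon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class InteractionModel:
    """Parameters of the pair interaction and of the relaxation dynamics.

    epsilon         characteristic spring energy scale (results are
                    independent of its value; kept at 1)
    neighbor_cutoff center-to-center criterion r_ij/d_ij < cutoff defining
                    connected neighbors in the initial packing
    damping         pairwise dissipative coefficient b of the damped
                    velocity-Verlet relaxation
    drag            small global drag removing rigid-body drift
    dt              integration timestep (natural units, unit mass)
    energy_tol      relative potential-energy change threshold of the
                    energy-window stopping rule
    energy_window   number of steps per energy check
    method          production minimizer: "fire" (force criterion
                    ``force_tol``) or "damped_verlet" (energy criterion)
    """

    epsilon: float = 1.0
    neighbor_cutoff: float = 1.1
    damping: float = 0.5
    drag: float = 0.01
    dt: float = 0.02
    energy_tol: float = 1e-3
    energy_window: int = 1000
    method: str = "fire"
    force_tol: float = 1e-6
    fire_dt_max: float = 0.2
    max_iter: int = 400_000

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.energy_tol <= 0 or self.dt <= 0:
            raise ValueError("energy_tol and dt must be positive")


_EMPTY_IDX = np.empty(0, dtype=np.int64)
_EMPTY_ANCHOR = np.empty((0, 2), dtype=np.float64)


@dataclass
class ParticleSystem:
    """State of the particle monolayer in a periodic (Lx, Ly) box."""

    positions: np.ndarray           # (N, 2) float, wrapped to [0, L)
    diameters: np.ndarray           # (N,) float, > 0
    box: tuple                      # (Lx, Ly)
    active: np.ndarray = None       # (N,) bool, mesoderm-primordium stripe
    constricted: np.ndarray = None  # (N,) bool
    neighbor_pairs: np.ndarray = None   # (M, 2) int, i < j, fixed after init
    spring_idx: np.ndarray = field(default_factory=lambda: _EMPTY_IDX.copy())
    spring_anchor: np.ndarray = field(default_factory=lambda: _EMPTY_ANCHOR.copy())
    k_eff: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.diameters = np.ascontiguousarray(self.diameters, dtype=np.float64)
        if np.any(self.diameters <= 0):
            raise ValueError("all diameters must be positive")
        n = len(self.diameters)
        if self.active is None:
            self.active = np.zeros(n, dtype=bool)
        if self.constricted is None:
            self.constricted = np.zeros(n, dtype=bool)
        self.wrap()

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def wrap(self) -> None:
        """Fold all coordinates back into [0, Lx) x [0, Ly)."""
        lx, ly = self.box
        self.positions[:, 0] %= lx
        self.positions[:, 1] %= ly

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            diameters=self.diameters.copy(),
            box=tuple(self.box),
            active=self.active.copy(),
            constricted=self.constricted.copy(),
            neighbor_pairs=None if self.neighbor_pairs is None
            else self.neighbor_pairs.copy(),
            spring_idx=self.spring_idx.copy(),
            spring_anchor=self.spring_anchor.copy(),
            k_eff=self.k_eff,
        )

    def minimum_image(self, i: int, j: int) -> np.ndarray:
        """Displacement r_i - r_j under the minimum-image convention."""
        lx, ly = self.box
        d = self.positions[i] - self.positions[j]
        d[0] -= lx * np.rint(d[0] / lx)
        d[1] -= ly * np.rint(d[1] / ly)
        return d

    # ------------------------------------------------------------------
    def candidate_pairs(self, cushion: float = 1.2):
        """Interaction pair arrays (pi, pj, connected) for the kernels.

        The unconnected repulsive branch only acts at r < d_ij, so
        candidate unconnected pairs are collected within
        ``cushion * max(d_ij)`` with a periodic KD-tree; connected pairs
        are always included regardless of distance.
        """
        self.wrap()
        lx, ly = self.box
        rmax = cushion * float(self.diameters.max())
        if rmax >= 0.5 * min(lx, ly):
            # tiny box: every pair is a candidate (no KD-tree, no skin)
            iu = np.triu_indices(self.n, k=1)
            pairs = np.column_stack(iu).astype(np.int64)
        else:
            tree = cKDTree(self.positions, boxsize=(lx, ly))
            pairs = tree.query_pairs(rmax, output_type="ndarray")
        if self.neighbor_pairs is not None and len(self.neighbor_pairs):
            conn_set = self.neighbor_pairs
            # mark candidate pairs that are connected; then append any
            # connected pair that fell outside the search radius
            cand_keys = pairs[:, 0].astype(np.int64) * self.n + pairs[:, 1]
            conn_keys = conn_set[:, 0].astype(np.int64) * self.n + conn_set[:, 1]
            conn_flag = np.isin(cand_keys, conn_keys)
            missing = ~np.isin(conn_keys, cand_keys)
            if missing.any():
                pairs = np.vstack([pairs, conn_set[missing]])
                conn_flag = np.concatenate(
                    [conn_flag, np.ones(int(missing.sum()), dtype=bool)])
        else:
            conn_flag = np.zeros(len(pairs), dtype=bool)
        pi = np.ascontiguousarray(pairs[:, 0], dtype=np.int64)
        pj = np.ascontiguousarray(pairs[:, 1], dtype=np.int64)
        return pi, pj, np.ascontiguousarray(conn_flag)

    # ------------------------------------------------------------------
    # snapshot I/O: CSV of per-particle state + JSON sidecar
    def save(self, prefix) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        header = "id,x,y,diameter,active,constricted"
        rows = np.column_stack([
            np.arange(self.n), self.positions[:, 0], self.positions[:, 1],
            self.diameters, self.active.astype(int), self.constricted.astype(int),
        ])
        np.savetxt(f"{prefix}.csv", rows, delimiter=",", header=header,
                   comments="", fmt=["%d", "%.12g", "%.12g", "%.12g", "%d", "%d"])
        if self.neighbor_pairs is not None:
            np.savetxt(f"{prefix}_neighbors.csv", self.neighbor_pairs,
                       delimiter=",", header="i,j", comments="", fmt="%d")
        meta = {"box": list(self.box), "n": self.n, "k_eff": self.k_eff}
        Path(f"{prefix}.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix) -> "ParticleSystem":
        prefix = Path(prefix)
        rows = np.loadtxt(f"{prefix}.csv", delimiter=",", skiprows=1, ndmin=2)
        meta = json.loads(Path(f"{prefix}.json").read_text())
        pairs_path = Path(f"{prefix}_neighbors.csv")
        pairs = None
        if pairs_path.exists():
            pairs = np.loadtxt(pairs_path, delimiter=",", skiprows=1,
                               dtype=np.int64, ndmin=2)
        return cls(positions=rows[:, 1:3], diameters=rows[:, 3],
                   box=tuple(meta["box"]), active=rows[:, 4].astype(bool),
                   constricted=rows[:, 5].astype(bool), neighbor_pairs=pairs,
                   k_eff=float(meta.get("k_eff", 0.0)))
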