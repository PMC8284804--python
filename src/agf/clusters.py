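"""Constricted-cell cluster statistics, disruption recovery, and theory.

Clusters are connected components of the constricted cells on the fixed
connected-neighbor graph.  The summary statistics mirror the ones used
to compare model and embryo:

* C_norm = N_clu / N_a0        normalized cluster count (its replicate
  average is C_ave),
* eta_s, eta_d, eta_m          fractions of constricted cells in
  singlets (size 1), doublets (2) and multiplets (>= 3),
* %N_c = N_c / N_a0            fraction of active cells constricted.

The constriction perturbation coefficient chi_cp = <%N_c^test>/<%N_c^ref>
quantifies how well a disrupted region keeps up with the unaffected
tissue (1 = full recovery).  For uncorrelated random constrictions the
whole process is a pair of exponential saturation laws,

    %N_c^t = 1 - exp(-alpha_r tau),   %N_c^u = 1 - exp(-tau),
    %N_c   = q %N_c^t + (1 - q) %N_c^u,

with tau a rescaled time and q the affected fraction of active cells,
which gives chi_cp in closed form at any global %N_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ClusterReport", "ChiReport", "identify_clusters", "cluster_report",
    "chi_cp", "chi_ellipse_suite", "random_theory_chi",
    "random_theory_chi_EB",
]


@dataclass
class ClusterReport:
    """Cluster-size statistics of one frame/snapshot."""

    n_clusters: int
    n_active_total: int
    n_constricted: int
    n_in_singlets: int
    n_in_doublets: int
    n_in_multiplets: int

    @property
    def c_norm(self) -> float:
        return self.n_clusters / self.n_active_total

    @property
    def pct_nc(self) -> float:
        return self.n_constricted / self.n_active_total

    def _eta(self, count: int):
        return count / self.n_constricted if self.n_constricted else None

    @property
    def eta_s(self):
        return self._eta(self.n_in_singlets)

    @property
    def eta_d(self):
        return self._eta(self.n_in_doublets)

    @property
    def eta_m(self):
        return self._eta(self.n_in_multiplets)


def identify_clusters(constricted_ids, neighbor_pairs) -> list:
    """Connected components of constricted cells on the fixed graph.

    Returns a list of sorted id lists, ordered by smallest member id.
    """
    cset = set(int(i) for i in constricted_ids)
    g = nx.Graph()
    g.add_nodes_from(cset)
    for a, b in np.asarray(neighbor_pairs).reshape(-1, 2):
        a, b = int(a), int(b)
        if a in cset and b in cset:
            g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def cluster_report(clusters, n_active_total: int) -> ClusterReport:
    """Classify clusters into singlets/doublets/multiplets and count cells."""
    sizes = np.array([len(c) for c in clusters], dtype=int)
    n_c = int(sizes.sum())
    if n_active_total < n_c:
        raise ValueError("n_active_total smaller than constricted count")
    return ClusterReport(
        n_clusters=len(clusters),
        n_active_total=n_active_total,
        n_constricted=n_c,
        n_in_singlets=int(sizes[sizes == 1].sum()),
        n_in_doublets=int(sizes[sizes == 2].sum()),
        n_in_multiplets=int(sizes[sizes >= 3].sum()),
    )


def trajectory_cluster_report(traj, level: float) -> ClusterReport:
    """Cluster report of a trajectory at the first snapshot with %N_c >= level."""
    ids = traj.constricted_at_level(level)
    clusters = identify_clusters(ids, traj.initial.neighbor_pairs)
    return cluster_report(clusters, traj.n_active0)


# ----------------------------------------------------------------------
@dataclass
class ChiReport:
    """Ratio of mean constricted fractions, test vs reference region."""

    chi: float
    se: float
    pct_nc_test: float
    pct_nc_ref: float
    n_replicates: int


def _region_fractions(traj, test_mask, ref_mask, level):
    active = traj.initial.active
    test_ids = np.flatnonzero(active & test_mask)
    ref_ids = np.flatnonzero(active & ref_mask)
    if ref_ids.size == 0:
        raise ValueError("reference region has no active cells")
    if test_ids.size == 0:
        raise ValueError("test region has no active cells")
    con = np.zeros(traj.initial.n, dtype=bool)
    con[traj.constricted_at_level(level)] = True
    return con[test_ids].mean(), con[ref_ids].mean()


def _ratio_of_means(t, u, n) -> tuple:
    """Delta-method SE for mean(t)/mean(u) over replicates."""
    tbar, ubar = t.mean(), u.mean()
    chi = tbar / ubar
    if n > 1:
        var_t = t.var(ddof=1) / n
        var_u = u.var(ddof=1) / n
        cov = np.cov(t, u, ddof=1)[0, 1] / n
        var = (var_t / ubar ** 2 + tbar ** 2 * var_u / ubar ** 4
               - 2 * tbar * cov / ubar ** 3)
        se = float(np.sqrt(max(var, 0.0)))
    else:
        se = float("nan")
    return float(chi), se, float(tbar), float(ubar)


def chi_cp(trajectories, test_mask, ref_mask, at_pct_nc: float) -> ChiReport:
    """Constriction perturbation coefficient over replicate trajectories.

    At the first snapshot of each trajectory where the global %N_c
    reaches ``at_pct_nc``, the constricted fractions of the test and
    reference regions are recorded; chi is the ratio of their replicate
    means with a delta-method standard error.
    """
    fracs = np.array([_region_fractions(tr, test_mask, ref_mask, at_pct_nc)
                      for tr in trajectories])
    chi, se, tbar, ubar = _ratio_of_means(fracs[:, 0], fracs[:, 1], len(fracs))
    return ChiReport(chi=chi, se=se, pct_nc_test=tbar, pct_nc_ref=ubar,
                     n_replicates=len(fracs))


def chi_ellipse_suite(trajectories, spec, at_pct_nc: float) -> dict:
    """chi_E (ellipse), chi_B (bypass), chi_EB (whole strip) vs outside.

    ``spec`` is the elliptical DisruptionSpec; the reference region is
    the active tissue outside the ellipse's bounding vertical strip.
    """
    sys0 = trajectories[0].initial
    ellipse = spec.region_mask(sys0)
    strip = spec.strip_mask(sys0)
    bypass = strip & ~ellipse
    outside = ~strip
    out = {}
    for name, mask in (("chi_E", ellipse), ("chi_B", bypass),
                       ("chi_EB", strip)):
        out[name] = chi_cp(trajectories, mask, outside, at_pct_nc)
    return out


# ----------------------------------------------------------------------
def random_theory_chi(alpha_r: float, q: float, pct_nc: float):
    """Closed-form (tau, chi_cp) for uncorrelated random constrictions.

    Solves q(1-e^{-alpha_r tau}) + (1-q)(1-e^{-tau}) = pct_nc for tau by
    bracketed root finding and returns chi = (1-e^{-alpha_r tau}) /
    (1-e^{-tau}).  chi -> alpha_r as pct_nc -> 0, and chi -> 1 as the
    unaffected region saturates.
    """
    if not (0 <= alpha_r <= 1):
        raise ValueError("alpha_r must lie in [0, 1]")
    if not (0 <= q < 1):
        raise ValueError("q must lie in [0, 1)")
    if not (0 <= pct_nc < 1):
        raise ValueError("pct_nc must lie in [0, 1)")
    limit = q * (1.0 if alpha_r > 0 else 0.0) + (1 - q)
    if pct_nc >= limit - 1e-12 and pct_nc > 0:
        raise ValueError(
            f"pct_nc={pct_nc} unreachable: saturation limit {limit}")
    if pct_nc == 0:
        return 0.0, alpha_r if alpha_r >= 0 else 0.0

    def f(tau):
        return (q * (1 - np.exp(-alpha_r * tau))
                + (1 - q) * (1 - np.exp(-tau)) - pct_nc)

    hi = 50.0
    while f(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("failed to bracket tau")
    tau = brentq(f, 0.0, hi, rtol=1e-10)
    chi = (1 - np.exp(-alpha_r * tau)) / (1 - np.exp(-tau))
    return float(tau), float(chi)


def random_theory_chi_EB(alpha_r: float, q: float, b_frac: float,
                         pct_nc: float) -> float:
    """Closed-form chi for the combined affected + bypass strip.

    With the bypass unaffected (chi_B = 1), chi_EB = b chi_cp + (1 - b)
    where b is the affected fraction of the strip.
    """
    if not (0 <= b_frac <= 1):
        raise ValueError("b_frac must lie in [0, 1]")
    if pct_nc == 0:
        return b_frac * alpha_r + (1 - b_frac)
    _, chi = random_theory_chi(alpha_r, q, pct_nc)
    return float(b_frac * chi + (1 - b_frac))
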