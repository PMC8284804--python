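"""Bidisperse jammed packings and quasistatic relaxation.

The initial tissue is a disordered, mechanically stable 50/50 mixture of
soft disks with diameter ratio 1.1 in a periodic square box, prepared by
seeding particles at low area fraction and inflating their diameters with
an energy minimization after each inflation step.  The box size is fixed
so that the final state sits at a prescribed area fraction (default
0.845, just above the jamming point of the bidisperse mixture: a random
close-packed state) with the mean large diameter equal to one, which
sets the unit of length.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .system import InteractionModel, ParticleSystem

__all__ = [
    "generate_initial_packing",
    "mark_active_region",
    "build_neighbor_list",
    "pair_force",
    "relax",
    "potential_energy",
    "net_forces",
    "attach_implicit_mesoderm",
]


def pair_force(r_ij: float, d_ij: float, connected: bool,
               model: InteractionModel | None = None) -> float:
    """Radial spring force between two cells; positive = repulsive.

    Connected neighbors feel the full spring f = (eps/d_ij)(1 - r/d_ij)
    (attractive beyond the rest length d_ij, repulsive inside it);
    unconnected cells feel only the repulsive branch r < d_ij.
    """
    eps = 1.0 if model is None else model.epsilon
    if r_ij <= 0:
        raise ValueError("separation must be positive")
    if d_ij <= 0:
        raise ValueError("mean diameter must be positive")
    if not connected and r_ij >= d_ij:
        return 0.0
    return (eps / d_ij) * (1.0 - r_ij / d_ij)


def _spring_args(system: ParticleSystem):
    return (system.spring_idx.astype(np.int64), system.spring_anchor,
            float(system.k_eff))


def net_forces(system: ParticleSystem,
               model: InteractionModel | None = None) -> np.ndarray:
    """Net conservative force on every particle at the current positions."""
    model = model or InteractionModel()
    pi, pj, conn = system.candidate_pairs()
    forces = np.zeros_like(system.positions)
    _kernels.compute_forces(system.positions, system.diameters, pi, pj, conn,
                            system.box[0], system.box[1], model.epsilon,
                            *_spring_args(system), forces)
    return forces


def potential_energy(system: ParticleSystem,
                     model: InteractionModel | None = None) -> float:
    model = model or InteractionModel()
    pi, pj, conn = system.candidate_pairs()
    return float(_kernels.potential_energy(
        system.positions, system.diameters, pi, pj, conn,
        system.box[0], system.box[1], model.epsilon, *_spring_args(system)))


def _minimize(system: ParticleSystem, model: InteractionModel,
              pairs=None, method: str | None = None,
              force_tol: float | None = None,
              cushion: float = 1.4) -> None:
    """Minimize the potential energy in place with the configured method.

    The interaction pair list is a truncated candidate list (unconnected
    pairs only act at r < d_ij), so the kernels track particle
    displacement against a Verlet skin and hand control back whenever a
    particle moved far enough that the list may miss a new contact; the
    list is then rebuilt and the minimization resumes.  Passing a fixed
    ``pairs`` list disables the refresh (the caller guarantees validity).
    """
    lx, ly = system.box
    method = method or model.method
    fixed = pairs is not None
    dmax = float(system.diameters.max())
    # pairs beyond cushion*dmax can first touch (r < d_ij <= dmax) only
    # after a joint displacement of (cushion-1)*dmax
    max_disp = 0.45 * (cushion - 1.0) * dmax if not fixed else 1e18
    if cushion * dmax >= 0.5 * min(lx, ly):
        max_disp = 1e18     # candidate list is all pairs: never stale
    # stiff boundary tethers shrink the stable timestep
    dt = model.dt
    dt_max = model.fire_dt_max
    if system.k_eff > 0:
        dt = min(dt, 0.5 / np.sqrt(system.k_eff))
        dt_max = min(dt_max, 10 * dt)
    total = 0
    stalls = 0
    while total < model.max_iter:
        plist = pairs if fixed else system.candidate_pairs(cushion=cushion)
        pi, pj, conn = plist
        budget = model.max_iter - total
        if method == "fire":
            ftol = model.force_tol if force_tol is None else force_tol
            it, _, status = _kernels.fire_minimize(
                system.positions, system.diameters, pi, pj, conn, lx, ly,
                model.epsilon, *_spring_args(system),
                dt, dt_max, ftol, min(budget, 100_000), max_disp)
        elif method == "damped_verlet":
            it, _, status = _kernels.damped_verlet_minimize(
                system.positions, system.diameters, pi, pj, conn, lx, ly,
                model.epsilon, *_spring_args(system),
                dt, model.damping, model.drag,
                model.energy_tol, model.energy_window, budget, max_disp)
        else:
            raise ValueError(f"unknown relaxation method: {method!r}")
        total += it
        system.wrap()
        if status == 0:
            return
        # status 1: pair list invalidated by motion -> rebuild and resume;
        # status 2: local budget exhausted -> FIRE can limit-cycle on flat
        # or degenerate landscapes; a burst of physically damped dynamics
        # breaks the cycle before retrying
        if status == 2:
            if method != "fire" or stalls >= 4:
                break
            stalls += 1
            _kernels.damped_verlet_minimize(
                system.positions, system.diameters, pi, pj, conn, lx, ly,
                model.epsilon, *_spring_args(system),
                dt, model.damping, model.drag,
                model.energy_tol, model.energy_window, 5000, max_disp)
            system.wrap()
    raise RuntimeError(
        f"{method} minimization did not converge within {model.max_iter} "
        f"iterations")


def relax(system: ParticleSystem, model: InteractionModel | None = None,
          method: str | None = None) -> ParticleSystem:
    """Relax the system to its potential-energy minimum (in place).

    The default method follows ``model.method``: damped velocity-Verlet
    dynamics (pairwise dissipation b, energy-window stopping rule) or the
    faster FIRE minimizer with a force criterion.  Both drive the system
    to the same quasistatic minimum; the choice only affects numerical
    efficiency.  Raises RuntimeError if the iteration budget is exceeded.
    """
    model = model or InteractionModel()
    _minimize(system, model, method=method)
    return system


def generate_initial_packing(n_total: int, diameter_ratio: float = 1.1,
                             seed: int = 0, target_phi: float = 0.845,
                             model: InteractionModel | None = None,
                             force_tol: float = 1e-8,
                             n_inflation_steps: int = 24) -> ParticleSystem:
    """Build a mechanically stable bidisperse packing in a periodic box.

    floor(n/2) small and ceil(n/2) large particles (diameter ratio
    ``diameter_ratio``) are seeded uniformly at random, then inflated to
    the target area fraction with a force minimization after each
    inflation step, and finally polished until max|F| < ``force_tol``.
    Lengths are rescaled so the large diameter is exactly 1.
    """
    if n_total < 2:
        raise ValueError("need at least two particles")
    if diameter_ratio < 1:
        raise ValueError("diameter_ratio must be >= 1")
    model = model or InteractionModel()
    rng = np.random.default_rng(seed)

    n_small = n_total // 2
    diam = np.ones(n_total)
    diam[:n_small] = 1.0 / diameter_ratio
    rng.shuffle(diam)
    # box for the final state: phi = (pi/4) sum d_i^2 / L^2 with d_large = 1
    area = np.pi / 4.0 * float(np.sum(diam ** 2))
    box_l = float(np.sqrt(area / target_phi))
    # the minimum-image convention requires the box to exceed twice the
    # largest interaction range; tiny systems are packed more loosely
    min_box = 2.0 * model.neighbor_cutoff * float(diam.max())
    box_l = max(box_l, min_box)
    system = ParticleSystem(
        positions=rng.uniform(0.0, box_l, size=(n_total, 2)),
        diameters=diam.copy(), box=(box_l, box_l))

    # grow diameters from ~60% of final size (area fraction ~0.34); small
    # systems get a larger iteration budget: near-degenerate few-particle
    # landscapes converge by slow creep, but their iterations are cheap
    if n_total < 200:
        import dataclasses
        model = dataclasses.replace(model, max_iter=20_000_000)
    scales = np.linspace(0.6, 1.0, n_inflation_steps)
    for k, s in enumerate(scales):
        system.diameters = diam * s
        # loose tolerance while growing, tight at the end
        ftol = 1e-3 if k < n_inflation_steps - 1 else force_tol
        try:
            _minimize(system, model, method="fire", force_tol=ftol,
                      cushion=1.4)
        except RuntimeError as err:
            if k == n_inflation_steps - 1:
                raise RuntimeError(
                    f"packing polish did not converge: {err}") from err
            # intermediate stages need not fully converge
    system.diameters = diam
    return system


def mark_active_region(system: ParticleSystem,
                       stripe_width: float) -> ParticleSystem:
    """Flag the central horizontal stripe of the given width as active.

    The mesoderm primordium is a band about 12 cell diameters wide
    spanning the box in x; particles with y inside
    [Ly/2 - w/2, Ly/2 + w/2) become active.
    """
    ly = system.box[1]
    if stripe_width > ly:
        raise ValueError("stripe_width exceeds the box height")
    cy = ly / 2.0
    y = system.positions[:, 1]
    mask = (y >= cy - stripe_width / 2.0) & (y < cy + stripe_width / 2.0)
    if not mask.any():
        raise ValueError("active stripe selects zero particles")
    system.active = mask
    return system


def build_neighbor_list(system: ParticleSystem,
                        cutoff_ratio: float = 1.1) -> ParticleSystem:
    """Fix the connected-neighbor list from the relaxed initial state.

    Pairs with minimum-image r_ij / d_ij < cutoff_ratio become connected
    neighbors; the list never changes afterwards (no intercalation).
    """
    from scipy.spatial import cKDTree

    system.wrap()
    lx, ly = system.box
    dmax = float(system.diameters.max())
    tree = cKDTree(system.positions, boxsize=(lx, ly))
    pairs = tree.query_pairs(cutoff_ratio * dmax, output_type="ndarray")
    if len(pairs):
        d = system.positions[pairs[:, 0]] - system.positions[pairs[:, 1]]
        d[:, 0] -= lx * np.rint(d[:, 0] / lx)
        d[:, 1] -= ly * np.rint(d[:, 1] / ly)
        r = np.hypot(d[:, 0], d[:, 1])
        dij = 0.5 * (system.diameters[pairs[:, 0]] + system.diameters[pairs[:, 1]])
        pairs = pairs[r / dij < cutoff_ratio]
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    system.neighbor_pairs = np.ascontiguousarray(pairs[order], dtype=np.int64)
    return system


def attach_implicit_mesoderm(system: ParticleSystem, explicit_margin: float,
                             k_eff: float,
                             border_depth: float = 1.5) -> ParticleSystem:
    """Replace the outer inactive region by elastic boundary tethers.

    Particles farther than ``explicit_margin`` from the box mid-line are
    removed; retained particles within ``border_depth`` of the new border
    are tethered to their current positions by springs of constant
    ``k_eff`` that stand in for the elastic response of the removed
    lateral tissue.  Returns a new, reindexed system.
    """
    if k_eff <= 0:
        raise ValueError("k_eff must be positive")
    lx, ly = system.box
    if explicit_margin >= ly / 2.0:
        raise ValueError("explicit_margin must be smaller than Ly/2 "
                         "(otherwise there is nothing to replace)")
    cy = ly / 2.0
    dy = np.abs(system.positions[:, 1] - cy)
    keep = dy <= explicit_margin
    if not keep.any():
        raise ValueError("no particles retained")
    idx_map = -np.ones(system.n, dtype=np.int64)
    idx_map[keep] = np.arange(int(keep.sum()))
    pairs = system.neighbor_pairs
    if pairs is not None and len(pairs):
        ok = keep[pairs[:, 0]] & keep[pairs[:, 1]]
        pairs = idx_map[pairs[ok]]
    border = keep & (dy > explicit_margin - border_depth)
    spring_idx = idx_map[np.flatnonzero(border)]
    new = ParticleSystem(
        positions=system.positions[keep].copy(),
        diameters=system.diameters[keep].copy(),
        box=(lx, ly),
        active=system.active[keep].copy(),
        constricted=system.constricted[keep].copy(),
        neighbor_pairs=pairs,
        spring_idx=spring_idx,
        spring_anchor=system.positions[keep][spring_idx].copy(),
        k_eff=float(k_eff),
    )
    return new
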