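"""Quasistatic stochastic constriction process with tensile-stress feedback.

Active cells constrict stochastically, one simulation step at a time.  At
each step the constriction probability of an unconstricted active cell i
is

    P_i = alpha_i (1 + beta s_i) / (N_a (1 + beta)),

where N_a is the current number of unconstricted active cells, beta >= 0
the stress-coupling constant, and

    s_i = (sigma_i / sigma_ref)^p   for sigma_i > 0, else 0

the tensile-feedback parameter built from the triggering stress sigma_i
of the relaxed pre-step configuration.  sigma_ref is the mean tensile
stress a single constricted cell experiences in the initial state, so
s ~ 1 marks stresses comparable to one constriction event.  Successful
cells shrink their diameter once and permanently (d -> f_c d, a ratcheted
constriction) and the system is mechanically relaxed, keeping the process
quasistatic.  beta = 0 recovers uncorrelated random constrictions, in
which case the pattern statistics do not depend on the mechanics at all.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .packing import _minimize
from .stress import stress_field
from .system import InteractionModel, ParticleSystem

logger = logging.getLogger(__name__)

__all__ = [
    "FeedbackConfig", "DisruptionSpec", "NeighborTriggerConfig", "Trajectory",
    "feedback_parameter", "constriction_probability", "calibrate_sigma_ref",
    "apply_disruption", "constriction_step", "neighbor_trigger_probability",
    "run_simulation",
]


@dataclass
class FeedbackConfig:
    """Parameters of the stochastic constriction feedback."""

    p: float = 3.0                  # stress-sensitivity exponent
    beta: float = 250.0             # stress-coupling constant (0 = random)
    f_c: float = 0.6                # diameter constriction factor
    sigma_ref: float | None = None  # calibrated reference tensile stress
    alpha: float | np.ndarray = 1.0  # per-cell probability amplitude
    target_fraction: float = 0.4    # stop when %N_c reaches this

    def __post_init__(self):
        if self.p < 0 or self.beta < 0:
            raise ValueError("p and beta must be non-negative")
        if not (0 < self.f_c <= 1):
            raise ValueError("f_c must lie in (0, 1]")
        if self.sigma_ref is not None and self.sigma_ref <= 0:
            raise ValueError("sigma_ref must be positive")

    def alpha_array(self, n: int) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        out = np.broadcast_to(a, (n,)).copy() if a.ndim else np.full(n, float(a))
        if np.any(out < 0):
            raise ValueError("alpha amplitudes must be non-negative")
        return out


@dataclass
class DisruptionSpec:
    """Region of reduced constriction-probability amplitude.

    shape "band": vertical band x in [x0, x1); shape "ellipse": region
    ((x-cx)/ax)^2 + ((y-cy)/ay)^2 <= 1.  alpha_r in [0, 1] is the reduced
    amplitude inside the region.  ``q`` (fraction of active cells inside
    the region) and ``b_frac`` (affected fraction of the affected+bypass
    strip) are filled in by :func:`apply_disruption`.
    """

    shape: str = "none"
    x_interval: tuple | None = None
    center: tuple | None = None
    semi_axes: tuple | None = None
    alpha_r: float = 1.0
    q: float | None = field(default=None, compare=False)
    b_frac: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not (0 <= self.alpha_r <= 1):
            raise ValueError("alpha_r must lie in [0, 1]")
        if self.shape not in ("none", "band", "ellipse"):
            raise ValueError(f"unknown disruption shape {self.shape!r}")

    def region_mask(self, system: ParticleSystem) -> np.ndarray:
        """Particles whose center lies in the disrupted region."""
        x, y = system.positions[:, 0], system.positions[:, 1]
        if self.shape == "none":
            return np.zeros(system.n, dtype=bool)
        if self.shape == "band":
            x0, x1 = self.x_interval
            return (x >= x0) & (x < x1)
        cx, cy = self.center
        ax, ay = self.semi_axes
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0

    def strip_mask(self, system: ParticleSystem) -> np.ndarray:
        """Vertical strip bounding the region (band itself, or the
        ellipse's bounding strip = affected + bypass cells)."""
        x = system.positions[:, 0]
        if self.shape == "band":
            x0, x1 = self.x_interval
        elif self.shape == "ellipse":
            x0, x1 = self.center[0] - self.semi_axes[0], \
                self.center[0] + self.semi_axes[0]
        else:
            return np.zeros(system.n, dtype=bool)
        return (x >= x0) & (x < x1)


@dataclass
class NeighborTriggerConfig:
    """Constriction enhancement by already-constricted neighbors.

    The probability of an unconstricted active cell with n_c constricted
    connected neighbors is multiplied by beta_cn = 1 + slope * n_c.
    """

    slope: float = 3.33

    def __post_init__(self):
        if self.slope < 0:
            raise ValueError("slope must be non-negative")


def feedback_parameter(sigma_i, config: FeedbackConfig):
    """s_i = (sigma_i/sigma_ref)^p for tensile sigma_i, else 0 (vectorized)."""
    if config.sigma_ref is None or config.sigma_ref <= 0:
        raise ValueError("sigma_ref must be calibrated (positive)")
    sig = np.asarray(sigma_i, dtype=float)
    s = np.where(sig > 0, (np.maximum(sig, 0) / config.sigma_ref) ** config.p, 0.0)
    return float(s) if np.isscalar(sigma_i) else s


def constriction_probability(s_i, alpha_i, beta: float,
                             n_active_unconstricted: int):
    """P_i = alpha_i (1 + beta s_i) / (N_a (1 + beta)), capped at 1."""
    if n_active_unconstricted < 1:
        raise ValueError("need at least one unconstricted active cell")
    alpha = np.asarray(alpha_i, dtype=float)
    if np.any(alpha < 0):
        raise ValueError("alpha must be non-negative")
    p = alpha * (1.0 + beta * np.asarray(s_i, dtype=float)) \
        / (n_active_unconstricted * (1.0 + beta))
    if np.any(p > 1.0):
        warnings.warn("constriction probability capped at 1; the process is "
                      "no longer quasistatic", stacklevel=2)
        p = np.minimum(p, 1.0)
    return float(p) if np.isscalar(s_i) and np.ndim(alpha_i) == 0 else p


def neighbor_trigger_probability(n_constricted_neighbors: int, base: float,
                                 config: NeighborTriggerConfig) -> float:
    """base * (1 + slope n_c), capped at 1."""
    if not (0 <= base <= 1):
        raise ValueError("base probability must lie in [0, 1]")
    return min(1.0, base * (1.0 + config.slope * n_constricted_neighbors))


# ----------------------------------------------------------------------
def calibrate_sigma_ref(reference_system: ParticleSystem,
                        config: FeedbackConfig,
                        n_trials: int = 50, seed: int = 0,
                        model: InteractionModel | None = None) -> float:
    """Mean tensile stress on a single cell constricted in the initial state.

    For ``n_trials`` randomly chosen active cells: constrict that cell
    alone (d -> f_c d), relax, record its triggering stress, restore.
    The mean is the normalization sigma_ref of the feedback parameter.
    """
    model = model or InteractionModel()
    if config.f_c >= 1.0:
        raise ValueError("f_c = 1 is a no-op constriction; the reference "
                         "stress of a constriction event is undefined")
    rng = np.random.default_rng(seed)
    active_ids = np.flatnonzero(reference_system.active)
    if active_ids.size == 0:
        raise ValueError("reference system has no active cells")
    n_trials = min(n_trials, active_ids.size)
    chosen = rng.choice(active_ids, size=n_trials, replace=False)
    work = reference_system.copy()
    pos0 = work.positions.copy()
    diam0 = work.diameters.copy()
    vals = np.empty(n_trials)
    for t, i in enumerate(chosen):
        work.positions[:] = pos0
        work.diameters[:] = diam0
        work.diameters[i] *= config.f_c
        _minimize(work, model)
        sigma, _ = stress_field(work, model)
        vals[t] = sigma[i]
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError(
            f"calibrated sigma_ref is not positive ({mean:.3g}); a single "
            "constriction must leave the constricted cell under net tension")
    return mean


def apply_disruption(config: FeedbackConfig, spec: DisruptionSpec,
                     system: ParticleSystem) -> FeedbackConfig:
    """Reduce alpha to alpha_r for active cells inside the disrupted region.

    Also records the geometry fractions used by the closed-form theory:
    q = affected/active and b_frac = affected/(affected + bypass in the
    bounding strip).
    """
    region = spec.region_mask(system)
    affected = region & system.active
    if spec.shape != "none" and not affected.any():
        raise ValueError("disrupted region contains no active cells")
    alpha = config.alpha_array(system.n)
    alpha[affected] = spec.alpha_r
    n_active = int(system.active.sum())
    spec.q = float(affected.sum() / n_active) if n_active else 0.0
    strip = spec.strip_mask(system) & system.active
    spec.b_frac = float(affected.sum() / strip.sum()) if strip.any() else 0.0
    return replace(config, alpha=alpha)


# ----------------------------------------------------------------------
class _Workspace:
    """Cached stresses between constriction events."""

    def __init__(self, system: ParticleSystem, model: InteractionModel):
        self.model = model
        self.sigma = None

    def relax(self, system: ParticleSystem) -> None:
        _minimize(system, self.model)

    def stresses(self, system: ParticleSystem) -> np.ndarray:
        if self.sigma is None:
            pi, pj, conn = system.candidate_pairs()
            self.sigma, _ = _kernels.stress_sums(
                system.positions, system.diameters, pi, pj, conn,
                system.box[0], system.box[1], self.model.epsilon)
        return self.sigma

    def invalidate(self) -> None:
        self.sigma = None


def constriction_step(system: ParticleSystem, config: FeedbackConfig,
                      model: InteractionModel | None = None,
                      rng: np.random.Generator | None = None,
                      workspace: _Workspace | None = None):
    """One step of the stochastic process; returns (system, new_ids).

    Stresses, feedback parameters and probabilities are all evaluated at
    the relaxed pre-step configuration; every candidate draws one uniform
    variate; all successes constrict simultaneously (d_i -> f_c d_i,
    permanently), followed by a single relaxation.
    """
    model = model or InteractionModel()
    rng = rng or np.random.default_rng()
    ws = workspace or _Workspace(system, model)
    candidates = np.flatnonzero(system.active & ~system.constricted)
    if candidates.size == 0:
        return system, []
    alpha = config.alpha_array(system.n)[candidates]
    if config.beta > 0:
        sigma = ws.stresses(system)[candidates]
        s = feedback_parameter(sigma, config)
    else:
        s = np.zeros(candidates.size)
    probs = constriction_probability(s, alpha, config.beta, candidates.size)
    hit = rng.random(candidates.size) < probs
    new_ids = candidates[hit]
    if new_ids.size:
        system.diameters[new_ids] *= config.f_c
        system.constricted[new_ids] = True
        ws.relax(system)
        ws.invalidate()
    return system, list(map(int, new_ids))


@dataclass
class Trajectory:
    """Ordered record of one constriction run.

    ``events`` is a list of (step, [constricted ids]); since constricted
    cells never unconstrict, the constricted set at any %N_c level is a
    prefix of the concatenated event ids.
    """

    initial: ParticleSystem
    final: ParticleSystem
    events: list
    n_active0: int
    sigma_ref: float | None
    seed: int | None = None
    snapshots: dict = field(default_factory=dict)   # level -> ParticleSystem
    #: per constricted cell: (step, id, sigma_i, s_i, P_i) at its event
    event_details: list = field(default_factory=list)

    @property
    def constricted_order(self) -> np.ndarray:
        ids = [i for _, ids in self.events for i in ids]
        return np.asarray(ids, dtype=np.int64)

    def pct_nc_final(self) -> float:
        return len(self.constricted_order) / self.n_active0

    def constricted_at_level(self, level: float) -> np.ndarray:
        """Constricted ids at the first event where %N_c >= level."""
        order = self.constricted_order
        need = int(np.ceil(level * self.n_active0))
        if need == 0:
            return order[:0]
        if len(order) < need:
            raise ValueError(f"trajectory never reached %N_c = {level}")
        # complete the event that crossed the threshold
        count = 0
        for _, ids in self.events:
            count += len(ids)
            if count >= need:
                break
        return order[:count]


def run_simulation(system: ParticleSystem, config: FeedbackConfig,
                   model: InteractionModel | None = None,
                   seed: int = 0, mechanics: bool = True,
                   snapshot_levels=(), max_steps: int = 2_000_000,
                   max_idle_steps: int = 200_000,
                   neighbor_trigger: NeighborTriggerConfig | None = None,
                   ) -> Trajectory:
    """Run constriction steps until %N_c reaches the target fraction.

    ``mechanics=False`` skips all relaxations and stress evaluations;
    this is exact for beta = 0 (and for the neighbor-trigger variant),
    whose constriction pattern statistics do not depend on the mechanics.
    Fully reproducible from ``seed``.
    """
    model = model or InteractionModel()
    if config.beta > 0 and neighbor_trigger is None:
        if not mechanics:
            raise ValueError("beta > 0 requires mechanics")
        if config.sigma_ref is None:
            raise ValueError("sigma_ref must be calibrated before running "
                             "a stress-sensitive simulation")
    rng = np.random.default_rng(seed)
    initial = system.copy()
    work = system.copy()
    n_active0 = int(work.active.sum())
    if n_active0 == 0:
        raise ValueError("system has no active cells")
    ws = _Workspace(work, model) if mechanics else None
    events: list = []
    details: list = []
    snapshots: dict = {}
    pending_levels = sorted(snapshot_levels)
    alpha_full = config.alpha_array(work.n)
    target = config.target_fraction
    n_constricted = 0
    idle = 0
    step = 0
    if alpha_full[work.active & ~work.constricted].sum() == 0 and target > 0:
        raise RuntimeError("all active cells have alpha = 0; "
                           "no constriction can ever occur")
    while n_constricted < target * n_active0 and step < max_steps:
        step += 1
        candidates = np.flatnonzero(work.active & ~work.constricted)
        if candidates.size == 0:
            break
        alpha = alpha_full[candidates]
        if neighbor_trigger is not None:
            n_c = _constricted_neighbor_counts(work, candidates)
            base = alpha / candidates.size
            probs = np.minimum(1.0, base * (1.0 + neighbor_trigger.slope * n_c))
        elif config.beta > 0:
            sigma = ws.stresses(work)[candidates]
            s = feedback_parameter(sigma, config)
            probs = constriction_probability(s, alpha, config.beta,
                                             candidates.size)
        else:
            probs = constriction_probability(
                np.zeros(candidates.size), alpha, 0.0, candidates.size)
        hit = rng.random(candidates.size) < probs
        new_ids = candidates[hit]
        if new_ids.size == 0:
            idle += 1
            if idle >= max_idle_steps:
                raise RuntimeError(
                    f"no constriction for {max_idle_steps} consecutive steps "
                    f"at %N_c = {n_constricted / n_active0:.3f}; "
                    "check alpha/beta settings")
            continue
        idle = 0
        hit_idx = np.flatnonzero(hit)
        if config.beta > 0 and neighbor_trigger is None:
            for k in hit_idx:
                details.append((step, int(candidates[k]), float(sigma[k]),
                                float(s[k]), float(probs[k])))
        else:
            for k in hit_idx:
                details.append((step, int(candidates[k]), 0.0, 0.0,
                                float(np.atleast_1d(probs)[k])))
        work.diameters[new_ids] *= config.f_c
        work.constricted[new_ids] = True
        if mechanics:
            ws.relax(work)
            ws.invalidate()
        events.append((step, list(map(int, new_ids))))
        n_constricted += int(new_ids.size)
        logger.info("step %d: %%N_c=%.3f (+%d)", step,
                    n_constricted / n_active0, new_ids.size)
        while pending_levels and n_constricted >= pending_levels[0] * n_active0:
            snapshots[pending_levels.pop(0)] = work.copy()
    if n_constricted < target * n_active0:
        raise RuntimeError(
            f"step budget exhausted at %N_c = {n_constricted / n_active0:.3f} "
            f"< target {target}")
    return Trajectory(initial=initial, final=work, events=events,
                      n_active0=n_active0, sigma_ref=config.sigma_ref,
                      seed=seed, snapshots=snapshots, event_details=details)


def _constricted_neighbor_counts(system: ParticleSystem,
                                 candidates: np.ndarray) -> np.ndarray:
    """Number of constricted connected neighbors for each candidate."""
    counts = np.zeros(system.n, dtype=np.int64)
    pairs = system.neighbor_pairs
    if pairs is not None and len(pairs):
        con = system.constricted
        np.add.at(counts, pairs[:, 0], con[pairs[:, 1]])
        np.add.at(counts, pairs[:, 1], con[pairs[:, 0]])
    return counts[candidates]
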