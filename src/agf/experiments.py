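"""Experiment orchestration: presets, replicate ensembles, run manifests.

An :class:`ExperimentConfig` bundles everything needed to reproduce a
constriction study: packing geometry, interaction/relaxation parameters,
feedback parameters, and an optional disruption template.  A master seed
deterministically derives the packing seed, the calibration seed and one
child seed per replicate, so a whole ensemble is reproducible from a
single integer.

The reduced scale (default) uses a 1,600-particle box with the 12-wide
active stripe, i.e. the full-scale geometry with the stripe length and
inactive margins halved; the full scale is the 6,400-particle system.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clusters import chi_cp, chi_ellipse_suite, trajectory_cluster_report
from .constriction import (DisruptionSpec, FeedbackConfig,
                           NeighborTriggerConfig, Trajectory,
                           apply_disruption, calibrate_sigma_ref,
                           run_simulation)
from .packing import (build_neighbor_list, generate_initial_packing,
                      mark_active_region, relax)
from .system import InteractionModel, ParticleSystem

__all__ = ["DisruptionTemplate", "ExperimentConfig", "PRESETS",
           "prepare_system", "make_disruption", "calibrate_reference_stress",
           "run_ensemble", "run_experiment", "cluster_table", "chi_table",
           "save_trajectory", "load_trajectory"]


@dataclass
class DisruptionTemplate:
    """Scale-independent description of a disrupted zone.

    band:    vertical band of ``band_width`` diameters centered at mid-x;
    ellipse: semi-axes (a_x, a_y_frac * stripe_width) at the box center.
    """

    kind: str = "none"              # none | band | ellipse
    alpha_r: float = 1.0
    band_width: float = 10.0
    a_x: float = 9.0
    a_y_frac: float = 0.375


@dataclass
class ExperimentConfig:
    n_total: int = 1600
    diameter_ratio: float = 1.1
    stripe_width: float = 12.0
    #: area fraction of the initial packing: just above the jamming point
    #: of a 50:50 bidisperse disk mixture (a random close-packed state)
    target_phi: float = 0.845
    interaction: InteractionModel = field(default_factory=InteractionModel)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    disruption: DisruptionTemplate = field(default_factory=DisruptionTemplate)
    neighbor_trigger: NeighborTriggerConfig | None = None
    calibration_trials: int = 50
    #: sigma_ref is calibrated on the full 6,400-particle system regardless
    #: of the production scale (the reference stress is a property of the
    #: embryo-scale tissue, and a smaller periodic box overestimates it)
    calibration_n_total: int = 6400
    levels: tuple = (0.1, 0.2, 0.3, 0.4)

    def scaled(self, full: bool = False) -> "ExperimentConfig":
        out = dataclasses.replace(self)
        out.n_total = 6400 if full else 1600
        return out


#: named presets for the main simulation studies
PRESETS = {
    # chain formation: tensile feedback vs the uncorrelated random process
    "chains": [
        ExperimentConfig(feedback=FeedbackConfig(beta=b, f_c=0.6))
        for b in (250.0, 0.0)
    ],
    # cluster statistics for strong and weak constrictions, both couplings
    "cluster-stats": [
        ExperimentConfig(feedback=FeedbackConfig(beta=b, f_c=fc))
        for fc in (0.6, 0.85) for b in (250.0, 0.0)
    ],
    # banded zone of reduced contractility at three disruption strengths
    "band-disruption": [
        ExperimentConfig(
            feedback=FeedbackConfig(beta=250.0, f_c=0.6),
            disruption=DisruptionTemplate(kind="band", alpha_r=a))
        for a in (0.6, 0.4, 0.2)
    ],
    # elliptical disrupted zone: partial and complete reduction
    "ellipse-disruption": [
        ExperimentConfig(
            feedback=FeedbackConfig(beta=250.0, f_c=0.6),
            disruption=DisruptionTemplate(kind="ellipse", alpha_r=a))
        for a in (0.4, 0.0)
    ],
    # neighbor-triggered enhancement instead of stress feedback
    "neighbor-trigger": [
        ExperimentConfig(feedback=FeedbackConfig(beta=0.0, f_c=0.6),
                         neighbor_trigger=NeighborTriggerConfig())
    ],
}


def _child_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2 ** 31 - 1, size=n)


def prepare_system(cfg: ExperimentConfig, seed: int) -> ParticleSystem:
    """Packed, relaxed system with active stripe and fixed neighbor list."""
    system = generate_initial_packing(
        cfg.n_total, cfg.diameter_ratio, seed=seed,
        target_phi=cfg.target_phi, model=cfg.interaction)
    mark_active_region(system, cfg.stripe_width)
    build_neighbor_list(system, cfg.interaction.neighbor_cutoff)
    relax(system, cfg.interaction)
    return system


def make_disruption(template: DisruptionTemplate, system: ParticleSystem,
                    stripe_width: float) -> DisruptionSpec:
    lx, ly = system.box
    if template.kind == "none":
        return DisruptionSpec(shape="none", alpha_r=1.0)
    if template.kind == "band":
        half = template.band_width / 2.0
        return DisruptionSpec(shape="band",
                              x_interval=(lx / 2 - half, lx / 2 + half),
                              alpha_r=template.alpha_r)
    if template.kind == "ellipse":
        return DisruptionSpec(
            shape="ellipse", center=(lx / 2, ly / 2),
            semi_axes=(template.a_x, template.a_y_frac * stripe_width),
            alpha_r=template.alpha_r)
    raise ValueError(f"unknown disruption kind {template.kind!r}")


def calibrate_reference_stress(cfg: ExperimentConfig, seed: int) -> float:
    """sigma_ref from single-constriction probes on the full-scale system."""
    full_cfg = dataclasses.replace(cfg, n_total=cfg.calibration_n_total)
    seeds = _child_seeds(seed, 2)
    reference = prepare_system(full_cfg, int(seeds[0]))
    return calibrate_sigma_ref(reference, cfg.feedback,
                               n_trials=cfg.calibration_trials,
                               seed=int(seeds[1]), model=cfg.interaction)


def run_ensemble(cfg: ExperimentConfig, replicates: int, seed: int,
                 system: ParticleSystem | None = None,
                 sigma_ref: float | None = None,
                 snapshot_levels=()):
    """Replicate trajectories from one packing with child RNG streams.

    Returns (trajectories, system, feedback, spec).  The packing and the
    sigma_ref calibration are shared across replicates; only the
    constriction RNG differs.  beta = 0 and neighbor-trigger runs skip
    the mechanics (their pattern statistics are mechanics-independent).
    """
    seeds = _child_seeds(seed, replicates + 2)
    if system is None:
        system = prepare_system(cfg, int(seeds[0]))
    feedback = cfg.feedback
    needs_mech = feedback.beta > 0 and cfg.neighbor_trigger is None
    if needs_mech and feedback.sigma_ref is None:
        if sigma_ref is None:
            sigma_ref = calibrate_reference_stress(cfg, int(seeds[1]))
        feedback = dataclasses.replace(feedback, sigma_ref=sigma_ref)
    spec = make_disruption(cfg.disruption, system, cfg.stripe_width)
    if spec.shape != "none":
        feedback = apply_disruption(feedback, spec, system)
    trajectories = [
        run_simulation(system, feedback, cfg.interaction, seed=int(s),
                       mechanics=needs_mech, snapshot_levels=snapshot_levels,
                       neighbor_trigger=cfg.neighbor_trigger)
        for s in seeds[2:]
    ]
    return trajectories, system, feedback, spec


def cluster_table(trajectories, levels) -> pd.DataFrame:
    """Tidy per-(replicate, level) cluster statistics table."""
    rows = []
    for rep, tr in enumerate(trajectories):
        for level in levels:
            rpt = trajectory_cluster_report(tr, level)
            rows.append({
                "replicate": rep, "level": level, "n_clusters": rpt.n_clusters,
                "n_constricted": rpt.n_constricted, "c_norm": rpt.c_norm,
                "eta_s": rpt.eta_s, "eta_d": rpt.eta_d, "eta_m": rpt.eta_m,
            })
    return pd.DataFrame(rows)


def chi_table(trajectories, spec: DisruptionSpec, levels) -> pd.DataFrame:
    """chi_cp per level (band) or the ellipse suite per level."""
    sys0 = trajectories[0].initial
    rows = []
    for level in levels:
        if spec.shape == "band":
            rpt = chi_cp(trajectories, spec.region_mask(sys0),
                         ~spec.region_mask(sys0), level)
            rows.append({"level": level, "region": "band", "chi": rpt.chi,
                         "se": rpt.se})
        elif spec.shape == "ellipse":
            for name, rpt in chi_ellipse_suite(trajectories, spec,
                                               level).items():
                rows.append({"level": level, "region": name, "chi": rpt.chi,
                             "se": rpt.se})
    return pd.DataFrame(rows)


def run_experiment(cfg: ExperimentConfig, replicates: int, seed: int,
                   out_dir, overwrite: bool = False) -> Path:
    """Run an ensemble and write tidy result tables plus a manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    if replicates == 0:
        (out / "manifest.json").write_text(json.dumps(
            {"config": _cfg_dict(cfg), "seed": seed, "replicates": 0},
            indent=1, default=str))
        return out
    trajs, system, feedback, spec = run_ensemble(cfg, replicates, seed)
    cluster_table(trajs, cfg.levels).to_csv(out / "clusters.csv", index=False)
    if spec.shape != "none":
        chi_table(trajs, spec, cfg.levels).to_csv(out / "chi.csv", index=False)
    for rep, tr in enumerate(trajs):
        save_trajectory(tr, out / f"run_{rep:03d}")
    system.save(out / "initial")
    (out / "manifest.json").write_text(json.dumps({
        "config": _cfg_dict(cfg), "seed": seed, "replicates": replicates,
        "sigma_ref": feedback.sigma_ref,
        "q": spec.q, "b_frac": spec.b_frac,
    }, indent=1, default=str))
    return out


def _cfg_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    fb = d.get("feedback", {})
    if isinstance(fb.get("alpha"), np.ndarray):
        fb["alpha"] = "per-particle"
    return d


def save_trajectory(traj: Trajectory, directory) -> None:
    """Event log as CSV plus the initial snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if traj.event_details:
        table = pd.DataFrame(traj.event_details,
                             columns=["step", "particle_id", "sigma_i",
                                      "s_i", "P_i"])
    else:
        rows = [(step, i) for step, ids in traj.events for i in ids]
        table = pd.DataFrame(rows, columns=["step", "particle_id"])
    table.to_csv(directory / "events.csv", index=False)
    traj.initial.save(directory / "initial")
    meta = {"n_active0": traj.n_active0, "sigma_ref": traj.sigma_ref,
            "seed": traj.seed}
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_trajectory(directory) -> Trajectory:
    directory = Path(directory)
    ev = pd.read_csv(directory / "events.csv")
    events = [(int(step), [int(i) for i in grp["particle_id"]])
              for step, grp in ev.groupby("step", sort=True)]
    initial = ParticleSystem.load(directory / "initial")
    meta = json.loads((directory / "meta.json").read_text())
    final = initial.copy()
    ids = [i for _, g in events for i in g]
    final.constricted[ids] = True
    return Trajectory(initial=initial, final=final, events=events,
                      n_active0=int(meta["n_active0"]),
                      sigma_ref=meta.get("sigma_ref"),
                      seed=meta.get("seed"))
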