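"""YAML run configuration.

A run config mirrors the experiment dataclasses section by section:

.. code-block:: yaml

    packing:      {n_total: 1600, diameter_ratio: 1.1, stripe_width: 12,
                   target_phi: 0.95}
    interaction:  {epsilon: 1.0, neighbor_cutoff: 1.1, damping: 0.5,
                   dt: 0.02, energy_tol: 1.0e-3, energy_window: 1000,
                   method: fire}
    feedback:     {p: 3, beta: 250, f_c: 0.6, target_fraction: 0.4}
    disruption:   {kind: band, alpha_r: 0.2, band_width: 10}
    levels:       [0.1, 0.2, 0.3, 0.4]
    replicates:   20

Unknown keys raise immediately, so a typo cannot silently fall back to a
default.  Every run writes a frozen copy of its resolved configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .constriction import FeedbackConfig, NeighborTriggerConfig
from .experiments import DisruptionTemplate, ExperimentConfig
from .system import InteractionModel

__all__ = ["load_config", "dump_config"]

_SECTION_TYPES = {
    "interaction": InteractionModel,
    "feedback": FeedbackConfig,
    "disruption": DisruptionTemplate,
    "neighbor_trigger": NeighborTriggerConfig,
}
_PACKING_KEYS = ("n_total", "diameter_ratio", "stripe_width", "target_phi")


def _build(cls, data: dict, where: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in '{where}'")
    return cls(**data)


def load_config(path) -> tuple:
    """Parse a YAML run config; returns (ExperimentConfig, replicates)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"packing", "interaction", "feedback", "disruption",
             "neighbor_trigger", "levels", "replicates", "calibration_trials"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    packing = raw.get("packing", {})
    bad = set(packing) - set(_PACKING_KEYS)
    if bad:
        raise ValueError(f"unknown key(s) {sorted(bad)} in 'packing'")
    kwargs.update(packing)
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            kwargs[section] = _build(cls, raw[section] or {}, section)
    if "levels" in raw:
        kwargs["levels"] = tuple(float(x) for x in raw["levels"])
    if "calibration_trials" in raw:
        kwargs["calibration_trials"] = int(raw["calibration_trials"])
    cfg = ExperimentConfig(**kwargs)
    return cfg, int(raw.get("replicates", 1))


def dump_config(cfg: ExperimentConfig, replicates: int, path) -> None:
    """Write the resolved configuration back out (frozen copy)."""
    d = dataclasses.asdict(cfg)
    out = {
        "packing": {k: d[k] for k in _PACKING_KEYS},
        "interaction": d["interaction"],
        "feedback": {k: v for k, v in d["feedback"].items()
                     if k != "alpha"},
        "disruption": d["disruption"],
        "levels": list(d["levels"]),
        "replicates": replicates,
        "calibration_trials": d["calibration_trials"],
    }
    if cfg.neighbor_trigger is not None:
        out["neighbor_trigger"] = d["neighbor_trigger"]
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
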