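"""Recovery of constrictions in a disrupted zone, simulation vs theory.

Reduces the constriction-probability amplitude in a central band of the
active stripe (alpha_r = 0.2, an 80% reduction), runs a few replicates
of the feedback model, and compares the constriction perturbation
coefficient chi_cp against the closed-form result for purely random
constrictions.  Feedback rescues the disrupted zone; the random process
does not.
"""

import dataclasses

from agf.clusters import chi_cp, random_theory_chi
from agf.experiments import (DisruptionTemplate, ExperimentConfig,
                             run_ensemble)

cfg = ExperimentConfig(
    n_total=400, stripe_width=8.0,
    calibration_n_total=400,   # keep this demo self-contained and quick
    disruption=DisruptionTemplate(kind="band", band_width=6.0, alpha_r=0.2))
trajs, system, feedback, spec = run_ensemble(cfg, replicates=6, seed=11)
mask = spec.region_mask(system)

print(f"band of {spec.q:.0%} of active cells has its constriction "
      f"probability reduced to alpha_r = {spec.alpha_r}")
for level in (0.1, 0.2, 0.3, 0.4):
    rpt = chi_cp(trajs, mask, ~mask, level)
    _, chi_rand = random_theory_chi(spec.alpha_r, spec.q, level)
    print(f"  %N_c={level:.1f}: chi_cp = {rpt.chi:.2f} +- {rpt.se:.2f} "
          f"(random-constriction theory: {chi_rand:.2f})")
print("chi_cp = 1 would be full recovery. With tensile feedback the band "
      "recovers far above the\nrandom baseline as precursor stress chains "
      "cross it and trigger constrictions there.")
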