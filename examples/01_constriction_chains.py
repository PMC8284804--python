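"""Chain formation with and without tensile-stress feedback.

Builds a small jammed monolayer, runs the stochastic constriction
process to 40% constricted once with strong stress coupling (beta = 250)
and once stress-blind (beta = 0), and compares the constricted-cell
cluster statistics.  With feedback, constrictions organize into chains:
fewer clusters, almost everything in multiplets.
"""

import dataclasses

from agf import FeedbackConfig, calibrate_sigma_ref, run_simulation
from agf.clusters import trajectory_cluster_report
from agf.experiments import ExperimentConfig, prepare_system

cfg = ExperimentConfig(n_total=400, stripe_width=8.0)
system = prepare_system(cfg, seed=1)
print(f"packed {system.n} cells in a {system.box[0]:.1f}-wide periodic box; "
      f"{int(system.active.sum())} active")

feedback = FeedbackConfig(beta=250.0, f_c=0.6)
sigma_ref = calibrate_sigma_ref(system, feedback, n_trials=30, seed=2)
feedback = dataclasses.replace(feedback, sigma_ref=sigma_ref)
print(f"reference tensile stress of one constriction: sigma_ref = "
      f"{sigma_ref:.3f} (epsilon/d units)")

for name, fb, mech in [
        ("tensile feedback (beta=250)", feedback, True),
        ("random (beta=0)", FeedbackConfig(beta=0.0, f_c=0.6), False)]:
    traj = run_simulation(system, fb, seed=7, mechanics=mech)
    rpt = trajectory_cluster_report(traj, 0.4)
    print(f"{name}: {rpt.n_clusters} clusters at %N_c=0.4 "
          f"(C_norm={rpt.c_norm:.3f}), eta_s={rpt.eta_s:.2f}, "
          f"eta_d={rpt.eta_d:.2f}, eta_m={rpt.eta_m:.2f}")

print("\nWith feedback the cluster count drops and nearly all constricted "
      "cells sit in multiplets --\nconstriction chains, the pattern seen on "
      "the embryo's ventral side before invagination.")
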