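"""Per-particle stress measures.

Two scalar/tensor measures are derived from the pair forces at a relaxed
configuration:

* the triggering stress  sigma_i = -eps^-1 sum_j d_ij f_ij,  a scalar
  that is positive when the net pair forces put the cell under tension;
  it drives the constriction feedback;
* the normalized virial stress tensor
  S_ab(i) = -(1/2 eps) sum_j r_ij,a f_ij,b,  symmetric because the
  particles are torque-free; its eigenvalue of larger magnitude is the
  "major stress" (positive = tension) and the corresponding eigenvector
  the major axis.  It enters the stress-augmented tessellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .system import InteractionModel, ParticleSystem

__all__ = ["CellStressState", "stress_field", "triggering_stresses",
           "triggering_stress", "virial_stress"]


@dataclass
class CellStressState:
    """Virial stress of one cell with its eigen-decomposition."""

    S: np.ndarray               # 2x2 symmetric tensor
    sigma: float                # triggering stress scalar
    major_stress: float         # eigenvalue of larger magnitude
    minor_stress: float
    major_axis: np.ndarray      # unit eigenvector of the major stress

    @classmethod
    def from_tensor(cls, S: np.ndarray, sigma: float) -> "CellStressState":
        S = 0.5 * (S + S.T)
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(np.abs(vals))[::-1]
        return cls(S=S, sigma=float(sigma),
                   major_stress=float(vals[order[0]]),
                   minor_stress=float(vals[order[1]]),
                   major_axis=vecs[:, order[0]].copy())


def stress_field(system: ParticleSystem,
                 model: InteractionModel | None = None):
    """(sigma, S) for all particles at the current configuration.

    sigma has shape (N,); S has shape (N, 2, 2).
    """
    model = model or InteractionModel()
    pi, pj, conn = system.candidate_pairs()
    sigma, S3 = _kernels.stress_sums(
        system.positions, system.diameters, pi, pj, conn,
        system.box[0], system.box[1], model.epsilon)
    S = np.empty((system.n, 2, 2))
    S[:, 0, 0] = S3[:, 0]
    S[:, 1, 1] = S3[:, 1]
    S[:, 0, 1] = S3[:, 2]
    S[:, 1, 0] = S3[:, 2]
    return sigma, S


def triggering_stresses(system: ParticleSystem,
                        model: InteractionModel | None = None) -> np.ndarray:
    """Triggering stress sigma_i for every particle (positive = tension)."""
    sigma, _ = stress_field(system, model)
    return sigma


def triggering_stress(system: ParticleSystem, i: int,
                      model: InteractionModel | None = None) -> float:
    return float(triggering_stresses(system, model)[i])


def virial_stress(system: ParticleSystem, i: int,
                  model: InteractionModel | None = None) -> CellStressState:
    """Full virial stress state of particle ``i`` (see module docstring)."""
    sigma, S = stress_field(system, model)
    return CellStressState.from_tensor(S[i], sigma[i])
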