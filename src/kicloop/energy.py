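"""Surrogate score function and annealing weight schedules.

The score is NOT a molecular-mechanics force field: it is a deliberately
small surrogate with three terms that the sampling strategies interact with —

* ``fa_rep_like`` — a soft-sphere repulsive term over pairs of (segment
  backbone atom, non-adjacent backbone atom or environment sphere):
  ``k (1 - d/(r1+r2))^2`` for ``d < r1 + r2``, else 0, with k = 1 score
  unit and the bump-filter element radii shrunk by a documented factor so
  that ordinary packed contacts score zero.
* ``rama`` / ``rama2b`` — the negative log-probability of each segment
  residue's (phi, psi) under the standard or neighbour-dependent tables.
* ``omega_restraint`` — a harmonic restraint on each segment residue's
  omega towards the nearer of trans (180) and cis (0), scaled by the
  observed spread of omega in high-resolution structures (sd 6.3 degrees).

Annealing multiplies a ramped component's full weight by k/n in outer cycle
k of n, reaching the full weight exactly in the last cycle; it applies in
the high-resolution stage only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import repulsive_kernel
from .closure import _BACKBONE_RADII
from .geometry import Pose, SegmentDefinition, normalize_angle
from .priors import OMEGA_SD, Tables, rama_energy

#: soft-sphere prefactor (score units)
REPULSIVE_K = 1.0

#: the repulsive term sees slightly shrunken radii so that ordinary packed
#: contacts (e.g. helical O(i)..N(i+4) hydrogen-bond distances ~2.9 A) score
#: zero while genuine overlap is still penalised; the bump filter keeps the
#: full radii
REP_RADIUS_SCALE = 0.9

#: default full weights; fa_rep_like follows the conventional Rosetta value
#: for the repulsive weight purely as a familiar default
DEFAULT_FA_REP_WEIGHT = 0.44
DEFAULT_RAMA_WEIGHT = 0.2
DEFAULT_OMEGA_WEIGHT = 0.1


@dataclass
class EnergyWeights:
    """Component weights of the surrogate score (all nonnegative)."""

    fa_rep_like: float = DEFAULT_FA_REP_WEIGHT
    rama: float = DEFAULT_RAMA_WEIGHT
    rama2b: float = 0.0
    omega_restraint: float = DEFAULT_OMEGA_WEIGHT

    def __post_init__(self):
        for name in ("fa_rep_like", "rama", "rama2b", "omega_restraint"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative weight for {name}")
        if self.rama2b > 0 and self.rama > 0:
            raise ValueError("with rama2b active the standard rama weight must be 0")


@dataclass
class AnnealingSchedule:
    """Outer-cycle count and which components ramp (high-resolution only)."""

    n_outer: int = 5
    ramp_fa_rep: bool = False
    ramp_rama: bool = False

    def __post_init__(self):
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")


def weight_at_cycle(full_weight: float, cycle: int,
                    schedule: AnnealingSchedule, ramped: bool = True,
                    stage: str = "highres") -> float:
    """Weight of one component in outer cycle ``cycle`` (1-based).

    Ramped components start at full/n and grow by full/n each cycle,
    reaching the full weight exactly in the last cycle; non-ramped
    components (and every component in the low-resolution stage) keep the
    full weight.
    """
    n = schedule.n_outer
    if not 1 <= cycle <= n:
        raise ValueError(f"cycle {cycle} outside [1, {n}]")
    if not ramped or stage != "highres" or cycle == n:
        return full_weight  # exact full weight in the last cycle
    return full_weight * cycle / n


def weights_at_cycle(full: EnergyWeights, cycle: int,
                     schedule: AnnealingSchedule,
                     stage: str = "highres") -> EnergyWeights:
    """The full weight set with the schedule applied for one outer cycle."""
    return replace(
        full,
        fa_rep_like=weight_at_cycle(full.fa_rep_like, cycle, schedule,
                                    schedule.ramp_fa_rep, stage),
        rama=weight_at_cycle(full.rama, cycle, schedule,
                             schedule.ramp_rama, stage),
        rama2b=weight_at_cycle(full.rama2b, cycle, schedule,
                               schedule.ramp_rama, stage),
    )


def configure_ramp(ramp_fa_rep: bool = False, ramp_rama: bool = False,
                   rama2b_active: bool = False, n_outer: int = 5):
    """Full weights plus schedule for a protocol configuration.

    With rama2b active the standard rama weight is 0 and the rama2b term
    carries the Ramachandran weight; if ramp_rama is also set, the rama2b
    weight is the one that ramps.
    """
    weights = EnergyWeights(
        rama=0.0 if rama2b_active else DEFAULT_RAMA_WEIGHT,
        rama2b=DEFAULT_RAMA_WEIGHT if rama2b_active else 0.0,
    )
    schedule = AnnealingSchedule(n_outer=n_outer, ramp_fa_rep=ramp_fa_rep,
                                 ramp_rama=ramp_rama)
    return weights, schedule


def repulsive_energy(pose: Pose, segment: SegmentDefinition) -> float:
    """Unweighted soft-sphere repulsion of the segment against the rest of
    the structure and the environment spheres.

    Pairs within the segment (non-adjacent residues) are counted once.
    """
    return float(repulsive_kernel(
        pose.coords, segment.start, segment.end, _BACKBONE_RADII,
        REP_RADIUS_SCALE, pose.env_xyz, pose.env_radius, REPULSIVE_K))


def rama_term(pose: Pose, segment: SegmentDefinition, tables: Tables,
              mode: str = "standard") -> float:
    """Sum of per-residue Ramachandran energies over the segment."""
    total = 0.0
    n = len(pose)
    for resi in segment.residues():
        i = resi - 1
        left = pose.aa[i - 1] if resi > 1 else None
        right = pose.aa[i + 1] if resi < n else None
        total += rama_energy(pose.aa[i], pose.phi[i], pose.psi[i], tables,
                             mode=mode, left_aa=left, right_aa=right,
                             next_aa=right)
    return total


def omega_term(pose: Pose, segment: SegmentDefinition) -> float:
    """Harmonic omega restraint towards the nearer of trans and cis."""
    om = pose.omega[segment.start - 1:segment.end]
    dev_trans = np.abs(normalize_angle(om - 180.0))
    dev_cis = np.abs(normalize_angle(om))
    dev = np.minimum(dev_trans, dev_cis)
    return float(np.sum(dev ** 2 / (2.0 * OMEGA_SD ** 2)))


def score(pose: Pose, segment: SegmentDefinition, weights: EnergyWeights,
          tables: Tables) -> float:
    """Weighted surrogate score of the segment in its environment.

    Deterministic, additive over components, invariant under rigid
    transforms of the whole pose.
    """
    total = 0.0
    if weights.fa_rep_like:
        total += weights.fa_rep_like * repulsive_energy(pose, segment)
    if weights.rama:
        total += weights.rama * rama_term(pose, segment, tables, "standard")
    if weights.rama2b:
        total += weights.rama2b * rama_term(pose, segment, tables, "rama2b")
    if weights.omega_restraint:
        total += weights.omega_restraint * omega_term(pose, segment)
    return total
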