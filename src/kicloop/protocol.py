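"""The Monte-Carlo minimisation protocol driving kinematic closure moves.

A trajectory has two stages.  The low-resolution stage builds an initial
closed conformation of the whole segment from scratch (the information about
the starting segment conformation is discarded).  The high-resolution stage
runs ``n_outer`` outer cycles of ``inner_per_residue * L`` inner cycles; each
inner cycle is one closure trial: choose a sub-segment, propose non-pivot
torsions from the configured source (standard Ramachandran, neighbour-
dependent, taboo-prescribed bins or the constant native bin vector), propose
omegas and N-CA-C bond angles, attempt closure until a bump-surviving
solution appears (up to ``max_closure_attempts``), greedily minimise, and
accept or reject by the Metropolis criterion.  Weight ramping, when enabled,
applies to the high-resolution stage only.  The lowest-scoring pose seen is
the trajectory's reported model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .closure import (
    DEFAULT_OVERLAP_FACTOR,
    KicMove,
    apply_move,
    bump_filter,
    choose_subsegment,
    sample_bond_angles,
    solve_closure,
)
from .energy import (
    AnnealingSchedule,
    EnergyWeights,
    configure_ramp,
    score,
    weights_at_cycle,
)
from .geometry import Pose, SegmentDefinition, normalize_angle, segment_rmsd
from .priors import (
    Tables,
    classify_bin,
    default_tables,
    sample_bin_restricted,
    sample_omega,
    sample_phi_psi,
    sample_phi_psi_rama2b,
)
from .taboo import TabooSampler, native_bin_vector

logger = logging.getLogger(__name__)

#: factor applied to the repulsive weight in the low-resolution stage
LOWRES_REP_FACTOR = 0.25


@dataclass
class ProtocolConfig:
    """Flags and knobs of one modelling run.

    The defaults mirror the printed protocol: 5 outer cycles, 20 inner
    cycles per segment residue, up to 2000 closure attempts per trial.
    """

    taboo: bool = False
    rama2b: bool = False
    omega_sampling: bool = False
    ramp_fa_rep: bool = False
    ramp_rama: bool = False
    torsion_restricted: bool = False
    idealize_bond_angles: bool = False
    n_outer: int = 5
    inner_per_residue: int = 20
    max_closure_attempts: int = 2000
    kT: float = 1.0
    seed: int = 0
    n_models: int = 1
    overlap_factor: float = DEFAULT_OVERLAP_FACTOR
    minimize_steps: int = 2

    def __post_init__(self):
        if self.n_outer < 1:
            raise ValueError("n_outer must be >= 1")
        if self.taboo and self.torsion_restricted:
            raise ValueError("taboo and torsion-restricted sampling are "
                             "mutually exclusive")

    @classmethod
    def ngk(cls, **kw) -> "ProtocolConfig":
        """Next-generation preset: Rama2b + Omega sampling + Ramp repulsive
        + Ramp rama (taboo excluded)."""
        return cls(rama2b=True, omega_sampling=True, ramp_fa_rep=True,
                   ramp_rama=True, **kw)

    @classmethod
    def legacy(cls, **kw) -> "ProtocolConfig":
        """The original protocol: 3 outer cycles, no ramping, planar omega."""
        kw.setdefault("n_outer", 3)
        return cls(**kw)


@dataclass
class TrajectoryResult:
    """Outcome of one Monte-Carlo trajectory."""

    final_pose: Pose
    final_score: float
    best_pose: Pose
    best_score: float
    accept_log: list = field(default_factory=list)  # (outer cycle, accepted)
    n_closure_attempts: int = 0
    failed: bool = False
    rmsd: float = np.nan


def metropolis_accept(delta: float, kT: float,
                      rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-delta/kT))."""
    if kT <= 0:
        raise ValueError("kT must be positive")
    if delta <= 0:
        return True
    return rng.random() < np.exp(-delta / kT)


def _propose(pose: Pose, move: KicMove, config: ProtocolConfig,
             tables: Tables, rng: np.random.Generator,
             taboo_state: TabooSampler | None, native_bins: str | None,
             segment: SegmentDefinition) -> KicMove:
    """Fill a move skeleton with non-pivot phi/psi, omega and bond angles."""
    n = len(pose)
    pivots = set(move.pivots)
    sample_bond_angles(
        move, "idealized" if config.idealize_bond_angles else "varied", rng)
    bins = None
    if config.torsion_restricted:
        bins = native_bins
    elif config.taboo:
        bins = taboo_state.next_vector(rng)
    omega_mode = "sampled" if config.omega_sampling else "planar"
    for resi in range(move.sub_start, move.sub_end + 1):
        i = resi - 1
        k = resi - move.sub_start
        aa = pose.aa[i]
        left = pose.aa[i - 1] if resi > 1 else None
        right = pose.aa[i + 1] if resi < n else None
        # omega of the peptide bond entering this residue; a lowercase bin
        # letter prescribes a cis bond
        seg_pos = resi - segment.start
        forced_cis = bins is not None and bins[seg_pos].islower()
        if forced_cis:
            move.omega[k] = (float(normalize_angle(rng.normal(0.0, 6.3)))
                             if config.omega_sampling else 0.0)
        elif config.omega_sampling:
            move.omega[k] = sample_omega(aa == "P", "sampled", rng)
        else:
            move.omega[k] = 180.0
        if resi in pivots:
            continue
        if bins is not None:
            move.phi[k], move.psi[k] = sample_bin_restricted(
                aa, bins[seg_pos].upper(), tables, rng, next_aa=right)
        elif config.rama2b:
            move.phi[k], move.psi[k] = sample_phi_psi_rama2b(
                aa, left, right, tables, rng, next_aa=right)
        else:
            move.phi[k], move.psi[k] = sample_phi_psi(
                aa, tables, rng, next_aa=right)
    return move


def _realized_bin_vector(pose: Pose, segment: SegmentDefinition,
                         move: KicMove, solution) -> str:
    """Bin vector of the full segment with the move's solution applied
    (positions outside the sub-segment keep the pose's current bins)."""
    chars = []
    s, m, e = move.pivots
    piv = {s: (solution.pivot_torsions[0], solution.pivot_torsions[1]),
           m: (solution.pivot_torsions[2], solution.pivot_torsions[3]),
           e: (solution.pivot_torsions[4], solution.pivot_torsions[5])}
    for resi in segment.residues():
        i = resi - 1
        if resi in piv:
            phi, psi = piv[resi]
            omega = move.omega[resi - move.sub_start]
        elif move.sub_start <= resi <= move.sub_end:
            k = resi - move.sub_start
            phi = move.phi[k] if np.isfinite(move.phi[k]) else pose.phi[i]
            psi = move.psi[k] if np.isfinite(move.psi[k]) else pose.psi[i]
            omega = move.omega[k] if np.isfinite(move.omega[k]) else pose.omega[i]
        else:
            phi, psi, omega = pose.phi[i], pose.psi[i], pose.omega[i]
        ch = classify_bin(phi, psi)
        if np.isfinite(omega) and abs(omega) < 90.0:
            ch = ch.lower()
        chars.append(ch)
    return "".join(chars)


def _attempt_closure(pose: Pose, segment: SegmentDefinition, move_factory,
                     config: ProtocolConfig, tables: Tables,
                     rng: np.random.Generator,
                     taboo_state: TabooSampler | None,
                     native_bins: str | None):
    """Repeat propose-solve-filter until a bump-surviving solution appears.

    Returns (move, solution, attempts used) or (None, None, attempts).
    """
    for attempt in range(1, config.max_closure_attempts + 1):
        move = move_factory()
        move = _propose(pose, move, config, tables, rng, taboo_state,
                        native_bins, segment)
        solutions = solve_closure(pose, move)
        if config.taboo and taboo_state is not None:
            for sol in solutions:
                taboo_state.record(
                    _realized_bin_vector(pose, segment, move, sol))
        survivors = bump_filter(pose, move, solutions, config.overlap_factor)
        if survivors:
            sol = survivors[int(rng.integers(len(survivors)))]
            return move, sol, attempt
    return None, None, config.max_closure_attempts


def _minimize(pose: Pose, pose_score: float, segment: SegmentDefinition,
              weights: EnergyWeights, tables: Tables,
              rng: np.random.Generator, steps: int,
              overlap_factor: float) -> tuple:
    """Greedy closure-preserving descent; returns (pose, score).

    Each step perturbs the non-pivot phi/psi of a random sub-segment by a
    small Gaussian kick, re-closes, and keeps one randomly chosen
    bump-surviving solution if it improves the score.  The score never
    increases and the chain stays closed (every candidate is an exact
    closure solution).
    """
    current, current_score = pose, pose_score
    for _ in range(steps):
        move = choose_subsegment(segment, rng)
        pivots = set(move.pivots)
        for resi in range(move.sub_start, move.sub_end + 1):
            if resi in pivots:
                continue
            k = resi - move.sub_start
            i = resi - 1
            move.phi[k] = float(normalize_angle(
                current.phi[i] + rng.normal(0.0, 2.0)))
            move.psi[k] = float(normalize_angle(
                current.psi[i] + rng.normal(0.0, 2.0)))
            move.omega[k] = float(normalize_angle(
                current.omega[i] + rng.normal(0.0, 1.5)))
        survivors = bump_filter(current, move, solve_closure(current, move),
                                overlap_factor)
        if not survivors:
            continue
        sol = survivors[int(rng.integers(len(survivors)))]
        cand = apply_move(current, move, sol)
        sc = score(cand, segment, weights, tables)
        if sc < current_score:
            current, current_score = cand, sc
    return current, current_score


def minimize_segment(pose: Pose, segment: SegmentDefinition,
                     weights: EnergyWeights, tables: Tables | None = None,
                     rng: np.random.Generator | None = None,
                     steps: int = 2,
                     overlap_factor: float = DEFAULT_OVERLAP_FACTOR) -> Pose:
    """Greedy closure-preserving minimisation of the segment score; the
    output score is never above the input score (see :func:`_minimize`)."""
    tables = tables if tables is not None else default_tables()
    rng = rng if rng is not None else np.random.default_rng()
    pose_score = score(pose, segment, weights, tables)
    out, _ = _minimize(pose, pose_score, segment, weights, tables, rng,
                       steps, overlap_factor)
    return out


def kic_trial(pose: Pose, segment: SegmentDefinition, config: ProtocolConfig,
              weights: EnergyWeights, tables: Tables,
              rng: np.random.Generator,
              taboo_state: TabooSampler | None = None,
              native_bins: str | None = None,
              full_segment: bool = False,
              current_score: float | None = None):
    """One inner-cycle closure trial.

    Returns (pose, accepted, attempts, score of the returned pose under
    ``weights``).  The pose is returned unchanged when no bump-surviving
    closure is found within the attempt budget or when the Metropolis
    criterion rejects.
    """
    if full_segment:
        def factory():
            return KicMove(sub_start=segment.start, sub_end=segment.end)
    else:
        def factory():
            return choose_subsegment(segment, rng)
    if current_score is None:
        current_score = score(pose, segment, weights, tables)
    move, sol, attempts = _attempt_closure(
        pose, segment, factory, config, tables, rng, taboo_state, native_bins)
    if move is None:
        return pose, False, attempts, current_score
    candidate = apply_move(pose, move, sol)
    cand_score = score(candidate, segment, weights, tables)
    if config.minimize_steps:
        candidate, cand_score = _minimize(
            candidate, cand_score, segment, weights, tables, rng,
            config.minimize_steps, config.overlap_factor)
    if metropolis_accept(cand_score - current_score, config.kT, rng):
        return candidate, True, attempts, cand_score
    return pose, False, attempts, current_score


def run_trajectory(start: Pose, native: Pose, segment: SegmentDefinition,
                   config: ProtocolConfig,
                   rng: np.random.Generator | None = None,
                   tables: Tables | None = None) -> TrajectoryResult:
    """One full two-stage Monte-Carlo trajectory.

    Deterministic given the rng state; the reported model is the pose with
    the lowest full-weight score seen over the high-resolution stage.
    """
    tables = tables if tables is not None else default_tables()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = segment.length
    full_weights, schedule = configure_ramp(
        config.ramp_fa_rep, config.ramp_rama, rama2b_active=config.rama2b,
        n_outer=config.n_outer)
    native_bins = (native_bin_vector(native, segment)
                   if config.torsion_restricted else None)
    taboo_state = None
    if config.taboo:
        aas = [start.aa[i - 1] for i in segment.residues()]
        left = start.aa[segment.start - 2] if segment.start > 1 else None
        right = start.aa[segment.end] if segment.end < len(start) else None
        taboo_state = TabooSampler(
            aas=aas, tables=tables,
            mode="rama2b" if config.rama2b else "standard",
            left_flank_aa=left, right_flank_aa=right)

    # --- low-resolution stage: initial closure from scratch
    lowres = replace(full_weights,
                     fa_rep_like=full_weights.fa_rep_like * LOWRES_REP_FACTOR)
    pose = start.copy()
    move, sol, attempts = _attempt_closure(
        pose, segment,
        lambda: KicMove(sub_start=segment.start, sub_end=segment.end),
        config, tables, rng, taboo_state, native_bins)
    total_attempts = attempts
    if move is None:
        logger.warning("initial closure failed after %d attempts", attempts)
        return TrajectoryResult(final_pose=pose, final_score=np.inf,
                                best_pose=pose, best_score=np.inf,
                                n_closure_attempts=total_attempts,
                                failed=True)
    pose = apply_move(pose, move, sol)
    pose = minimize_segment(pose, segment, lowres, tables, rng,
                            config.minimize_steps, config.overlap_factor)

    # --- high-resolution stage
    best_pose = pose
    best_score = score(pose, segment, full_weights, tables)
    accept_log = []
    inner = config.inner_per_residue * L
    first_trial = True
    for cycle in range(1, config.n_outer + 1):
        cycle_weights = weights_at_cycle(full_weights, cycle, schedule)
        current = None  # weights changed; recompute lazily
        for _ in range(inner):
            pose, accepted, attempts, current = kic_trial(
                pose, segment, config, cycle_weights, tables, rng,
                taboo_state, native_bins, full_segment=first_trial,
                current_score=current)
            first_trial = False
            total_attempts += attempts
            accept_log.append((cycle, accepted))
            if accepted:
                full_sc = score(pose, segment, full_weights, tables)
                if full_sc < best_score:
                    best_pose, best_score = pose, full_sc
    final_score = score(pose, segment, full_weights, tables)
    if final_score < best_score:
        best_pose, best_score = pose, final_score
    return TrajectoryResult(final_pose=pose, final_score=final_score,
                            best_pose=best_pose, best_score=best_score,
                            accept_log=accept_log,
                            n_closure_attempts=total_attempts)


def run_ensemble(start: Pose, native: Pose, segment: SegmentDefinition,
                 config: ProtocolConfig, tables: Tables | None = None,
                 out_dir=None) -> list:
    """Independent trajectories with derived seeds (base seed + index).

    Each result carries the segment RMSD of its reported model to the
    native.  With ``out_dir`` set, endpoint models are written as PDB files
    plus a tab-separated score table (model_id, score, rmsd).
    """
    from . import pdbio

    tables = tables if tables is not None else default_tables()
    results = []
    for t in range(config.n_models):
        rng = np.random.default_rng(config.seed + t)
        res = run_trajectory(start, native, segment, config, rng, tables)
        if not res.failed:
            res.rmsd = segment_rmsd(res.best_pose, native, segment)
        results.append(res)
        logger.info("trajectory %d: score %.3f rmsd %.3f%s", t,
                    res.best_score, res.rmsd, " FAILED" if res.failed else "")
    if out_dir is not None:
        import pandas as pd
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for t, res in enumerate(results):
            name = f"model_{t:04d}"
            if not res.failed:
                pdbio.write_pdb(res.best_pose, out_dir / f"{name}.pdb")
            rows.append({"model_id": name, "score": res.best_score,
                         "rmsd": res.rmsd, "failed": res.failed})
        pd.DataFrame(rows).to_csv(out_dir / "scores.tsv", sep="\t",
                                  index=False)
    return results
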