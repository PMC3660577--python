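"""Synthetic mini-protein fixtures with an embedded loop to remodel.

A fixture stands in for a benchmark case: a single chain with ideal-geometry
helical flanks, a central segment whose native torsions are drawn from the
bundled Ramachandran tables, and a shell of fixed environment spheres placed
around the native segment.  The spheres are positioned just outside contact
distance of the native conformation, so the native scores clash-free while a
substantial fraction of alternative segment conformations collide with them
— a crude, controllable stand-in for the packing of a real protein core.

The start structure is the native with the segment's torsion information
discarded (re-randomised from the tables) and the segment rebuilt from the
N-terminal flank, leaving a chain break at the segment end: the analogue of
deleting the segment and reconstructing it de novo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .closure import _BACKBONE_RADII
from .geometry import (
    Pose,
    SegmentDefinition,
    build_coordinates,
    new_pose,
)
from .priors import Tables, default_tables, sample_phi_psi
from .protocol import ProtocolConfig
from . import pdbio

logger = logging.getLogger(__name__)

#: clearance between the native segment and each environment sphere beyond
#: hard contact, in Angstrom; smaller values sculpt a tighter funnel
ENV_MARGIN = 1.0

#: residue alphabet used for synthetic sequences (general class plus glycine)
_SEQ_ALPHABET = "ASLVTNDKG"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic fixture (all lengths in residues)."""

    n_residues: int = 36
    segment_start: int = 13
    segment_end: int = 24
    seed: int = 0
    env_count: int = 30
    env_radius: float = 1.6
    env_margin: float = ENV_MARGIN
    cis_proline_at: int | None = None  # 1-based residue index or None

    def __post_init__(self):
        seg = SegmentDefinition(self.segment_start, self.segment_end)
        if seg.start < 3 or seg.end > self.n_residues - 2:
            raise ValueError("segment too close to the chain termini")


@dataclass
class Fixture:
    native: Pose
    start: Pose
    segment: SegmentDefinition
    spec: FixtureSpec


def _draw_segment_torsions(pose: Pose, segment: SegmentDefinition,
                           tables: Tables, rng: np.random.Generator) -> None:
    n = len(pose)
    for resi in segment.residues():
        i = resi - 1
        next_aa = pose.aa[i + 1] if resi < n else None
        pose.phi[i], pose.psi[i] = sample_phi_psi(pose.aa[i], tables, rng,
                                                  next_aa=next_aa)


def _place_environment(native: Pose, segment: SegmentDefinition,
                       spec: FixtureSpec, rng: np.random.Generator) -> None:
    """Spheres seeded off random native segment atoms, just beyond contact."""
    seg_xyz = native.coords[segment.start - 1:segment.end].reshape(-1, 3)
    seg_rad = np.tile(_BACKBONE_RADII, segment.length)
    all_xyz = native.coords.reshape(-1, 3)
    all_rad = np.tile(_BACKBONE_RADII, len(native))
    spheres = []
    attempts = 0
    while len(spheres) < spec.env_count and attempts < 200 * spec.env_count:
        attempts += 1
        k = int(rng.integers(len(seg_xyz)))
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        dist = seg_rad[k] + spec.env_radius + spec.env_margin
        pos = seg_xyz[k] + dist * v
        clearance = np.linalg.norm(all_xyz - pos, axis=1) - all_rad \
            - spec.env_radius
        if clearance.min() < spec.env_margin - 1e-9:
            continue
        spheres.append(pos)
    if len(spheres) < spec.env_count:
        logger.warning("placed only %d of %d environment spheres",
                       len(spheres), spec.env_count)
    native.env_xyz = np.array(spheres) if spheres else np.zeros((0, 3))
    native.env_radius = np.full(len(spheres), spec.env_radius)


def _make_sequence(spec: FixtureSpec, rng: np.random.Generator) -> list:
    aa = [str(_SEQ_ALPHABET[int(rng.integers(len(_SEQ_ALPHABET)))])
          for _ in range(spec.n_residues)]
    if spec.cis_proline_at is not None:
        aa[spec.cis_proline_at - 1] = "P"
    return aa


def _build_native(spec: FixtureSpec, tables: Tables,
                  rng: np.random.Generator) -> Pose | None:
    """Clash-free native: segment torsions are redrawn from the tables until
    the segment packs against the flanks without soft-sphere overlap."""
    from .energy import repulsive_energy

    segment = SegmentDefinition(spec.segment_start, spec.segment_end)
    pose = new_pose(_make_sequence(spec, rng))
    pose.phi[:] = -60.0
    pose.psi[:] = -45.0
    pose.omega[:] = 180.0
    pose.theta[:] = rng.uniform(109.62, 112.1, len(pose))
    for _ in range(300):
        _draw_segment_torsions(pose, segment, tables, rng)
        if spec.cis_proline_at is not None:
            # cis peptide bond entering the proline
            pose.omega[spec.cis_proline_at - 1] = float(rng.normal(0.0, 3.0))
        built = build_coordinates(pose)
        if repulsive_energy(built, segment) == 0.0:
            return built
    return None


def _relax_native(native: Pose, segment: SegmentDefinition, tables: Tables,
                  rng: np.random.Generator, steps: int = 40) -> Pose:
    """Greedy clash-constrained relaxation of the native segment.

    Drives the native into a local minimum of the Ramachandran + omega
    terms while keeping the segment strictly clash-free, emulating the role
    of a relaxed crystal structure as a reference energy minimum.  Uses the
    same closure machinery as the protocol.
    """
    from .closure import apply_move, bump_filter, choose_subsegment, solve_closure
    from .energy import EnergyWeights, omega_term, rama_term, repulsive_energy
    from .geometry import normalize_angle

    def objective(pose):
        return rama_term(pose, segment, tables) + omega_term(pose, segment)

    current = native
    current_obj = objective(current)
    for _ in range(steps):
        move = choose_subsegment(segment, rng)
        pivots = set(move.pivots)
        for resi in range(move.sub_start, move.sub_end + 1):
            if resi in pivots:
                continue
            k = resi - move.sub_start
            i = resi - 1
            move.phi[k] = float(normalize_angle(
                current.phi[i] + rng.normal(0.0, 4.0)))
            move.psi[k] = float(normalize_angle(
                current.psi[i] + rng.normal(0.0, 4.0)))
        for sol in bump_filter(current, move, solve_closure(current, move)):
            cand = apply_move(current, move, sol)
            if repulsive_energy(cand, segment) > 0.0:
                continue
            obj = objective(cand)
            if obj < current_obj:
                current, current_obj = cand, obj
    return current


def _make_start(native: Pose, segment: SegmentDefinition, tables: Tables,
                rng: np.random.Generator) -> Pose:
    """Native with the segment torsions re-randomised and the segment
    rebuilt from the N-terminal flank (chain break at the segment end)."""
    start = native.copy()
    _draw_segment_torsions(start, segment, tables, rng)
    return build_coordinates(start, segment.start, segment.end)


def _closable(fixture: Fixture, tables: Tables, seed: int,
              max_attempts: int = 60) -> bool:
    """Can the full segment be closed (bump-filtered) from scratch?"""
    from .closure import KicMove
    from .protocol import _attempt_closure

    cfg = ProtocolConfig(max_closure_attempts=max_attempts)
    rng = np.random.default_rng(seed)
    seg = fixture.segment
    move, _, _ = _attempt_closure(
        fixture.start, seg,
        lambda: KicMove(sub_start=seg.start, sub_end=seg.end),
        cfg, tables, rng, None, None)
    return move is not None


def generate_fixture(spec: FixtureSpec, tables: Tables | None = None,
                     out_dir=None) -> Fixture:
    """Deterministically generate a fixture from its spec.

    If the geometry turns out unclosable (the environment shell blocks every
    closure of the segment), regeneration is retried with an incremented
    seed up to 10 times before raising.  With ``out_dir`` set, writes
    ``native.pdb``, ``start.pdb`` and ``segment.loop``.
    """
    tables = tables if tables is not None else default_tables()
    last_err = None
    for bump in range(10):
        seed = spec.seed + bump
        rng = np.random.default_rng(seed)
        segment = SegmentDefinition(spec.segment_start, spec.segment_end)
        native = _build_native(spec, tables, rng)
        if native is None:
            last_err = f"seed {seed}: no clash-free native in 300 draws"
            logger.info(last_err)
            continue
        native = _relax_native(native, segment, tables, rng)
        _place_environment(native, segment, spec, rng)
        start = _make_start(native, segment, tables, rng)
        start.env_xyz = native.env_xyz.copy()
        start.env_radius = native.env_radius.copy()
        fixture = Fixture(native=native, start=start, segment=segment,
                          spec=spec)
        if _closable(fixture, tables, seed):
            if bump:
                logger.info("fixture seed bumped %d -> %d for closability",
                            spec.seed, seed)
            if out_dir is not None:
                out = Path(out_dir)
                out.mkdir(parents=True, exist_ok=True)
                pdbio.write_pdb(native, out / "native.pdb")
                pdbio.write_pdb(start, out / "start.pdb")
                pdbio.write_loop_file(segment, out / "segment.loop")
            return fixture
        last_err = f"seed {seed} produced an unclosable fixture"
        logger.info(last_err)
    raise RuntimeError(f"could not generate a closable fixture: {last_err}")


def bundled_specs() -> list:
    """The five bundled 12-residue benchmark fixtures (fixed seeds)."""
    return [
        FixtureSpec(seed=11),
        FixtureSpec(seed=23),
        FixtureSpec(seed=37),
        FixtureSpec(seed=51, cis_proline_at=18),
        FixtureSpec(seed=64),
    ]


def bundled_fixtures(tables: Tables | None = None) -> list:
    return [generate_fixture(s, tables) for s in bundled_specs()]
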