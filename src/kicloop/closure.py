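"""The kinematic closure move.

A move designates the first, middle and last residue of a randomly chosen
sub-segment as pivots, proposes new torsions/omegas/bond angles for the
non-pivot residues, and solves analytically-constrained geometry for the six
pivot phi/psi torsions so that the chain reconnects exactly to the anchor
atoms flanking the sub-segment.

The solver uses the triaxial reduction: with all non-pivot internal
coordinates frozen, the chain pieces between consecutive pivot CA atoms are
rigid bodies, the three pivot CA atoms form a triangle with fixed side
lengths, and the remaining degrees of freedom are one rotation of the middle
CA about the anchor-anchor axis (tau) plus one spin of each rigid body about
its chord (alpha1, alpha2).  The three N-CA-C bond-angle constraints at the
pivots couple these cyclically; the two spin equations are cone-angle
equations solved in closed form (two branches each), leaving a single smooth
residual in tau per branch combination, bracketed on a dense grid and
refined by bisection.  A closure polynomial of degree 16 bounds the number
of solutions at 16.

Every returned solution is verified by rebuilding the sub-segment from
internal coordinates and checking that the downstream anchor atoms are
reproduced to within 1e-4 Angstrom; non-pivot internal coordinates are
preserved exactly because the rebuilt pose uses them verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kernels import bump_kernel, solve_closure_kernel
from .geometry import Pose, SegmentDefinition

logger = logging.getLogger(__name__)

# N-CA-C bond-angle sampling range (degrees), from sub-Angstrom crystal
# structure statistics; width 2.48 degrees around the mean.
BOND_ANGLE_MIN = 109.62
BOND_ANGLE_MAX = 112.1

#: default bump-check overlap factor on the squared sum of radii
DEFAULT_OVERLAP_FACTOR = 0.36

#: surrogate per-element van der Waals radii (Angstrom) for the bump check
ATOM_RADII = {"N": 1.55, "C": 1.7, "O": 1.52}
_BACKBONE_RADII = np.array([ATOM_RADII["N"], ATOM_RADII["C"],
                            ATOM_RADII["C"], ATOM_RADII["O"]])

ANCHOR_TOL = 1e-4  # Angstrom


@dataclass
class KicMove:
    """One kinematic closure proposal on a sub-segment.

    The per-residue proposal arrays cover ``sub_start..sub_end`` inclusive;
    NaN entries mean "keep the pose's current value".  Pivot phi/psi entries
    are ignored (they are solved).  ``omega[k]`` is the torsion of the
    peptide bond entering residue ``sub_start + k``.
    """

    sub_start: int
    sub_end: int
    phi: np.ndarray = None
    psi: np.ndarray = None
    omega: np.ndarray = None
    theta: np.ndarray = None

    def __post_init__(self):
        if self.sub_end - self.sub_start + 1 < 3:
            raise ValueError("sub-segment must span at least 3 residues")
        L = self.length
        for name in ("phi", "psi", "omega", "theta"):
            if getattr(self, name) is None:
                setattr(self, name, np.full(L, np.nan))

    @property
    def length(self) -> int:
        return self.sub_end - self.sub_start + 1

    @property
    def pivots(self) -> tuple:
        mid = (self.sub_start + self.sub_end) // 2
        return (self.sub_start, mid, self.sub_end)


@dataclass
class ClosureSolution:
    """Six solved pivot torsions plus the rebuilt sub-segment coordinates."""

    pivot_torsions: np.ndarray  # phi_s, psi_s, phi_m, psi_m, phi_e, psi_e
    coords: np.ndarray          # (sub_len, 4, 3)
    internals: dict = field(default_factory=dict)


def choose_subsegment(segment: SegmentDefinition,
                      rng: np.random.Generator) -> KicMove:
    """Uniformly choose a sub-segment of length >= 3 within the segment.

    All (start, end) pairs with end - start >= 2 are equally likely; the
    pivots are the sub-segment ends plus the floor-midpoint residue.
    """
    pairs = [(a, b)
             for a in range(segment.start, segment.end - 1)
             for b in range(a + 2, segment.end + 1)]
    a, b = pairs[int(rng.integers(len(pairs)))]
    return KicMove(sub_start=a, sub_end=b)


def sample_bond_angles(move: KicMove, mode: str,
                       rng: np.random.Generator) -> KicMove:
    """Fill the move's N-CA-C bond angles: i.i.d. uniform on
    [109.62, 112.1] degrees in ``varied`` mode, or the ideal constant in
    ``idealized`` mode."""
    from .geometry import IDEAL_ANGLE_N_CA_C

    if mode == "varied":
        move.theta = rng.uniform(BOND_ANGLE_MIN, BOND_ANGLE_MAX, move.length)
    elif mode == "idealized":
        move.theta = np.full(move.length, IDEAL_ANGLE_N_CA_C)
    else:
        raise ValueError(f"unknown bond-angle mode {mode!r}")
    return move


# ---------------------------------------------------------------------------
# solver internals

def _merge_internals(pose: Pose, move: KicMove) -> Pose:
    """Pose copy whose internal-coordinate arrays carry the move's proposals
    (NaN proposals keep the pose's values)."""
    out = pose.copy()
    s = move.sub_start
    for name in ("phi", "psi", "omega", "theta"):
        prop = getattr(move, name)
        tgt = getattr(out, name)
        ok = np.isfinite(prop)
        tgt[s - 1:s - 1 + move.length][ok] = prop[ok]
    return out


def solve_closure(pose: Pose, move: KicMove) -> list:
    """All distinct closure solutions for the move's six pivot torsions.

    Each solution, applied to the pose, reproduces the downstream anchor
    atoms to within 1e-4 Angstrom (verified by rebuild before returning) and
    leaves every non-pivot internal coordinate of the proposal untouched.
    Degenerate geometry yields an empty list with a logged diagnostic.
    """
    work = _merge_internals(pose, move)
    s, m, e = move.pivots
    if s < 2 or e > len(pose) - 1:
        raise ValueError(f"sub-segment [{s}, {e}] needs flanking anchor residues")
    torsions, coords, n_found, status = solve_closure_kernel(
        s, m, e, work.coords, work.phi, work.psi, work.omega, work.theta,
        work.bond_n_ca, work.bond_ca_c, work.bond_c_n,
        work.angle_ca_c_n, work.angle_c_n_ca, ANCHOR_TOL)
    if status:
        logger.debug("degenerate closure geometry for sub-segment [%d, %d]; "
                     "empty solution set", s, e)
        return []
    return [ClosureSolution(pivot_torsions=torsions[i].copy(),
                            coords=coords[i].copy())
            for i in range(n_found)]


def bump_filter(pose: Pose, move: KicMove, solutions: list,
                overlap_factor: float = DEFAULT_OVERLAP_FACTOR) -> list:
    """Solutions surviving the soft-sphere bump check.

    A solution is rejected if any pair of (moved sub-segment backbone atom,
    backbone atom of a non-adjacent residue or environment sphere) has
    squared distance below ``overlap_factor`` times the squared sum of the
    atomic radii.
    """
    s, e = move.sub_start, move.sub_end
    return [sol for sol in solutions
            if not bump_kernel(sol.coords.reshape(-1, 3), pose.coords, s, e,
                               _BACKBONE_RADII, pose.env_xyz,
                               pose.env_radius, overlap_factor)]


def apply_move(pose: Pose, move: KicMove, solution: ClosureSolution) -> Pose:
    """New pose with the move and chosen solution applied.

    All atoms outside the sub-segment are bit-identical to the input; the
    sub-segment's internal coordinates equal the proposal plus the solved
    pivot torsions.
    """
    if solution.coords.shape != (move.length, 4, 3):
        raise ValueError("solution does not match the move's sub-segment")
    out = _merge_internals(pose, move)
    s, m, e = move.pivots
    piv = solution.pivot_torsions
    out.phi[s - 1], out.psi[s - 1] = piv[0], piv[1]
    out.phi[m - 1], out.psi[m - 1] = piv[2], piv[3]
    out.phi[e - 1], out.psi[e - 1] = piv[4], piv[5]
    out.coords[s - 1:e] = solution.coords
    return out
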