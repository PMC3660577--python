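"""Backbone geometry: internal/Cartesian conversion, superposition and segment RMSD.

The backbone is represented per residue by the heavy atoms N, CA, C, O and by
internal coordinates: the torsions phi (C'-N-CA-C), psi (N-CA-C-N'') and omega,
the N-CA-C bond angle, and the three backbone bond lengths.  Omega is stored as
the torsion of the peptide bond *entering* a residue, i.e. ``omega[i]`` is the
dihedral CA(i-1)-C(i-1)-N(i)-CA(i); a cis peptide bond before residue ``i``
therefore shows up as ``|omega[i]| < 90``.

Angles are degrees in (-180, 180] at the API surface; lengths are Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

# Ideal backbone geometry (Engh/Huber-style constants, Angstrom and degrees).
IDEAL_BOND_N_CA = 1.458
IDEAL_BOND_CA_C = 1.525
IDEAL_BOND_C_N = 1.329
IDEAL_BOND_C_O = 1.231
IDEAL_ANGLE_N_CA_C = 111.2  # the "theta" angle varied by bond-angle sampling
IDEAL_ANGLE_CA_C_N = 116.2
IDEAL_ANGLE_C_N_CA = 121.7
IDEAL_ANGLE_CA_C_O = 120.1

BACKBONE_ATOMS = ("N", "CA", "C", "O")
ATOM_INDEX = {name: i for i, name in enumerate(BACKBONE_ATOMS)}


def normalize_angle(angle):
    """Map an angle in degrees onto (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle, dtype=float), 360.0)


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(normalize_angle(np.degrees(np.arctan2(y, x))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees).  Standard NeRF construction."""
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("collinear reference atoms for placement")
    n /= nn
    m = np.cross(n, bc)
    frame = np.stack([bc, m, n], axis=1)
    return c + frame @ d_local


@dataclass
class SegmentDefinition:
    """The loop to remodel: 1-based inclusive residue range with a cutpoint."""

    start: int
    end: int
    cutpoint: int | None = None

    def __post_init__(self):
        if self.cutpoint is None:
            self.cutpoint = (self.start + self.end) // 2
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} must precede end {self.end}")
        if self.length < 3:
            raise ValueError(f"segment [{self.start}, {self.end}] shorter than 3 residues")
        if not (self.start <= self.cutpoint < self.end):
            raise ValueError(f"cutpoint {self.cutpoint} outside [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        """1-based residue indices of the segment."""
        return range(self.start, self.end + 1)


@dataclass
class Pose:
    """Ordered backbone residues with internal and Cartesian coordinates.

    Arrays are indexed 0-based internally; the public residue numbering used in
    :class:`SegmentDefinition` and file formats is 1-based and contiguous.
    ``env_xyz``/``env_radius`` hold fixed environment spheres standing in for
    the surrounding protein.
    """

    aa: list
    coords: np.ndarray  # (n, 4, 3) for N, CA, C, O; NaN where unknown
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    theta: np.ndarray  # N-CA-C bond angle
    bond_n_ca: np.ndarray
    bond_ca_c: np.ndarray
    bond_c_n: np.ndarray  # bond_c_n[i] links C(i) to N(i+1); last entry unused
    angle_ca_c_n: np.ndarray
    angle_c_n_ca: np.ndarray
    chain_id: str = "A"
    env_xyz: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    env_radius: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        n = len(self.aa)
        if self.coords.shape != (n, 4, 3):
            raise ValueError("coords must have shape (n_residues, 4, 3)")
        for name in ("phi", "psi", "omega", "theta", "bond_n_ca", "bond_ca_c",
                     "bond_c_n", "angle_ca_c_n", "angle_c_n_ca"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")

    def __len__(self) -> int:
        return len(self.aa)

    def copy(self) -> "Pose":
        return replace(
            self,
            aa=list(self.aa),
            coords=self.coords.copy(),
            phi=self.phi.copy(),
            psi=self.psi.copy(),
            omega=self.omega.copy(),
            theta=self.theta.copy(),
            bond_n_ca=self.bond_n_ca.copy(),
            bond_ca_c=self.bond_ca_c.copy(),
            bond_c_n=self.bond_c_n.copy(),
            angle_ca_c_n=self.angle_ca_c_n.copy(),
            angle_c_n_ca=self.angle_c_n_ca.copy(),
            env_xyz=self.env_xyz.copy(),
            env_radius=self.env_radius.copy(),
        )

    def atom(self, resi: int, name: str) -> np.ndarray:
        """Coordinates of atom ``name`` of 1-based residue ``resi``."""
        return self.coords[resi - 1, ATOM_INDEX[name]]


def new_pose(aa, chain_id: str = "A") -> Pose:
    """A pose with ideal internal coordinates, extended torsions and no
    Cartesian coordinates yet."""
    n = len(aa)
    return Pose(
        aa=list(aa),
        coords=np.full((n, 4, 3), np.nan),
        phi=np.full(n, 180.0),
        psi=np.full(n, 180.0),
        omega=np.full(n, 180.0),
        theta=np.full(n, IDEAL_ANGLE_N_CA_C),
        bond_n_ca=np.full(n, IDEAL_BOND_N_CA),
        bond_ca_c=np.full(n, IDEAL_BOND_CA_C),
        bond_c_n=np.full(n, IDEAL_BOND_C_N),
        angle_ca_c_n=np.full(n, IDEAL_ANGLE_CA_C_N),
        angle_c_n_ca=np.full(n, IDEAL_ANGLE_C_N_CA),
        chain_id=chain_id,
    )


def place_carbonyl_oxygen(pose: Pose, resi: int) -> None:
    """Place O(resi) in the peptide plane: anti to N(resi+1) across the CA-C
    bond, or from psi for the final residue.  Deterministic ideal geometry."""
    i = resi - 1
    ca, c = pose.coords[i, 1], pose.coords[i, 2]
    if resi < len(pose) and np.all(np.isfinite(pose.coords[i + 1, 0])):
        ref = pose.coords[i + 1, 0]  # next N
        pose.coords[i, 3] = place_atom(ref, ca, c, IDEAL_BOND_C_O,
                                       IDEAL_ANGLE_CA_C_O, 180.0)
    else:
        n_atom = pose.coords[i, 0]
        tor = normalize_angle(pose.psi[i] - 180.0)
        pose.coords[i, 3] = place_atom(n_atom, ca, c, IDEAL_BOND_C_O,
                                       IDEAL_ANGLE_CA_C_O, float(tor))


def build_coordinates(pose: Pose, start: int = 1, end: int | None = None) -> Pose:
    """Compute Cartesian coordinates for residues ``start..end`` (1-based,
    inclusive) from internal coordinates by sequential atom placement.

    Residues preceding ``start`` must already have coordinates (they provide
    the anchor frame); atoms outside the range are untouched.  A chain built
    from residue 1 is seeded at the origin in a canonical orientation.

    Returns a new :class:`Pose`; raises ``ValueError`` naming the residue if
    anchor coordinates are missing.
    """
    if end is None:
        end = len(pose)
    out = pose.copy()
    c = out.coords
    for resi in range(start, end + 1):
        i = resi - 1
        if resi == 1:
            c[0, 0] = np.zeros(3)
            c[0, 1] = c[0, 0] + np.array([out.bond_n_ca[0], 0.0, 0.0])
            ang = np.radians(out.theta[0])
            c[0, 2] = c[0, 1] + out.bond_ca_c[0] * np.array(
                [-np.cos(ang), np.sin(ang), 0.0]
            )
            continue
        prev = i - 1
        if not np.all(np.isfinite(c[prev, :3])):
            raise ValueError(
                f"anchor residue {resi - 1} lacks backbone coordinates"
            )
        c[i, 0] = place_atom(c[prev, 0], c[prev, 1], c[prev, 2],
                             out.bond_c_n[prev], out.angle_ca_c_n[prev],
                             out.psi[prev])
        c[i, 1] = place_atom(c[prev, 1], c[prev, 2], c[i, 0],
                             out.bond_n_ca[i], out.angle_c_n_ca[i],
                             out.omega[i])
        c[i, 2] = place_atom(c[prev, 2], c[i, 0], c[i, 1],
                             out.bond_ca_c[i], out.theta[i], out.phi[i])
    for resi in range(start, end + 1):
        place_carbonyl_oxygen(out, resi)
    return out


def measure_internal(pose: Pose, start: int = 1, end: int | None = None) -> dict:
    """Internal coordinates measured from Cartesian coordinates.

    Inverse of :func:`build_coordinates`.  Chain-terminal torsions that lack
    the four atoms of their dihedral are returned as NaN.
    """
    if end is None:
        end = len(pose)
    n = len(pose)
    rng = range(start, end + 1)
    out = {k: np.full(len(pose), np.nan) for k in
           ("phi", "psi", "omega", "theta", "bond_n_ca", "bond_ca_c",
            "bond_c_n", "angle_ca_c_n", "angle_c_n_ca")}
    c = pose.coords
    for resi in rng:
        i = resi - 1
        N, CA, C = c[i, 0], c[i, 1], c[i, 2]
        out["bond_n_ca"][i] = np.linalg.norm(CA - N)
        out["bond_ca_c"][i] = np.linalg.norm(C - CA)
        out["theta"][i] = bond_angle(N, CA, C)
        if resi > 1:
            pC = c[i - 1, 2]
            out["phi"][i] = dihedral(pC, N, CA, C)
            out["omega"][i] = dihedral(c[i - 1, 1], pC, N, CA)
            out["angle_c_n_ca"][i] = bond_angle(pC, N, CA)
        if resi < n:
            nN = c[i + 1, 0]
            out["psi"][i] = dihedral(N, CA, C, nN)
            out["bond_c_n"][i] = np.linalg.norm(nN - C)
            out["angle_ca_c_n"][i] = bond_angle(CA, C, nN)
    return out


def sync_internal(pose: Pose, start: int = 1, end: int | None = None) -> Pose:
    """Pose whose internal-coordinate arrays are refreshed from Cartesian
    coordinates over ``start..end``; NaN measurements leave entries as-is."""
    meas = measure_internal(pose, start, end)
    out = pose.copy()
    for key, arr in meas.items():
        tgt = getattr(out, key)
        ok = np.isfinite(arr)
        tgt[ok] = arr[ok]
    return out


def _gather(pose: Pose, residues, atoms=BACKBONE_ATOMS) -> np.ndarray:
    idx = [ATOM_INDEX[a] for a in atoms]
    return pose.coords[np.asarray(list(residues)) - 1][:, idx, :].reshape(-1, 3)


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares (Kabsch) superposition of point set ``mobile`` onto
    ``target``; returns (rotation matrix, mobile centroid, target centroid)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.as_matrix(), mc, tc


def segment_rmsd(model: Pose, native: Pose, segment: SegmentDefinition,
                 atoms=BACKBONE_ATOMS) -> float:
    """Backbone RMSD of the remodeled segment after superposing everything else.

    The model is superposed onto the native on the N/CA/C/O atoms of all
    residues *outside* the segment, then the RMSD is computed over the
    N/CA/C/O atoms of the residues *inside* the segment.  Symmetric in its
    arguments and invariant under rigid transforms of either pose.
    """
    if len(model) != len(native):
        raise ValueError(
            f"model has {len(model)} residues but native has {len(native)}"
        )
    inside = list(segment.residues())
    outside = [r for r in range(1, len(model) + 1) if r not in set(inside)]
    if not outside:
        raise ValueError("segment covers the whole chain; nothing to superpose on")
    R, mc, tc = superpose(_gather(model, outside, atoms),
                          _gather(native, outside, atoms))
    mob = (_gather(model, inside, atoms) - mc) @ R.T + tc
    ref = _gather(native, inside, atoms)
    return float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
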