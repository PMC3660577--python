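"""PDB and loop-file I/O plus YAML configuration loading.

Only single-chain backbone (N, CA, C, O) structures are handled; environment
spheres are stored as HETATM records with residue name ENV so that fixtures
round-trip through a single file.  The loop file is a minimal whitespace
dialect: ``start end [cutpoint]`` per line, '#' comments, 1-based inclusive
boundaries.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .geometry import (
    BACKBONE_ATOMS,
    IDEAL_ANGLE_C_N_CA,
    IDEAL_ANGLE_CA_C_N,
    IDEAL_BOND_C_N,
    Pose,
    SegmentDefinition,
    new_pose,
    sync_internal,
)

#: a C(i)-N(i+1) distance above this (Angstrom) is treated as a chain break
CHAIN_BREAK_CUTOFF = 2.0

logger = logging.getLogger(__name__)

_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O"}

# minimal three-letter lookup for the one-letter codes we emit
_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
_ONE = {v: k for k, v in _THREE.items()}


def write_pdb(pose: Pose, path) -> None:
    """Write the backbone as fixed-column ATOM records (plus ENV HETATMs for
    environment spheres, radius stored in the B-factor column)."""
    lines = []
    serial = 1
    for i, aa in enumerate(pose.aa):
        res3 = _THREE.get(aa.upper(), "ALA")
        for j, name in enumerate(BACKBONE_ATOMS):
            x, y, z = pose.coords[i, j]
            if not np.isfinite([x, y, z]).all():
                continue
            pad_name = f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {pad_name}{res3:>4s} {pose.chain_id}"
                f"{i + 1:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {_ELEMENTS[name]:>2s}"
            )
            serial += 1
    for k in range(len(pose.env_xyz)):
        x, y, z = pose.env_xyz[k]
        r = pose.env_radius[k]
        lines.append(
            f"HETATM{serial:>5d}  C   ENV Z{k + 1:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{r:6.2f}           C"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> Pose:
    """Parse a single-chain backbone PDB written by this package (or any
    fixed-column PDB restricted to N/CA/C/O).

    Missing O atoms are rebuilt from ideal peptide geometry; a missing N, CA
    or C raises an error naming the residue.  Residues are renumbered
    contiguously from 1 (with a logged mapping) if the file has gaps.
    """
    residues: dict = {}
    env = []
    chains = set()
    for line in Path(path).read_text().splitlines():
        if line.startswith("HETATM") and line[17:20].strip() == "ENV":
            xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            env.append((xyz, float(line[60:66])))
            continue
        if not line.startswith("ATOM"):
            continue
        name = line[12:16].strip()
        if name not in BACKBONE_ATOMS:
            continue
        chain = line[21]
        chains.add(chain)
        resi = int(line[22:26])
        res3 = line[17:20].strip()
        xyz = np.array([float(line[30:38]), float(line[38:46]),
                        float(line[46:54])])
        residues.setdefault(resi, {"aa": _ONE.get(res3, "A")})[name] = xyz
    if len(chains) > 1:
        raise ValueError(
            f"file contains chains {sorted(chains)}; extract one chain first")
    if not residues:
        raise ValueError(f"no backbone ATOM records found in {path}")
    keys = sorted(residues)
    if keys != list(range(1, len(keys) + 1)):
        logger.info("renumbering residues contiguously: %s -> 1..%d",
                    keys[:5], len(keys))
    pose = new_pose([residues[k]["aa"] for k in keys],
                    chain_id=(chains.pop() if chains else "A"))
    for new_i, k in enumerate(keys):
        rec = residues[k]
        for name in ("N", "CA", "C"):
            if name not in rec:
                raise ValueError(f"residue {k} is missing backbone atom {name}")
        for j, name in enumerate(BACKBONE_ATOMS):
            if name in rec:
                pose.coords[new_i, j] = rec[name]
    if env:
        pose.env_xyz = np.array([x for x, _ in env])
        pose.env_radius = np.array([r for _, r in env])
    pose = sync_internal(pose)
    repair_chain_breaks(pose)
    from .geometry import place_carbonyl_oxygen

    for i in range(len(pose)):
        if not np.all(np.isfinite(pose.coords[i, 3])):
            place_carbonyl_oxygen(pose, i + 1)
    return pose


def repair_chain_breaks(pose: Pose, reference: Pose | None = None,
                        cutoff: float = CHAIN_BREAK_CUTOFF) -> list:
    """Re-idealise the internal coordinates spanning chain breaks.

    A start structure for loop remodeling carries a break at the segment
    boundary; internal coordinates measured across the gap (the peptide
    bond length/angles, omega and the downstream phi) are meaningless and
    would corrupt the closure anchors.  They are reset to ideal trans
    values, or copied from ``reference`` (e.g. the native structure, whose
    flanks are identical) when one is given.  Returns the 1-based residue
    indices i whose bond to i+1 was repaired.
    """
    repaired = []
    for i in range(len(pose) - 1):
        gap = float(np.linalg.norm(pose.coords[i + 1, 0] - pose.coords[i, 2]))
        if not np.isfinite(gap) or gap <= cutoff:
            continue
        if reference is not None:
            pose.bond_c_n[i] = reference.bond_c_n[i]
            pose.angle_ca_c_n[i] = reference.angle_ca_c_n[i]
            pose.angle_c_n_ca[i + 1] = reference.angle_c_n_ca[i + 1]
            pose.omega[i + 1] = reference.omega[i + 1]
            pose.phi[i + 1] = reference.phi[i + 1]
        else:
            pose.bond_c_n[i] = IDEAL_BOND_C_N
            pose.angle_ca_c_n[i] = IDEAL_ANGLE_CA_C_N
            pose.angle_c_n_ca[i + 1] = IDEAL_ANGLE_C_N_CA
            pose.omega[i + 1] = 180.0
            pose.phi[i + 1] = 180.0
        repaired.append(i + 1)
    if repaired:
        logger.info("re-idealised chain break(s) after residue(s) %s",
                    repaired)
    return repaired


def parse_loop_file(path) -> SegmentDefinition:
    """First record of a loop file: ``start end [cutpoint]`` (1-based,
    inclusive; cutpoint defaults to the midpoint)."""
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 'start end [cutpoint]'")
        try:
            nums = [int(p) for p in parts]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer field in {line!r}")
        try:
            return SegmentDefinition(*nums)
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: {err}")
    raise ValueError(f"{path}: no loop record found")


def write_loop_file(segment: SegmentDefinition, path) -> None:
    Path(path).write_text(
        f"{segment.start} {segment.end} {segment.cutpoint}\n")


def load_config(path) -> dict:
    """YAML key/value configuration for ProtocolConfig / EnergyWeights."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of options")
    return data
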