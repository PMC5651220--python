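"""Contact/clash classification from van der Waals overlap, and geometric H-bonds.

The central quantity is the *overlap* of an atom pair,

    overlap(i, j) = (r_vdW(i) + r_vdW(j)) - D(i, j),

so favorable near-touching pairs (``overlap >= -0.4`` Å by default) are
*contacts* and sterically impossible pairs (``overlap >= 1.0`` Å) are
*clashes*. The two classes are disjoint: a clash is not additionally a
contact (configurable). Hydrogen bonds use the standard geometric criterion:
donor–acceptor heavy-atom distance ≤ 3.5 Å and, when the donor carries an
explicit hydrogen, hydrogen–donor–acceptor angle ≤ 30°.

``enumerate_pose_interactions`` uses a k-d tree for the neighbor search but is
defined to be exactly equivalent to the exhaustive all-pairs double loop.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Set, Union

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .radii import BONDI_RADII, radius_for
from .structures import Atom, Pose, Receptor, ResidueKey

__all__ = [
    "InteractionParams",
    "HBond",
    "PoseInteractionRecord",
    "pair_overlap",
    "classify_pair",
    "assign_radii",
    "detect_hbonds",
    "enumerate_pose_interactions",
]

# Max distance (Å) at which an explicit H counts as covalently bonded to a donor.
DONOR_H_BOND_MAX = 1.25


@dataclass(frozen=True)
class InteractionParams:
    """Geometric thresholds for contact, clash and hydrogen-bond detection.

    contact_cutoff / clash_cutoff are *overlap* thresholds in Å: a pair is a
    contact when overlap >= contact_cutoff (default −0.4) and a clash when
    overlap >= clash_cutoff (default 1.0). ``clash_also_contact`` makes a
    clashing pair additionally count as a contact (off by default).
    """

    contact_cutoff: float = -0.4
    clash_cutoff: float = 1.0
    hbond_da_max: float = 3.5
    hbond_angle_max: float = 30.0
    include_hydrogens_in_contacts: bool = True
    clash_also_contact: bool = False

    def __post_init__(self) -> None:
        if not self.clash_cutoff > self.contact_cutoff:
            raise ConfigurationError(
                f"clash_cutoff ({self.clash_cutoff}) must exceed "
                f"contact_cutoff ({self.contact_cutoff})"
            )
        if self.hbond_da_max <= 0:
            raise ConfigurationError("hbond_da_max must be positive")
        if not 0 < self.hbond_angle_max < 90:
            raise ConfigurationError("hbond_angle_max must lie in (0, 90) degrees")


@dataclass
class HBond:
    """One detected hydrogen bond (donor may sit on either molecule)."""

    donor: Atom
    acceptor: Atom
    da_distance: float
    hydrogen: Optional[Atom] = None
    hda_angle: Optional[float] = None

    @property
    def receptor_residue(self) -> Optional[ResidueKey]:
        """Residue of whichever partner belongs to the receptor."""
        if self.donor.residue_key is not None:
            return self.donor.residue_key
        return self.acceptor.residue_key


@dataclass
class PoseInteractionRecord:
    """Per-residue contact/clash/H-bond event tallies for one pose."""

    pose_index: int
    contacts: Dict[ResidueKey, int] = field(default_factory=dict)
    clashes: Dict[ResidueKey, int] = field(default_factory=dict)
    hbonds: Dict[ResidueKey, int] = field(default_factory=dict)
    clashing_residues: Set[ResidueKey] = field(default_factory=set)


def pair_overlap(atom_i: Atom, atom_j: Atom) -> float:
    """Van der Waals overlap (r_i + r_j) − |x_i − x_j| in Å; symmetric."""
    for atom in (atom_i, atom_j):
        if atom.vdw_radius is None:
            raise ConfigurationError(
                f"atom {atom.serial} ({atom.element}) has no assigned vdW radius"
            )
    dist = float(np.linalg.norm(atom_i.coords - atom_j.coords))
    return atom_i.vdw_radius + atom_j.vdw_radius - dist


def classify_pair(
    atom_i: Atom, atom_j: Atom, params: InteractionParams = InteractionParams()
) -> Literal["clash", "contact", "none"]:
    """Classify a pair from its overlap: clash wins, then contact, else none."""
    overlap = pair_overlap(atom_i, atom_j)
    if overlap >= params.clash_cutoff:
        return "clash"
    if overlap >= params.contact_cutoff:
        return "contact"
    return "none"


def assign_radii(
    structure: Union[Receptor, Pose],
    radii_table: Optional[Dict[str, float]] = None,
    default_radius: Optional[float] = None,
) -> Union[Receptor, Pose]:
    """Set every atom's vdw_radius from its element; returns the same structure.

    Unknown elements fall back to ``default_radius`` (with a warning) or raise
    a ConfigurationError naming the element.
    """
    table = BONDI_RADII if radii_table is None else radii_table
    atoms: Sequence[Atom] = structure.atoms
    warned: Set[str] = set()
    for atom in atoms:
        key = atom.element.upper()
        if key in table:
            atom.vdw_radius = table[key]
        else:
            atom.vdw_radius = radius_for(atom.element, table, default_radius)
            if atom.element not in warned:
                warnings.warn(
                    f"element {atom.element!r} not in radii table; "
                    f"using default radius {default_radius} Å",
                    stacklevel=2,
                )
                warned.add(atom.element)
    return structure


def _donor_hydrogens(atoms: Sequence[Atom]) -> Dict[int, List[Atom]]:
    """Map atom-list index of each N/O to its covalently bonded explicit hydrogens.

    A hydrogen is bonded to a heavy atom when it lies within DONOR_H_BOND_MAX
    and (for receptor atoms) belongs to the same residue.
    """
    heavies = [
        (i, a) for i, a in enumerate(atoms) if a.element.upper() in ("N", "O")
    ]
    hydrogens = [a for a in atoms if a.is_hydrogen]
    out: Dict[int, List[Atom]] = {}
    if not heavies or not hydrogens:
        return out
    h_coords = np.array([h.coords for h in hydrogens])
    tree = cKDTree(h_coords)
    for i, heavy in heavies:
        for hj in tree.query_ball_point(heavy.coords, DONOR_H_BOND_MAX):
            h = hydrogens[hj]
            if heavy.residue_key is not None and h.residue_key != heavy.residue_key:
                continue
            out.setdefault(i, []).append(h)
    return out


def _hda_angle(donor: Atom, hydrogen: Atom, acceptor: Atom) -> float:
    """Angle (degrees) at the donor between donor→hydrogen and donor→acceptor."""
    v_h = hydrogen.coords - donor.coords
    v_a = acceptor.coords - donor.coords
    denom = np.linalg.norm(v_h) * np.linalg.norm(v_a)
    if denom == 0:
        return 0.0
    cosang = float(np.clip(np.dot(v_h, v_a) / denom, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def detect_hbonds(
    pose: Pose,
    receptor: Receptor,
    params: InteractionParams = InteractionParams(),
) -> List[HBond]:
    """Geometric hydrogen bonds between ligand and receptor, both directions.

    A donor is an N or O with at least one bonded explicit hydrogen; every N
    or O is a potential acceptor. When the donor carries no explicit hydrogen
    at all, the heavy-atom distance criterion alone decides and the angle is
    left unset (docking ligands frequently have non-polar hydrogens merged).
    """
    lig_atoms = pose.atoms
    rec_atoms = receptor.atoms
    lig_h = _donor_hydrogens(lig_atoms)
    rec_h = _donor_hydrogens(rec_atoms)
    lig_polar = [(i, a) for i, a in enumerate(lig_atoms) if a.element.upper() in ("N", "O")]
    rec_polar = [(i, a) for i, a in enumerate(rec_atoms) if a.element.upper() in ("N", "O")]
    if not lig_polar or not rec_polar:
        return []

    rec_tree = cKDTree(np.array([a.coords for _, a in rec_polar]))
    lig_has_h = any(a.is_hydrogen for a in lig_atoms)
    rec_has_h = any(a.is_hydrogen for a in rec_atoms)

    bonds: List[HBond] = []

    def _try(donor: Atom, d_hs: List[Atom], acceptor: Atom, dist: float,
             molecule_has_h: bool) -> None:
        if donor is acceptor:
            return
        if d_hs:
            best: Optional[float] = None
            best_h: Optional[Atom] = None
            for h in d_hs:
                ang = _hda_angle(donor, h, acceptor)
                if ang <= params.hbond_angle_max and (best is None or ang < best):
                    best, best_h = ang, h
            if best is not None:
                bonds.append(HBond(donor, acceptor, dist, best_h, best))
        elif not molecule_has_h:
            # No explicit hydrogens anywhere on the donor's molecule:
            # fall back to the distance-only criterion.
            bonds.append(HBond(donor, acceptor, dist))

    for li, lig in lig_polar:
        for rj in rec_tree.query_ball_point(lig.coords, params.hbond_da_max):
            ri, rec = rec_polar[rj]
            dist = float(np.linalg.norm(lig.coords - rec.coords))
            if dist > params.hbond_da_max:
                continue
            # ligand donor -> receptor acceptor
            _try(lig, lig_h.get(li, []), rec, dist, lig_has_h)
            # receptor donor -> ligand acceptor
            _try(rec, rec_h.get(ri, []), lig, dist, rec_has_h)
    return bonds


def enumerate_pose_interactions(
    pose: Pose,
    receptor: Receptor,
    params: InteractionParams = InteractionParams(),
) -> PoseInteractionRecord:
    """Tally contacts, clashes and H-bonds of one pose onto receptor residues.

    Equivalent to classifying every ligand-atom/receptor-atom pair with
    ``classify_pair`` and accumulating onto the receptor atom's residue;
    the k-d tree only prunes pairs that cannot reach the contact cutoff.
    """
    record = PoseInteractionRecord(pose_index=pose.index)
    lig_atoms = [
        a for a in pose.atoms
        if params.include_hydrogens_in_contacts or not a.is_hydrogen
    ]
    rec_atoms = [
        a for a in receptor.atoms
        if params.include_hydrogens_in_contacts or not a.is_hydrogen
    ]
    if lig_atoms and rec_atoms:
        for atom in lig_atoms + rec_atoms:
            if atom.vdw_radius is None:
                raise ConfigurationError(
                    f"atom {atom.serial} ({atom.element}) has no assigned vdW radius"
                )
        rec_coords = np.array([a.coords for a in rec_atoms])
        lig_coords = np.array([a.coords for a in lig_atoms])
        max_rsum = max(a.vdw_radius for a in lig_atoms) + max(
            a.vdw_radius for a in rec_atoms
        )
        # largest distance any pair could still be a contact at
        search_radius = max(max_rsum - params.contact_cutoff, 0.0)
        tree = cKDTree(rec_coords)
        for li, neighbors in enumerate(
            tree.query_ball_point(lig_coords, search_radius)
        ):
            lig = lig_atoms[li]
            for rj in neighbors:
                rec = rec_atoms[rj]
                dist = float(np.linalg.norm(lig_coords[li] - rec_coords[rj]))
                overlap = lig.vdw_radius + rec.vdw_radius - dist
                key = rec.residue_key
                if overlap >= params.clash_cutoff:
                    record.clashes[key] = record.clashes.get(key, 0) + 1
                    record.clashing_residues.add(key)
                    if params.clash_also_contact:
                        record.contacts[key] = record.contacts.get(key, 0) + 1
                elif overlap >= params.contact_cutoff:
                    record.contacts[key] = record.contacts.get(key, 0) + 1

    for hb in detect_hbonds(pose, receptor, params):
        key = hb.receptor_residue
        if key is not None:
            record.hbonds[key] = record.hbonds.get(key, 0) + 1
    return record
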