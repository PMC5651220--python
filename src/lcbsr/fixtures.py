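"""Synthetic receptors and pose ensembles with interaction counts known by
construction.

The toy receptor places small residues (N, CA, C, O backbone pattern plus a
hydrogen on N) on a widely spaced lattice — 30 Å between residues and 6 Å
between atoms within a residue — so every receptor atom's interaction sphere
(at most ~4 Å for the largest vdW pair) is independent. Each prescribed
event then puts one ligand atom at an exact distance from one receptor atom:

* contact: a carbon at vdW overlap +0.3 Å (inside the [−0.4, 1.0) window),
* clash:   a carbon at overlap +1.3 Å (≥ 1.0),
* H-bond:  a ligand N donor 2.9 Å from the residue's backbone O with a
  collinear H 1.0 Å from the N.

The H-bond geometry necessarily also registers contact pairs (N···O overlap
0.17 Å; H···O overlap 0.82 Å when hydrogens count), so the *expected* contact
count of a prescription is n_contacts + 2·n_hbonds (or + 1·n_hbonds with
hydrogens excluded); ``expected_pose_counts`` performs that bookkeeping.
Binding energies are prescribed, never sampled, so tier membership is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import FixtureError
from .structures import Atom, Pose, PoseEnsemble, Receptor, ResidueKey

__all__ = [
    "PosePrescription",
    "FixtureSpec",
    "make_toy_receptor",
    "make_pose_ensemble",
    "expected_pose_counts",
    "random_fixture_spec",
    "make_random_pose",
    "demo_fixture_specs",
]

RESIDUE_LATTICE = 30.0   # Å between residue origins
ATOM_SPACING = 6.0       # Å between atoms within one toy residue
CONTACT_OVERLAP = 0.3    # Å, safely inside the contact window
CLASH_OVERLAP = 1.3      # Å, safely past the clash threshold
HBOND_DA = 2.9           # Å donor–acceptor distance
NH_BOND = 1.0            # Å donor–hydrogen distance

# toy residue template: (atom name, element, z-offset)
_TEMPLATE = (
    ("N", "N", 0.0),
    ("CA", "C", 1.0 * ATOM_SPACING),
    ("C", "C", 2.0 * ATOM_SPACING),
    ("O", "O", 3.0 * ATOM_SPACING),
    ("H", "H", -NH_BOND),  # amide hydrogen, bonded to N
)
_RESNAMES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR", "ASP", "LYS")

_CARBON_R = 1.70
_OXYGEN_R = 1.52
_NITROGEN_R = 1.55


@dataclass(frozen=True)
class PosePrescription:
    """Intended events for one pose: residue index → (contacts, clashes, hbonds)."""

    binding_energy: float
    events: Mapping[int, Tuple[int, int, int]] = field(default_factory=dict)

    @property
    def n_event_atoms(self) -> int:
        return sum(c + cl + 2 * h for c, cl, h in self.events.values())


@dataclass(frozen=True)
class FixtureSpec:
    """Full prescription of a synthetic receptor + ensemble; seed-deterministic."""

    n_residues: int
    poses: Tuple[PosePrescription, ...] = ()
    seed: int = 0
    n_ligand_atoms: Optional[int] = None
    with_hydrogens: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "poses", tuple(self.poses))
        if self.n_residues <= 0:
            raise FixtureError("fixture needs at least one residue")
        for p, pres in enumerate(self.poses):
            for ridx, counts in pres.events.items():
                if not 0 <= ridx < self.n_residues:
                    raise FixtureError(f"pose {p}: residue index {ridx} out of range")
                if any(c < 0 for c in counts):
                    raise FixtureError(f"pose {p}: negative event count")


def make_toy_receptor(spec: FixtureSpec) -> Receptor:
    """Residues of 4–5 atoms on a ≥20 Å lattice; fully determined by the spec."""
    atoms: List[Atom] = []
    serial = 0
    template = _TEMPLATE if spec.with_hydrogens else _TEMPLATE[:4]
    for r in range(spec.n_residues):
        key = ResidueKey(
            chain="A", resnum=r + 1, icode="",
            resname=_RESNAMES[r % len(_RESNAMES)],
        )
        origin = np.array([r * RESIDUE_LATTICE, 0.0, 0.0])
        for name, element, dz in template:
            serial += 1
            atoms.append(
                Atom(
                    serial=serial, name=name, element=element,
                    coords=origin + np.array([0.0, 0.0, dz]),
                    is_hydrogen=element == "H", residue_key=key,
                )
            )
    return Receptor(atoms)


def _event_distance(overlap: float, rec_radius: float, lig_radius: float) -> float:
    return rec_radius + lig_radius - overlap


def expected_pose_counts(
    prescription: PosePrescription,
    include_hydrogens_in_contacts: bool = True,
) -> Dict[int, Tuple[int, int, int]]:
    """Expected per-residue (contacts, clashes, hbonds) as the interactions
    module will recover them, including the contacts induced by H-bond geometry."""
    induced = 2 if include_hydrogens_in_contacts else 1
    return {
        ridx: (c + induced * h, cl, h)
        for ridx, (c, cl, h) in prescription.events.items()
    }


def make_pose_ensemble(
    receptor: Receptor,
    spec: FixtureSpec,
    experiment_id: str = "exp1",
) -> PoseEnsemble:
    """Realize every prescription geometrically; all poses share one atom count.

    Contact and clash atoms alternate between the CA and C target atoms of a
    residue; H-bond donors always target the backbone O (the amide N carries
    the residue's hydrogen, so placing events there would induce extra
    contacts). Event directions lie in the x-y plane, perpendicular to the
    intra-residue z axis, so no unintended receptor atom is reachable. Filler
    atoms pad each pose to the common atom count ≥ 60 Å from the receptor.
    """
    if not spec.poses:
        raise FixtureError("fixture spec prescribes no poses")
    rng = np.random.default_rng(spec.seed)
    needed = max(p.n_event_atoms for p in spec.poses)
    n_atoms = spec.n_ligand_atoms if spec.n_ligand_atoms is not None else max(needed, 1)
    if n_atoms < needed:
        raise FixtureError(
            f"n_ligand_atoms={n_atoms} below the {needed} atoms events require"
        )

    poses: List[Pose] = []
    for pidx, pres in enumerate(spec.poses):
        atoms: List[Atom] = []
        serial = 0
        for ridx in sorted(pres.events):
            n_contacts, n_clashes, n_hbonds = pres.events[ridx]
            key = receptor.residues[ridx]
            res_atoms = {a.name: a for a in receptor.residue_atoms(key)}
            n_events = n_contacts + n_clashes + n_hbonds
            if n_events == 0:
                continue
            # distinct in-plane directions per event of this residue
            offset = rng.uniform(0.0, 2.0 * np.pi)
            angles = offset + 2.0 * np.pi * np.arange(n_events) / n_events
            e = 0
            for kind, count in (("contact", n_contacts), ("clash", n_clashes),
                                ("hbond", n_hbonds)):
                for _ in range(count):
                    direction = np.array(
                        [np.cos(angles[e]), np.sin(angles[e]), 0.0]
                    )
                    e += 1
                    if kind == "hbond":
                        target = res_atoms["O"]
                        donor_pos = target.coords + HBOND_DA * direction
                        h_pos = donor_pos - NH_BOND * direction
                        serial += 1
                        atoms.append(Atom(serial, "N1", "N", donor_pos))
                        serial += 1
                        atoms.append(
                            Atom(serial, "H1", "H", h_pos, is_hydrogen=True)
                        )
                    else:
                        target = res_atoms["CA"] if e % 2 else res_atoms["C"]
                        overlap = CONTACT_OVERLAP if kind == "contact" else CLASH_OVERLAP
                        dist = _event_distance(overlap, _CARBON_R, _CARBON_R)
                        serial += 1
                        atoms.append(
                            Atom(serial, "C1", "C", target.coords + dist * direction)
                        )
        while len(atoms) < n_atoms:
            serial += 1
            j = n_atoms - len(atoms)
            atoms.append(
                Atom(serial, "C1", "C",
                     np.array([5.0 * j, -60.0, -60.0]))
            )
        poses.append(
            Pose(index=pidx + 1, atoms=atoms, binding_energy=pres.binding_energy)
        )
    return PoseEnsemble(experiment_id=experiment_id, poses=poses)


def random_fixture_spec(
    seed: int,
    n_residues_range: Tuple[int, int] = (3, 10),
    n_poses_range: Tuple[int, int] = (2, 5),
    max_events: int = 3,
) -> FixtureSpec:
    """A random but realizable prescription: random residues, poses, event
    counts and binding energies spanning the default tier thresholds."""
    rng = np.random.default_rng(seed)
    n_res = int(rng.integers(*n_residues_range, endpoint=True))
    n_poses = int(rng.integers(*n_poses_range, endpoint=True))
    poses = []
    for _ in range(n_poses):
        events = {}
        for ridx in range(n_res):
            if rng.random() < 0.6:
                events[ridx] = (
                    int(rng.integers(0, max_events + 1)),
                    int(rng.integers(0, max_events + 1)),
                    int(rng.integers(0, 2)),
                )
        energy = float(np.round(rng.uniform(-9.0, -1.0), 2))
        poses.append(PosePrescription(binding_energy=energy, events=events))
    return FixtureSpec(n_residues=n_res, poses=tuple(poses), seed=seed)


def make_random_pose(
    receptor: Receptor,
    n_atoms: int,
    rng: np.random.Generator,
    index: int = 1,
    binding_energy: float = -5.0,
) -> Pose:
    """A geometry-free random pose for oracle-equivalence testing.

    Half the atoms are scattered near randomly chosen receptor atoms
    (offsets 1.2–8 Å, so contacts, clashes and H-bond distances all occur);
    the rest are uniform in the receptor bounding box padded by 5 Å. Counts
    are *not* known by construction — they are whatever the geometry gives.
    """
    rec_coords = receptor.coords()
    lo, hi = rec_coords.min(axis=0) - 5.0, rec_coords.max(axis=0) + 5.0
    elements = ("C", "N", "O", "H", "S")
    atoms: List[Atom] = []
    for i in range(n_atoms):
        if rng.random() < 0.5:
            anchor = rec_coords[rng.integers(len(rec_coords))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = anchor + rng.uniform(1.2, 8.0) * direction
        else:
            pos = rng.uniform(lo, hi)
        element = elements[rng.integers(len(elements))]
        atoms.append(
            Atom(i + 1, f"{element}{i + 1}", element, pos,
                 is_hydrogen=element == "H")
        )
    return Pose(index=index, atoms=atoms, binding_energy=binding_energy)


def demo_fixture_specs(seed: int = 0) -> Tuple[FixtureSpec, ...]:
    """Three blind-docking experiments over one 4-residue receptor.

    Residues 0 and 1 interact in every experiment (residue 0 more strongly
    and mostly through low-energy poses), residue 2 only in the first
    experiment (so the presence filter drops it), residue 3 never. Energies
    straddle all three default tier thresholds.
    """
    energies = (-7.5, -5.0, -4.5, -3.5, -2.5, -1.5)
    specs = []
    for e in range(3):
        poses = []
        for p, energy in enumerate(energies):
            events: Dict[int, Tuple[int, int, int]] = {}
            if p <= 3:
                events[0] = (4, 1, 1)
            elif p == 4:
                events[0] = (2, 0, 0)
            if p <= 2:
                events[1] = (3, 1, 1)
            if e == 0 and p <= 1:
                events[2] = (2, 1, 1)
            poses.append(PosePrescription(binding_energy=energy, events=events))
        specs.append(
            FixtureSpec(n_residues=4, poses=tuple(poses), seed=seed + e)
        )
    return tuple(specs)
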