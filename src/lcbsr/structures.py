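"""Core in-memory containers: atoms, residues, receptors and docked-pose ensembles.

Coordinates are ångström 3-vectors (numpy float64). A ``Receptor`` is a flat,
file-ordered atom list grouped into residues; a ``PoseEnsemble`` is one docking
experiment's set of ligand conformations, each carrying the docking engine's
estimated free energy of binding in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .errors import DataError, FormatError

__all__ = [
    "Atom",
    "ResidueKey",
    "Receptor",
    "Pose",
    "PoseEnsemble",
]


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, sequence number, insertion code, name.

    Ordering is (chain, resnum, icode), matching the tie-break used when
    score tables are written.
    """

    chain: str
    resnum: int
    icode: str = ""
    resname: str = field(default="UNK", compare=False)

    @property
    def label(self) -> str:
        """Human-readable label in the conventional RES-NUM style, e.g. ``ASP-564``."""
        suffix = self.icode.strip()
        return f"{self.resname}-{self.resnum}{suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chain}/{self.label}"


@dataclass
class Atom:
    """One atom: serial, name, element, coordinates and (once assigned) a vdW radius.

    ``residue_key`` is set for receptor atoms only; ligand atoms carry ``None``.
    ``element`` is an element symbol or the sentinel ``"unknown"``.
    """

    serial: int
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: Optional[float] = None
    is_hydrogen: bool = False
    residue_key: Optional[ResidueKey] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (3,):
            raise DataError(f"atom {self.serial}: coords must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise DataError(f"atom {self.serial}: non-finite coordinates")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise DataError(f"atom {self.serial}: vdw_radius must be positive")


class Receptor:
    """A parsed receptor: ordered atoms grouped into ordered residues."""

    def __init__(self, atoms: Sequence[Atom]):
        if not atoms:
            raise DataError("receptor must contain at least one atom")
        self.atoms: List[Atom] = list(atoms)
        self.residues: List[ResidueKey] = []
        self._residue_atoms: Dict[ResidueKey, List[Atom]] = {}
        for atom in self.atoms:
            if atom.residue_key is None:
                raise DataError(f"receptor atom {atom.serial} has no residue key")
            key = atom.residue_key
            if key not in self._residue_atoms:
                self._residue_atoms[key] = []
                self.residues.append(key)
            self._residue_atoms[key].append(atom)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_atoms(self, key: ResidueKey) -> List[Atom]:
        return self._residue_atoms[key]

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in file order."""
        return np.array([a.coords for a in self.atoms], dtype=np.float64)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)


@dataclass
class Pose:
    """One docked ligand conformation with its predicted binding energy (kcal/mol)."""

    index: int
    atoms: List[Atom]
    binding_energy: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.binding_energy):
            raise DataError(f"pose {self.index}: non-finite binding energy")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=np.float64)


@dataclass
class PoseEnsemble:
    """All poses from one blind-docking experiment."""

    experiment_id: str
    poses: List[Pose]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.poses:
            raise DataError(f"ensemble {self.experiment_id!r} has no poses")
        indices = [p.index for p in self.poses]
        if len(set(indices)) != len(indices):
            raise FormatError(f"ensemble {self.experiment_id!r}: duplicate pose indices")
        counts = {p.n_atoms for p in self.poses}
        if len(counts) != 1:
            raise FormatError(
                f"ensemble {self.experiment_id!r}: inconsistent atom counts "
                f"across poses ({sorted(counts)})"
            )

    @property
    def n_poses(self) -> int:
        return len(self.poses)

    def energies(self) -> Tuple[float, ...]:
        return tuple(p.binding_energy for p in self.poses)
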