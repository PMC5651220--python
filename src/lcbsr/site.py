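"""Binding-site construction: residue selection, center of geometry, grid box.

The refined-docking search box is an AutoDock-style grid: a center, a number
of grid points per axis (npts, even integers by autogrid convention) and a
point spacing (0.375 Å default). The physical edge length per axis is
npts × spacing, which is also the Vina-style box size in Å.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Literal, Mapping, Sequence, Tuple, Union

import numpy as np

from .errors import ConfigurationError, DataError, InputOutputError
from .scoring import AggregatedScore
from .structures import Receptor, ResidueKey

__all__ = [
    "BindingSite",
    "GridSpec",
    "select_residues",
    "center_of_geometry",
    "build_grid",
    "write_site_report",
]

DEFAULT_SPACING = 0.375


@dataclass(frozen=True)
class BindingSite:
    """Selected residues with their center of geometry and bounding box."""

    residues: Tuple[ResidueKey, ...]
    center: Tuple[float, float, float]
    bbox_min: Tuple[float, float, float]
    bbox_max: Tuple[float, float, float]


@dataclass(frozen=True)
class GridSpec:
    """An AutoDock search box: center, even npts per axis, spacing in Å."""

    center: Tuple[float, float, float]
    npts: Tuple[int, int, int]
    spacing: float = DEFAULT_SPACING

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ConfigurationError("grid spacing must be positive")
        if any(n <= 0 or n % 2 for n in self.npts):
            raise ConfigurationError(f"npts must be positive even integers: {self.npts}")

    @property
    def size_angstrom(self) -> Tuple[float, float, float]:
        """Physical edge lengths npts × spacing (the Vina box size)."""
        return tuple(n * self.spacing for n in self.npts)

    def gpf_fragment(self) -> str:
        """autogrid parameter-file lines for this box."""
        cx, cy, cz = self.center
        return (
            f"npts {self.npts[0]} {self.npts[1]} {self.npts[2]}"
            "                        # num. grid points in xyz\n"
            f"spacing {self.spacing:.3f}"
            "                          # spacing (A)\n"
            f"gridcenter {cx:.3f} {cy:.3f} {cz:.3f}"
            "     # xyz-coordinates or auto\n"
        )

    def vina_config(self) -> str:
        """AutoDock Vina configuration lines (sizes in Å)."""
        cx, cy, cz = self.center
        sx, sy, sz = self.size_angstrom
        return (
            f"center_x = {cx:.3f}\ncenter_y = {cy:.3f}\ncenter_z = {cz:.3f}\n"
            f"size_x = {sx:.3f}\nsize_y = {sy:.3f}\nsize_z = {sz:.3f}\n"
        )


def select_residues(
    scores: Mapping[ResidueKey, AggregatedScore],
    threshold: Union[float, Literal["mean"], None] = "mean",
    top_k: int = 0,
) -> List[ResidueKey]:
    """Pick high-scoring residues.

    Absolute mode (numeric ``threshold``) keeps residues with final_score
    strictly above it; ``"mean"`` mode keeps those strictly above the mean
    final score; ``top_k`` > 0 keeps the k best, with boundary ties all kept.
    Result order follows (chain, resnum, icode).
    """
    if not scores:
        raise DataError("cannot select residues from an empty score map")
    finals = {key: s.final_score for key, s in scores.items()}
    if top_k > 0:
        if top_k >= len(finals):
            if top_k > len(finals):
                warnings.warn(
                    f"top_k={top_k} exceeds the {len(finals)} scored residues; "
                    "keeping all",
                    stacklevel=2,
                )
            selected = set(finals)
        else:
            cutoff = sorted(finals.values(), reverse=True)[top_k - 1]
            selected = {k for k, v in finals.items() if v >= cutoff}
    else:
        if threshold == "mean":
            cut = float(np.mean(list(finals.values())))
        elif isinstance(threshold, (int, float)):
            cut = float(threshold)
        else:
            raise ConfigurationError(
                f"threshold must be a number or 'mean', got {threshold!r}"
            )
        selected = {k for k, v in finals.items() if v > cut}
    return sorted(selected)


def center_of_geometry(
    residues: Sequence[ResidueKey],
    receptor: Receptor,
    mode: Literal["all_atoms", "ca_only"] = "all_atoms",
) -> np.ndarray:
    """Unweighted mean coordinate of the selected residues' atoms.

    ``ca_only`` uses the CA atom of each residue, falling back (with a
    warning) to all atoms of a residue that lacks one.
    """
    if not residues:
        raise DataError("center_of_geometry needs at least one residue")
    coords: List[np.ndarray] = []
    for key in residues:
        atoms = receptor.residue_atoms(key)
        if mode == "ca_only":
            cas = [a for a in atoms if a.name.strip().upper() == "CA"]
            if not cas:
                warnings.warn(
                    f"residue {key.label} has no CA atom; using all its atoms",
                    stacklevel=2,
                )
                cas = atoms
            coords.extend(a.coords for a in cas)
        else:
            coords.extend(a.coords for a in atoms)
    return np.mean(np.array(coords), axis=0)


def _selected_coords(residues: Sequence[ResidueKey], receptor: Receptor) -> np.ndarray:
    return np.array(
        [a.coords for key in residues for a in receptor.residue_atoms(key)]
    )


def build_site(residues: Sequence[ResidueKey], receptor: Receptor) -> BindingSite:
    """Bounding box and all-atom center of geometry of a residue selection."""
    coords = _selected_coords(residues, receptor)
    center = center_of_geometry(residues, receptor)
    return BindingSite(
        residues=tuple(sorted(residues)),
        center=tuple(float(v) for v in center),
        bbox_min=tuple(float(v) for v in coords.min(axis=0)),
        bbox_max=tuple(float(v) for v in coords.max(axis=0)),
    )


def build_grid(
    residues: Sequence[ResidueKey],
    receptor: Receptor,
    spacing: float = DEFAULT_SPACING,
    padding: float = 0.0,
) -> GridSpec:
    """Smallest even-npts grid centered on the selection's center of geometry
    that contains every selected atom center plus ``padding`` Å per side."""
    if not residues:
        raise DataError("build_grid needs at least one residue")
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be positive")
    coords = _selected_coords(residues, receptor)
    center = center_of_geometry(residues, receptor)
    half_extent = np.abs(coords - center).max(axis=0) + padding
    npts = []
    for h in half_extent:
        n = int(np.ceil(2.0 * h / spacing))
        n += n % 2  # round up to even
        npts.append(max(n, 2))
    return GridSpec(
        center=tuple(float(v) for v in center),
        npts=tuple(npts),
        spacing=spacing,
    )


def write_site_report(
    site: BindingSite,
    grid: GridSpec,
    scores: Mapping[ResidueKey, AggregatedScore],
    path: Union[str, Path],
) -> Dict:
    """Write the JSON site report plus sibling GPF fragment and Vina config.

    ``path`` names the JSON file; ``<stem>.gpf`` and ``<stem>.vina.txt`` are
    written next to it. Output is deterministic (sorted keys, fixed float
    formatting). Returns the report dict.
    """
    if not site.residues:
        raise DataError("refusing to write a site report with no residues")
    report = {
        "residues": [
            {
                "chain": key.chain,
                "resnum": key.resnum,
                "icode": key.icode,
                "resname": key.resname,
                "label": key.label,
                "final_score": round(scores[key].final_score, 6)
                if key in scores else None,
            }
            for key in site.residues
        ],
        "n_residues": len(site.residues),
        "center": [round(v, 6) for v in site.center],
        "bbox_min": [round(v, 6) for v in site.bbox_min],
        "bbox_max": [round(v, 6) for v in site.bbox_max],
        "grid": {
            "center": [round(v, 6) for v in grid.center],
            "npts": list(grid.npts),
            "spacing": grid.spacing,
            "size_angstrom": [round(v, 6) for v in grid.size_angstrom],
        },
        "gpf_fragment": grid.gpf_fragment(),
        "vina_config": grid.vina_config(),
    }
    path = Path(path)
    try:
        path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        path.with_suffix(".gpf").write_text(grid.gpf_fragment())
        path.with_suffix(".vina.txt").write_text(grid.vina_config())
    except OSError as exc:
        raise InputOutputError(f"cannot write site report {path}: {exc}") from exc
    return report
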