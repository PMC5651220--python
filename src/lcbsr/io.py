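"""Readers and writers for docking file formats and score tables.

Plain PDB files (receptor or multi-model pose files) are parsed with gemmi.
PDBQT (AutoDock's PDB dialect with partial charges and atom types) and DLG
(AutoDock docking logs, whose pose blocks are ``DOCKED:``-prefixed PDBQT
records containing an "Estimated Free Energy of Binding" line) are AutoDock-
specific dialects parsed here directly.

Multi-model pose files that carry no embedded energies require an *energy
sidecar*: two whitespace-delimited columns, model index and kcal/mol.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import gemmi
import numpy as np
import pandas as pd

from .errors import (
    EmptyStructureError,
    FormatError,
    InputOutputError,
    MissingEnergyError,
)
from .structures import Atom, Pose, PoseEnsemble, Receptor, ResidueKey

__all__ = [
    "read_receptor",
    "read_pose_ensemble",
    "read_energy_table",
    "write_receptor_pdb",
    "write_pose_ensemble_pdbqt",
    "write_energy_table",
    "write_pose_ensemble_dlg",
    "write_score_table",
    "read_score_table",
]

WATER_NAMES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP3"})

# AutoDock atom type -> element. 'A' is aromatic carbon; trailing letters
# mark H-bond capability (OA, NA, HD, SA ...).
AUTODOCK_ELEMENTS: Dict[str, str] = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N",
    "O": "O", "OA": "O", "OS": "O", "S": "S", "SA": "S",
    "H": "H", "HD": "H", "HS": "H", "P": "P", "F": "F",
    "CL": "Cl", "BR": "Br", "I": "I", "MG": "Mg", "MN": "Mn",
    "ZN": "Zn", "CA": "Ca", "FE": "Fe", "W": "O",
}

_ENERGY_MARKER = "Estimated Free Energy of Binding"


def _element_from_name(name: str) -> str:
    """Heuristic element from a PDB atom name (fallback when no element column)."""
    stripped = name.strip()
    if not stripped:
        return "unknown"
    if len(name) >= 2 and name[0] != " " and name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA"):
        return name[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "unknown"


def _autodock_element(ad_type: str) -> str:
    elem = AUTODOCK_ELEMENTS.get(ad_type.upper())
    if elem is None:
        alpha = next((c for c in ad_type if c.isalpha()), None)
        elem = alpha.upper() if alpha else "unknown"
        warnings.warn(
            f"unknown AutoDock atom type {ad_type!r}; treating element as {elem!r}",
            stacklevel=3,
        )
    return elem


def _parse_pdbqt_atom_line(line: str, is_pdbqt: bool) -> Optional[dict]:
    """Parse one ATOM/HETATM record (fixed PDB columns). Returns None for blanks."""
    record = line[:6].strip()
    if record not in ("ATOM", "HETATM"):
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16]
        altloc = line[16:17]
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resnum = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise FormatError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    if is_pdbqt:
        ad_type = line[77:79].strip() or line[76:].strip()
        element = _autodock_element(ad_type) if ad_type else _element_from_name(name)
    else:
        element = line[76:78].strip().capitalize() or _element_from_name(name)
    return {
        "serial": serial, "name": name.strip(), "altloc": altloc.strip(),
        "resname": resname, "chain": chain, "resnum": resnum, "icode": icode,
        "coords": np.array([x, y, z]), "element": element, "het": record == "HETATM",
    }


def _atoms_from_lines(
    lines: Sequence[str], is_pdbqt: bool
) -> List[dict]:
    parsed = []
    for line in lines:
        rec = _parse_pdbqt_atom_line(line, is_pdbqt)
        if rec is not None:
            parsed.append(rec)
    return parsed


def _build_receptor(
    records: Sequence[dict],
    keep_waters: bool,
    keep_hetero: bool,
    water_names: frozenset,
) -> Receptor:
    atoms: List[Atom] = []
    seen_altloc: Dict[tuple, str] = {}
    for rec in records:
        if not keep_waters and rec["resname"].upper() in water_names:
            continue
        if not keep_hetero and rec["het"]:
            continue
        # keep the first altloc only
        atom_id = (rec["chain"], rec["resnum"], rec["icode"], rec["name"])
        if rec["altloc"]:
            if atom_id in seen_altloc and seen_altloc[atom_id] != rec["altloc"]:
                continue
            seen_altloc[atom_id] = rec["altloc"]
        key = ResidueKey(rec["chain"], rec["resnum"], rec["icode"], rec["resname"])
        elem = rec["element"]
        atoms.append(
            Atom(
                serial=rec["serial"], name=rec["name"], element=elem,
                coords=rec["coords"], is_hydrogen=elem.upper() in ("H", "D"),
                residue_key=key,
            )
        )
    if not atoms:
        raise EmptyStructureError("no atoms parsed from structure")
    return Receptor(atoms)


def _receptor_from_gemmi(
    path: Path, keep_waters: bool, keep_hetero: bool, water_names: frozenset
) -> Receptor:
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, OSError, ValueError) as exc:
        raise InputOutputError(f"cannot read {path}: {exc}") from exc
    records = []
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                elem = at.element.name if at.element.name != "X" else _element_from_name(at.name)
                records.append({
                    "serial": at.serial, "name": at.name,
                    "altloc": at.altloc if at.altloc != "\x00" else "",
                    "resname": res.name, "chain": chain.name or "A",
                    "resnum": res.seqid.num, "icode": res.seqid.icode.strip(),
                    "coords": np.array([at.pos.x, at.pos.y, at.pos.z]),
                    "element": elem, "het": res.het_flag == "H",
                })
    return _build_receptor(records, keep_waters, keep_hetero, water_names)


def read_receptor(
    path: Union[str, Path],
    format: str = "auto",
    keep_waters: bool = False,
    keep_hetero: bool = True,
    water_names: frozenset = WATER_NAMES,
) -> Receptor:
    """Read a receptor from PDB or PDBQT; waters stripped by default."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"receptor file not found: {path}")
    if format == "auto":
        format = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    if format == "pdb":
        return _receptor_from_gemmi(path, keep_waters, keep_hetero, water_names)
    if format == "pdbqt":
        try:
            lines = path.read_text().splitlines()
        except OSError as exc:
            raise InputOutputError(f"cannot read {path}: {exc}") from exc
        records = _atoms_from_lines(lines, is_pdbqt=True)
        return _build_receptor(records, keep_waters, keep_hetero, water_names)
    raise InputOutputError(f"unknown receptor format {format!r}")


def _ligand_atoms(records: Sequence[dict]) -> List[Atom]:
    atoms = []
    for rec in records:
        elem = rec["element"]
        atoms.append(
            Atom(
                serial=rec["serial"], name=rec["name"], element=elem,
                coords=rec["coords"], is_hydrogen=elem.upper() in ("H", "D"),
            )
        )
    return atoms


def read_energy_table(path: Union[str, Path]) -> Dict[int, float]:
    """Energy sidecar: two whitespace-delimited columns, model index and kcal/mol."""
    energies: Dict[int, float] = {}
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InputOutputError(f"cannot read energy table {path}: {exc}") from exc
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'INDEX ENERGY', got {raw!r}")
        try:
            energies[int(parts[0])] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad entry {raw!r}") from exc
    return energies


def _poses_from_model_blocks(
    blocks: List[tuple], energies: Optional[Dict[int, float]]
) -> List[Pose]:
    poses = []
    for index, atoms, embedded in blocks:
        if embedded is not None:
            energy = embedded
        elif energies is not None and index in energies:
            energy = energies[index]
        else:
            raise MissingEnergyError(
                f"pose {index}: no binding energy (embedded or sidecar)"
            )
        poses.append(Pose(index=index, atoms=atoms, binding_energy=energy))
    return poses


def _parse_multimodel_text(
    lines: Sequence[str], is_pdbqt: bool
) -> List[tuple]:
    """Split MODEL/ENDMDL blocks into (index, atoms, embedded_energy) tuples."""
    blocks: List[tuple] = []
    current: Optional[List[str]] = None
    index = 0
    energy: Optional[float] = None
    for line in lines:
        if line.startswith("MODEL"):
            parts = line.split()
            index = int(parts[1]) if len(parts) > 1 else index + 1
            current = []
            energy = None
        elif line.startswith("ENDMDL"):
            if current is not None:
                records = _atoms_from_lines(current, is_pdbqt)
                blocks.append((index, _ligand_atoms(records), energy))
            current = None
        elif current is not None:
            if _ENERGY_MARKER in line:
                energy = _extract_energy(line)
            current.append(line)
    if not blocks:
        # single-model file without MODEL records
        records = _atoms_from_lines(lines, is_pdbqt)
        if records:
            blocks.append((1, _ligand_atoms(records), None))
    return blocks


def _extract_energy(line: str) -> float:
    after = line.split("=", 1)
    field = after[1] if len(after) == 2 else line.split(_ENERGY_MARKER, 1)[1]
    for token in field.split():
        try:
            return float(token)
        except ValueError:
            continue
    raise FormatError(f"cannot parse binding energy from line: {line.rstrip()!r}")


def read_pose_ensemble(
    path: Union[str, Path],
    format: str = "auto",
    energy_table: Optional[Union[str, Path]] = None,
    experiment_id: Optional[str] = None,
) -> PoseEnsemble:
    """Read a docked-pose ensemble from DLG, multi-model PDBQT or multi-model PDB.

    DLG embeds one "Estimated Free Energy of Binding" per DOCKED block; plain
    multi-model files need ``energy_table`` unless each MODEL block carries its
    own energy line.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"pose file not found: {path}")
    if format == "auto":
        suffix = path.suffix.lower()
        format = {
            ".dlg": "dlg", ".pdbqt": "multimodel_pdbqt", ".pdb": "multimodel_pdb",
        }.get(suffix, "multimodel_pdb")
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise InputOutputError(f"cannot read {path}: {exc}") from exc

    energies = read_energy_table(energy_table) if energy_table is not None else None

    if format == "dlg":
        docked = [ln[8:] for ln in lines if ln.startswith("DOCKED: ")]
        docked += [ln[7:] for ln in lines if ln.startswith("DOCKED:") and not ln.startswith("DOCKED: ")]
        blocks = _parse_multimodel_text(docked, is_pdbqt=True)
    elif format == "multimodel_pdbqt":
        blocks = _parse_multimodel_text(lines, is_pdbqt=True)
    elif format == "multimodel_pdb":
        blocks = _parse_multimodel_text(lines, is_pdbqt=False)
    else:
        raise InputOutputError(f"unknown ensemble format {format!r}")

    if not blocks:
        raise EmptyStructureError(f"{path}: no poses parsed")
    poses = _poses_from_model_blocks(blocks, energies)
    return PoseEnsemble(
        experiment_id=experiment_id or path.stem,
        poses=poses,
        source_path=str(path),
    )


# ---------------------------------------------------------------------------
# writers


def _format_atom_line(
    atom: Atom, serial: int, resname: str, chain: str, resnum: int,
    record: str = "ATOM", pdbqt: bool = False,
) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    line = (
        f"{record:<6s}{serial:>5d} {name:<4s} {resname:<3s} {chain:1s}"
        f"{resnum:>4d}    {atom.coords[0]:8.3f}{atom.coords[1]:8.3f}"
        f"{atom.coords[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
    )
    if pdbqt:
        ad_type = {"C": "C", "N": "N", "O": "OA", "H": "HD", "S": "SA"}.get(
            atom.element.upper(), atom.element[:2].upper()
        )
        line += f"    {0.000:6.3f} {ad_type:<2s}"
    else:
        line += f"          {atom.element[:2]:>2s}"
    return line


def write_receptor_pdb(receptor: Receptor, path: Union[str, Path]) -> None:
    """Write a receptor as a single-model PDB file."""
    lines = []
    serial = 0
    for key in receptor.residues:
        for atom in receptor.residue_atoms(key):
            serial += 1
            lines.append(
                _format_atom_line(atom, serial, key.resname, key.chain, key.resnum)
            )
    lines.append("END")
    _write_text(path, "\n".join(lines) + "\n")


def _pose_block_lines(pose: Pose, pdbqt: bool, resname: str = "LIG") -> List[str]:
    lines = []
    for i, atom in enumerate(pose.atoms, start=1):
        lines.append(
            _format_atom_line(atom, i, resname, "X", 1, record="HETATM", pdbqt=pdbqt)
        )
    return lines


def write_pose_ensemble_pdbqt(
    ensemble: PoseEnsemble, path: Union[str, Path],
    energy_table_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write an ensemble as multi-model PDBQT; energies go to a sidecar table."""
    lines = []
    for pose in ensemble.poses:
        lines.append(f"MODEL {pose.index:>8d}")
        lines.extend(_pose_block_lines(pose, pdbqt=True))
        lines.append("ENDMDL")
    _write_text(path, "\n".join(lines) + "\n")
    if energy_table_path is not None:
        write_energy_table(ensemble, energy_table_path)


def write_energy_table(ensemble: PoseEnsemble, path: Union[str, Path]) -> None:
    rows = [f"{p.index}\t{p.binding_energy:.4f}" for p in ensemble.poses]
    _write_text(path, "# model\tbinding_energy_kcal_mol\n" + "\n".join(rows) + "\n")


def write_pose_ensemble_dlg(ensemble: PoseEnsemble, path: Union[str, Path]) -> None:
    """Write an ensemble in AutoDock DLG style (DOCKED:-prefixed pose blocks)."""
    lines = [f"DLG written for experiment {ensemble.experiment_id}", ""]
    for pose in ensemble.poses:
        lines.append(f"DOCKED: MODEL {pose.index:>8d}")
        lines.append(
            "DOCKED: USER    Estimated Free Energy of Binding    ="
            f" {pose.binding_energy:+8.2f} kcal/mol  [=(1)+(2)+(3)-(4)]"
        )
        for ln in _pose_block_lines(pose, pdbqt=True):
            lines.append(f"DOCKED: {ln}")
        lines.append("DOCKED: ENDMDL")
    lines.append("")
    _write_text(path, "\n".join(lines) + "\n")


def write_score_table(scores, path: Union[str, Path]) -> None:
    """Write aggregated residue scores as TSV, best final score first.

    Ties are broken by chain then residue number. Raises on an empty
    collection before touching the filesystem.
    """
    from .scoring import AggregatedScore  # local import to avoid a cycle

    items: List[AggregatedScore] = (
        list(scores.values()) if isinstance(scores, dict) else list(scores)
    )
    if not items:
        raise InputOutputError("refusing to write an empty score table")
    experiment_ids = sorted({eid for s in items for eid in s.experiment_scores})
    rows = []
    for s in items:
        row = {
            "residue": s.residue_key.label,
            "chain": s.residue_key.chain,
            "resnum": s.residue_key.resnum,
            "icode": s.residue_key.icode,
            "resname": s.residue_key.resname,
        }
        for eid in experiment_ids:
            row[f"score_{eid}"] = s.experiment_scores.get(eid, float("nan"))
        row["presence"] = s.presence
        row["final_score"] = s.final_score
        rows.append((s, row))
    rows.sort(key=lambda t: (-t[0].final_score, t[0].residue_key.chain,
                             t[0].residue_key.resnum, t[0].residue_key.icode))
    df = pd.DataFrame([r for _, r in rows])
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    except OSError as exc:
        raise InputOutputError(f"cannot write score table {path}: {exc}") from exc


def read_score_table(path: Union[str, Path]):
    """Read back a TSV score table into AggregatedScore objects (file order)."""
    from .scoring import AggregatedScore

    try:
        df = pd.read_csv(path, sep="\t", dtype={"icode": str, "chain": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise InputOutputError(f"cannot read score table {path}: {exc}") from exc
    score_cols = [c for c in df.columns if c.startswith("score_")]
    out = {}
    for _, row in df.iterrows():
        key = ResidueKey(
            chain=str(row["chain"]),
            resnum=int(row["resnum"]),
            icode="" if pd.isna(row["icode"]) else str(row["icode"]),
            resname=str(row["resname"]),
        )
        exp_scores = {
            c[len("score_"):]: float(row[c])
            for c in score_cols if not pd.isna(row[c])
        }
        out[key] = AggregatedScore(
            residue_key=key,
            experiment_scores=exp_scores,
            presence=int(row["presence"]),
            final_score=float(row["final_score"]),
        )
    return out


def _write_text(path: Union[str, Path], text: str) -> None:
    try:
        Path(path).write_text(text)
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
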