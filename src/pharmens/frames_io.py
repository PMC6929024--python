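"""Reading and writing protein-ligand complex frames.

Frames are snapshots of a complex extracted from a trajectory to PDB —
either one multi-model PDB (MODEL/ENDMDL) or a directory of per-frame PDB
files.  On read, water molecules are stripped and each frame is partitioned
into protein and ligand atom lists.  Binary trajectory formats are out of
scope here: the contract is PDB-based, and converters (e.g. MDTraj) can
produce the multi-model PDB upstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio.PDB import PDBParser

WATER_RESIDUES = {"HOH", "WAT", "SOL", "TIP3", "T3P"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation/terminal variants
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN", "ACE", "NME",
}


@dataclass(frozen=True)
class Atom:
    element: str
    res_name: str
    res_seq: int
    chain: str
    name: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.xyz):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class ComplexFrame:
    """One snapshot of a protein-ligand complex, waters removed."""

    frame_index: int
    time_ps: float
    protein_atoms: list[Atom] = field(default_factory=list)
    ligand_atoms: list[Atom] = field(default_factory=list)
    source_id: str = ""


def sample_frame_count(total_time_ps: float, interval_ps: float) -> int:
    """Number of frames sampled at t = dt, 2 dt, ..., <= T (t = 0 excluded).

    floor(T / dt): a 50 ns run sampled every 20 ps yields 2500 frames.
    """
    if total_time_ps <= 0 or interval_ps <= 0:
        raise ValueError("total_time_ps and interval_ps must be positive")
    return int(math.floor(total_time_ps / interval_ps + 1e-9))


def _default_ligand_residues(model):
    return [
        res
        for chain in model
        for res in chain
        if res.get_resname().strip() not in STANDARD_RESIDUES
        and res.get_resname().strip() not in WATER_RESIDUES
    ]


def _partition_model(model, ligand_selector, frame_index, time_ps, source_id) -> ComplexFrame:
    if isinstance(ligand_selector, str):
        lig_residues = [
            res for chain in model for res in chain
            if res.get_resname().strip() == ligand_selector
        ]
    elif callable(ligand_selector):
        lig_residues = [res for chain in model for res in chain if ligand_selector(res)]
    elif ligand_selector is None:
        lig_residues = _default_ligand_residues(model)
    else:
        raise TypeError("ligand_selector must be a residue name, a callable, or None")

    if len(lig_residues) == 0:
        raise ValueError(f"frame {frame_index}: ligand selector matched no residue")
    if len(lig_residues) > 1:
        names = sorted({r.get_resname().strip() for r in lig_residues})
        raise ValueError(
            f"frame {frame_index}: ligand selector matched {len(lig_residues)} residues ({names}); "
            "pass an explicit residue name or callable"
        )
    lig = lig_residues[0]

    frame = ComplexFrame(frame_index, time_ps, source_id=source_id)
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if resname in WATER_RESIDUES:
                continue
            target = frame.ligand_atoms if res is lig else frame.protein_atoms
            for atom in res:
                el = (atom.element or "").strip() or atom.get_name().strip()[0]
                x, y, z = (float(v) for v in atom.coord)
                target.append(
                    Atom(el.capitalize(), resname, res.id[1], chain.id, atom.get_name().strip(), (x, y, z))
                )
    return frame


def _numeric_key(path: Path):
    m = re.findall(r"\d+", path.stem)
    return (int(m[-1]), path.name) if m else (float("inf"), path.name)


def read_frames(path, ligand_selector=None, interval_ps: float = 20.0) -> list[ComplexFrame]:
    """Read complex frames from a multi-model PDB or a directory of PDBs.

    Waters (HOH/WAT/SOL) are stripped; each frame is split into protein and
    ligand parts.  By default the ligand is the single non-standard,
    non-water residue; pass a residue name or a ``callable(residue) -> bool``
    to override.  Frame times are assigned as (index + 1) * interval_ps,
    matching sampling at t = dt, 2 dt, ...
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    frames: list[ComplexFrame] = []
    if path.is_dir():
        files = sorted(path.glob("*.pdb"), key=_numeric_key)
        if not files:
            raise ValueError(f"no PDB files found in {path}")
        for i, f in enumerate(files):
            structure = parser.get_structure(f.stem, str(f))
            models = list(structure)
            if not models:
                raise ValueError(f"{f}: no models")
            frames.append(
                _partition_model(models[0], ligand_selector, i, (i + 1) * interval_ps, f.stem)
            )
    else:
        structure = parser.get_structure(path.stem, str(path))
        models = list(structure)
        if not models:
            raise ValueError(f"{path}: no frames found")
        for i, model in enumerate(models):
            frames.append(
                _partition_model(model, ligand_selector, i, (i + 1) * interval_ps, path.stem)
            )
    return frames


def _pdb_atom_line(record: str, serial: int, a: Atom) -> str:
    name = a.name
    if len(name) < 4:
        # standard alignment: 1-letter elements start in column 14
        name = (" " + name) if len(a.element) == 1 else name
    x, y, z = a.xyz
    return (
        f"{record:<6s}{serial:5d} {name:<4s} {a.res_name:<3s} {a.chain:1s}"
        f"{a.res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element:>2s}"
    )


def write_frames(frames: list[ComplexFrame], path) -> None:
    """Write frames as a multi-model PDB (protein as ATOM, ligand as HETATM)."""
    lines = []
    for frame in frames:
        lines.append(f"MODEL     {frame.frame_index + 1:4d}")
        serial = 1
        for a in frame.protein_atoms:
            lines.append(_pdb_atom_line("ATOM", serial, a))
            serial += 1
        for a in frame.ligand_atoms:
            lines.append(_pdb_atom_line("HETATM", serial, a))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_frame(frame: ComplexFrame, path) -> None:
    """Write a single frame as a PDB file (debug export)."""
    write_frames([frame], path)
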