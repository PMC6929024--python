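"""Ligand feature typing from a plain-text pattern dictionary.

One pattern dictionary types both ligands extracted from complex frames
(bond skeleton perceived from interatomic distances) and library molecules
read from SDF, so that "feature" means exactly the same thing on the model
side and on the conformer side of a screen.  The shipped dictionary lives in
``pharmens/data/feature_patterns.txt`` and is user-replaceable; its format
is documented in the file header.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdDetermineBonds
from rdkit.Geometry import Point3D

from .core import FEATURE_LABELS, Feature


@dataclass(frozen=True)
class FeatureCandidate:
    """A typed anchor on a ligand: label, position, and the atoms behind it."""

    label: str
    xyz: tuple[float, float, float]
    atom_indices: tuple[int, ...]

    def to_feature(self) -> Feature:
        return Feature(self.label, self.xyz)


@dataclass
class _Rule:
    label: str
    kind: str
    query: "Chem.Mol | None"
    params: dict


class PatternSet:
    """A parsed feature-pattern dictionary."""

    def __init__(self, rules: list[_Rule]):
        self.rules = rules

    @classmethod
    def from_file(cls, path) -> "PatternSet":
        rules = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected '<label> <kind> <definition>'")
            label, kind, definition = parts[0], parts[1], parts[2]
            if label not in FEATURE_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown label {label!r}")
            params = {}
            for kv in parts[3:]:
                k, _, v = kv.partition("=")
                params[k] = v
            query = None
            if kind in ("smarts", "smarts_group", "apolar_group"):
                query = Chem.MolFromSmarts(definition)
                if query is None:
                    raise ValueError(f"{path}:{lineno}: bad SMARTS {definition!r}")
            elif kind != "ring":
                raise ValueError(f"{path}:{lineno}: unknown kind {kind!r}")
            rules.append(_Rule(label, kind, query, params))
        return cls(rules)

    # -- assignment ---------------------------------------------------------

    def assign(self, mol: Chem.Mol) -> list[FeatureCandidate]:
        """Feature candidates for a molecule with a 3D conformer."""
        if mol.GetNumConformers() == 0:
            raise ValueError("molecule has no 3D coordinates")
        conf = mol.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])
        out: list[FeatureCandidate] = []
        seen: set[tuple[str, tuple[int, ...]]] = set()

        def add(label, idxs):
            idxs = tuple(sorted(idxs))
            key = (label, idxs)
            if key in seen:
                return
            seen.add(key)
            centroid = coords[list(idxs)].mean(axis=0)
            out.append(FeatureCandidate(label, tuple(float(v) for v in centroid), idxs))

        for rule in self.rules:
            if rule.kind == "smarts":
                for match in mol.GetSubstructMatches(rule.query):
                    add(rule.label, (match[0],))
            elif rule.kind == "smarts_group":
                for match in mol.GetSubstructMatches(rule.query):
                    add(rule.label, match)
            elif rule.kind == "apolar_group":
                minsize = int(rule.params.get("minsize", 2))
                apolar = {m[0] for m in mol.GetSubstructMatches(rule.query)}
                for group in _connected_groups(mol, apolar):
                    if len(group) >= minsize:
                        add(rule.label, group)
            elif rule.kind == "ring":
                sizes = {int(s) for s in rule.params.get("sizes", "5,6").split(",")}
                planarity = float(rule.params.get("planarity", 0.15))
                for ring in mol.GetRingInfo().AtomRings():
                    if len(ring) not in sizes:
                        continue
                    atoms = [mol.GetAtomWithIdx(i) for i in ring]
                    aromatic = all(a.GetIsAromatic() for a in atoms)
                    carbocycle = all(a.GetAtomicNum() == 6 for a in atoms)
                    if aromatic or (carbocycle and _is_planar(coords[list(ring)], planarity)):
                        add(rule.label, ring)
        return out


def _connected_groups(mol: Chem.Mol, atom_set: set[int]) -> list[set[int]]:
    remaining = set(atom_set)
    groups = []
    while remaining:
        seed = remaining.pop()
        group, stack = {seed}, [seed]
        while stack:
            i = stack.pop()
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in remaining:
                    remaining.remove(j)
                    group.add(j)
                    stack.append(j)
        groups.append(group)
    return groups


def _is_planar(pts: np.ndarray, tol: float) -> bool:
    centered = pts - pts.mean(axis=0)
    # smallest singular direction = best-fit plane normal
    _, s, vt = np.linalg.svd(centered)
    dev = np.abs(centered @ vt[-1])
    return float(dev.max()) <= tol


def default_pattern_file() -> Path:
    return Path(str(resources.files("pharmens").joinpath("data/feature_patterns.txt")))


def load_patterns(path=None) -> PatternSet:
    """Load a pattern dictionary; the shipped default when ``path`` is None."""
    return PatternSet.from_file(path if path is not None else default_pattern_file())


def mol_from_atoms(atoms) -> Chem.Mol:
    """RDKit molecule from (element, xyz) records, bonds perceived by distance.

    Used for ligands carved out of complex frames, where only elements and
    coordinates are known.  Implicit hydrogens are re-enabled after bond
    perception so H-count-dependent patterns behave as for SDF input.
    """
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, (element, xyz) in enumerate(atoms):
        rw.AddAtom(Chem.Atom(element))
        conf.SetAtomPosition(i, Point3D(*(float(v) for v in xyz)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    if mol.GetNumAtoms() > 1:
        rdDetermineBonds.DetermineConnectivity(mol)
    for atom in mol.GetAtoms():
        atom.SetNoImplicit(False)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        # odd valences from distance-perceived bonds: keep going with ring
        # info and aromaticity only, feature typing degrades gracefully
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_SYMMRINGS | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
            catchErrors=True,
        )
    return mol
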