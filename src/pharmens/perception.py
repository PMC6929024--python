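"""Structure-based pharmacophore perception from a complex frame.

A ligand-side pharmacophore is derived in two passes: (1) the ligand is
typed against the feature-pattern dictionary, giving candidate anchors;
(2) each candidate is kept only if a geometric protein-ligand interaction of
the matching kind exists — H-bond (donor-acceptor heavy-atom distance, plus
a D-H...A angle test when hydrogens are present), hydrophobic carbon-carbon
contact, aromatic ring-centroid contact, or an ionic short contact between a
charged amino-acid side chain (Glu/Asp/Lys/Arg/His) and an oppositely
charged ligand group.  All cutoffs are configuration, not constants.

Features are undirected points placed on the ligand side: H-bond features on
the donor/acceptor heavy atom, aromatic at the ring centroid, hydrophobic at
the apolar-group centroid, ionic at the charged-group centroid.  Candidates
supported by several protein partners collapse to one feature (same label,
same anchor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Pharmacophore
from .featuredefs import FeatureCandidate, load_patterns, mol_from_atoms
from .frames_io import Atom, ComplexFrame

HYDROXYL_DONORS = {("SER", "OG"), ("THR", "OG1"), ("TYR", "OH")}

AROMATIC_RING_ATOMS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"), ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HID": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIE": [("CG", "ND1", "CD2", "CE1", "NE2")],
    "HIP": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

NEGATIVE_SIDECHAIN = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2"), "ASH": ("OD1", "OD2"), "GLH": ("OE1", "OE2")}
POSITIVE_SIDECHAIN = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2", "CZ"), "HIP": ("ND1", "NE2")}


class EmptyPharmacophoreError(ValueError):
    """Raised when a frame yields no features; callers may skip the frame."""


@dataclass
class InteractionConfig:
    """Geometric cutoffs for interaction perception (all in Angstrom).

    Defaults sit near the values published for common interaction profilers;
    ``ionic_max`` defaults to the 3.8 A short-contact criterion for charged
    side chains.
    """

    hbond_da_max: float = 3.5
    hbond_angle_min: float = 120.0
    hydrophobic_cc_max: float = 4.0
    aromatic_centroid_max: float = 5.5
    ionic_max: float = 3.8
    water_strip: bool = True
    pattern_file: str | None = None

    def __post_init__(self):
        for name in ("hbond_da_max", "hydrophobic_cc_max", "aromatic_centroid_max", "ionic_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Interaction:
    """One detected protein-ligand contact (indices into the frame atom lists)."""

    kind: str
    protein_atoms: tuple[int, ...]
    ligand_atoms: tuple[int, ...]
    candidate: FeatureCandidate = field(compare=False, default=None)


def _coords(atoms: list[Atom]) -> np.ndarray:
    return np.array([a.xyz for a in atoms], dtype=float) if atoms else np.zeros((0, 3))


def _his_is_protonated(res_atoms: list[tuple[int, Atom]], pcoords: np.ndarray) -> bool:
    """HIS counts as positive only when both ring nitrogens carry a hydrogen."""
    ring_n = [i for i, a in res_atoms if a.name in ("ND1", "NE2")]
    hydrogens = [i for i, a in res_atoms if a.element == "H"]
    if len(ring_n) < 2 or not hydrogens:
        return False
    protonated = 0
    for n_idx in ring_n:
        dists = np.linalg.norm(pcoords[hydrogens] - pcoords[n_idx], axis=1)
        if (dists < 1.25).any():
            protonated += 1
    return protonated >= 2


class _ProteinView:
    """Index of protein-side interaction partners in one frame."""

    def __init__(self, atoms: list[Atom]):
        self.atoms = atoms
        self.coords = _coords(atoms)
        by_res: dict[tuple, list[tuple[int, Atom]]] = {}
        for i, a in enumerate(atoms):
            by_res.setdefault((a.chain, a.res_seq, a.res_name), []).append((i, a))

        self.donors: list[int] = []
        self.acceptors: list[int] = []
        self.apolar_c: list[int] = []
        self.rings: list[tuple[tuple[int, ...], np.ndarray]] = []
        self.positive: list[int] = []
        self.negative: list[int] = []
        self.hydrogens: list[int] = [i for i, a in enumerate(atoms) if a.element == "H"]

        for (chain, seq, resname), res_atoms in by_res.items():
            name_to_idx = {a.name: i for i, a in res_atoms}
            for i, a in res_atoms:
                if a.element == "N":
                    self.donors.append(i)
                elif a.element == "O":
                    self.acceptors.append(i)
                    if (resname, a.name) in HYDROXYL_DONORS:
                        self.donors.append(i)
                elif a.element == "C":
                    # apolar unless covalently tied to N/O within the residue
                    polar = False
                    for j, b in res_atoms:
                        if b.element in ("N", "O") and np.linalg.norm(
                            np.subtract(a.xyz, b.xyz)
                        ) < 1.75:
                            polar = True
                            break
                    if not polar:
                        self.apolar_c.append(i)
            for ring_names in AROMATIC_RING_ATOMS.get(resname, []):
                idxs = tuple(name_to_idx[n] for n in ring_names if n in name_to_idx)
                if len(idxs) >= 5:
                    self.rings.append((idxs, self.coords[list(idxs)].mean(axis=0)))
            if resname in NEGATIVE_SIDECHAIN:
                self.negative.extend(name_to_idx[n] for n in NEGATIVE_SIDECHAIN[resname] if n in name_to_idx)
            pos_res = resname
            if resname == "HIS" and _his_is_protonated(res_atoms, self.coords):
                pos_res = "HIP"
            if pos_res in POSITIVE_SIDECHAIN:
                self.positive.extend(
                    name_to_idx[n] for n in POSITIVE_SIDECHAIN[pos_res] if n in name_to_idx
                )

    def attached_hydrogens(self, idx: int) -> list[int]:
        if not self.hydrogens:
            return []
        d = np.linalg.norm(self.coords[self.hydrogens] - self.coords[idx], axis=1)
        return [h for h, dd in zip(self.hydrogens, d) if dd < 1.25]


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _hbond_ok(donor_xyz, acceptor_xyz, donor_h_xyz: list[np.ndarray], angle_min: float) -> bool:
    """Angle test D-H...A >= angle_min; skipped when no hydrogen is resolved."""
    if not donor_h_xyz:
        return True
    return any(_angle(donor_xyz, h, acceptor_xyz) >= angle_min for h in donor_h_xyz)


def detect_interactions(frame: ComplexFrame, cfg: InteractionConfig | None = None) -> list[Interaction]:
    """Geometric protein-ligand interaction records for one frame."""
    cfg = cfg or InteractionConfig()
    if not frame.ligand_atoms:
        raise ValueError("frame has no ligand atoms")

    patterns = load_patterns(cfg.pattern_file)
    mol = mol_from_atoms([(a.element, a.xyz) for a in frame.ligand_atoms])
    candidates = patterns.assign(mol)

    prot = _ProteinView(frame.protein_atoms)
    lig_coords = _coords(frame.ligand_atoms)
    lig_h = [i for i, a in enumerate(frame.ligand_atoms) if a.element == "H"]

    def lig_attached_h(idx: int) -> list[np.ndarray]:
        if not lig_h:
            return []
        d = np.linalg.norm(lig_coords[lig_h] - lig_coords[idx], axis=1)
        return [lig_coords[h] for h, dd in zip(lig_h, d) if dd < 1.25]

    out: list[Interaction] = []
    for cand in candidates:
        anchor = np.array(cand.xyz)
        group = list(cand.atom_indices)
        if cand.label == "A":
            lig_idx = cand.atom_indices[0]
            for d_idx in prot.donors:
                if np.linalg.norm(prot.coords[d_idx] - lig_coords[lig_idx]) <= cfg.hbond_da_max:
                    hs = [prot.coords[h] for h in prot.attached_hydrogens(d_idx)]
                    if _hbond_ok(prot.coords[d_idx], lig_coords[lig_idx], hs, cfg.hbond_angle_min):
                        out.append(Interaction("hbond_lig_acceptor", (d_idx,), (lig_idx,), cand))
        elif cand.label == "D":
            lig_idx = cand.atom_indices[0]
            for a_idx in prot.acceptors:
                if np.linalg.norm(prot.coords[a_idx] - lig_coords[lig_idx]) <= cfg.hbond_da_max:
                    if _hbond_ok(
                        lig_coords[lig_idx], prot.coords[a_idx], lig_attached_h(lig_idx), cfg.hbond_angle_min
                    ):
                        out.append(Interaction("hbond_lig_donor", (a_idx,), (lig_idx,), cand))
        elif cand.label == "H":
            for c_idx in prot.apolar_c:
                d = np.linalg.norm(lig_coords[group] - prot.coords[c_idx], axis=1)
                if d.min() <= cfg.hydrophobic_cc_max:
                    out.append(Interaction("hydrophobic", (c_idx,), tuple(group), cand))
        elif cand.label == "a":
            for ring_idx, centroid in prot.rings:
                if np.linalg.norm(centroid - anchor) <= cfg.aromatic_centroid_max:
                    out.append(Interaction("aromatic", ring_idx, tuple(group), cand))
        elif cand.label == "P":
            for n_idx in prot.negative:
                d = np.linalg.norm(lig_coords[group] - prot.coords[n_idx], axis=1)
                if d.min() < cfg.ionic_max:
                    out.append(Interaction("ionic_pos", (n_idx,), tuple(group), cand))
        elif cand.label == "N":
            for p_idx in prot.positive:
                d = np.linalg.norm(lig_coords[group] - prot.coords[p_idx], axis=1)
                if d.min() < cfg.ionic_max:
                    out.append(Interaction("ionic_neg", (p_idx,), tuple(group), cand))
    return out


def perceive_pharmacophore(frame: ComplexFrame, cfg: InteractionConfig | None = None) -> Pharmacophore:
    """Ligand-side pharmacophore from one frame.

    One feature per accepted interaction candidate; duplicate (label, anchor)
    pairs merge.  Raises :class:`EmptyPharmacophoreError` when no interaction
    survives, so trajectory-level callers can skip the frame.
    """
    cfg = cfg or InteractionConfig()
    interactions = detect_interactions(frame, cfg)
    features = {}
    for rec in interactions:
        cand = rec.candidate
        anchor_key = tuple(round(v, 6) for v in cand.xyz)
        features[(cand.label, anchor_key)] = cand.to_feature()
    if not features:
        raise EmptyPharmacophoreError(
            f"frame {frame.frame_index} of {frame.source_id!r} yields no pharmacophore features"
        )
    return Pharmacophore(
        list(features.values()), source_id=frame.source_id, frame_index=frame.frame_index
    )
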