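"""Synthetic complex trajectories and screening libraries.

Everything the pipeline consumes can be generated here, with no downloads:
toy protein-ligand frames whose perceived pharmacophores fall into a
controlled number of hash states, and conformer libraries with planted
actives and verified-non-matching decoys.

The scenes are abstract but geometrically honest: each realized interaction
kind is one ligand "part" (a small atom group whose feature anchor is a
known point) paired with a protein fragment placed inside the corresponding
perception cutoff.  Distinct states displace one part by a couple of
Angstrom, changing binned interfeature distances; within-state frames add
small rigid per-part jitter plus a global rigid motion of the whole frame.
Every planted property — state count, active match, decoy non-match — is
verified at generation time with the same public operations the pipeline
uses, so fixtures cannot drift from the implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Geometry import Point3D
from scipy.spatial.transform import Rotation

from .core import Feature, Pharmacophore, RigidTransform
from .frames_io import Atom, ComplexFrame, _pdb_atom_line
from .hashing import HashConfig, hash_pharmacophore
from .perception import InteractionConfig, perceive_pharmacophore
from .screening import CompoundEntry, ConformerRecord, conformer_matches_model, assign_ligand_features

ALL_KINDS = ("hbond_acceptor", "hbond_donor", "aromatic", "hydrophobic", "ionic_pos", "ionic_neg")

KIND_LABEL = {
    "hbond_acceptor": "A",
    "hbond_donor": "D",
    "aromatic": "a",
    "hydrophobic": "H",
    "ionic_pos": "P",
    "ionic_neg": "N",
}


@dataclass
class SceneSpec:
    """Parameters of a synthetic trajectory.

    ``jitter_sd`` is the per-part rigid translation noise (A, per axis)
    within a state; it must stay well below half the 1 A binning step so the
    intra-state hash is stable (the generator enforces a distance margin of
    ``max(0.2, 6 * jitter_sd)`` A from bin boundaries and rejects specs
    where that margin is unattainable).
    """

    n_frames: int = 50
    n_states: int = 3
    jitter_sd: float = 0.05
    interaction_menu: tuple[str, ...] = ALL_KINDS
    seed: int = 0

    def __post_init__(self):
        if self.n_states > self.n_frames:
            raise ValueError("n_states must not exceed n_frames")
        unknown = set(self.interaction_menu) - set(ALL_KINDS)
        if unknown:
            raise ValueError(f"unknown interaction kinds {sorted(unknown)}")


@dataclass
class LibrarySpec:
    """Parameters of a synthetic screening library."""

    n_actives: int = 20
    n_decoys: int = 980
    conformers_per_compound: int = 5
    match_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_actives, self.n_decoys, self.conformers_per_compound) < 0:
            raise ValueError("counts must be non-negative")
        if not (0 < self.match_fraction <= 1):
            raise ValueError("match_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# interaction parts: ligand atoms + protein partner, feature anchor at origin,
# partner on the local -x side
# ---------------------------------------------------------------------------

_RING6 = [
    (0.0, 1.39 * math.cos(k * math.pi / 3), 1.39 * math.sin(k * math.pi / 3)) for k in range(6)
]


@dataclass
class _Part:
    kind: str
    label: str
    lig_atoms: list[tuple[str, str, tuple[float, float, float]]]  # element, name, local xyz
    partner_res: str
    partner_atoms: list[tuple[str, str, tuple[float, float, float]]]


def _make_part(kind: str) -> _Part:
    if kind == "hbond_acceptor":
        return _Part(
            kind, "A",
            [("O", "O1", (0.0, 0.0, 0.0)), ("C", "C1", (1.23, 0.0, 0.0))],
            "GLN",
            [("N", "NE2", (-3.0, 0.0, 0.0)), ("C", "CD", (-4.33, 0.0, 0.0))],
        )
    if kind == "hbond_donor":
        return _Part(
            kind, "D",
            [("N", "N1", (0.0, 0.0, 0.0)), ("C", "C1", (1.47, 0.0, 0.0))],
            "GLN",
            [("O", "OE1", (-3.0, 0.0, 0.0)), ("C", "CD", (-4.23, 0.0, 0.0))],
        )
    if kind == "aromatic":
        lig = [("C", f"C{i+1}", xyz) for i, xyz in enumerate(_RING6)]
        ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
        partner = [("C", n, (-4.0, x[1], x[2])) for n, x in zip(ring_names, _RING6)]
        return _Part(kind, "a", lig, "PHE", partner)
    if kind == "hydrophobic":
        return _Part(
            kind, "H",
            [("C", "C1", (0.0, 0.77, 0.0)), ("C", "C2", (0.0, -0.77, 0.0))],
            "LEU",
            [("C", "CD1", (-3.6, 0.0, 0.0)), ("C", "CD2", (-3.6, 1.5, 0.0))],
        )
    if kind == "ionic_pos":
        return _Part(
            kind, "P",
            [("N", "N1", (0.0, 0.0, 0.0)), ("C", "C1", (1.47, 0.0, 0.0))],
            "ASP",
            [
                ("O", "OD1", (-3.65, 0.55, 0.0)),
                ("O", "OD2", (-3.65, -0.55, 0.0)),
                ("C", "CG", (-4.75, 0.0, 0.0)),
            ],
        )
    if kind == "ionic_neg":
        return _Part(
            kind, "N",
            [
                ("C", "C1", (-0.66, 0.0, 0.0)),
                ("O", "O1", (0.33, 1.05, 0.0)),
                ("O", "O2", (0.33, -1.05, 0.0)),
            ],
            "LYS",
            [("N", "NZ", (-3.8, 0.0, 0.0)), ("C", "CE", (-5.1, 0.0, 0.0))],
        )
    raise ValueError(f"unknown kind {kind!r}")


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation mapping local -x onto ``direction`` (unit)."""
    target = -np.asarray(direction, dtype=float)  # local -x -> direction
    src = np.array([1.0, 0.0, 0.0])
    v = np.cross(src, target)
    c = float(np.dot(src, target))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_euler("z", 180, degrees=True).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _layout_ok(anchors, margin: float, volmargin: float = 0.05, dmin: float = 6.5, dmax: float = 18.0) -> bool:
    pts = np.asarray(anchors, dtype=float)
    n = len(pts)
    for i, j in itertools.combinations(range(n), 2):
        d = float(np.linalg.norm(pts[i] - pts[j]))
        if d < dmin or d > dmax:
            return False
        if abs((d % 1.0) - 0.5) < margin:
            return False
    for quad in itertools.combinations(range(n), 4):
        a, b, c, d = (pts[k] for k in quad)
        u, v, w = b - a, c - a, d - a
        nv = float(np.dot(np.cross(u, v), w)) / (
            np.linalg.norm(u) * np.linalg.norm(v) * np.linalg.norm(w)
        )
        if abs(nv) < volmargin:
            return False
    return True


def _sample_layout(rng: np.random.Generator, n: int, margin: float) -> np.ndarray:
    for _ in range(500):
        pts = [np.zeros(3)]
        failed = False
        for _k in range(n - 1):
            for _t in range(800):
                p = rng.uniform(-9.0, 9.0, 3)
                if _layout_ok(pts + [p], margin):
                    pts.append(p)
                    break
            else:
                failed = True
                break
        if not failed:
            return np.array(pts)
    raise RuntimeError("could not sample a feasible pocket layout")


def _build_frame(
    parts: list[_Part],
    anchors: np.ndarray,
    rotations: list[np.ndarray],
    frame_index: int,
    time_ps: float,
    source_id: str,
    part_shifts: np.ndarray | None = None,
    global_motion: RigidTransform | None = None,
) -> ComplexFrame:
    protein: list[Atom] = []
    ligand: list[Atom] = []
    shifts = part_shifts if part_shifts is not None else np.zeros((len(parts), 3))
    for pi, (part, anchor, R) in enumerate(zip(parts, anchors, rotations)):
        offset = np.asarray(anchor) + shifts[pi]

        def place(xyz):
            p = R @ np.asarray(xyz, dtype=float) + offset
            if global_motion is not None:
                p = global_motion.apply(p)[0]
            return tuple(float(v) for v in p)

        for el, name, xyz in part.lig_atoms:
            ligand.append(Atom(el, "LIG", 1, "B", f"{name}{pi}", place(xyz)))
        for el, name, xyz in part.partner_atoms:
            protein.append(Atom(el, part.partner_res, pi + 1, "A", name, place(xyz)))
    return ComplexFrame(frame_index, time_ps, protein, ligand, source_id)


def make_frames(
    spec: SceneSpec,
    interaction_config: InteractionConfig | None = None,
    hash_config: HashConfig | None = None,
) -> tuple[list[ComplexFrame], list[int]]:
    """Generate frames in memory together with the frame -> state truth.

    The perceived pharmacophores of the returned frames fall into exactly
    ``spec.n_states`` hash groups at the given (default) hash resolution;
    this is verified during generation frame by frame.
    """
    icfg = interaction_config or InteractionConfig()
    hcfg = hash_config or HashConfig()
    rng = np.random.default_rng(spec.seed)
    margin = max(0.2, 6.0 * spec.jitter_sd)
    if margin >= 0.45:
        raise ValueError(
            f"jitter_sd={spec.jitter_sd} is too large for binning step {hcfg.binning_step}"
        )
    parts = [_make_part(k) for k in spec.interaction_menu]
    n_parts = len(parts)
    if n_parts == 0:
        raise ValueError("interaction_menu must not be empty")
    if n_parts == 1 and spec.n_states > 1:
        raise ValueError("need at least two parts to plant multiple states")

    for _attempt in range(30):
        base = _sample_layout(rng, n_parts, margin)
        center = base.mean(axis=0)
        rotations = []
        for anchor in base:
            d = np.asarray(anchor) - center
            nd = np.linalg.norm(d)
            u = d / nd if nd > 1e-6 else np.array([1.0, 0.0, 0.0])
            rotations.append(_rotation_to(u))

        # state geometries: state 0 = base, each further state displaces one part
        state_anchors = [base]
        state_hashes: list[str] = []
        feasible = True
        frame0 = _build_frame(parts, base, rotations, 0, 0.0, "synthetic")
        try:
            ph0 = perceive_pharmacophore(frame0, icfg)
        except ValueError:
            continue
        if len(ph0) != n_parts:
            continue
        state_hashes.append(hash_pharmacophore(ph0, hcfg).digest)

        for s in range(1, spec.n_states):
            pi = (s - 1) % n_parts
            placed = False
            for _t in range(400):
                v = rng.normal(0.0, 2.0, 3)
                if np.linalg.norm(v) < 1.2:
                    continue
                anchors = state_anchors[0].copy()
                anchors[pi] = anchors[pi] + v
                if not _layout_ok(anchors, margin):
                    continue
                fr = _build_frame(parts, state_anchors[0], rotations, 0, 0.0, "synthetic",
                                  part_shifts=_shift_matrix(n_parts, pi, v))
                try:
                    ph = perceive_pharmacophore(fr, icfg)
                except ValueError:
                    continue
                if len(ph) != n_parts:
                    continue
                digest = hash_pharmacophore(ph, hcfg).digest
                if digest in state_hashes:
                    continue
                state_anchors.append(anchors)
                state_hashes.append(digest)
                placed = True
                break
            if not placed:
                feasible = False
                break
        if not feasible:
            continue

        # frames: round-robin states, per-part jitter + global rigid motion
        frames: list[ComplexFrame] = []
        truth: list[int] = []
        ok = True
        for f in range(spec.n_frames):
            s = f % spec.n_states
            accepted = False
            for _t in range(50):
                shifts = rng.normal(0.0, spec.jitter_sd, (n_parts, 3)) if spec.jitter_sd > 0 else np.zeros((n_parts, 3))
                motion = RigidTransform.random(rng, max_translation=5.0)
                fr = _build_frame(
                    parts, state_anchors[s], rotations, f, (f + 1) * 20.0, "synthetic",
                    part_shifts=shifts, global_motion=motion,
                )
                try:
                    ph = perceive_pharmacophore(fr, icfg)
                except ValueError:
                    continue
                if hash_pharmacophore(ph, hcfg).digest == state_hashes[s]:
                    frames.append(fr)
                    truth.append(s)
                    accepted = True
                    break
            if not accepted:
                ok = False
                break
        if ok:
            return frames, truth
    raise RuntimeError("scene spec infeasible: jitter too large for the binning step or menu too tight")


def _shift_matrix(n_parts: int, pi: int, v: np.ndarray) -> np.ndarray:
    shifts = np.zeros((n_parts, 3))
    shifts[pi] = v
    return shifts


def make_trajectory(
    spec: SceneSpec,
    out_path,
    interaction_config: InteractionConfig | None = None,
    hash_config: HashConfig | None = None,
    n_waters: int = 3,
) -> tuple[Path, list[int]]:
    """Write a synthetic multi-model PDB trajectory; returns (path, truth).

    A few water molecules are embedded in every model so the reader's
    water stripping is exercised on realistic input.
    """
    frames, truth = make_frames(spec, interaction_config, hash_config)
    out_path = Path(out_path)
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
        for w in range(n_waters):
            wat = Atom("O", "HOH", 900 + w, "W", "O", (30.0 + 3.0 * w, 30.0, 30.0))
            lines.append(_pdb_atom_line("HETATM", serial, wat))
            serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    out_path.write_text("\n".join(lines) + "\n")
    return out_path, truth


# ---------------------------------------------------------------------------
# screening libraries
# ---------------------------------------------------------------------------

_LIB_RING_BONDS = [(i, (i + 1) % 6, Chem.BondType.AROMATIC) for i in range(6)]


def _lib_part(label: str):
    """Ligand-only part: (atoms [(element, xyz, charge)], bonds, anchor at origin)."""
    if label == "A":  # carbonyl
        return ([("O", (0.0, 0.0, 0.0), 0), ("C", (1.23, 0.0, 0.0), 0)],
                [(0, 1, Chem.BondType.DOUBLE)])
    if label in ("D", "P"):  # amine
        return ([("N", (0.0, 0.0, 0.0), 0), ("C", (1.47, 0.0, 0.0), 0)],
                [(0, 1, Chem.BondType.SINGLE)])
    if label == "a":
        return ([("C", xyz, 0) for xyz in _RING6], list(_LIB_RING_BONDS))
    if label == "H":
        return ([("C", (0.0, 0.77, 0.0), 0), ("C", (0.0, -0.77, 0.0), 0)],
                [(0, 1, Chem.BondType.SINGLE)])
    if label == "N":  # carboxylate
        return (
            [("C", (-0.66, 0.0, 0.0), 0), ("O", (0.33, 1.05, 0.0), 0), ("O", (0.33, -1.05, 0.0), -1)],
            [(0, 1, Chem.BondType.DOUBLE), (0, 2, Chem.BondType.SINGLE)],
        )
    raise ValueError(label)


def _assemble_conformer(
    placements: list[tuple[str, np.ndarray, np.ndarray]],
) -> tuple[list[tuple[str, tuple[float, float, float]]], Chem.Mol]:
    """Build a multi-fragment molecule from (label, anchor, rotation) parts."""
    rw = Chem.RWMol()
    coords: list[tuple[float, float, float]] = []
    elements: list[str] = []
    for label, anchor, R in placements:
        atoms, bonds = _lib_part(label)
        base = rw.GetNumAtoms()
        for el, xyz, charge in atoms:
            a = Chem.Atom(el)
            if charge:
                a.SetFormalCharge(charge)
            rw.AddAtom(a)
            p = R @ np.asarray(xyz, dtype=float) + anchor
            coords.append(tuple(float(v) for v in p))
            elements.append(el)
        for i, j, bt in bonds:
            rw.AddBond(base + i, base + j, bt)
    mol = rw.GetMol()
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*xyz))
    mol.AddConformer(conf)
    Chem.SanitizeMol(mol)
    return list(zip(elements, coords)), mol


def _placements_for_model(
    model: Pharmacophore, rng: np.random.Generator, displace: tuple[int, np.ndarray] | None = None
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    anchors = model.coords().copy()
    if displace is not None:
        idx, v = displace
        anchors[idx] = anchors[idx] + v
    center = anchors.mean(axis=0)
    # spacer: an extra apolar pair far from the pocket, making conformers of
    # one compound mutually distinct (>|0.5 A| RMSD) without touching the
    # planted geometry
    for _ in range(100):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        spacer = center + u * rng.uniform(9.0, 14.0)
        if np.linalg.norm(anchors - spacer, axis=1).min() >= 5.0:
            break
    placements = []
    for feat, anchor in zip(model.features, anchors):
        R = Rotation.random(random_state=rng).as_matrix()
        placements.append((feat.label, np.asarray(anchor, dtype=float), R))
    placements.append(("H", spacer, Rotation.random(random_state=rng).as_matrix()))
    return placements


def _make_conformer_record(
    cid: str, sid: str, conf_id: int, placements, pattern_file=None
) -> tuple[ConformerRecord, Chem.Mol]:
    atoms, mol = _assemble_conformer(placements)
    feats = assign_ligand_features(mol, pattern_file)
    rec = ConformerRecord(cid, sid, conf_id, atoms, feats)
    return rec, mol


def make_library(
    spec: LibrarySpec,
    models: list[Pharmacophore],
    sdf_path,
    labels_path,
    hash_config: HashConfig | None = None,
) -> tuple[Path, Path]:
    """Write a synthetic screening library (SDF V2000 + label TSV).

    Actives: for each compound a model is chosen round-robin; a fraction
    ``match_fraction`` of its conformers realize the model's feature
    geometry exactly (verified to match), the rest have one feature group
    displaced off the binning grid (verified not to match any model).
    Decoys: the same construction with the displaced geometry for every
    conformer — hard decoys sharing the model's feature labels but breaking
    one binned distance; every decoy conformer is verified non-matching
    against every model.
    """
    entries, mols = build_library(spec, models, hash_config)
    sdf_path, labels_path = Path(sdf_path), Path(labels_path)
    writer = Chem.SDWriter(str(sdf_path))
    writer.SetKekulize(True)
    for entry in entries:
        for rec in entry.conformers:
            mol = mols[(entry.compound_id, rec.stereoisomer_id, rec.conformer_id)]
            mol.SetProp("_Name", entry.compound_id)
            mol.SetProp("compound_id", entry.compound_id)
            mol.SetProp("stereoisomer_id", rec.stereoisomer_id)
            mol.SetProp("conformer_id", str(rec.conformer_id))
            writer.write(mol)
    writer.close()
    pd.DataFrame(
        [(e.compound_id, "active" if e.is_active else "decoy") for e in entries],
        columns=["compound_id", "label"],
    ).to_csv(labels_path, sep="\t", index=False)
    return sdf_path, labels_path


def build_library(
    spec: LibrarySpec,
    models: list[Pharmacophore],
    hash_config: HashConfig | None = None,
) -> tuple[list[CompoundEntry], dict]:
    """In-memory form of :func:`make_library`; returns entries and RDKit mols."""
    if not models:
        raise ValueError("need at least one model to plant a library against")
    hcfg = hash_config or HashConfig()
    rng = np.random.default_rng(spec.seed)
    step = hcfg.binning_step
    entries: list[CompoundEntry] = []
    mols: dict = {}

    def displaced(model, feat_idx):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return (feat_idx, u * 2.2 * step)

    def build_compound(cid: str, model: Pharmacophore, n_match: int, n_total: int, active: bool):
        confs: list[ConformerRecord] = []
        split_stereo = active and (len(entries) % 3 == 0)
        for j in range(n_total):
            sid = "2" if (split_stereo and j >= n_total // 2 and n_total > 1) else "1"
            want_match = j < n_match
            for _try in range(60):
                if want_match:
                    placements = _placements_for_model(model, rng)
                else:
                    fi = int(rng.integers(len(model)))
                    placements = _placements_for_model(model, rng, displace=displaced(model, fi))
                if not _parts_clash_free(placements):
                    continue
                rec, mol = _make_conformer_record(cid, sid, j, placements)
                if want_match:
                    if conformer_matches_model(rec, model, hcfg):
                        break
                else:
                    if not any(conformer_matches_model(rec, m, hcfg) for m in models):
                        break
            else:
                raise RuntimeError(
                    f"could not construct a {'matching' if want_match else 'non-matching'} "
                    f"conformer for {cid} after bounded retries (spec too tight)"
                )
            confs.append(rec)
            mols[(cid, sid, j)] = mol
        entries.append(CompoundEntry(cid, confs, is_active=active))

    for i in range(spec.n_actives):
        model = models[i % len(models)]
        n_match = max(1, int(math.floor(spec.match_fraction * spec.conformers_per_compound + 0.5)))
        build_compound(f"ACT{i:05d}", model, n_match, spec.conformers_per_compound, True)
    for i in range(spec.n_decoys):
        model = models[i % len(models)]
        build_compound(f"DEC{i:05d}", model, 0, spec.conformers_per_compound, False)
    return entries, mols


def _parts_clash_free(placements, min_dist: float = 2.0) -> bool:
    groups = []
    for label, anchor, R in placements:
        atoms, _ = _lib_part(label)
        groups.append(np.array([R @ np.asarray(x, dtype=float) + anchor for _, x, _ in atoms]))
    for gi, gj in itertools.combinations(range(len(groups)), 2):
        d = np.linalg.norm(groups[gi][:, None, :] - groups[gj][None, :, :], axis=-1)
        if d.min() < min_dist:
            return False
    return True


# ---------------------------------------------------------------------------
# random pharmacophores (property tests, hash validation)
# ---------------------------------------------------------------------------

def random_pharmacophore(
    rng: np.random.Generator,
    n_features: int,
    box: float = 10.0,
    min_separation: float = 2.0,
    labels=None,
) -> Pharmacophore:
    """A random pharmacophore with well-separated features."""
    from .core import FEATURE_LABELS

    labels = labels or FEATURE_LABELS
    pts: list[np.ndarray] = []
    while len(pts) < n_features:
        p = rng.uniform(0.0, box, 3)
        if all(np.linalg.norm(p - q) >= min_separation for q in pts):
            pts.append(p)
    feats = [
        Feature(str(rng.choice(list(labels))), tuple(float(v) for v in p)) for p in pts
    ]
    # regenerate on the (improbable) duplicate label+coords collision
    return Pharmacophore(feats)


def jitter_pharmacophore(
    p: Pharmacophore, rng: np.random.Generator, radius: float = 0.25
) -> Pharmacophore:
    """Copy of ``p`` with each feature displaced uniformly within a sphere."""
    feats = []
    for f in p.features:
        while True:
            v = rng.uniform(-radius, radius, 3)
            if np.linalg.norm(v) <= radius:
                break
        feats.append(Feature(f.label, tuple(float(a + b) for a, b in zip(f.xyz, v))))
    return Pharmacophore(feats, source_id=p.source_id, frame_index=p.frame_index)
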