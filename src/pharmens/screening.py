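"""Conformer typing, deduplication, and conformer-vs-model matching.

A conformer matches a pharmacophore model when some label-preserving
injective mapping from the model features onto the conformer features
selects a subset whose canonical binned 3D hash equals the model's hash —
same binned interfeature distances and the same stereo signature.  This
makes "match" exactly the same relation as "duplicate" in the ensemble
deduplication, at the same binning step.  The search runs label filtering
and pairwise binned-distance compatibility pruning before hash
verification.

Stereoisomers of a compound are pooled: a compound entry holds conformers
across all its stereoisomers, and screening scores treat them as one
compound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .core import Feature, Pharmacophore, kabsch_superpose
from .featuredefs import load_patterns
from .hashing import Hash3D, HashConfig, bin_distance, hash_pharmacophore


@dataclass
class ConformerRecord:
    compound_id: str
    stereoisomer_id: str
    conformer_id: int
    atoms: list[tuple[str, tuple[float, float, float]]]
    features: list[Feature] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.stereoisomer_id, self.conformer_id)


@dataclass
class CompoundEntry:
    """All conformers of a compound, pooled across its stereoisomers."""

    compound_id: str
    conformers: list[ConformerRecord]
    is_active: bool | None = None

    def __post_init__(self):
        if not self.conformers:
            raise ValueError(f"compound {self.compound_id}: no conformers")


def assign_ligand_features(mol: Chem.Mol, pattern_file=None) -> list[Feature]:
    """Type a molecule's 3D conformer against the pattern dictionary."""
    patterns = load_patterns(pattern_file)
    return [c.to_feature() for c in patterns.assign(mol)]


def _heavy_coords(atoms) -> np.ndarray:
    return np.array([xyz for el, xyz in atoms if el != "H"], dtype=float)


def dedup_conformers(conformers: list[ConformerRecord], rmsd_cut: float = 0.5) -> list[ConformerRecord]:
    """Greedy keep-first duplicate filter at a heavy-atom best-fit RMSD cut.

    Conformers must belong to one stereoisomer and share atom ordering; a
    conformer is dropped when its RMSD to any already-kept conformer is
    below ``rmsd_cut`` (default 0.5 A).
    """
    kept: list[ConformerRecord] = []
    kept_coords: list[np.ndarray] = []
    for c in conformers:
        coords = _heavy_coords(c.atoms)
        duplicate = False
        for other in kept_coords:
            if other.shape != coords.shape:
                raise ValueError("conformers must share atom count and ordering")
            _, rmsd = kabsch_superpose(other, coords)
            if rmsd < rmsd_cut:
                duplicate = True
                break
        if not duplicate:
            kept.append(c)
            kept_coords.append(coords)
    return kept


def read_library(
    sdf_path,
    labels_path=None,
    pattern_file=None,
    dedup_rmsd: float | None = None,
) -> list[CompoundEntry]:
    """Read an SDF conformer library into compound entries.

    Each record should carry ``compound_id``, ``stereoisomer_id`` and
    ``conformer_id`` properties (falling back to the molecule title, "0",
    and per-stereoisomer order).  ``labels_path`` is a TSV with columns
    compound_id and label ("active"/"decoy" or 1/0).  Pass ``dedup_rmsd``
    to apply the duplicate-conformer filter per stereoisomer on read.
    """
    labels: dict[str, bool] = {}
    if labels_path is not None:
        tab = pd.read_csv(labels_path, sep="\t", dtype=str)
        for _, row in tab.iterrows():
            labels[row["compound_id"]] = str(row["label"]).strip().lower() in ("1", "active", "true")

    per_stereo: dict[tuple[str, str], list[ConformerRecord]] = {}
    order: list[str] = []
    supplier = Chem.SDMolSupplier(str(sdf_path), removeHs=False, sanitize=True)
    for mol in supplier:
        if mol is None:
            continue
        cid = mol.GetProp("compound_id") if mol.HasProp("compound_id") else mol.GetProp("_Name")
        sid = mol.GetProp("stereoisomer_id") if mol.HasProp("stereoisomer_id") else "0"
        key = (cid, sid)
        conf_id = (
            int(mol.GetProp("conformer_id"))
            if mol.HasProp("conformer_id")
            else len(per_stereo.get(key, []))
        )
        conf = mol.GetConformer()
        atoms = [
            (a.GetSymbol(), tuple(float(v) for v in conf.GetAtomPosition(a.GetIdx())))
            for a in mol.GetAtoms()
        ]
        rec = ConformerRecord(cid, sid, conf_id, atoms, assign_ligand_features(mol, pattern_file))
        if cid not in order:
            order.append(cid)
        per_stereo.setdefault(key, []).append(rec)

    if not per_stereo:
        raise ValueError(f"no molecules read from {sdf_path}")

    entries: dict[str, list[ConformerRecord]] = {}
    for (cid, _sid), confs in per_stereo.items():
        if dedup_rmsd is not None:
            confs = dedup_conformers(confs, dedup_rmsd)
        entries.setdefault(cid, []).extend(confs)
    return [
        CompoundEntry(cid, entries[cid], is_active=labels.get(cid)) for cid in order
    ]


def _match_mappings(model: Pharmacophore, conf_features: list[Feature], step: float):
    """Backtracking generator of bin-compatible injective mappings.

    Yields tuples of conformer-feature indices (aligned with model feature
    order) whose pairwise binned distances all equal the model's.
    """
    m = len(model)
    mcoords = model.coords()
    ccoords = np.array([f.xyz for f in conf_features], dtype=float)
    mbins = np.floor(
        np.linalg.norm(mcoords[:, None, :] - mcoords[None, :, :], axis=-1) / step + 0.5
    ).astype(int)
    cbins = np.floor(
        np.linalg.norm(ccoords[:, None, :] - ccoords[None, :, :], axis=-1) / step + 0.5
    ).astype(int)

    cand = []
    for i in range(m):
        lab = model.features[i].label
        cand.append([j for j, f in enumerate(conf_features) if f.label == lab])
    if any(not c for c in cand):
        return
    # assign scarcest model features first
    order = sorted(range(m), key=lambda i: len(cand[i]))

    assignment = [None] * m

    def backtrack(k: int):
        if k == m:
            yield tuple(assignment)
            return
        i = order[k]
        for j in cand[i]:
            if j in assignment:
                continue
            ok = True
            for kk in range(k):
                i2 = order[kk]
                if cbins[j, assignment[i2]] != mbins[i, i2]:
                    ok = False
                    break
            if ok:
                assignment[i] = j
                yield from backtrack(k + 1)
                assignment[i] = None

    yield from backtrack(0)


def conformer_matches_model(
    c: ConformerRecord, m: Pharmacophore, cfg: HashConfig | None = None
) -> bool:
    """True iff some feature subset of the conformer carries the model's hash."""
    cfg = cfg or HashConfig()
    if not c.features or not len(m):
        return False
    target = hash_pharmacophore(m, cfg).digest
    tested: set[frozenset[int]] = set()
    for mapping in _match_mappings(m, c.features, cfg.binning_step):
        subset = frozenset(mapping)
        if subset in tested:
            continue
        tested.add(subset)
        feats = [c.features[j] for j in sorted(subset)]
        try:
            sub = Pharmacophore(feats)
        except ValueError:
            continue
        if hash_pharmacophore(sub, cfg).digest == target:
            return True
    return False


@dataclass
class MatchMatrix:
    """Boolean model x conformer match matrix for one compound."""

    compound_id: str
    model_hashes: list[str]
    conformer_keys: list[tuple[str, int]]
    matrix: np.ndarray  # bool, shape (n_models, n_conformers)
    is_active: bool | None = None


def screen(
    library: list[CompoundEntry],
    models: list[Pharmacophore],
    cfg: HashConfig | None = None,
) -> dict[str, MatchMatrix]:
    """Full match matrices for every compound against every model."""
    cfg = cfg or HashConfig()
    if not models:
        raise ValueError("no models selected")
    if not library:
        raise ValueError("empty library")
    hashes = [hash_pharmacophore(m, cfg).digest for m in models]
    out: dict[str, MatchMatrix] = {}
    for entry in library:
        mat = np.zeros((len(models), len(entry.conformers)), dtype=bool)
        for jc, conf in enumerate(entry.conformers):
            for im, model in enumerate(models):
                mat[im, jc] = conformer_matches_model(conf, model, cfg)
        out[entry.compound_id] = MatchMatrix(
            entry.compound_id,
            hashes,
            [c.key for c in entry.conformers],
            mat,
            is_active=entry.is_active,
        )
    return out


def write_matches(matrices: dict[str, MatchMatrix], path) -> None:
    """Persist match matrices as TSV (compound_id, stereoisomer_id,
    conformer_id, model_hash, matched)."""
    rows = []
    for mm in matrices.values():
        for im, h in enumerate(mm.model_hashes):
            for jc, (sid, conf_id) in enumerate(mm.conformer_keys):
                rows.append((mm.compound_id, sid, conf_id, h, int(mm.matrix[im, jc])))
    pd.DataFrame(
        rows, columns=["compound_id", "stereoisomer_id", "conformer_id", "model_hash", "matched"]
    ).to_csv(path, sep="\t", index=False)


def read_matches(path) -> dict[str, MatchMatrix]:
    """Reload match matrices written by :func:`write_matches`."""
    tab = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "stereoisomer_id": str})
    out: dict[str, MatchMatrix] = {}
    for cid, grp in tab.groupby("compound_id", sort=False):
        hashes = list(dict.fromkeys(grp["model_hash"]))
        keys = list(dict.fromkeys(zip(grp["stereoisomer_id"], grp["conformer_id"])))
        mat = np.zeros((len(hashes), len(keys)), dtype=bool)
        hidx = {h: i for i, h in enumerate(hashes)}
        kidx = {k: j for j, k in enumerate(keys)}
        for _, row in grp.iterrows():
            mat[hidx[row["model_hash"]], kidx[(row["stereoisomer_id"], row["conformer_id"])]] = bool(
                row["matched"]
            )
        out[cid] = MatchMatrix(cid, hashes, keys, mat)
    return out


def save_representatives(reps, groups, outdir) -> Path:
    """Write a representative-model set: one record per model plus a TSV
    manifest (hash, n_features, frame_indices, file)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    # groups preserve insertion order aligned with reps
    for rep, (digest, members) in zip(reps, groups.items()):
        fname = f"model_{digest[:12]}.json"
        rep.save(outdir / fname)
        rows.append((digest, len(rep), ",".join(str(i) for i in members), fname))
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=["hash", "n_features", "frame_indices", "file"]).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest
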