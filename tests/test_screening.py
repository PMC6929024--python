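import itertools
import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Geometry import Point3D

from pharmens.core import Feature, Pharmacophore, RigidTransform
from pharmens.hashing import HashConfig, hash_pharmacophore
from pharmens.screening import (
    ConformerRecord,
    assign_ligand_features,
    conformer_matches_model,
    dedup_conformers,
    read_library,
    screen,
)
from pharmens.synth import LibrarySpec, build_library, make_library, random_pharmacophore


def _mol(atoms, bonds):
    rw = Chem.RWMol()
    conf = Chem.Conformer(len(atoms))
    for i, (el, xyz, q) in enumerate(atoms):
        a = Chem.Atom(el)
        if q:
            a.SetFormalCharge(q)
        rw.AddAtom(a)
        conf.SetAtomPosition(i, Point3D(*xyz))
    for i, j, bt in bonds:
        rw.AddBond(i, j, bt)
    m = rw.GetMol()
    m.AddConformer(conf)
    Chem.SanitizeMol(m)
    return m


RING6 = [(1.39 * math.cos(k * math.pi / 3), 1.39 * math.sin(k * math.pi / 3), 0.0) for k in range(6)]


class TestAssignFeatures:
    def test_benzene_gives_one_aromatic_centroid_feature(self):
        mol = _mol(
            [("C", xyz, 0) for xyz in RING6],
            [(i, (i + 1) % 6, Chem.BondType.AROMATIC) for i in range(6)],
        )
        feats = assign_ligand_features(mol)
        assert [f.label for f in feats] == ["a"]
        assert np.allclose(feats[0].xyz, (0, 0, 0), atol=1e-9)

    def test_acetate_features(self):
        """Acetate: one negative-ionizable feature at the carboxylate centroid
        plus one acceptor per oxygen; the methyl is a lone apolar atom and
        stays below the hydrophobic group-size threshold."""
        atoms = [
            ("C", (-1.5, 0.0, 0.0), 0),
            ("C", (0.0, 0.0, 0.0), 0),
            ("O", (0.6, 1.05, 0.0), 0),
            ("O", (0.6, -1.05, 0.0), -1),
        ]
        bonds = [
            (0, 1, Chem.BondType.SINGLE),
            (1, 2, Chem.BondType.DOUBLE),
            (1, 3, Chem.BondType.SINGLE),
        ]
        feats = assign_ligand_features(_mol(atoms, bonds))
        labels = sorted(f.label for f in feats)
        assert labels == ["A", "A", "N"]
        nfeat = next(f for f in feats if f.label == "N")
        assert np.allclose(nfeat.xyz, np.mean([atoms[i][1] for i in (1, 2, 3)], axis=0), atol=1e-9)

    def test_methane_has_no_features(self):
        feats = assign_ligand_features(_mol([("C", (0, 0, 0), 0)], []))
        assert feats == []

    def test_cyclohexane_chair_is_not_aromatic(self):
        # chair geometry: alternating z, clearly non-planar
        chair = [
            (1.45 * math.cos(k * math.pi / 3), 1.45 * math.sin(k * math.pi / 3), 0.25 * (-1) ** k)
            for k in range(6)
        ]
        mol = _mol(
            [("C", xyz, 0) for xyz in chair],
            [(i, (i + 1) % 6, Chem.BondType.SINGLE) for i in range(6)],
        )
        assert all(f.label != "a" for f in assign_ligand_features(mol))


def _conf(length, cid="X", sid="1", conf_id=0):
    # two-point conformer: best-fit RMSD between lengths L1, L2 is |L1-L2|/2
    atoms = [("C", (-length / 2, 0.0, 0.0)), ("C", (length / 2, 0.0, 0.0))]
    return ConformerRecord(cid, sid, conf_id, atoms, [])


class TestDedupConformers:
    def test_identical_conformers_collapse(self):
        assert len(dedup_conformers([_conf(10.0), _conf(10.0, conf_id=1)])) == 1

    def test_rmsd_above_cutoff_kept(self):
        kept = dedup_conformers([_conf(10.0), _conf(11.2, conf_id=1)])  # rmsd 0.6
        assert len(kept) == 2

    def test_greedy_keep_first_chain(self):
        """RMSD(1,2)=0.4, RMSD(1,3)=0.8, RMSD(2,3)=0.4: greedy keep-first
        drops 2 (near kept 1) and keeps 3 (far from 1)."""
        c1, c2, c3 = _conf(10.0), _conf(10.8, conf_id=1), _conf(11.6, conf_id=2)
        kept = dedup_conformers([c1, c2, c3])
        assert [c.conformer_id for c in kept] == [0, 2]

    def test_atom_count_mismatch_raises(self):
        bad = ConformerRecord("X", "1", 1, [("C", (0, 0, 0))], [])
        with pytest.raises(ValueError):
            dedup_conformers([_conf(10.0), bad])


from tests._oracles import oracle_match as _oracle_match
from tests._oracles import record_from_features as _record_from_features


class TestMatcher:
    def test_identity_match(self, rng):
        m = random_pharmacophore(rng, 5)
        c = _record_from_features(m.features)
        assert conformer_matches_model(c, m)

    def test_rigid_motion_plus_decoy_features(self, rng):
        m = random_pharmacophore(rng, 4)
        moved = m.transformed(RigidTransform.random(rng))
        extras = [Feature("H", (50.0 + 3 * i, 50.0, 50.0)) for i in range(3)]
        c = _record_from_features(list(moved.features) + extras)
        assert conformer_matches_model(c, m)

    def test_mirror_image_does_not_match(self):
        m = Pharmacophore(
            [Feature(l, xyz) for l, xyz in zip("ADHa", [(0, 0, 0), (3, 0, 0), (0, 3, 0), (1, 1, 3)])]
        )
        mirror = [Feature(f.label, (-f.xyz[0], f.xyz[1], f.xyz[2])) for f in m.features]
        assert not conformer_matches_model(_record_from_features(mirror), m)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_exhaustive_oracle(self, seed):
        """Pruned clique-style search == brute-force mapping enumeration on
        random small instances, planted and unplanted."""
        rng = np.random.default_rng(seed)
        cfg = HashConfig()
        n_checked = 0
        for trial in range(125):
            m = random_pharmacophore(rng, int(rng.integers(3, 5)))
            if trial % 2 == 0:
                base = m.transformed(RigidTransform.random(rng))
                feats = list(base.features)
            else:
                feats = list(random_pharmacophore(rng, len(m), labels=m.labels).features)
            extra = random_pharmacophore(rng, int(rng.integers(1, 4)), box=14.0)
            feats = feats + list(extra.features)
            c = _record_from_features(feats)
            assert conformer_matches_model(c, m, cfg) == _oracle_match(c, m, cfg)
            n_checked += 1
        assert n_checked == 125

    def test_monotone_under_model_simplification(self, rng):
        """If a conformer matches a model it matches every sub-model obtained
        by deleting features (same binning)."""
        m = random_pharmacophore(rng, 6)
        c = _record_from_features(m.transformed(RigidTransform.random(rng)).features)
        assert conformer_matches_model(c, m)
        for drop in range(len(m)):
            sub = Pharmacophore([f for i, f in enumerate(m.features) if i != drop])
            assert conformer_matches_model(c, sub)


class TestScreen:
    def test_single_identity_cell(self, rng):
        m = random_pharmacophore(rng, 4)
        c = _record_from_features(m.features, cid="CPD")
        from pharmens.screening import CompoundEntry

        mats = screen([CompoundEntry("CPD", [c])], [m])
        assert mats["CPD"].matrix.shape == (1, 1) and bool(mats["CPD"].matrix[0, 0])

    def test_no_models_after_filter_raises(self, rng):
        from pharmens.screening import CompoundEntry

        c = _record_from_features(random_pharmacophore(rng, 4).features, cid="CPD")
        with pytest.raises(ValueError, match="no models"):
            screen([CompoundEntry("CPD", [c])], [])

    def test_planted_library_matrix_guarantees(self, representatives):
        """Planted actives have >= 1 true cell; verified-non-matching decoys
        have all-false matrices; matrix content is order-independent."""
        reps, _ = representatives
        spec = LibrarySpec(n_actives=3, n_decoys=5, conformers_per_compound=3,
                           match_fraction=1.0, seed=5)
        entries, _ = build_library(spec, reps)
        mats = screen(entries, reps)
        for e in entries:
            mm = mats[e.compound_id]
            if e.is_active:
                assert mm.matrix.any()
            else:
                assert not mm.matrix.any()
        # model/library order independence of matrix content
        mats_rev = screen(entries[::-1], reps[::-1])
        for e in entries:
            assert np.array_equal(mats[e.compound_id].matrix[::-1], mats_rev[e.compound_id].matrix)


class TestLibraryIO:
    def test_sdf_roundtrip_with_stereo_pooling(self, tmp_path, representatives):
        reps, _ = representatives
        spec = LibrarySpec(n_actives=3, n_decoys=2, conformers_per_compound=4,
                           match_fraction=0.5, seed=7)
        sdf, labels = make_library(spec, reps, tmp_path / "lib.sdf", tmp_path / "lab.tsv")
        lib = read_library(sdf, labels)
        assert len(lib) == 5
        by_id = {e.compound_id: e for e in lib}
        # every third active splits conformers over two stereoisomer ids,
        # pooled into one compound entry
        sids = {c.stereoisomer_id for c in by_id["ACT00000"].conformers}
        assert sids == {"1", "2"}
        assert len(by_id["ACT00000"].conformers) == 4
        assert by_id["ACT00000"].is_active is True
        assert by_id["DEC00000"].is_active is False

    def test_read_dedup_applies_per_stereoisomer(self, tmp_path, representatives):
        reps, _ = representatives
        spec = LibrarySpec(n_actives=2, n_decoys=0, conformers_per_compound=3,
                           match_fraction=1.0, seed=9)
        sdf, labels = make_library(spec, reps, tmp_path / "lib.sdf", tmp_path / "lab.tsv")
        lib = read_library(sdf, labels, dedup_rmsd=0.5)
        # spacer groups make planted conformers mutually distinct
        assert all(len(e.conformers) == 3 for e in lib)
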