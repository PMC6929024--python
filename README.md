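# pharmens — ensemble pharmacophore virtual screening

`pharmens` implements structure-based virtual screening with *ensembles* of
pharmacophore models extracted from protein–ligand complex trajectories.  A
single crystal structure gives one static pharmacophore, which is often
either too specific (too many features, no hits) or too loose (few features,
poor enrichment).  Sampling a molecular-dynamics trajectory instead gives
thousands of frame pharmacophores; the problem is reducing them to a
tractable, representative set and ranking screening compounds against all of
them.  This package is aimed at computational medicinal chemists who have
complex frames (multi-model PDB) and a conformer library (SDF) and want
ranked compounds with precision/enrichment statistics.

## Method

1. **Perception.**  Each frame is split into protein and ligand (waters
   stripped).  Geometric criteria detect H-bonds, hydrophobic contacts,
   aromatic ring stacking, and ionic short contacts (< 3.8 Å between charged
   side chains of Glu/Asp/Lys/Arg/His and oppositely charged ligand groups).
   Accepted interactions become undirected ligand-side features with labels
   from the alphabet {A, D, a, H, P, N} (acceptor, donor, aromatic,
   hydrophobic, positive, negative), refined against a SMARTS-based feature
   pattern dictionary.

2. **3D pharmacophore hashing.**  A pharmacophore with features
   {(ℓᵢ, xᵢ)} is serialized canonically from its labels, the binned pairwise
   distance matrix ⌊‖xᵢ−xⱼ‖/s + ½⌋ at binning step *s* (default 1 Å), and a
   stereo signature sign(det[x_b−x_a, x_c−x_a, x_d−x_a]) over all feature
   quadruplets; the MD5 of that text is the hash.  Equal hashes ⇔
   near-congruent pharmacophores including stereoconfiguration.  Removing
   duplicate hashes reduces the frame ensemble to *representative models*.

3. **Screening and ranking.**  A conformer *matches* a model when some
   label-preserving injective mapping of the model features onto the
   conformer features reproduces the model's hash.  From the per-compound
   model × conformer match matrix:

   * CHA (common hits approach): `100 · |models matched by ≥1 conformer| / |models|`
   * CCA (conformers coverage approach): `100 · |conformers matching ≥1 model| / |conformers|`
   * consensus: mean CCA across several complex ensembles.

4. **Evaluation.**  At each cutoff p%, the top `round(p/100·N)` compounds
   plus all score-ties are selected (zero-score compounds are never
   retrieved); `precision = TP/(TP+FP)` and
   `EF = precision / baseline precision` with the baseline the library's
   active fraction.

Stereoisomers of a compound are pooled and treated as one compound; CCA
denominators count conformers across all stereoisomers.

## Worked example

Everything below is synthetic and self-contained (no downloads); the
`pharmens.synth` module generates trajectories with a planted number of
distinct binned geometries and libraries with planted actives and
verified-non-matching decoys.

```python
from pathlib import Path
from pharmens import (read_frames, perceive_pharmacophore, select_representatives,
                      read_library, screen, evaluate)
from pharmens.scoring import score_matrices
from pharmens.synth import SceneSpec, LibrarySpec, make_trajectory, make_library

work = Path("demo"); work.mkdir(exist_ok=True)
traj, truth = make_trajectory(SceneSpec(n_frames=50, n_states=4, seed=7), work / "traj.pdb")
frames = read_frames(traj)
models = [perceive_pharmacophore(f) for f in frames]
reps, groups = select_representatives(models)
print(f"{len(frames)} frames -> {len(reps)} representative models "
      f"({100*len(reps)/len(frames):.1f}% of the ensemble)")

sdf, labels = make_library(
    LibrarySpec(n_actives=10, n_decoys=190, conformers_per_compound=4,
                match_fraction=0.5, seed=8),
    reps, work / "library.sdf", work / "labels.tsv")
library = read_library(sdf, labels)
table = score_matrices(screen(library, reps))
scored = [(r.compound_id, r.cca, r.is_active) for r in table.itertuples()]
print(evaluate(scored, (1.0, 5.0, 100.0)).to_string(index=False))
```

Output:

```
50 frames -> 4 representative models (8.0% of the ensemble)
 cutoff_percent  n_selected  TP  FP  precision  enrichment_factor  baseline_precision
            1.0          10  10   0        1.0               20.0                0.05
            5.0          10  10   0        1.0               20.0                0.05
          100.0          10  10   0        1.0               20.0                0.05
```

The 50-frame trajectory collapses to exactly the 4 planted geometry states.
Half the conformers of each planted active reproduce a representative model
(CCA 50), decoys are constructed to match nothing (CCA 0), so every
selection contains only actives: precision 1.0 against a baseline active
fraction of 10/200 = 0.05, hence EF = 20 at every cutoff (only the 10
retrieved compounds are selectable).

The same pipeline is available as a CLI:

```sh
pharmens perceive traj.pdb --out ensemble/
pharmens reduce ensemble/ --out reps/
pharmens screen library.sdf reps/ --out matches.tsv --min-features 4
pharmens rank matches.tsv --labels labels.tsv --out report/ --score cca
```

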