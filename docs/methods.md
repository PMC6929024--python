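# Methods

## Model and scope

`pharmens` treats a pharmacophore as an order-free set of undirected, typed
3D points.  Directed features (H-bond vectors, ring normals) and excluded
volumes are deliberately out of scope: the hash, matcher and scores are all
defined on point sets with labels from {A, D, a, H, P, N}.  The package
consumes trajectory frames; producing them (force fields, thermostats,
simulation engines) is outside its contract, as is conformer generation for
screening libraries — conformers arrive in SDF with compound and
stereoisomer identifiers.

## Frame handling

Frames are read from multi-model PDB or a directory of per-frame PDBs
(Biopython parser, strict mode).  Waters (HOH/WAT/SOL) are stripped; the
ligand defaults to the unique non-standard, non-water residue and is
overridable by residue name or predicate.  Frame sampling at interval dt
over a run of length T counts frames at t = dt, 2dt, …, ≤ T — t = 0 is
excluded, so 50 ns sampled every 20 ps gives exactly 2500 frames.  Whether
the t = 0 structure belongs in the ensemble is genuinely ambiguous; the
exclusive convention was chosen because it reproduces the canonical count,
and the crystal-structure baseline model is handled separately anyway (it is
simply perception applied to the first/static frame).

## Interaction perception

Perception is geometric and fully configurable (`InteractionConfig`):

| interaction | criterion | default |
|---|---|---|
| H-bond | donor–acceptor heavy-atom distance | ≤ 3.5 Å |
| H-bond (H present) | D–H…A angle | ≥ 120° |
| hydrophobic | ligand apolar C group to protein apolar C | ≤ 4.0 Å |
| aromatic | ring centroid to protein aromatic ring centroid | ≤ 5.5 Å |
| ionic | charged side chain to oppositely charged ligand group, closest atoms | < 3.8 Å |

The ionic 3.8 Å short-contact rule for Glu/Asp/Lys/Arg/His side chains is a
fixed reference value; the others sit near the published defaults of common
interaction profilers.  Since different profilers (and versions) disagree on
exact cutoffs, per-frame feature counts on real systems are not expected to
reproduce any particular external tool — the downstream contracts
(hashing, dedup, scoring) are independent of those choices.  Hydrogens are
optional: when a donor has no resolved H, the angle test is skipped and the
distance test decides.  Histidine counts as positively charged only as the
HIP variant or when both ring nitrogens carry a resolved hydrogen.

Ligand-side feature typing uses a plain-text pattern dictionary
(`pharmens/data/feature_patterns.txt`, user-replaceable).  The SMARTS
entries avoid bond orders and formal charges so the same dictionary types
both SDF molecules and ligands carved out of PDB frames, whose bonds are
perceived from interatomic distances (RDKit).  Aromatic rings are accepted
either by RDKit aromaticity or as planar all-carbon 5/6-rings (max deviation
from the best-fit plane ≤ 0.15 Å), which excludes saturated carbocycles
when only a single-bond skeleton is known.  Hydrophobic features require a
bonded group of ≥ 2 apolar carbons, so an isolated methyl (or methane)
yields nothing.

## Canonical 3D hash

The hash serializes labels, the binned distance matrix, and the quadruplet
stereo signature in a canonical feature order, then digests with MD5.  The
serialization, not the digest algorithm, is the contract.

* **Binning** is round-half-up of d/step; default step 1 Å.  Any consistent
  convention satisfies the invariants; this one is fixed and documented.
* **Canonical order** comes from iterative rank refinement (seeded by label,
  refined by sorted multisets of (neighbor rank, binned distance)); residual
  ties are resolved by exploring each tied branch and keeping the
  lexicographically minimal serialization.  Cost is worst-case factorial in
  a fully symmetric tied class, irrelevant at ≤ ~10 features.
* **Stereo signature**: for each feature quadruplet in canonical order, the
  sign of the signed tetrahedron volume, normalized by the product of the
  three edge lengths from the first vertex (dimensionless).  Magnitudes
  ≤ the planarity tolerance give 0; default tolerance 0.  A numerical guard
  (1e-9) treats exactly coplanar quadruplets as planar even at tolerance 0 —
  without it, floating-point noise under rigid motion would assign random
  signs to flat arrangements and break rotation invariance.

Consequences, verified by property tests: digests are invariant to rigid
motion and feature order; mirror images of chiral (4+ feature, non-planar)
pharmacophores hash differently, planar ones identically; equal digests at
step 1 Å bound the best-fit RMSD well below the binning step, while equal
RMSD does not imply equal digest.  Distances exactly on a bin boundary (or
quadruplets exactly at the tolerance) are knife-edge cases where jitter can
flip the digest; the synthetic generator keeps all planted distances ≥ 0.2 Å
away from boundaries for this reason.

Representative selection keeps the first frame of each hash group.  The
choice of member is arbitrary by construction (group members are
near-congruent); first occurrence is deterministic and needs no auxiliary
quantity such as conformer energies.

## Best-fit RMSD

Pairs of pharmacophores with identical label multisets are compared by the
minimum Kabsch RMSD over all label-preserving bijections (proper rotations
only, so chirality is respected; scipy's `Rotation.align_vectors` supplies
the superposition).  The search enumerates bijections within label classes
with a branch-and-bound prune based on the inequality
rmsd ≥ √(Σ_{i<j} (Δd_ij)² / (2n(n−1))).  RMSD is unweighted across feature
points.

## Matching and screening

`conformer_matches_model` asks for a label-preserving injective mapping of
model features onto conformer features whose selected subset reproduces the
model's hash.  The backtracking search assigns scarcest labels first and
prunes on pairwise binned-distance equality; surviving subsets are verified
by hash (which also enforces the stereo signature, rejecting mirror-image
fits).  Matching is therefore *exactly* the duplicate relation of the
ensemble dedup, at the same binning step: no tolerance spheres, no partial
(k-of-n) credit.  Exact full-model matching is assumed; a looser policy
would be a different screening contract, not a parameter.

Conformer deduplication is a greedy keep-first filter at heavy-atom best-fit
RMSD < 0.5 Å, applied per stereoisomer (same atom ordering assumed).  The
threshold is the conventional duplicate cutoff; the greedy rule is the
simplest deterministic clustering consistent with it.

## Scoring and evaluation

CHA and CCA are percentages over the match matrix rows/columns; stereoisomer
pooling means CCA denominators span all conformers of a compound.  Consensus
ranking is the arithmetic mean of per-complex CCA scores, with missing
entries scored 0 (consistent with "not retrieved").  Top-p% selection uses
k = round(p/100·N) half-up — the tie-extension and under-retrieval rules
make the rounding convention nearly immaterial — extends the selection
across score ties with the k-th compound, never retrieves zero scores, and
degrades to the retrieved set when fewer than k compounds score > 0.
Baseline precision is always computed from the evaluated library's own
labels, never hard-coded.  Report order among tied scores is lexicographic
by compound id, for reproducible output files.

## Synthetic data

The generator emulates the *inputs* of the pipeline, not physics:

* **Trajectories** (`SceneSpec`): each realized interaction kind is one
  ligand part (2–6 atoms with the feature anchor at a known point) plus a
  complementary protein fragment placed inside the corresponding cutoff
  (e.g. carboxylate with a Lys NZ at 3.14 Å closest contact but > 3.5 Å
  from the carboxylate oxygens, so the ionic channel fires without a
  spurious H-bond).  Part anchors are sampled 6.5–18 Å apart with all
  pairwise distances ≥ 0.2 Å from bin boundaries and all quadruplets
  ≥ 0.05 normalized volume from planarity.  Distinct states displace one
  part by ~2 Å; frames add per-part rigid jitter (default sd 0.05 Å, part
  and partner move together so interaction distances are exact) and a random
  global rigid motion.  Every frame is verified at generation time to hash
  to its state's digest, with bounded resampling; specs whose jitter defeats
  the bin margin are rejected as infeasible.
* **Libraries** (`LibrarySpec`): actives place ligand parts at a chosen
  model's feature coordinates (verified to match); their non-matching
  conformers, and all decoy conformers, displace one part by 2.2 binning
  steps and are verified to match *no* model — hard decoys that share the
  model's labels but break one binned distance, exercising the matcher's
  distance pruning specifically.  A far-away apolar "spacer" pair makes
  conformers of one compound mutually distinct under the 0.5 Å dedup rule.
  Default fixture conditions: 20 actives, 980 decoys, 5 conformers per
  compound, match fraction 0.5.

What passing synthetic tests shows: the pipeline recovers planted state
counts, separates verified matches from verified non-matches, and turns that
separation into the expected enrichment.  What it does not show: performance
on real MD ensembles, where feature noise is not rigid-part jitter, decoys
are property-matched rather than geometry-broken, and protonation/tautomer
assignment matters.  Headline screening figures on real targets require
real trajectories and a real actives/decoys benchmark.

## Numerical choices and degenerate inputs

* Kabsch on collinear/single-point sets: degenerate optima are accepted
  (any minimizer); n = 1 returns RMSD 0 with a pure translation.
* Empty frames raise a dedicated `EmptyPharmacophoreError`; trajectory-level
  callers skip and log such frames.
* Distances are Å throughout; PDB I/O is fixed-width standard columns, so
  round-trips preserve coordinates to 0.001 Å.
* All randomness flows through `numpy.random.Generator` seeds; generation
  and the CLI are bit-deterministic for a fixed seed.

## Problem sizes in the shipped tests

The test suite and acceptance script run on deliberately small instances:
trajectories of 12–50 frames with 2–5 planted states, libraries up to
20 actives / 980 decoys × 5 conformers, 1000-trial hash property loops, and
500-instance matcher/oracle comparisons.  These sizes were chosen to
exercise every code path and statistical claim while keeping a full run in
the minutes range on one CPU; all of them scale linearly (frames, library
size) or polynomially (feature counts) if increased.

## Known limitations

* Undirected features make models less specific than vector-aware
  pharmacophores; this is a scope decision, not a shortcoming of the hash.
* Perception quality on real PDB frames depends on element records and
  (optionally) hydrogens; exotic residues and metal sites are untyped.
* The matcher's exact-hash criterion is conservative: a conformer missing a
  single model feature scores zero against that model.
* Binning half-up at exact bin boundaries is knife-edged by construction;
  real-valued inputs sit on boundaries with probability zero, but adversarial
  integer-distance inputs can flip digests under infinitesimal perturbation.
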