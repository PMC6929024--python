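"""Typed pharmacophore point sets and rigid-body geometry.

A pharmacophore is an order-free set of typed 3D points ("features")
abstracting the interaction capabilities of a bound ligand: H-bond
acceptors/donors, aromatic ring centers, hydrophobic group centers, and
positive/negative ionizable group centers.  Two pharmacophores are compared
by the best-fit RMSD over proper rigid superpositions, minimized over all
label-preserving correspondences between their feature sets.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: The closed feature alphabet: A = H-bond acceptor, D = H-bond donor,
#: a = aromatic ring, H = hydrophobic group, P = positive ionizable,
#: N = negative ionizable.
FEATURE_LABELS = ("A", "D", "a", "H", "P", "N")


@dataclass(frozen=True)
class Feature:
    """One typed pharmacophore point.

    Parameters
    ----------
    label : str
        One of :data:`FEATURE_LABELS`.
    xyz : tuple of float
        Cartesian coordinates in Angstrom.
    """

    label: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if self.label not in FEATURE_LABELS:
            raise ValueError(f"unknown feature label {self.label!r}")
        xyz = tuple(float(v) for v in self.xyz)
        if len(xyz) != 3 or not all(math.isfinite(v) for v in xyz):
            raise ValueError(f"feature coordinates must be 3 finite floats, got {self.xyz!r}")
        object.__setattr__(self, "xyz", xyz)


@dataclass
class Pharmacophore:
    """A set of features with provenance.

    ``features`` has order-free semantics: every operation downstream
    (hashing, matching, RMSD) is invariant to the list order.  The list
    must be non-empty and may not contain two features sharing both the
    label and identical coordinates.
    """

    features: list[Feature]
    source_id: str = ""
    frame_index: int | None = None

    def __post_init__(self):
        if not self.features:
            raise ValueError("pharmacophore must contain at least one feature")
        seen = set()
        for f in self.features:
            key = (f.label, f.xyz)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.features)

    def coords(self) -> np.ndarray:
        """Feature coordinates as an (n, 3) array, in list order."""
        return np.array([f.xyz for f in self.features], dtype=float)

    def transformed(self, transform: "RigidTransform") -> "Pharmacophore":
        """Return a copy with all features moved by ``transform``."""
        xyz = transform.apply(self.coords())
        feats = [Feature(f.label, tuple(p)) for f, p in zip(self.features, xyz)]
        return Pharmacophore(feats, source_id=self.source_id, frame_index=self.frame_index)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "frame_index": self.frame_index,
            "features": [{"label": f.label, "xyz": list(f.xyz)} for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pharmacophore":
        feats = [Feature(f["label"], tuple(f["xyz"])) for f in d["features"]]
        return cls(feats, source_id=d.get("source_id", ""), frame_index=d.get("frame_index"))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Pharmacophore":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        self.rotation, self.translation = R, t

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 10.0) -> "RigidTransform":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(R, t)


def kabsch_superpose(ref, mov) -> tuple[RigidTransform, float]:
    """Least-squares proper superposition of paired point lists.

    Finds the proper rotation R and translation t minimizing
    ``sum_i |R mov_i + t - ref_i|**2`` and returns the transform together
    with the residual RMSD.  Points are paired by index.
    """
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    mov = np.atleast_2d(np.asarray(mov, dtype=float))
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"point lists must have equal (n, 3) shapes, got {ref.shape} and {mov.shape}")
    n = ref.shape[0]
    if n == 0:
        raise ValueError("empty point lists")
    cref, cmov = ref.mean(axis=0), mov.mean(axis=0)
    if n == 1:
        return RigidTransform(np.eye(3), cref - cmov), 0.0
    with warnings.catch_warnings():
        # degenerate (collinear/planar) point sets give a non-unique optimum;
        # any minimizer is acceptable here
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(ref - cref, mov - cmov)
    R = rot.as_matrix()
    t = cref - R @ cmov
    return RigidTransform(R, t), float(rssd) / math.sqrt(n)


def _rmsd_lower_bound(dref: np.ndarray, dmov: np.ndarray, n: int) -> float:
    # after any rigid superposition |d_ij(ref) - d_ij(mov)| <= e_i + e_j with
    # e_i the per-point residuals, hence
    # rmsd >= sqrt(sum_{i<j} (delta d)^2 / (2 n (n-1)))
    diff2 = (dref - dmov) ** 2
    total = (diff2.sum() - np.trace(diff2)) / 2.0
    return math.sqrt(total / (2.0 * n * (n - 1)))


def best_fit_rmsd(p: Pharmacophore, q: Pharmacophore) -> float | None:
    """Minimum Kabsch RMSD over all label-preserving bijections.

    Returns ``None`` when the label multisets differ (the pharmacophores are
    not comparable).  The search enumerates bijections within label classes
    with a distance-matrix branch-and-bound prune; feature counts in this
    problem are small (typically <= 10), so the factorial worst case within
    a class is acceptable.
    """
    if sorted(p.labels) != sorted(q.labels):
        return None
    n = len(p)
    pc, qc = p.coords(), q.coords()
    if n == 1:
        return 0.0

    by_label: dict[str, list[int]] = {}
    for j, lab in enumerate(q.labels):
        by_label.setdefault(lab, []).append(j)

    dref = np.linalg.norm(pc[:, None, :] - pc[None, :, :], axis=-1)
    dmov = np.linalg.norm(qc[:, None, :] - qc[None, :, :], axis=-1)

    order = sorted(range(n), key=lambda i: len(by_label[p.labels[i]]))
    best = math.inf

    def recurse(k: int, mapping: list[int], used: set[int], pair_sum: float):
        nonlocal best
        # partial lower bound from accumulated squared distance discrepancies
        if pair_sum > 0 and math.sqrt(pair_sum / (2.0 * n * (n - 1))) >= best:
            return
        if k == n:
            perm = [0] * n
            for kk, i in enumerate(order):
                perm[i] = mapping[kk]
            _, rmsd = kabsch_superpose(pc, qc[perm])
            if rmsd < best:
                best = rmsd
            return
        i = order[k]
        for j in by_label[p.labels[i]]:
            if j in used:
                continue
            add = 0.0
            for kk in range(k):
                dd = dref[i, order[kk]] - dmov[j, mapping[kk]]
                add += dd * dd
            recurse(k + 1, mapping + [j], used | {j}, pair_sum + add)

    recurse(0, [], set(), 0.0)
    return best


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Dense pairwise Euclidean distance matrix for an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    return np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)


def enumerate_label_bijections(p_labels, q_labels):
    """Yield every label-preserving bijection p index -> q index.

    Brute-force helper used as an independent oracle in tests; kept simple
    on purpose (no pruning).
    """
    if sorted(p_labels) != sorted(q_labels):
        return
    classes: dict[str, list[int]] = {}
    for j, lab in enumerate(q_labels):
        classes.setdefault(lab, []).append(j)
    p_classes: dict[str, list[int]] = {}
    for i, lab in enumerate(p_labels):
        p_classes.setdefault(lab, []).append(i)
    labs = sorted(classes)
    pools = [itertools.permutations(classes[lab]) for lab in labs]
    for combo in itertools.product(*pools):
        perm = [0] * len(p_labels)
        for lab, qperm in zip(labs, combo):
            for i, j in zip(p_classes[lab], qperm):
                perm[i] = j
        yield perm
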