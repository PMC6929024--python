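"""Canonical binned 3D pharmacophore hashes and ensemble deduplication.

The hash is a stable digest of a canonical serialization built from three
rigid-motion-invariant ingredients: the feature labels, the pairwise
interfeature distances discretized on a binning grid, and a stereo
signature recording the chirality sign of every feature quadruplet.  Two
pharmacophores receive the same digest exactly when some label-preserving
correspondence maps one onto the other with identical binned distances and
identical quadruplet signs — i.e. when they are near-congruent at the
resolution of the binning step, including stereoconfiguration.

Deduplicating an ensemble of frame-derived pharmacophores by digest yields
the representative model set used for screening.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import Pharmacophore

# numerical guard: normalized quadruplet volumes below this magnitude are
# treated as exactly planar even at tolerance 0, so that coplanar feature
# sets keep a zero stereo sign under floating-point rigid motions
_PLANAR_EPS = 1e-9


@dataclass(frozen=True)
class HashConfig:
    """Hash resolution parameters.

    binning_step : float
        Width (A) of the distance discretization grid; default 1 A.
    planarity_tolerance : float
        Dimensionless threshold on the normalized quadruplet volume below
        which the stereo sign is 0; default 0 (strict sign).
    """

    binning_step: float = 1.0
    planarity_tolerance: float = 0.0

    def __post_init__(self):
        if self.binning_step <= 0:
            raise ValueError("binning_step must be positive")
        if self.planarity_tolerance < 0:
            raise ValueError("planarity_tolerance must be >= 0")


@dataclass(frozen=True)
class Hash3D:
    """Canonical identifier of a pharmacophore at a given hash resolution."""

    digest: str
    n_features: int
    config: HashConfig


def bin_distance(d: float, step: float) -> int:
    """Nearest-integer bin of ``d / step`` with half-up rounding."""
    if step <= 0:
        raise ValueError("step must be positive")
    if d < 0:
        raise ValueError("distance must be non-negative")
    return int(math.floor(d / step + 0.5))


def _binned_matrix(p: Pharmacophore, cfg: HashConfig) -> np.ndarray:
    coords = p.coords()
    dm = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    return np.floor(dm / cfg.binning_step + 0.5).astype(int)


def _quadruplet_sign(coords: np.ndarray, quad, tol: float) -> int:
    a, b, c, d = (coords[i] for i in quad)
    u, v, w = b - a, c - a, d - a
    vol = float(np.dot(np.cross(u, v), w))
    denom = np.linalg.norm(u) * np.linalg.norm(v) * np.linalg.norm(w)
    if denom == 0:
        return 0
    nv = vol / denom
    if abs(nv) <= max(tol, _PLANAR_EPS):
        return 0
    return 1 if nv > 0 else -1


def _refine_ranks(labels, binned, ranks):
    """One pass of neighborhood rank refinement; returns the new dense ranks."""
    n = len(labels)
    sigs = []
    for i in range(n):
        neigh = sorted((ranks[j], int(binned[i, j])) for j in range(n) if j != i)
        sigs.append((ranks[i], tuple(neigh)))
    order = sorted(range(n), key=lambda i: sigs[i])
    new = [0] * n
    r = 0
    for k, i in enumerate(order):
        if k > 0 and sigs[i] != sigs[order[k - 1]]:
            r = k
        new[i] = r
    return new


def _stable_ranks(labels, binned):
    lab_sorted = sorted(set(labels))
    ranks = [lab_sorted.index(lab) for lab in labels]
    # dense-rank normalization
    ranks = _refine_ranks(labels, binned, ranks)
    while True:
        new = _refine_ranks(labels, binned, ranks)
        if new == ranks:
            return ranks
        ranks = new


def _serialize(p: Pharmacophore, cfg: HashConfig, order) -> str:
    labels = [p.features[i].label for i in order]
    binned = _binned_matrix(p, cfg)
    rows = []
    n = len(order)
    for a in range(n):
        rows.append(",".join(str(int(binned[order[a], order[b]])) for b in range(a + 1, n)))
    coords = p.coords()
    signs = [
        str(_quadruplet_sign(coords, [order[i] for i in quad], cfg.planarity_tolerance))
        for quad in itertools.combinations(range(n), 4)
    ]
    return (
        f"step={cfg.binning_step:g};tol={cfg.planarity_tolerance:g}"
        f"|L:{','.join(labels)}|D:{';'.join(rows)}|S:{','.join(signs)}"
    )


def _canonical(p: Pharmacophore, cfg: HashConfig) -> tuple[list[int], str]:
    """Canonical feature order and serialization.

    Iterative rank refinement seeded by label and refined by the sorted
    multiset of (neighbor rank, binned distance); residual ties are resolved
    by branching on each tied candidate and keeping the lexicographically
    minimal full serialization, so the result is invariant to input order.
    """
    labels = list(p.labels)
    binned = _binned_matrix(p, cfg)
    n = len(labels)

    best: list[str | list[int] | None] = [None, None]  # serialization, order

    def explore(ranks):
        counts: dict[int, list[int]] = {}
        for i, r in enumerate(ranks):
            counts.setdefault(r, []).append(i)
        tied = sorted(r for r, members in counts.items() if len(members) > 1)
        if not tied:
            order = sorted(range(n), key=lambda i: ranks[i])
            ser = _serialize(p, cfg, order)
            if best[0] is None or ser < best[0]:
                best[0], best[1] = ser, order
            return
        r = tied[0]
        for i in counts[r]:
            forced = list(ranks)
            for j in counts[r]:
                if j != i:
                    forced[j] += 1
            forced = _refine_ranks(labels, binned, forced)
            while True:
                nxt = _refine_ranks(labels, binned, forced)
                if nxt == forced:
                    break
                forced = nxt
            explore(forced)

    explore(_stable_ranks(labels, binned))
    return best[1], best[0]


def canonical_order(p: Pharmacophore, cfg: HashConfig | None = None) -> list[int]:
    """Deterministic, input-order-invariant permutation of feature indices."""
    cfg = cfg or HashConfig()
    order, _ = _canonical(p, cfg)
    return order


def canonical_serialization(p: Pharmacophore, cfg: HashConfig | None = None) -> str:
    """The canonical text the digest is computed from (the real contract)."""
    cfg = cfg or HashConfig()
    _, ser = _canonical(p, cfg)
    return ser


def stereo_signature(p: Pharmacophore, order, cfg: HashConfig | None = None) -> list[int]:
    """Chirality signs (-1, 0, +1) of every canonical feature quadruplet.

    The sign is that of the signed volume of the tetrahedron spanned by the
    quadruplet, normalized by the product of the three edge lengths from its
    first vertex; magnitudes within ``planarity_tolerance`` give 0.  With
    fewer than four features the signature is empty.
    """
    cfg = cfg or HashConfig()
    n = len(p)
    if n < 4:
        return []
    coords = p.coords()
    return [
        _quadruplet_sign(coords, [order[i] for i in quad], cfg.planarity_tolerance)
        for quad in itertools.combinations(range(n), 4)
    ]


def hash_pharmacophore(p: Pharmacophore, cfg: HashConfig | None = None) -> Hash3D:
    """Canonical binned 3D hash of a pharmacophore."""
    cfg = cfg or HashConfig()
    ser = canonical_serialization(p, cfg)
    return Hash3D(hashlib.md5(ser.encode()).hexdigest(), len(p), cfg)


def select_representatives(
    models: list[Pharmacophore], cfg: HashConfig | None = None
) -> tuple[list[Pharmacophore], dict[str, list[int]]]:
    """Deduplicate an ensemble to one representative per distinct digest.

    The representative of a hash group is its first member in input (frame)
    order.  Returns the representatives and a table mapping each digest to
    the frame indices of all group members (falling back to list position
    when a model carries no frame index).
    """
    if not models:
        raise ValueError("empty model list")
    cfg = cfg or HashConfig()
    reps: list[Pharmacophore] = []
    groups: dict[str, list[int]] = {}
    for pos, m in enumerate(models):
        h = hash_pharmacophore(m, cfg)
        idx = m.frame_index if m.frame_index is not None else pos
        if h.digest not in groups:
            groups[h.digest] = []
            reps.append(m)
        groups[h.digest].append(idx)
    return reps, groups
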