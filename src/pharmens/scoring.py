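"""Compound ranking and screening evaluation.

Two ranking strategies over a compound's model x conformer match matrix:

* CHA (common hits approach): score = percentage of representative models
  matched by at least one conformer of the compound.
* CCA (conformers coverage approach): score = percentage of the compound's
  conformers (pooled over stereoisomers) matching at least one model.

When several complex ensembles are available, a consensus ranking averages
the per-complex CCA scores.  Evaluation follows the precision / enrichment
factor scheme: at each cutoff p%, the top round(p/100 * N) compounds are
selected, extended by every compound tied with the last selected score;
compounds with score 0 are "not retrieved", and when fewer than the
requested count are retrieved the selection is exactly the retrieved set.
Precision = TP / (TP + FP); EF = precision / baseline precision, with the
baseline the active fraction of the evaluated library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Pharmacophore

#: Selection-percentage grid used in evaluation reports.
DEFAULT_CUTOFFS = (0.25, 0.5, 1.0, 2.0, 5.0, 10.0, 100.0)


@dataclass
class ScreenResult:
    compound_id: str
    cha_score: float
    cca_score: float
    n_models_matched: int
    n_conformers_matched: int
    n_models: int
    n_conformers: int


@dataclass
class EvalReport:
    cutoff_percent: float
    n_selected: int
    TP: int
    FP: int
    precision: float
    enrichment_factor: float
    baseline_precision: float


def cha_score(matrix: np.ndarray) -> float:
    """Percentage of models (rows) with at least one matching conformer."""
    matrix = np.asarray(matrix, dtype=bool)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("match matrix must have at least one model row")
    return 100.0 * float(matrix.any(axis=1).sum()) / matrix.shape[0]


def cca_score(matrix: np.ndarray) -> float:
    """Percentage of conformers (columns) matching at least one model."""
    matrix = np.asarray(matrix, dtype=bool)
    if matrix.ndim != 2 or matrix.shape[1] == 0:
        raise ValueError("match matrix must have at least one conformer column")
    return 100.0 * float(matrix.any(axis=0).sum()) / matrix.shape[1]


def score_compound(compound_id: str, matrix: np.ndarray) -> ScreenResult:
    matrix = np.asarray(matrix, dtype=bool)
    return ScreenResult(
        compound_id,
        cha_score(matrix),
        cca_score(matrix),
        int(matrix.any(axis=1).sum()),
        int(matrix.any(axis=0).sum()),
        matrix.shape[0],
        matrix.shape[1],
    )


def score_matrices(matrices) -> pd.DataFrame:
    """CHA/CCA table for a dict of per-compound match matrices."""
    rows = []
    for cid, mm in matrices.items():
        r = score_compound(cid, mm.matrix)
        rows.append((cid, r.cha_score, r.cca_score, mm.is_active))
    return pd.DataFrame(rows, columns=["compound_id", "cha", "cca", "is_active"])


def consensus_score(per_complex_scores: dict[str, list[float]]) -> dict[str, float]:
    """Arithmetic mean CCA score per compound across complex ensembles.

    Every compound must be scored against every complex; a missing score is
    entered as 0 upstream (consistent with "not retrieved").
    """
    if not per_complex_scores:
        raise ValueError("no compounds to average")
    lengths = {len(v) for v in per_complex_scores.values()}
    if lengths == {0}:
        raise ValueError("empty complex list")
    return {cid: float(np.mean(scores)) for cid, scores in per_complex_scores.items()}


def select_top(scored, percent: float, n_total: int) -> list:
    """Tie-aware top-p% selection.

    ``scored`` is an iterable of (compound_id, score, is_active).  The target
    count is k = round(p/100 * n_total) (half-up); selection is the k
    best-scoring compounds extended by all compounds whose score ties the
    k-th.  Zero-score compounds are never retrieved, and if fewer than k
    compounds are retrieved the selection is exactly the retrieved set.
    """
    if percent <= 0 or percent > 100:
        raise ValueError("percent must be in (0, 100]")
    k = int(math.floor(percent / 100.0 * n_total + 0.5))
    retrieved = sorted(
        (t for t in scored if t[1] > 0), key=lambda t: (-t[1], t[0])
    )
    if len(retrieved) <= k:
        return retrieved
    threshold = retrieved[k - 1][1]
    return [t for t in retrieved if t[1] >= threshold]


def baseline_precision(n_active: int, n_decoy: int) -> float:
    """Active fraction of the library: n_active / (n_active + n_decoy)."""
    if n_active < 0 or n_decoy < 0 or n_active + n_decoy == 0:
        raise ValueError("need a non-empty library with non-negative counts")
    return n_active / (n_active + n_decoy)


def precision_ef(selected, baseline: float) -> EvalReport:
    """Precision and enrichment factor of a selected, labelled compound set."""
    if baseline <= 0 or baseline >= 1:
        raise ValueError("baseline precision must be in (0, 1)")
    tp = sum(1 for t in selected if t[2])
    fp = len(selected) - tp
    precision = tp / (tp + fp) if selected else 0.0
    return EvalReport(
        cutoff_percent=float("nan"),
        n_selected=len(selected),
        TP=tp,
        FP=fp,
        precision=precision,
        enrichment_factor=precision / baseline,
        baseline_precision=baseline,
    )


def evaluate(scored, cutoffs=DEFAULT_CUTOFFS) -> pd.DataFrame:
    """Precision/EF table over a cutoff grid.

    ``scored`` is a list of (compound_id, score, is_active) covering the
    whole library; the baseline is computed from these labels.
    """
    scored = list(scored)
    n_total = len(scored)
    n_active = sum(1 for t in scored if t[2])
    base = baseline_precision(n_active, n_total - n_active)
    rows = []
    for p in cutoffs:
        sel = select_top(scored, p, n_total)
        rep = precision_ef(sel, base)
        rows.append(
            (p, rep.n_selected, rep.TP, rep.FP, rep.precision, rep.enrichment_factor, base)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cutoff_percent", "n_selected", "TP", "FP",
            "precision", "enrichment_factor", "baseline_precision",
        ],
    )


def complexity_filter(representatives: list[Pharmacophore], min_features: int) -> list[Pharmacophore]:
    """Keep models with at least ``min_features`` features."""
    if min_features < 1:
        raise ValueError("min_features must be >= 1")
    return [m for m in representatives if len(m) >= min_features]
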