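"""Evaluation metrics for trajectory alignments.

* normalized alignment distance — cluster-matching quality of an aligned
  tree: ``d_norm = alpha * d_M/(M+1) + (1-alpha) * d_U/(U+1)`` where d_M/d_U
  are the matched/gap parts of the alignment distance and M/U the matched/
  unmatched pair counts. Lower is better.
* average trajectory conservation (ATC) — cell-level pseudotime fidelity:
  per lineage, Spearman's rho between ground-truth simulation time and
  predicted pseudotime, scaled to [0, 1] by (rho+1)/2 and averaged (over the
  two datasets of a pairwise alignment, then over lineages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .tree_align import AlignedTree


@dataclass
class NormalizedDistanceParams:
    alpha: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LineageConservation:
    lineage: str
    rho_1: float
    rho_2: float | None
    score: float


def normalized_distance(at: AlignedTree, params: NormalizedDistanceParams | None = None) -> float:
    """Eq-style normalized alignment distance of an aligned tree."""
    p = params or NormalizedDistanceParams()
    M, U = at.matched_pairs, at.unmatched_pairs
    return p.alpha * at.d_matched / (M + 1) + (1 - p.alpha) * at.d_unmatched / (U + 1)


def _scaled_rho(reference: np.ndarray, prediction: np.ndarray) -> float:
    reference = np.asarray(reference, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if reference.shape != prediction.shape or reference.size < 2:
        raise ValueError("series must share a length >= 2")
    if np.all(reference == reference[0]):
        raise ValueError("constant reference (simulation time) series")
    if np.all(prediction == prediction[0]):
        warnings.warn(
            "constant pseudotime series; treating undefined Spearman rho as 0",
            stacklevel=3,
        )
        return 0.5
    rho = spearmanr(reference, prediction).statistic
    return (float(rho) + 1.0) / 2.0


def atc_score(lineages) -> float:
    """Average trajectory conservation over lineages.

    ``lineages`` is a list; each lineage is a list of one or two
    ``(sim_time, pseudotime)`` series pairs (two for a pairwise alignment —
    one per dataset — whose scaled correlations are averaged first).
    """
    if not lineages:
        raise ValueError("no lineages")
    scores = []
    for lin in lineages:
        pairs = list(lin)
        if not 1 <= len(pairs) <= 2:
            raise ValueError("each lineage carries one or two (reference, prediction) pairs")
        scores.append(float(np.mean([_scaled_rho(r, p) for r, p in pairs])))
    return float(np.mean(scores))


def lineage_conservation(lineage_id: str, pairs) -> LineageConservation:
    """Per-lineage detail record (scaled Spearman per dataset + mean score)."""
    rhos = [2 * _scaled_rho(r, p) - 1 for r, p in pairs]
    score = float(np.mean([(r + 1) / 2 for r in rhos]))
    return LineageConservation(
        lineage=lineage_id,
        rho_1=rhos[0],
        rho_2=rhos[1] if len(rhos) > 1 else None,
        score=score,
    )
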