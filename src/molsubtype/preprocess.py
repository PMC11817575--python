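"""High-variance feature selection by median absolute deviation (MAD).

Clustering is run on the most variable features only: the top 10% of genes
and the top 30% of pathways by default. MAD is unscaled (no 1.4826
normal-consistency factor) — the constant cannot change the ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .io_formats import ExpressionMatrix, PathwayScoreMatrix

__all__ = ["mad", "mad_select", "FeatureSelection",
           "GENE_MAD_FRACTION", "PATHWAY_MAD_FRACTION"]

logger = logging.getLogger(__name__)

#: Default fraction of genes retained for the gene-wise clustering arm.
GENE_MAD_FRACTION = 0.10
#: Default fraction of pathways retained for the pathway-wise clustering arm.
PATHWAY_MAD_FRACTION = 0.30


@dataclass
class FeatureSelection:
    """Result of MAD-based feature filtering.

    ``selected_ids`` is ordered by MAD descending (ties broken by feature id,
    lexicographic) so that selection at a smaller fraction is always a prefix.
    """

    fraction: float
    selected_ids: list[str]
    mad_values: dict[str, float]


def mad(values) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("mad requires a non-empty 1-D vector")
    if not np.isfinite(x).all():
        raise ValueError("mad input contains non-finite values")
    return float(np.median(np.abs(x - np.median(x))))


def mad_select(matrix: ExpressionMatrix | PathwayScoreMatrix,
               fraction: float) -> FeatureSelection:
    """Retain the ``ceil(fraction * n_features)`` features with largest MAD.

    Ranking is (MAD descending, feature id ascending); the lexicographic
    tie-break makes the selection deterministic and prefix-monotone in the
    fraction.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if isinstance(matrix, ExpressionMatrix):
        ids, values = matrix.gene_ids, matrix.values
    else:
        ids, values = matrix.set_names, matrix.scores
    if len(ids) == 0:
        raise ValueError("matrix has no features")
    med = np.median(values, axis=1, keepdims=True)
    mads = np.median(np.abs(values - med), axis=1)
    order = sorted(range(len(ids)), key=lambda i: (-mads[i], ids[i]))
    n_keep = min(math.ceil(fraction * len(ids)), len(ids))
    selected = [ids[i] for i in order[:n_keep]]
    n_zero = int(np.sum(mads[order[:n_keep]] == 0))
    if n_zero:
        logger.warning("%d selected features have MAD = 0 (uninformative for NMF)", n_zero)
    return FeatureSelection(fraction=fraction, selected_ids=selected,
                            mad_values={ids[i]: float(mads[i]) for i in range(len(ids))})
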