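"""Single-sample gene-set variation scoring (GSVA-family).

Converts a gene x sample expression matrix into a pathway x sample activity
matrix in two steps:

1. A Gaussian-kernel CDF transform per gene: the expression of sample j on
   gene g becomes z_gj = (1/n) sum_k Phi((e_gj - e_gk) / h_g) with bandwidth
   h_g = sd(e_g) / 4 — a smoothed within-gene empirical CDF in (0, 1).
2. A weighted Kolmogorov-Smirnov random walk per (sample, gene set): genes
   are ranked by the transformed statistic (descending), the walk steps up
   by |stat|^tau (normalized over set members) at member genes and down by
   1/(N - |S|) elsewhere. ``classic`` mode returns the signed
   maximum-magnitude deviation; ``diff`` mode (default) returns
   max(0, max walk) + min(0, min walk).

This is one explicit, deterministic member of the GSVA family; the kernel,
bandwidth, tau and mode are pinned here and exposed as parameters.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.special import ndtr

from .io_formats import ExpressionMatrix, GeneSetCollection, PathwayScoreMatrix

__all__ = ["kernel_cdf_transform", "enrichment_score", "ssgsva_matrix",
           "normalize_scores"]

logger = logging.getLogger(__name__)


def kernel_cdf_transform(matrix: ExpressionMatrix, chunk: int = 256):
    """Gaussian-kernel cumulative-density transform, per gene across samples.

    Returns ``(Z, kept_gene_ids)`` where Z is genes x samples with entries in
    (0, 1). Genes with zero variance across samples carry no ordering
    information and are excluded with a logged warning.

    Bandwidth is h_g = sd(e_g)/4 (sample standard deviation, ddof=1).
    """
    if matrix.n_samples < 2:
        raise ValueError("kernel CDF transform needs >= 2 samples")
    values = matrix.values
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("excluding %d zero-variance genes from the CDF transform", n_dropped)
    values = values[keep]
    sd = sd[keep]
    if values.shape[0] == 0:
        raise ValueError("all genes have zero variance")
    h = sd / 4.0
    n = matrix.n_samples
    Z = np.empty_like(values)
    for start in range(0, values.shape[0], chunk):
        block = values[start:start + chunk]
        hb = h[start:start + chunk, None, None]
        diffs = (block[:, :, None] - block[:, None, :]) / hb
        Z[start:start + chunk] = ndtr(diffs).mean(axis=2)
    kept_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return Z, kept_ids


def _rank_order(stat: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    # descending by stat, ties broken by gene id (lexicographic, ascending)
    return np.lexsort((np.asarray(gene_ids), -np.asarray(stat, dtype=float)))


def enrichment_score(stat, gene_ids: list[str], gene_set, tau: float = 1.0,
                     mode: str = "diff") -> float:
    """Weighted KS enrichment score of one gene set in one sample.

    ``stat`` is the per-gene statistic for the sample (aligned with
    ``gene_ids``); the result lies in [-1, 1].
    """
    stat = np.asarray(stat, dtype=float)
    if mode not in ("classic", "diff"):
        raise ValueError(f"unknown mode {mode!r}")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if len(gene_ids) != stat.size:
        raise ValueError("stat and gene_ids lengths differ")
    members = np.array([g in gene_set for g in gene_ids])
    n_hit = int(members.sum())
    N = stat.size
    if n_hit == 0:
        raise ValueError("gene set has no measured genes")
    if n_hit == N:
        raise ValueError("gene set covers every measured gene; complement empty")
    order = _rank_order(stat, gene_ids)
    m = members[order]
    w = np.abs(stat[order]) ** tau
    hit_w = np.where(m, w, 0.0)
    tot = hit_w.sum()
    if tot == 0:  # all member stats are zero: fall back to unweighted steps
        hit_w = m / n_hit
    else:
        hit_w = hit_w / tot
    steps = hit_w - (~m) / (N - n_hit)
    walk = np.cumsum(steps)
    if mode == "classic":
        return float(walk[np.argmax(np.abs(walk))])
    return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))


def ssgsva_matrix(matrix: ExpressionMatrix, collection: GeneSetCollection,
                  tau: float = 1.0, mode: str = "diff", min_set_size: int = 5,
                  max_set_size: int = 500) -> PathwayScoreMatrix:
    """Score every retained gene set in every sample.

    Sets are intersected with the measured genes and filtered to the size
    band [min_set_size, max_set_size] (MSigDB-style defaults 5..500); sets
    covering every measured gene are unusable and dropped too.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    Z, kept_ids = kernel_cdf_transform(matrix)
    universe = set(kept_ids)
    retained = collection.restricted(universe, min_size=min_set_size,
                                     max_size=max_set_size)
    dropped = set(collection.names()) - set(retained.names())
    full = [name for name in retained.names() if len(retained.members(name)) == len(universe)]
    for name in full:
        dropped.add(name)
    if dropped:
        logger.warning("dropping %d gene sets outside size band %d..%d after "
                       "intersection with %d measured genes",
                       len(dropped), min_set_size, max_set_size, len(universe))
    names = [n for n in retained.names() if n not in full]
    if not names:
        raise ValueError("no gene set survives the size filter")

    gene_pos = {g: i for i, g in enumerate(kept_ids)}
    M = np.zeros((len(names), len(kept_ids)), dtype=bool)
    for si, name in enumerate(names):
        for g in retained.members(name):
            M[si, gene_pos[g]] = True
    sizes = M.sum(axis=1)
    N = len(kept_ids)
    ids_arr = np.asarray(kept_ids)

    scores = np.empty((len(names), matrix.n_samples))
    for j in range(matrix.n_samples):
        stat = Z[:, j]
        order = np.lexsort((ids_arr, -stat))
        m = M[:, order]
        w = np.abs(stat[order]) ** tau
        hit_w = m * w
        tot = hit_w.sum(axis=1)
        safe = np.where(tot > 0, tot, 1.0)
        hit_w = np.where(tot[:, None] > 0, hit_w / safe[:, None], m / sizes[:, None])
        steps = hit_w - (~m) / (N - sizes)[:, None]
        walk = np.cumsum(steps, axis=1)
        if mode == "classic":
            idx = np.argmax(np.abs(walk), axis=1)
            scores[:, j] = walk[np.arange(len(names)), idx]
        else:
            scores[:, j] = np.maximum(walk.max(axis=1), 0.0) + np.minimum(walk.min(axis=1), 0.0)
    return PathwayScoreMatrix(names, list(matrix.sample_ids), scores)


def normalize_scores(scores: PathwayScoreMatrix) -> PathwayScoreMatrix:
    """Z-score each gene set across samples (mean 0, sd 1, ddof=1).

    Constant rows have no z-score and are dropped with a warning. The
    operation is idempotent. Required before cross-cohort classification so
    scores are comparable between cohorts.
    """
    if scores.n_samples < 2:
        raise ValueError("normalization needs >= 2 samples")
    sd = scores.scores.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant score rows during normalization",
                       int((~keep).sum()))
    vals = scores.scores[keep]
    sd = sd[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    names = [n for n, k in zip(scores.set_names, keep) if k]
    if not names:
        raise ValueError("all score rows are constant; nothing to normalize")
    return PathwayScoreMatrix(names, list(scores.sample_ids), z, normalized=True)
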