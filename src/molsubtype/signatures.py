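"""Cluster-specific signature extraction and over-representation analysis.

A feature (gene or pathway) belongs to a cluster's *up* signature when

1. it is significantly higher in that cluster than in all remaining samples
   pooled (*collective* gate: two-sample t-test, one-sided BH-FDR < q*);
2. its cluster mean exceeds its mean in every other cluster, and the
   one-sided t-test against each other cluster is nominally significant
   (*individual* gate, default alpha 0.05).

The down signature is symmetric. The individual gate matters because a
feature shifted down in some *other* cluster is higher than the pooled rest
without being specific to this one; per-cluster tests remove such
cross-contamination. The collective test uses the pooled-variance Student t
by default (``equal_var=False`` switches to Welch); the individual gate can
be disabled (``pairwise_alpha=None``) or tightened.

Signatures are annotated by hypergeometric over-representation against a
pathway collection, with the measured genes (not the whole genome) as the
universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection, PathwayScoreMatrix
from .targets import enrichment_factor

__all__ = [
    "ClusterSignature",
    "EnrichmentResult",
    "welch_t",
    "bh_fdr",
    "extract_signatures",
    "hypergeom_p",
    "enrich_signature",
    "celltype_profile",
    "signatures_to_frame",
    "frame_to_signatures",
    "enrichments_to_frame",
    "DEFAULT_Q",
]

logger = logging.getLogger(__name__)

#: Default FDR threshold for signature membership.
DEFAULT_Q = 0.01


@dataclass
class ClusterSignature:
    """Up- or down-signature of one cluster.

    ``features`` holds (feature id, Welch t, raw one-sided p, BH q) for every
    feature passing both the FDR gate and the per-cluster mean-ordering gate.
    """

    cluster: int | str
    direction: str  # "up" | "down"
    features: list[tuple[str, float, float, float]]
    q_threshold: float = DEFAULT_Q

    @property
    def feature_ids(self) -> list[str]:
        return [f[0] for f in self.features]

    def __len__(self) -> int:
        return len(self.features)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    signature_size: int
    set_size: int
    universe_size: int
    ef: float
    p: float
    q: float


def welch_t(x, y) -> tuple[float, float]:
    """Unequal-variance t statistic (x minus y) and two-sided p.

    Both groups need >= 2 observations. If both groups have zero variance
    and equal means the test is vacuous and (0, 1) is returned by
    convention; zero variance with different means gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _vector_t(x: np.ndarray, y: np.ndarray,
              equal_var: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t (x minus y) and two-sided p for feature matrices."""
    t, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # degenerate rows: both groups constant
    both_const = (x.var(axis=1, ddof=1) == 0) & (y.var(axis=1, ddof=1) == 0)
    if both_const.any():
        dm = x.mean(axis=1) - y.mean(axis=1)
        eq = both_const & (dm == 0)
        ne = both_const & (dm != 0)
        t[eq], p[eq] = 0.0, 1.0
        t[ne] = np.where(dm[ne] > 0, np.inf, -np.inf)
        p[ne] = 0.0
    return t, p


def extract_signatures(matrix: ExpressionMatrix | PathwayScoreMatrix,
                       labels, q_threshold: float = DEFAULT_Q,
                       pairwise_alpha: float | None = 0.05,
                       equal_var: bool = True) -> list[ClusterSignature]:
    """Per-cluster up/down signatures at FDR < ``q_threshold``.

    ``labels`` is one cluster label per sample, in sample order. BH
    correction is applied across all features within each (cluster,
    direction) family, on one-sided p-values from the cluster-vs-rest test;
    features additionally need the correct mean ordering against every other
    cluster and, if ``pairwise_alpha`` is set, a nominally significant
    one-sided per-cluster test.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    if isinstance(matrix, ExpressionMatrix):
        ids, values = matrix.gene_ids, matrix.values
    else:
        ids, values = matrix.set_names, matrix.scores
    labels = np.asarray(labels)
    if labels.size != values.shape[1]:
        raise ValueError("labels length does not match sample count")
    clusters = sorted(set(labels.tolist()))
    counts = {c: int((labels == c).sum()) for c in clusters}
    small = [c for c in clusters if counts[c] < 2]
    if small:
        raise ValueError(f"cluster(s) {small} have < 2 samples; cannot test")

    means = {c: values[:, labels == c].mean(axis=1) for c in clusters}
    out: list[ClusterSignature] = []
    for c in clusters:
        in_c = labels == c
        x = values[:, in_c]
        y = values[:, ~in_c]
        t, p2 = _vector_t(x, y, equal_var)
        with np.errstate(invalid="ignore"):
            p_up = np.where(t > 0, p2 / 2.0, 1.0 - p2 / 2.0)
        p_down = 1.0 - p_up

        others = [o for o in clusters if o != c]
        above_all = np.logical_and.reduce([means[c] > means[o] for o in others])
        below_all = np.logical_and.reduce([means[c] < means[o] for o in others])
        if pairwise_alpha is not None:
            for o in others:
                to, po = _vector_t(x, values[:, labels == o], equal_var)
                with np.errstate(invalid="ignore"):
                    p_o_up = np.where(to > 0, po / 2.0, 1.0 - po / 2.0)
                above_all &= p_o_up < pairwise_alpha
                below_all &= (1.0 - p_o_up) < pairwise_alpha

        for direction, p_one, gate in (("up", p_up, above_all),
                                       ("down", p_down, below_all)):
            q = bh_fdr(p_one)
            hit = (q < q_threshold) & gate
            feats = [(ids[i], float(t[i]), float(p_one[i]), float(q[i]))
                     for i in np.flatnonzero(hit)]
            feats.sort(key=lambda f: (f[3], f[2], f[0]))
            out.append(ClusterSignature(cluster=c, direction=direction,
                                        features=feats, q_threshold=q_threshold))
    return out


def hypergeom_p(overlap: int, signature_size: int, set_size: int,
                universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts members of a ``set_size`` set among ``signature_size`` draws
    without replacement from a universe of ``universe`` genes.
    """
    if min(overlap, signature_size, set_size, universe) < 0 or universe == 0:
        raise ValueError("counts must be non-negative with a positive universe")
    if overlap > min(signature_size, set_size) or max(signature_size, set_size) > universe:
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, signature={signature_size}, "
            f"set={set_size}, universe={universe}")
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, signature_size))


def enrich_signature(signature: ClusterSignature, collection: GeneSetCollection,
                     universe: set[str], q_threshold: float = DEFAULT_Q,
                     ) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a signature in each gene set.

    The universe is the measured genes; sets are intersected with it first.
    Results cover every retained set (callers filter on q), sorted by q
    ascending then enrichment factor descending.
    """
    genes = set(signature.feature_ids) & universe
    if not genes:
        logger.warning("signature for cluster %s (%s) is empty after universe "
                       "intersection; no enrichment computed",
                       signature.cluster, signature.direction)
        return []
    n_total = len(universe)
    n_a = len(genes)
    rows: list[EnrichmentResult] = []
    for name, (_, members) in collection.items():
        hit = members & universe
        if not hit:
            continue
        n_b = len(hit)
        k = len(genes & hit)
        rows.append(EnrichmentResult(
            set_name=name, overlap=k, signature_size=n_a, set_size=n_b,
            universe_size=n_total,
            ef=enrichment_factor(k, n_a, n_b, n_total),
            p=hypergeom_p(k, n_a, n_b, n_total), q=np.nan))
    if not rows:
        return []
    q = bh_fdr([r.p for r in rows])
    for r, qi in zip(rows, q):
        r.q = float(qi)
    rows.sort(key=lambda r: (r.q, -r.ef, r.set_name))
    return rows


def celltype_profile(matrix: ExpressionMatrix, labels,
                     marker_collection: GeneSetCollection,
                     pathway_collection: GeneSetCollection,
                     q_threshold: float = DEFAULT_Q, min_markers: int = 5,
                     ) -> dict[str, dict]:
    """Cluster signatures restricted to each cell-type marker set.

    For every marker set (e.g. liver cell types): restrict the expression
    matrix to its measured genes, extract cluster up/down signatures on the
    restriction, then annotate those signatures against the pathway
    collection with the restricted genes as universe. Marker sets with fewer
    than ``min_markers`` measured genes are dropped with a warning.
    """
    measured = set(matrix.gene_ids)
    out: dict[str, dict] = {}
    for celltype, (_, markers) in marker_collection.items():
        genes = sorted(markers & measured)
        if len(genes) < min_markers:
            logger.warning("cell type %s: only %d measured marker genes (< %d); dropped",
                           celltype, len(genes), min_markers)
            continue
        sub = matrix.subset_genes(genes)
        sigs = extract_signatures(sub, labels, q_threshold=q_threshold)
        enr = {(s.cluster, s.direction):
               enrich_signature(s, pathway_collection, set(genes), q_threshold)
               for s in sigs}
        out[celltype] = {"signatures": sigs, "enrichments": enr}
    return out


def signatures_to_frame(signatures: list[ClusterSignature]) -> pd.DataFrame:
    rows = [(s.cluster, s.direction, fid, t, p, q)
            for s in signatures for (fid, t, p, q) in s.features]
    return pd.DataFrame(rows, columns=["cluster", "direction", "feature_id",
                                       "t_stat", "p_value", "q_value"])


def frame_to_signatures(frame: pd.DataFrame,
                        q_threshold: float = DEFAULT_Q) -> list[ClusterSignature]:
    out = []
    for (cluster, direction), grp in frame.groupby(["cluster", "direction"], sort=True):
        feats = [(str(r.feature_id), float(r.t_stat), float(r.p_value), float(r.q_value))
                 for r in grp.itertuples()]
        out.append(ClusterSignature(cluster=cluster, direction=str(direction),
                                    features=feats, q_threshold=q_threshold))
    return out


def enrichments_to_frame(enrichments: dict[tuple, list[EnrichmentResult]]) -> pd.DataFrame:
    rows = [(c, d, r.set_name, r.overlap, r.signature_size, r.set_size,
             r.universe_size, r.ef, r.p, r.q)
            for (c, d), results in enrichments.items() for r in results]
    return pd.DataFrame(rows, columns=["cluster", "direction", "set_name", "overlap",
                                       "signature_size", "set_size", "universe_size",
                                       "ef", "p_value", "q_value"])
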