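"""External-cohort classification and clustering-agreement statistics.

An external cohort never goes through NMF again: its samples are scored
with the single-sample pathway scorer, the scores are z-normalized across
the cohort, and each sample is assigned to the derived cluster whose
signature it matches best. The default rule scores cluster c as
mean(z over c's up pathways) - mean(z over c's down pathways); a
nearest-centroid rule (Pearson correlation to the per-cluster mean
normalized score profile) is available as ``rule="centroid"``.

Agreement between two clusterings of the same samples is the fraction of
samples matched under the best injective mapping between the two label
alphabets (optimal assignment on the contingency table).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .io_formats import PathwayScoreMatrix
from .signatures import ClusterSignature

__all__ = ["ClassifierModel", "AgreementReport", "fit_classifier",
           "classify_samples", "cluster_agreement", "adjusted_rand"]


@dataclass
class ClassifierModel:
    clusters: list  # ordered cluster labels; tie-break follows this order
    up_sets: dict   # cluster -> list of up pathway names
    down_sets: dict  # cluster -> list of down pathway names
    rule: str = "signature"
    centroids: dict = field(default_factory=dict)  # cluster -> {pathway: mean z}


@dataclass
class AgreementReport:
    n_samples: int
    n_matched: int
    rate: float
    mapping: dict  # label in a -> label in b (injective; unmatched labels absent)


def fit_classifier(signatures: list[ClusterSignature], rule: str = "signature",
                   scores: PathwayScoreMatrix | None = None,
                   labels=None) -> ClassifierModel:
    """Build a cluster classifier from pathway-level signatures.

    Every cluster must contribute at least one up or down pathway. For the
    centroid rule, the training score matrix (normalized) and its labels
    must be supplied so per-cluster mean profiles can be stored.
    """
    if rule not in ("signature", "centroid"):
        raise ValueError(f"unknown rule {rule!r}")
    clusters: list = []
    up_sets: dict = {}
    down_sets: dict = {}
    for sig in signatures:
        if sig.cluster not in clusters:
            clusters.append(sig.cluster)
        d = up_sets if sig.direction == "up" else down_sets
        d[sig.cluster] = list(sig.feature_ids)
    empty = [c for c in clusters if not up_sets.get(c) and not down_sets.get(c)]
    if empty or not clusters:
        raise ValueError(f"cluster(s) {empty or '<none>'} have no signature pathways; "
                         "cannot build a score rule")
    centroids: dict = {}
    if rule == "centroid":
        if scores is None or labels is None:
            raise ValueError("centroid rule needs training scores and labels")
        labels = np.asarray(labels)
        for c in clusters:
            prof = scores.scores[:, labels == c].mean(axis=1)
            centroids[c] = dict(zip(scores.set_names, prof))
    return ClassifierModel(clusters=clusters, up_sets=up_sets,
                           down_sets=down_sets, rule=rule, centroids=centroids)


def classify_samples(scores: PathwayScoreMatrix, model: ClassifierModel):
    """Assign each sample to the best-matching cluster.

    ``scores`` must already be normalized (z-scores across the cohort).
    Returns (labels array, per-sample per-cluster score matrix as a dict
    cluster -> vector). Signature pathways missing from the score matrix
    are dropped; a cluster losing all its pathways is an error.
    """
    if not scores.normalized:
        raise ValueError("scores must be normalized (normalize_scores) before classification")
    pos = {name: i for i, name in enumerate(scores.set_names)}
    per_cluster: dict = {}
    for c in model.clusters:
        if model.rule == "centroid":
            common = [p for p in model.centroids[c] if p in pos]
            if not common:
                raise ValueError(f"cluster {c!r}: no centroid pathway present in scores")
            ref = np.array([model.centroids[c][p] for p in common])
            block = scores.scores[[pos[p] for p in common]]
            ref_c = ref - ref.mean()
            blk_c = block - block.mean(axis=0, keepdims=True)
            denom = np.linalg.norm(ref_c) * np.linalg.norm(blk_c, axis=0)
            denom = np.where(denom == 0, 1.0, denom)
            per_cluster[c] = (ref_c @ blk_c) / denom
            continue
        up = [p for p in model.up_sets.get(c, []) if p in pos]
        down = [p for p in model.down_sets.get(c, []) if p in pos]
        if not up and not down:
            raise ValueError(f"cluster {c!r}: no signature pathway present in the score matrix")
        up_term = scores.scores[[pos[p] for p in up]].mean(axis=0) if up else 0.0
        down_term = scores.scores[[pos[p] for p in down]].mean(axis=0) if down else 0.0
        per_cluster[c] = np.asarray(up_term - down_term, dtype=float) * np.ones(scores.n_samples)
    stacked = np.vstack([per_cluster[c] for c in model.clusters])
    # argmax with ties resolved to the first cluster in model order
    idx = stacked.argmax(axis=0)
    labels = np.array([model.clusters[i] for i in idx])
    return labels, per_cluster


def cluster_agreement(labels_a, labels_b) -> AgreementReport:
    """Best-mapping agreement rate between two labelings of the same samples.

    Maximizes the matched-sample count over injective mappings from the
    smaller label alphabet into the larger (optimal assignment on the
    contingency table); symmetric in its arguments.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.size != b.size:
        raise ValueError("labelings must be non-empty and cover the same samples")
    ua = sorted(set(a.tolist()))
    ub = sorted(set(b.tolist()))
    cont = np.zeros((len(ua), len(ub)), dtype=int)
    ia = {l: i for i, l in enumerate(ua)}
    ib = {l: i for i, l in enumerate(ub)}
    for x, y in zip(a, b):
        cont[ia[x], ib[y]] += 1
    ri, ci = linear_sum_assignment(-cont)
    matched = int(cont[ri, ci].sum())
    mapping = {ua[i]: ub[j] for i, j in zip(ri, ci)}
    return AgreementReport(n_samples=int(a.size), n_matched=matched,
                           rate=matched / a.size, mapping=mapping)


def adjusted_rand(labels_a, labels_b) -> float:
    """Chance-corrected Rand index between two partitions (pair counting)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size:
        raise ValueError("labelings must cover the same samples")
    if a.size < 2:
        raise ValueError("adjusted Rand index needs >= 2 samples")
    return float(adjusted_rand_score(a, b))
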