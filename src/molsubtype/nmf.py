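"""NMF consensus clustering with cophenetic-correlation rank selection.

The factorization V ~ W H (all non-negative) is fitted by multiplicative
updates for the Kullback-Leibler divergence D(V||WH), the classic update
rule of consensus-NMF tooling; a Frobenius objective is available behind
``objective="frobenius"``. Cluster stability at a given rank is measured by
the consensus matrix over seeded random restarts, summarized by the
cophenetic correlation coefficient, and the number of clusters is chosen at
the elbow of the cophenetic curve.

Sample clusters are read from the coefficient matrix H: per restart each
sample goes to its argmax component, and the final hard labels come from
average-linkage hierarchical clustering of the consensus matrix, which is
more stable than any single run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "NMFFactorization",
    "ConsensusResult",
    "RankSelection",
    "shift_nonnegative",
    "nonnegative_representation",
    "nmf_factorize",
    "assign_labels",
    "consensus_cluster",
    "cophenetic_coefficient",
    "choose_elbow",
    "select_rank",
    "DegenerateConsensusError",
]

_EPS = 1e-12  # floor keeping W, H strictly positive


class DegenerateConsensusError(ValueError):
    """The consensus matrix admits no cophenetic correlation (constant distances)."""


@dataclass
class NMFFactorization:
    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    seed: int
    converged: bool
    objective: str = "kl"


@dataclass
class ConsensusResult:
    rank: int
    consensus: np.ndarray
    cophenetic: float
    labels: np.ndarray  # per-sample cluster index in 1..rank
    n_restarts: int


@dataclass
class RankSelection:
    ranks: list[int]
    cophenetic_by_rank: dict[int, float]
    chosen_rank: int
    results: dict[int, ConsensusResult] = field(default_factory=dict)


def shift_nonnegative(V: np.ndarray) -> np.ndarray:
    """Make a matrix non-negative by a global shift V - min(V).

    Needed before NMF for inputs that can be negative (z-scored pathway
    scores, log-ratio expression). Matrices already non-negative are
    returned unchanged.
    """
    V = np.asarray(V, dtype=float)
    lo = V.min()
    return V - lo if lo < 0 else V


def nonnegative_representation(values: np.ndarray, method: str = "split") -> np.ndarray:
    """Non-negative NMF input from a (possibly signed) feature matrix.

    ``"split"`` (default): z-score each feature across samples and stack the
    positive and negative parts row-wise (the standard nonnegative double
    split used for NMF on signed/standardized expression). Removing each
    feature's baseline level this way stops large additive offsets from
    dominating the factorization, which otherwise flattens the objective
    across very different sample partitions. Zero-variance features are
    dropped. ``"shift"``: global shift by the matrix minimum, features kept
    on their original scale.
    """
    V = np.asarray(values, dtype=float)
    if method == "shift":
        return shift_nonnegative(V)
    if method != "split":
        raise ValueError(f"unknown representation {method!r}")
    sd = V.std(axis=1, ddof=1)
    V = V[sd > 0]
    if V.shape[0] == 0:
        raise ValueError("all features have zero variance")
    Z = (V - V.mean(axis=1, keepdims=True)) / sd[sd > 0][:, None]
    return np.vstack([np.maximum(Z, 0.0), np.maximum(-Z, 0.0)])


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    # D(V||WH) = sum(V log(V/WH) - V + WH); V=0 terms contribute WH only
    pos = V > 0
    out = float(WH.sum() - V.sum())
    out += float(np.sum(V[pos] * np.log(V[pos] / WH[pos])))
    return out


def nmf_factorize(V: np.ndarray, rank: int, seed: int, max_iter: int = 2000,
                  tol: float = 1e-6, objective: str = "kl",
                  check_every: int = 10,
                  label_stall: int | None = None) -> NMFFactorization:
    """Factorize a non-negative matrix by seeded multiplicative updates.

    W and H are initialized i.i.d. uniform(0, 1) scaled by mean(V); the
    objective is evaluated every ``check_every`` iterations and iteration
    stops when its relative change drops below ``tol`` or at ``max_iter``.

    ``label_stall`` enables the classic connectivity-based stopping of
    consensus-NMF tooling: iteration also stops once the argmax sample
    assignment of H has been unchanged for that many iterations. Used by
    :func:`consensus_cluster`, where the assignment — not the residual —
    is the quantity of interest.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if V.min() < 0:
        raise ValueError("V must be non-negative; apply shift_nonnegative first")
    if not (1 <= rank < min(V.shape)):
        raise ValueError(f"rank must be in [1, min(dims)), got {rank} for shape {V.shape}")
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    W = rng.uniform(size=(V.shape[0], rank)) * scale
    H = rng.uniform(size=(rank, V.shape[1])) * scale
    W = np.maximum(W, _EPS)
    H = np.maximum(H, _EPS)

    def obj() -> float:
        WH = W @ H
        if objective == "kl":
            return _kl_divergence(V, np.maximum(WH, _EPS))
        return 0.5 * float(np.sum((V - WH) ** 2))

    trace = [obj()]
    converged = False
    prev_lab: np.ndarray | None = None
    stable = 0
    for it in range(1, max_iter + 1):
        if objective == "kl":
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            H = np.maximum(H, _EPS)
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
            W = np.maximum(W, _EPS)
        else:
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
            H = np.maximum(H, _EPS)
            W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
            W = np.maximum(W, _EPS)
        if it % check_every == 0 or it == max_iter:
            cur = obj()
            prev = trace[-1]
            trace.append(cur)
            if prev - cur < tol * max(abs(prev), _EPS):
                converged = True
                break
            if label_stall is not None:
                lab = H.argmax(axis=0)
                if prev_lab is not None and np.array_equal(lab, prev_lab):
                    stable += check_every
                    if stable >= label_stall:
                        converged = True
                        break
                else:
                    stable = 0
                prev_lab = lab
    return NMFFactorization(W=W, H=H, objective_trace=trace, seed=seed,
                            converged=converged, objective=objective)


def assign_labels(H: np.ndarray) -> np.ndarray:
    """Hard labels from the coefficient matrix: argmax component per sample.

    Ties go to the lowest component index; labels are 1-based.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be rank x samples")
    if (H.max(axis=0) <= 0).any():
        bad = int(np.argmax(H.max(axis=0) <= 0))
        raise ValueError(f"sample column {bad} of H is all zero; no assignable component")
    return H.argmax(axis=0) + 1


def _consensus_linkage(consensus: np.ndarray):
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return average(np.maximum(condensed, 0.0)), condensed


def consensus_cluster(V: np.ndarray, rank: int, n_restarts: int = 30,
                      base_seed: int = 0, max_iter: int = 2000,
                      tol: float = 1e-6, objective: str = "kl",
                      label_stall: int | None = 40) -> ConsensusResult:
    """Consensus matrix over seeded restarts, with hard labels.

    Restart r uses seed ``base_seed + r``. The consensus entry (i, j) is the
    fraction of restarts co-assigning samples i and j; final labels cut the
    average-linkage dendrogram of 1 - consensus at ``rank`` clusters.
    Restarts stop once the sample assignment has stalled for ``label_stall``
    iterations (the classic consensus-NMF stopping rule).
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be >= 2 (stability undefined for a single run)")
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    co = np.zeros((n, n))
    for r in range(1, n_restarts + 1):
        fac = nmf_factorize(V, rank, seed=base_seed + r, max_iter=max_iter,
                            tol=tol, objective=objective, label_stall=label_stall)
        lab = assign_labels(fac.H)
        co += (lab[:, None] == lab[None, :]).astype(float)
    consensus = co / n_restarts
    np.fill_diagonal(consensus, 1.0)
    Z, _ = _consensus_linkage(consensus)
    labels = fcluster(Z, t=rank, criterion="maxclust")
    try:
        coph = cophenetic_coefficient(consensus)
    except DegenerateConsensusError:
        coph = float("nan")
    return ConsensusResult(rank=rank, consensus=consensus, cophenetic=coph,
                           labels=np.asarray(labels), n_restarts=n_restarts)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Correlation between consensus distances and their dendrogram distances.

    Builds the average-linkage dendrogram on 1 - consensus and returns the
    Pearson correlation between the off-diagonal consensus distances and the
    cophenetic distances of that dendrogram; near 1 means the consensus
    matrix is nearly ultrametric, i.e. clustering is stable.
    """
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    if consensus.ndim != 2 or consensus.shape[1] != n:
        raise ValueError("consensus must be square")
    if n < 3:
        raise ValueError("cophenetic coefficient needs >= 3 samples")
    Z, condensed = _consensus_linkage(consensus)
    coph_d = cophenet(Z)
    if np.std(condensed) == 0 or np.std(coph_d) == 0:
        raise DegenerateConsensusError(
            "off-diagonal consensus distances are constant; correlation undefined")
    return float(np.corrcoef(condensed, coph_d)[0, 1])


def choose_elbow(cophenetic_by_rank: dict[int, float], min_coph: float = 0.95,
                 min_drop: float = 0.02, tie_tol: float = 5e-4) -> int:
    """Pick the rank at the elbow of the cophenetic curve.

    Two curve regimes occur in practice and the rule handles both:

    1. *Cliff*: the curve decreases and falls off sharply after the true
       rank. Among ranks k (with an evaluated successor) whose cophenetic
       coefficient is at least ``min_coph``, if the largest drop
       cophenetic(k) - cophenetic(k+1) reaches ``min_drop``, that k is the
       elbow (ties to the smallest k).
    2. *Peak*: stability is maximal at the true rank and degrades only
       gradually beyond it, so no successor drop is large. The elbow is
       then the rank of maximal consensus: the smallest k whose cophenetic
       coefficient lies within ``tie_tol`` of the curve maximum (near-ties
       resolved by parsimony).

    If no rank passes ``min_coph`` the peak rule is applied to the whole
    curve as a fallback.
    """
    if not cophenetic_by_rank:
        raise ValueError("empty cophenetic map")
    ranks = sorted(cophenetic_by_rank)
    finite = [k for k in ranks if np.isfinite(cophenetic_by_rank[k])] or ranks
    admissible = [k for k in finite if cophenetic_by_rank[k] >= min_coph]

    candidates = [k for k in admissible if k + 1 in cophenetic_by_rank
                  and np.isfinite(cophenetic_by_rank[k + 1])]
    if candidates:
        drops = {k: cophenetic_by_rank[k] - cophenetic_by_rank[k + 1] for k in candidates}
        best = max(drops.values())
        if best >= min_drop:
            return min(k for k in candidates if drops[k] == best)

    pool = admissible or finite
    top = max(cophenetic_by_rank[k] for k in pool)
    return min(k for k in pool if cophenetic_by_rank[k] >= top - tie_tol)


def select_rank(V: np.ndarray, rank_range=range(2, 8), n_restarts: int = 30,
                base_seed: int = 0, min_coph: float = 0.95,
                min_drop: float = 0.02, max_iter: int = 2000, tol: float = 1e-6,
                objective: str = "kl", label_stall: int | None = 40) -> RankSelection:
    """Evaluate cophenetic stability over a rank range and pick the elbow.

    Each rank gets its own seed stream (``base_seed + 1000 * rank``) so the
    whole sweep is reproducible from one base seed.
    """
    ranks = sorted(set(int(k) for k in rank_range))
    V = np.asarray(V, dtype=float)
    if not ranks:
        raise ValueError("empty rank range")
    if ranks[0] < 2 or ranks[-1] > V.shape[1] - 1:
        raise ValueError(f"rank range {ranks[0]}..{ranks[-1]} outside [2, n_samples-1]")
    results: dict[int, ConsensusResult] = {}
    coph: dict[int, float] = {}
    for k in ranks:
        res = consensus_cluster(V, k, n_restarts=n_restarts,
                                base_seed=base_seed + 1000 * k,
                                max_iter=max_iter, tol=tol, objective=objective,
                                label_stall=label_stall)
        results[k] = res
        coph[k] = res.cophenetic
    chosen = choose_elbow(coph, min_coph=min_coph, min_drop=min_drop)
    return RankSelection(ranks=ranks, cophenetic_by_rank=coph,
                         chosen_rank=chosen, results=results)
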