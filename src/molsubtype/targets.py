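"""Inverse drug-signature matching and enrichment-factor target ranking.

A drug is a candidate for a disease cluster when its induced expression
signature inverts the cluster's signature: its up-regulated genes overlap
the cluster's down genes and vice versa. The reversal score is a symmetric
overlap contrast built on J(A, B) = |A n B| / min(|A|, |B|):

    score = 1/2 [J(dis_up, drug_up) + J(dis_down, drug_down)]
          - 1/2 [J(dis_up, drug_down) + J(dis_down, drug_up)]

so -1 is a perfect inverter and +1 a perfect mimic. The most negative
decile of drugs is selected per cluster, and their consensus targets are
ranked by the enrichment factor

    EF = (N_AnB + 1) / (N_A * N_B / N_total + 1)

where N_A = selected drugs, N_B = library drugs annotated with the target,
N_AnB their overlap, and N_total the annotated library size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_formats import DrugSignature, DrugSignatureLibrary

__all__ = [
    "ReversalScore",
    "TargetRanking",
    "reversal_score",
    "score_library",
    "select_reversing_drugs",
    "enrichment_factor",
    "consensus_targets",
    "DEFAULT_SELECTION_QUANTILE",
]

#: Fraction of the drug library selected as reversers (most negative scores).
DEFAULT_SELECTION_QUANTILE = 0.10


@dataclass
class ReversalScore:
    drug_id: str
    cell_line: str
    score: float
    components: dict[str, float]


@dataclass
class TargetRanking:
    target: str
    n_selected: int        # N_A
    n_annotated: int       # N_B
    n_overlap: int         # N_AnB
    n_total: int
    ef: float
    rank: int


def _j(a: frozenset, b: frozenset) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def reversal_score(disease_up, disease_down, drug: DrugSignature) -> ReversalScore:
    """Overlap-contrast reversal score of one drug signature vs one cluster."""
    disease_up = frozenset(disease_up)
    disease_down = frozenset(disease_down)
    if not disease_up or not disease_down:
        raise ValueError("disease up and down signatures must both be non-empty")
    if disease_up & disease_down:
        raise ValueError("disease up/down signatures overlap")
    comp = {
        "up_up": _j(disease_up, drug.up),
        "down_down": _j(disease_down, drug.down),
        "up_down": _j(disease_up, drug.down),
        "down_up": _j(disease_down, drug.up),
    }
    score = 0.5 * (comp["up_up"] + comp["down_down"]) - 0.5 * (comp["up_down"] + comp["down_up"])
    return ReversalScore(drug_id=drug.drug_id, cell_line=drug.cell_line,
                         score=score, components=comp)


def score_library(disease_up, disease_down,
                  library: DrugSignatureLibrary) -> list[ReversalScore]:
    """Reversal score for every (drug, cell line) entry in the library."""
    return [reversal_score(disease_up, disease_down, e) for e in library.entries]


def select_reversing_drugs(scores: list[ReversalScore],
                           quantile: float = DEFAULT_SELECTION_QUANTILE,
                           ) -> set[str]:
    """Drugs in the most-negative ``quantile`` of reversal scores.

    Per-cell-line entries are scored separately; a drug is selected if any
    of its entries falls in the selected tail (its best/most negative entry
    represents it). The count is ceil(quantile * n_drugs) over unique
    drugs; ties at the boundary go to the lexicographically first drug ids.
    """
    import math

    if not scores:
        raise ValueError("empty score list")
    if not (0 < quantile < 1):
        raise ValueError("quantile must be in (0, 1)")
    best: dict[str, float] = {}
    for s in scores:
        best[s.drug_id] = min(best.get(s.drug_id, float("inf")), s.score)
    n_keep = math.ceil(quantile * len(best))
    ranked = sorted(best, key=lambda d: (best[d], d))
    return set(ranked[:n_keep])


def enrichment_factor(n_overlap: int, n_a: int, n_b: int, n_total: int) -> float:
    """EF = (observed + 1) / (expected + 1) with expected = n_a * n_b / n_total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if min(n_overlap, n_a, n_b) < 0 or n_overlap > min(n_a, n_b) or max(n_a, n_b) > n_total:
        raise ValueError(
            f"inconsistent counts: overlap={n_overlap}, n_a={n_a}, n_b={n_b}, n_total={n_total}")
    return (n_overlap + 1) / (n_a * n_b / n_total + 1)


def consensus_targets(selected: set[str], library: DrugSignatureLibrary,
                      target_map: Mapping[str, frozenset[str]],
                      ) -> list[TargetRanking]:
    """Rank targets of the selected drugs by enrichment factor.

    N_total counts library drugs with at least one target annotation (drugs
    without annotation cannot contribute to observed or expected counts).
    Sorted by EF descending, ties alphabetical by target.
    """
    lib_drugs = set(library.drug_ids())
    missing = set(selected) - lib_drugs
    if missing:
        raise ValueError(f"selected drugs absent from library: {sorted(missing)[:5]}")
    annotated = {d for d in lib_drugs if target_map.get(d)}
    n_total = len(annotated)
    if n_total == 0:
        raise ValueError("no library drug has a target annotation")
    sel_annot = set(selected) & annotated
    n_a = len(sel_annot)
    by_target: dict[str, set[str]] = {}
    for d in annotated:
        for t in target_map[d]:
            by_target.setdefault(t, set()).add(d)
    rows = []
    for t, drugs in by_target.items():
        n_b = len(drugs)
        k = len(drugs & sel_annot)
        rows.append(TargetRanking(target=t, n_selected=n_a, n_annotated=n_b,
                                  n_overlap=k, n_total=n_total,
                                  ef=enrichment_factor(k, n_a, n_b, n_total),
                                  rank=0))
    rows.sort(key=lambda r: (-r.ef, r.target))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def rankings_to_frame(rankings: list[TargetRanking]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.rank, r.target, r.n_overlap, r.n_selected, r.n_annotated, r.n_total, r.ef)
         for r in rankings],
        columns=["rank", "target", "n_overlap", "n_selected", "n_annotated",
                 "n_total", "ef"])


def scores_to_frame(scores: list[ReversalScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.drug_id, s.cell_line, s.score) for s in scores],
        columns=["drug_id", "cell_line", "score"])
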