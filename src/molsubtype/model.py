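"""Two-arm molecular subtyping: model object, fitted results, pipeline runner.

:class:`MolecularSubtypingModel` is constructed from an expression matrix
and a pathway collection and, on :meth:`~MolecularSubtypingModel.fit`, runs
the full derivation analysis:

1. single-sample pathway scoring of every sample (ssGSVA);
2. MAD feature selection — top 10% of genes and top 30% of pathways;
3. NMF consensus clustering of each arm with cophenetic rank selection
   (the two arms are clustered independently and then compared);
4. cluster up/down signature extraction (t-test vs the pooled rest with
   BH-FDR < 0.01, plus per-cluster ordering/significance gates) at gene and
   pathway level;
5. hypergeometric pathway enrichment of the gene signatures;
6. the agreement rate between the gene-wise and pathway-wise partitions.

The returned :class:`SubtypingResults` carries every intermediate product
and exposes external-cohort classification and inverse drug-signature
target inference; :func:`run_pipeline` drives it from a config file and
writes diffable TSV outputs plus a manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (DrugSignatureLibrary, ExpressionMatrix,
                         GeneSetCollection, PathwayScoreMatrix,
                         read_drug_library, read_expression, read_gmt,
                         read_target_map, write_labels, write_scores,
                         write_signatures)
from .gsva import normalize_scores, ssgsva_matrix
from .nmf import (ConsensusResult, RankSelection, consensus_cluster,
                  nonnegative_representation, select_rank)
from .preprocess import GENE_MAD_FRACTION, PATHWAY_MAD_FRACTION, mad_select
from .signatures import (DEFAULT_Q, enrichments_to_frame, enrich_signature,
                         extract_signatures, signatures_to_frame)
from .stratify import (AgreementReport, classify_samples, cluster_agreement,
                       fit_classifier)
from .targets import (DEFAULT_SELECTION_QUANTILE, consensus_targets,
                      rankings_to_frame, score_library, scores_to_frame,
                      select_reversing_drugs)

__all__ = ["MolecularSubtypingModel", "SubtypingResults", "RunConfig",
           "run_pipeline"]

logger = logging.getLogger(__name__)


class MolecularSubtypingModel:
    """Unsupervised molecular-subtyping model for a bulk expression cohort.

    Parameters
    ----------
    expression
        Genes x samples log-scale normalized expression.
    gene_sets
        Pathway collection (GMT semantics) used for single-sample scoring.
    rank_range
        Candidate cluster numbers for cophenetic rank selection; ignored if
        ``fixed_rank`` is given.
    fixed_rank
        Skip rank selection and cluster both arms at this k.
    seed
        Root seed; every restart seed is derived from it.
    """

    def __init__(self, expression: ExpressionMatrix,
                 gene_sets: GeneSetCollection, *,
                 gene_mad_fraction: float = GENE_MAD_FRACTION,
                 pathway_mad_fraction: float = PATHWAY_MAD_FRACTION,
                 rank_range=range(2, 8), fixed_rank: int | None = None,
                 n_restarts: int = 30, min_coph: float = 0.95,
                 tau: float = 1.0, es_mode: str = "diff",
                 min_set_size: int = 5, max_set_size: int = 500,
                 q_threshold: float = DEFAULT_Q, objective: str = "kl",
                 nmf_input: str = "split", max_iter: int = 2000,
                 tol: float = 1e-6, seed: int = 0):
        self.expression = expression
        self.gene_sets = gene_sets
        self.gene_mad_fraction = gene_mad_fraction
        self.pathway_mad_fraction = pathway_mad_fraction
        self.rank_range = list(rank_range)
        self.fixed_rank = fixed_rank
        self.n_restarts = n_restarts
        self.min_coph = min_coph
        self.tau = tau
        self.es_mode = es_mode
        self.min_set_size = min_set_size
        self.max_set_size = max_set_size
        self.q_threshold = q_threshold
        self.objective = objective
        self.nmf_input = nmf_input
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    @classmethod
    def from_files(cls, expression_path, gmt_path, **kwargs) -> "MolecularSubtypingModel":
        return cls(read_expression(expression_path), read_gmt(gmt_path), **kwargs)

    def _cluster_arm(self, values: np.ndarray, base_seed: int,
                     ) -> tuple[RankSelection | None, ConsensusResult]:
        V = nonnegative_representation(values, method=self.nmf_input)
        if self.fixed_rank is not None:
            res = consensus_cluster(V, self.fixed_rank, n_restarts=self.n_restarts,
                                    base_seed=base_seed + 1000 * self.fixed_rank,
                                    max_iter=self.max_iter, tol=self.tol,
                                    objective=self.objective)
            return None, res
        sel = select_rank(V, self.rank_range, n_restarts=self.n_restarts,
                          base_seed=base_seed, min_coph=self.min_coph,
                          max_iter=self.max_iter, tol=self.tol,
                          objective=self.objective)
        return sel, sel.results[sel.chosen_rank]

    def fit(self) -> "SubtypingResults":
        expr = self.expression
        logger.info("scoring %d gene sets on %d samples", len(self.gene_sets),
                    expr.n_samples)
        scores = ssgsva_matrix(expr, self.gene_sets, tau=self.tau,
                               mode=self.es_mode, min_set_size=self.min_set_size,
                               max_set_size=self.max_set_size)
        norm_scores = normalize_scores(scores)

        gene_sel = mad_select(expr, self.gene_mad_fraction)
        pathway_sel = mad_select(scores, self.pathway_mad_fraction)
        logger.info("gene arm: %d features; pathway arm: %d features",
                    len(gene_sel.selected_ids), len(pathway_sel.selected_ids))

        gene_V = expr.subset_genes(gene_sel.selected_ids).values
        set_pos = {n: i for i, n in enumerate(scores.set_names)}
        pathway_V = scores.scores[[set_pos[n] for n in pathway_sel.selected_ids]]

        gene_rank, gene_cons = self._cluster_arm(gene_V, self.seed)
        pathway_rank, pathway_cons = self._cluster_arm(pathway_V, self.seed + 500_000)

        gene_sigs = extract_signatures(expr, gene_cons.labels, self.q_threshold)
        pathway_sigs = extract_signatures(scores, pathway_cons.labels, self.q_threshold)

        universe = set(expr.gene_ids)
        enrichments = {(s.cluster, s.direction):
                       enrich_signature(s, self.gene_sets, universe, self.q_threshold)
                       for s in gene_sigs if len(s)}
        agreement = cluster_agreement(gene_cons.labels, pathway_cons.labels)
        return SubtypingResults(
            model=self, scores=scores, normalized_scores=norm_scores,
            gene_selection=gene_sel, pathway_selection=pathway_sel,
            gene_rank_selection=gene_rank, pathway_rank_selection=pathway_rank,
            gene_consensus=gene_cons, pathway_consensus=pathway_cons,
            gene_signatures=gene_sigs, pathway_signatures=pathway_sigs,
            enrichments=enrichments, arm_agreement=agreement)


@dataclass
class SubtypingResults:
    """Fitted two-arm subtyping results."""

    model: MolecularSubtypingModel
    scores: PathwayScoreMatrix
    normalized_scores: PathwayScoreMatrix
    gene_selection: object
    pathway_selection: object
    gene_rank_selection: RankSelection | None
    pathway_rank_selection: RankSelection | None
    gene_consensus: ConsensusResult
    pathway_consensus: ConsensusResult
    gene_signatures: list
    pathway_signatures: list
    enrichments: dict
    arm_agreement: AgreementReport

    @property
    def gene_labels(self) -> np.ndarray:
        return self.gene_consensus.labels

    @property
    def pathway_labels(self) -> np.ndarray:
        return self.pathway_consensus.labels

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        lines = ["Molecular subtyping results", "=" * 54]
        for arm, sel, cons in (("gene", self.gene_rank_selection, self.gene_consensus),
                               ("pathway", self.pathway_rank_selection, self.pathway_consensus)):
            lines.append(f"{arm}-wise arm: k = {cons.rank}, cophenetic = {cons.cophenetic:.4f}, "
                         f"{cons.n_restarts} restarts")
            if sel is not None:
                curve = ", ".join(f"k={k}: {v:.3f}"
                                  for k, v in sorted(sel.cophenetic_by_rank.items()))
                lines.append(f"  cophenetic by rank: {curve}")
            sizes = pd.Series(cons.labels).value_counts().sort_index()
            lines.append("  cluster sizes: " +
                         ", ".join(f"{c}: {n}" for c, n in sizes.items()))
        n_gene = sum(len(s) for s in self.gene_signatures)
        n_path = sum(len(s) for s in self.pathway_signatures)
        lines.append(f"signature features (q < {self.model.q_threshold}): "
                     f"{n_gene} genes, {n_path} pathways")
        a = self.arm_agreement
        lines.append(f"arm agreement: {a.rate:.1%} ({a.n_matched}/{a.n_samples})")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    # downstream applications

    def build_classifier(self, rule: str = "signature"):
        """Classifier over the pathway-level signatures of the pathway arm."""
        return fit_classifier(self.pathway_signatures, rule=rule,
                              scores=self.normalized_scores,
                              labels=self.pathway_consensus.labels)

    def classify_external(self, expression: ExpressionMatrix,
                          rule: str = "signature"):
        """Score, normalize and classify an external cohort.

        The external cohort is scored with the same gene sets and scorer
        settings, z-normalized across its own samples, and assigned by the
        pathway-signature rule. Returns (labels, per-cluster score dict,
        normalized external scores).
        """
        m = self.model
        ext_scores = ssgsva_matrix(expression, m.gene_sets, tau=m.tau,
                                   mode=m.es_mode, min_set_size=m.min_set_size,
                                   max_set_size=m.max_set_size)
        ext_norm = normalize_scores(ext_scores)
        clf = self.build_classifier(rule=rule)
        labels, per_cluster = classify_samples(ext_norm, clf)
        return labels, per_cluster, ext_norm

    def infer_targets(self, library: DrugSignatureLibrary, target_map,
                      quantile: float = DEFAULT_SELECTION_QUANTILE) -> dict:
        """Inverse-signature drug selection and EF target ranking per cluster.

        Uses each cluster's gene-level up/down signature. Clusters whose up
        or down gene signature is empty are skipped with a warning.
        """
        by_cluster: dict = {}
        sig = {(s.cluster, s.direction): set(s.feature_ids)
               for s in self.gene_signatures}
        clusters = sorted({c for c, _ in sig})
        for c in clusters:
            up = sig.get((c, "up"), set())
            down = sig.get((c, "down"), set())
            if not up or not down:
                logger.warning("cluster %s lacks an up or down gene signature; "
                               "skipping target inference", c)
                continue
            scores = score_library(up, down, library)
            selected = select_reversing_drugs(scores, quantile=quantile)
            rankings = consensus_targets(selected, library, target_map)
            by_cluster[c] = {"scores": scores, "selected": selected,
                             "rankings": rankings}
        return by_cluster

    def plot_cophenetic(self, path) -> None:
        """Elbow plot of cophenetic coefficient vs rank for both arms."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for arm, sel, cons in (("gene-wise", self.gene_rank_selection, self.gene_consensus),
                               ("pathway-wise", self.pathway_rank_selection,
                                self.pathway_consensus)):
            if sel is None:
                continue
            ks = sorted(sel.cophenetic_by_rank)
            ax.plot(ks, [sel.cophenetic_by_rank[k] for k in ks], marker="o", label=arm)
            ax.axvline(sel.chosen_rank, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("cophenetic correlation")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# config-driven pipeline


@dataclass
class RunConfig:
    """End-to-end run configuration (paths + analysis settings)."""

    expression: str
    gene_sets: str
    out_dir: str
    external_expression: str | None = None
    drug_library: str | None = None
    target_map: str | None = None
    celltype_sets: str | None = None
    gene_mad_fraction: float = GENE_MAD_FRACTION
    pathway_mad_fraction: float = PATHWAY_MAD_FRACTION
    rank_min: int = 2
    rank_max: int = 7
    fixed_rank: int | None = None
    n_restarts: int = 30
    min_coph: float = 0.95
    tau: float = 1.0
    es_mode: str = "diff"
    min_set_size: int = 5
    max_set_size: int = 500
    q_threshold: float = DEFAULT_Q
    drug_quantile: float = DEFAULT_SELECTION_QUANTILE
    classifier_rule: str = "signature"
    objective: str = "kl"
    nmf_input: str = "split"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        """Fail fast: every referenced input must exist before any compute."""
        for key in ("expression", "gene_sets", "external_expression",
                    "drug_library", "target_map", "celltype_sets"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config key {key!r}: path {val} does not exist")
        if self.drug_library is not None and self.target_map is None:
            raise ValueError("drug_library given without target_map")
        if self.target_map is not None and self.drug_library is None:
            raise ValueError("target_map given without drug_library")


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and write all outputs under ``config.out_dir``.

    Outputs are deterministic given the config (no timestamps); the manifest
    records the config, its hash, the package version and per-stage sizes.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = read_expression(config.expression)
    gene_sets = read_gmt(config.gene_sets)
    model = MolecularSubtypingModel(
        expr, gene_sets, gene_mad_fraction=config.gene_mad_fraction,
        pathway_mad_fraction=config.pathway_mad_fraction,
        rank_range=range(config.rank_min, config.rank_max + 1),
        fixed_rank=config.fixed_rank, n_restarts=config.n_restarts,
        min_coph=config.min_coph, tau=config.tau, es_mode=config.es_mode,
        min_set_size=config.min_set_size, max_set_size=config.max_set_size,
        q_threshold=config.q_threshold, objective=config.objective,
        nmf_input=config.nmf_input, seed=config.seed)
    res = model.fit()

    sample_ids = expr.sample_ids
    write_labels(dict(zip(sample_ids, map(int, res.gene_labels))),
                 out / "gene_labels.tsv")
    write_labels(dict(zip(sample_ids, map(int, res.pathway_labels))),
                 out / "pathway_labels.tsv")
    write_scores(res.normalized_scores, out / "pathway_scores_normalized.tsv")
    for arm, cons in (("gene", res.gene_consensus), ("pathway", res.pathway_consensus)):
        pd.DataFrame(cons.consensus, index=sample_ids, columns=sample_ids).to_csv(
            out / f"{arm}_consensus.tsv", sep="\t", index_label="sample_id",
            lineterminator="\n")
    coph_rows = []
    for arm, sel in (("gene", res.gene_rank_selection),
                     ("pathway", res.pathway_rank_selection)):
        if sel is not None:
            coph_rows += [(arm, k, sel.cophenetic_by_rank[k],
                           int(k == sel.chosen_rank)) for k in sel.ranks]
    pd.DataFrame(coph_rows, columns=["arm", "rank", "cophenetic", "chosen"]).to_csv(
        out / "cophenetic_by_rank.tsv", sep="\t", index=False, lineterminator="\n")
    write_signatures(signatures_to_frame(res.gene_signatures),
                     out / "gene_signatures.tsv")
    write_signatures(signatures_to_frame(res.pathway_signatures),
                     out / "pathway_signatures.tsv")
    write_signatures(enrichments_to_frame(res.enrichments), out / "enrichment.tsv")
    agreement = {"n_samples": res.arm_agreement.n_samples,
                 "n_matched": res.arm_agreement.n_matched,
                 "rate": res.arm_agreement.rate,
                 "mapping": {str(k): str(v) for k, v in res.arm_agreement.mapping.items()}}
    (out / "agreement.json").write_text(json.dumps(agreement, indent=2) + "\n")

    manifest = {"config": asdict(config), "config_hash": _config_hash(config),
                "version": __version__,
                "stages": {"n_genes": expr.n_genes, "n_samples": expr.n_samples,
                           "n_gene_sets": len(gene_sets),
                           "n_scored_sets": res.scores.n_sets,
                           "gene_arm_features": len(res.gene_selection.selected_ids),
                           "pathway_arm_features": len(res.pathway_selection.selected_ids),
                           "gene_rank": res.gene_consensus.rank,
                           "pathway_rank": res.pathway_consensus.rank}}

    if config.external_expression:
        ext = read_expression(config.external_expression)
        labels, _, _ = res.classify_external(ext, rule=config.classifier_rule)
        write_labels(dict(zip(ext.sample_ids, map(int, labels))),
                     out / "external_labels.tsv")
        manifest["stages"]["n_external_samples"] = ext.n_samples

    if config.drug_library:
        library = read_drug_library(config.drug_library)
        target_map = read_target_map(config.target_map)
        per_cluster = res.infer_targets(library, target_map,
                                        quantile=config.drug_quantile)
        score_frames, rank_frames = [], []
        for c, d in per_cluster.items():
            sf = scores_to_frame(d["scores"])
            sf.insert(0, "cluster", c)
            sf["selected"] = sf["drug_id"].isin(d["selected"]).astype(int)
            score_frames.append(sf)
            rf = rankings_to_frame(d["rankings"])
            rf.insert(0, "cluster", c)
            rank_frames.append(rf)
        write_signatures(pd.concat(score_frames, ignore_index=True),
                         out / "reversal_scores.tsv")
        write_signatures(pd.concat(rank_frames, ignore_index=True),
                         out / "target_ranking.tsv")
        manifest["stages"]["n_drugs"] = len(library.drug_ids())

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "summary.txt").write_text(res.summary() + "\n")
    return out
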