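"""Synthetic cohorts with planted cluster structure and ground truth.

The generator emulates the data model the analysis assumes: log-scale
expression with k sample clusters driven by pathway-level mean shifts, so
gene-wise and pathway-wise clustering see the same partition. Per gene g a
baseline mean mu_g is drawn once; every sample adds Gaussian noise sd
``noise_sd``; for each cluster, ``effect_size`` is added (up pathways) or
subtracted (down pathways) on all member genes of that cluster's affected
pathways, for that cluster's samples only. Planted pathways are disjoint in
their member genes across clusters; the remaining gene sets are pure noise.

Every cluster — including the reference/"normal" one — carries its own
planted pathway program: a cluster with no distinguishing features would
have no signature and would be invisible to any signature-based classifier.

The drug library contains, per cluster, reversers whose up set is a subset
of the cluster's planted down genes and vice versa (perfect inverters),
plus decoy drugs with random disjoint up/down sets; the target map gives
most reversers of a cluster one designated planted target and decoys random
targets, so target inference has a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (DrugSignature, DrugSignatureLibrary, ExpressionMatrix,
                         GeneSetCollection)

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "split_cohort"]


@dataclass
class CohortConfig:
    """Simulation settings; the defaults define the package's study conditions."""

    n_clusters: int = 4
    samples_per_cluster: int = 30
    n_genes: int = 2000
    n_gene_sets: int = 150
    set_size_min: int = 10
    set_size_max: int = 50
    pathways_per_cluster: int = 8
    effect_size: float = 1.0      # delta, log-units added to member genes
    noise_sd: float = 1.0         # sigma
    baseline_mean: float = 7.0    # location of per-gene baseline means
    baseline_sd: float = 1.0
    n_reversers_per_cluster: int = 15
    n_decoy_drugs: int = 600
    drug_set_min: int = 10
    drug_set_max: int = 20
    reverser_target_fraction: float = 0.8  # share of reversers annotated with the planted target
    n_decoy_targets: int = 150
    seed: int = 42

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    true_labels: np.ndarray                    # per-sample cluster index in 1..k
    gene_sets: GeneSetCollection
    planted_signatures: dict                   # cluster -> dict(up_genes, down_genes, up_sets, down_sets)
    drug_library: DrugSignatureLibrary
    target_map: dict                           # drug_id -> frozenset of targets
    planted_reversers: dict                    # cluster -> set of drug_ids
    planted_targets: dict                      # cluster -> designated target gene
    seed: int
    config: CohortConfig = field(default_factory=CohortConfig)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a fully reproducible cohort with planted ground truth."""
    cfg = config or CohortConfig()
    if cfg.n_clusters < 2 or cfg.samples_per_cluster < 2:
        raise ValueError("need >= 2 clusters with >= 2 samples each")
    if not (1 <= cfg.set_size_min <= cfg.set_size_max):
        raise ValueError("invalid gene-set size range")
    n_planted_sets = cfg.n_clusters * cfg.pathways_per_cluster
    if n_planted_sets > cfg.n_gene_sets:
        raise ValueError("pathways_per_cluster * n_clusters exceeds n_gene_sets")

    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, cfg.n_genes + 1)]
    n_samples = cfg.n_clusters * cfg.samples_per_cluster
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    labels = np.repeat(np.arange(1, cfg.n_clusters + 1), cfg.samples_per_cluster)

    # planted pathways: disjoint member genes across all planted sets
    planted_sizes = rng.integers(cfg.set_size_min, cfg.set_size_max + 1,
                                 size=n_planted_sets)
    if planted_sizes.sum() > cfg.n_genes:
        raise ValueError(
            f"planted signature genes ({int(planted_sizes.sum())}) exceed n_genes "
            f"({cfg.n_genes}); reduce pathways_per_cluster or set sizes")
    pool = rng.permutation(cfg.n_genes)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    planted_signatures: dict = {}
    cursor = 0
    set_idx = 0
    for c in range(1, cfg.n_clusters + 1):
        up_genes: set[str] = set()
        down_genes: set[str] = set()
        up_sets: list[str] = []
        down_sets: list[str] = []
        for p in range(cfg.pathways_per_cluster):
            size = int(planted_sizes[set_idx])
            members = frozenset(genes[i] for i in pool[cursor:cursor + size])
            cursor += size
            direction = "up" if p < cfg.pathways_per_cluster / 2 else "down"
            name = f"SET_C{c}_{direction.upper()}_{p + 1:02d}"
            sets[name] = (f"planted {direction} pathway of cluster {c}", members)
            if direction == "up":
                up_genes |= members
                up_sets.append(name)
            else:
                down_genes |= members
                down_sets.append(name)
            set_idx += 1
        planted_signatures[c] = {"up_genes": frozenset(up_genes),
                                 "down_genes": frozenset(down_genes),
                                 "up_sets": tuple(up_sets),
                                 "down_sets": tuple(down_sets)}
    # noise sets: random genes, may overlap anything
    for i in range(cfg.n_gene_sets - n_planted_sets):
        size = int(rng.integers(cfg.set_size_min, cfg.set_size_max + 1))
        members = frozenset(genes[j] for j in
                            rng.choice(cfg.n_genes, size=size, replace=False))
        sets[f"SET_NOISE_{i + 1:03d}"] = ("noise pathway", members)
    gene_sets = GeneSetCollection(sets)

    # expression: baseline + noise + planted shifts
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c in range(1, cfg.n_clusters + 1):
        cols = np.flatnonzero(labels == c)
        up_rows = [gene_pos[g] for g in sorted(planted_signatures[c]["up_genes"])]
        down_rows = [gene_pos[g] for g in sorted(planted_signatures[c]["down_genes"])]
        values[np.ix_(up_rows, cols)] += cfg.effect_size
        values[np.ix_(down_rows, cols)] -= cfg.effect_size
    expression = ExpressionMatrix(genes, samples, values)

    # drug library: per-cluster perfect reversers + decoys
    cells = ("HEPG2", "HUH7")
    entries: list[DrugSignature] = []
    planted_reversers: dict = {}
    planted_targets: dict = {}
    target_map: dict[str, frozenset[str]] = {}
    decoy_targets = [f"T_dec{i:03d}" for i in range(1, cfg.n_decoy_targets + 1)]
    for c in range(1, cfg.n_clusters + 1):
        sig = planted_signatures[c]
        down_list = sorted(sig["down_genes"])
        up_list = sorted(sig["up_genes"])
        planted_targets[c] = f"T_clu{c}"
        ids = set()
        n_with_target = int(round(cfg.reverser_target_fraction *
                                  cfg.n_reversers_per_cluster))
        for i in range(cfg.n_reversers_per_cluster):
            drug_id = f"drug_c{c}_r{i + 1:02d}"
            hi_u = min(cfg.drug_set_max, len(down_list))
            hi_d = min(cfg.drug_set_max, len(up_list))
            su = int(rng.integers(min(cfg.drug_set_min, hi_u), hi_u + 1))
            sd_ = int(rng.integers(min(cfg.drug_set_min, hi_d), hi_d + 1))
            up = frozenset(rng.choice(down_list, size=su, replace=False))
            down = frozenset(rng.choice(up_list, size=sd_, replace=False))
            entries.append(DrugSignature(drug_id, cells[i % 2], up, down))
            ids.add(drug_id)
            if i < n_with_target:
                target_map[drug_id] = frozenset({planted_targets[c]})
            else:
                target_map[drug_id] = frozenset(
                    rng.choice(decoy_targets, size=1))
        planted_reversers[c] = ids
    for i in range(cfg.n_decoy_drugs):
        drug_id = f"drug_dec{i + 1:04d}"
        su = int(rng.integers(cfg.drug_set_min, cfg.drug_set_max + 1))
        sd_ = int(rng.integers(cfg.drug_set_min, cfg.drug_set_max + 1))
        both = rng.choice(cfg.n_genes, size=su + sd_, replace=False)
        up = frozenset(genes[j] for j in both[:su])
        down = frozenset(genes[j] for j in both[su:])
        entries.append(DrugSignature(drug_id, cells[i % 2], up, down))
        n_t = int(rng.integers(1, 4))
        target_map[drug_id] = frozenset(rng.choice(decoy_targets, size=n_t,
                                                   replace=False))
    library = DrugSignatureLibrary(entries)

    return SyntheticCohort(expression=expression, true_labels=labels,
                           gene_sets=gene_sets,
                           planted_signatures=planted_signatures,
                           drug_library=library, target_map=target_map,
                           planted_reversers=planted_reversers,
                           planted_targets=planted_targets,
                           seed=cfg.seed, config=cfg)


def split_cohort(cohort: SyntheticCohort, fraction: float, seed: int,
                 ) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Stratified disjoint split into (derivation, validation) cohorts.

    Per cluster, round(fraction * n_c) samples go to the first split; both
    splits must retain >= 2 samples of every cluster.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = cohort.true_labels
    take_a: list[int] = []
    take_b: list[int] = []
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        n_a = int(round(fraction * idx.size))
        if n_a < 2 or idx.size - n_a < 2:
            raise ValueError(
                f"fraction {fraction} leaves cluster {c} with < 2 samples in one split")
        perm = rng.permutation(idx)
        take_a += perm[:n_a].tolist()
        take_b += perm[n_a:].tolist()
    take_a.sort()
    take_b.sort()

    def _make(idx: list[int]) -> SyntheticCohort:
        sample_ids = [cohort.expression.sample_ids[i] for i in idx]
        return SyntheticCohort(
            expression=cohort.expression.subset_samples(sample_ids),
            true_labels=labels[idx], gene_sets=cohort.gene_sets,
            planted_signatures=cohort.planted_signatures,
            drug_library=cohort.drug_library, target_map=cohort.target_map,
            planted_reversers=cohort.planted_reversers,
            planted_targets=cohort.planted_targets,
            seed=seed, config=cohort.config)

    return _make(take_a), _make(take_b)
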