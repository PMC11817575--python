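# molsubtype

Molecular subtyping of bulk liver transcriptomes — and, in general, of any
normalized bulk RNA-seq cohort — by parallel **gene-wise and pathway-wise
NMF consensus clustering**, with downstream cluster signatures,
external-cohort classification, and in-silico therapeutic-target
nomination from drug-induced expression signatures.

The package is written for computational biologists who have a normalized
log-scale expression matrix and a GMT pathway collection and want a
reproducible, testable implementation of this analysis rather than a chain
of one-off scripts. It targets the study design used in metabolic
dysfunction-associated steatotic liver disease (MASLD) subtyping: cluster
patients two independent ways, check the two partitions agree, then mine
each subtype's signature for drugs that invert it.

## What it computes

**Pathway activity (ssGSVA).** Expression is transformed per gene by a
Gaussian-kernel CDF, z_gj = (1/n) Σ_k Φ((e_gj − e_gk)/h_g) with
h_g = sd(e_g)/4, then each (sample, gene set) pair is scored by a weighted
Kolmogorov–Smirnov random walk over the ranked genes (hit steps ∝ |z|^τ,
miss steps 1/(N−|S|); ES = max(0, max walk) + min(0, min walk)).

**Clustering.** Each arm keeps its top-MAD features (10% of genes, 30% of
pathways), builds a non-negative representation, and factorizes V ≈ WH by
multiplicative updates for the KL divergence D(V‖WH) over 30 seeded
restarts. The consensus matrix of co-assignment frequencies is summarized
by the cophenetic correlation coefficient, and the number of clusters k is
chosen at the elbow of the cophenetic curve; hard labels cut the
average-linkage dendrogram of 1 − consensus.

**Signatures.** Feature f is in cluster c's up-signature iff the one-sided
t-test of c vs the pooled rest passes BH-FDR < 0.01 *and* c beats every
other cluster individually (mean ordering + nominal one-sided test).
Gene signatures are annotated by hypergeometric over-representation against
the pathway collection (measured-gene universe, BH across sets).

**Classification.** External samples are scored, z-normalized, and assigned
to argmax_c [mean z(up pathways of c) − mean z(down pathways of c)].
Two clusterings are compared by the best-mapping agreement rate (optimal
assignment on the contingency table) and the adjusted Rand index.

**Target ranking.** Drugs whose up/down gene sets invert a cluster's
signature (overlap-contrast score in [−1,1]; most negative decile selected)
vote for their annotated targets, ranked by the enrichment factor

```
EF = (N_A∩B + 1) / (N_A · N_B / N_total + 1)
```

with N_A selected drugs, N_B drugs annotated with the target, N_A∩B their
overlap, N_total annotated drugs.

A seeded synthetic-cohort generator (`molsubtype.simulate`) plants all of
this structure — clusters driven by pathway-level mean shifts, signature
genes, reversing drugs, targets — so every stage can be tested against
ground truth. See `docs/methods.md` for assumptions and numerical details.

## Worked example

```python
import molsubtype as m

cohort = m.generate_cohort()            # default: 4 planted clusters x 30 samples
model = m.MolecularSubtypingModel(cohort.expression, cohort.gene_sets, seed=42)
res = model.fit()
print(res.summary())
```

```
Molecular subtyping results
======================================================
gene-wise arm: k = 4, cophenetic = 1.0000, 30 restarts
  cophenetic by rank: k=2: 0.978, k=3: 0.972, k=4: 1.000, k=5: 0.999, k=6: 0.997, k=7: 0.992
  cluster sizes: 1: 30, 2: 30, 3: 30, 4: 30
pathway-wise arm: k = 4, cophenetic = 1.0000, 30 restarts
  cophenetic by rank: k=2: 0.987, k=3: 0.979, k=4: 1.000, k=5: 1.000, k=6: 1.000, k=7: 0.999
  cluster sizes: 1: 30, 2: 30, 3: 30, 4: 30
signature features (q < 0.01): 950 genes, 52 pathways
arm agreement: 100.0% (120/120)
```

Both arms select k = 4 (the planted number) at the cophenetic peak, recover
the planted 30/30/30/30 partition exactly, and agree with each other on
every sample. Downstream:

```python
tgt = res.infer_targets(cohort.drug_library, cohort.target_map)
for c, d in tgt.items():
    print(c, d["rankings"][0].target, round(d["rankings"][0].ef, 2))
```

prints each cluster's top-ranked target — the planted target of that
cluster, at EF ≈ 5.9 against a ≈660-drug library — and

```python
deriv, valid = m.split_cohort(cohort, 0.5, seed=1)
```

supports the held-out classification experiment (100% of held-out samples
recover their planted subtype under the default conditions).

The same stages are exposed as a CLI (`molsubtype simulate | score | select |
cluster | signatures | enrich | celltypes | classify | agree | targets | run`);
`molsubtype run --config cfg.yaml` executes the whole pipeline and writes
diffable TSV outputs plus a manifest with the config hash and seeds.

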