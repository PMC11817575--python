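import math
from fractions import Fraction

import numpy as np
import pytest

from molsubtype.io_formats import ExpressionMatrix, GeneSetCollection
from molsubtype.signatures import (bh_fdr, celltype_profile, enrich_signature,
                                   extract_signatures, hypergeom_p,
                                   signatures_to_frame, welch_t)


def welch_oracle(x, y):
    """Textbook Welch formula, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist
    return t, 2 * tdist.sf(abs(t), df)


def bh_oracle(p):
    """Step-up BH by direct definition."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def hypergeom_oracle(k, n_a, n_b, n_total):
    """Exact upper-tail sum with rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(n_total, n_a)
    for i in range(k, min(n_a, n_b) + 1):
        total += Fraction(math.comb(n_b, i) * math.comb(n_total - n_b, n_a - i), denom)
    return float(total)


class TestWelch:
    def test_identical_groups(self):
        assert welch_t([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_direction_convention(self):
        t, _ = welch_t([1, 2, 3], [11, 12, 13])
        assert t < 0

    def test_against_textbook_formula(self):
        x = [5.1, 4.9, 5.0, 5.2]
        y = [3.0, 3.1, 2.9]
        t, p = welch_t(x, y)
        t0, p0 = welch_oracle(x, y)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_both_constant_equal_means(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def test_bh_matches_brute_force(rng):
    for _ in range(20):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)
    # q monotone non-decreasing in raw p
    p = rng.uniform(size=50)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestHypergeom:
    def test_exact_worked_example(self):
        # C(5,3)C(15,1)+C(5,4)C(15,0) over C(20,4) = 155/4845
        assert hypergeom_p(3, 4, 5, 20) == pytest.approx(155 / 4845, abs=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_p(0, 10, 5, 100) == pytest.approx(1.0, abs=1e-12)

    def test_saturated_universe(self):
        assert hypergeom_p(5, 5, 5, 5) == pytest.approx(1.0, abs=1e-12)

    def test_matches_rational_sum_on_random_instances(self, rng):
        for _ in range(25):
            n_total = int(rng.integers(10, 40))
            n_a = int(rng.integers(1, n_total))
            n_b = int(rng.integers(1, n_total))
            k = int(rng.integers(0, min(n_a, n_b) + 1))
            assert hypergeom_p(k, n_a, n_b, n_total) == pytest.approx(
                hypergeom_oracle(k, n_a, n_b, n_total), abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_p(6, 5, 10, 20)


class TestExtract:
    def test_recovers_planted_genes(self, small_cohort):
        sigs = extract_signatures(small_cohort.expression,
                                  small_cohort.true_labels, q_threshold=0.01)
        by = {(s.cluster, s.direction): set(s.feature_ids) for s in sigs}
        for c, sig in small_cohort.planted_signatures.items():
            up_recall = len(by[(c, "up")] & sig["up_genes"]) / len(sig["up_genes"])
            down_recall = len(by[(c, "down")] & sig["down_genes"]) / len(sig["down_genes"])
            assert up_recall > 0.7 and down_recall > 0.7
            # direction lists disjoint
            assert not by[(c, "up")] & by[(c, "down")]

    def test_null_data_yields_almost_no_signatures(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(300, 40))
        m = ExpressionMatrix([f"g{i:03d}" for i in range(300)],
                             [f"s{j}" for j in range(40)], vals)
        labels = np.repeat([1, 2, 3, 4], 10)
        sigs = extract_signatures(m, labels, q_threshold=0.01)
        assert sum(len(s) for s in sigs) <= 3

    def test_permutation_stability(self, small_cohort):
        m = small_cohort.expression
        labels = small_cohort.true_labels
        perm = np.random.default_rng(5).permutation(m.n_samples)
        mp = m.subset_samples([m.sample_ids[i] for i in perm])
        a = signatures_to_frame(extract_signatures(m, labels))
        b = signatures_to_frame(extract_signatures(mp, labels[perm]))
        key = ["cluster", "direction", "feature_id"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        assert a[key].equals(b[key])
        np.testing.assert_allclose(a[["t_stat", "p_value", "q_value"]],
                                   b[["t_stat", "p_value", "q_value"]], rtol=1e-9)

    def test_small_cluster_rejected(self):
        m = ExpressionMatrix(["g1"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="< 2 samples"):
            extract_signatures(m, np.array([1, 1, 2]))


class TestEnrich:
    def _signature(self, genes):
        from molsubtype.signatures import ClusterSignature
        return ClusterSignature(1, "up", [(g, 5.0, 1e-6, 1e-4) for g in genes])

    def test_perfect_overlap_is_top_ranked_and_tiny_p(self):
        genes = [f"g{i:04d}" for i in range(1000)]
        inside = genes[:10]
        coll = GeneSetCollection({"hit": ("", frozenset(inside)),
                                  "other": ("", frozenset(genes[500:540]))})
        res = enrich_signature(self._signature(inside), coll, set(genes))
        assert res[0].set_name == "hit"
        assert res[0].overlap == 10
        assert res[0].p < 1e-20
        assert res[0].p == pytest.approx(
            1 / math.comb(1000, 10) * math.comb(990, 0) * math.comb(10, 10), rel=1e-9)

    def test_disjoint_signature_all_p_one(self):
        genes = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection({"a": ("", frozenset(genes[:10]))})
        res = enrich_signature(self._signature(genes[50:60]), coll, set(genes))
        assert all(r.overlap == 0 and r.p == 1.0 for r in res)

    def test_ef_column_matches_standalone_formula(self):
        from molsubtype.targets import enrichment_factor
        genes = [f"g{i}" for i in range(50)]
        coll = GeneSetCollection({"a": ("", frozenset(genes[:20]))})
        res = enrich_signature(self._signature(genes[10:25]), coll, set(genes))
        r = res[0]
        assert r.ef == enrichment_factor(r.overlap, r.signature_size,
                                         r.set_size, r.universe_size)

    def test_empty_signature_warns_and_returns_empty(self):
        from molsubtype.signatures import ClusterSignature
        sig = ClusterSignature(1, "up", [])
        coll = GeneSetCollection({"a": ("", frozenset({"g1", "g2", "g3", "g4", "g5"}))})
        assert enrich_signature(sig, coll, {"g1", "g2"}) == []


class TestCellTypes:
    def test_planted_pathway_reported_for_its_marker_set(self, small_cohort):
        # marker set spans two clusters' planted pathways so the enrichment
        # of each cluster's restricted signature is non-degenerate
        c = small_cohort
        path1 = c.planted_signatures[1]["up_sets"][0]
        path2 = c.planted_signatures[2]["up_sets"][0]
        marker_genes = c.gene_sets.members(path1) | c.gene_sets.members(path2)
        markers = GeneSetCollection({"celltypeA": ("", marker_genes)})
        prof = celltype_profile(c.expression, c.true_labels, markers,
                                c.gene_sets, q_threshold=0.01)
        assert "celltypeA" in prof
        enr = prof["celltypeA"]["enrichments"].get((1, "up"), [])
        hits = [r.set_name for r in enr if r.q < 0.05]
        assert path1 in hits and path2 not in hits

    def test_unmeasured_marker_set_dropped(self, small_cohort):
        markers = GeneSetCollection({"ghost": ("", frozenset({"zz1", "zz2"}))})
        prof = celltype_profile(small_cohort.expression, small_cohort.true_labels,
                                markers, small_cohort.gene_sets)
        assert prof == {}

    def test_blocks_have_disjoint_up_down_lists(self, small_cohort):
        c = small_cohort
        name = c.planted_signatures[2]["down_sets"][0]
        markers = GeneSetCollection({"ct": ("", c.gene_sets.members(name))})
        prof = celltype_profile(c.expression, c.true_labels, markers, c.gene_sets)
        sigs = prof["ct"]["signatures"]
        by = {(s.cluster, s.direction): set(s.feature_ids) for s in sigs}
        for cl in set(c.true_labels.tolist()):
            assert not by.get((cl, "up"), set()) & by.get((cl, "down"), set())
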