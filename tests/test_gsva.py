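
import numpy as np
import pytest

from molsubtype.gsva import (enrichment_score, kernel_cdf_transform,
                             normalize_scores, ssgsva_matrix)
from molsubtype.io_formats import ExpressionMatrix, GeneSetCollection


def brute_force_es(stat, gene_ids, gene_set, tau, mode):
    """Independent step-by-step random walk (plain Python, no vectorization)."""
    pairs = sorted(zip(stat, gene_ids), key=lambda p: (-p[0], p[1]))
    hits = [(s, g) for s, g in pairs if g in gene_set]
    n, n_hit = len(pairs), len(hits)
    tot = sum(abs(s) ** tau for s, _ in hits)
    running, walk = 0.0, []
    for s, g in pairs:
        if g in gene_set:
            running += (abs(s) ** tau) / tot if tot > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        walk.append(running)
    if mode == "classic":
        return max(walk, key=abs)
    return max(max(walk), 0.0) + min(min(walk), 0.0)


class TestKernelCdf:
    def test_two_sample_symmetry(self):
        m = ExpressionMatrix(["g1"], ["s1", "s2"], [[0.0, 10.0]])
        Z, kept = kernel_cdf_transform(m)
        assert kept == ["g1"]
        assert Z[0, 0] == pytest.approx(0.25, abs=1e-6)
        assert Z[0, 1] == pytest.approx(0.75, abs=1e-6)
        assert Z[0, 0] + Z[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_expression(self):
        m = ExpressionMatrix(["g1"], [f"s{i}" for i in range(5)],
                             [[1.0, 2.0, 3.0, 4.0, 5.0]])
        Z, _ = kernel_cdf_transform(m)
        assert (np.diff(Z[0]) > 0).all()

    def test_matches_double_loop(self, rng):
        vals = rng.normal(size=(4, 6))
        m = ExpressionMatrix([f"g{i}" for i in range(4)],
                             [f"s{j}" for j in range(6)], vals)
        Z, _ = kernel_cdf_transform(m)
        from scipy.stats import norm
        for i in range(4):
            h = vals[i].std(ddof=1) / 4
            for j in range(6):
                direct = np.mean([norm.cdf((vals[i, j] - vals[i, k]) / h)
                                  for k in range(6)])
                assert Z[i, j] == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_gene_dropped(self):
        m = ExpressionMatrix(["flat", "var"], ["s1", "s2"], [[1.0, 1.0], [0.0, 1.0]])
        Z, kept = kernel_cdf_transform(m)
        assert kept == ["var"] and Z.shape == (1, 2)

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(["g1"], ["s1"], [[1.0]])
        with pytest.raises(ValueError):
            kernel_cdf_transform(m)


class TestEnrichmentScore:
    def test_hand_walk_six_genes(self):
        # genes a..f with stats 6..1, set {a, c}, tau 0: walk
        # +1/2, -1/4, +1/2, -1/4, -1/4, -1/4 -> peak 0.75 after c
        ids = list("abcdef")
        stat = [6, 5, 4, 3, 2, 1]
        es = enrichment_score(stat, ids, {"a", "c"}, tau=0.0, mode="classic")
        assert es == pytest.approx(0.75, abs=1e-12)
        assert es == pytest.approx(
            brute_force_es(stat, ids, {"a", "c"}, 0.0, "classic"), abs=1e-12)

    def test_top_ranked_set_scores_positive(self):
        ids = [f"g{i}" for i in range(10)]
        stat = np.arange(10, 0, -1).astype(float)
        s = set(ids[:3])
        assert enrichment_score(stat, ids, s, mode="diff") > 0.5
        assert enrichment_score(stat, ids, s, tau=0.0, mode="classic") > 0.5

    def test_sign_flip_negates_diff_score_at_tau_zero(self, rng):
        ids = [f"g{i}" for i in range(12)]
        stat = rng.normal(size=12)
        s = set(ids[2:7])
        a = enrichment_score(stat, ids, s, tau=0.0, mode="diff")
        b = enrichment_score([-x for x in stat], ids, s, tau=0.0, mode="diff")
        assert a == pytest.approx(-b, abs=1e-12)

    @pytest.mark.parametrize("mode", ["classic", "diff"])
    @pytest.mark.parametrize("tau", [0.0, 0.5, 1.0, 2.0])
    def test_matches_brute_force_on_random_instances(self, mode, tau, rng):
        ids_pool = [f"g{i:02d}" for i in range(30)]
        for _ in range(30):
            n = int(rng.integers(8, 31))
            ids = list(rng.choice(ids_pool, size=n, replace=False))
            stat = np.round(rng.normal(size=n), 3)  # rounding forces ties
            size = int(rng.integers(3, min(11, n)))
            s = set(rng.choice(ids, size=size, replace=False))
            got = enrichment_score(stat, ids, s, tau=tau, mode=mode)
            want = brute_force_es(stat, ids, s, tau, mode)
            assert got == pytest.approx(want, abs=1e-12)
            assert -1.0 - 1e-12 <= got <= 1.0 + 1e-12

    def test_degenerate_sets_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            enrichment_score([1, 2, 3], ids, {"z"})
        with pytest.raises(ValueError):
            enrichment_score([1, 2, 3], ids, {"a", "b", "c"})


class TestSsgsvaMatrix:
    def _cohort(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(40, 8))
        m = ExpressionMatrix([f"g{i:02d}" for i in range(40)],
                             [f"s{j}" for j in range(8)], vals)
        coll = GeneSetCollection({
            "big": ("", frozenset(m.gene_ids[:10])),
            "tiny": ("", frozenset(m.gene_ids[:2])),   # below min size
            "mid": ("", frozenset(m.gene_ids[20:30]))})
        return m, coll

    def test_small_sets_filtered(self):
        m, coll = self._cohort()
        scores = ssgsva_matrix(m, coll, min_set_size=5)
        assert set(scores.set_names) == {"big", "mid"}
        assert scores.scores.shape == (2, 8)

    def test_deterministic(self):
        m, coll = self._cohort()
        a = ssgsva_matrix(m, coll)
        b = ssgsva_matrix(m, coll)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_matches_per_sample_enrichment_score(self):
        m, coll = self._cohort()
        scores = ssgsva_matrix(m, coll, tau=1.0, mode="diff")
        Z, kept = kernel_cdf_transform(m)
        for si, name in enumerate(scores.set_names):
            for j in range(m.n_samples):
                direct = enrichment_score(Z[:, j], kept, coll.members(name),
                                          tau=1.0, mode="diff")
                assert scores.scores[si, j] == pytest.approx(direct, abs=1e-12)

    def test_set_order_invariance(self):
        m, coll = self._cohort()
        reordered = GeneSetCollection(dict(reversed(list(coll.items()))))
        a = ssgsva_matrix(m, coll).to_frame().sort_index()
        b = ssgsva_matrix(m, reordered).to_frame().sort_index()
        assert a.equals(b)

    def test_planted_up_pathway_scores_highest_in_its_cluster(self, small_cohort):
        scores = ssgsva_matrix(small_cohort.expression, small_cohort.gene_sets)
        frame = scores.to_frame()
        labels = small_cohort.true_labels
        for c, sig in small_cohort.planted_signatures.items():
            for name in sig["up_sets"]:
                per_cluster = {k: frame.loc[name].to_numpy()[labels == k].mean()
                               for k in set(labels.tolist())}
                assert max(per_cluster, key=per_cluster.get) == c


class TestNormalize:
    def test_rows_zero_mean_unit_sd_and_idempotent(self, rng):
        from molsubtype.io_formats import PathwayScoreMatrix
        raw = PathwayScoreMatrix([f"p{i}" for i in range(5)],
                                 [f"s{j}" for j in range(7)],
                                 rng.uniform(-1, 1, size=(5, 7)))
        z = normalize_scores(raw)
        np.testing.assert_allclose(z.scores.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.scores.std(axis=1, ddof=1), 1, atol=1e-12)
        zz = normalize_scores(z)
        np.testing.assert_allclose(zz.scores, z.scores, atol=1e-12)

    def test_constant_row_dropped(self):
        from molsubtype.io_formats import PathwayScoreMatrix
        raw = PathwayScoreMatrix(["flat", "ok"], ["s1", "s2", "s3"],
                                 [[0.5, 0.5, 0.5], [0.1, 0.2, 0.3]])
        z = normalize_scores(raw)
        assert z.set_names == ["ok"]

    def test_single_sample_rejected(self):
        from molsubtype.io_formats import PathwayScoreMatrix
        raw = PathwayScoreMatrix(["p"], ["s"], [[0.5]])
        with pytest.raises(ValueError):
            normalize_scores(raw)
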