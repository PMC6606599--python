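"""Enrichment statistics, profiles, MDS and co-occurrence clustering."""
import itertools
import math

import numpy as np
import pytest

from dmrkit.enrich import (anchored_signal_matrix, classical_mds,
                           cluster_binary_matrix, high_low_ratio,
                           mds_methylation, overlap_enrichment, trend_chi2,
                           tss_metaplot)
from dmrkit.types import (ConfigurationError, DMR, GeneModel, GenomicFeature,
                          MethTrack)

from conftest import flat_matrix


def _feat(chrom, start, end, cls="DMR", **attrs):
    return GenomicFeature(chrom, start, end, cls, attrs)


def _peak(chrom, start, end=None):
    return GenomicFeature(chrom, start, end or start + 300, "PEAK", {})


def hypergeom_upper_tail_by_enumeration(N, K, n, k):
    """P(X >= k) by exact combinatorial summation."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total


class TestOverlapEnrichment:
    def _fixture(self, N, K, n, k):
        """Universe of N 100-bp features; K of them carry peaks; the tested
        subset of n features includes k peak-carrying ones."""
        universe = [_feat("chr1", i * 1000, i * 1000 + 100) for i in range(N)]
        peaks = [_peak("chr1", i * 1000 + 20, i * 1000 + 60) for i in range(K)]
        features = universe[:k] + universe[K:K + (n - k)]
        return features, peaks, universe

    def test_zero_successes_give_p_one(self):
        features, peaks, universe = self._fixture(10, 4, 3, 0)
        assert overlap_enrichment(features, peaks, universe).p_value == 1.0

    def test_textbook_value_one_in_252(self):
        features, peaks, universe = self._fixture(10, 5, 5, 5)
        r = overlap_enrichment(features, peaks, universe)
        assert r.p_value == pytest.approx(1 / 252, abs=1e-12)

    def test_saturated_universe_gives_p_one(self):
        features, peaks, universe = self._fixture(8, 8, 5, 5)
        assert overlap_enrichment(features, peaks, universe).p_value == \
            pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_for_all_small_universes(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            N = int(rng.integers(2, 21))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(max(0, n - (N - K)), min(K, n) + 1))
            features, peaks, universe = self._fixture(N, K, n, k)
            r = overlap_enrichment(features, peaks, universe)
            assert r.p_value == pytest.approx(
                hypergeom_upper_tail_by_enumeration(N, K, n, k), abs=1e-9)

    def test_feature_set_exceeding_universe_rejected(self):
        features, peaks, universe = self._fixture(5, 2, 5, 2)
        with pytest.raises(ConfigurationError):
            overlap_enrichment(features + features, peaks, universe)


class TestHighLowRatio:
    def _dmr(self, start, delta):
        d = DMR("chr1", start, start + 500, 10, 0.5, 0.5 - delta, delta,
                "g1_hyper", 0.0)
        d.stratum = "high" if abs(delta) >= 0.3 else "low"
        return d

    def test_fourfold_percentage_gives_log2_two(self):
        high = [self._dmr(i * 10000, 0.4) for i in range(10)]
        low = [self._dmr(500000 + i * 10000, 0.2) for i in range(20)]
        peaks = [_peak("chr1", h.start + 100) for h in high[:2]]      # 20 %
        peaks += [_peak("chr1", l.start + 100) for l in low[:1]]       # 5 %
        rows = high_low_ratio(high + low, {"TF": peaks})
        assert rows[0]["log2_ratio_high_low"] == pytest.approx(2.0)

    def test_equal_percentages_give_zero(self):
        high = [self._dmr(i * 10000, 0.4) for i in range(10)]
        low = [self._dmr(500000 + i * 10000, 0.2) for i in range(10)]
        peaks = [_peak("chr1", h.start + 100) for h in high[:3]]
        peaks += [_peak("chr1", l.start + 100) for l in low[:3]]
        rows = high_low_ratio(high + low, {"TF": peaks})
        assert rows[0]["log2_ratio_high_low"] == pytest.approx(0.0)

    def test_zero_denominator_flagged_infinite(self):
        high = [self._dmr(i * 10000, 0.4) for i in range(5)]
        low = [self._dmr(500000 + i * 10000, 0.2) for i in range(5)]
        peaks = [_peak("chr1", high[0].start + 100)]
        rows = high_low_ratio(high + low, {"TF": peaks})
        assert rows[0]["log2_ratio_high_low"] == float("inf")
        assert rows[0]["flag"] == "infinite"

    def test_missing_stratum_rejected(self):
        high = [self._dmr(0, 0.4)]
        with pytest.raises(ConfigurationError):
            high_low_ratio(high, {"TF": []})


def cochran_armitage_by_expansion(strata, scores=None):
    """Independent oracle: expand to per-subject 0/1 outcomes and compute
    N * (population Pearson correlation of score and outcome)^2."""
    scores = scores or list(range(1, len(strata) + 1))
    xs, ys = [], []
    for (k, n), s in zip(strata, scores):
        xs += [s] * n
        ys += [1] * k + [0] * (n - k)
    x = np.asarray(xs, float)
    y = np.asarray(ys, float)
    r = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    return len(x) * r ** 2


class TestTrendChi2:
    def test_equal_proportions_give_zero(self):
        r = trend_chi2([(10, 100), (10, 100), (10, 100)])
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_monotone_table_matches_expansion_oracle(self):
        strata = [(10, 100), (20, 100), (30, 100), (40, 100)]
        r = trend_chi2(strata)
        assert r.chi2 == pytest.approx(cochran_armitage_by_expansion(strata),
                                       abs=1e-6)

    def test_fifty_random_tables_match_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            strata = []
            for _ in range(k):
                n = int(rng.integers(5, 200))
                strata.append((int(rng.integers(0, n + 1)), n))
            succ = sum(s for s, _ in strata)
            tot = sum(n for _, n in strata)
            if succ == 0 or succ == tot:
                continue
            r = trend_chi2(strata)
            assert r.chi2 == pytest.approx(
                cochran_armitage_by_expansion(strata), abs=1e-6)

    def test_reversed_order_preserves_statistic(self):
        strata = [(5, 50), (15, 60), (30, 70)]
        assert trend_chi2(strata).chi2 == pytest.approx(
            trend_chi2(strata[::-1]).chi2, abs=1e-9)

    def test_degenerate_pooled_fraction(self):
        r = trend_chi2([(0, 50), (0, 60)])
        assert (r.chi2, r.p) == (0.0, 1.0)
        r = trend_chi2([(50, 50), (60, 60)])
        assert (r.chi2, r.p) == (0.0, 1.0)


def _track(pos, values, chrom="chr1", weight=50.0):
    n = len(pos)
    return MethTrack(np.full(n, chrom, dtype=object), np.asarray(pos),
                     np.asarray(values, float), np.full(n, weight))


class TestTssMetaplot:
    def _genes(self, tss_list, strand="+"):
        return [GeneModel(f"g{i}", "chr1", t if strand == "+" else t - 5000,
                          t + 5000 if strand == "+" else t + 1, strand)
                for i, t in enumerate(tss_list)]

    def test_constant_signal_gives_flat_profile(self):
        pos = np.arange(0, 200_000, 100)
        track = _track(pos, np.full(len(pos), 0.8))
        grid, curve = tss_metaplot(track, self._genes([50_000, 100_000]))
        assert np.allclose(curve, 0.8, atol=1e-6)

    def test_minus_strand_profile_mirrors_plus(self):
        pos = np.arange(0, 100_000, 50)
        vals = 0.5 + 0.4 * np.tanh((pos - 50_000) / 2000)   # asymmetric step
        track = _track(pos, vals)
        _, plus = tss_metaplot(track, self._genes([50_000], "+"))
        _, minus = tss_metaplot(track, self._genes([50_001], "-"))
        assert np.allclose(plus, minus[::-1], atol=1e-3)

    def test_island_dip_centered_at_tss(self, default_result):
        g2 = default_result.ref.config.group_names[1]
        track = default_result.tracks[g2]
        genes = [g for g in default_result.ref.genes
                 if g.biotype == "protein_coding"][:150]
        grid, curve = tss_metaplot(track, genes)
        assert abs(grid[int(np.argmin(curve))]) <= 200

    def test_no_genes_rejected(self):
        track = _track(np.arange(100) * 100, np.full(100, 0.5))
        with pytest.raises(ConfigurationError):
            tss_metaplot(track, [])


class TestAnchoredMatrix:
    def test_constant_signal_gives_ones(self):
        pos = np.arange(0, 50_000, 40)
        track = _track(pos, np.ones(len(pos)))
        feats = [_feat("chr1", 10_000, 11_000), _feat("chr1", 30_000, 31_000)]
        mat, order, col = anchored_signal_matrix(track, feats)
        assert np.allclose(mat[~np.isnan(mat)], 1.0)
        assert np.allclose(col[~np.isnan(col)], 1.0)

    def test_row_order_follows_sort_contract(self):
        pos = np.arange(0, 50_000, 40)
        track = _track(pos, np.ones(len(pos)))
        feats = [_feat("chr1", i * 10_000, i * 10_000 + 500) for i in range(3)]
        _, order, _ = anchored_signal_matrix(track, feats,
                                             order_by=np.array([3.0, 1.0, 2.0]))
        assert list(order) == [1, 2, 0]

    def test_triangular_signal_matches_per_bin_oracle(self):
        pos = np.arange(0, 20_000, 10)
        centre = 10_000
        vals = np.maximum(0.0, 1.0 - np.abs(pos - centre) / 2000)
        track = _track(pos, vals)
        feat = _feat("chr1", centre - 250, centre + 250)
        n_bins, flank = 50, 2000
        mat, _, _ = anchored_signal_matrix(track, [feat], flank_bp=flank,
                                           n_bins=n_bins)
        edges = np.linspace(-flank, flank, n_bins + 1)
        for b in range(n_bins):
            sel = (pos - centre >= edges[b]) & (pos - centre < edges[b + 1])
            if sel.any():
                assert mat[0, b] == pytest.approx(vals[sel].mean(), abs=1e-12)

    def test_umr_profile_has_central_minimum(self, default_result):
        g1 = default_result.ref.config.group_names[0]
        track = default_result.tracks[g1]
        umrs = [s.to_feature() for s in default_result.umrs(g1)][:150]
        mat, _, col = anchored_signal_matrix(track, umrs)
        centre = len(col) // 2
        assert abs(int(np.nanargmin(col)) - centre) <= 5


class TestMds:
    def test_rank_two_configuration_reproduced(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = classical_mds(D, k=2)
        D2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-9)

    def test_duplicated_sample_at_zero_distance(self):
        m = flat_matrix(n_sites=200, frac=0.5, coverage=20, n_per_group=2)
        coords, D = mds_methylation(m, min_cov=5)
        assert D[0, 1] == 0.0
        assert np.allclose(coords[0], coords[1], atol=1e-9)

    def test_groups_separate_on_default_simulation(self, default_result):
        coords, D = mds_methylation(default_result.methylome)
        labels = [default_result.methylome.groups[s]
                  for s in default_result.methylome.samples]
        n = len(labels)
        within = [D[i, j] for i in range(n) for j in range(i + 1, n)
                  if labels[i] == labels[j]]
        between = [D[i, j] for i in range(n) for j in range(i + 1, n)
                   if labels[i] != labels[j]]
        assert max(within) < min(between)

    def test_too_few_samples_rejected(self):
        m = flat_matrix(n_sites=50, n_per_group=1)
        with pytest.raises(ConfigurationError):
            mds_methylation(m)


class TestClusterBinary:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        base = rng.random((6, 12)) < 0.5
        mat = np.vstack([base, base[2]])   # row 6 duplicates row 2
        row_order, _, _ = cluster_binary_matrix(mat)
        pos = {r: i for i, r in enumerate(row_order)}
        assert abs(pos[2] - pos[6]) == 1

    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(1)
        a = np.zeros((8, 10), dtype=bool)
        a[:, :5] = rng.random((8, 5)) < 0.9
        b = np.zeros((8, 10), dtype=bool)
        b[:, 5:] = rng.random((8, 5)) < 0.9
        mat = np.vstack([a, b])
        _, _, labels = cluster_binary_matrix(mat, n_clusters=2)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_row_permutation_preserves_partition(self):
        """Permuting input rows yields the same cluster partition of the
        underlying (planted) row identities."""
        rng = np.random.default_rng(2)
        mat = rng.random((10, 8)) < 0.4
        mat[:, 0] = True  # no all-empty rows
        _, _, labels1 = cluster_binary_matrix(mat, n_clusters=3)
        perm = rng.permutation(10)
        _, _, labels2 = cluster_binary_matrix(mat[perm], n_clusters=3)

        def partition(labels, ids):
            cells = {}
            for lab, i in zip(labels, ids):
                cells.setdefault(lab, set()).add(i)
            return {frozenset(c) for c in cells.values()}

        assert partition(labels1, range(10)) == partition(labels2, perm)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_binary_matrix(np.zeros((0, 0)))
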