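"""Promoters, nearest genes, differential expression and DE × DM joins."""
import numpy as np
import pytest

from dmrkit.integrate import (call_de, call_dlmrs, dedm_quadrants,
                              define_promoters, detect_cliffs,
                              dmv_association, nearest_protein_coding_gene)
from dmrkit.types import (ConfigurationError, CpGMethylomeMatrix, DEDMRecord,
                          DEResult, DMR, ExpressionCounts, GeneModel,
                          GenomicFeature, Segment)


def _gene(gid="g1", chrom="chr1", start=10000, end=15000, strand="+",
          biotype="protein_coding"):
    return GeneModel(gid, chrom, start, end, strand, biotype)


def _dmr(dmr_id, chrom="chr1", start=9000, end=9500, delta=0.25):
    return DMR(chrom, start, end, 10, 0.5 + delta / 2, 0.5 - delta / 2, delta,
               "g1_hyper" if delta > 0 else "g2_hyper", 0.0,
               "high" if abs(delta) >= 0.3 else "low", None, dmr_id)


class TestPromoters:
    def test_plus_strand_window(self):
        p = define_promoters([_gene(start=10000, end=20000, strand="+")])[0]
        assert (p.start, p.end) == (8000, 12000)

    def test_minus_strand_clipped(self):
        p = define_promoters([_gene(start=100, end=600, strand="-")])[0]
        # tss = 599; window [599-2000, 599+2000) clipped at zero
        assert (p.start, p.end) == (0, 2599)

    def test_zero_flank_degenerates_to_single_base(self):
        p = define_promoters([_gene(start=10000, end=20000)], flank_bp=0)[0]
        assert (p.start, p.end) == (10000, 10001)


class TestNearestGene:
    def test_midpoint_at_tss(self):
        g = _gene("g1", start=10000)
        f = GenomicFeature("chr1", 9900, 10100, "DMR", {"delta_me": 0.2})
        assert nearest_protein_coding_gene(f, [g]) == ("g1", 0.0)

    def test_tie_broken_lexicographically(self):
        ga = _gene("ga", start=9000)
        gb = _gene("gb", start=11000)
        f = GenomicFeature("chr1", 9990, 10010, "DMR", {})
        assert nearest_protein_coding_gene(f, [gb, ga])[0] == "ga"

    def test_non_coding_ignored_and_missing_reported(self):
        lnc = _gene("lnc", biotype="lncRNA")
        f = GenomicFeature("chr1", 0, 100, "DMR", {})
        assert nearest_protein_coding_gene(f, [lnc]) == (None, None)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        genes = [_gene(f"g{i:02d}", start=int(rng.integers(0, 1_000_000)),
                       end=int(rng.integers(0, 1_000_000)) + 1_000_001)
                 for i in range(20)]
        for _ in range(100):
            s = int(rng.integers(0, 1_000_000))
            f = GenomicFeature("chr1", s, s + 200, "DMR", {})
            mid = (f.start + f.end) / 2
            exp = min(genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            gid, dist = nearest_protein_coding_gene(f, genes)
            assert gid == exp.gene_id
            assert dist == abs(mid - exp.tss)


def _nb_counts(rng, mu, disp, shape):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=shape)


class TestCallDe:
    SAMPLES = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
    GROUPS = {s: s.split("_")[0] for s in SAMPLES}

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        mu = np.exp(rng.normal(np.log(300), 0.8, 2000)).clip(20, 5000)
        counts = _nb_counts(rng, mu[:, None], 0.05, (2000, 6))
        ec = ExpressionCounts([f"g{i}" for i in range(2000)], self.SAMPLES,
                              counts, self.GROUPS)
        ps = np.array([r.p for r in call_de(ec)])
        assert 0.03 <= (ps < 0.05).mean() <= 0.07

    def test_power_on_planted_fold_change(self):
        rng = np.random.default_rng(7)
        mu = np.exp(rng.normal(np.log(300), 0.8, 1000)).clip(20, 5000)
        null = _nb_counts(rng, mu[:, None], 0.05, (1000, 6))
        a = _nb_counts(rng, 500 * 2 ** 1.5, 0.05, (200, 3))
        b = _nb_counts(rng, 500 * 2 ** -1.5, 0.05, (200, 3))
        counts = np.vstack([null, np.hstack([a, b])])
        ec = ExpressionCounts([f"g{i}" for i in range(1200)], self.SAMPLES,
                              counts, self.GROUPS)
        res = call_de(ec)
        detected = np.mean([r.is_de for r in res[1000:]])
        assert detected >= 0.95

    def test_all_zero_gene(self):
        counts = np.vstack([np.zeros(6, dtype=int), np.full(6, 100)])
        ec = ExpressionCounts(["dead", "alive"], self.SAMPLES, counts, self.GROUPS)
        res = call_de(ec)
        assert res[0].p == 1.0 and res[0].log2fc == 0.0

    def test_single_replicate_rejected(self):
        samples = ["A_1", "B_1", "B_2"]
        ec = ExpressionCounts(["g"], samples, np.array([[5, 5, 5]]),
                              {s: s.split("_")[0] for s in samples})
        with pytest.raises(ConfigurationError):
            call_de(ec)


class TestQuadrants:
    def _setup(self):
        genes = [_gene("g1", start=10000, end=20000)]
        promoters = define_promoters(genes)
        return promoters

    def test_concordant_when_signs_agree(self):
        de = [DEResult("g1", 1.5, 1e-9, 1e-6, True)]
        recs, summary = dedm_quadrants(de, [_dmr("d1", delta=0.25)], self._setup())
        assert len(recs) == 1
        assert recs[0].quadrant == "meth-up/expr-up"
        assert recs[0].concordance == "concordant"

    def test_inverse_when_signs_differ(self):
        de = [DEResult("g1", 1.5, 1e-9, 1e-6, True)]
        recs, _ = dedm_quadrants(de, [_dmr("d1", delta=-0.25)], self._setup())
        assert recs[0].quadrant == "meth-down/expr-up"
        assert recs[0].concordance == "inverse"

    def test_below_delta_threshold_excluded(self):
        de = [DEResult("g1", 1.5, 1e-9, 1e-6, True)]
        recs, _ = dedm_quadrants(de, [_dmr("d1", delta=0.15)], self._setup())
        assert recs == []

    def test_fixture_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        genes = [_gene(f"g{i:02d}", start=int(20000 * i + 10000),
                       end=int(20000 * i + 18000)) for i in range(12)]
        promoters = define_promoters(genes)
        de = [DEResult(g.gene_id, float(rng.normal()), 1e-5, 1e-4,
                       bool(rng.random() < 0.7)) for g in genes]
        dmrs = [_dmr(f"d{i:02d}", start=int(rng.integers(0, 240000)),
                     end=0, delta=float(rng.uniform(-0.5, 0.5)))
                for i in range(15)]
        for d in dmrs:
            d.end = d.start + 800
        recs, summary = dedm_quadrants(de, dmrs, promoters)

        expected = set()
        for der in de:
            if not der.is_de:
                continue
            prom = next(p for p in promoters
                        if p.attributes["gene_id"] == der.gene_id)
            for d in dmrs:
                if abs(d.delta_me) < 0.2:
                    continue
                if d.chrom == prom.chrom and d.start < prom.end and prom.start < d.end:
                    expected.add((der.gene_id, d.dmr_id))
        assert {(r.gene_id, r.dmr_id) for r in recs} == expected
        assert summary["n_records"] == len(recs)
        assert summary["n_inverse"] + summary["n_concordant"] == len(recs)
        assert sum(summary["records"].values()) == len(recs)

    def test_label_swap_mirrors_quadrants(self):
        """Negating both ΔMe and log2FC (a group swap) mirrors each quadrant
        but leaves concordance labels unchanged."""
        de = [DEResult("g1", 1.5, 1e-9, 1e-6, True)]
        fwd, _ = dedm_quadrants(de, [_dmr("d1", delta=0.25)], self._setup())
        de_sw = [DEResult("g1", -1.5, 1e-9, 1e-6, True)]
        rev, _ = dedm_quadrants(de_sw, [_dmr("d1", delta=-0.25)], self._setup())
        assert fwd[0].quadrant == "meth-up/expr-up"
        assert rev[0].quadrant == "meth-down/expr-down"
        assert fwd[0].concordance == rev[0].concordance == "concordant"


def _region_matrix(frac1, frac2, n_sites=10):
    pos = np.arange(n_sites) * 50 + 9000
    samples = ["SA_1", "SA_2", "VA_1", "VA_2"]
    groups = {s: s.split("_")[0] for s in samples}
    total = np.full((n_sites, 4), 100)
    meth = np.column_stack([np.full(n_sites, int(100 * frac1))] * 2
                           + [np.full(n_sites, int(100 * frac2))] * 2)
    return CpGMethylomeMatrix(np.full(n_sites, "chr1", dtype=object), pos,
                              samples, groups, meth, total)


class TestCliffs:
    @pytest.mark.parametrize("f1,f2,expected", [
        (0.10, 0.45, True),
        (0.40, 0.70, False),
        (0.25, 0.80, True),   # boundary inclusive
    ])
    def test_cliff_rule(self, f1, f2, expected):
        m = _region_matrix(f1, f2)
        d = _dmr("d1", start=9000, end=9500, delta=f1 - f2)
        rec = DEDMRecord("g1", "d1", "meth-down/expr-up", "inverse",
                         f1 - f2, 1.0)
        recs, summary = detect_cliffs([rec], [d], m, groups=["SA", "VA"])
        assert recs[0].cliff is expected

    def test_uncovered_dmr_reported_undefined(self):
        m = _region_matrix(0.1, 0.5)
        d = _dmr("far", chrom="chr2", start=5_000_000, end=5_000_500, delta=0.3)
        rec = DEDMRecord("g1", "far", "meth-up/expr-up", "concordant", 0.3, 1.0)
        recs, summary = detect_cliffs([rec], [d], m)
        assert recs[0].cliff is None
        assert summary["n_undefined"] == 1


class TestDmvAssociation:
    def _rec(self, dmr_id, delta):
        return DEDMRecord("g", dmr_id, "meth-up/expr-up", "concordant",
                          delta, 1.0)

    def test_no_dmvs_all_false(self):
        recs, summary = dmv_association([self._rec("d1", 0.3)],
                                        [_dmr("d1")], {"SA": [], "VA": []})
        assert recs[0].in_dmv is False

    def test_dmr_inside_valley_flagged(self):
        dmv = Segment("chr1", 8000, 14000, 200, 0.03, "DMV")
        recs, summary = dmv_association([self._rec("d1", 0.3)],
                                        [_dmr("d1", start=9000, end=9500)],
                                        {"SA": [dmv]})
        assert recs[0].in_dmv is True

    def test_contingency_matches_hand_count(self):
        dmv = Segment("chr1", 0, 10000, 200, 0.03, "DMV")
        dmrs = [_dmr("in_hi", start=1000, end=1500, delta=0.4),
                _dmr("in_lo", start=2000, end=2500, delta=0.25),
                _dmr("out_hi", start=20000, end=20500, delta=0.4)]
        recs = [self._rec("in_hi", 0.4), self._rec("in_lo", 0.25),
                self._rec("out_hi", 0.4)]
        _, summary = dmv_association(recs, dmrs, {"SA": [dmv]})
        assert summary["high"] == (1, 2)   # one of two High records in a DMV
        assert summary["low"] == (1, 1)


class TestDlmrs:
    def _lmr(self, start, meth, chrom="chr1"):
        return Segment(chrom, start, start + 500, 8, meth, "LMR")

    def test_quantile_and_overlap_rules(self):
        lmrs_sa = [self._lmr(i * 10000, 0.10 + 0.02 * i) for i in range(10)]
        dmr_va_hyper = _dmr("d1", start=0, end=600, delta=-0.4)  # VA (g2) hyper
        out = call_dlmrs({"SA": lmrs_sa, "VA": [self._lmr(0, 0.2)] * 4},
                         [dmr_va_hyper], group_order=["SA", "VA"])
        # only the first SA LMR overlaps the DMR and sits in the lowest quartile
        assert [f.start for f in out["SA"]] == [0]
        assert out["VA"] == []

    def test_high_quantile_lmr_excluded_despite_overlap(self):
        lmrs_sa = [self._lmr(i * 10000, 0.05 + 0.03 * i) for i in range(10)]
        # LMR at index 8 (meth 0.29, ~0.8 quantile) overlaps a VA-hyper DMR
        d = _dmr("d1", start=80000, end=80600, delta=-0.4)
        out = call_dlmrs({"SA": lmrs_sa, "VA": [self._lmr(0, 0.2)] * 4}, [d],
                         group_order=["SA", "VA"])
        assert out["SA"] == []

    def test_too_few_lmrs_rejected(self):
        with pytest.raises(ConfigurationError):
            call_dlmrs({"SA": [self._lmr(0, 0.1)] * 3,
                        "VA": [self._lmr(0, 0.1)] * 4}, [],
                       group_order=["SA", "VA"])

    def test_thirty_lmr_fixture_matches_brute_force(self):
        """Both directions against a filter-then-intersect oracle."""
        rng = np.random.default_rng(11)
        lmrs = {g: [self._lmr(int(rng.integers(0, 900) * 1000),
                              float(rng.uniform(0.05, 0.45)))
                    for _ in range(30)] for g in ("SA", "VA")}
        dmrs = []
        for i in range(25):
            delta = float(rng.choice([-1, 1]) * rng.uniform(0.15, 0.5))
            s = int(rng.integers(0, 900) * 1000)
            dmrs.append(_dmr(f"d{i}", start=s, end=s + 700, delta=delta))
        out = call_dlmrs(lmrs, dmrs, group_order=["SA", "VA"])
        for gi, g in enumerate(("SA", "VA")):
            thr = np.quantile([s.mean_meth for s in lmrs[g]], 0.25)
            opposite = "g2_hyper" if gi == 0 else "g1_hyper"
            expected = {(s.chrom, s.start, s.end) for s in lmrs[g]
                        if s.mean_meth <= thr and any(
                            d.direction == opposite and d.chrom == s.chrom
                            and d.start < s.end and s.start < d.end
                            for d in dmrs)}
            got = {(f.chrom, f.start, f.end) for f in out[g]}
            assert got == expected
            # D-LMRs are a subset of the group's LMRs
            assert got <= {(s.chrom, s.start, s.end) for s in lmrs[g]}
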