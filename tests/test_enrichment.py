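"""2x2 enrichment statistics, stratified series and the KS comparison."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from ebml.enrichment import (TwoByTwo, category_enrichment, chi2_2x2,
                             ks_two_sample, odds_ratio_ci,
                             pairwise_overlap_tests, stratified_series)


class TestChi2:
    def test_closed_form_worked_example(self):
        res = chi2_2x2(TwoByTwo(10, 20, 20, 10))
        assert res.chi2 == pytest.approx(20 / 3, rel=1e-9)
        assert res.p_value == pytest.approx(0.009823, rel=1e-3)
        assert res.residuals[0, 0] == pytest.approx((10 - 15) / math.sqrt(15))
        assert res.direction == "under"

    def test_balanced_table_null(self):
        res = chi2_2x2(TwoByTwo(5, 5, 5, 5))
        assert res.chi2 == 0 and res.p_value == 1 and res.direction == "none"

    def test_yates_worked_example(self):
        res = chi2_2x2(TwoByTwo(10, 20, 20, 10), yates=True)
        assert res.chi2 == pytest.approx(60 * 270**2 / 810000, rel=1e-9)

    def test_zero_margin_is_na(self):
        res = chi2_2x2(TwoByTwo(0, 0, 5, 5))
        assert res.is_na and res.note == "zero margin"

    def test_identity_and_residual_decomposition(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(1, 40, size=4)
            res = chi2_2x2(TwoByTwo(int(a), int(b), int(c), int(d)))
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / \
                ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.chi2 == pytest.approx(closed, rel=1e-9)
            assert (res.residuals ** 2).sum() == pytest.approx(res.chi2, abs=1e-9)
            sp = st.chi2_contingency(res.table.as_array(), correction=False)
            assert res.chi2 == pytest.approx(sp.statistic, rel=1e-9)
            assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            r1 = chi2_2x2(TwoByTwo(a, b, c, d))
            r2 = chi2_2x2(TwoByTwo(a, c, b, d))  # swap factors = transpose
            assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
            assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-12)


class TestOddsRatio:
    def test_woolf_interval_worked_example(self):
        or_, lo, hi = odds_ratio_ci(TwoByTwo(10, 20, 20, 10))
        assert or_ == pytest.approx(0.25)
        assert lo == pytest.approx(0.0854, rel=2e-3)
        assert hi == pytest.approx(0.731, rel=2e-3)

    def test_unit_table(self):
        assert odds_ratio_ci(TwoByTwo(1, 1, 1, 1))[0] == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        or_, lo, hi = odds_ratio_ci(TwoByTwo(0, 10, 10, 10))
        assert or_ == pytest.approx((0.5 * 10.5) / (10.5 * 10.5), rel=1e-9)
        assert lo < or_ < hi

    def test_inverse_under_row_swap(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            or1 = odds_ratio_ci(TwoByTwo(a, b, c, d))[0]
            or2 = odds_ratio_ci(TwoByTwo(c, d, a, b))[0]
            assert or1 == pytest.approx(1 / or2, rel=1e-9)


class TestCategoryEnrichment:
    def test_by_hand_cell_counts(self):
        universe = [f"L{i}" for i in range(100)]
        ebml = pd.Series([i < 10 for i in range(100)], index=universe)
        cat = pd.Series([i < 6 or (10 <= i < 24) for i in range(100)],
                        index=universe)
        res = category_enrichment(ebml, cat, universe=universe)
        t = res.table
        assert (t.a, t.b, t.c, t.d) == (6, 4, 14, 76)

    def test_perfect_association_direction_over(self):
        universe = [f"L{i}" for i in range(50)]
        flags = pd.Series([i < 8 for i in range(50)], index=universe)
        res = category_enrichment(flags, flags.copy(), universe=universe)
        assert res.direction == "over"
        assert res.residuals[0, 0] == res.residuals.max()

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="empty"):
            category_enrichment(pd.Series(dtype=bool), pd.Series(dtype=bool),
                                universe=[])

    def test_planted_category_bias_detected(self):
        """Bias planted only inside the category is called 'over' in >= 95%
        of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            universe = [f"L{i}" for i in range(400)]
            cat = pd.Series(rng.uniform(size=400) < 0.25, index=universe)
            p_ebml = np.where(cat, 0.35, 0.05)
            ebml = pd.Series(rng.uniform(size=400) < p_ebml, index=universe)
            res = category_enrichment(ebml, cat, universe=universe)
            hits += res.direction == "over"
        assert hits >= 19


class TestPairwiseOverlap:
    def test_identical_sets_all_over(self):
        sets = {p: {f"L{i}" for i in range(20)} for p in ("A", "B", "C", "D", "E")}
        # identical sets over their own union give a zero margin (nothing
        # outside); perturb one locus per population to keep margins positive
        for j, p in enumerate(sets):
            sets[p] = set(list(sets[p])[:15]) | {f"X{j}"}
        df = pairwise_overlap_tests(sets)
        assert len(df) == 10
        assert (df["direction"] == "over").all()

    def test_disjoint_set_under(self):
        rng = np.random.default_rng(0)
        base = {f"L{i}" for i in range(60)}
        sets = {p: set(rng.choice(sorted(base), 30, replace=False))
                for p in ("A", "B", "C", "D")}
        sets["E"] = {f"Z{i}" for i in range(30)}
        df = pairwise_overlap_tests(sets)
        e_rows = df[(df["pop_a"] == "E") | (df["pop_b"] == "E")]
        assert (e_rows["direction"] == "under").all()

    def test_single_set_raises(self):
        with pytest.raises(ValueError):
            pairwise_overlap_tests({"A": {"L1"}})


class TestStratifiedSeries:
    def _inputs(self, seed=0, n=600):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"L{i}" for i in range(n)], name="locus_id")
        intron = pd.Series(rng.uniform(size=n) < 0.5, index=idx)
        regions = pd.DataFrame({
            "intron": intron,
            "exon": ~intron & (rng.uniform(size=n) < 0.4),
            "cds": pd.Series(rng.uniform(size=n) < 0.15, index=idx) & ~intron,
            "utr5": pd.Series(rng.uniform(size=n) < 0.1, index=idx),
            "utr3": pd.Series(rng.uniform(size=n) < 0.1, index=idx),
        })
        # exome-like availability: coding well covered, introns poorly
        lam = np.where(regions["cds"], 60, np.where(intron, 12, 30))
        counts = pd.Series(rng.poisson(lam) + 2, index=idx)
        p_ebml = np.where(intron, 0.30, 0.06)  # planted intron bias
        ebml = pd.Series(rng.uniform(size=n) < p_ebml, index=idx)
        return counts, ebml, regions

    def test_threshold_strata_are_nested(self):
        counts, ebml, regions = self._inputs()
        series = stratified_series(counts, ebml, regions, mode="threshold")
        sizes = [it["n_loci"] for it in series.iterations]
        assert sizes == sorted(sizes, reverse=True)
        assert series.iterations[0]["stratum"] == "all"
        assert series.iterations[1]["stratum"] == ">4"
        assert series.iterations[2]["stratum"] == ">8"

    def test_threshold_boundaries(self):
        counts = pd.Series({"L1": 4, "L2": 5})
        ebml = pd.Series({"L1": True, "L2": False})
        regions = pd.DataFrame({"intron": pd.Series({"L1": True, "L2": False})})
        series = stratified_series(counts, ebml, regions, mode="threshold",
                                   n_iter=3)
        assert series.iterations[1]["n_loci"] == 1  # only the 5-sample locus

    def test_window_boundaries(self):
        counts = pd.Series({"L1": 5})
        ebml = pd.Series({"L1": True})
        regions = pd.DataFrame({"intron": pd.Series({"L1": True})})
        series = stratified_series(counts, ebml, regions, mode="window",
                                   n_iter=4)
        in_strata = [it["n_loci"] for it in series.iterations]
        assert in_strata == [0, 1, 0, 0]  # [2,3], [4,7], [8,15], [16,31]

    def test_both_modes_agree_on_planted_intron_bias(self):
        counts, ebml, regions = self._inputs(seed=3)
        thr = stratified_series(counts, ebml, regions, mode="threshold")
        win = stratified_series(counts, ebml, regions, mode="window")
        agreements = 0
        for series in (thr, win):
            for it in series.iterations:
                res = it["intron"]
                if res is not None and it["n_loci"] >= 50:
                    assert res.direction == "over"
                    agreements += 1
        assert agreements >= 5  # both series populated and concordant


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(1.0)

    def test_ecdf_by_hand(self):
        d, _ = ks_two_sample([1, 2], [1, 3])
        assert d == pytest.approx(0.5)

    def test_symmetry_and_monotone_invariance(self, rng):
        x = rng.poisson(6, size=40) + 1
        y = rng.poisson(8, size=60) + 1
        d1, p1 = ks_two_sample(x, y)
        d2, p2 = ks_two_sample(y, x)
        assert d1 == pytest.approx(d2) and p1 == pytest.approx(p2)
        d3, p3 = ks_two_sample(np.log(x), np.log(y))
        assert d3 == pytest.approx(d1) and p3 == pytest.approx(p1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1, 2])
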