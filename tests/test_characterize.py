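import math

import numpy as np
import pandas as pd
import pytest

from cyclops_screen import characterize as char
from cyclops_screen.stats import mann_whitney

from oracles import binomial_tail_oracle, hypergeom_tail_oracle


class TestExpressionUniformity:
    def test_constant_gene_zero(self):
        expr = pd.DataFrame([[5.0] * 6], index=["g"])
        assert char.normalized_expression_variance(expr)["g"] == 0.0

    def test_scale_invariance(self, rng):
        expr = pd.DataFrame(np.exp(rng.normal(size=(10, 20))))
        a = char.normalized_expression_variance(expr)
        b = char.normalized_expression_variance(expr * 2.0)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_low_dispersion_class_detected(self, rng):
        # 200 uniformly-expressed genes vs 200 background genes: one-sided
        # Mann-Whitney flags the lower normalized variance
        tight = np.exp(rng.normal(np.log(100), 0.1, size=(200, 50)))
        loose = np.exp(rng.normal(np.log(100), 0.4, size=(200, 50)))
        expr = pd.DataFrame(np.vstack([tight, loose]))
        cv2 = char.normalized_expression_variance(expr)
        p = mann_whitney(cv2[:200], cv2[200:], alternative="less")
        assert p < 0.01

    def test_variance_of_log_strategy(self, rng):
        expr = pd.DataFrame(np.exp(rng.normal(size=(5, 30))))
        out = char.normalized_expression_variance(expr, strategy="variance_of_log")
        assert (out > 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            char.normalized_expression_variance(pd.DataFrame([[1.0, 2.0]]))


class TestCnExpressionResponse:
    def _inputs(self, loss_expr, neutral_expr):
        samples = [f"s{i}" for i in range(6)]
        expr = pd.DataFrame([list(loss_expr) + list(neutral_expr)],
                            index=["g"], columns=samples)
        states = pd.DataFrame([["loss"] * len(loss_expr)
                               + ["neutral"] * len(neutral_expr)],
                              index=["g"], columns=samples)
        return expr, states

    def test_identical_groups_zero_percent(self):
        expr, states = self._inputs([10, 10, 10], [10, 10, 10])
        out = char.cn_expression_response(expr, states)
        assert out.loc["g", "percent_decrease"] == pytest.approx(0.0)

    def test_28_percent_decrease(self):
        expr, states = self._inputs([7.2, 7.2, 7.2], [10, 10, 10])
        out = char.cn_expression_response(expr, states)
        assert out.loc["g", "percent_decrease"] == pytest.approx(28.0)

    def test_insufficient_groups_na(self):
        expr, states = self._inputs([10.0], [10, 10, 10, 10, 10])
        out = char.cn_expression_response(expr, states)
        assert np.isnan(out.loc["g", "percent_decrease"])

    def test_correlation_with_continuous_cn(self, rng):
        samples = [f"s{i}" for i in range(40)]
        cn = pd.DataFrame([np.linspace(-1, 0.2, 40)], index=["g"], columns=samples)
        expr = pd.DataFrame([100 * 2.0 ** cn.iloc[0].to_numpy()], index=["g"],
                            columns=samples)
        states = pd.DataFrame([np.where(cn.iloc[0] <= -0.35, "loss", "neutral")],
                              index=["g"], columns=samples)
        out = char.cn_expression_response(expr, states, cn)
        assert out.loc["g", "r_cn_expression"] > 0.99


class TestGenomeBurden:
    def _seg(self, rows):
        return pd.DataFrame(rows, columns=["sample", "chromosome", "start",
                                           "end", "log2"])

    def test_half_genome_lost(self):
        seg = self._seg([("T1", "chr1", 0, 500, -1.0), ("T1", "chr1", 500, 1000, 0.0)])
        lengths = pd.Series({"chr1": 1000})
        assert char.fraction_genome_lost(seg, lengths)["T1"] == 0.5

    def test_no_loss_zero(self):
        seg = self._seg([("T1", "chr1", 0, 1000, 0.0)])
        assert char.fraction_genome_lost(seg, pd.Series({"chr1": 1000}))["T1"] == 0.0

    def test_unknown_chromosome_rejected(self):
        seg = self._seg([("T1", "chrX", 0, 10, 0.0)])
        with pytest.raises(ValueError, match="chrX"):
            char.fraction_genome_lost(seg, pd.Series({"chr1": 1000}))

    def test_additive_and_split_invariant(self, rng):
        rows, lengths = [], pd.Series({"chr1": 10_000})
        pos = 0
        for _ in range(10):
            end = pos + int(rng.integers(100, 900))
            rows.append(("T1", "chr1", pos, min(end, 10_000), float(rng.choice([-1, 0]))))
            pos = min(end, 10_000)
        rows[-1] = ("T1", "chr1", rows[-1][2], 10_000, rows[-1][4])
        seg = self._seg(rows)
        base = char.fraction_genome_lost(seg, lengths)["T1"]
        split_rows = []
        for s, c, a, b, v in rows:  # split every segment at its midpoint
            mid = (a + b) // 2
            if mid > a:
                split_rows += [(s, c, a, mid, v), (s, c, mid, b, v)]
            else:
                split_rows.append((s, c, a, b, v))
        split = char.fraction_genome_lost(self._seg(split_rows), lengths)["T1"]
        assert split == pytest.approx(base)


class TestEventSizes:
    def _arms(self):
        return pd.DataFrame({
            "chromosome": ["chr1", "chr1"], "arm": ["p", "q"],
            "start": [0, 400], "end": [400, 1000],
        })

    @pytest.mark.parametrize("start,end,expected", [
        (0, 400, 1.0),    # exactly one arm
        (0, 200, 0.5),    # half an arm
        (400, 1000, 1.0),  # exactly the q arm (length 600)
    ])
    def test_relative_sizes(self, start, end, expected):
        seg = pd.DataFrame([("T1", "chr1", start, end, -1.0)],
                           columns=["sample", "chromosome", "start", "end", "log2"])
        sizes, _, _ = char.event_size_profile(seg, self._arms())
        assert sizes[0] == pytest.approx(expected)

    def test_whole_chromosome_equal_arms_scores_two(self):
        arms = pd.DataFrame({"chromosome": ["chr1"] * 2, "arm": ["p", "q"],
                             "start": [0, 500], "end": [500, 1000]})
        seg = pd.DataFrame([("T1", "chr1", 0, 1000, -1.0)],
                           columns=["sample", "chromosome", "start", "end", "log2"])
        sizes, _, _ = char.event_size_profile(seg, arms)
        assert sizes[0] == 2.0


class TestGenesLost:
    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["a", "b"], "chromosome": ["chr1", "chr1"],
            "arm": ["p", "p"], "start": [0, 500], "end": [100, 600],
        })

    def test_fully_covered_counted(self):
        seg = pd.DataFrame([("T1", "chr1", 0, 200, -1.0)],
                           columns=["sample", "chromosome", "start", "end", "log2"])
        assert char.count_genes_lost(seg, self._genes()) == 1

    def test_forty_percent_overlap_not_counted(self):
        seg = pd.DataFrame([("T1", "chr1", 0, 40, -1.0)],
                           columns=["sample", "chromosome", "start", "end", "log2"])
        assert char.count_genes_lost(seg, self._genes(), overlap_fraction=0.5) == 0

    def test_empty_profile_zero(self):
        seg = pd.DataFrame(columns=["sample", "chromosome", "start", "end", "log2"])
        assert char.count_genes_lost(seg, self._genes()) == 0


class TestEnrichment:
    def test_disjoint_set_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = char.set_enrichment({"g0", "g1"}, universe, {"S": {"g10", "g11"}})
        assert out.loc[0, "p"] == 1.0

    def test_most_extreme_table(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        out = char.set_enrichment(query, universe, {"S": set(query)})
        assert out.loc[0, "p"] == pytest.approx(1 / 15504)

    def test_monotone_in_overlap(self):
        universe = {f"g{i}" for i in range(40)}
        ps = []
        for k in range(1, 6):
            query = {f"g{i}" for i in range(10)}
            member = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(30, 35)}
            out = char.set_enrichment(query, universe, {"S": member})
            ps.append(out.loc[0, "p"])
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_rational_oracle(self, rng):
        universe = {f"g{i}" for i in range(25)}
        query = set(rng.choice(sorted(universe), 8, replace=False))
        member = set(rng.choice(sorted(universe), 10, replace=False))
        out = char.set_enrichment(query, universe, {"S": member})
        k = len(query & member)
        expected = float(hypergeom_tail_oracle(k, 10, 8, 25))
        assert out.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            char.set_enrichment({"zzz"}, {"g1"}, {"S": {"g1"}})


class TestMutualExclusivity:
    def test_perfectly_exclusive_events(self):
        a = [True] * 5 + [False] * 5
        b = [False] * 5 + [True] * 5
        res = char.mutual_exclusivity(a, b)
        assert res["p"] == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_p_one(self):
        res = char.mutual_exclusivity([False] * 10, [True] * 3 + [False] * 7)
        assert res["p"] == 1.0


class TestOverlapProportion:
    def test_all_hits_closed_form(self):
        assert char.overlap_proportion_test(6, 6, 0.3) == pytest.approx(0.3 ** 6)

    def test_zero_hits_p_one(self):
        assert char.overlap_proportion_test(0, 12, 0.4) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rational_summation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 51))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.1, 0.9))
        expected = float(binomial_tail_oracle(k, n, p0))
        assert math.isclose(char.overlap_proportion_test(k, n, p0), expected,
                            rel_tol=1e-9)
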