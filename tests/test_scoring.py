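"""ssGSEA, rank tests, BH FDR, log-rank, TMB, differential expression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grndriver as gd
from grndriver.scoring import (
    bh_fdr,
    differential_expression,
    driver_infiltration_correlation,
    kruskal_wallis,
    lineage_infiltration,
    log_rank,
    response_association,
    ssgsea,
    tmb,
    wilcoxon_rank_sum,
)

from helpers_oracles import brute_bh, brute_ssgsea_score


class TestSsgsea:
    def test_matches_brute_force_enumeration(self, rng):
        expr = pd.DataFrame(
            rng.uniform(1, 100, size=(4, 3)),
            index=["g0", "g1", "g2", "g3"],
            columns=["s0", "s1", "s2"],
        )
        sets = {"S": ["g1", "g3"]}
        scores = ssgsea(expr, sets, alpha=0.25)
        for j, s in enumerate(expr.columns):
            in_set = np.isin(expr.index, sets["S"])
            expected = brute_ssgsea_score(expr[s].to_numpy(), in_set, alpha=0.25)
            assert scores.loc["S", s] == pytest.approx(expected, abs=1e-12)

    def test_top_gene_set_scores_positive(self):
        expr = pd.DataFrame(
            {"s": [40.0, 3.0, 2.0, 1.0]}, index=["top", "a", "b", "c"]
        )
        score = ssgsea(expr, {"S": ["top"]}).loc["S", "s"]
        assert score > 0
        # hand enumeration: positions 1..4, diff = 1, 2/3, 1/3, 0
        assert score == pytest.approx(1 + 2 / 3 + 1 / 3 + 0)

    def test_bottom_genes_score_negative(self):
        expr = pd.DataFrame(
            {"s": [40.0, 30.0, 2.0, 1.0]}, index=["a", "b", "low1", "low2"]
        )
        assert ssgsea(expr, {"S": ["low1", "low2"]}).loc["S", "s"] < 0

    def test_identical_rankings_identical_scores(self, rng):
        base = rng.uniform(1, 10, size=20)
        expr = pd.DataFrame(
            {"s1": base, "s2": base**2}, index=[f"g{i}" for i in range(20)]
        )  # same ranking, different values
        scores = ssgsea(expr, {"S": ["g3", "g7", "g11"]})
        assert scores["s1"].iloc[0] == pytest.approx(scores["s2"].iloc[0], abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(
            rng.uniform(size=(50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(8)],
        )
        sets = {"A": [f"g{i}" for i in range(0, 50, 5)]}
        s1 = ssgsea(expr, sets)
        s2 = ssgsea(np.exp(expr), sets)
        assert np.allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_set_covering_all_genes_rejected(self, small_expr):
        with pytest.raises(ValueError, match="out-set empty"):
            ssgsea(small_expr, {"S": list(small_expr.index)})

    def test_normalization_divides_by_range(self, rng):
        expr = pd.DataFrame(
            rng.uniform(size=(30, 5)),
            index=[f"g{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(5)],
        )
        sets = {"A": ["g0", "g1"], "B": ["g28", "g29"]}
        raw = ssgsea(expr, sets)
        norm = ssgsea(expr, sets, normalize=True)
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        assert np.allclose(norm.to_numpy(), raw.to_numpy() / rng_)


class TestLineageInfiltration:
    def test_spiked_markers_rank_first(self, rng):
        genes = [f"g{i}" for i in range(60)]
        expr = pd.DataFrame(
            rng.uniform(1, 10, size=(60, 4)), index=genes,
            columns=[f"s{j}" for j in range(4)],
        )
        markers = {
            "lymphoid": genes[:5],
            "myeloid": genes[5:10],
            "tumor": genes[10:15],
        }
        expr.loc[markers["lymphoid"], "s0"] = 100.0
        scores = lineage_infiltration(expr, markers)
        assert scores["s0"].idxmax() == "lymphoid"

    def test_absent_marker_set_named_in_error(self, small_expr):
        with pytest.raises(ValueError, match="ghost"):
            lineage_infiltration(small_expr, {"ghost": ["nope1", "nope2"]})


class TestDriverInfiltrationCorrelation:
    def test_perfect_and_inverse_correlation(self):
        scores = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0]], index=["lymphoid"],
            columns=[f"s{j}" for j in range(5)],
        )
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0], [5.0, 4.0, 3.0, 2.0, 1.0]],
            index=["same", "reversed"], columns=scores.columns,
        )
        out = driver_infiltration_correlation(expr, scores).set_index("gene")
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["reversed", "rho"] == pytest.approx(-1.0)

    def test_constant_gene_reported_missing(self):
        scores = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["lin"], columns=list("abcd")
        )
        expr = pd.DataFrame([[7.0, 7.0, 7.0, 7.0]], index=["flat"], columns=list("abcd"))
        out = driver_infiltration_correlation(expr, scores)
        assert np.isnan(out["rho"].iloc[0])

    def test_null_noise_rho_small(self, rng):
        n = 200
        scores = pd.DataFrame(
            rng.normal(size=(3, n)), index=["l", "m", "t"],
            columns=[f"s{j}" for j in range(n)],
        )
        expr = pd.DataFrame(
            rng.normal(size=(25, n)) ** 2, index=[f"g{i}" for i in range(25)],
            columns=scores.columns,
        )
        out = driver_infiltration_correlation(expr, scores)
        assert (out["rho"].abs() < 0.2).mean() >= 0.95


class TestRankTests:
    def test_wilcoxon_exact_small_sample(self):
        # 2 of the C(6,3)=20 equally likely arrangements are as extreme
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_wilcoxon_identical_samples(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_wilcoxon_large_shift_tiny_p(self, rng):
        x = rng.normal(0, 1, 100)
        y = rng.normal(10, 1, 100)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 1e-10

    def test_wilcoxon_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_kruskal_worked_example(self):
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(4.571, abs=5e-4)

    def test_kruskal_shifted_group_significant(self, rng):
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0, 1, 30)
        g3 = rng.normal(3, 1, 30)
        _, p = kruskal_wallis([g1, g2, g3])
        assert p < 0.05

    def test_kruskal_requires_three_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], [3, 4]])


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        assert np.allclose(bh_fdr(pvals), brute_bh(np.asarray(pvals)), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_sorted_q_non_decreasing(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestLogRank:
    def test_identical_groups_null(self):
        times = [5, 8, 12, 20, 25]
        events = [1, 1, 0, 1, 0]
        chi2, p = log_rank(times * 2, events * 2, ["a"] * 5 + ["b"] * 5)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_planted_hazard_difference_detected(self, rng):
        n = 150
        t1 = rng.exponential(1.0, n)
        t2 = rng.exponential(0.5, n)
        c = rng.uniform(0, 2.2, 2 * n)
        times = np.minimum(np.r_[t1, t2], c)
        events = (np.r_[t1, t2] <= c).astype(int)
        _, p = log_rank(times, events, ["a"] * n + ["b"] * n)
        assert p < 0.05

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="events"):
            log_rank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])


class TestTmb:
    def test_class_list_counting(self):
        rows = [("s1", "TP53", "Missense_Mutation")] * 5 + [("s1", "KRAS", "Silent")] * 2
        muts = pd.DataFrame(rows, columns=["sample", "gene", "variant_classification"])
        out = tmb(muts)
        assert out.loc["s1", "tmb"] == 5

    def test_recurrent_gene_counted_once(self):
        muts = pd.DataFrame(
            [("s1", "TP53", "Missense_Mutation"), ("s1", "TP53", "Nonsense_Mutation")],
            columns=["sample", "gene", "variant_classification"],
        )
        out = tmb(muts)
        assert out.loc["s1", "tmb"] == 2
        assert out.loc["s1", "mutated_genes"] == 1

    def test_empty_table_zero_counts(self):
        muts = pd.DataFrame(columns=["sample", "gene", "variant_classification"])
        out = tmb(muts, samples=["s1", "s2"])
        assert (out["tmb"] == 0).all()

    def test_additive_over_partitions(self, bulk_cohort):
        _, _, muts, _ = bulk_cohort
        samples = sorted(muts["sample"].unique())
        half = len(muts) // 2
        t_all = tmb(muts, samples=samples)
        t_a = tmb(muts.iloc[:half], samples=samples)
        t_b = tmb(muts.iloc[half:], samples=samples)
        assert (t_all["tmb"] == t_a["tmb"] + t_b["tmb"]).all()


class TestDifferentialExpression:
    def test_doubled_gene_top_hit(self, rng):
        genes = [f"g{i}" for i in range(20)]
        cols = [f"s{j}" for j in range(40)]
        expr = pd.DataFrame(rng.uniform(10, 20, size=(20, 40)), index=genes, columns=cols)
        expr.loc["g5", cols[:20]] = expr.loc["g5", cols[:20]] * 8 + 50
        labels = pd.Series(["A"] * 20 + ["B"] * 20, index=cols)
        out = differential_expression(expr, labels).set_index("gene")
        assert out["fdr"].idxmin() == "g5"
        assert out.loc["g5", "log2fc"] > 0

    def test_identical_groups_fdr_one(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [5.0, 5.0, 5.0, 5.0]],
            index=["a", "b"], columns=["s1", "s2", "s3", "s4"],
        )
        labels = pd.Series(["A", "A", "B", "B"], index=expr.columns)
        out = differential_expression(expr, labels)
        assert (out["fdr"] == 1.0).all()

    def test_single_gene_fdr_equals_p(self, rng):
        expr = pd.DataFrame(
            rng.uniform(size=(1, 10)), index=["g"], columns=[f"s{j}" for j in range(10)]
        )
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=expr.columns)
        out = differential_expression(expr, labels)
        assert out["fdr"].iloc[0] == out["p"].iloc[0]


class TestResponseAssociation:
    def test_shifted_responders_positive_direction(self, rng):
        n = 60
        resp = pd.Series(["CR", "PR", "SD", "PD"] * 15)
        scores = pd.Series(rng.normal(0, 1, n))
        scores[resp.isin(["CR", "PR"])] += 2.0
        out = response_association(scores, resp)
        assert out["p"] < 0.01
        assert out["direction"] > 0

    def test_null_rejection_rate_nominal(self, rng):
        n = 40
        rejections = 0
        reps = 400
        for _ in range(reps):
            resp = pd.Series(rng.permutation(["CR"] * 20 + ["PD"] * 20))
            scores = pd.Series(rng.normal(size=n))
            if response_association(scores, resp)["p"] < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            response_association(pd.Series([1.0, 2.0]), pd.Series(["CR", "PR"]))
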