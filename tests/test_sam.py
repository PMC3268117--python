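"""Sample partitioning and the SAM permutation engine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenosig import (
    AlignmentError,
    DegenerateInputError,
    ExpressionMatrix,
    SamConfig,
    SAMTwoClass,
    choose_s0,
    fold_change,
    load_gene_list,
    partition_by_proxy,
    sam_d,
    sam_qvalues,
    tf_panel_report,
)
from xenosig.sam import DEGene


def _proxy_mat(values: dict[str, float]) -> ExpressionMatrix:
    df = pd.DataFrame(
        [list(values.values()), [1.0] * len(values)],
        index=["HS_COL11A1", "HS_OTHER"],
        columns=list(values),
    )
    return ExpressionMatrix(
        df, species="human", annotation={"HS_COL11A1": "COL11A1", "HS_OTHER": "OTHER"}
    )


class TestPartition:
    def test_largest_gap_split(self):
        mat = _proxy_mat({"A": 9.0, "B": 8.8, "C": 3.1, "D": 3.0, "E": 2.9})
        part = partition_by_proxy(mat, "COL11A1")
        assert sorted(part.high) == ["A", "B"] and sorted(part.low) == ["C", "D", "E"]

    def test_high_values_dominate_low(self):
        rng = np.random.default_rng(5)
        vals = dict(zip("abcdefgh", rng.normal(8, 2, 8)))
        part = partition_by_proxy(_proxy_mat(vals), "COL11A1")
        assert min(vals[s] for s in part.high) >= max(vals[s] for s in part.low)

    def test_fixed_n_high(self, small_experiment):
        human, _, _ = small_experiment
        part = partition_by_proxy(human, "COL11A1", fixed_n_high=7)
        assert len(part.high) == 7 and len(part.low) == 11

    def test_constant_proxy_degenerate(self):
        mat = _proxy_mat({"A": 2.0, "B": 2.0, "C": 2.0, "D": 2.0})
        with pytest.raises(DegenerateInputError):
            partition_by_proxy(mat, "COL11A1")

    def test_too_few_samples(self):
        mat = _proxy_mat({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(ValueError, match="4 samples"):
            partition_by_proxy(mat, "COL11A1")

    def test_boundary_tie_warns_and_uses_sample_order(self):
        mat = _proxy_mat({"A": 9.0, "B": 5.0, "C": 5.0, "D": 4.9, "E": 1.0})
        with pytest.warns(UserWarning, match="tie"):
            part = partition_by_proxy(mat, "COL11A1", fixed_n_high=2)
        assert sorted(part.high) == ["A", "B"]


class TestSamD:
    def test_equal_means_give_zero(self):
        d, _ = sam_d([2.0, 4.0], [1.0, 5.0], s0=0.5)
        assert d == 0.0

    def test_hand_worked_example(self):
        d, s = sam_d([2.0, 4.0], [1.0, 3.0], s0=0.0)
        assert s == pytest.approx(np.sqrt(2))
        assert d == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert sam_d(a, b, 0.3)[0] == pytest.approx(-sam_d(b, a, 0.3)[0])

    def test_matches_pooled_t_statistic_when_s0_zero(self):
        """With s0 = 0 the relative difference is exactly the two-sample
        pooled-variance t statistic."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = rng.normal(size=6), rng.normal(1, 2, size=9)
            d, _ = sam_d(a, b, 0.0)
            t = stats.ttest_ind(a, b, equal_var=True).statistic
            assert d == pytest.approx(t, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sam_d([1.0], [2.0, 3.0], 0.0)

    def test_zero_scatter_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sam_d([2.0, 2.0], [1.0, 1.0], 0.0)


class TestChooseS0:
    def test_homoscedastic_ties_give_smallest_candidate(self):
        s = np.full(40, 0.7)
        num = np.random.default_rng(0).normal(size=40)
        assert choose_s0(num, s) == pytest.approx(0.7)  # all candidates equal s

    def test_single_candidate_grid(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0.5, 2.0, 50)
        num = rng.normal(size=50)
        assert choose_s0(num, s, grid=(50,)) == pytest.approx(np.percentile(s, 50))

    def test_scatter_dependent_spread_selects_positive_s0(self):
        """Numerators independent of s: small-s genes get inflated d at
        s0 = 0, so the CV objective prefers a large fudge factor.  Checked
        against a brute-force recomputation of the objective."""
        rng = np.random.default_rng(3)
        s = np.sort(rng.uniform(0.05, 5.0, 500))
        num = rng.normal(0, 1, 500)
        chosen = choose_s0(num, s)
        assert chosen > 0

        def objective(cand):
            d = num / (s + cand)
            edges = np.percentile(s, [25, 50, 75])
            bins = np.digitize(s, edges)
            mads = [np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
                    for b in range(4) if np.any(bins == b)]
            return np.std(mads) / np.mean(mads)

        grid_vals = np.percentile(s, np.arange(0, 101, 5))
        brute = grid_vals[int(np.argmin([objective(c) for c in grid_vals]))]
        assert chosen == pytest.approx(brute)

    def test_few_genes_falls_back_to_median(self):
        with pytest.warns(UserWarning, match="median"):
            assert choose_s0([1.0] * 5, [2.0] * 5) == 2.0


def _planted(n_genes=40, n=12, n_high=5, effect=3.0, seed=0, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(8, noise, size=(n, n_genes))
    y = np.zeros(n, dtype=int)
    y[:n_high] = 1
    X[y == 1, 0] += effect  # gene 0 planted up
    return X, y


class TestSAMTwoClass:
    def test_exhaustive_null_is_seed_independent(self):
        X, y = _planted(seed=4)
        a = SAMTwoClass(random_state=1).fit(X, y)
        b = SAMTwoClass(random_state=999).fit(X, y)
        assert a.exhaustive_ and a.n_permutations_ == 792  # C(12, 5)
        np.testing.assert_array_equal(a.q_values_, b.q_values_)
        np.testing.assert_array_equal(a.d_, b.d_)

    def test_sampled_null_is_seeded(self):
        X, y = _planted(n=24, n_high=12, seed=4)
        est = SAMTwoClass(exhaustive_threshold=100, n_permutations=150, random_state=5)
        a = est.fit(X, y)
        qa = a.q_values_.copy()
        b = SAMTwoClass(exhaustive_threshold=100, n_permutations=150, random_state=5).fit(X, y)
        assert not a.exhaustive_ and a.n_permutations_ == 150
        np.testing.assert_array_equal(qa, b.q_values_)

    def test_planted_gene_dominates(self):
        X, y = _planted(effect=5.0, noise=0.3, seed=6)
        est = SAMTwoClass().fit(X, y)
        assert np.nanargmax(np.abs(est.d_)) == 0
        assert est.q_values_[0] == est.q_values_.min()
        assert est.significant_up_[0]

    def test_q_monotone_in_abs_d(self):
        X, y = _planted(n_genes=80, seed=8)
        est = SAMTwoClass().fit(X, y)
        order = np.argsort(-np.abs(est.d_))
        q = est.q_values_[order]
        assert np.all(np.diff(q) >= 0)
        assert np.all((q >= 0) & (q <= 1))

    def test_calling_rule_requires_both_thresholds(self):
        """No gene with fold change inside [1/2, 2] is ever flagged, no
        matter how small its q-value."""
        rng = np.random.default_rng(9)
        X = rng.normal(8, 0.05, size=(12, 30))
        y = np.array([1] * 5 + [0] * 7)
        X[y == 1, 0] += 0.6  # FC 2^0.6 ~ 1.5: tiny q, FC below threshold
        est = SAMTwoClass().fit(X, y)
        inside = (est.fold_change_ >= 0.5) & (est.fold_change_ <= 2.0)
        assert inside[0]
        assert not (est.significant_up_[inside] | est.significant_down_[inside]).any()

    def test_too_few_permutations_refused(self):
        X = np.random.default_rng(0).normal(size=(4, 10))
        y = np.array([1, 1, 0, 0])  # C(4,2) = 6 < 10
        with pytest.raises(ValueError, match="10"):
            SAMTwoClass().fit(X, y)

    def test_degenerate_gene_surfaced_not_ranked(self):
        X, y = _planted(seed=10)
        X[:, 3] = 7.0  # zero scatter everywhere
        est = SAMTwoClass(s0=0.0).fit(X, y)
        assert est.degenerate_[3]
        assert not est.significant_up_[3] and not est.significant_down_[3]
        assert np.isnan(est.d_[3])


class TestFoldChange:
    @pytest.mark.parametrize("diff,expected", [(0.0, 1.0), (1.0, 2.0), (-1.0, 0.5)])
    def test_log2_arithmetic(self, diff, expected):
        assert fold_change(8.0 + diff, 8.0) == pytest.approx(expected)

    def test_printed_value(self):
        assert fold_change(10.384, 8.0) == pytest.approx(5.22, abs=0.01)

    def test_linear_scale_is_plain_ratio(self):
        assert fold_change(6.0, 3.0, scale="linear") == 2.0


class TestWrappers:
    def test_sample_mismatch_raises_alignment_error(self, small_experiment):
        human, _, _ = small_experiment
        part = partition_by_proxy(human, "COL11A1", fixed_n_high=7)
        shifted = ExpressionMatrix(
            human.data.rename(columns={"S01": "WRONG"}),
            species="human",
            annotation=human.annotation,
        )
        with pytest.raises(AlignmentError, match="WRONG"):
            sam_qvalues(shifted, part, SamConfig())

    def test_tf_panel_report(self):
        panel = load_gene_list("emt_tf_panel")
        de = [
            DEGene("SNAI2", 5.0, 10.0, 7.6, 5.22, 0.0003, True, False),
            DEGene("ZEB1", 0.1, 8.0, 7.9, 1.07, 0.9, False, False),
        ]
        rep = tf_panel_report(de, panel)
        assert len(rep) == len(panel)
        snai2 = rep[rep.gene == "SNAI2"].iloc[0]
        assert snai2.significant_up and not snai2.missing
        assert rep[rep.gene == "TWIST1"].iloc[0].missing
        assert not rep[rep.gene == "ZEB1"].iloc[0].significant_up
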