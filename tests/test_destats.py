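"""The permutation-based integrative DE statistic and selection rules."""

import numpy as np
import pandas as pd
import pytest

from amtpipe import destats
from amtpipe.destats import GroupDesign
from amtpipe.errors import DegenerateDesignError, InputError


def design_2x3():
    return GroupDesign(samples=[f"s{i}" for i in range(6)],
                       groups=["WT"] * 3 + ["CKO"] * 3,
                       control="WT", condition="CKO")


def matrix(rows, columns=None):
    columns = columns or [f"s{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=columns,
                        index=[f"f{i}" for i in range(len(rows))])


class TestComputeStatistics:
    def test_identical_groups_zero_statistics(self):
        m = matrix([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        out = destats.compute_statistics(m, design_2x3())
        assert out.at["f0", "t_value"] == 0.0
        assert out.at["f0", "log2_median_ratio"] == 0.0

    def test_hand_computed_t_and_ratio(self):
        # control (1,2,3), condition (3,4,5): pooled sd = 1,
        # t = 2 / sqrt(2/3) = 2.449..., ratio = 4 - 2 = 2
        m = matrix([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
        out = destats.compute_statistics(m, design_2x3())
        assert out.at["f0", "t_value"] == pytest.approx(2.449489742783178)
        assert out.at["f0", "log2_median_ratio"] == pytest.approx(2.0)

    def test_label_swap_flips_signs(self):
        m = matrix([[1.0, 2.0, 3.0, 3.0, 4.0, 5.5]])
        fwd = destats.compute_statistics(m, design_2x3())
        swapped = GroupDesign(samples=[f"s{i}" for i in range(6)],
                              groups=["CKO"] * 3 + ["WT"] * 3,
                              control="WT", condition="CKO")
        rev = destats.compute_statistics(m, swapped)
        assert rev.at["f0", "t_value"] == pytest.approx(-fwd.at["f0", "t_value"])
        assert rev.at["f0", "log2_median_ratio"] == pytest.approx(
            -fwd.at["f0", "log2_median_ratio"])

    def test_insufficient_observations_marked_untestable(self):
        m = matrix([[1.0, np.nan, np.nan, 3.0, 4.0, 5.0],
                    [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
        out = destats.compute_statistics(m, design_2x3())
        assert not out.at["f0", "testable"]
        assert out.at["f1", "testable"]

    def test_zero_variance_unequal_means_flagged_and_capped(self):
        m = matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                    [1.0, 2.0, 3.0, 3.0, 4.0, 5.0]])
        out = destats.compute_statistics(m, design_2x3())
        assert out.at["f0", "zero_variance"]
        assert out.at["f0", "t_value"] == pytest.approx(out.at["f1", "t_value"])
        assert out.at["f0", "t_value"] > 0

    def test_one_group_design_rejected(self):
        d = GroupDesign(samples=["a", "b"], groups=["WT", "WT"],
                        control="WT", condition="CKO")
        with pytest.raises(InputError):
            d.validate()


class TestNull:
    def test_pool_size_bookkeeping(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.normal(size=(10, 6)))
        null = destats.build_null(m, design_2x3(), n_permutations=2, seed=1)
        assert null.null_t.shape == (2, 10)
        assert len(null.t_pool()) == 20
        assert len(null.ratio_pool()) == 20

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        m = matrix(rng.normal(size=(10, 6)))
        a = destats.build_null(m, design_2x3(), n_permutations=5, seed=9)
        b = destats.build_null(m, design_2x3(), n_permutations=5, seed=9)
        np.testing.assert_array_equal(a.null_t, b.null_t)
        np.testing.assert_array_equal(a.null_ratio, b.null_ratio)

    def test_degenerate_design_rejected(self):
        m = matrix([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        d = GroupDesign(samples=["a", "b", "c"], groups=["WT", "WT", "CKO"],
                        control="WT", condition="CKO")
        with pytest.raises((DegenerateDesignError, InputError)):
            destats.build_null(m, d, n_permutations=2, seed=0)

    def test_null_pool_matches_observed_distribution_under_null(self):
        from scipy import stats as sps
        rng = np.random.default_rng(3)
        m = matrix(rng.normal(size=(2000, 6)))
        obs = destats.compute_statistics(m, design_2x3())
        null = destats.build_null(m, design_2x3(), n_permutations=50, seed=3)
        ks = sps.ks_2samp(obs["t_value"], null.t_pool())
        assert ks.pvalue > 0.01
        ks_r = sps.ks_2samp(obs["log2_median_ratio"], null.ratio_pool())
        assert ks_r.pvalue > 0.01


class TestEmpiricalP:
    def test_direct_count_example(self):
        assert destats.empirical_p(1.5, [-2, -1, 0, 1, 2]) == pytest.approx(0.5)

    def test_least_extreme_gives_one(self):
        assert destats.empirical_p(0.0, [-2, -1, 0, 1, 2]) == 1.0

    def test_add_one_rule_floor(self):
        pool = np.arange(999) / 1000.0
        assert destats.empirical_p(5.0, pool) == pytest.approx(1 / 1000)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(1)
        pool = rng.normal(size=500)
        obs = rng.normal(size=20)
        vec = destats.empirical_p(obs, pool)
        for o, p in zip(obs, vec):
            assert destats.empirical_p(float(o), pool) == pytest.approx(p)


class TestStouffer:
    def test_uninformative_inputs_give_one(self):
        z, p = destats.stouffer_combine(1.0, 1.0)
        assert z == pytest.approx(0.0)
        assert p == 1.0

    def test_closed_form_value(self):
        z, p = destats.stouffer_combine(0.05, 0.05, 1.0, 1.0)
        assert abs(z) == pytest.approx(2.771808, abs=1e-5)
        assert p == pytest.approx(0.0055778, abs=1e-4)

    def test_opposite_signs_cancel(self):
        z, p = destats.stouffer_combine(0.05, 0.05, 1.0, -1.0)
        assert z == pytest.approx(0.0)
        assert p == 1.0

    def test_zero_p_rejected(self):
        with pytest.raises(InputError):
            destats.stouffer_combine(0.0, 0.5)

    def test_monotone_in_component_significance(self):
        ps = [0.5, 0.2, 0.1, 0.05, 0.01]
        combined = [destats.stouffer_combine(p, 0.2, 1.0, 1.0)[1] for p in ps]
        assert all(a >= b for a, b in zip(combined, combined[1:]))


class TestDeTest:
    def test_feature_order_invariance(self):
        rng = np.random.default_rng(5)
        m = matrix(rng.normal(size=(50, 6)))
        fwd = destats.de_test(m, design_2x3(), n_permutations=20, seed=2)
        rev = destats.de_test(m.iloc[::-1], design_2x3(), n_permutations=20, seed=2)
        pd.testing.assert_frame_equal(fwd.results.sort_index(),
                                      rev.results.sort_index())

    def test_untestable_features_reported_not_tested(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(5, 6))
        vals[0, :2] = np.nan
        vals[0, 2] = np.nan
        m = matrix(vals)
        de = destats.de_test(m, design_2x3(), n_permutations=10, seed=0)
        assert not de.results.at["f0", "testable"]
        assert np.isnan(de.results.at["f0", "p_overall"])
        assert de.results["testable"].sum() == 4

    def test_planted_feature_gets_smallest_p(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 0.1, size=(200, 6))
        vals[0, 3:] += 3.0
        m = matrix(vals)
        de = destats.de_test(m, design_2x3(), n_permutations=100, seed=1)
        assert de.results["p_overall"].idxmin() == "f0"
        assert de.results.at["f0", "direction"] == "up"


class TestSelection:
    def _results(self, rows):
        df = pd.DataFrame(rows, columns=["p_overall", "log2_median_ratio"])
        df.index = [f"f{i}" for i in range(len(rows))]
        df["testable"] = True
        df["direction"] = np.where(df["log2_median_ratio"] > 0, "up",
                                   np.where(df["log2_median_ratio"] < 0, "down",
                                            "none"))
        return df

    def test_empty_results_give_empty_deg_list(self):
        out, cutoff = destats.select_degs(self._results([]),
                                          null_ratio_pool=np.array([0.1, -0.1, 0.2]))
        assert out["is_de"].sum() == 0

    def test_deg_needs_both_gates(self):
        pool = np.concatenate([np.linspace(-1, 1, 1000)])
        out, cutoff = destats.select_degs(
            self._results([(0.04, 0.1), (0.04, 0.99), (0.2, 0.99)]),
            null_ratio_pool=pool)
        assert cutoff == pytest.approx(np.percentile(pool, 95))
        assert list(out["is_de"]) == [False, True, False]

    def test_all_null_deg_fraction_bounded_by_p_gate(self):
        rng = np.random.default_rng(11)
        m = matrix(rng.normal(size=(3000, 6)))
        de = destats.de_test(m, design_2x3(), n_permutations=200, seed=4)
        out, _ = destats.select_degs(de)
        p_frac = (de.results["p_overall"] < 0.05).mean()
        deg_frac = out["is_de"].mean()
        sd = np.sqrt(0.05 * 0.95 / len(m))
        assert p_frac == pytest.approx(0.05, abs=3 * sd)
        assert deg_frac <= p_frac

    @pytest.mark.parametrize(
        "p,ratio,expected",
        [(0.01, 0.6, True), (0.01, 0.5, False), (0.2, 3.0, False),
         (0.01, -0.58, True)],
    )
    def test_depeptide_fixed_cut(self, p, ratio, expected):
        out = destats.select_depeptides(self._results([(p, ratio)]))
        assert bool(out["is_de"].iloc[0]) is expected

    def _depeptides(self, spec):
        """spec: list of (seq, direction, protein, proteotypic)"""
        rows = []
        meta = []
        for seq, direction, protein, proto in spec:
            rows.append({"p_overall": 0.01,
                         "log2_median_ratio": 1.0 if direction == "up" else -1.0,
                         "testable": True, "direction": direction, "is_de": True})
            meta.append({"peptide_seq": seq, "protein_ids": (protein,),
                         "proteotypic": proto})
        df = pd.DataFrame(rows, index=[s[0] for s in spec])
        return df, pd.DataFrame(meta)

    def test_two_up_peptides_make_a_dep(self):
        df, meta = self._depeptides([("A", "up", "P1", True), ("B", "up", "P1", True)])
        deps, conflicts = destats.select_deps(df, meta)
        assert list(deps["protein_id"]) == ["P1"]
        assert list(deps["direction"]) == ["up"]
        assert conflicts.empty

    def test_one_up_one_down_is_not_a_dep(self):
        df, meta = self._depeptides([("A", "up", "P1", True), ("B", "down", "P1", True)])
        deps, conflicts = destats.select_deps(df, meta)
        assert deps.empty and conflicts.empty

    def test_two_up_two_down_is_a_conflict(self):
        df, meta = self._depeptides([
            ("A", "up", "P1", True), ("B", "up", "P1", True),
            ("C", "down", "P1", True), ("D", "down", "P1", True),
        ])
        deps, conflicts = destats.select_deps(df, meta)
        assert deps.empty
        assert list(conflicts["protein_id"]) == ["P1"]

    def test_non_proteotypic_peptides_do_not_count(self):
        df, meta = self._depeptides([("A", "up", "P1", True), ("B", "up", "P1", False)])
        deps, _ = destats.select_deps(df, meta)
        assert deps.empty

    def test_min_unique_configurable(self):
        df, meta = self._depeptides([("A", "up", "P1", True)])
        deps, _ = destats.select_deps(df, meta, min_unique=1)
        assert list(deps["protein_id"]) == ["P1"]
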