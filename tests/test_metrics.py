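"""Overyielding metrics: worked example, identities, filters, contributions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overyield import metrics

# the canonical two-species plot used throughout: O observed in mixture,
# M monoculture means, p sown proportions
O2, M2, P2 = np.array([150.0, 40.0]), np.array([200.0, 100.0]), np.array([0.5, 0.5])


def plots(min_n=2, max_n=8):
    """Random plot strategy: aligned positive O, M and equal sowing."""
    return st.integers(min_n, max_n).flatmap(
        lambda n: st.tuples(
            st.lists(st.floats(0.1, 1e3), min_size=n, max_size=n),
            st.lists(st.floats(0.1, 1e3), min_size=n, max_size=n),
        )
    )


class TestSpeciesLnrr:
    def test_worked_example_matches_direct_log_evaluation(self):
        got = metrics.species_lnrr(O2, M2, P2)
        assert got[0] == pytest.approx(math.log(150 / (200 * 0.5)), abs=1e-12)
        assert got[1] == pytest.approx(math.log(40 / (100 * 0.5)), abs=1e-12)
        assert got == pytest.approx([0.405465, -0.223144], abs=1e-6)

    def test_zero_at_expected_performance(self):
        assert metrics.species_lnrr(60.0, 120.0, 0.5) == pytest.approx(0.0, abs=1e-15)

    def test_nonpositive_inputs_are_nan_not_errors(self):
        assert np.isnan(metrics.species_lnrr(0.0, 100.0, 0.5))
        assert np.isnan(metrics.species_lnrr(10.0, 0.0, 0.5))

    def test_monoculture_proportion_rejected(self):
        with pytest.raises(ValueError, match="mixtures"):
            metrics.species_lnrr(10.0, 10.0, 1.0)

    def test_equals_log_relative_yield_over_p(self):
        # lnRR = ln(RY_i / p_i) with RY_i = O/M, and D_i = exp(lnRR) - 1
        lnrr = metrics.species_lnrr(O2, M2, P2)
        ry = O2 / M2
        np.testing.assert_allclose(lnrr, np.log(ry / P2), rtol=1e-12)
        d_i = O2 / (M2 * P2) - 1
        np.testing.assert_allclose(np.exp(lnrr) - 1, d_i, rtol=1e-12)


class TestCommunityLnrr:
    def test_worked_example(self):
        assert metrics.community_lnrr(O2, M2, P2) == pytest.approx(
            math.log(190 / 150), abs=1e-9
        )

    def test_zero_when_all_species_at_expectation(self):
        assert metrics.community_lnrr(M2 * P2, M2, P2) == pytest.approx(0.0, abs=1e-15)

    def test_invariant_to_within_plot_allocation(self):
        assert metrics.community_lnrr([190.0, 0.0], M2, P2) == pytest.approx(
            metrics.community_lnrr(O2, M2, P2)
        )

    def test_equals_log1p_total_deviation(self):
        # community lnRR = ln(1 + D_T), D_T = (ΣO - ΣE)/ΣE
        e = (M2 * P2).sum()
        d_t = (O2.sum() - e) / e
        assert metrics.community_lnrr(O2, M2, P2) == pytest.approx(np.log1p(d_t))


class TestAdditivePartition:
    def test_worked_example_hand_values(self):
        ne, ce, se = metrics.partition_additive(O2, M2, P2)
        # brute-force identity: NE must equal sum(O) - sum(M*p) = 190 - 150
        assert ne == pytest.approx(190 - 150, abs=1e-9)
        assert ce == pytest.approx(22.5, abs=1e-9)
        assert se == pytest.approx(17.5, abs=1e-9)

    def test_null_plot_partitions_to_zero(self):
        ne, ce, se = metrics.partition_additive(M2 * P2, M2, P2)
        assert (ne, ce, se) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    def test_equal_monocultures_have_zero_selection(self):
        ne, ce, se = metrics.partition_additive([80.0, 30.0, 40.0], [100.0] * 3, [1 / 3] * 3)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert ne == pytest.approx(ce)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(plots())
    def test_identity_ne_equals_deltay_and_ce_plus_se(self, om):
        O, M = (np.asarray(v) for v in om)
        p = np.full(len(O), 1.0 / len(O))
        ne, ce, se = metrics.partition_additive(O, M, p)
        dy = O.sum() - (M * p).sum()
        assert ne == pytest.approx(dy, rel=1e-9, abs=1e-9)
        assert ne == pytest.approx(ce + se, rel=1e-9, abs=1e-9)
        # sign(community lnRR) agrees with sign(ΔY)
        clnrr = metrics.community_lnrr(O, M, p)
        assert np.sign(clnrr) == pytest.approx(np.sign(dy)) or dy == 0

    def test_increasing_any_observation_increases_ne_and_lnrr(self, rng):
        O = rng.uniform(10, 100, 5)
        M = rng.uniform(50, 200, 5)
        p = np.full(5, 0.2)
        base_ne = metrics.partition_additive(O, M, p)[0]
        base_c = metrics.community_lnrr(O, M, p)
        O2_ = O.copy()
        O2_[2] *= 1.5
        assert metrics.partition_additive(O2_, M, p)[0] > base_ne
        assert metrics.community_lnrr(O2_, M, p) > base_c
        assert metrics.species_lnrr(O2_, M, p)[2] > metrics.species_lnrr(O, M, p)[2]


class TestPercentileFilter:
    def test_seeded_normal_sample_matches_quantile_oracle(self, rng):
        v = rng.standard_normal(1000)
        kept, removed, (qlo, qhi) = metrics.filter_percentile(v)
        # independent oracle: count points outside the numpy quantiles
        expect = np.flatnonzero((v < np.quantile(v, 0.005)) | (v > np.quantile(v, 0.995)))
        np.testing.assert_array_equal(removed, expect)
        assert len(removed) == 10  # 5 per tail on 1000 continuous draws
        assert len(kept) + len(removed) == 1000

    def test_degenerate_equal_values_remove_nothing(self):
        kept, removed, _ = metrics.filter_percentile(np.ones(50))
        assert len(removed) == 0

    def test_two_extremes_removed(self):
        v = np.array([-10.0] + [0.0] * 98 + [10.0])
        _, removed, _ = metrics.filter_percentile(v)
        assert sorted(removed) == [0, 99]

    def test_tiny_samples_left_alone(self):
        kept, removed, _ = metrics.filter_percentile([1.0, 2.0])
        assert len(kept) == 2 and len(removed) == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(10, 400), st.integers(0, 2**31 - 1))
    def test_removal_fraction_bounded(self, n, seed):
        v = np.random.default_rng(seed).standard_normal(n)
        _, removed, _ = metrics.filter_percentile(v)
        assert len(removed) <= (0.005 + 0.005) * n + 2


class TestProportionOveryielding:
    @pytest.mark.parametrize(
        "lnrrs, po, group",
        [
            ([0.4, -0.2], 0.5, "ge_half"),
            ([0.4, 0.1, 0.2], 1.0, "all"),
            ([0.4, -0.1, -0.1, -0.1], 0.25, "lt_half"),
            ([0.9, 0.9, -0.1], 2 / 3, "ge_half"),
        ],
    )
    def test_count_oracle_and_grouping(self, lnrrs, po, group):
        got_po, got_group = metrics.proportion_overyielding(lnrrs, 0.3)
        assert got_po == pytest.approx(po)
        assert got_group == group

    def test_undefined_for_non_overyielding_community(self):
        po, group = metrics.proportion_overyielding([0.4, -0.2], -0.1)
        assert np.isnan(po) and group is None

    def test_undefined_lnrr_counts_as_non_overyielding_in_sown_richness(self):
        po, group = metrics.proportion_overyielding([0.4, np.nan], 0.3, richness=2)
        assert po == pytest.approx(0.5) and group == "ge_half"


class TestCoMax:
    def test_worked_example_direct_evaluation(self):
        cmax, contrib, imax = metrics.co_max(O2, M2, P2)
        assert cmax == pytest.approx((150 - 100) / 40)  # = 1.25, exceeds 1
        np.testing.assert_allclose(contrib, [1.25, -0.25], rtol=1e-12)
        assert contrib.sum() == pytest.approx(1.0)
        assert imax == 0

    def test_symmetric_overyielding_gives_one_over_n(self):
        n = 4
        M = np.full(n, 100.0)
        p = np.full(n, 1.0 / n)
        O = M * p * 1.3  # every species overyields equally
        cmax, contrib, _ = metrics.co_max(O, M, p)
        assert cmax == pytest.approx(1.0 / n)

    def test_partial_contribution_between_zero_and_one(self):
        # deviations (25, 15): max-lnRR species holds the 25
        O = np.array([50.0 + 25.0, 50.0 + 15.0])
        M = np.array([100.0, 100.0])
        p = np.array([0.5, 0.5])
        cmax, contrib, _ = metrics.co_max(O, M, p)
        assert cmax == pytest.approx(25 / 40) == pytest.approx(0.625)

    def test_zero_delta_y_undefined(self):
        cmax, contrib, imax = metrics.co_max(M2 * P2, M2, P2)
        assert np.isnan(cmax) and imax == -1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(plots())
    def test_contributions_sum_to_one_whatever_the_signs(self, om):
        O, M = (np.asarray(v) for v in om)
        p = np.full(len(O), 1.0 / len(O))
        dy = O.sum() - (M * p).sum()
        if dy == 0:
            return
        _, contrib, _ = metrics.co_max(O, M, p)
        assert contrib.sum() == pytest.approx(1.0, rel=1e-9)


class TestComputeOveryielding:
    def test_tables_consistent_with_componentwise_functions(self, grassland_metrics):
        st_, ct, summary, _ = grassland_metrics
        # community NE identity on every plot-year
        ok = np.isfinite(ct["NE"])
        np.testing.assert_allclose(ct.loc[ok, "NE"], ct.loc[ok, "CE"] + ct.loc[ok, "SE"],
                                   rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(ct.loc[ok, "NE"], ct.loc[ok, "delta_y"],
                                   rtol=1e-9, atol=1e-9)
        # per-plot contributions sum to 1
        grp = st_[np.isfinite(st_["contribution"])].groupby(["site", "plot", "year"])
        sums = grp["contribution"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-9)

    def test_po_defined_exactly_for_overyielding_communities(self, grassland_metrics):
        _, ct, _, _ = grassland_metrics
        over = ct["community_lnrr"] > 0
        assert ct.loc[over, "PO"].notna().all()
        assert ct.loc[~over, "PO"].isna().all()

    def test_exclusion_summary_counts_match_table(self, grassland_metrics):
        st_, _, summary, _ = grassland_metrics
        assert sum(summary["exclusions"].values()) == int(st_["excluded"].sum())
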