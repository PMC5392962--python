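"""Statistics layer: odds and intervals, score test, ranks, cross-tabs,
bilateral symmetry, and t-test oracles."""

import numpy as np
import pytest

import mammoquad as mq
from mammoquad.cohort import CohortRecord
from mammoquad.density import QuadrantProfile
from mammoquad.errors import InputError


def profile_from(da, pd=None, ba=None):
    """QuadrantProfile from per-quadrant DA values (UO, UI, LO, LI); BA is
    chosen so PD comes out as requested (default: BA = 10*DA)."""
    da = dict(zip(mq.QUADRANTS, da))
    if ba is None:
        if pd is None:
            ba = {q: 10 * max(da[q], 0.1) for q in mq.QUADRANTS}
        else:
            pd = dict(zip(mq.QUADRANTS, pd))
            ba = {q: 100 * da[q] / pd[q] for q in mq.QUADRANTS}
    else:
        ba = dict(zip(mq.QUADRANTS, ba))
    return QuadrantProfile.from_areas(ba, da)


class TestQuadrantOdds:
    def test_even_split_gives_unit_odds(self):
        est = mq.quadrant_odds(55, 110)
        assert est.odds == 1.0

    def test_ci_brackets_estimate(self):
        for n in (1, 10, 55, 80, 109):
            est = mq.quadrant_odds(n, 110)
            assert est.ci_low <= est.odds <= est.ci_high

    def test_ci_shrinks_with_n(self):
        """Fixed proportion, growing N: the interval narrows monotonically."""
        widths = []
        for scale in (1, 2, 4, 8):
            est = mq.quadrant_odds(20 * scale, 110 * scale)
            widths.append(np.log(est.ci_high) - np.log(est.ci_low))
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_boundary_counts_flagged(self):
        with pytest.warns(UserWarning):
            est = mq.quadrant_odds(0, 10)
        assert est.continuity_corrected
        with pytest.raises(InputError):
            mq.quadrant_odds(11, 10)


class TestProportionsTest:
    def test_exact_null(self):
        res = mq.proportions_difference_test([25, 25, 25, 25])
        assert res["statistic"] == 0.0
        assert res["p_value"] == 1.0

    def test_hand_computed_chi_square(self):
        """(40,30,20,10): sum (o-e)^2/e with e = 25 equals 20."""
        res = mq.proportions_difference_test([40, 30, 20, 10])
        assert res["statistic"] == pytest.approx(20.0)

    def test_pairwise_bonferroni(self):
        res = mq.proportions_difference_test([67, 16, 7, 20])
        pair = res["pairwise"]
        assert len(pair) == 6
        assert np.all(pair["p_adj"] >= pair["p_raw"] - 1e-15)
        assert np.all(pair["p_adj"] <= 1.0 + 1e-15)

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            mq.proportions_difference_test([0, 0, 0, 0])


class TestRanks:
    def test_descending_values(self):
        prof = profile_from([7.1, 6.0, 5.3, 4.3])
        assert mq.rank_quadrants(prof, "DA") == {
            "UO": 1, "UI": 2, "LO": 3, "LI": 4}

    def test_tie_rule_fixed_quadrant_order(self):
        prof = profile_from([5.0, 5.0, 5.0, 5.0])
        assert mq.rank_quadrants(prof, "DA") == {
            "UO": 1, "UI": 2, "LO": 3, "LI": 4}

    def test_always_a_permutation(self, rng):
        """1000 random profiles: the rank vector is a permutation of
        1..4 and agrees with a sorting oracle."""
        for _ in range(1000):
            da = rng.uniform(0.5, 10, 4)
            prof = profile_from(da)
            ranks = mq.rank_quadrants(prof, "DA")
            assert sorted(ranks.values()) == [1, 2, 3, 4]
            order = np.argsort(-da, kind="stable")
            for pos, qi in enumerate(order):
                assert ranks[mq.QUADRANTS[qi]] == pos + 1

    def test_undefined_pd_excluded(self):
        prof = QuadrantProfile.from_areas(
            ba={"UO": 0.0, "UI": 10, "LO": 10, "LI": 10},
            da={"UO": 0.0, "UI": 1, "LO": 1, "LI": 1})
        with pytest.raises(InputError):
            mq.rank_quadrants(prof, "PD")


def certainty_cohort(n=20):
    """Every woman has tumor in UO and maximal UO dense area."""
    return [CohortRecord(
        woman_id=f"W{i}", tumor_quadrant="UO",
        normal_breast=profile_from([9.0, 6.0, 5.0, 4.0]))
        for i in range(n)]


class TestCrossTab:
    def test_constructed_certainty(self):
        with pytest.warns(UserWarning):  # three empty tumor groups
            ct = mq.build_rank_crosstab(certainty_cohort(15), "DA")
        np.testing.assert_array_equal(ct.counts[0], [15, 0, 0, 0])
        assert ct.counts.sum() == 15

    def test_conservation(self, default_cohort):
        ct = mq.build_rank_crosstab(default_cohort, "DA")
        assert ct.counts.sum() + ct.n_excluded == len(default_cohort)

    def test_self_consistency_with_summary(self, default_cohort):
        """Tumor-in-highest-DA equals the rank-1 column sum of the DA
        cross-tab."""
        ct = mq.build_rank_crosstab(default_cohort, "DA")
        summary = mq.highest_quadrant_summary(default_cohort)
        assert summary.loc["tumor_in_highest_DA"].sum() == ct.counts[:, 0].sum()
        assert summary.loc["tumor_location"].sum() == len(default_cohort)

    def test_permutation_oracle(self, rng):
        """With tumor labels shuffled uniformly, the expected proportions of
        row g equal the cohort's marginal rank frequencies of quadrant g."""
        recs = mq.generate_cohort(mq.CohortSpec(n_women=60, seed=17))
        marg = np.zeros((4, 4))
        for r in recs:
            ranks = mq.rank_quadrants(r.normal_breast, "DA")
            for g, q in enumerate(mq.QUADRANTS):
                marg[g, ranks[q] - 1] += 1
        marg /= len(recs)
        acc = np.zeros((4, 4))
        n_shuffles = 1000
        for _ in range(n_shuffles):
            labels = rng.choice(list(mq.QUADRANTS), size=len(recs))
            shuffled = [CohortRecord(woman_id=r.woman_id,
                                     tumor_quadrant=lab,
                                     normal_breast=r.normal_breast)
                        for r, lab in zip(recs, labels)]
            ct = mq.build_rank_crosstab(shuffled, "DA")
            with np.errstate(invalid="ignore"):
                acc += np.nan_to_num(ct.row_proportions)
        acc /= n_shuffles
        # every row's average proportions converge to its quadrant's
        # marginal rank distribution
        for g in range(4):
            np.testing.assert_allclose(acc[g], marg[g], atol=0.06)

    def test_single_woman_summary(self):
        recs = certainty_cohort(1)
        summary = mq.highest_quadrant_summary(recs)
        assert set(np.unique(summary.values)) <= {0, 1}
        assert summary.loc["tumor_location"].sum() == 1


class TestBilateralSymmetry:
    def test_perfect_correlation(self):
        recs = mq.generate_cohort(
            mq.CohortSpec(n_women=20, bilateral_correlation=1.0, seed=3))
        res = mq.bilateral_symmetry(recs)
        assert res["r"] == pytest.approx(1.0, abs=1e-12)
        assert res["n_pairs"] == 60

    def test_permutation_null(self, rng):
        """Pairing a woman's diseased-breast PDs with an unrelated woman's
        normal breast destroys the bilateral association.

        The pooled pairs are not exchangeable draws: members of a pair
        share the quadrant mean, and each woman contributes three
        intra-correlated values. The null band therefore uses
        quadrant-centred values and the clustered variance
        (1 + (m-1) rho^2) / n_pairs with cluster size m = 3."""
        recs = mq.generate_cohort(mq.CohortSpec(n_women=110, seed=19))
        perm = rng.permutation(len(recs))
        q_means = {q: np.mean([r.normal_breast.pd[q] for r in recs])
                   for q in mq.QUADRANTS}
        xs, ys = [], []
        for a, j in zip(recs, perm):
            for q in mq.QUADRANTS:
                if q == a.tumor_quadrant:
                    continue
                xs.append(a.diseased_breast.pd[q] - q_means[q])
                ys.append(recs[j].normal_breast.pd[q] - q_means[q])
        r_null = np.corrcoef(xs, ys)[0, 1]
        rho = mq.CohortSpec().intra_breast_correlation_PD
        band = 3.0 * np.sqrt((1 + 2 * rho**2) / len(xs))
        assert abs(r_null) < band

    def test_too_few_pairs(self):
        with pytest.raises(InputError):
            mq.bilateral_symmetry(certainty_cohort(2))


class TestComparisonTests:
    def test_identical_paired_samples(self):
        recs = certainty_cohort(10)
        # duplicate a quadrant so a paired comparison is exactly zero
        frame = mq.quadrant_comparison_tests(recs)
        row = frame[(frame.kind == "paired") & (frame.variable == "DA")
                    & (frame.comparison == "UO vs UI")].iloc[0]
        # constant non-zero difference: degenerate, flagged
        assert row.skipped or row.p_value <= 1.0

    def test_exact_zero_difference(self):
        prof = profile_from([5.0, 5.0, 3.0, 2.0])
        recs = [CohortRecord(woman_id=f"W{i}", tumor_quadrant="UO",
                             normal_breast=prof) for i in range(6)]
        frame = mq.quadrant_comparison_tests(recs)
        row = frame[(frame.kind == "paired") & (frame.variable == "DA")
                    & (frame.comparison == "UO vs UI")].iloc[0]
        assert row.t == 0.0 and row.p_value == 1.0

    def test_closed_form_paired_t(self):
        """Five-pair toy sample matches t = dbar / (s_d / sqrt(n))."""
        uo = np.array([5.0, 6.0, 7.0, 5.5, 6.5])
        ui = np.array([4.0, 6.5, 6.0, 5.0, 5.0])
        recs = []
        for i, (a, b) in enumerate(zip(uo, ui)):
            recs.append(CohortRecord(
                woman_id=f"W{i}", tumor_quadrant="UO",
                normal_breast=profile_from([a, b, 1.0, 0.5])))
        frame = mq.quadrant_comparison_tests(recs)
        row = frame[(frame.kind == "paired") & (frame.variable == "DA")
                    & (frame.comparison == "UO vs UI")].iloc[0]
        d = uo - ui
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert row.t == pytest.approx(t_expected, rel=1e-12)

    def test_uo_vs_lo_ba_power(self):
        """At the default effect sizes and n = 110, the paired UO vs LO BA
        comparison is significant in >= 95% of 100 replicates."""
        hits = 0
        for seed in range(100):
            recs = mq.generate_cohort(mq.CohortSpec(n_women=110, seed=seed))
            frame = mq.quadrant_comparison_tests(recs)
            row = frame[(frame.kind == "paired") & (frame.variable == "BA")
                        & (frame.comparison == "UO vs LO")].iloc[0]
            if row.p_value < 0.05:
                hits += 1
        assert hits >= 95
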