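import numpy as np
import pytest

from conftest import make_table
from oracles import grid_log_odds_median, quad_binomial_log_evidence
from replibayes.contingency_bayes import (
    ContingencyTable2x2,
    GunelDickeyConfig,
    PosteriorSummary,
    bf_one_sided,
    bf_two_sided,
    direction_probability,
    dm_log_evidence,
    posterior_contrast,
)


class TestMarginalLikelihood:
    def test_uniform_prior_single_trial(self):
        # ∫ p(1−p) dp = 1/6
        assert dm_log_evidence([1, 1], a=1.0) == pytest.approx(np.log(1 / 6))

    @pytest.mark.parametrize("n", [1, 4, 9])
    def test_uniform_marginal_over_counts(self, n):
        # with a = 1 every count 0..n is equally likely: evidence 1/(n+1)
        assert dm_log_evidence([0, n], a=1.0) == pytest.approx(np.log(1 / (n + 1)))

    def test_row_against_quadrature(self):
        got = dm_log_evidence([12, 30], a=1.0)
        assert got == pytest.approx(quad_binomial_log_evidence(12, 30), abs=1e-6)

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            dm_log_evidence([1, 2], a=0.0)

    def test_shared_pools_rows(self):
        pooled = dm_log_evidence([[3, 2], [1, 4]], shared=True)
        assert pooled == pytest.approx(dm_log_evidence([4, 6]))


class TestTwoSided:
    def test_identical_rows_favour_null(self):
        res = bf_two_sided(make_table(10, 20, 10, 20))
        assert res.bf10 < 1

    def test_group_swap_symmetry(self):
        t = make_table(12, 42, 22, 54)
        assert bf_two_sided(t).bf10 == pytest.approx(bf_two_sided(t.swapped()).bf10)

    def test_against_quadrature(self):
        t = make_table(12, 42, 22, 54)
        res = bf_two_sided(t)
        log_alt = quad_binomial_log_evidence(12, 30) + quad_binomial_log_evidence(22, 32)
        log_null = quad_binomial_log_evidence(34, 62)
        assert res.bf10 == pytest.approx(np.exp(log_alt - log_null), abs=1e-4)

    def test_large_concentration_shrinks_evidence_toward_null(self):
        # on a strongly discordant table the data favour the alternative;
        # as a grows the prior dominates and the evidence drains away
        t = make_table(40, 50, 10, 50)
        bfs = [bf_two_sided(t, a=a).bf10 for a in (1, 10, 100)]
        assert bfs[0] > bfs[1] > bfs[2] > 1


class TestOneSided:
    def test_direction_probabilities_sum_to_one(self):
        t = make_table(12, 42, 22, 54)
        p1 = direction_probability(t, t.group_labels[0], method="quad")
        p2 = direction_probability(t, t.group_labels[1], method="quad")
        assert p1 + p2 == pytest.approx(1.0, abs=1e-8)

    def test_sampled_probability_agrees_with_quadrature(self):
        t = make_table(12, 42, 22, 54)
        pq = direction_probability(t, t.group_labels[0], method="quad")
        ps = direction_probability(
            t, t.group_labels[0], method="sample", n_samples=200_000, seed=3
        )
        assert ps == pytest.approx(pq, abs=0.005)

    def test_balanced_table_has_symmetric_direction(self):
        t = make_table(10, 40, 10, 40)
        cfg = GunelDickeyConfig(direction=t.group_labels[0], method="quad")
        res = bf_one_sided(t, cfg)
        assert res.bf_plus0 == pytest.approx(res.bf10, rel=1e-6)
        assert res.bf_0plus * res.bf_plus0 == pytest.approx(1.0)

    def test_unknown_direction_rejected(self):
        t = make_table(1, 2, 1, 2)
        with pytest.raises(ValueError):
            bf_one_sided(t, GunelDickeyConfig(direction="nobody"))


def test_closed_form_matches_quadrature_on_all_small_tables():
    """Exhaustive sweep: every 2×2 table with cell entries ≤ 5."""
    cache = {}

    def q(y, f):
        if (y, f) not in cache:
            cache[(y, f)] = quad_binomial_log_evidence(y, f)
        return cache[(y, f)]

    for a in range(6):
        for b in range(6):
            for c in range(6):
                for d in range(6):
                    if a + b == 0 or c + d == 0:
                        continue
                    rows = [[a, b], [c, d]]
                    assert dm_log_evidence(rows) == pytest.approx(
                        q(a, b) + q(c, d), abs=1e-6
                    )
                    assert dm_log_evidence(rows, shared=True) == pytest.approx(
                        q(a + c, b + d), abs=1e-6
                    )


class TestPosteriorContrast:
    def test_symmetric_table_centres_on_zero(self):
        t = make_table(15, 40, 15, 40)
        cfg = GunelDickeyConfig(seed=5)
        s = posterior_contrast(t, cfg, "log_odds_ratio")
        assert abs(s.median) < 0.02
        assert s.ci_low < 0 < s.ci_high

    def test_log_odds_median_matches_grid_oracle(self):
        t = make_table(50, 100, 25, 100)
        cfg = GunelDickeyConfig(seed=8, n_posterior_samples=400_000)
        s = posterior_contrast(t, cfg, "log_odds_ratio")
        oracle = grid_log_odds_median(51, 51, 26, 76)
        assert s.median == pytest.approx(oracle, abs=0.01)

    def test_reproducible_under_fixed_seed(self):
        t = make_table(12, 42, 22, 54)
        cfg = GunelDickeyConfig(seed=11)
        a = posterior_contrast(t, cfg, "proportion_difference")
        b = posterior_contrast(t, cfg, "proportion_difference")
        assert (a.median, a.ci_low, a.ci_high) == (b.median, b.ci_low, b.ci_high)

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError):
            PosteriorSummary("x", median=1.0, ci_low=0.0, ci_high=0.5)


class TestTableValidation:
    @pytest.mark.parametrize(
        "successes, totals",
        [((5, 1), (4, 10)), ((-1, 0), (4, 10)), ((0, 0), (0, 10))],
    )
    def test_invalid_counts_rejected(self, successes, totals):
        with pytest.raises(ValueError):
            ContingencyTable2x2(("a", "b"), successes, totals)
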