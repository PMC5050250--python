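import numpy as np
import pytest

from oracles import folded_null_effect_mean, selected_abs_effect, two_look_stop_rate
from replibayes.qrp_simulator import (
    OptionalStoppingDesign,
    PublicationFilter,
    QRPWorldConfig,
    apply_harking,
    apply_publication_bias,
    simulate_optional_stopping,
    simulate_publication_record,
)


class TestOptionalStopping:
    @pytest.mark.parametrize("test", ["one_sample", "two_sample"])
    def test_single_look_holds_nominal_level(self, test):
        design = OptionalStoppingDesign(
            n_min=40, n_max=40, test=test, n_sims=20_000, seed=1
        )
        rate = simulate_optional_stopping(design).false_positive_rate
        se = np.sqrt(0.05 * 0.95 / design.n_sims)
        assert abs(rate - 0.05) < 3 * se

    def test_two_looks_match_brute_force_oracle(self):
        design = OptionalStoppingDesign(
            n_min=25, n_max=50, step=25, n_sims=20_000, seed=2
        )
        rate = simulate_optional_stopping(design).false_positive_rate
        oracle = two_look_stop_rate(25, 50, 0.05, 40_000, seed=777)
        tol = 3 * np.sqrt(rate * (1 - rate) / 20_000 + oracle * (1 - oracle) / 40_000)
        assert abs(rate - oracle) < tol

    def test_continuous_peeking_inflates_false_positives(self):
        design = OptionalStoppingDesign(n_min=10, n_max=50, step=1, n_sims=20_000, seed=3)
        rate = simulate_optional_stopping(design).false_positive_rate
        assert 0.15 < rate < 0.40  # far above the nominal 5%

    def test_rate_nondecreasing_in_peeks_under_common_random_numbers(self):
        rates = []
        for step, n_min in ((50, 50), (25, 25), (5, 10), (1, 10)):
            design = OptionalStoppingDesign(
                n_min=n_min, n_max=50, step=step, n_sims=10_000, seed=9
            )
            rates.append(simulate_optional_stopping(design).false_positive_rate)
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_power_grows_with_true_effect(self):
        null = simulate_optional_stopping(
            OptionalStoppingDesign(n_min=20, n_max=20, n_sims=5_000, seed=4)
        )
        strong = simulate_optional_stopping(
            OptionalStoppingDesign(
                n_min=20, n_max=20, true_effect=0.8, n_sims=5_000, seed=4
            )
        )
        assert strong.false_positive_rate > 0.5 > null.false_positive_rate

    def test_bit_reproducible(self):
        design = OptionalStoppingDesign(n_sims=500, seed=123)
        a = simulate_optional_stopping(design)
        b = simulate_optional_stopping(design)
        assert np.array_equal(a.p_values, b.p_values)
        assert np.array_equal(a.stop_n, b.stop_n)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            OptionalStoppingDesign(n_min=50, n_max=10)
        with pytest.raises(ValueError):
            OptionalStoppingDesign(step=0)


class TestPublicationBias:
    def test_full_reporting_is_identity(self):
        p = np.array([0.01, 0.2, 0.8])
        e = np.array([0.5, 0.1, -0.2])
        out = apply_publication_bias(p, e, PublicationFilter(1.0), seed=0)
        assert out["n_published"] == 3
        assert np.array_equal(out["published_effects"], e)

    def test_zero_reporting_keeps_only_significant(self):
        p = np.array([0.01, 0.2, 0.04, 0.8])
        e = np.arange(4.0)
        out = apply_publication_bias(p, e, PublicationFilter(0.0), seed=0)
        assert np.array_equal(out["published_p_values"], [0.01, 0.04])

    def test_selection_inflates_null_effects_to_oracle_level(self):
        rng = np.random.default_rng(5)
        n, n_sims = 20, 40_000
        x = rng.standard_normal((n_sims, n))
        y = rng.standard_normal((n_sims, n))
        sp2 = (x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2
        d = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(sp2)
        from scipy import stats

        p = 2 * stats.t.sf(np.abs(d) * np.sqrt(n / 2), 2 * n - 2)
        out = apply_publication_bias(p, d, PublicationFilter(0.0), seed=1)
        published = np.abs(out["published_effects"]).mean()
        assert published > np.abs(d).mean()  # inflation is non-negative
        oracle = selected_abs_effect(n, 0.05, 80_000, seed=314)
        k = out["n_published"]
        tol = 3 * published / np.sqrt(k)
        assert abs(published - oracle) < tol


class TestHARKing:
    def test_examples(self):
        assert np.array_equal(apply_harking([-0.3, 0.2]), [0.3, 0.2])
        pos = np.array([0.1, 0.4])
        assert np.array_equal(apply_harking(pos), pos)

    def test_null_mean_matches_folded_oracle(self):
        design = OptionalStoppingDesign(n_min=20, n_max=20, n_sims=30_000, seed=6)
        res = simulate_optional_stopping(design)
        harked = apply_harking(res.effects).mean()
        oracle = folded_null_effect_mean(20, 60_000, seed=2718)
        assert harked > 0
        assert abs(harked - oracle) < 3 * harked / np.sqrt(design.n_sims)


class TestPublicationRecord:
    def test_internal_replication_matches_binomial_tail(self):
        # QRPs off: fixed n, full reporting, no harking
        world = QRPWorldConfig(
            n_candidate_studies=4,
            optional_stopping=None,
            publication_filter=PublicationFilter(1.0),
            harking=False,
            n_per_study=30,
        )
        df = simulate_publication_record(world, n_effects=20_000, seed=7)
        alpha = 0.05
        k = 4
        expected = 1 - (1 - alpha) ** k - k * alpha * (1 - alpha) ** (k - 1)
        got = df["internally_replicated"].mean()
        se = np.sqrt(expected * (1 - expected) / len(df))
        assert abs(got - expected) < 4 * se

    def test_full_reporting_publishes_everything(self):
        world = QRPWorldConfig(
            n_candidate_studies=3,
            optional_stopping=None,
            publication_filter=PublicationFilter(1.0),
        )
        df = simulate_publication_record(world, n_effects=200, seed=8)
        assert (df["n_published"] == 3).all()

    def test_qrps_make_null_internal_replication_easier(self):
        base = dict(n_candidate_studies=3, n_per_study=30)
        clean = QRPWorldConfig(
            optional_stopping=None,
            publication_filter=PublicationFilter(1.0),
            harking=False,
            **base,
        )
        shady = QRPWorldConfig(
            optional_stopping=OptionalStoppingDesign(n_min=10, n_max=50),
            publication_filter=PublicationFilter(0.0),
            harking=True,
            **base,
        )
        f_clean = simulate_publication_record(clean, 5_000, seed=11)
        f_shady = simulate_publication_record(shady, 5_000, seed=11)
        frac = lambda df: (df["internal_replication_count"] >= 1).mean()
        assert frac(f_shady) > frac(f_clean)
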