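import numpy as np
import pandas as pd
import pytest

from avflux import (
    GeneratorConfig,
    compare_days,
    count_differential,
    exchange_series,
    induction_intestine,
    induction_liver,
    max_delta,
    per_animal_auc_exchange,
    simulate_concentrations,
    summarize_exchange,
    test_exchange_at_time,
    trapezoid_auc,
)
from avflux.exchange import ExchangeError, cohort_arrays, induction_array


class TestInductionFormulas:
    def test_steady_state_is_zero(self):
        assert induction_intestine(2.0, 2.0) == 0.0
        assert induction_liver(3.0, 3.0, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_uptake_and_release_signs(self):
        assert induction_intestine(1.1, 1.0) == pytest.approx(10.0)
        assert induction_intestine(0.9, 1.0) == pytest.approx(-10.0)

    def test_liver_weighted_balance(self):
        # weighted inflow 0.2*1.0 + 0.8*1.25 = 1.2 equals outflow
        assert induction_liver(1.0, 1.25, 1.2) == pytest.approx(0.0)
        assert induction_liver(1.0, 1.0, 0.9) == pytest.approx(100 / 9)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ExchangeError):
            induction_intestine(1.0, 0.0)
        with pytest.raises(ExchangeError):
            induction_liver(1.0, 1.0, -1.0)


class TestTrapezoidAuc:
    def test_constant_and_triangle(self):
        grid = [0, 60, 180, 330, 510]
        assert trapezoid_auc(grid, [10] * 5) == pytest.approx(5100.0)
        assert trapezoid_auc([0, 60], [0, 10]) == pytest.approx(300.0)

    def test_matches_segment_sum_oracle(self):
        rng = np.random.default_rng(2)
        t = np.array([0.0, 60, 180, 330, 510])
        v = rng.normal(size=5)
        by_hand = sum(
            (t[k + 1] - t[k]) * (v[k] + v[k + 1]) / 2 for k in range(4)
        )
        assert trapezoid_auc(t, v) == pytest.approx(by_hand, abs=1e-12)

    def test_linear_and_additive_over_segments(self):
        t = np.array([0.0, 60, 180, 330, 510])
        rng = np.random.default_rng(3)
        v, w = rng.normal(size=5), rng.normal(size=5)
        assert trapezoid_auc(t, 2 * v + 3 * w) == pytest.approx(
            2 * trapezoid_auc(t, v) + 3 * trapezoid_auc(t, w)
        )
        assert trapezoid_auc(t, v) == pytest.approx(
            trapezoid_auc(t[:3], v[:3]) + trapezoid_auc(t[2:], v[2:])
        )

    def test_unsorted_times_rejected(self):
        with pytest.raises(ExchangeError):
            trapezoid_auc([0, 180, 60], [1, 2, 3])


class TestPairedTests:
    def test_hand_computed_t_and_p(self):
        t, p = test_exchange_at_time([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_identical_vectors_give_p_one(self):
        t, p = test_exchange_at_time([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_swap_flips_sign_keeps_p(self):
        a, b = [2.0, 4.0, 7.0], [1.0, 2.0, 3.0]
        t1, p1 = test_exchange_at_time(a, b)
        t2, p2 = test_exchange_at_time(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ExchangeError):
            test_exchange_at_time([1.0, 2.0], [0.0, 1.0])

    def test_compare_days_identical_deltas(self):
        _, p = compare_days([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0


class TestExchangeSeries:
    def test_constant_extraction_constant_series(self, extraction_cohort):
        _, met, _ = extraction_cohort
        for s in exchange_series(met, "intestine"):
            np.testing.assert_allclose(s.induction_pct, 25.0, atol=1e-9)
        for s in exchange_series(met, "liver"):
            np.testing.assert_allclose(s.induction_pct, 100 / 9, atol=1e-9)

    def test_null_cohort_all_zero(self, null_cohort):
        _, met, _ = null_cohort
        for organ in ("intestine", "liver"):
            for s in exchange_series(met, organ):
                np.testing.assert_allclose(s.induction_pct, 0.0, atol=1e-9)

    def test_missing_hv_gives_gap_exactly_there(self, extraction_cohort):
        _, met, _ = extraction_cohort
        drop = (met.annotations["vessel"] == "HV") & (met.annotations["time_min"] == 180) \
            & (met.annotations["animal_id"] == "A1") & (met.annotations["day"] == "D0")
        keep = ~drop.to_numpy()
        from avflux import MetaboliteTable
        met2 = MetaboliteTable(met.values[keep], met.metabolite_names,
                               met.annotations.loc[keep].reset_index(drop=True))
        series = [s for s in exchange_series(met2, "liver")
                  if s.animal == "A1" and s.day == "D0"]
        for s in series:
            assert np.isnan(s.induction_pct[2])
            assert np.isfinite(np.delete(s.induction_pct, 2)).all()
        # intestinal series are unaffected
        for s in exchange_series(met2, "intestine"):
            assert np.isfinite(s.induction_pct).all()


class TestAucExchange:
    def test_constant_concentration_matches_per_time(self, extraction_cohort):
        # constant extraction: AUC-based induction equals the per-time value
        _, met, _ = extraction_cohort
        df = per_animal_auc_exchange(met, "intestine")
        np.testing.assert_allclose(df["auc_induction_pct"], 25.0, atol=1e-9)

    def test_closed_form_small_extraction(self):
        cfg = GeneratorConfig.uniform_extraction(2, e_int=0.1, e_liv=0.1)
        met, _ = simulate_concentrations(cfg, seed=0)
        for organ in ("intestine", "liver"):
            df = per_animal_auc_exchange(met, organ)
            np.testing.assert_allclose(df["auc_induction_pct"], 100 / 9, atol=1e-9)

    def test_null_cohort_auc_zero_p_one(self, null_cohort):
        _, met, _ = null_cohort
        summary = summarize_exchange(met, "intestine")
        np.testing.assert_allclose(summary["auc_induction_pct"], 0.0, atol=1e-9)
        assert np.all(summary["auc_p"] == 1.0)


class TestFastingComparison:
    def test_flat_curve_p_one(self, null_cohort):
        # zero extraction: the induction curve is identically 0, so the
        # time-averaged value equals the fasting value for every animal
        _, met, _ = null_cohort
        summary = summarize_exchange(met, "intestine")
        assert np.all(summary["fasting_comparison_p"] == 1.0)

    def test_postprandial_only_extraction_raises_average(self):
        # e(0) = 0, e(t>0) = 0.2: time-averaged induction > fasting for all
        e = np.zeros((2, 2, 5))
        e[:, :, 1:] = 0.2
        cfg = GeneratorConfig.uniform_extraction(2)
        cfg.e_int = e
        met, _ = simulate_concentrations(cfg, seed=0)
        arr = cohort_arrays(met)
        ind = induction_array(arr, "intestine")  # (a, d, t, m)
        t = arr.times.astype(float)
        avg = np.trapezoid(ind, t, axis=2) / (t[-1] - t[0])
        assert np.all(avg > ind[:, :, 0, :])
        summary = summarize_exchange(met, "intestine")
        assert np.all(summary["fasting_comparison_p"] < 0.05)


class TestMaxDelta:
    @pytest.mark.parametrize(
        "curve,expected",
        [((0, 5, 10, 5, 0), 10.0), ((2, 2, 2, 2, 2), 0.0), ((0, 3, -8, 2, 1), -8.0)],
    )
    def test_signed_max_excursion(self, curve, expected):
        assert max_delta(np.array(curve, dtype=float)) == expected

    def test_all_postprandial_missing_is_error(self):
        with pytest.raises(ExchangeError):
            max_delta(np.array([1.0, np.nan, np.nan, np.nan, np.nan]))


class TestCompareDaysAndCounts:
    def test_doubled_extraction_at_d60_same_sign_differences(self):
        e = np.zeros((2, 2, 5))
        e[:, 0, :], e[:, 1, :] = 0.1, 0.2
        cfg = GeneratorConfig.uniform_extraction(2)
        cfg.e_int = e
        met, _ = simulate_concentrations(cfg, seed=0)
        df = per_animal_auc_exchange(met, "intestine")
        pivot = df.pivot_table(index=["metabolite", "animal"], columns="day",
                               values="auc_induction_pct")
        diff = pivot["D60"] - pivot["D0"]
        assert np.all(diff > 0)

    def test_identical_days_count_zero(self, extraction_cohort):
        _, met, _ = extraction_cohort
        summary = pd.concat(
            [summarize_exchange(met, organ) for organ in ("intestine", "liver")],
            ignore_index=True,
        )
        counts = count_differential(summary, "postprandial_auc")
        assert counts == {"intestine": 0, "liver": 0}

    def test_constructed_significant_metabolites_counted(self):
        e = np.zeros((3, 2, 5))
        e[0, 1, :] = 0.3  # two metabolites shift at D60, one does not
        e[1, 1, :] = 0.25
        cfg = GeneratorConfig.uniform_extraction(3, noise_sd=0.02, animal_sd=0.05)
        cfg.e_int = e
        met, _ = simulate_concentrations(cfg, seed=1)
        summary = summarize_exchange(met, "intestine")
        counts = count_differential(summary, "postprandial_auc")
        assert counts["intestine"] == 2

    def test_missing_day_is_error(self, extraction_cohort):
        _, met, _ = extraction_cohort
        summary = summarize_exchange(met, "intestine")
        with pytest.raises(ExchangeError):
            count_differential(summary[summary["day"] == "D0"], "postprandial_auc")
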