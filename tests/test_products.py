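import math

import numpy as np
import pandas as pd
import pytest

from occtrend.model import PosteriorDraws
from occtrend.products import (
    InclusionRule,
    UndefinedGrowthError,
    annual_growth_rate,
    apply_inclusion_rules,
    first_last_record_years,
    species_trend,
    summarise,
    thin_to_1000,
    trends_frame,
    write_sample_table,
    write_species_trends,
    write_summary_table,
)


def fake_draws(psi, rhat_psi=None):
    psi = np.asarray(psi, dtype=float)
    return PosteriorDraws(
        psi=psi, region_labels=["GB"], years=np.arange(1970, 1970 + psi.shape[-1]),
        params={}, z_mean=np.zeros((psi.shape[0], 1, 1)),
        rhat_psi=rhat_psi if rhat_psi is not None
        else np.ones((1, psi.shape[-1])))


class TestThinTo1000:
    def test_exactly_1000_is_identity_up_to_order(self):
        rng = np.random.default_rng(0)
        psi = rng.random((2, 500, 1, 3))
        table = thin_to_1000(fake_draws(psi), rng, "Ants", "Formica fusca")
        assert len(table) == 1000
        for year_col in ("1970", "1971", "1972"):
            assert sorted(table[year_col]) == sorted(psi[..., 0, int(year_col) - 1970].ravel())

    def test_seed_reproducible(self):
        psi = np.random.default_rng(1).random((3, 400, 1, 2))
        t1 = thin_to_1000(fake_draws(psi), np.random.default_rng(5), "g", "s")
        t2 = thin_to_1000(fake_draws(psi), np.random.default_rng(5), "g", "s")
        pd.testing.assert_frame_equal(t1, t2)

    def test_joint_structure_preserved(self):
        """The same draw indices select every year's value, so per-row values
        come from one coherent posterior draw (here year2 = year1 + 1)."""
        base = np.random.default_rng(2).random((1, 1200, 1, 1))
        psi = np.concatenate([base, base + 1.0], axis=-1)
        table = thin_to_1000(fake_draws(psi), np.random.default_rng(0), "g", "s")
        assert np.allclose(table["1971"] - table["1970"], 1.0)

    def test_too_few_draws_fails(self):
        psi = np.random.default_rng(3).random((1, 999, 1, 1))
        with pytest.raises(ValueError, match="lengthen"):
            thin_to_1000(fake_draws(psi), np.random.default_rng(0), "g", "s")


class TestSummarise:
    def test_constant_draws(self):
        psi = np.full((2, 100, 1, 1), 0.25)
        s = summarise(fake_draws(psi), "Ants", "Formica fusca")
        row = s.iloc[0]
        assert (row["Mean"], row["Lower_CI"], row["Upper_CI"],
                row["Standard_deviation"]) == (0.25, 0.25, 0.25, 0.0)

    def test_bernoulli_mixture_mean(self):
        psi = np.concatenate([np.zeros((1, 50, 1, 1)), np.ones((1, 50, 1, 1))],
                             axis=1)
        s = summarise(fake_draws(psi), "g", "s")
        assert s.iloc[0]["Mean"] == 0.5

    def test_quantiles_match_independent_type7(self):
        """Cross-check the credible bounds against a hand-rolled type-7
        (linear interpolation) quantile."""
        x = np.random.default_rng(4).random(400)
        s = summarise(fake_draws(x.reshape(1, 400, 1, 1)), "g", "s")

        def type7(v, q):
            v = np.sort(v)
            h = (len(v) - 1) * q
            lo = int(math.floor(h))
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])

        assert s.iloc[0]["Lower_CI"] == pytest.approx(type7(x, 0.025), abs=1e-12)
        assert s.iloc[0]["Upper_CI"] == pytest.approx(type7(x, 0.975), abs=1e-12)


class TestGrowthRate:
    def test_no_change_is_zero(self):
        assert annual_growth_rate(0.3, 0.3, 10) == 0.0

    def test_doubling_in_one_year_is_100(self):
        assert annual_growth_rate(0.4, 0.2, 1) == pytest.approx(100.0)

    def test_direct_evaluation(self):
        assert annual_growth_rate(0.04, 0.02, 45) == pytest.approx(1.552, abs=5e-4)

    def test_zero_start_undefined(self):
        with pytest.raises(UndefinedGrowthError):
            annual_growth_rate(0.1, 0.0, 5)

    @pytest.mark.parametrize("c", [0.1, 2.0, 7.5])
    def test_scale_invariance(self, c):
        assert annual_growth_rate(0.04 * c, 0.02 * c, 45) == pytest.approx(
            annual_growth_rate(0.04, 0.02, 45))

    def test_monotonicity(self):
        assert annual_growth_rate(0.5, 0.2, 9) > annual_growth_rate(0.4, 0.2, 9)
        assert annual_growth_rate(0.4, 0.3, 9) < annual_growth_rate(0.4, 0.2, 9)


def sample_table_from_matrix(values, years, region="GB"):
    df = pd.DataFrame(values, columns=[str(y) for y in years])
    df.insert(0, "Iteration", np.arange(1, len(df) + 1))
    df.insert(0, "Region", region)
    df.insert(0, "Species", "Focal species")
    df.insert(0, "Group", "Ants")
    return df


class TestSpeciesTrend:
    def test_constant_samples_degenerate(self):
        table = sample_table_from_matrix(np.full((1000, 2), 0.3), [1970, 1971])
        row = species_trend(table, 1970, 1971, "GB", "Ants", "sp", 100)
        assert row.mean_growth_rate == 0.0
        assert (row.lower_CI, row.upper_CI) == (0.0, 0.0)
        assert math.isinf(row.precision)

    def test_two_point_hand_arithmetic(self):
        """Two samples with growth -1% and +1%: mean 0, sample variance 2
        (n-1 denominator), precision 0.5."""
        y = 1
        s = np.array([0.5, 0.5])
        f = s * (1 + np.array([-0.01, 0.01])) ** y
        table = sample_table_from_matrix(np.column_stack([s, f]), [1970, 1971])
        row = species_trend(table, 1970, 1971, "GB", "Ants", "sp", 100,
                            year_count="span")
        assert row.mean_growth_rate == pytest.approx(0.0, abs=1e-9)
        assert row.precision == pytest.approx(0.5, rel=1e-6)

    def test_identical_first_last_year_zero_growth(self):
        vals = np.random.default_rng(0).random((100, 1)) * 0.5 + 0.2
        table = sample_table_from_matrix(vals, [1980])
        row = species_trend(table, 1980, 1980, "GB", "Ants", "sp", 100)
        assert row.mean_growth_rate == 0.0 and row.n_years == 1

    def test_zero_start_samples_excluded_and_counted(self):
        vals = np.array([[0.0, 0.5], [0.2, 0.4], [0.1, 0.2]])
        table = sample_table_from_matrix(vals, [1970, 1971])
        row = species_trend(table, 1970, 1971, "GB", "Ants", "sp", 100)
        assert row.n_zero_start_excluded == 1

    @pytest.mark.parametrize("first, last, n", [(1981, 2014, 34), (1970, 2015, 46)])
    def test_n_years_is_inclusive_count(self, first, last, n):
        years = np.arange(1970, 2016)
        vals = np.random.default_rng(1).random((10, len(years))) * 0.5 + 0.1
        table = sample_table_from_matrix(vals, years)
        row = species_trend(table, first, last, "GB", "Ants", "sp", 100)
        assert row.n_years == n == row.last_year - row.first_year + 1


class TestInclusionRules:
    def test_record_count_boundary(self):
        years_49 = np.repeat(np.arange(1970, 2015), 2)[:49]
        years_50 = np.repeat(np.arange(1970, 2015), 2)[:50]
        assert apply_inclusion_rules(years_49) == (False, "min_records")
        assert apply_inclusion_rules(years_50)[0]

    def test_interior_gap_boundary(self):
        """A 10-year interior gap is tolerated; an 11-year gap excludes."""
        ok = np.concatenate([np.full(25, 1980), np.full(25, 1991)])   # gap 10
        bad = np.concatenate([np.full(25, 1980), np.full(25, 1992)])  # gap 11
        assert apply_inclusion_rules(ok)[0]
        assert apply_inclusion_rules(bad) == (False, "gap")

    def test_edge_gaps_do_not_exclude(self):
        """Recordless runs before the first / after the last record year are
        clipped by the trend span, not penalised."""
        years = np.repeat([2000, 2001, 2002], 20)   # nothing before 2000
        assert apply_inclusion_rules(years)[0]


def test_first_last_record_years():
    clean = pd.DataFrame({"species": ["a"] * 3, "year": [1974, 1990, 2013]})
    assert first_last_record_years(clean, "a") == (1974, 2013)
    with pytest.raises(ValueError):
        first_last_record_years(clean, "b")


class TestExports:
    def test_round_trip_to_rounded_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        psi = rng.random((1, 1200, 1, 2))
        draws = fake_draws(psi)
        table = thin_to_1000(draws, rng, "Ants", "Formica fusca")
        p = tmp_path / "samples.csv"
        write_sample_table(table, p)
        back = pd.read_csv(p)
        assert np.allclose(back["1970"], table["1970"].round(5))

        s = summarise(draws, "Ants", "Formica fusca")
        p2 = tmp_path / "summary.csv"
        write_summary_table(s, p2)
        back2 = pd.read_csv(p2)
        assert np.allclose(back2["Mean"], s["Mean"].round(3))

    def test_trend_table_layout(self, tmp_path):
        table = sample_table_from_matrix(
            np.random.default_rng(2).random((1000, 2)) * 0.4 + 0.3, [1970, 1971])
        row = species_trend(table, 1970, 1971, "GB", "Ants", "sp", 77)
        p = tmp_path / "Species_Trends.csv"
        write_species_trends([row], p)
        back = pd.read_csv(p)
        assert list(back.columns) == ["Group", "Species", "N_Years", "First_Year",
                                      "Last_year", "N_Records", "Mean_growth_rate",
                                      "Lower_CI", "Upper_CI", "Precision"]
        assert back.iloc[0]["N_Records"] == 77
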