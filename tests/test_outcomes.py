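import itertools

import numpy as np
import pandas as pd
import pytest

from loopsim.outcomes import (
    CATEGORIES,
    OutcomeTriple,
    classify,
    classify_signs,
    conditional_probability_profile,
    core_subset,
    loop_roi,
    mean_roi,
)


class TestROI:
    def test_ratio_arithmetic(self):
        assert loop_roi(100.0, 1000.0) == pytest.approx(1.0)
        assert loop_roi(300.0, 1000.0) == pytest.approx(3.0)

    def test_full_subsidy_gives_zero(self):
        assert loop_roi(0.0, 1000.0) == 0.0

    def test_zero_sales_undefined(self):
        with pytest.raises(ZeroDivisionError):
            loop_roi(10.0, 0.0)

    def test_mean_skips_zero_sale_half_days(self):
        fees = np.array([100.0, 999.0, 300.0])
        kg = np.array([1000.0, 0.0, 1000.0])
        assert mean_roi(fees, kg) == pytest.approx(2.0)

    def test_all_zero_sales_flagged_nan(self):
        assert np.isnan(mean_roi(np.zeros(5), np.zeros(5)))


class TestClassifier:
    BASE = OutcomeTriple(10.0, 1000.0, 1.0)

    def test_all_octants_map_to_exactly_one_category(self):
        """Exhaustive: the 8 win/lose octants cover the 6 categories."""
        seen = {}
        for wins in itertools.product([True, False], repeat=3):
            cat = classify_signs(*wins)
            assert cat in CATEGORIES
            seen[wins] = cat
        assert seen[(True, True, True)] == "win_win_win"
        assert seen[(True, True, False)] == "access_profit_wins"
        assert seen[(True, False, True)] == "access_wins"
        assert seen[(True, False, False)] == "access_wins"
        assert seen[(False, True, True)] == "profit_wins"
        assert seen[(False, True, False)] == "profit_wins"
        assert seen[(False, False, True)] == "others"
        assert seen[(False, False, False)] == "lose_lose_lose"
        assert set(seen.values()) == set(CATEGORIES)

    def test_strict_win_rule_ties_count_as_losses(self):
        assert classify(self.BASE, self.BASE) == "lose_lose_lose"

    @pytest.mark.parametrize(
        "delta, expected",
        [
            ((1, 1, 1), "win_win_win"),
            ((1, -1, 1), "access_wins"),
            ((-1, -1, 1), "others"),
            ((-1, 1, -1), "profit_wins"),
            ((1, 1, -1), "access_profit_wins"),
            ((-1, -1, -1), "lose_lose_lose"),
        ],
    )
    def test_delta_examples(self, delta, expected):
        out = OutcomeTriple(
            self.BASE.cum_purchases_B + delta[0],
            self.BASE.cum_profit_loop + delta[1],
            self.BASE.mean_roi + delta[2],
        )
        assert classify(out, self.BASE) == expected

    def test_nan_roi_counts_as_loss(self):
        out = OutcomeTriple(11.0, 1001.0, float("nan"))
        assert classify(out, self.BASE) == "access_profit_wins"


def _brute_force_core(df, baseline, normalize):
    """Independent oracle: explicit z-scoring + distance + threshold."""
    dims = ["cum_purchases_B", "cum_profit_loop", "mean_roi"]
    pts = df[dims].to_numpy(float)
    base = np.array([baseline.cum_purchases_B, baseline.cum_profit_loop,
                     baseline.mean_roi])
    if normalize == "zscore":
        allp = np.vstack([pts, base])
        mu, sd = allp.mean(0), allp.std(0)
        sd[sd == 0] = 1.0
        pts, base = (pts - mu) / sd, (base - mu) / sd
    d = np.linalg.norm(pts - base, axis=1)
    flags = np.zeros(len(df), bool)
    for cat in df["category"].unique():
        m = (df["category"] == cat).to_numpy()
        if m.sum() < 2:
            continue
        dd = d[m]
        flags[m] = dd > dd.mean() + dd.std(ddof=1)
    return flags


class TestCoreSubset:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["cum_purchases_B", "cum_profit_loop", "mean_roi",
                           "category"]
        )

    def test_equidistant_members_have_no_core(self):
        rows = [(1.0, 0.0, 0.0, "access_wins"), (0.0, 1.0, 0.0, "access_wins"),
                (0.0, 0.0, 1.0, "access_wins")]
        df = self._frame(rows)
        core = core_subset(df, OutcomeTriple(0, 0, 0), normalize="raw")
        assert not core.any()

    def test_single_extreme_outlier_flagged(self):
        rows = [(0.1 * i, 0.0, 0.0, "access_wins") for i in range(9)]
        rows.append((50.0, 0.0, 0.0, "access_wins"))
        df = self._frame(rows)
        core = core_subset(df, OutcomeTriple(0, 0, 0), normalize="raw")
        assert core[-1]
        assert core.sum() == 1

    def test_singleton_category_warns_and_has_no_core(self):
        df = self._frame([(5.0, 5.0, 5.0, "win_win_win")])
        with pytest.warns(UserWarning):
            core = core_subset(df, OutcomeTriple(0, 0, 0))
        assert not core.any()

    @pytest.mark.parametrize("normalize", ["zscore", "raw"])
    def test_agrees_with_brute_force_oracle_on_random_sets(self, normalize, rng):
        df = self._frame([
            (rng.normal(0, 5), rng.normal(0, 500), rng.normal(0, 0.5),
             rng.choice(["access_wins", "profit_wins", "others"]))
            for _ in range(50)
        ])
        base = OutcomeTriple(1.0, 100.0, 0.1)
        got = core_subset(df, base, normalize=normalize)
        want = _brute_force_core(df, base, normalize)
        np.testing.assert_array_equal(got, want)


class TestConditionalProfile:
    def test_single_category_gives_unit_proportion(self):
        prof = conditional_probability_profile(
            np.linspace(0, 1, 20), ["access_wins"] * 20, n_bins=4
        )
        assert (prof["access_wins"].dropna() == 1.0).all()

    def test_counting_example(self):
        values = np.array([0.1, 0.2, 0.3, 0.4, 0.6, 0.7, 0.8, 0.9])
        labels = (["access_wins"] * 3 + ["profit_wins"]
                  + ["profit_wins"] * 4)
        prof = conditional_probability_profile(values, labels, n_bins=2,
                                               value_range=(0.0, 1.0))
        assert prof.loc[0, "access_wins"] == pytest.approx(0.75)
        assert prof.loc[0, "profit_wins"] == pytest.approx(0.25)
        assert prof.loc[1, "profit_wins"] == pytest.approx(1.0)

    def test_empty_bins_marked_missing(self):
        prof = conditional_probability_profile(
            np.array([0.05, 0.95]), ["others", "others"], n_bins=5,
            value_range=(0.0, 1.0)
        )
        assert prof["n"].tolist() == [1, 0, 0, 0, 1]
        assert prof["others"].isna().sum() == 3

    def test_proportions_sum_to_one_in_nonempty_bins(self, rng):
        values = rng.uniform(0, 3, 200)
        labels = rng.choice(list(CATEGORIES), 200)
        prof = conditional_probability_profile(values, labels, n_bins=6)
        sums = prof[list(CATEGORIES)].sum(axis=1)
        for s, n in zip(sums, prof["n"]):
            if n:
                assert s == pytest.approx(1.0)
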