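"""Prevalence tables, chi-square screening, and the published tabulations."""

import logging

import numpy as np
import pandas as pd
import pytest

from geologit.dataset import OUTCOME, SurveyDataset
from geologit.descriptives import (
    crosstab,
    prevalence_by_method,
    round_half_up,
    screen_covariates,
)
from geologit.published import (
    CROSSTAB_COUNTS,
    method_mix_dataset,
    records_from_counts,
)


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (46.85, 46.9),   # half goes up, not to even
        (46.853, 46.9),
        (5.871, 5.9),
        (52.72, 52.7),
        (0.25, 0.3),
        (-1.25, -1.3),   # half-up acts on the magnitude
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x) == expected


class TestMethodMix:
    def test_published_counts_reproduce_published_percentages(self):
        tab = prevalence_by_method(method_mix_dataset())
        assert list(tab["n"]) == [3237, 402, 3208]
        assert list(tab["percent"]) == [47.3, 5.9, 46.9]

    def test_single_method_dataset(self):
        ds = SurveyDataset(pd.DataFrame({
            "method_type": ["modern"] * 10, OUTCOME: [1] * 10
        }))
        tab = prevalence_by_method(ds)
        assert list(tab["percent"]) == [0.0, 0.0, 100.0]

    def test_percentages_partition(self):
        rng = np.random.default_rng(5)
        m = rng.choice(["none", "traditional", "modern"], size=997)
        ds = SurveyDataset(pd.DataFrame({
            "method_type": m, OUTCOME: (m != "none").astype(int)
        }))
        assert abs(prevalence_by_method(ds)["percent"].sum() - 100.0) <= 0.1

    def test_unknown_label_rejected(self):
        ds = SurveyDataset(pd.DataFrame({
            "method_type": ["pill"], OUTCOME: [1]
        }))
        with pytest.raises(ValueError, match="pill"):
            prevalence_by_method(ds)


class TestCrossTab:
    def test_working_status_prevalence_and_significance(self):
        ct = crosstab(records_from_counts("working"), "working")
        assert ct.row_percent.loc["yes", 1] == 53.6
        # the published counts give chi2 = 13.9 on 1 df: p ~ 1.9e-4
        assert ct.p_value < 1e-3
        assert ct.significant

    def test_homogeneous_table_gives_zero_statistic(self):
        df = pd.DataFrame({
            "g": ["a"] * 40 + ["b"] * 80,
            OUTCOME: [1] * 10 + [0] * 30 + [1] * 20 + [0] * 60,
        })
        ct = crosstab(SurveyDataset(df), "g")
        assert np.isclose(ct.statistic, 0.0)
        assert np.isclose(ct.p_value, 1.0)

    def test_hand_computed_two_by_two(self):
        # (10,20;20,10): chi2 = sum (O-E)^2/E = 6.667 on 1 df
        df = pd.DataFrame({
            "g": ["a"] * 30 + ["b"] * 30,
            OUTCOME: [0] * 10 + [1] * 20 + [0] * 20 + [1] * 10,
        })
        ct = crosstab(SurveyDataset(df), "g")
        assert ct.df == 1
        assert np.isclose(ct.statistic, 20.0 / 3.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_statistic_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.choice(list("abcd"), size=600)
        y = rng.integers(0, 2, size=600)
        ds = SurveyDataset(pd.DataFrame({"g": levels, OUTCOME: y}))
        ct = crosstab(ds, "g")
        obs = ct.counts.to_numpy(dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        brute = ((obs - exp) ** 2 / exp).sum()
        assert np.isclose(ct.statistic, brute)
        assert ct.df == (obs.shape[0] - 1) * (obs.shape[1] - 1)

    def test_row_percentages_sum_to_100(self):
        ct = crosstab(records_from_counts("religion"), "religion")
        sums = ct.row_percent.sum(axis=1)
        assert ((sums - 100).abs() <= 0.1).all()

    def test_single_level_rejected(self):
        ds = SurveyDataset(pd.DataFrame({"g": ["a"] * 5, OUTCOME: [0, 1, 0, 1, 0]}))
        with pytest.raises(ValueError, match="single level"):
            crosstab(ds, "g")

    def test_published_row_prevalences(self):
        expected = {
            ("education", "tertiary"): 56.8,
            ("working", "yes"): 53.6,
            ("fp_worker_visit", "yes"): 59.3,
            ("newspapers", "yes"): 63.9,
            ("religion", "catholic"): 56.9,
            ("radio", "yes"): 55.8,
            ("tv", "yes"): 60.1,
        }
        for (cov, lev), pct in expected.items():
            ct = crosstab(records_from_counts(cov), cov)
            assert ct.row_percent.loc[lev, 1] == pct, (cov, lev)


class TestScreening:
    def test_strong_effect_is_included(self):
        rng = np.random.default_rng(31)
        g = rng.choice(["x", "y"], size=4000)
        p = np.where(g == "x", 0.4, 0.6)
        y = (rng.random(4000) < p).astype(int)
        noise = rng.choice(["u", "v"], size=4000)
        ds = SurveyDataset(pd.DataFrame({"g": g, "noise": noise, OUTCOME: y}))
        assert "g" in screen_covariates(ds, ["g", "noise"])

    def test_alpha_one_passes_everything(self):
        rng = np.random.default_rng(32)
        df = pd.DataFrame({
            "a": rng.choice(["p", "q"], 200),
            "b": rng.choice(["r", "s"], 200),
            OUTCOME: rng.integers(0, 2, 200),
        })
        ds = SurveyDataset(df)
        assert screen_covariates(ds, ["a", "b"], alpha=1.0) == ["a", "b"]

    def test_order_preserved(self):
        rng = np.random.default_rng(33)
        g1 = rng.choice(["x", "y"], size=3000)
        g2 = rng.choice(["u", "v"], size=3000)
        p = 0.3 + 0.3 * (g1 == "x") + 0.2 * (g2 == "u")
        y = (rng.random(3000) < p).astype(int)
        ds = SurveyDataset(pd.DataFrame({"g2": g2, "g1": g1, OUTCOME: y}))
        assert screen_covariates(ds, ["g2", "g1"]) == ["g2", "g1"]

    def test_zero_margin_level_dropped_with_warning(self, caplog):
        df = pd.DataFrame({
            "g": pd.Categorical(["a"] * 50 + ["b"] * 50,
                                categories=["a", "b", "c"]),
            OUTCOME: [0, 1] * 50,
        })
        with caplog.at_level(logging.WARNING):
            ct = crosstab(SurveyDataset(df), "g")
        assert "c" not in ct.counts.index
        assert ct.df == 1


def test_published_counts_are_self_consistent():
    # every published cross-tab covers the full 6,847 respondents except
    # those with item nonresponse; totals must never exceed the sample
    for cov, table in CROSSTAB_COUNTS.items():
        total = sum(a + b for a, b in table.values())
        assert total <= 6847, cov
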