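"""Mixed-model fitting, marginal means and their oracles."""
import warnings

import numpy as np
import pandas as pd
import pytest

from trailgait.stats import (ConditionLMM, simulate_outcome_table,
                             summary_table)


@pytest.fixture(autouse=True)
def _quiet_convergence():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def _balanced_table(emm_wrap, emm_lace, n_subjects=6, n_per=10):
    """Noise-free balanced table with exact per-config means."""
    rows = []
    for s in range(n_subjects):
        for config, mu in (("Wrap", emm_wrap), ("Lace", emm_lace)):
            rows.append(pd.DataFrame({"subject": s, "config": config,
                                      "outcome": np.full(n_per, mu)}))
    return pd.concat(rows, ignore_index=True)


class TestFitting:
    def test_degenerate_random_effects_equal_group_mean_difference(self):
        """With zero subject SDs the estimate is the paired means oracle."""
        rng = np.random.default_rng(8)
        df = simulate_outcome_table(8, 25, effect=3.0, rng=rng,
                                    intercept_sd=0.0, slope_sd=0.0,
                                    residual_sd=2.0)
        res = ConditionLMM(df, "outcome", form="random_slope").fit()
        gm = df.groupby("config")["outcome"].mean()
        assert res.effect == pytest.approx(gm["Wrap"] - gm["Lace"],
                                           abs=1e-8)

    def test_effect_recovery_within_two_se(self):
        rng = np.random.default_rng(9)
        df = simulate_outcome_table(25, 80, effect=-16.0, rng=rng,
                                    mean=340.0, intercept_sd=45.0,
                                    slope_sd=8.0, residual_sd=60.0)
        res = ConditionLMM(df, "outcome").fit()
        assert abs(res.effect - (-16.0)) < 2 * res.effect_se
        vc = res.variance_components
        assert vc["intercept_sd"] == pytest.approx(45.0, rel=0.35)
        assert vc["residual_sd"] == pytest.approx(60.0, rel=0.05)
        assert abs(vc.get("correlation", 0.0)) <= 1.0

    def test_reml_loglik_nondecreasing_with_richer_structure(self):
        rng = np.random.default_rng(10)
        df = simulate_outcome_table(12, 30, effect=2.0, rng=rng,
                                    slope_sd=6.0)
        r1 = ConditionLMM(df, "outcome", form="intercept_only").fit()
        r2 = ConditionLMM(df, "outcome", form="random_slope").fit()
        assert r2._result.llf >= r1._result.llf - 1e-6

    def test_speed_covariate_form(self):
        rng = np.random.default_rng(12)
        df = simulate_outcome_table(10, 40, effect=5.0, rng=rng)
        df["speed"] = rng.normal(2.7, 0.3, len(df))
        df["outcome"] = df["outcome"] + 10.0 * df["speed"]
        res = ConditionLMM(df, "outcome",
                           form="random_slope_with_speed").fit()
        assert res.params["Speed"] == pytest.approx(10.0, abs=1.0)
        assert res.effect == pytest.approx(5.0, abs=3 * res.effect_se)

    def test_bad_inputs_rejected(self):
        df = _balanced_table(1.0, 2.0)
        with pytest.raises(ValueError, match="form"):
            ConditionLMM(df, "outcome", form="anova")
        with pytest.raises(ValueError, match="two subjects"):
            ConditionLMM(df[df.subject == 0], "outcome")
        df3 = df.copy()
        df3.loc[0, "outcome"] = np.inf
        with pytest.raises(ValueError, match="finite"):
            ConditionLMM(df3, "outcome")


class TestEmmeans:
    def test_known_emmeans_and_percent_difference(self):
        """A balanced noise-free table reproduces the printed contrast:
        emm 328.1 vs 343.8 -> difference -15.7, about -4.6%."""
        df = _balanced_table(328.1, 343.8)
        res = ConditionLMM(df, "outcome").fit()
        con = res.emm_contrast()
        assert con["emmean_wrap"] == pytest.approx(328.1, abs=1e-6)
        assert con["emmean_lace"] == pytest.approx(343.8, abs=1e-6)
        assert con["difference"] == pytest.approx(-15.7, abs=1e-6)
        assert con["percent_difference"] == pytest.approx(-4.566, abs=0.01)
        assert round(-con["percent_difference"]) == 5

    def test_equal_emmeans_zero_percent(self):
        df = _balanced_table(100.0, 100.0)
        res = ConditionLMM(df, "outcome").fit()
        assert res.emm_contrast()["percent_difference"] \
            == pytest.approx(0.0, abs=1e-9)

    def test_emmeans_equal_brute_force_prediction_average(self):
        rng = np.random.default_rng(13)
        df = simulate_outcome_table(8, 20, effect=4.0, rng=rng)
        res = ConditionLMM(df, "outcome").fit()
        beta = res.params
        wrap_col = (df["config"] == "Wrap").to_numpy(float)
        brute = {}
        for level, w in (("Wrap", 1.0), ("Lace", 0.0)):
            x = np.column_stack([np.ones(len(df)),
                                 np.full(len(df), w)])
            brute[level] = (x @ beta.to_numpy()).mean()
        emm = res.emmeans
        assert emm["Wrap"] == pytest.approx(brute["Wrap"])
        assert emm["Lace"] == pytest.approx(brute["Lace"])

    def test_percent_difference_uses_emmeans_not_raw_means(self):
        """Unbalanced data: raw means and emmeans disagree; the reported
        percent difference must follow the emmeans."""
        rng = np.random.default_rng(14)
        rows = []
        for s in range(8):
            b0 = 10.0 * s        # strong subject spread
            for config, n in (("Lace", 40 if s < 4 else 5),
                              ("Wrap", 5 if s < 4 else 40)):
                mu = 100.0 + b0 + (3.0 if config == "Wrap" else 0.0)
                rows.append(pd.DataFrame({
                    "subject": s, "config": config,
                    "outcome": mu + rng.normal(0, 1.0, n)}))
        df = pd.concat(rows, ignore_index=True)
        res = ConditionLMM(df, "outcome").fit()
        con = res.emm_contrast()
        emm = res.emmeans
        assert con["percent_difference"] == pytest.approx(
            100.0 * (emm["Wrap"] - emm["Lace"]) / emm["Lace"])
        raw = df.groupby("config")["outcome"].mean()
        raw_pct = 100.0 * (raw["Wrap"] - raw["Lace"]) / raw["Lace"]
        assert abs(con["percent_difference"] - raw_pct) > 1.0

    def test_summary_is_printable(self):
        df = _balanced_table(10.0, 12.0)
        text = ConditionLMM(df, "outcome").fit().summary()
        assert "Config[Wrap]" in text and "emmeans" in text


class TestSummaryTable:
    def test_shape_and_content(self):
        rng = np.random.default_rng(15)
        strides = pd.DataFrame({
            "section": np.repeat(["uphill", "top", "downhill"], 40),
            "config": np.tile(["Wrap", "Lace"], 60),
            "subject": 0,
            "speed": rng.normal(2.7, 0.3, 120),
        })
        tab = summary_table(strides, pd.DataFrame(), pd.DataFrame())
        assert set(tab["outcome"]) == {"speed"}
        assert len(tab) == 6                      # 3 sections x 2 configs
        assert (tab["sd"] > 0).all()
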