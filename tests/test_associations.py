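"""Variance decomposition, feature correlations, and group statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucflux import (
    chromatin_state_comparison,
    group_rate_comparison,
    pausing_index,
    rate_feature_correlation,
    rbp_overlap,
    variance_contributions,
)
from nucflux.simulate import (
    plant_chromatin_states,
    plant_label_effect,
    sample_rates_with_variance_shares,
)

G = math.log(2) / 1440.0


def _rates(rng, n=2000):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "kS": np.exp(1.0 + 1.5 * rng.standard_normal(n)),
            "kE": 0.0083 * np.exp(0.35 * rng.standard_normal(n)),
            "kD": 0.0140 * np.exp(0.63 * rng.standard_normal(n)),
        }
    )


class TestVarianceContributions:
    def test_only_transcription_varies(self, rng):
        n = 100
        rates = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "kS": np.exp(rng.standard_normal(n)),
                "kE": 0.0083,
                "kD": 0.0140,
            }
        )
        shares = variance_contributions(rates, G)
        assert shares["transcription"] == pytest.approx(1.0)
        assert shares["export"] == pytest.approx(0.0, abs=1e-12)
        assert shares["decay"] == pytest.approx(0.0, abs=1e-12)

    def test_shares_sum_to_one_and_scale_invariance(self, rng):
        rates = _rates(rng)
        shares = variance_contributions(rates, G)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        scaled = rates.assign(kS=rates["kS"] * 37.0)
        shares2 = variance_contributions(scaled, G)
        for key in shares:
            assert shares2[key] == pytest.approx(shares[key], abs=1e-10)

    def test_planted_generative_shares_recovered(self):
        rates = sample_rates_with_variance_shares(5000, (0.85, 0.05, 0.10), G, rng=17)
        shares = variance_contributions(rates, G)
        assert shares["transcription"] == pytest.approx(0.85, abs=0.05)
        assert shares["export"] == pytest.approx(0.05, abs=0.05)
        assert shares["decay"] == pytest.approx(0.10, abs=0.05)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError, match="10 genes"):
            variance_contributions(_rates(rng, 5), G)
        flat = _rates(rng, 50).assign(kS=1.0, kE=0.0083, kD=0.0140)
        with pytest.raises(ValueError, match="variance"):
            variance_contributions(flat, G)


class TestRateFeatureCorrelation:
    def test_self_correlation_null_and_planted_slope(self, rng):
        rates = _rates(rng, 5000)
        features = pd.DataFrame(
            {
                "gene_id": rates["gene_id"],
                "self": rates["kD"],  # identical to the rate
                "independent": np.exp(rng.standard_normal(5000)),
                # planted: kD ~ length^0.25 with modest noise
                "length": (rates["kD"] / 0.0140) ** 4
                * 2000.0
                * np.exp(0.2 * math.log(10) * rng.standard_normal(5000)),
            }
        )
        table = rate_feature_correlation(rates, features, rate_cols=("kD",))
        row = table.set_index("feature")
        assert row.loc["self", "rho"] == pytest.approx(1.0)
        assert abs(row.loc["independent", "rho"]) < 0.05
        assert row.loc["length", "loglog_slope"] == pytest.approx(0.25, abs=0.05)

    def test_constant_feature_reported_missing(self, rng):
        rates = _rates(rng, 100)
        features = pd.DataFrame({"gene_id": rates["gene_id"], "flat": 5.0})
        table = rate_feature_correlation(rates, features)
        assert table["rho"].isna().all()
        assert (table["reason"] == "constant-or-sparse").all()


class TestGroupRateComparison:
    def test_identical_groups_null(self, rng):
        rates = _rates(rng, 1000)
        labels = pd.DataFrame(
            {
                "gene_id": rates["gene_id"],
                "label": "setA",
                "value": (rng.random(1000) < 0.3).astype(int),
            }
        )
        out = group_rate_comparison(rates, labels)
        assert (out["p"] > 0.01).all()
        assert out["log2_median_ratio"].abs().max() < 0.5

    def test_planted_twofold_shift_detected(self, rng):
        rates = _rates(rng, 3000)
        shifted, labels = plant_label_effect(rates, 300, "kD", 2.0, rng)
        out = group_rate_comparison(shifted, labels)
        row = out[(out["label"] == "rbp") & (out["rate"] == "kD")].iloc[0]
        assert row["significant"]
        assert row["log2_median_ratio"] == pytest.approx(1.0, abs=0.35)

    def test_holm_step_down_matches_textbook_sequence(self):
        """Raw p-values (0.001, 0.02, 0.04) at alpha 0.05 with m=3: the
        step-down thresholds are 0.05/3, 0.05/2, 0.05, and each p passes its
        own (0.001<0.0167, 0.02<0.025, 0.04<0.05), so all three are rejected
        with adjusted p-values (0.003, 0.04, 0.04)."""
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests([0.001, 0.02, 0.04], alpha=0.05, method="holm")
        assert reject.tolist() == [True, True, True]
        np.testing.assert_allclose(p_adj, [0.003, 0.04, 0.04])
        # and the procedure stops at the first failure: bump the middle p
        reject2, *_ = multipletests([0.001, 0.03, 0.04], alpha=0.05, method="holm")
        assert reject2.tolist() == [True, False, False]

    def test_expression_filter_restricts_to_top_fraction(self, rng):
        rates = _rates(rng, 1000)
        labels = pd.DataFrame(
            {"gene_id": rates["gene_id"], "label": "setA",
             "value": np.ones(1000, dtype=int)}
        )
        # all genes labeled -> unbound group empty -> label skipped
        out = group_rate_comparison(rates, labels)
        assert out.empty


class TestOverlapAndPausing:
    def test_overlap_values(self):
        x = {f"g{i}" for i in range(100)}
        y = {f"g{i}" for i in range(75, 125)}
        assert rbp_overlap(x, x) == (1.0, 1.0)
        assert rbp_overlap(x, y) == (0.25, 0.5)
        assert rbp_overlap({"a"}, {"b"}) == (0.0, 0.0)
        with pytest.raises(ValueError):
            rbp_overlap(set(), {"a"})

    def test_pausing_index_ratios_and_uniform_track(self):
        assert pausing_index(10.0, 5.0) == 2.0
        assert pausing_index(3.0, 3.0) == 1.0
        assert np.isnan(pausing_index(3.0, 0.0))
        # uniform coverage 1x over a 10 kb gene: window signal 400 (200 bp
        # around TSS on both strandsides = 400 bp), body 201..10000 = 9800
        window, body = 400.0, 9800.0
        assert pausing_index(window, body) == pytest.approx(400 / 9800)


class TestChromatinStates:
    def test_null_states_no_significant_pairs(self, rng):
        rates = _rates(rng, 1000)
        _, states = plant_chromatin_states(rates, rng, shifted_state=None)
        out = chromatin_state_comparison(
            rates, states.set_index("gene_id")["tss_state"]
        )
        assert out["significant_pairs"] == []
        assert out["anova_p"] > 0.01

    def test_shifted_state_separates(self, rng):
        rates = _rates(rng, 1000)
        shifted, states = plant_chromatin_states(
            rates, rng, shifted_state="BLUE", rate_col="kS", fold=0.05
        )
        out = chromatin_state_comparison(
            shifted, states.set_index("gene_id")["tss_state"]
        )
        blue_pairs = [p for p in out["significant_pairs"] if "BLUE" in p]
        assert len(blue_pairs) == 4  # BLUE differs from all other states
        assert out["anova_p"] < 1e-10

    def test_two_state_tukey_equals_t_test(self, rng):
        rates = _rates(rng, 400)
        states = pd.Series(
            np.where(np.arange(400) < 200, "A", "B"),
            index=rates["gene_id"],
        )
        shifted = rates.copy()
        shifted.loc[:99, "kS"] *= 3.0
        out = chromatin_state_comparison(shifted, states)
        a = np.log(shifted.loc[:199, "kS"])
        b = np.log(shifted.loc[200:, "kS"])
        t_p = stats.ttest_ind(a, b).pvalue
        tukey_p = float(out["tukey"]["p-adj"].iloc[0])
        assert tukey_p == pytest.approx(t_p, abs=2e-3)

    def test_small_states_merged_or_dropped(self, rng):
        rates = _rates(rng, 100)
        # two tiny states merge into an "other" group big enough to keep
        states = pd.Series(
            ["A"] * 50 + ["B"] * 38 + ["t1"] * 6 + ["t2"] * 6,
            index=rates["gene_id"],
        )
        with pytest.warns(UserWarning, match="other"):
            out = chromatin_state_comparison(rates, states)
        assert set(out["tukey"]["group1"]) | set(out["tukey"]["group2"]) == {
            "A", "B", "other",
        }
        # a single tiny state leaves only one usable group -> error
        states2 = pd.Series(["A"] * 95 + ["tiny"] * 5, index=rates["gene_id"])
        with pytest.warns(UserWarning, match="merged"):
            with pytest.raises(ValueError, match="2 states"):
                chromatin_state_comparison(rates, states2)
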