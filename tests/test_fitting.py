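"""Per-gene rate fitting: objective, recovery, goodness of fit, retention."""

import math

import numpy as np
import pandas as pd
import pytest

from nucflux import (
    CellCycleParams,
    FitConfig,
    GeneTimeSeries,
    KineticRates,
    NoiseModel,
    SteadyState,
    consistent_gene,
    filter_retained,
    fit_dataset,
    fit_gene,
    goodness_of_fit,
    mitotic_transfer_rates,
    objective_components,
    unlabeled_cytoplasmic,
    unlabeled_nuclear,
)
from nucflux.fitting import FitResult

T = np.array([0.0, 30.0, 90.0, 180.0, 300.0, 450.0])


def _clean_series(ccp, kE=0.0083, kD=0.0140, W0=120.0, gene="g0", rep=1):
    """Noise-free series from a fully quasi-steady-state-consistent gene."""
    ss, rates = consistent_gene(kE, kD, W0, ccp)
    series = GeneTimeSeries(
        gene_id=gene,
        t=T,
        Nm=unlabeled_nuclear(T, ss, rates),
        Cm=unlabeled_cytoplasmic(T, ss, rates),
        replicate=rep,
    )
    return series, ss, rates


class TestObjectiveComponents:
    def test_exact_model_is_a_fixed_point(self, ccp, flat_noise, rng):
        """Theta vanishes on noise-free data from consistent parameters,
        across random parameter draws."""
        for _ in range(100):
            kE = 0.0083 * math.exp(0.8 * rng.standard_normal())
            kD = 0.0140 * math.exp(0.8 * rng.standard_normal())
            w0 = 10 ** rng.uniform(0.5, 3)
            series, ss, rates = _clean_series(ccp, kE, kD, w0)
            comps = objective_components(
                {"kE": kE, "kD": kD, "kT": rates.kT}, series, ss, ccp, flat_noise
            )
            assert np.all(comps <= 1e-12)

    def test_component3_zero_on_balance_and_hand_evaluation(self, ccp):
        noise = NoiseModel.constant(0.25)
        series, ss, rates = _clean_series(ccp)
        kf, kfp = mitotic_transfer_rates(ccp, ss)
        # pick kE so the cytoplasmic balance holds exactly
        kE_bal = (rates.kD + kf + ccp.g) * ss.C0 / ss.N0 - kfp
        comps = objective_components(
            {"kE": kE_bal, "kD": rates.kD, "kT": rates.kT}, series, ss, ccp, noise
        )
        assert comps[2] == pytest.approx(0.0, abs=1e-18)

        # hand evaluation of components 3-4 at an off-balance trial point
        kE, kD, kT = 0.01, 0.02, 0.005
        comps = objective_components(
            {"kE": kE, "kD": kD, "kT": kT}, series, ss, ccp, noise
        )
        c3 = (0.25 / 0.25) * math.log(
            (kE + kfp) * ss.N0 / ((kD + kf + ccp.g) * ss.C0)
        ) ** 2
        c4 = (0.25 / 0.25) * math.log(kT * ss.W0 / (kD * ss.C0)) ** 2
        assert comps[2] == pytest.approx(c3, rel=1e-12)
        assert comps[3] == pytest.approx(c4, rel=1e-12)

    def test_dynamic_components_hand_arithmetic(self, ccp):
        noise = NoiseModel.constant(0.2)
        series, ss, rates = _clean_series(ccp)
        # perturb the measured nuclear series by a factor 1.1 everywhere:
        # component 1 = mean (0.2 * log 1.1)^2
        bumped = GeneTimeSeries(
            gene_id="g0", t=T, Nm=series.Nm * 1.1, Cm=series.Cm, replicate=1
        )
        comps = objective_components(
            {"kE": rates.kE, "kD": rates.kD, "kT": rates.kT},
            bumped, ss, ccp, noise,
        )
        assert comps[0] == pytest.approx((0.2 * math.log(1.1)) ** 2, rel=1e-10)
        assert comps[1] == pytest.approx(0.0, abs=1e-18)


class TestFitGene:
    def test_noise_free_recovery_within_rtol(self, ccp, flat_noise):
        series, ss, rates = _clean_series(ccp, kE=0.0083, kD=0.0140)
        fit = fit_gene(series, ccp, flat_noise)
        assert fit.converged
        assert fit.rates.kE == pytest.approx(rates.kE, rel=1e-4)
        assert fit.rates.kD == pytest.approx(rates.kD, rel=1e-4)
        assert fit.rates.kT == pytest.approx(rates.kT, rel=1e-4)
        assert fit.r2_nuclear == pytest.approx(1.0, abs=1e-9)

    def test_derived_transcription_rate_consistent(self, ccp, flat_noise):
        series, ss, rates = _clean_series(ccp)
        fit = fit_gene(series, ccp, flat_noise)
        kf, kfp = mitotic_transfer_rates(ccp, ss)
        expected_ks = (ccp.g + fit.rates.kE + kfp) * ss.N0 - kf * ss.C0
        assert fit.rates.kS == pytest.approx(expected_ks, rel=1e-12)

    def test_degenerate_series_fail_gracefully(self, ccp, flat_noise):
        zero_c = GeneTimeSeries("g0", T, np.ones(6), np.zeros(6))
        out = fit_gene(zero_c, ccp, flat_noise)
        assert not out.converged and not out.retained
        mostly_zero = GeneTimeSeries(
            "g1", T, np.ones(6), np.array([1.0, 0, 0, 0, 1.0, 1.0])
        )
        out2 = fit_gene(mostly_zero, ccp, flat_noise)
        assert not out2.converged and "zero" in out2.message

    def test_fit_is_deterministic(self, ccp, flat_noise, rng):
        series, _, _ = _clean_series(ccp)
        noisy = GeneTimeSeries(
            "g0", T,
            series.Nm * np.exp(0.1 * rng.standard_normal(6)),
            series.Cm * np.exp(0.1 * rng.standard_normal(6)),
        )
        a = fit_gene(noisy, ccp, flat_noise)
        b = fit_gene(noisy, ccp, flat_noise)
        assert a.rates == b.rates and a.theta.tolist() == b.theta.tolist()


class TestGoodnessOfFit:
    def test_perfect_fit_and_hand_computed_r2(self, ccp, flat_noise):
        series, ss, rates = _clean_series(ccp)
        fit = fit_gene(series, ccp, flat_noise)
        assert fit.r2_nuclear == pytest.approx(1.0, abs=1e-10)
        assert fit.r2_cytoplasmic == pytest.approx(1.0, abs=1e-10)

        # hand-computed r2 on a perturbed 6-point series
        noisy = GeneTimeSeries("g0", T, series.Nm * 1.2, series.Cm)
        result = FitResult("g0", 1, fit.rates, ss)
        r2n, r2c = goodness_of_fit(noisy, result)
        obs = np.log10(series.Nm * 1.2)
        pred = np.log10(unlabeled_nuclear(T, ss, fit.rates))
        expected = 1 - np.sum((obs - pred) ** 2) / np.sum((obs - obs.mean()) ** 2)
        assert r2n == pytest.approx(expected, abs=1e-12)

    def test_constant_series_has_undefined_r2(self, ccp):
        series, ss, rates = _clean_series(ccp)
        flat = GeneTimeSeries("g0", T, np.full(6, 2.0), series.Cm)
        result = FitResult("g0", 1, rates, ss)
        r2n, _ = goodness_of_fit(flat, result)
        assert np.isnan(r2n)


class TestRetention:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "replicate", "r2_nuclear", "r2_cytoplasmic", "converged"],
        )

    def test_threshold_is_strict_and_all_replicates_required(self):
        df = self._frame(
            [
                ("a", 1, 1.0, 1.0, True), ("a", 2, 0.95, 0.9, True),
                ("b", 1, 0.79, 0.95, True), ("b", 2, 0.99, 0.95, True),
                ("c", 1, 0.85, 0.81, True), ("c", 2, 0.80, 0.9, True),
            ]
        )
        assert filter_retained(df, 0.8) == {"a"}
        assert filter_retained(df, 0.8, rule="any") == {"a", "b", "c"}

    def test_model_violating_genes_are_separated(self, ccp, flat_noise, rng):
        """A planted mixture of well-modeled genes and genes violating the
        first-order model is split by the r2 filter with high balanced
        accuracy."""
        rows = []
        truth = {}
        for i in range(40):
            gene = f"g{i:03d}"
            well = i < 32
            truth[gene] = well
            series, ss, rates = _clean_series(
                ccp,
                kE=0.0083 * math.exp(0.3 * rng.standard_normal()),
                kD=0.0140 * math.exp(0.3 * rng.standard_normal()),
                W0=80 * math.exp(rng.standard_normal()),
                gene=gene,
            )
            nm, cm = series.Nm.copy(), series.Cm.copy()
            if not well:
                # biphasic violation: second half of the series plateaus
                nm[3:] = nm[2]
                cm[3:] = cm[2]
            noise_factor = np.exp(0.05 * rng.standard_normal((2, 6)))
            for rep in (1, 2):
                s = GeneTimeSeries(gene, T, nm * noise_factor[rep - 1],
                                   cm * noise_factor[rep - 1], rep)
                fit = fit_gene(s, ccp, flat_noise)
                rows.append(
                    (gene, rep, fit.r2_nuclear, fit.r2_cytoplasmic, fit.converged)
                )
        retained = filter_retained(self._frame(rows), 0.8)
        tp = sum(1 for genes, well in truth.items() if well and genes in retained)
        tn = sum(1 for genes, well in truth.items() if not well and genes not in retained)
        balanced_acc = 0.5 * (tp / 32 + tn / 8)
        assert balanced_acc >= 0.9


class TestFitDataset:
    def test_identical_replicates_concordance_one(self, ccp, flat_noise):
        frames = []
        for i in range(8):
            series, _, _ = _clean_series(
                ccp, kE=0.005 + 0.001 * i, kD=0.01 + 0.002 * i, gene=f"g{i}"
            )
            for rep in (1, 2):
                frames.append(
                    pd.DataFrame(
                        {
                            "gene_id": f"g{i}",
                            "fraction": ["nuclear"] * 6 + ["cytoplasmic"] * 6,
                            "replicate": rep,
                            "time_min": np.tile(T, 2),
                            "abundance": np.concatenate([series.Nm, series.Cm]),
                        }
                    )
                )
        results, report = fit_dataset(
            pd.concat(frames, ignore_index=True), ccp, flat_noise
        )
        assert report["n_retained"] == 8
        assert results["converged"].all()
        for rho in report["concordance"].values():
            assert rho == pytest.approx(1.0)
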