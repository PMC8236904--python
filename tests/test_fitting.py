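"""Rate-law fitting, model comparison and in vivo curve assembly."""

import logging

import numpy as np
import pandas as pd
import pytest

from invivokin import (
    KineticTrace,
    MetabolomicsTable,
    build_invivo_curve,
    compare_models_ftest,
    competitive_inhibition_rate,
    estimate_initial_rate,
    fit_hill,
    fit_inhibition_4pl,
    fit_mm,
    mm_rate,
)
from invivokin.chain import DataError
from invivokin.fitting import DoseResponsePoints, EmptyResultError


def hill_y(x, amplitude, k_half, n):
    return amplitude * x**n / (k_half**n + x**n)


class TestInitialRate:
    def trace(self, slope=-0.5, sd=0.0, rng=None):
        t = np.arange(0.0, 61.0, 5.0)
        y = 100.0 + slope * t
        if sd:
            y = y + rng.normal(0, sd, t.size)
        return KineticTrace(t, y)

    def test_exact_on_linear_consumption(self):
        est = estimate_initial_rate(self.trace(), window=20.0)
        assert est.rate == pytest.approx(0.5)
        assert est.n_points == 5

    @pytest.mark.parametrize("window", [15.0, 20.0, 40.0, 60.0])
    def test_exact_for_any_window(self, window):
        assert estimate_initial_rate(self.trace(), window).rate == pytest.approx(0.5)

    def test_noisy_rate_within_three_se(self, rng):
        est = estimate_initial_rate(self.trace(sd=0.1, rng=rng), window=20.0)
        assert abs(est.rate - 0.5) < 3 * est.stderr

    def test_constant_signal_gives_zero(self):
        assert estimate_initial_rate(self.trace(slope=0.0), 20.0).rate == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            estimate_initial_rate(self.trace(), window=6.0)


class TestFitMM:
    def test_noiseless_recovery(self):
        x = np.geomspace(1.0, 200.0, 8)
        fit = fit_mm(DoseResponsePoints(x=x, y=mm_rate(x, 1.0, 13.0)))
        assert fit.params["vmax"] == pytest.approx(1.0, rel=1e-4)
        assert fit.params["k_m"] == pytest.approx(13.0, rel=1e-4)
        assert fit.ssr < 1e-12

    def test_all_zero_response_flagged(self):
        fit = fit_mm(DoseResponsePoints(x=np.arange(5.0), y=np.zeros(5)))
        assert fit.params["vmax"] == 0.0
        assert "non_identifiable" in fit.flags

    def test_noisy_km_recovery_rate(self):
        # CV 10%, 24 points: the Michaelis constant lands within 20% of
        # truth in the overwhelming majority of experiments
        x = np.tile(np.geomspace(2.0, 150.0, 8), 3)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = mm_rate(x, 1.0, 13.0) * rng.lognormal(0, 0.1, x.size)
            fit = fit_mm(DoseResponsePoints(x=x, y=y))
            hits += abs(fit.params["k_m"] / 13.0 - 1.0) < 0.2
        assert hits >= 45


class TestFitHill:
    def test_noiseless_recovery(self):
        x = np.geomspace(0.02, 3.0, 12)
        fit = fit_hill(DoseResponsePoints(x=x, y=hill_y(x, 1.0, 0.3, 2.5)))
        assert fit.params["amplitude"] == pytest.approx(1.0, rel=1e-6)
        assert fit.params["k_half"] == pytest.approx(0.3, rel=1e-6)
        assert fit.params["exponent"] == pytest.approx(2.5, rel=1e-6)
        assert fit.params["k_m_apparent"] == pytest.approx(0.3**2.5, rel=1e-5)

    def test_mm_data_yields_unit_exponent(self):
        x = np.geomspace(1.0, 200.0, 12)
        fit = fit_hill(DoseResponsePoints(x=x, y=mm_rate(x, 1.0, 13.0)))
        assert fit.params["exponent"] == pytest.approx(1.0, abs=1e-4)

    def test_exponent_pinned_to_one_matches_mm_ssr(self, rng):
        x = np.tile(np.geomspace(1.0, 200.0, 8), 2)
        y = mm_rate(x, 1.0, 13.0) * rng.lognormal(0, 0.15, x.size)
        points = DoseResponsePoints(x=x, y=y)
        ssr_mm = fit_mm(points).ssr
        ssr_hill1 = fit_hill(points, exponent_bounds=(1.0, 1.0 + 1e-9)).ssr
        assert ssr_hill1 == pytest.approx(ssr_mm, rel=1e-8)


class TestFTest:
    def points(self, rng, truth="mm", cv=0.05, n_rep=3):
        x = np.tile(np.geomspace(1.0, 200.0, 12), n_rep)
        y = mm_rate(x, 1.0, 13.0) if truth == "mm" else hill_y(x, 1.0, 13.0, 2.5)
        return DoseResponsePoints(x=x, y=y + rng.normal(0, cv, x.size))

    def test_identical_ssr_prefers_nested(self, rng):
        pts = self.points(rng)
        mm = fit_mm(pts)
        hill = fit_mm(pts)
        hill.model_name, hill.n_params = "Hill3", 3
        cmp_ = compare_models_ftest(mm, hill)
        assert cmp_.f_stat == 0.0
        assert cmp_.p_value == 1.0
        assert cmp_.preferred == "MM"

    def test_hill_truth_detected(self):
        detected = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pts = self.points(rng, truth="hill", cv=0.02)
            cmp_ = compare_models_ftest(fit_mm(pts), fit_hill(pts))
            detected += cmp_.p_value < 0.05 and cmp_.preferred == "Hill3"
        assert detected >= 38  # >= 95% power at low noise

    def test_p_value_scale_equivariant(self, rng):
        pts = self.points(rng, truth="hill", cv=0.05)
        scaled = DoseResponsePoints(x=pts.x, y=1000.0 * pts.y)
        p1 = compare_models_ftest(fit_mm(pts), fit_hill(pts)).p_value
        p2 = compare_models_ftest(fit_mm(scaled), fit_hill(scaled)).p_value
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_mismatched_points_rejected(self, rng):
        a, b = self.points(rng), self.points(rng, truth="hill")
        with pytest.raises(ValueError):
            compare_models_ftest(fit_mm(a), fit_hill(b))


class TestFit4PL:
    def test_noiseless_recovery(self):
        x = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.9, 6.0, 10.0])
        y = 0.0 + (1.0 - 0.0) / (1.0 + np.where(x > 0, x / 3.9, 0.0))
        fit = fit_inhibition_4pl(DoseResponsePoints(x=x, y=y))
        assert fit.params["top"] == pytest.approx(1.0, abs=1e-6)
        assert fit.params["bottom"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["apparent_ki"] == pytest.approx(3.9, rel=1e-5)
        assert fit.params["slope"] == pytest.approx(1.0, rel=1e-5)

    def test_flat_data_flagged_non_identifiable(self):
        fit = fit_inhibition_4pl(
            DoseResponsePoints(x=np.array([0.0, 1, 2, 4, 8.0]), y=np.ones(5))
        )
        assert "slope_non_identifiable" in fit.flags

    @pytest.mark.parametrize("seed", range(5))
    def test_distinct_midpoints_distinguished(self, seed):
        # the two dCTP apparent K_I values at different Mg2+ levels are
        # statistically distinguishable: 8 concentrations in technical
        # triplicate at CV 5% give non-overlapping 95% CIs
        x = np.tile(np.r_[0.0, np.geomspace(0.5, 30.0, 7)], 3)
        rng = np.random.default_rng(seed)
        cis = {}
        for ki in (2.3, 4.2):
            y = 1.0 / (1.0 + np.where(x > 0, x / ki, 0.0))
            y = y * rng.lognormal(0, 0.05, x.size)
            fit = fit_inhibition_4pl(DoseResponsePoints(x=x, y=y))
            half = 1.96 * fit.param_se["ic50"]
            cis[ki] = (fit.params["ic50"] - half, fit.params["ic50"] + half)
        assert cis[2.3][1] < cis[4.2][0]  # non-overlapping 95% CIs


class TestCompetitiveInhibition:
    def test_no_inhibitor_is_mm(self):
        s = np.geomspace(1.0, 500.0, 10)
        assert competitive_inhibition_rate(s, 0.0, 1.0, 13.0, 3.9) == pytest.approx(
            mm_rate(s, 1.0, 13.0)
        )

    def test_rate_halved_at_ki_when_substrate_scarce(self):
        v0 = competitive_inhibition_rate(1e-6, 0.0, 1.0, 13.0, 5.0)
        vi = competitive_inhibition_rate(1e-6, 5.0, 1.0, 13.0, 5.0)
        assert vi / v0 == pytest.approx(0.5, rel=1e-4)

    def test_mutant_pools_cannot_inhibit_much(self):
        # dUMP at ~0.5 mM vs apparent K_I 3.9 mM, dTMP at 100 uM, K_M 13 uM
        v0 = competitive_inhibition_rate(100.0, 0.0, 1.0, 13.0, 3900.0)
        vi = competitive_inhibition_rate(100.0, 500.0, 1.0, 13.0, 3900.0)
        assert vi / v0 == pytest.approx(0.985, abs=0.002)  # ~1.5% inhibition


def toy_table(rows):
    base = {
        "strain": "WT",
        "condition": "minimal+AA",
        "supplement_mM": 0.0,
        "timepoint_h": 4.0,
        "replicate": 1,
        "is_censored": False,
    }
    return MetabolomicsTable(pd.DataFrame([{**base, **r} for r in rows]))


class TestBuildInvivoCurve:
    def test_single_key_single_point(self):
        table = toy_table(
            [
                {"metabolite": "dTMP", "relative_abundance": 0.5},
                {"metabolite": "dTDP", "relative_abundance": 0.2},
            ]
        )
        pts = build_invivo_curve(table, "dTMP", "dTDP")
        assert len(pts) == 1
        assert (pts.x[0], pts.y[0]) == (0.5, 0.2)

    def test_censored_product_excluded_with_warning(self, caplog):
        table = toy_table(
            [
                {"metabolite": "dTMP", "relative_abundance": 0.5},
                {"metabolite": "dTTP", "relative_abundance": 0.005, "is_censored": True},
                {"metabolite": "dTMP", "relative_abundance": 0.9, "replicate": 2},
                {"metabolite": "dTTP", "relative_abundance": 0.8, "replicate": 2},
            ]
        )
        with caplog.at_level(logging.WARNING, logger="invivokin.fitting"):
            pts = build_invivo_curve(table, "dTMP", "dTTP")
        assert len(pts) == 1  # replicate 1 dropped
        assert "detection limit" in caplog.text

    def test_replicates_kept_individually(self):
        rows = []
        for rep in (1, 2, 3):
            rows.append({"metabolite": "dTMP", "relative_abundance": 0.5, "replicate": rep})
            rows.append({"metabolite": "dTDP", "relative_abundance": 0.2 + 0.01 * rep, "replicate": rep})
        pts = build_invivo_curve(toy_table(rows), "dTMP", "dTDP")
        assert len(pts) == 3  # never averaged

    def test_no_matching_keys_is_an_error(self):
        table = toy_table([{"metabolite": "dTMP", "relative_abundance": 0.5}])
        with pytest.raises(EmptyResultError):
            build_invivo_curve(table, "dTMP", "dTDP")
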