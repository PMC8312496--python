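"""Heat-sensitivity slopes, sporulation fractions and colony summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from thermonorms import (
    ValidationError,
    colony_size_summary,
    group_mean_k,
    heat_sensitivity_k,
    sporulation_fraction,
    sporulation_summary,
)
from thermonorms.plate_io import validate_cfu


def _records(totals, temps=(37.0, 44.0, 50.0), strain="s1", replicate=1):
    return pd.DataFrame(
        {
            "strain_id": strain,
            "temperature_c": list(temps),
            "replicate": replicate,
            "total_cfu_ml": list(totals),
            "spore_cfu_ml": 0.0,
        }
    )


class TestHeatSensitivity:
    def test_flat_survival_gives_zero_slope(self):
        est = heat_sensitivity_k(_records([1e8, 1e8, 1e8]))
        assert est.k == 0.0

    def test_halving_per_degree_gives_minus_ln2(self):
        temps = np.arange(37.0, 51.0)
        totals = 1e8 * 0.5 ** (temps - 37.0)
        for method in ("endpoint", "least_squares"):
            est = heat_sensitivity_k(_records(totals, temps), method=method)
            assert est.k == pytest.approx(-math.log(2), rel=1e-12)

    def test_noiseless_exponential_recovered_to_1e9(self):
        k_true = -2.3
        temps = np.array([37.0, 44.0, 50.0])
        totals = 1e8 * np.exp(k_true * (temps - 37.0))
        for method in ("endpoint", "least_squares"):
            est = heat_sensitivity_k(_records(totals, temps), method=method)
            assert abs(est.k - k_true) < 1e-9

    def test_least_squares_matches_two_pass_regression_oracle(self, rng):
        temps = np.repeat([37.0, 44.0, 50.0], 3)
        totals = 1e8 * np.exp(-1.5 * (temps - 37.0)) * np.exp(rng.normal(0, 0.2, 9))
        frame = _records(totals, temps, replicate=1)
        frame["replicate"] = np.tile([1, 2, 3], 3)
        est = heat_sensitivity_k(frame, method="least_squares")
        # independent two-pass recomputation: centered covariance / variance
        x, y = temps, np.log(totals)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert est.k == pytest.approx(slope, rel=1e-12)

    def test_least_squares_is_the_squared_log_error_minimizer(self):
        """Cross-check against a brute-force grid minimizer of the squared
        ln-CFU residuals (the ML criterion under lognormal noise)."""
        temps = np.array([37.0, 44.0, 50.0])
        totals = np.array([1e8, 5e5, 2e2])
        est = heat_sensitivity_k(_records(totals, temps), method="least_squares")
        y = np.log(totals)
        ks = np.linspace(est.k - 0.5, est.k + 0.5, 2001)
        sse = [np.sum((y - (y.mean() + k * (temps - temps.mean()))) ** 2) for k in ks]
        assert abs(ks[int(np.argmin(sse))] - est.k) < 1e-3

    def test_endpoint_equals_least_squares_on_two_points(self):
        a = heat_sensitivity_k(_records([1e8, 1e4], (37.0, 50.0)), method="endpoint")
        b = heat_sensitivity_k(_records([1e8, 1e4], (37.0, 50.0)), method="least_squares")
        assert a.k == pytest.approx(b.k, rel=1e-12)

    def test_dilution_invariance(self):
        base = _records([1e8, 1e5, 1e2])
        for method in ("endpoint", "least_squares"):
            k1 = heat_sensitivity_k(base, method=method).k
            diluted = base.assign(total_cfu_ml=base["total_cfu_ml"] * 1e-3)
            assert heat_sensitivity_k(diluted, method=method).k == pytest.approx(k1, rel=1e-12)

    def test_zero_cfu_excluded_with_complete_kill_flag(self):
        est = heat_sensitivity_k(_records([1e8, 1e3, 0.0]))
        assert est.complete_kill
        assert est.excluded_temperatures == (50.0,)
        assert est.temperatures == (37.0, 44.0)

    def test_fewer_than_two_usable_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 2 temperatures"):
            heat_sensitivity_k(_records([1e8, 0.0, 0.0]))

    def test_identical_temperatures_rejected(self):
        # identical temperatures collapse to a single usable grid point
        with pytest.raises(ValidationError, match=">= 2 temperatures"):
            heat_sensitivity_k(_records([1e8, 1e6], temps=(37.0, 37.0)))

    def test_literal_difference_compat_form(self):
        est = heat_sensitivity_k(
            _records([100.0, 1100.0], (37.0, 47.0)), literal_difference=True
        )
        assert est.k == pytest.approx(math.log(1000.0) / 10.0)
        # undefined when counts decline (N2 <= N1)
        est = heat_sensitivity_k(_records([1e8, 1e2], (37.0, 50.0)), literal_difference=True)
        assert math.isnan(est.k)


class TestGroupMeanK:
    def _est(self, strain, k):
        return heat_sensitivity_k(
            _records(np.exp([18.0, 18.0 + 13 * k]), (37.0, 50.0), strain=strain)
        )

    def test_hand_mean(self):
        table = group_mean_k([self._est("a", -10 / 13), self._est("b", -20 / 13)], {"a": "G", "b": "G"})
        assert table["K"].tolist() == pytest.approx([-15 / 13])
        assert table["n"].tolist() == [2]

    def test_singleton_group_has_undefined_sd(self):
        table = group_mean_k([self._est("a", -1.0)], {"a": "G"})
        assert table["K"].iloc[0] == pytest.approx(-1.0)
        assert math.isnan(table["sd_k"].iloc[0])

    def test_unmapped_strain_rejected_and_empty_group_warned(self, caplog):
        est = self._est("a", -1.0)
        with pytest.raises(ValidationError, match="without a group"):
            group_mean_k([est], {})
        with caplog.at_level("WARNING"):
            table = group_mean_k([est], {"a": "G", "other": "H"})
        assert table["group"].tolist() == ["G"]
        assert any("no sensitivity estimates" in r.message for r in caplog.records)


class TestSporulation:
    def _rec(self, total, spore):
        return {
            "strain_id": "s1", "temperature_c": 44.0, "replicate": 1,
            "total_cfu_ml": total, "spore_cfu_ml": spore,
        }

    def test_extremes(self):
        assert sporulation_fraction(self._rec(1e6, 1e6)).fraction == 1.0
        assert sporulation_fraction(self._rec(1e6, 0.0)).fraction == 0.0

    def test_excess_capped_at_one(self):
        rec = sporulation_fraction(self._rec(100.0, 104.0))
        assert rec.fraction == 1.0 and rec.capped

    def test_zero_total_is_undefined_and_flagged(self):
        rec = sporulation_fraction(self._rec(0.0, 0.0))
        assert rec.undefined and math.isnan(rec.fraction)

    def test_dilution_invariance(self):
        a = sporulation_fraction(self._rec(2e6, 6e5)).fraction
        b = sporulation_fraction(self._rec(2e3, 6e2)).fraction
        assert a == pytest.approx(b, rel=1e-12)

    def test_binomial_sampling_is_unbiased(self, rng):
        """Mean of 500 binomially sampled fraction estimates at true
        fraction 0.3 lies within 0.02 of the truth."""
        total = 200
        estimates = [
            sporulation_fraction(self._rec(total, rng.binomial(total, 0.3))).fraction
            for _ in range(500)
        ]
        assert abs(np.mean(estimates) - 0.3) < 0.02

    def test_summary_aggregates_replicates(self):
        frame = pd.DataFrame(
            [self._rec(100.0, 30.0), self._rec(100.0, 50.0)]
        ).assign(replicate=[1, 2])
        out = sporulation_summary(validate_cfu(frame))
        assert out["mean_fraction"].iloc[0] == pytest.approx(0.4)
        assert out["n"].iloc[0] == 2


class TestColonySummary:
    def _table(self, diameters):
        return pd.DataFrame(
            {
                "strain_id": "s1", "temperature_c": 37.0, "time_h": 24.0,
                "colony_index": range(1, len(diameters) + 1), "diameter_mm": diameters,
            }
        )

    def test_hand_arithmetic(self):
        out = colony_size_summary(self._table([2.0, 3.0, 4.0]))
        assert out["mean_diameter_mm"].iloc[0] == pytest.approx(3.0)
        assert out["sd_diameter_mm"].iloc[0] == pytest.approx(1.0)
        assert not out["no_growth"].iloc[0]

    def test_all_zero_diameters_flag_no_growth(self):
        out = colony_size_summary(self._table([0.0, 0.0, 0.0]))
        assert out["no_growth"].iloc[0]

    def test_matches_independent_recomputation(self, rng):
        d = rng.uniform(0.5, 6.0, size=3)
        out = colony_size_summary(self._table(d))
        assert out["mean_diameter_mm"].iloc[0] == pytest.approx(float(np.mean(d)))
        assert out["sd_diameter_mm"].iloc[0] == pytest.approx(float(np.std(d, ddof=1)))
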