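"""Reaction-norm assembly, optimum detection and thermal-niche geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermonorms import (
    NoGrowthError,
    ReactionNorm,
    ReplicateSummary,
    ValidationError,
    build_reaction_norm,
    compute_thermal_niche,
    find_optima,
)


def _summary(strain, temp, mu, sd=0.05, n=3, no_growth=False):
    return ReplicateSummary(
        strain_id=strain, temperature_c=temp, n=n, mean_mu=mu, sd_mu=sd,
        mean_td_h=math.log(2) / mu if mu > 0 else math.nan,
        n_no_growth=n if no_growth else 0, no_growth=no_growth,
    )


def _norm(temps, mus, strain="s"):
    temps = np.asarray(temps, float)
    return ReactionNorm(
        strain_id=strain, temperatures=temps, mean_mu=np.asarray(mus, float),
        sd_mu=np.zeros_like(temps), n=np.full(len(temps), 3),
    )


def _dense_crossings(norm, f, step=1e-4):
    """Dense-grid oracle: scan the piecewise-linear interpolant at ``step``
    resolution for the first sub-threshold points outward from the optima."""
    thr = f * norm.mu_max
    grid = np.arange(norm.temperatures[0], norm.temperatures[-1] + step / 2, step)
    v = np.interp(grid, norm.temperatures, norm.mean_mu)
    optima = find_optima(norm)
    left = grid <= optima[0]
    below_left = np.flatnonzero(left & (v < thr))
    t_lo = grid[below_left[-1]] if below_left.size else norm.temperatures[0]
    right = grid >= optima[-1]
    below_right = np.flatnonzero(right & (v < thr))
    t_hi = grid[below_right[0]] if below_right.size else norm.temperatures[-1]
    return t_lo, t_hi


class TestBuildReactionNorm:
    def test_grid_sorted_ascending(self):
        norm = build_reaction_norm(
            [_summary("s", 17, 0.2), _summary("s", 27, 0.5), _summary("s", 37, 0.7)]
        )
        assert len(norm.temperatures) == 3
        assert np.all(np.diff(norm.temperatures) > 0)

    def test_shuffled_input_gives_identical_norm(self):
        summaries = [_summary("s", t, m) for t, m in [(17, 0.2), (27, 0.5), (37, 0.7)]]
        a = build_reaction_norm(summaries)
        b = build_reaction_norm(summaries[::-1])
        np.testing.assert_array_equal(a.temperatures, b.temperatures)
        np.testing.assert_array_equal(a.mean_mu, b.mean_mu)

    def test_no_growth_consensus_contributes_zero(self):
        norm = build_reaction_norm(
            [_summary("s", 37, 0.7), _summary("s", 55, 0.05, no_growth=True)]
        )
        assert norm.mean_mu[-1] == 0.0

    def test_duplicate_temperature_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_reaction_norm([_summary("s", 37, 0.7), _summary("s", 37, 0.6)])

    def test_means_match_independent_recomputation(self, rng):
        temps = [17.0, 27.0, 37.0, 43.0]
        raw = {t: rng.uniform(0.1, 1.0, size=3) for t in temps}
        summaries = [
            _summary("s", t, float(np.mean(v)), sd=float(np.std(v, ddof=1))) for t, v in raw.items()
        ]
        norm = build_reaction_norm(summaries)
        for t, v in raw.items():
            i = int(np.searchsorted(norm.temperatures, t))
            assert norm.mean_mu[i] == pytest.approx(float(np.mean(v)))


class TestFindOptima:
    def test_unique_argmax(self):
        assert find_optima(_norm([17, 37, 49], [0.2, 0.7, 0.5]), plateau_tol=0.0) == [37.0]

    def test_two_near_equal_peaks_within_tolerance(self):
        # a plateau norm with two peaks differing by <5% yields co-optima
        norm = _norm([17, 27, 37, 43, 46, 49, 55], [0.1, 0.5, 0.88, 0.8, 0.86, 0.87, 0.0])
        assert find_optima(norm, plateau_tol=0.05) == [37.0, 46.0, 49.0]

    def test_all_zero_norm_gives_empty_list_and_flag(self):
        norm = _norm([17, 37], [0.0, 0.0])
        assert find_optima(norm) == []
        assert norm.no_growth

    def test_matches_bruteforce_threshold_scan(self, rng):
        mus = rng.uniform(0, 1, size=8)
        temps = np.arange(8) * 5.0 + 17
        tol = 0.1
        norm = _norm(temps, mus)
        expected = [float(t) for t, m in zip(temps, mus) if m >= (1 - tol) * mus.max()]
        assert find_optima(norm, plateau_tol=tol) == expected


class TestThermalNiche:
    def test_triangular_norm_exact_crossings(self):
        niche = compute_thermal_niche(_norm([17, 37, 47], [0.0, 1.0, 0.0]), f=0.75)
        assert niche.t_lo == pytest.approx(32.0, abs=1e-12)
        assert niche.t_hi == pytest.approx(39.5, abs=1e-12)
        assert niche.breadth == pytest.approx(7.5, abs=1e-12)
        assert not (niche.censored_low or niche.censored_high)

    def test_edge_above_threshold_is_clamped_and_censored(self):
        niche = compute_thermal_niche(_norm([17, 37, 47], [0.9, 1.0, 0.0]), f=0.75)
        assert niche.t_lo == 17.0 and niche.censored_low
        assert not niche.censored_high

    def test_all_zero_norm_rejected(self):
        with pytest.raises(NoGrowthError):
            compute_thermal_niche(_norm([17, 37], [0.0, 0.0]))

    def test_crossings_match_dense_grid_oracle_on_random_tpcs(self):
        """Interpolated crossings agree with a 1e-4 °C dense-grid scan of the
        same interpolant, over 50 random synthetic TPC-shaped norms."""
        from thermonorms import TPCModel, tpc_rate

        rng = np.random.default_rng(42)
        grid = np.array([17.0, 27.0, 37.0, 41.0, 43.0, 46.0, 49.0, 55.0])
        checked = 0
        while checked < 50:
            t_min = rng.uniform(2, 15)
            t_opt_lo = t_min + rng.uniform(8, 25)
            width = rng.choice([0.0, rng.uniform(2, 8)])
            t_opt_hi = t_opt_lo + width
            model = TPCModel(
                "plateau" if width else "sharp_drop",
                t_min, t_opt_lo, t_opt_hi, t_opt_hi + rng.uniform(2, 8),
                rng.uniform(0.3, 1.5),
            )
            norm = _norm(grid, tpc_rate(model, grid))
            if norm.mu_max == 0:
                continue
            checked += 1
            niche = compute_thermal_niche(norm, f=0.75)
            t_lo, t_hi = _dense_crossings(norm, f=0.75)
            assert abs(niche.t_lo - t_lo) < 1e-3
            assert abs(niche.t_hi - t_hi) < 1e-3

    def test_optimum_lies_inside_niche(self, rng):
        for _ in range(20):
            mus = rng.uniform(0, 1, size=6)
            mus[rng.integers(6)] = 1.0
            niche = compute_thermal_niche(_norm(np.arange(6) * 6.0 + 15, mus))
            assert niche.t_lo <= min(niche.optima) <= max(niche.optima) <= niche.t_hi


@st.composite
def norms(draw):
    n = draw(st.integers(4, 9))
    temps = 15 + np.cumsum(np.array(draw(
        st.lists(st.floats(1.0, 8.0), min_size=n, max_size=n)
    )))
    mus = np.array(draw(st.lists(st.floats(0.0, 2.0), min_size=n, max_size=n)))
    if mus.max() == 0:
        mus[draw(st.integers(0, n - 1))] = 1.0
    return _norm(temps, mus)


class TestNicheProperties:
    @settings(derandomize=True, max_examples=100)
    @given(norm=norms(), f_pair=st.tuples(st.floats(0.2, 0.9), st.floats(0.2, 0.9)))
    def test_niche_nesting(self, norm, f_pair):
        """A stricter threshold always yields a nested niche."""
        f1, f2 = min(f_pair), max(f_pair)
        if f1 == f2:
            return
        wide = compute_thermal_niche(norm, f=f1)
        narrow = compute_thermal_niche(norm, f=f2)
        assert wide.t_lo <= narrow.t_lo + 1e-9
        assert narrow.t_hi <= wide.t_hi + 1e-9

    @settings(derandomize=True, max_examples=100)
    @given(norm=norms(), c=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, norm, c):
        """Rescaling all growth rates moves neither optima nor crossings."""
        scaled = _norm(norm.temperatures, norm.mean_mu * c)
        a = compute_thermal_niche(norm)
        b = compute_thermal_niche(scaled)
        assert a.optima == b.optima
        assert b.t_lo == pytest.approx(a.t_lo, rel=1e-9, abs=1e-9)
        assert b.t_hi == pytest.approx(a.t_hi, rel=1e-9, abs=1e-9)
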