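import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from oracles import grid_search_cosinor
from wormclock import (
    DegenerateDesignError,
    circadian_design,
    classify_rhythmic,
    fit_cosinor,
    rhythm_test,
    scan_periods,
    simulate_expression,
)
import pandas as pd

T48 = np.arange(0.0, 48.0, 4.0)


class TestFitCosinor:
    def test_exact_recovery_on_noiseless_cosine(self):
        y = 2.0 + np.cos(2 * np.pi * T48 / 24.0)
        fit = fit_cosinor(y, T48, 24.0)
        assert fit.mesor == pytest.approx(2.0)
        assert fit.amplitude == pytest.approx(2.0)  # peak-to-trough of a unit cosine
        assert fit.phase == pytest.approx(0.0, abs=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_phase_is_peak_position(self):
        y = 3.0 + 0.5 * np.cos(2 * np.pi * T48 / 24.0 - 1.0)
        fit = fit_cosinor(y, T48, 24.0)
        assert fit.amplitude == pytest.approx(1.0)
        assert fit.phase == pytest.approx(1.0)

    def test_constant_series_convention(self):
        fit = fit_cosinor(np.full_like(T48, 5.0), T48, 24.0)
        assert fit.amplitude == 0.0
        assert fit.phase == 0.0
        assert fit.mesor == pytest.approx(5.0)

    def test_preconditions(self):
        with pytest.raises(DegenerateDesignError):
            fit_cosinor([1.0, 2.0, 3.0], [0.0, 4.0, 8.0], 24.0)  # < 4 obs
        with pytest.raises(DegenerateDesignError):
            fit_cosinor([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 4.0, 4.0], 24.0)  # < 3 times
        with pytest.raises(ValueError, match="period"):
            fit_cosinor([1.0, 2.0, 3.0, 4.0], [0.0, 4.0, 8.0, 12.0], -1.0)

    def test_aliasing_period_is_degenerate(self):
        # at period 8 h with 4 h sampling the sine column vanishes
        y = np.random.default_rng(0).normal(size=T48.size)
        with pytest.raises(DegenerateDesignError):
            fit_cosinor(y, T48, 8.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(2.0, 1.0) + rng.normal(0, 1) * np.cos(
            2 * np.pi * T48 / 24.0
        ) + rng.normal(0, 1) * np.sin(2 * np.pi * T48 / 24.0) + rng.normal(0, 0.3, T48.size)
        fit = fit_cosinor(y, T48, 24.0)
        m, amp, phase, rss = grid_search_cosinor(y, T48, 24.0)
        assert fit.mesor == pytest.approx(m, abs=1e-3)
        assert fit.amplitude == pytest.approx(amp, abs=1e-3)
        dphi = np.angle(np.exp(1j * (fit.phase - phase)))
        assert abs(dphi) < 1e-3
        assert fit.rss == pytest.approx(rss, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        c=st.floats(min_value=0.1, max_value=10.0),
        d=st.floats(min_value=-5.0, max_value=5.0),
    )
    def test_scale_and_shift_equivariance(self, c, d):
        rng = np.random.default_rng(99)
        y = 1.0 + 0.8 * np.cos(2 * np.pi * T48 / 24.0 - 0.7) + rng.normal(0, 0.2, T48.size)
        base = fit_cosinor(y, T48, 24.0)
        moved = fit_cosinor(c * y + d, T48, 24.0)
        assert moved.mesor == pytest.approx(c * base.mesor + d, rel=1e-9, abs=1e-9)
        assert moved.amplitude == pytest.approx(c * base.amplitude, rel=1e-9)
        assert moved.rss == pytest.approx(c**2 * base.rss, rel=1e-6, abs=1e-12)
        assert moved.phase == pytest.approx(base.phase, abs=1e-9)


class TestScanPeriods:
    def test_recovers_planted_grid_period(self):
        y = 1.0 + np.cos(2 * np.pi * T48 / 24.0 - 0.5)
        assert scan_periods(y, T48, 20.0, 28.0, 0.5).period == 24.0

    def test_off_grid_period_snaps_to_nearest_rss_minimum(self):
        y = 1.0 + np.cos(2 * np.pi * T48 / 22.3)
        best = scan_periods(y, T48, 20.0, 28.0, 0.5)
        # independent check: rss at 22.5 below every other grid period
        assert best.period == 22.5

    def test_constant_series_takes_shortest_period(self):
        best = scan_periods(np.full_like(T48, 3.0), T48, 20.0, 28.0, 0.5)
        assert best.period == 20.0
        assert best.amplitude == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scan_periods(np.ones_like(T48), T48, 28.0, 20.0, 0.5)


class TestRhythmTest:
    def test_refuses_mixed_conditions(self):
        from wormclock import knockdown_design

        m, _ = simulate_expression(knockdown_design(seed=0), 20, 0.0)
        with pytest.raises(ValueError, match="subset_condition"):
            rhythm_test(m, 20, 28, n_permutations=99)

    def test_refuses_few_timepoints(self):
        from wormclock import SimulationDesign

        d = SimulationDesign(timepoints=tuple(float(x) for x in range(0, 28, 4)))
        m, _ = simulate_expression(d, 20, 0.0)
        with pytest.raises(ValueError, match="8 distinct timepoints"):
            rhythm_test(m, 20, 28, n_permutations=99)

    def test_refuses_too_few_permutations(self, circ_matrix_truth):
        m, _ = circ_matrix_truth
        with pytest.raises(ValueError, match="99"):
            rhythm_test(m, 20, 28, n_permutations=10)

    def test_strong_gene_attains_minimal_p(self):
        d = circadian_design(seed=2, noise_sd=0.1)
        from wormclock import Fixed, TruncatedNormal

        m, _ = simulate_expression(
            d, 30, 1.0, amplitude_dist=TruncatedNormal(mean_=2.0, sd=0.0)
        )
        table = rhythm_test(m, 20, 28, n_permutations=199, seed=0)
        assert (table["p_raw"] == 1.0 / 200.0).all()

    def test_null_pvalues_roughly_uniform(self):
        m, _ = simulate_expression(circadian_design(seed=5), 200, 0.0)
        table = rhythm_test(m, 20, 28, n_permutations=299, seed=5)
        frac = (table["p_raw"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / len(table))
        assert kstest(table["p_raw"], "uniform").pvalue > 0.01

    def test_q_monotone_in_p(self, circ_matrix_truth):
        m, _ = circ_matrix_truth
        table = rhythm_test(m, 20, 28, n_permutations=99, seed=1)
        srt = table.sort_values("p_raw")
        assert (np.diff(srt["q"]) >= -1e-12).all()
        assert table["rss"].le(((m.values.sub(m.values.mean(axis=1), axis=0)) ** 2).sum(axis=1) + 1e-9).all()

    def test_bh_qvalues_match_step_up_on_tied_vector(self):
        """The BH convention used by the table: p (.01,.02,.03,.04) -> all .04."""
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(q, 0.04)


class TestClassifyRhythmic:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["q", "amplitude_log2"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_amplitude_threshold_is_strict(self):
        table = self._table([(0.05, 1.5), (0.05, 0.9), (0.05, 1.0), (0.2, 3.0)])
        assert classify_rhythmic(table, 0.10, 1.0) == {"g0"}

    def test_empty_table(self):
        assert classify_rhythmic(self._table([]), 0.1, 1.0) == set()

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_rhythmic(self._table([(0.5, 1.0)]), 0.0, 1.0)
        with pytest.raises(ValueError):
            classify_rhythmic(self._table([(0.5, 1.0)]), 0.1, -1.0)
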