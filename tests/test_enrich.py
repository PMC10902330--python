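import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import fisher_two_sided, holm_by_hand, hypergeom_upper_tail
from wormclock import (
    compare_conditions,
    dual_period_overlap,
    fisher_exact_2x2,
    holm_adjust,
    knockdown_design,
    phase_enrichment,
    shuffle_null,
    simulate_expression,
)


class TestFisher:
    def test_balanced_table_is_null(self):
        odds, p = fisher_exact_2x2([[1, 1], [1, 1]])
        assert p == 1.0 and odds == 1.0

    def test_diagonal_table(self):
        odds, p = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)
        assert odds == np.inf

    def test_zero_margin(self):
        odds, p = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0 and np.isnan(odds)

    def test_sample_odds_ratio(self):
        odds, _ = fisher_exact_2x2([[6, 2], [3, 4]])
        assert odds == pytest.approx(6 * 4 / (2 * 3))

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0.5, 1], [1, 1]])

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(100):
            a, b, c, d = rng.integers(0, 9, size=4)
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(fisher_two_sided(int(a), int(b), int(c), int(d)), abs=1e-12)


class TestHolm:
    def test_hand_worked_example(self):
        assert np.allclose(holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_and_degenerate(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)
        assert holm_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=8))
    def test_dominates_raw_p_and_matches_hand_rule(self, ps):
        adj = holm_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert np.allclose(adj, holm_by_hand(ps))

    def test_order_invariance(self, rng):
        ps = rng.uniform(size=6)
        perm = rng.permutation(6)
        assert np.allclose(holm_adjust(ps)[perm], holm_adjust(ps[perm]))


def _presence_frame(spec):
    """spec: list of (prefix, n, n_present) -> one-motif presence frame."""
    genes, present = [], []
    for prefix, n, k in spec:
        genes += [f"{prefix}{i}" for i in range(n)]
        present += [True] * k + [False] * (n - k)
    return pd.DataFrame({"RORE": present}, index=genes)


class TestPhaseEnrichment:
    def _bins(self, spec):
        out = {}
        for prefix, n, _ in spec:
            if prefix != "bg":
                out.update({f"{prefix}{i}": prefix for i in range(n)})
        return pd.Series(out)

    def test_planted_enrichment_detected_only_in_planted_bin(self):
        spec = [("magenta", 100, 80), ("navy", 100, 20), ("gray", 100, 20), ("bg", 700, 140)]
        pres = _presence_frame(spec)
        result = phase_enrichment(self._bins(spec), pres, pres.index)
        r = result.set_index("bin")
        assert r.loc["magenta", "p_holm"] < 1e-3
        assert r.loc["magenta", "odds_ratio"] > 1
        assert (r.drop("magenta")["p_holm"] >= 0.05).all()

    def test_two_by_two_margins_consistent(self):
        spec = [("magenta", 50, 30), ("bg", 100, 20)]
        pres = _presence_frame(spec)
        result = phase_enrichment(self._bins(spec), pres, pres.index)
        row = result.iloc[0]
        assert row["a"] + row["b"] == 50
        assert row["c"] + row["d"] == 100
        assert row["a"] == 30 and row["c"] == 20

    def test_null_placement_false_positive_rate(self, rng):
        hits = 0
        trials = 0
        for _ in range(40):
            spec = [
                ("magenta", 60, rng.binomial(60, 0.2)),
                ("navy", 60, rng.binomial(60, 0.2)),
                ("bg", 200, rng.binomial(200, 0.2)),
            ]
            pres = _presence_frame(spec)
            result = phase_enrichment(self._bins(spec), pres, pres.index)
            hits += (result["p"] < 0.05).sum()
            trials += len(result)
        # pre-Holm false-positive count within loose binomial bounds of 5%
        assert hits <= 0.05 * trials + 3 * np.sqrt(trials * 0.05 * 0.95)

    def test_requested_empty_bin_flagged(self):
        spec = [("magenta", 20, 10), ("bg", 40, 10)]
        pres = _presence_frame(spec)
        result = phase_enrichment(
            self._bins(spec), pres, pres.index, test_bins=["magenta", "gray"]
        )
        gray = result.set_index("bin").loc["gray"]
        assert gray["empty_bin"] and gray["p"] == 1.0

    def test_background_modes_differ(self):
        spec = [("magenta", 30, 25), ("navy", 30, 25), ("bg", 100, 10)]
        pres = _presence_frame(spec)
        bins = self._bins(spec)
        rest = phase_enrichment(bins, pres, pres.index, background="rest").set_index("bin")
        arr = phase_enrichment(bins, pres, pres.index, background="arrhythmic").set_index("bin")
        # navy's presence inflates magenta's "rest" background but not the
        # arrhythmic-only background
        assert rest.loc["magenta", "c"] > arr.loc["magenta", "c"]

    def test_binned_gene_outside_universe_rejected(self):
        pres = _presence_frame([("magenta", 5, 3)])
        with pytest.raises(ValueError, match="universe"):
            phase_enrichment(pd.Series({"zzz": "magenta"}), pres, pres.index)


class TestDualPeriodOverlap:
    def test_disjoint_and_subset(self):
        uni = [f"g{i}" for i in range(20)]
        r = dual_period_overlap(uni[:5], uni[5:10], uni)
        assert r.proportion == 0.0 and r.intersection_size == 0
        r = dual_period_overlap(uni[:5], uni[:10], uni)
        assert r.proportion == 1.0

    def test_empty_circadian_flagged(self):
        r = dual_period_overlap([], ["g1"], ["g1", "g2"])
        assert r.undefined and np.isnan(r.proportion)

    def test_hypergeometric_matches_enumeration(self, rng):
        uni = [f"g{i}" for i in range(18)]
        for _ in range(20):
            circ = list(rng.choice(uni, size=7, replace=False))
            dev = list(rng.choice(uni, size=6, replace=False))
            r = dual_period_overlap(circ, dev, uni)
            expect = hypergeom_upper_tail(r.intersection_size, 18, 6, 7)
            assert r.p_hypergeom == pytest.approx(expect, abs=1e-12)

    def test_per_bin_proportions(self):
        uni = [f"g{i}" for i in range(10)]
        bins = pd.Series({"g0": "magenta", "g1": "magenta", "g2": "navy"})
        r = dual_period_overlap(["g0", "g1", "g2"], ["g0", "g5"], uni, bins)
        assert r.per_bin["magenta"]["proportion"] == 0.5
        assert r.per_bin["navy"]["proportion"] == 0.0

    def test_sets_must_be_in_universe(self):
        with pytest.raises(ValueError, match="universe"):
            dual_period_overlap(["x"], [], ["g1"])


RHYTHM_KW = dict(period_min=20.0, period_max=28.0, n_permutations=99)


class TestShuffleNullAndComparison:
    def test_shuffle_null_deterministic(self):
        from wormclock import circadian_design

        m, _ = simulate_expression(circadian_design(seed=4), 40, 0.0)
        a = shuffle_null(m, n_shuffles=3, seed=9, **RHYTHM_KW)
        b = shuffle_null(m, n_shuffles=3, seed=9, **RHYTHM_KW)
        pd.testing.assert_frame_equal(a, b)
        assert (a["q_lt_0.05"] <= a["q_lt_0.3"]).all()

    def test_identical_conditions_lose_nothing(self):
        d = knockdown_design(seed=8, noise_sd=0.15)
        from wormclock import TruncatedNormal

        m, _ = simulate_expression(
            d, 60, 0.4, amplitude_dist=TruncatedNormal(mean_=2.5, sd=0.2)
        )
        comp = compare_conditions(m, "mock", "auxin", q_threshold=0.30, seed=3, **RHYTHM_KW)
        # same planted signal in both conditions: loss is threshold noise only
        assert comp.lost.mean() <= 0.05
        assert comp.counts.loc["mock", "q_lt_0.3"] > 0

    def test_missing_condition_rejected(self, circ_matrix_truth):
        m, _ = circ_matrix_truth
        with pytest.raises(KeyError):
            compare_conditions(m, "main", "auxin", **RHYTHM_KW)
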