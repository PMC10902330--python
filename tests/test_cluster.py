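import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from wormclock import (
    DEFAULT_PHASE_BINS,
    PhaseBin,
    assign_phase_bin,
    assign_phase_bins,
    cosine_distance,
    hierarchical_cluster,
    normalize_profile,
    phase_histogram,
)
from wormclock.cluster import PhaseBinConfigError

T48 = np.arange(0.0, 48.0, 4.0)


class TestNormalizeProfile:
    def test_amplitude_mode_centers_and_scales(self):
        v = normalize_profile([0.0, 1.0, 0.0, -1.0])
        assert v.mean() == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(v) == pytest.approx(1.0)
        assert np.argmax(v) == 1 and np.argmin(v) == 3

    def test_affine_invariance(self):
        x = np.array([1.0, 3.0, 2.0, 0.5])
        assert np.allclose(normalize_profile(x), normalize_profile(4.2 * x + 7.0))

    def test_constant_series_errors_in_amplitude_mode(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_profile([2.0, 2.0, 2.0])

    def test_minmax_mode(self):
        assert np.allclose(normalize_profile([3.0, 5.0, 4.0], mode="minmax"), [0.0, 1.0, 0.5])
        assert np.allclose(normalize_profile([2.0, 2.0], mode="minmax"), [0.0, 0.0])

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            normalize_profile([1.0, 2.0], mode="zscore")


class TestCosineDistance:
    def test_identity_and_antipode(self):
        x = np.array([1.0, 2.0, -1.0])
        assert cosine_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert cosine_distance(x, -x) == pytest.approx(2.0)

    def test_quadrature_cosines_are_orthogonal(self):
        c = np.cos(2 * np.pi * T48 / 24.0)
        s = np.sin(2 * np.pi * T48 / 24.0)
        assert cosine_distance(c, s) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_range(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=12), rng.normal(size=12)
            d = cosine_distance(x, y)
            assert d == pytest.approx(cosine_distance(y, x))
            assert -1e-12 <= d <= 2 + 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_distance([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            cosine_distance([1.0], [1.0, 2.0])


def _waveforms(phases, n_per, noise, rng):
    rows, labels = [], []
    for k, ph in enumerate(phases):
        for _ in range(n_per):
            y = np.cos(2 * np.pi * T48 / 24.0 - ph) + rng.normal(0, noise, T48.size)
            rows.append(normalize_profile(y))
            labels.append(k)
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))]), labels


class TestHierarchicalCluster:
    def test_antiphase_groups_perfectly_separated(self, rng):
        profiles, truth = _waveforms([0.0, np.pi], 20, 0.1, rng)
        got = hierarchical_cluster(profiles, 2).labels
        assert adjusted_rand_score(truth, got) == 1.0

    def test_single_cluster(self, rng):
        profiles, _ = _waveforms([0.0], 5, 0.1, rng)
        assert set(hierarchical_cluster(profiles, 1).labels) == {1}

    def test_order_invariance(self, rng):
        profiles, _ = _waveforms([0.0, 2.0, 4.0], 10, 0.15, rng)
        a = hierarchical_cluster(profiles, 3).labels
        shuffled = profiles.sample(frac=1.0, random_state=1)
        b = hierarchical_cluster(shuffled, 3).labels.loc[a.index]
        assert adjusted_rand_score(a, b) == 1.0

    def test_too_few_genes(self, rng):
        profiles, _ = _waveforms([0.0], 2, 0.1, rng)
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles, 5)
        with pytest.raises(ValueError):
            hierarchical_cluster(profiles, 0)

    def test_magenta_phase_genes_cocluster(self, rng):
        """Genes peaking in the early phase bin should land in one cluster
        even among other peaks and arrhythmic shapes."""
        profiles, truth = _waveforms(
            [np.pi / 3, 2 * np.pi / 3, 3 * np.pi / 2], 30, 0.2, rng
        )
        noise = pd.DataFrame(
            [normalize_profile(rng.normal(size=T48.size)) for _ in range(30)],
            index=[f"n{i}" for i in range(30)],
        )
        allp = pd.concat([profiles, noise])
        labels = hierarchical_cluster(allp, 4).labels
        magenta_ids = profiles.index[:30]
        top = labels.loc[magenta_ids].mode()[0]
        recall = (labels.loc[magenta_ids] == top).mean()
        assert recall >= 0.9


class TestPhaseBins:
    def test_paper_bin_membership(self):
        assert assign_phase_bin(np.pi / 3) == "magenta"
        assert assign_phase_bin(np.pi) == "other"
        assert assign_phase_bin(np.pi / 2) == "navy"  # half-open boundary
        assert assign_phase_bin(1.5 * np.pi) == "gray"

    def test_phase_out_of_range(self):
        with pytest.raises(ValueError):
            assign_phase_bin(-0.1)
        with pytest.raises(ValueError):
            assign_phase_bin(2 * np.pi)

    def test_overlapping_bins_rejected(self):
        bad = (PhaseBin("a", 0.0, 1.0), PhaseBin("b", 0.5, 2.0))
        with pytest.raises(PhaseBinConfigError, match="overlap"):
            assign_phase_bin(0.2, bad)

    def test_vectorized_matches_scalar(self, rng):
        phases = pd.Series(rng.uniform(0, 2 * np.pi, 200))
        vec = assign_phase_bins(phases)
        for ph, label in zip(phases, vec):
            assert label == assign_phase_bin(ph)


class TestPhaseHistogram:
    def test_empty_input(self):
        h = phase_histogram([], 12)
        assert h["count"].sum() == 0 and len(h) == 12

    def test_point_mass(self):
        h = phase_histogram([np.pi / 4] * 100, 12)
        assert h["count"].max() == 100 and h["count"].sum() == 100

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=6.28), max_size=50))
    def test_counts_conserved(self, phases):
        assert phase_histogram(phases, 8)["count"].sum() == len(phases)

    def test_mixture_modes_land_in_planted_bins(self, rng):
        from wormclock import DEFAULT_PHASE_MIXTURE

        phases = DEFAULT_PHASE_MIXTURE.draw(rng, 600)
        n_bins = 12
        h = phase_histogram(phases, n_bins)
        width = 2 * np.pi / n_bins
        mids = (h["lower"] + h["upper"]).to_numpy() / 2
        near_any = np.zeros(n_bins, dtype=bool)
        for center, _, _ in DEFAULT_PHASE_MIXTURE.components:
            d = np.abs(np.angle(np.exp(1j * (mids - center))))
            near = d < 1.5 * width  # center may sit on a bin edge
            near_any |= near
            # each planted peak holds most of its component's ~200 draws
            assert h.loc[near, "count"].sum() > 0.8 * 200
        # bins far from every planted peak are nearly empty
        assert h.loc[~near_any, "count"].sum() < 0.1 * 600
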