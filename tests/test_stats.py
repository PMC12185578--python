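import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dabdepth import (
    histogram, ks_normality, pool_distribution, tertile_compare, wilcoxon_compare,
)
from dabdepth.stats import DepthDistribution, results_table


def make_dist(values, condition="x"):
    values = np.asarray(values, dtype=float)
    return DepthDistribution(
        condition=condition,
        pixel_d_rel=values,
        pixel_dist_epi_um=values * 100,
        pixel_dist_derm_um=(1 - values) * 100,
        blob_mean_d_rel=values,
        replicate_of_pixel=np.zeros(values.size, dtype=int),
        replicate_of_blob=np.zeros(values.size, dtype=int),
    )


class _FakeBlob:
    def __init__(self, pixels, d_rel):
        self.pixels = np.asarray(pixels)
        self.d_rel_values = np.asarray(d_rel, dtype=float)
        self.mean_d_rel = float(self.d_rel_values.mean())


class _FakeField:
    def __init__(self, shape=(20, 20)):
        self.d_top_epi_um = np.fromfunction(lambda r, c: r * 1.0, shape)
        self.d_top_derm_um = np.fromfunction(lambda r, c: (shape[0] - r) * 1.0, shape)


class TestPooling:
    def test_per_pixel_and_per_blob_values(self):
        blob = _FakeBlob([[1, 1], [1, 2], [2, 1], [2, 2]], [0.2, 0.2, 0.4, 0.4])
        dist = pool_distribution([[blob]], [_FakeField()], "c")
        assert sorted(dist.pixel_d_rel.tolist()) == [0.2, 0.2, 0.4, 0.4]
        assert dist.blob_mean_d_rel.tolist() == [pytest.approx(0.3)]

    def test_large_blob_dominates_per_pixel_only(self):
        big = _FakeBlob([[0, i % 20] for i in range(100)], [0.8] * 100)
        small = _FakeBlob([[1, 0], [1, 1], [1, 2], [1, 3]], [0.2] * 4)
        dist = pool_distribution([[big, small]], [_FakeField()], "c")
        assert dist.pixel_d_rel.mean() == pytest.approx((100 * 0.8 + 4 * 0.2) / 104)
        assert dist.blob_mean_d_rel.mean() == pytest.approx(0.5)

    def test_equal_area_blobs_pixel_and_blob_means_agree(self):
        blobs = [
            _FakeBlob([[0, 0], [0, 1]], [0.1, 0.3]),
            _FakeBlob([[1, 0], [1, 1]], [0.7, 0.9]),
        ]
        dist = pool_distribution([blobs], [_FakeField()], "c")
        assert dist.pixel_d_rel.mean() == pytest.approx(dist.blob_mean_d_rel.mean())

    def test_zero_blobs_valid_empty(self):
        dist = pool_distribution([[]], [_FakeField()], "c")
        assert dist.n_pixels == 0 and dist.n_blobs == 0

    def test_replicate_provenance(self):
        b1 = _FakeBlob([[0, 0]], [0.5])
        b2 = _FakeBlob([[0, 1]], [0.6])
        dist = pool_distribution([[b1], [b2]], [_FakeField(), _FakeField()], "c")
        assert dist.replicate_of_pixel.tolist() == [0, 1]


class TestHistogram:
    def test_point_mass_occupies_one_bin(self):
        edges, masses, _, _ = histogram(make_dist([0.5] * 20), n_bins=50)
        assert masses.max() == pytest.approx(1.0)
        assert (masses > 0).sum() == 1

    def test_uniform_sample_flat_within_binomial_error(self):
        rng = np.random.default_rng(0)
        n = 100_000
        _, masses, _, _ = histogram(make_dist(rng.uniform(0, 1, n)), n_bins=50)
        se = np.sqrt(0.02 * 0.98 / n)
        assert np.abs(masses - 0.02).max() < 3 * se + 1e-12

    def test_empty_distribution_raises(self):
        with pytest.raises(ValueError, match="no DAB-positive pixels"):
            histogram(make_dist([]))

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=300), st.integers(1, 80))
    def test_masses_always_sum_to_one(self, values, n_bins):
        _, masses, grid, density = histogram(make_dist(values), n_bins=n_bins)
        assert masses.sum() == pytest.approx(1.0)
        assert np.trapezoid(density, grid) == pytest.approx(1.0, abs=1e-6) or density.max() == 1.0


class TestRankSum:
    def test_fully_separated_small_sample_exact_p(self):
        res = wilcoxon_compare([1, 2, 3], [4, 5, 6], alternative="greater")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.note == "exact"

    def test_identical_tied_samples_symmetric(self):
        res = wilcoxon_compare([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # U = n·m/2 with ties
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_decisively_significant(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 0.7, 10_000)
        res = wilcoxon_compare(a, a + 0.3, alternative="greater")
        assert res.p_value < 1e-6
        assert res.significant

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])

    def test_enumeration_agrees_with_scipy_exact_when_tie_free(self):
        # same p from the enumeration path and scipy's exact method
        from dabdepth.stats import _exact_enumeration_p
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        from scipy.stats import mannwhitneyu
        for alt, scipy_alt in [("two-sided", "two-sided"), ("greater", "less")]:
            p_enum = _exact_enumeration_p(a, b, alt)
            p_scipy = mannwhitneyu(a, b, alternative=scipy_alt, method="exact").pvalue
            assert p_enum == pytest.approx(p_scipy, abs=1e-12)


class TestTertiles:
    def test_identical_inputs_no_signal_in_any_band(self):
        vals = [0.1, 0.2, 0.5, 0.6, 0.9, 0.95]
        for res in tertile_compare(vals, vals):
            assert res.p_value == pytest.approx(1.0)

    def test_shift_into_deep_band_detected_there(self):
        rng = np.random.default_rng(2)
        a = np.concatenate([rng.uniform(0.05, 0.30, 200), rng.uniform(0.70, 0.95, 30)])
        b = np.concatenate([rng.uniform(0.05, 0.30, 30), rng.uniform(0.70, 0.95, 200)])
        bands = tertile_compare(a, b)
        assert bands[2].n_b > bands[2].n_a  # mass moved into the deep band
        total = wilcoxon_compare(a, b, alternative="greater")
        assert total.significant

    def test_empty_band_flagged_not_raised(self):
        a = [0.1, 0.2, 0.9]   # nothing in the middle band
        b = [0.5, 0.55, 0.6]
        bands = tertile_compare(a, b)
        assert "insufficient data" in bands[2].note or "insufficient data" in bands[0].note
        assert any(np.isnan(r.p_value) for r in bands)

    def test_band_edges_partition_unit_interval(self):
        from dabdepth.stats import TERTILE_EDGES
        assert TERTILE_EDGES == (0.0, 1 / 3, 2 / 3, 1.0)


class TestNormality:
    def test_exact_normal_quantiles_not_rejected(self):
        from scipy.stats import norm
        q = norm.ppf(np.linspace(0.0005, 0.9995, 1000))
        assert ks_normality(q) > 0.5

    def test_uniform_data_rejected(self):
        rng = np.random.default_rng(4)
        assert ks_normality(rng.uniform(0, 1, 1000)) < 0.05

    def test_constant_sample_degenerate_rejection(self):
        assert ks_normality(np.full(50, 0.3)) < 1e-10

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


def test_results_table_flattens_nested_results():
    res = {
        "total": wilcoxon_compare([1, 2, 3], [4, 5, 6]),
        "tertiles": tertile_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]),
    }
    df = results_table(res)
    assert len(df) == 4
    assert set(df["comparison"]) == {"total", "tertiles"}
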