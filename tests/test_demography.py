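import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from velutina._neighbors import _BRUTE_MAX, _counts_brute, _counts_kdtree, crowding_counts
from velutina.demography import (
    DemographyParams,
    PosteriorDraws,
    expected_queens,
    latitude_scaling,
    local_crowding,
    sample_offspring,
    sample_params,
)
from velutina.landscape import LandscapeGrid


@pytest.fixture(scope="module")
def flat_grid():
    """Single-class land grid whose southern edge sits at the Andernos
    latitude, so any model latitude is reachable by choosing y."""
    classes = np.full((200, 10), 2, dtype=np.int16)
    return LandscapeGrid(
        classes=classes, cell_size_km=10.0, lat_at_origin_deg=44.74
    )


def y_at(grid, lat):
    return grid.origin_y_km + (lat - grid.lat_at_origin_deg) * grid.km_per_degree_lat


class TestLatitudeScaling:
    def test_tetbury_value(self, dem):
        # (55.9 - 51.64) / (55.9 - 44.74) = 0.3817: ~38% of the Andernos baseline
        assert latitude_scaling(51.64, dem) == pytest.approx(0.38, abs=0.005)

    def test_baseline_and_zero_cline(self, dem):
        assert latitude_scaling(dem.lat_A_deg, dem) == 1.0
        assert latitude_scaling(dem.lat_zero_deg, dem) == 0.0
        assert latitude_scaling(58.0, dem) == 0.0  # north of the cline
        assert latitude_scaling(40.0, dem) == 1.0  # clamped south of baseline

    def test_self_consistency_of_defaults(self, dem):
        # inverting the 38% value at Tetbury recovers the default zero cline
        frac = 0.38
        lat_zero = (51.64 - frac * dem.lat_A_deg) / (1 - frac)
        assert lat_zero == pytest.approx(dem.lat_zero_deg, abs=0.1)

    @given(st.floats(min_value=30.0, max_value=70.0))
    def test_bounded_and_nonincreasing(self, lat):
        dem = DemographyParams()
        s = float(latitude_scaling(lat, dem))
        assert 0.0 <= s <= 1.0
        assert latitude_scaling(lat + 0.5, dem) <= s


class TestCrowding:
    def test_boundary_inclusive_counts(self):
        rc = 3.0
        nests = [(0.5, 0.0), (rc, 0.0), (2 * rc, 0.0)]
        assert local_crowding(nests, 0.0, 0.0, rc) == 2

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, size=(40, 2))
        base = [local_crowding(pts, x, y, 5.0) for x, y in pts]
        shifted = pts + np.array([123.4, -56.7])
        moved = [local_crowding(shifted, x, y, 5.0) for x, y in shifted]
        assert base == moved

    def test_no_neighbours(self):
        assert local_crowding([], 0.0, 0.0, 1.0) == 0

    @given(st.integers(0, 120), st.integers(0, 2**31 - 1))
    def test_vectorised_counts_match_bruteforce(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 30, n)
        y = rng.uniform(0, 30, n)
        fast = crowding_counts(x, y, 2.5)
        slow = np.array(
            [local_crowding(np.column_stack([x, y]), x[i], y[i], 2.5) - 1 for i in range(n)]
        )
        # local_crowding counts the focal point itself when it is in the list
        np.testing.assert_array_equal(fast, slow)

    def test_backends_agree_above_bruteforce_cutoff(self):
        rng = np.random.default_rng(5)
        n = _BRUTE_MAX + 500
        x = rng.uniform(0, 120, n)
        y = rng.uniform(0, 120, n)
        expected = _counts_brute(x, y, 2.0)
        np.testing.assert_array_equal(crowding_counts(x, y, 2.0), expected)
        np.testing.assert_array_equal(_counts_kdtree(x, y, 2.0), expected)


class TestExpectedQueens:
    def test_low_density_at_tetbury(self, flat_grid, dem):
        mu = expected_queens(50.0, y_at(flat_grid, 51.64), 0, flat_grid, dem)
        assert mu == pytest.approx(3.3, rel=0.01)  # 8.7 x 0.3817

    def test_halving_at_K_half(self, flat_grid, dem):
        y = y_at(flat_grid, 50.0)
        mu0 = expected_queens(50.0, y, 0, flat_grid, dem)
        mu_k = expected_queens(50.0, y, dem.K_half, flat_grid, dem)
        assert mu_k == pytest.approx(mu0 / 2)

    def test_zero_north_of_cline(self, flat_grid, dem):
        assert expected_queens(50.0, y_at(flat_grid, 56.5), 0, flat_grid, dem) == 0.0

    def test_water_cell_zero(self, dem):
        classes = np.array([[2, 5]], dtype=np.int16)
        g = LandscapeGrid(classes=classes, cell_size_km=1.0, lat_at_origin_deg=44.74)
        assert expected_queens(1.5, 0.5, 0, g, dem) == 0.0
        assert expected_queens(0.5, 0.5, 0, g, dem) > 0.0

    def test_linear_in_scaling_and_monotone_in_crowding(self, flat_grid, dem):
        y = y_at(flat_grid, 51.0)
        mu1 = expected_queens(5.0, y, 0, flat_grid, dem)
        mu_scaled = expected_queens(5.0, y, 0, flat_grid, dem.with_(scaling_sigma=0.25))
        assert mu_scaled == pytest.approx(0.25 * mu1)
        mus = [float(expected_queens(5.0, y, c, flat_grid, dem)) for c in range(6)]
        assert all(a > b for a, b in zip(mus, mus[1:]))

    def test_exponential_density_form(self, flat_grid):
        dem = DemographyParams(density_form="exponential")
        y = y_at(flat_grid, 50.0)
        mu0 = expected_queens(5.0, y, 0, flat_grid, dem)
        mu3 = expected_queens(5.0, y, 3, flat_grid, dem)
        assert mu3 == pytest.approx(mu0 * np.exp(-3 / dem.K_half))


class TestSampleOffspring:
    def test_zero_mean_always_zero(self):
        rng = np.random.default_rng(0)
        assert np.all(sample_offspring(np.zeros(1000), rng) == 0)

    def test_poisson_moments(self):
        rng = np.random.default_rng(42)
        draws = sample_offspring(np.full(100_000, 3.3), rng)
        se = np.sqrt(3.3 / draws.size)
        assert abs(draws.mean() - 3.3) < 3 * se
        # equidispersion: var ~ mean, var of sample variance ~ (mu + 2 mu^2) / n
        se_var = np.sqrt((3.3 + 2 * 3.3**2) / draws.size)
        assert abs(draws.var(ddof=1) - 3.3) < 3 * se_var

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            sample_offspring(-0.1, np.random.default_rng(0))


class TestPosteriorDraws:
    def make_draws(self):
        return PosteriorDraws(
            pd.DataFrame({"R_A": [6.0, 8.7, 10.0, 12.0, 7.5], "K_half": [1, 2, 3, 2, 1]})
        )

    def test_single_row_always_returned(self):
        draws = PosteriorDraws(pd.DataFrame({"R_A": [9.9]}))
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert sample_params(draws, rng).R_A == 9.9

    def test_rows_sampled_uniformly(self):
        draws = self.make_draws()
        rng = np.random.default_rng(7)
        picks = [sample_params(draws, rng).R_A for _ in range(10_000)]
        counts = pd.Series(picks).value_counts()
        chi2 = (((counts - 2000) ** 2) / 2000).sum()
        assert stats.chi2.sf(chi2, df=4) > 0.01

    def test_merged_over_defaults_and_reproducible(self):
        draws = self.make_draws()
        p1 = sample_params(draws, np.random.default_rng(3))
        p2 = sample_params(draws, np.random.default_rng(3))
        assert p1 == p2
        assert p1.lat_zero_deg == DemographyParams().lat_zero_deg  # default kept

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            PosteriorDraws(pd.DataFrame({"R_A": []}))
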