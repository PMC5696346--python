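import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from mobisim import (
    FRACTAL_FAMILIES,
    FractalDomainSpec,
    SpatialDomain,
    box_counting_dimension,
    estimate_fractal_dimension,
    fractal_box_sizes,
    generate_fractal_domain,
    generate_synthetic_population,
    load_locations,
)
from mobisim.domain import fractal_points

from conftest import brute_force_W


class TestLoadLocations:
    def test_single_location(self):
        dom = load_locations(pd.DataFrame({"id": [0], "x": [1.0], "y": [2.0], "m": [7]}))
        assert dom.N == 1
        assert dom.W[0, 0] == 7

    def test_collinear_construction(self):
        df = pd.DataFrame({"id": [0, 1, 2], "x": [0.0, 1.0, 2.0],
                           "y": [0.0, 0.0, 0.0], "m": [1, 2, 3]})
        dom = load_locations(df)
        assert dom.N == 3
        assert dom.total_population == 6

    @pytest.mark.parametrize("df,msg", [
        (pd.DataFrame({"id": [0], "x": [0.0], "y": [0.0], "m": [0]}), "positive"),
        (pd.DataFrame({"id": [0, 0], "x": [0, 1], "y": [0, 0], "m": [1, 1]}), "duplicate"),
        (pd.DataFrame({"id": [0], "x": [0.0], "y": [0.0]}), "missing"),
        (pd.DataFrame({"id": [1, 2], "x": [0, 1], "y": [0, 0], "m": [1, 1]}), "contiguous"),
    ])
    def test_malformed_tables_rejected(self, df, msg):
        with pytest.raises(ValueError, match=msg):
            load_locations(df)

    def test_csv_round_trip(self, tmp_path, random_domain):
        path = tmp_path / "loc.csv"
        random_domain.to_frame().to_csv(path, index=False)
        dom = load_locations(path)
        np.testing.assert_allclose(dom.x, random_domain.x)
        np.testing.assert_array_equal(dom.m, random_domain.m)

    def test_lonlat_converted_to_km(self):
        # two points one degree of latitude apart ~ 111 km
        df = pd.DataFrame({"id": [0, 1], "lon": [10.0, 10.0], "lat": [45.0, 46.0],
                           "m": [1, 1]})
        dom = load_locations(df)
        d = dom.distances_from(0)[1]
        assert 105 < d < 118


class TestCumulativePopulation:
    def test_two_locations_inclusive(self, two_loc_domain):
        # both endpoints lie inside the circle by the inclusive convention
        assert two_loc_domain.W[1, 0] == 15
        assert two_loc_domain.W[0, 1] == 15
        B = two_loc_domain.competition_matrix()
        assert B[0, 1] == pytest.approx(10 / 15)

    def test_equilateral_tie_inclusive(self, triangle_domain):
        # the third vertex sits exactly on the circle boundary: included
        W = triangle_domain.W
        off = W[~np.eye(3, dtype=bool)]
        assert np.all(off == 12)

    def test_matches_brute_force_oracle(self, random_domain):
        np.testing.assert_array_equal(random_domain.W, brute_force_W(random_domain))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_various_sizes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 31))
        dom = SpatialDomain(rng.uniform(0, 10, n), rng.uniform(0, 10, n),
                            rng.integers(1, 100, n))
        np.testing.assert_array_equal(dom.W, brute_force_W(dom))

    def test_row_nondecreasing_in_distance(self, random_domain):
        for j in range(random_domain.N):
            d = random_domain.distances_from(j)
            w = random_domain.W[j][np.argsort(d)]
            assert np.all(np.diff(w) >= 0)
            assert w[-1] == random_domain.total_population
            assert random_domain.W[j, j] == random_domain.m[j]


class TestFractals:
    @pytest.mark.parametrize("family,depth", [
        ("cantor_dust_2d", 3), ("vicsek", 3), ("sierpinski_triangle", 5),
        ("hexaflake", 3)])
    def test_point_count_is_copies_to_depth(self, family, depth):
        copies = FRACTAL_FAMILIES[family][0]
        dom = generate_fractal_domain(FractalDomainSpec(family, depth))
        assert dom.N == copies ** depth
        assert np.all(dom.m == 1)

    def test_cantor_depth1_cell_corners(self):
        pts = fractal_points(FractalDomainSpec("cantor_dust_2d", 1, extent=1.0))
        # four cell centres at offsets {1/6, 2/3+1/6} in each axis
        expected = {(1 / 6, 1 / 6), (1 / 6 + 2 / 3, 1 / 6),
                    (1 / 6, 1 / 6 + 2 / 3), (1 / 6 + 2 / 3, 1 / 6 + 2 / 3)}
        got = {(round(p[0], 9), round(p[1], 9)) for p in pts}
        assert got == {(round(a, 9), round(b, 9)) for a, b in expected}

    def test_vicsek_depth2_matches_hand_expansion(self):
        # independent two-level IFS expansion
        offs = [(0, 0), (2 / 3, 0), (0, 2 / 3), (2 / 3, 2 / 3), (1 / 3, 1 / 3)]
        expected = set()
        for o1 in offs:
            for o2 in offs:
                x = (0.5 / 9 + o2[0] / 3 + o1[0], 0.5 / 9 + o2[1] / 3 + o1[1])
                expected.add((round(x[0], 9), round(x[1], 9)))
        pts = fractal_points(FractalDomainSpec("vicsek", 2, extent=1.0))
        got = {(round(p[0], 9), round(p[1], 9)) for p in pts}
        assert got == expected
        assert len(got) == 25

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown fractal family"):
            fractal_points(FractalDomainSpec("menger", 2))

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            fractal_points(FractalDomainSpec("vicsek", 0))


class TestBoxCounting:
    def test_cantor_dust_exact_dimension(self):
        spec = FractalDomainSpec("cantor_dust_2d", 5)
        dom = generate_fractal_domain(spec)
        dim = box_counting_dimension(dom, fractal_box_sizes(spec))
        assert dim == pytest.approx(math.log(4) / math.log(3), abs=1e-9)

    def test_sierpinski_exact_dimension(self):
        spec = FractalDomainSpec("sierpinski_triangle", 6)
        dom = generate_fractal_domain(spec)
        dim = box_counting_dimension(dom, fractal_box_sizes(spec))
        assert dim == pytest.approx(math.log(3) / math.log(2), abs=1e-9)

    def test_filled_grid_is_plane_filling(self):
        g = (np.arange(128) + 0.5) / 128  # cell centres, clear of box edges
        xx, yy = np.meshgrid(g, g)
        dom = SpatialDomain(xx.ravel(), yy.ravel(), np.ones(128 * 128, dtype=int))
        sizes = 1.0 / 2 ** np.arange(1, 7)
        assert box_counting_dimension(dom, sizes) == pytest.approx(2.0, abs=0.05)

    def test_refined_estimate_matches_plain_for_grid_families(self):
        spec = FractalDomainSpec("vicsek", 5)
        plain = box_counting_dimension(generate_fractal_domain(spec),
                                       fractal_box_sizes(spec))
        refined = estimate_fractal_dimension(spec)
        assert refined == pytest.approx(plain, abs=1e-9)

    def test_too_narrow_size_range_rejected(self):
        dom = generate_fractal_domain(FractalDomainSpec("vicsek", 3))
        with pytest.raises(ValueError, match="1.5 decades"):
            box_counting_dimension(dom, [1.0, 0.5, 0.25])

    def test_degenerate_point_set(self):
        dom = SpatialDomain([1.0, 1.0], [2.0, 2.0], [1, 1])
        assert box_counting_dimension(dom, [1.0, 0.1, 0.01]) == 0.0


class TestSyntheticPopulation:
    def test_rank_size_law(self):
        dom = generate_synthetic_population(10, zipf_exponent=1.0, seed=0)
        sizes = np.sort(dom.m)[::-1].astype(float)
        expected = np.maximum(1, np.round(10_000 / np.arange(1, 11)))
        np.testing.assert_array_equal(sizes, expected)

    def test_deterministic_under_seed(self):
        a = generate_synthetic_population(30, seed=9)
        b = generate_synthetic_population(30, seed=9)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.m, b.m)

    def test_nonpositive_exponent_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_population(10, zipf_exponent=0.0)

    def test_rank_size_slope_near_minus_one(self):
        dom = generate_synthetic_population(200, zipf_exponent=1.0, seed=4)
        sizes = np.sort(dom.m)[::-1].astype(float)
        ranks = np.arange(1, 201, dtype=float)
        res = linregress(np.log(ranks[:100]), np.log(sizes[:100]))
        assert res.slope == pytest.approx(-1.0, abs=0.05)
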