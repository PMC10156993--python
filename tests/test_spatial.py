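"""Spatial operations against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from phylounits.core import PointPattern, Site, UnitPartition
from phylounits.spatial import (EARTH_RADIUS_KM, assign_units, csr_envelope,
                                geodesic_distance, geodesic_matrix,
                                nearest_site_classify,
                                nearest_site_classify_many, quadrat_chisq,
                                ripley_k)

latitudes = st.floats(min_value=-90, max_value=90)
longitudes = st.floats(min_value=-180, max_value=180)


class TestGeodesic:
    def test_identity(self):
        assert geodesic_distance((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_antipodal_half_circumference(self):
        assert geodesic_distance((0, 0), (0, 180)) == pytest.approx(
            np.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_one_degree_on_equator(self):
        # closed-form arc length: 2*pi*R/360
        assert geodesic_distance((0, 0), (0, 1)) == pytest.approx(
            2 * np.pi * EARTH_RADIUS_KM / 360.0, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            geodesic_distance((91, 0), (0, 0))
        with pytest.raises(ValueError):
            geodesic_distance((0, 0), (0, 181))

    @settings(max_examples=50, deadline=None)
    @given(latitudes, longitudes, latitudes, longitudes)
    def test_symmetry_and_nonnegativity(self, lat1, lon1, lat2, lon2):
        d = geodesic_distance((lat1, lon1), (lat2, lon2))
        assert d >= 0
        assert d == pytest.approx(geodesic_distance((lat2, lon2), (lat1, lon1)))

    def test_triangle_inequality_on_random_triples(self, rng):
        for _ in range(1000):
            lats = rng.uniform(-90, 90, 3)
            lons = rng.uniform(-180, 180, 3)
            a, b, c = [(lats[i], lons[i]) for i in range(3)]
            assert (geodesic_distance(a, c)
                    <= geodesic_distance(a, b) + geodesic_distance(b, c) + 1e-9)

    def test_matrix_agrees_with_pairwise(self, rng):
        lats = rng.uniform(-60, 60, 12)
        lons = rng.uniform(-170, 170, 12)
        m = geodesic_matrix(lats, lons)
        for i in range(12):
            for j in range(12):
                assert m[i, j] == pytest.approx(
                    geodesic_distance((lats[i], lons[i]), (lats[j], lons[j])),
                    abs=1e-9)


def ray_cast(x, y, ring):
    """Even-odd ray casting oracle: is (x, y) inside the polygon ring?"""
    inside = False
    n = len(ring)
    for i in range(n - 1):
        (x1, y1), (x2, y2) = ring[i], ring[i + 1]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xcross:
                inside = not inside
    return inside


class TestAssignUnits:
    def make_partition(self):
        return UnitPartition(units={"A": box(0, 0, 1, 1), "B": box(1, 0, 2, 1)})

    def test_centroid_assignment(self):
        part = self.make_partition()
        sites = [Site("s1", lat=0.5, lon=0.5), Site("s2", lat=0.5, lon=1.5)]
        assignments, unassigned = assign_units(sites, part)
        assert assignments == {"s1": "A", "s2": "B"}
        assert unassigned == []

    def test_shared_edge_goes_to_lowest_unit_id(self):
        part = self.make_partition()
        sites = [Site("edge", lat=0.5, lon=1.0)]
        assignments, _ = assign_units(sites, part)
        assert assignments["edge"] == "A"

    def test_outside_site_flagged_not_assigned(self):
        part = self.make_partition()
        sites = [Site("out", lat=5.0, lon=5.0), Site("in", lat=0.2, lon=0.2)]
        assignments, unassigned = assign_units(sites, part)
        assert unassigned == ["out"]
        assert assignments == {"in": "A"}

    def test_against_ray_casting_oracle(self, rng, default_dataset):
        part = default_dataset.partition
        lon0, lat0, lon1, lat1 = default_dataset.config.bbox
        probes = [Site(f"p{i}", lat=rng.uniform(lat0, lat1),
                       lon=rng.uniform(lon0, lon1)) for i in range(1000)]
        assignments, unassigned = assign_units(probes, part)
        assert not unassigned
        for site in probes:
            oracle_hits = []
            for uid in part.unit_ids:
                geom = part.units[uid]
                polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
                for poly in polys:
                    ring = list(poly.exterior.coords)
                    if ray_cast(site.lon, site.lat, ring):
                        oracle_hits.append(uid)
                        break
            if len(oracle_hits) == 1:  # interior points: unambiguous
                assert assignments[site.site_id] == oracle_hits[0]


class TestNearestSiteClassify:
    def test_single_training_site(self):
        train = [Site("t", lat=0, lon=0, clade="X")]
        assert nearest_site_classify(train, Site("q", lat=50, lon=50)) == "X"

    def test_equidistant_tie_breaks_by_site_id(self):
        train = [Site("b", lat=0, lon=1, clade="CB"),
                 Site("a", lat=0, lon=-1, clade="CA")]
        assert nearest_site_classify(train, Site("q", lat=0, lon=0)) == "CA"

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_site_classify([], Site("q", lat=0, lon=0))

    def test_unlabelled_training_site_rejected(self):
        with pytest.raises(ValueError):
            nearest_site_classify([Site("t", lat=0, lon=0)], Site("q", lat=1, lon=1))

    @pytest.mark.parametrize("metric", ["planar", "geodesic"])
    def test_against_exhaustive_scan(self, rng, metric):
        for trial in range(50):
            n = int(rng.integers(2, 15))
            train = [Site(f"t{i}", lat=float(rng.uniform(-60, 60)),
                          lon=float(rng.uniform(-170, 170)),
                          clade=f"c{rng.integers(3)}") for i in range(n)]
            query = Site("q", lat=float(rng.uniform(-60, 60)),
                         lon=float(rng.uniform(-170, 170)))
            if metric == "planar":
                dists = [np.hypot(s.lon - query.lon, s.lat - query.lat) for s in train]
            else:
                dists = [geodesic_distance((s.lat, s.lon), (query.lat, query.lon))
                         for s in train]
            best = min(zip(dists, [s.site_id for s in train], [s.clade for s in train]))
            assert nearest_site_classify(train, query, metric=metric) == best[2]

    def test_self_nearest_property(self, default_dataset):
        sites = default_dataset.sites
        predicted = nearest_site_classify_many(sites, sites)
        assert predicted == [s.clade for s in sites]


class TestRipleyK:
    def test_two_points_below_distance(self):
        pat = PointPattern([[0, 0], [3, 0]], (0, 0, 10, 10))
        assert ripley_k(pat, [1.0])[0] == 0.0

    def test_two_points_at_or_beyond_distance(self):
        # plugging n=2 into the estimator: K = A * 2/(2*1) * ... = A
        pat = PointPattern([[0, 0], [3, 0]], (0, 0, 10, 10))
        assert ripley_k(pat, [3.0])[0] == pytest.approx(100.0)
        assert ripley_k(pat, [5.0])[0] == pytest.approx(100.0)

    def test_monotone_nondecreasing(self, rng):
        pat = PointPattern(rng.random((50, 2)), (0, 0, 1, 1))
        k = ripley_k(pat, np.linspace(0.01, 1.0, 25))
        assert (np.diff(k) >= 0).all()

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            ripley_k(PointPattern([[0.5, 0.5]], (0, 0, 1, 1)), [0.1])

    def test_invalid_radii(self, rng):
        pat = PointPattern(rng.random((5, 2)), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            ripley_k(pat, [0.2, 0.1])
        with pytest.raises(ValueError):
            ripley_k(pat, [-0.1, 0.2])

    def test_csr_mean_tracks_theoretical_k(self, rng):
        # mean K-hat over CSR replicates vs pi r^2, small r relative to window
        radii = np.array([0.02, 0.04, 0.06])
        ks = np.array([ripley_k(PointPattern(rng.random((200, 2)), (0, 0, 1, 1)), radii)
                       for _ in range(300)])
        mean, se = ks.mean(axis=0), ks.std(axis=0) / np.sqrt(300)
        # exact expectation of the uncorrected estimator on the unit square
        exact = np.pi * radii ** 2 - (8.0 / 3.0) * radii ** 3 + radii ** 4 / 2.0
        assert np.all(np.abs(mean - exact) < 4 * se)
        assert np.all(np.abs(mean - np.pi * radii ** 2) < np.pi * radii ** 2 * 0.08)


class TestCSREnvelope:
    def test_csr_pattern_inside_envelope(self, rng):
        pat = PointPattern(rng.random((100, 2)), (0, 0, 1, 1))
        env = csr_envelope(pat, [0.05, 0.1, 0.15], n_sim=99, seed=0)
        assert env.inside  # fails with prob ~ 3*2/100 under the null

    def test_clustered_pattern_outside_envelope(self, rng):
        pts = rng.uniform(0, 0.05, (100, 2))  # all points in one corner
        pat = PointPattern(pts, (0, 0, 1, 1))
        env = csr_envelope(pat, [0.05, 0.1], n_sim=99, seed=0)
        assert not env.inside
        assert env.observed[0] > env.hi[0]

    def test_fixed_seed_reproducible(self, rng):
        pat = PointPattern(rng.random((30, 2)), (0, 0, 1, 1))
        e1 = csr_envelope(pat, [0.1, 0.2], n_sim=39, seed=5)
        e2 = csr_envelope(pat, [0.1, 0.2], n_sim=39, seed=5)
        assert np.array_equal(e1.lo, e2.lo) and np.array_equal(e1.hi, e2.hi)

    def test_minimum_simulations_enforced(self, rng):
        pat = PointPattern(rng.random((10, 2)), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            csr_envelope(pat, [0.1], n_sim=5)


class TestQuadratChisq:
    def test_perfectly_even_counts_give_zero(self):
        pts = [[0.25, 0.25], [0.25, 0.75], [0.75, 0.25], [0.75, 0.75]]
        res = quadrat_chisq(PointPattern(pts, (0, 0, 1, 1)), 2, 2)
        assert res.statistic == 0.0
        assert res.df == 3

    @given(st.integers(min_value=2, max_value=60), st.integers(min_value=2, max_value=4))
    @settings(max_examples=25, deadline=None)
    def test_all_points_in_one_cell_closed_form(self, n, g):
        # X^2 = n(g^2 - 1) when all n points share one of g*g cells
        pts = np.full((n, 2), 0.1)
        res = quadrat_chisq(PointPattern(pts, (0, 0, 1, 1)), g, g)
        assert res.statistic == pytest.approx(n * (g * g - 1))

    def test_matches_histogram_recomputation(self, rng):
        pts = rng.random((200, 2))
        res = quadrat_chisq(PointPattern(pts, (0, 0, 1, 1)), 3, 4)
        counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[4, 3],
                                      range=[[0, 1], [0, 1]])
        e = 200 / 12
        assert res.statistic == pytest.approx(((counts - e) ** 2 / e).sum())
        assert res.df == 11
        from scipy.stats import chi2
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, 11))
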