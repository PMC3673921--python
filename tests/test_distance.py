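"""Jaccard, spatial/environmental distances and estuary geometry ops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from betadiv import (
    closure_index,
    environmental_distance,
    jaccard_dissimilarity,
    pairwise_jaccard,
    shell_class,
    shore_complexity,
    spatial_distance,
    value_difference_matrix,
    within_estuary_jaccard,
)

from conftest import build_incidence

taxon_sets = st.sets(st.sampled_from("ABCDEFGH"), max_size=8)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 0.5),
            ({"A", "B"}, {"A", "B"}, 0.0),
            ({"A"}, {"B", "C"}, 1.0),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert jaccard_dissimilarity(a, b) == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jaccard_dissimilarity(set(), set())

    @given(taxon_sets, taxon_sets)
    def test_symmetry_and_range(self, a, b):
        if not (a or b):
            return
        d = jaccard_dissimilarity(a, b)
        assert 0 <= d <= 1
        assert d == jaccard_dissimilarity(b, a)

    @given(
        st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
        st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
        st.sets(st.sampled_from("ABCDEF"), min_size=1, max_size=6),
    )
    def test_triangle_inequality(self, a, b, c):
        dab = jaccard_dissimilarity(a, b)
        dbc = jaccard_dissimilarity(b, c)
        dac = jaccard_dissimilarity(a, c)
        assert dac <= dab + dbc + 1e-12


class TestPairwiseJaccard:
    def test_two_site_pools(self, toy_estuary):
        dm = pairwise_jaccard(toy_estuary, level="site")
        assert dm["E1/S1", "E1/S2"] == pytest.approx(0.75)  # 1 - 1/4

    def test_identical_estuary_pools_zero(self):
        m = build_incidence(
            {
                ("E1", "S1", "R1"): {"A", "B"},
                ("E2", "S1", "R1"): {"A"},
                ("E2", "S1", "R2"): {"B"},
            }
        )
        dm = pairwise_jaccard(m, level="estuary")
        assert dm["E1", "E2"] == 0.0

    def test_disjoint_site_has_unit_rows(self):
        m = build_incidence(
            {
                ("E1", "S1", "R1"): {"A", "B"},
                ("E1", "S2", "R1"): {"A", "C"},
                ("E1", "S3", "R1"): {"X", "Y"},
            }
        )
        dm = pairwise_jaccard(m, level="site")
        assert dm["E1/S3", "E1/S1"] == 1.0
        assert dm["E1/S3", "E1/S2"] == 1.0

    def test_matches_scipy_binary_jaccard(self, small_meta):
        """Independent route: scipy's jaccard on pooled binary site vectors."""
        m = small_meta.incidence
        pools = np.stack(
            [m.site_incidence(k).to_numpy().any(axis=0) for k in m.sites()]
        )
        expected = squareform(pdist(pools, metric="jaccard"))
        dm = pairwise_jaccard(m, level="site")
        assert np.allclose(dm.data, expected)

    def test_frequency_threshold_composition(self):
        m = build_incidence(
            {
                ("E1", "S1", "R1"): {"A", "B"},
                ("E1", "S1", "R2"): {"A"},
                ("E1", "S2", "R1"): {"B"},
                ("E1", "S2", "R2"): {"B", "A"},
            }
        )
        dm = pairwise_jaccard(m, level="site", frequency_threshold=0.5)
        # S1 majority composition {A}... B in 1/2 -> kept at >= 0.5
        assert dm["E1/S1", "E1/S2"] == pytest.approx(0.0)

    def test_within_estuary_split(self, small_meta):
        per_est = within_estuary_jaccard(small_meta.incidence)
        assert set(per_est) == set(small_meta.incidence.estuaries())
        for e, dm in per_est.items():
            assert all(i.startswith(f"{e}/") for i in dm.ids)


class TestEnvironmentalDistance:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["u", "v"])
        dm = environmental_distance(df, standardize=False)
        assert dm["u", "v"] == 0.0

    def test_single_variable_unstandardized(self):
        df = pd.DataFrame({"a": [1.0, 3.0]}, index=["u", "v"])
        dm = environmental_distance(df, standardize=False)
        assert dm["u", "v"] == pytest.approx(2.0)

    def test_two_units_zscored(self):
        df = pd.DataFrame({"a": [0.0, 2.0], "b": [5.0, 9.0]}, index=["u", "v"])
        dm = environmental_distance(df, standardize=True)
        # population z-scores are +-1 per column -> sqrt(4 + 4)
        assert dm["u", "v"] == pytest.approx(np.sqrt(8.0))

    def test_standardization_affine_invariant(self, rng):
        df = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        scaled = df.copy()
        scaled["b"] = 100.0 * scaled["b"] - 7.0
        d1 = environmental_distance(df, standardize=True)
        d2 = environmental_distance(scaled, standardize=True)
        assert np.allclose(d1.data, d2.data)

    def test_strict_missing_drops_column(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 4.0], "b": [np.nan, 1.0, 2.0]},
            index=["u", "v", "w"],
        )
        with pytest.warns(UserWarning, match="missing"):
            dm = environmental_distance(df, standardize=False)
        assert dm["u", "v"] == pytest.approx(1.0)

    def test_pairwise_missing_scales_by_completeness(self):
        df = pd.DataFrame(
            {"a": [0.0, 3.0, 1.0], "b": [0.0, 4.0, np.nan]},
            index=["u", "v", "w"],
        )
        dm = environmental_distance(df, standardize=False, missing="pairwise")
        assert dm["u", "v"] == pytest.approx(5.0)  # complete pair
        assert dm["u", "w"] == pytest.approx(np.sqrt(1.0**2 * 2 / 1))


class TestSpatialDistance:
    def test_planar_345(self):
        df = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=["u", "v"])
        assert spatial_distance(df)["u", "v"] == pytest.approx(5.0)

    def test_haversine_one_degree_meridian(self):
        df = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 1.0]}, index=["u", "v"])
        dm = spatial_distance(df, mode="haversine")
        assert dm["u", "v"] == pytest.approx(6371 * np.pi / 180, rel=1e-6)

    def test_identical_coordinates_zero(self):
        df = pd.DataFrame({"lon": [10.0, 10.0], "lat": [-5.0, -5.0]},
                          index=["u", "v"])
        assert spatial_distance(df, mode="haversine")["u", "v"] == 0.0

    def test_bad_latitude_rejected(self):
        df = pd.DataFrame({"lon": [0.0, 0.0], "lat": [0.0, 95.0]}, index=["u", "v"])
        with pytest.raises(ValueError, match="latitude"):
            spatial_distance(df, mode="haversine")

    @given(st.lists(st.tuples(st.floats(-179, 179), st.floats(-89, 89)),
                    min_size=3, max_size=3, unique=True))
    def test_haversine_triangle_inequality(self, pts):
        df = pd.DataFrame(pts, columns=["lon", "lat"], index=["a", "b", "c"])
        dm = spatial_distance(df, mode="haversine")
        assert dm["a", "c"] <= dm["a", "b"] + dm["b", "c"] + 1e-6


class TestValueDifference:
    def test_worked_example(self):
        dm = value_difference_matrix(pd.Series([10, 12, 17], index=["a", "b", "c"]))
        assert dm["a", "b"] == 2 and dm["b", "c"] == 5 and dm["a", "c"] == 7

    def test_constant_values_all_zero(self):
        dm = value_difference_matrix(pd.Series([3, 3, 3], index=list("abc")))
        assert np.all(dm.data == 0)

    def test_missing_unit_excluded_with_warning(self):
        s = pd.Series([1.0, np.nan, 4.0], index=["a", "b", "c"])
        with pytest.warns(UserWarning, match="excluding"):
            dm = value_difference_matrix(s)
        assert list(dm.ids) == ["a", "c"]


class TestGeometryIndices:
    def test_circle_has_unit_complexity(self):
        assert shore_complexity(np.pi, 2 * np.pi) == pytest.approx(1.0)

    def test_simple_estuary_value(self):
        # shoreline 7.4 km around 0.6 km^2: same order as a published 0.34
        assert shore_complexity(0.6, 7.4) == pytest.approx(0.371, abs=0.001)

    def test_doubling_perimeter_halves_index(self):
        assert shore_complexity(2.0, 12.0) == pytest.approx(
            shore_complexity(2.0, 6.0) / 2
        )

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            shore_complexity(0, 5)

    @pytest.mark.parametrize(
        "width, perim, expected", [(0.5, 10, 0.05), (0, 10, 0.0), (4, 10, 0.4)]
    )
    def test_closure_index(self, width, perim, expected):
        assert closure_index(width, perim) == pytest.approx(expected)

    def test_closure_zero_perimeter_rejected(self):
        with pytest.raises(ValueError):
            closure_index(1, 0)


@pytest.mark.parametrize(
    "cover, expected",
    [(0, "none"), (3, "rare"), (5, "rare"), (20, "present"), (5.01, "present")],
)
def test_shell_class(cover, expected):
    assert shell_class(cover) == expected


def test_shell_class_domain():
    with pytest.raises(ValueError):
        shell_class(120)
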