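"""Distance builders against brute-force oracles and analytic values."""

import math

import numpy as np
import pandas as pd
import pytest

from yartsa.containers import CostRaster, DistanceMatrix, MultiLocusAlignment, SampleTable
from yartsa.distances import (
    EARTH_RADIUS_KM,
    climate_distance_matrix,
    genetic_distance,
    haversine_km,
    haversine_matrix,
    least_cost_distance,
    patristic_matrix,
)
from yartsa.errors import DistanceError
from yartsa.trees import parse_newick


def brute_force_p_distance(s1: str, s2: str) -> float:
    """Site-by-site oracle with pairwise deletion of '-'/'N'."""
    n = diff = 0
    for a, b in zip(s1, s2):
        if a in "ACGT" and b in "ACGT":
            n += 1
            diff += a != b
    return diff / n


class TestGeneticDistance:
    def test_identical_sequences_zero(self):
        aln = MultiLocusAlignment(["L1"], {"L1": {"a": "ACGT", "b": "ACGT"}})
        assert genetic_distance(aln).get("a", "b") == 0.0

    def test_half_divergent(self):
        aln = MultiLocusAlignment(["L1"], {"L1": {"a": "AAAA", "b": "AATT"}})
        assert genetic_distance(aln).get("a", "b") == 0.5

    def test_matches_bruteforce_on_simulated_data(self, small_bundle):
        aln = small_bundle.alignment
        D = genetic_distance(aln)
        concat = aln.concatenate()
        ids = D.labels
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                expected = brute_force_p_distance(concat[ids[i]], concat[ids[j]])
                assert D.get(ids[i], ids[j]) == expected

    def test_jc_correction_and_saturation_error(self):
        aln = MultiLocusAlignment(["L1"], {"L1": {"a": "AAAA" * 5, "b": "AATT" * 5}})
        d = genetic_distance(aln, correction="JC").get("a", "b")
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.5 / 3))
        sat = MultiLocusAlignment(["L1"], {"L1": {"a": "AAAA", "b": "TTTT"}})
        with pytest.raises(DistanceError, match="0.75"):
            genetic_distance(sat, correction="JC")

    def test_no_overlap_error(self):
        aln = MultiLocusAlignment(["L1"], {"L1": {"a": "ACNN", "b": "NNGT"}})
        with pytest.raises(DistanceError, match="overlap"):
            genetic_distance(aln)


def _table(rows):
    frame = pd.DataFrame(
        rows, columns=["id", "latitude", "longitude", "region", "climate", "year"]
    ).set_index("id")
    return SampleTable(frame)


class TestGeographicDistance:
    def test_analytic_values(self):
        table = _table(
            [
                ("a", 0.0, 0.0, "QTP", 0.0, 2000),
                ("b", 0.0, 90.0, "QTP", 0.0, 2000),
                ("c", 0.0, 180.0, "QTP", 0.0, 2000),
            ]
        )
        D = haversine_matrix(table)
        quarter = math.pi * EARTH_RADIUS_KM / 2
        assert D.get("a", "b") == pytest.approx(quarter, rel=1e-9)
        assert D.get("a", "c") == pytest.approx(2 * quarter, rel=1e-9)

    def test_equirectangular_close_to_haversine_at_small_scale(self):
        table = _table(
            [
                ("a", 30.0, 90.0, "QTP", 0.0, 2000),
                ("b", 30.5, 90.5, "QTP", 0.0, 2000),
                ("c", 31.0, 91.2, "QTP", 0.0, 2000),
            ]
        )
        h = haversine_matrix(table).condensed()
        e = haversine_matrix(table, method="equirectangular").condensed()
        assert np.allclose(h, e, rtol=5e-3)


class TestClimateDistance:
    def test_values_and_triangle_inequality(self):
        table = _table(
            [
                ("a", 30, 90, "QTP", -5.0, 2000),
                ("b", 30, 91, "QTP", 0.0, 2000),
                ("c", 30, 92, "QTP", 10.0, 2000),
            ]
        )
        D = climate_distance_matrix(table)
        assert D.values.max() == 15.0
        labels = D.labels
        for x in labels:
            for y in labels:
                for z in labels:
                    assert D.get(x, z) <= D.get(x, y) + D.get(y, z) + 1e-12


class TestLeastCostDistance:
    def _uniform_raster(self):
        return CostRaster(5, 8, 0.5, (28.0, 90.0), np.ones((5, 8)))

    def test_same_row_corridor_close_to_great_circle(self):
        raster = self._uniform_raster()
        table = _table(
            [
                ("a", 29.0, 90.0, "QTP", 0.0, 2000),
                ("b", 29.0, 93.0, "QTP", 0.0, 2000),
            ]
        )
        D = least_cost_distance(table, raster)
        direct = haversine_km(29.0, 90.0, 29.0, 93.0)
        assert 1.0 <= D.get("a", "b") / direct <= 1.09

    def test_barrier_forces_detour(self):
        costs = np.ones((5, 8))
        open_raster = CostRaster(5, 8, 0.5, (28.0, 90.0), costs.copy())
        blocked = costs.copy()
        blocked[2, :] = np.inf  # full barrier row
        table = _table(
            [
                ("a", 28.0, 91.0, "QTP", 0.0, 2000),
                ("b", 30.0, 91.0, "QTP", 0.0, 2000),
            ]
        )
        base = least_cost_distance(table, open_raster)
        with pytest.raises(DistanceError, match="barrier|path"):
            least_cost_distance(table, CostRaster(5, 8, 0.5, (28.0, 90.0), blocked))
        partial = costs.copy()
        partial[2, :-1] = np.inf  # barrier with one gap at the east edge
        detour = least_cost_distance(table, CostRaster(5, 8, 0.5, (28.0, 90.0), partial))
        assert detour.get("a", "b") > base.get("a", "b")

    def test_matches_bellman_ford_oracle(self):
        rng = np.random.default_rng(3)
        costs = rng.uniform(0.5, 3.0, size=(20, 20))
        raster = CostRaster(20, 20, 0.25, (28.0, 90.0), costs)
        pts = [(28.5, 90.5), (29.0, 92.0), (32.0, 94.0), (30.4, 91.3), (28.2, 94.6)]
        table = _table(
            [(f"s{i}", lat, lon, "QTP", 0.0, 2000) for i, (lat, lon) in enumerate(pts)]
        )
        D = least_cost_distance(table, raster)

        # independent oracle: rebuild the lattice and run Bellman-Ford
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import bellman_ford

        nr, nc = 20, 20
        rows, cols, w = [], [], []
        for r in range(nr):
            for c in range(nc):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        r2, c2 = r + dr, c + dc
                        if 0 <= r2 < nr and 0 <= c2 < nc:
                            lat1, lon1 = raster.cell_center(r, c)
                            lat2, lon2 = raster.cell_center(r2, c2)
                            length = haversine_km(lat1, lon1, lat2, lon2)
                            rows.append(r * nc + c)
                            cols.append(r2 * nc + c2)
                            w.append(0.5 * (costs[r, c] + costs[r2, c2]) * float(length))
        graph = coo_matrix((w, (rows, cols)), shape=(nr * nc, nr * nc)).tocsr()
        cells = [raster.cell_of(lat, lon) for lat, lon in pts]
        sources = [r * nc + c for r, c in cells]
        dist = bellman_ford(graph, directed=True, indices=sources)
        for i in range(len(pts)):
            for j in range(len(pts)):
                assert D.values[i, j] == pytest.approx(dist[i][sources[j]], abs=1e-9)

    def test_monotone_in_cell_cost(self):
        rng = np.random.default_rng(5)
        costs = rng.uniform(0.5, 2.0, size=(6, 6))
        raster = CostRaster(6, 6, 0.5, (28.0, 90.0), costs)
        table = _table(
            [("a", 28.0, 90.0, "QTP", 0, 2000), ("b", 30.5, 92.5, "QTP", 0, 2000)]
        )
        base = least_cost_distance(table, raster).get("a", "b")
        bumped = costs.copy()
        bumped[3, 3] += 5.0
        after = least_cost_distance(
            table, CostRaster(6, 6, 0.5, (28.0, 90.0), bumped)
        ).get("a", "b")
        assert after >= base


class TestPatristic:
    def test_hand_values(self):
        tree = parse_newick("((A:1,B:1):1,C:2.5);")
        D = patristic_matrix(tree)
        assert D.get("A", "B") == 2.0
        assert D.get("A", "C") == 4.5

    def test_ultrametric_through_root(self, five_tip_tree):
        D = patristic_matrix(five_tip_tree)
        assert D.get("A", "D") == pytest.approx(2 * five_tip_tree.root_height)

    def test_matches_naive_lca_oracle(self, default_bundle):
        tree = default_bundle.host_tree
        labels = sorted(tree.tip_labels)[:30]
        D = patristic_matrix(tree, labels)
        depths = tree.depths()
        below = tree.tipset_below()
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                lca = min(
                    (n for n in tree.postorder() if {a, b} <= below[n]),
                    key=lambda n: len(below[n]),
                )
                expected = (
                    depths[tree.find_tip(a)]
                    + depths[tree.find_tip(b)]
                    - 2 * depths[lca]
                )
                assert D.get(a, b) == pytest.approx(expected, abs=1e-12)


class TestGeometricProperties:
    """Property-based checks of the distance primitives."""

    from hypothesis import given, settings, strategies as st

    coords = st.tuples(
        st.floats(min_value=-80, max_value=80),
        st.floats(min_value=-179, max_value=179),
    )

    @given(a=coords, b=coords, c=coords)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_haversine_is_a_metric(self, a, b, c):
        dab = float(haversine_km(a[0], a[1], b[0], b[1]))
        dba = float(haversine_km(b[0], b[1], a[0], a[1]))
        dac = float(haversine_km(a[0], a[1], c[0], c[1]))
        dcb = float(haversine_km(c[0], c[1], b[0], b[1]))
        assert dab >= 0
        assert dab == pytest.approx(dba, rel=1e-12)
        assert float(haversine_km(a[0], a[1], a[0], a[1])) == 0.0
        assert dab <= dac + dcb + 1e-6

    @given(
        values=st.lists(
            st.floats(min_value=-50, max_value=50), min_size=3, max_size=8
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_climate_distance_triangle_inequality(self, values):
        rows = [
            (f"s{i}", 30.0, 90.0 + i * 0.1, "QTP", v, 2000)
            for i, v in enumerate(values)
        ]
        D = climate_distance_matrix(_table(rows))
        n = len(values)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert (
                        D.values[i, j]
                        <= D.values[i, k] + D.values[k, j] + 1e-9
                    )
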