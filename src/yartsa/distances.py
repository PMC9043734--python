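"""Distance matrices: genetic, great-circle, climatic, least-cost and patristic.

All builders return a labelled :class:`~yartsa.containers.DistanceMatrix`.
Missing data ('-'/'N') is pairwise-deleted in genetic distances — market
samples are degraded and column deletion would discard most sites.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .containers import CostRaster, DistanceMatrix, MultiLocusAlignment, SampleTable
from .errors import DistanceError, ValidationError
from .models import BASE_INDEX
from .trees import Tree

__all__ = [
    "genetic_distance",
    "haversine_matrix",
    "haversine_km",
    "climate_distance_matrix",
    "least_cost_distance",
    "patristic_matrix",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088
_MISSING = 255


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    out = np.full(arr.shape, _MISSING, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def genetic_distance(
    alignment: MultiLocusAlignment,
    loci: Sequence[str] | None = None,
    correction: str = "none",
    samples: Sequence[str] | None = None,
) -> DistanceMatrix:
    """Pairwise p-distance (optionally JC-corrected) over concatenated loci.

    Sites where either sequence is '-'/'N' are ignored per pair. A pair with
    no comparable sites, or JC correction at p >= 0.75, raises
    :class:`DistanceError` naming the pair.
    """
    if correction not in ("none", "JC"):
        raise ValidationError(f"unknown correction {correction!r}")
    loci = list(loci) if loci is not None else list(alignment.loci)
    if not loci:
        raise DistanceError("empty locus subset")
    concat = alignment.concatenate(loci=loci, samples=samples)
    ids = list(concat)
    if len(ids) < 2:
        raise DistanceError("need at least two samples")
    mat = np.stack([_encode(concat[sid]) for sid in ids])
    valid = mat != _MISSING
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        vi, si = valid[i], mat[i]
        for j in range(i + 1, n):
            both = vi & valid[j]
            n_sites = int(both.sum())
            if n_sites == 0:
                raise DistanceError(
                    f"no overlapping sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float(np.count_nonzero(si[both] != mat[j][both])) / n_sites
            if correction == "JC":
                if p >= 0.75:
                    raise DistanceError(
                        f"JC correction undefined (p={p:.3f} >= 0.75) for pair "
                        f"{ids[i]!r}, {ids[j]!r}"
                    )
                p = -0.75 * math.log1p(-4.0 * p / 3.0)
            out[i, j] = out[j, i] = p
    return DistanceMatrix(ids, out, kind="genetic")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (broadcasting over array inputs)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def haversine_matrix(samples: SampleTable, method: str = "haversine") -> DistanceMatrix:
    """Geographic distance matrix in km.

    ``method='haversine'`` (default) is the great-circle distance; at the
    2000-km scale of the study region a planar reading of lat/lon is
    ill-defined. ``method='equirectangular'`` gives the planar distance on an
    equirectangular projection at the mean latitude, for fidelity checks.
    """
    lat = samples.frame["latitude"].to_numpy()
    lon = samples.frame["longitude"].to_numpy()
    if method == "haversine":
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    elif method == "equirectangular":
        mean_lat = np.radians(lat.mean())
        x = np.radians(lon) * math.cos(mean_lat)
        y = np.radians(lat)
        d = EARTH_RADIUS_KM * np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    else:
        raise ValidationError(f"unknown method {method!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples.sample_ids, 0.5 * (d + d.T), kind="geographic")


def climate_distance_matrix(samples: SampleTable) -> DistanceMatrix:
    climate = samples.frame["climate"]
    if climate.isna().any():
        bad = climate.index[climate.isna()].tolist()
        raise DistanceError(f"missing climate values for samples {bad}")
    c = climate.to_numpy(dtype=float)
    d = np.abs(c[:, None] - c[None, :])
    return DistanceMatrix(samples.sample_ids, d, kind="climatic")


def least_cost_distance(samples: SampleTable, raster: CostRaster) -> DistanceMatrix:
    """Least-cost-path distance over the 8-connected raster lattice.

    Edge weight = mean of the endpoint cell costs x the great-circle length
    between cell centers; infinite-cost cells are barriers.
    """
    cells = {}
    for sid in samples.sample_ids:
        row = samples.frame.loc[sid]
        cell = raster.cell_of(float(row["latitude"]), float(row["longitude"]))
        if math.isinf(raster.costs[cell]):
            raise DistanceError(f"sample {sid!r} sits on an infinite-cost cell")
        cells[sid] = cell

    nr, nc = raster.n_rows, raster.n_cols
    idx = lambda r, c: r * nc + c
    rows, cols, weights = [], [], []
    neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    centers = np.array(
        [[raster.cell_center(r, c) for c in range(nc)] for r in range(nr)]
    )
    for r in range(nr):
        for c in range(nc):
            if math.isinf(raster.costs[r, c]):
                continue
            for dr, dc in neighbours:
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc):
                    continue
                if math.isinf(raster.costs[r2, c2]):
                    continue
                length = haversine_km(*centers[r, c], *centers[r2, c2])
                w = 0.5 * (raster.costs[r, c] + raster.costs[r2, c2]) * float(length)
                rows.append(idx(r, c))
                cols.append(idx(r2, c2))
                weights.append(w)
    graph = coo_matrix((weights, (rows, cols)), shape=(nr * nc, nr * nc))
    sources = sorted({idx(*cell) for cell in cells.values()})
    dist = dijkstra(graph.tocsr(), directed=False, indices=sources)
    source_pos = {s: i for i, s in enumerate(sources)}

    ids = samples.sample_ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        di = dist[source_pos[idx(*cells[ids[i]])]]
        for j in range(i + 1, n):
            d = di[idx(*cells[ids[j]])]
            if not np.isfinite(d):
                raise DistanceError(
                    f"no path between {ids[i]!r} and {ids[j]!r} (barrier)"
                )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids, out, kind="resistance")


def patristic_matrix(tree: Tree, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Sum of branch lengths along the tip-to-tip path."""
    tips = {t.label: t for t in tree.tips()}
    labels = list(labels) if labels is not None else sorted(tips)
    unknown = set(labels) - set(tips)
    if unknown:
        raise ValidationError(f"labels not in tree: {sorted(unknown)}")
    depths = tree.depths()

    # ancestor chains with cumulative depths for LCA lookup
    chains: dict[str, dict] = {}
    for label in labels:
        node = tips[label]
        anc = {}
        while node is not None:
            anc[id(node)] = depths[node]
            node = node.parent
        chains[label] = anc

    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = chains[labels[i]]
            node = tips[labels[j]]
            while id(node) not in anc_i:
                node = node.parent
            lca_depth = depths[node]
            d = (
                depths[tips[labels[i]]]
                + depths[tips[labels[j]]]
                - 2.0 * lca_depth
            )
            out[i, j] = out[j, i] = max(d, 0.0)
    return DistanceMatrix(labels, out, kind="patristic")
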