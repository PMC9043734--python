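"""Mantel tests and the two signal-localization sweeps.

Isolation-by-distance (IBD) is read as a positive Mantel correlation between
genetic and geographic (or climatic / resistance) distances. The two sweeps
localize where a signal lives: the *radius* sweep cuts a complete-linkage
geographic clustering at increasing diameters (100..2000 km by default) and
re-runs the Mantel test within each cluster; the *time-slice* sweep cuts an
ultrametric host tree at increasing ages, represents each surviving lineage
by its medoid tip, and re-runs the test among lineages.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import DistanceMatrix
from .distances import patristic_matrix
from .errors import AnalysisError
from .trees import Tree

__all__ = [
    "MantelResult",
    "SweepPoint",
    "SweepResult",
    "mantel_test",
    "geographic_cluster_sweep",
    "time_slice_sweep",
]


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    n_samples: int
    tail: str
    exact: bool
    seed: int | None

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise AnalysisError(f"Mantel r out of range: {self.r}")
        if not 0.0 < self.p <= 1.0:
            raise AnalysisError(f"Mantel p out of range: {self.p}")


@dataclass(frozen=True)
class SweepPoint:
    """Summary at one control value (radius in km, or slice age)."""

    control: float
    mean_r: float | None
    min_r: float | None
    max_r: float | None
    mean_p: float | None
    n_clusters_used: int
    n_clusters_skipped: int
    cluster_sizes: tuple[int, ...] = ()

    @property
    def empty(self) -> bool:
        return self.n_clusters_used == 0


@dataclass(frozen=True)
class SweepResult:
    mode: str  # "radius" | "timeslice"
    points: tuple[SweepPoint, ...]

    def __post_init__(self):
        controls = [p.control for p in self.points]
        if any(b <= a for a, b in zip(controls, controls[1:])):
            raise AnalysisError("sweep control values must be strictly increasing")

    @property
    def all_empty(self) -> bool:
        return all(p.empty for p in self.points)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "control": p.control,
                    "mean_r": p.mean_r,
                    "min_r": p.min_r,
                    "max_r": p.max_r,
                    "mean_p": p.mean_p,
                    "n_clusters_used": p.n_clusters_used,
                    "n_clusters_skipped": p.n_clusters_skipped,
                }
                for p in self.points
            ]
        )


def _check_pair(D1: DistanceMatrix, D2: DistanceMatrix) -> None:
    if D1.labels != D2.labels:
        raise AnalysisError("distance matrices must share labels in the same order")
    if len(D1) < 4:
        raise AnalysisError("Mantel test needs at least 4 samples")


def _standardize(v: np.ndarray, what: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise AnalysisError(f"zero off-diagonal variance in {what} matrix")
    return (v - v.mean()) / sd


def mantel_test(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    n_perm: int = 999,
    tail: str = "greater",
    seed: int | None = None,
) -> MantelResult:
    """Permutation Mantel test of matrix correlation.

    ``r`` is the Pearson correlation of the upper-triangle entries; the null
    is built by simultaneously permuting rows and columns of ``D2``. For
    n <= 7 with ``n_perm >= n!`` all permutations are enumerated and the
    p-value is exact (#{perm stat >= observed} / n!, the identity included);
    otherwise p = (1 + #{>=}) / (1 + n_perm).
    """
    _check_pair(D1, D2)
    if tail not in ("greater", "two-sided"):
        raise AnalysisError(f"unknown tail {tail!r}")
    n = len(D1)
    iu = np.triu_indices(n, k=1)
    v1 = _standardize(D1.values[iu], "first")
    v2 = _standardize(D2.values[iu], "second")
    m = v1.size
    r_obs = float(v1 @ v2) / m

    def perm_stat(order: np.ndarray) -> float:
        permuted = D2.values[np.ix_(order, order)][iu]
        sd = permuted.std()
        if sd == 0:  # cannot happen if the original had variance
            return 0.0
        return float(v1 @ ((permuted - permuted.mean()) / sd)) / m

    exact = n <= 7 and n_perm >= math.factorial(n)
    if exact:
        stats = np.array(
            [perm_stat(np.array(order)) for order in itertools.permutations(range(n))]
        )
        if tail == "greater":
            count = int(np.sum(stats >= r_obs - 1e-12))
        else:
            count = int(np.sum(np.abs(stats) >= abs(r_obs) - 1e-12))
        p = count / len(stats)
        n_used = len(stats)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            stat = perm_stat(rng.permutation(n))
            if tail == "greater":
                count += stat >= r_obs - 1e-12
            else:
                count += abs(stat) >= abs(r_obs) - 1e-12
        p = (1 + count) / (1 + n_perm)
        n_used = n_perm
    return MantelResult(
        r=r_obs, p=p, n_permutations=n_used, n_samples=n, tail=tail, exact=exact, seed=seed
    )


def geographic_cluster_sweep(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    radii: Sequence[float] | None = None,
    min_cluster: int = 5,
    n_perm: int = 199,
    linkage_method: str = "complete",
    seed: int | None = None,
) -> SweepResult:
    """Within-cluster Mantel signal across geographic cluster diameters.

    Complete linkage (default) bounds each cluster's diameter by the cut
    height, so a cut at 500 km means "samples within 500 km of each other".
    Clusters smaller than ``min_cluster``, or with degenerate (constant)
    induced matrices, are skipped and counted.
    """
    _check_pair(genetic, geographic)
    if radii is None:
        radii = [100.0 * k for k in range(1, 21)]
    radii = [float(r) for r in radii]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise AnalysisError("radii must be strictly increasing")
    Z = linkage(geographic.condensed(), method=linkage_method)
    labels = genetic.labels
    points = []
    for radius in radii:
        assignment = fcluster(Z, t=radius, criterion="distance")
        rs, ps, sizes = [], [], []
        skipped = 0
        for cluster_id in np.unique(assignment):
            members = [labels[i] for i in np.flatnonzero(assignment == cluster_id)]
            if len(members) < min_cluster:
                skipped += 1
                continue
            try:
                res = mantel_test(
                    genetic.submatrix(members),
                    geographic.submatrix(members),
                    n_perm=n_perm,
                    seed=seed,
                )
            except AnalysisError:
                skipped += 1
                continue
            rs.append(res.r)
            ps.append(res.p)
            sizes.append(len(members))
        if rs:
            points.append(
                SweepPoint(
                    control=radius,
                    mean_r=float(np.mean(rs)),
                    min_r=float(np.min(rs)),
                    max_r=float(np.max(rs)),
                    mean_p=float(np.mean(ps)),
                    n_clusters_used=len(rs),
                    n_clusters_skipped=skipped,
                    cluster_sizes=tuple(sizes),
                )
            )
        else:
            points.append(
                SweepPoint(
                    control=radius,
                    mean_r=None,
                    min_r=None,
                    max_r=None,
                    mean_p=None,
                    n_clusters_used=0,
                    n_clusters_skipped=skipped,
                )
            )
    return SweepResult(mode="radius", points=tuple(points))


def time_slice_sweep(
    tree: Tree,
    D_other: DistanceMatrix,
    ages: Sequence[float],
    n_perm: int = 199,
    min_lineages: int = 4,
    seed: int | None = None,
) -> SweepResult:
    """Mantel signal among the lineages alive at each age.

    At age ``t`` the branches crossing ``t`` partition the tips into clades.
    Each clade is represented by its medoid tip under ``D_other`` (ties
    broken lexicographically); the test correlates the sliced-tree patristic
    matrix (2 x (MRCA age - t) for an ultrametric tree) with the ``D_other``
    submatrix on the medoids. Ages with fewer than ``min_lineages`` lineages
    are skipped and flagged as empty points.
    """
    if not tree.is_ultrametric():
        raise AnalysisError("time slices require an ultrametric tree")
    ages = [float(a) for a in ages]
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise AnalysisError("ages must be strictly increasing")
    height = tree.root_height
    if ages and ages[-1] > height:
        raise AnalysisError(f"age {ages[-1]} exceeds root height {height:g}")
    missing = set(tree.tip_labels) - set(D_other.labels)
    if missing:
        raise AnalysisError(f"tips absent from distance matrix: {sorted(missing)}")

    node_ages = tree.node_ages()
    below = tree.tipset_below()
    points = []
    for t in ages:
        lineages = [
            node
            for node in tree.preorder()
            if node.parent is not None
            and node_ages[node] <= t < node_ages[node.parent]
        ]
        if t == 0:
            lineages = tree.tips()
        if len(lineages) < min_lineages:
            points.append(
                SweepPoint(
                    control=t, mean_r=None, min_r=None, max_r=None, mean_p=None,
                    n_clusters_used=0, n_clusters_skipped=1,
                )
            )
            continue
        medoids = []
        for node in lineages:
            members = sorted(below[node])
            if len(members) == 1:
                medoids.append(members[0])
            else:
                sub = D_other.submatrix(members)
                means = sub.values.sum(axis=1) / (len(members) - 1)
                best = min(range(len(members)), key=lambda i: (means[i], members[i]))
                medoids.append(members[best])
        # sliced patristic distance between lineages = 2 * (MRCA age - t);
        # on an ultrametric tree that is the full patristic distance minus 2t
        k = len(lineages)
        sliced = np.maximum(patristic_matrix(tree, medoids).values - 2.0 * t, 0.0)
        np.fill_diagonal(sliced, 0.0)
        try:
            res = mantel_test(
                DistanceMatrix(medoids, sliced, kind="patristic"),
                D_other.submatrix(medoids),
                n_perm=n_perm,
                seed=seed,
            )
            points.append(
                SweepPoint(
                    control=t, mean_r=res.r, min_r=res.r, max_r=res.r,
                    mean_p=res.p, n_clusters_used=1, n_clusters_skipped=0,
                    cluster_sizes=(k,),
                )
            )
        except AnalysisError:
            points.append(
                SweepPoint(
                    control=t, mean_r=None, min_r=None, max_r=None, mean_p=None,
                    n_clusters_used=0, n_clusters_skipped=1,
                )
            )
    return SweepResult(mode="timeslice", points=tuple(points))
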