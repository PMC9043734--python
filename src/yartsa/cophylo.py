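"""Host-parasite congruence tests: ParaFit and PACo.

ParaFit's global statistic is the sum of squares of the fourth-corner matrix
D = C' A B linking parasite (C) and host (B) principal coordinates through
the binary association A; its null permutes, independently for each
parasite, which hosts it links to. PACo embeds both distance matrices by
Cailliez-corrected principal coordinates, replicates rows per link, and
measures the Procrustes residual m2 of the parasite configuration
superimposed (translation, scaling, rotation) on the host configuration;
small m2 means congruence, and its null shuffles the rows of A.

Either sequence distances or tree (patristic) distances may be supplied;
``distance_kind`` metadata records which was used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, DistanceMatrix
from .errors import AnalysisError

__all__ = ["ParaFitResult", "PACoResult", "parafit_test", "paco_test"]

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class ParaFitResult:
    global_stat: float
    p_global: float
    link_stats: tuple[float, ...]  # F1 = statistic drop when the link is removed
    link_p: tuple[float, ...]
    links: tuple[tuple[str, str], ...]  # (parasite, host) per link
    n_permutations: int
    exact: bool
    seed: int | None
    distance_kind: tuple[str, str]

    def __post_init__(self):
        if self.global_stat < -1e-9:
            raise AnalysisError("ParaFit global statistic must be >= 0")
        for p in (self.p_global, *self.link_p):
            if not 0 < p <= 1:
                raise AnalysisError(f"p-value out of (0, 1]: {p}")


@dataclass(frozen=True)
class PACoResult:
    m2: float
    p: float
    link_residuals: tuple[float, ...]
    links: tuple[tuple[str, str], ...]
    n_permutations: int
    seed: int | None
    distance_kind: tuple[str, str]

    def __post_init__(self):
        if self.m2 < -1e-9:
            raise AnalysisError("m2 must be >= 0")
        if abs(sum(self.link_residuals) - self.m2) > 1e-9 * max(1.0, self.m2):
            raise AnalysisError("per-link residuals must sum to m2")


# ------------------------------------------------------------------- helpers
def _gower(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D**2) @ J


def _pcoa_coords(D: np.ndarray) -> np.ndarray:
    """Principal coordinates, keeping axes with eigenvalue > 1e-8 * max."""
    eigval, eigvec = np.linalg.eigh(_gower(D))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > _EIG_FLOOR * max(eigval.max(), 1e-300)
    if not keep.any():
        raise AnalysisError("distance matrix has no positive principal axes")
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making the off-diagonal distances Euclidean."""
    n = D.shape[0]
    d1 = _gower(D)
    d2 = _gower_linear(D)
    zero = np.zeros((n, n))
    block = np.block([[zero, 2.0 * d1], [-np.eye(n), -4.0 * d2]])
    eigs = np.linalg.eigvals(block)
    c = float(np.max(eigs.real))
    return max(c, 0.0)


def _gower_linear(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ D @ J


def _cailliez_coords(D: np.ndarray) -> np.ndarray:
    c = _cailliez_constant(D)
    if c > 1e-12:
        D = D + c
        np.fill_diagonal(D, 0.0)
    eigval, eigvec = np.linalg.eigh(_gower(D))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(eigval.max(), 1e-300)
    if eigval.min() < -1e-6 * scale:
        raise AnalysisError(
            "distances not embeddable after Cailliez correction "
            f"(residual eigenvalue {eigval.min():.3g})"
        )
    keep = eigval > _EIG_FLOOR * scale
    if not keep.any():
        raise AnalysisError("degenerate configuration after Cailliez correction")
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def _check_inputs(D_host, D_par, A) -> None:
    if A.hosts != D_host.labels:
        raise AnalysisError("association host labels must match host matrix labels")
    if A.parasites != D_par.labels:
        raise AnalysisError(
            "association parasite labels must match parasite matrix labels"
        )
    if len(D_host) < 2 or len(D_par) < 2:
        raise AnalysisError("need at least 2 hosts and 2 parasites")


# ------------------------------------------------------------------- parafit
def parafit_test(
    D_host: DistanceMatrix,
    D_par: DistanceMatrix,
    A: AssociationMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    link_tests: bool = True,
) -> ParaFitResult:
    """ParaFit global and per-link congruence test.

    The null redraws, independently for each parasite row, which hosts that
    parasite links to (uniform over host subsets of the same size). When
    every row has a single link and the n_hosts**n_parasites assignments
    number at most ``n_perm``, the null is enumerated exactly.
    ``link_tests=False`` skips the per-link permutation tests (the per-link
    F1 statistics are still reported; their p-values are set to 1).
    """
    _check_inputs(D_host, D_par, A)
    B = _pcoa_coords(D_host.values)  # hosts x axes
    C = _pcoa_coords(D_par.values)  # parasites x axes
    links = [
        (i, j) for i in range(len(A.parasites)) for j in np.flatnonzero(A.links[i])
    ]
    label_links = tuple((A.parasites[i], A.hosts[j]) for i, j in links)

    def global_stat(link_list) -> float:
        D = np.zeros((C.shape[1], B.shape[1]))
        for i, j in link_list:
            D += np.outer(C[i], B[j])
        return float(np.sum(D * D))

    def link_stats_for(link_list) -> np.ndarray:
        """F1_k = stat(all links) - stat(all links except k)."""
        D = np.zeros((C.shape[1], B.shape[1]))
        for i, j in link_list:
            D += np.outer(C[i], B[j])
        total = float(np.sum(D * D))
        out = np.empty(len(link_list))
        for k, (i, j) in enumerate(link_list):
            O = np.outer(C[i], B[j])
            out[k] = total - (total - 2.0 * float(np.sum(D * O)) + float(np.sum(O * O)))
        return out

    obs_global = global_stat(links)
    obs_links = link_stats_for(links)

    row_sizes = A.links.sum(axis=1)
    n_hosts = len(A.hosts)
    n_par = len(A.parasites)
    single_link = bool(np.all(row_sizes == 1))
    n_exact = n_hosts**n_par if single_link else None
    exact = single_link and n_exact is not None and n_exact <= n_perm

    if exact:
        ge_global = 0
        ge_link = np.zeros(len(links))
        for assignment in itertools.product(range(n_hosts), repeat=n_par):
            perm_links = [(i, j) for i, j in enumerate(assignment)]
            stat = global_stat(perm_links)
            if stat >= obs_global - 1e-12:
                ge_global += 1
            if link_tests:
                perm_link_stats = link_stats_for(perm_links)
                ge_link += perm_link_stats >= obs_links - 1e-12
        p_global = ge_global / n_exact
        link_p = ge_link / n_exact if link_tests else np.ones(len(links))
        n_used = n_exact
    else:
        rng = np.random.default_rng(seed)
        ge_global = 0
        ge_link = np.zeros(len(links))
        for _ in range(n_perm):
            perm_links = []
            for i in range(n_par):
                hosts = rng.choice(n_hosts, size=int(row_sizes[i]), replace=False)
                perm_links.extend((i, int(j)) for j in hosts)
            stat = global_stat(perm_links)
            if stat >= obs_global - 1e-12:
                ge_global += 1
            if link_tests:
                perm_link_stats = link_stats_for(perm_links)
                # compare link k against the permuted links of the same parasite
                starts = np.concatenate([[0], np.cumsum(row_sizes)])
                for k, (i, _) in enumerate(links):
                    block = perm_link_stats[starts[i] : starts[i + 1]]
                    ge_link[k] += np.any(block >= obs_links[k] - 1e-12)
        p_global = (1 + ge_global) / (1 + n_perm)
        link_p = (
            (1 + ge_link) / (1 + n_perm) if link_tests else np.ones(len(links))
        )
        n_used = n_perm

    return ParaFitResult(
        global_stat=obs_global,
        p_global=float(p_global),
        link_stats=tuple(float(x) for x in obs_links),
        link_p=tuple(float(x) for x in link_p),
        links=label_links,
        n_permutations=n_used,
        exact=exact,
        seed=seed,
        distance_kind=(D_host.kind, D_par.kind),
    )


# ---------------------------------------------------------------------- paco
def _procrustes_m2(X: np.ndarray, Y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares superimposition of Y onto X (translation, scaling,
    rotation); returns (m2, per-row squared residuals)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    dim = max(Xc.shape[1], Yc.shape[1])
    if Xc.shape[1] < dim:
        Xc = np.hstack([Xc, np.zeros((Xc.shape[0], dim - Xc.shape[1]))])
    if Yc.shape[1] < dim:
        Yc = np.hstack([Yc, np.zeros((Yc.shape[0], dim - Yc.shape[1]))])
    ynorm2 = float(np.sum(Yc * Yc))
    if ynorm2 == 0:
        raise AnalysisError("degenerate parasite configuration")
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    scale = float(np.sum(s)) / ynorm2
    fitted = scale * (Yc @ R)
    resid = Xc - fitted
    per_row = np.sum(resid * resid, axis=1)
    return float(per_row.sum()), per_row


def paco_test(
    D_host: DistanceMatrix,
    D_par: DistanceMatrix,
    A: AssociationMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> PACoResult:
    """Procrustean approach to cophylogeny.

    Small residual m2 indicates congruence, so the p-value counts
    permutations with m2 at most the observed value. The null shuffles the
    parasite rows of A (which parasite carries which link row).
    """
    _check_inputs(D_host, D_par, A)
    X_all = _cailliez_coords(D_host.values)  # hosts
    Y_all = _cailliez_coords(D_par.values)  # parasites
    rows, cols = np.nonzero(A.links)
    label_links = tuple((A.parasites[i], A.hosts[j]) for i, j in zip(rows, cols))

    def m2_for(row_order: np.ndarray) -> tuple[float, np.ndarray]:
        # row i of the permuted association carries parasite row_order[i]'s
        # links but parasite i's coordinates
        r, c = np.nonzero(A.links[row_order])
        Y = Y_all[r]
        X = X_all[c]
        return _procrustes_m2(X, Y)

    identity = np.arange(len(A.parasites))
    m2_obs, per_link = m2_for(identity)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        order = rng.permutation(len(A.parasites))
        m2_perm, _ = m2_for(order)
        if m2_perm <= m2_obs + 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PACoResult(
        m2=m2_obs,
        p=float(p),
        link_residuals=tuple(float(x) for x in per_link),
        links=label_links,
        n_permutations=n_perm,
        seed=seed,
        distance_kind=(D_host.kind, D_par.kind),
    )
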