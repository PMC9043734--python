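"""Discrete-range biogeography: DEC/DEC+J likelihoods, model fitting with
AIC comparison, and Mk-chain stochastic character mapping.

The dispersal-extinction-cladogenesis (DEC) model evolves geographic ranges
(non-empty area subsets up to size K) along branches — gaining an area at
rate d per occupied area, losing a non-last area at rate e — and resolves
ranges at cladogenesis into daughter pairs by subset sympatry or
single-area vicariance, every elementary event with weight 1. DEC+J adds
founder ("jump") events, one daughter receiving a single unoccupied area,
with weight j in [0, 3]; j = 0 reduces exactly to DEC.

Region-to-region movement at the sample level is summarized by stochastic
character mapping under an equal-rates Mk chain: full histories are drawn
conditional on tip regions (node states from pruning partials, branch
histories by uniformization) and reported as a mean directional
transition-count matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import expit, logit

from .errors import AnalysisError, ConfigError, ValidationError
from .trees import Tree, TreeNode

__all__ = [
    "RangeData",
    "RangeModelFit",
    "StochasticMapSummary",
    "dec_loglik",
    "fit_range_model",
    "simulate_ranges",
    "mk_stochastic_maps",
]

J_MAX = 3.0


# ------------------------------------------------------------------- ranges
@dataclass(frozen=True)
class RangeData:
    """Observed tip ranges over an ordered region set, max range size K."""

    regions: tuple[str, ...]
    tip_ranges: Mapping[str, frozenset]
    max_range_size: int = 2

    def __post_init__(self):
        if len(set(self.regions)) != len(self.regions):
            raise ValidationError("region names must be unique")
        if not 1 <= self.max_range_size <= len(self.regions):
            raise ValidationError("max_range_size must be in [1, n_regions]")
        for tip, rng in self.tip_ranges.items():
            if not rng:
                raise ValidationError(f"tip {tip!r} has an empty range")
            if not rng <= set(self.regions):
                raise ValidationError(f"tip {tip!r} range outside the region set")
            if len(rng) > self.max_range_size:
                raise ValidationError(
                    f"tip {tip!r} range exceeds max size {self.max_range_size}"
                )


def _states(regions: Sequence[str], k_max: int) -> list[frozenset]:
    out = []
    for size in range(1, k_max + 1):
        for combo in itertools.combinations(range(len(regions)), size):
            out.append(frozenset(regions[i] for i in combo))
    return out


def _anagenetic_q(
    states: list[frozenset], regions: Sequence[str], d: float, e: float
) -> np.ndarray:
    index = {s: i for i, s in enumerate(states)}
    k_max = max(len(s) for s in states)
    n = len(states)
    Q = np.zeros((n, n))
    for s, i in index.items():
        if len(s) < k_max:
            for a in regions:
                if a not in s:
                    Q[i, index[s | {a}]] += d * len(s)
        if len(s) >= 2:
            for a in s:
                Q[i, index[s - {a}]] += e
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _cladogenesis_events(
    state: frozenset, regions: Sequence[str], j: float
) -> list[tuple[frozenset, frozenset, float]]:
    """Ordered (left, right, weight) daughter-range events for a parent range."""
    events: list[tuple[frozenset, frozenset, float]] = []
    if len(state) == 1:
        events.append((state, state, 1.0))
    else:
        for a in state:
            single = frozenset([a])
            events.append((single, state, 1.0))  # subset sympatry
            events.append((state, single, 1.0))
            rest = state - {a}
            events.append((single, rest, 1.0))  # vicariance (1 vs rest)
            if len(rest) > 1:
                events.append((rest, single, 1.0))
    if j > 0:
        for a in regions:
            if a not in state:
                single = frozenset([a])
                events.append((state, single, j))  # founder event
                events.append((single, state, j))
    return events


def dec_loglik(
    tree: Tree, ranges: RangeData, d: float, e: float, j: float = 0.0
) -> float:
    """DEC(+J) log-likelihood by post-order pruning; root prior uniform."""
    if d < 0 or e < 0:
        raise AnalysisError("rates d, e must be >= 0")
    if not 0 <= j <= J_MAX:
        raise AnalysisError(f"j must lie in [0, {J_MAX}]")
    regions = ranges.regions
    states = _states(regions, ranges.max_range_size)
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    if n == 1:
        return 0.0  # single state: all probabilities are 1
    Q = _anagenetic_q(states, regions, d, e)

    events_by_state = []
    for s in states:
        ev = _cladogenesis_events(s, regions, j)
        total = sum(w for _, _, w in ev)
        events_by_state.append(
            [(index[l], index[r], w / total) for l, r, w in ev if w > 0]
        )

    expm_cache: dict[float, np.ndarray] = {}

    def P_of(t: float) -> np.ndarray:
        key = round(t, 15)
        if key not in expm_cache:
            expm_cache[key] = expm(Q * t)
        return expm_cache[key]

    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in ranges.tip_ranges:
                raise AnalysisError(f"tip {node.label!r} has no observed range")
            vec = np.zeros(n)
            vec[index[ranges.tip_ranges[node.label]]] = 1.0
            partial[id(node)] = vec
            logscale[id(node)] = 0.0
        else:
            if len(node.children) != 2:
                raise AnalysisError("DEC requires a binary tree")
            lc, rc = node.children
            el = P_of(lc.length) @ partial[id(lc)]
            er = P_of(rc.length) @ partial[id(rc)]
            vec = np.zeros(n)
            for si in range(n):
                acc = 0.0
                for li, ri, p in events_by_state[si]:
                    acc += p * el[li] * er[ri]
                vec[si] = acc
            m = max(vec.max(), 1e-300)
            partial[id(node)] = vec / m
            logscale[id(node)] = (
                logscale[id(lc)] + logscale[id(rc)] + float(np.log(m))
            )
    root = tree.root
    like = float(partial[id(root)].sum() / n)
    return float(np.log(max(like, 1e-300)) + logscale[id(root)])


# ---------------------------------------------------------------- model fit
@dataclass(frozen=True)
class RangeModelFit:
    model: str  # "DEC" | "DEC+J"
    d: float
    e: float
    j: float
    loglik: float
    k_params: int
    aic: float
    start_logliks: tuple[float, ...]
    converged: bool
    seed: int | None
    max_range_size: int

    def __post_init__(self):
        if abs(self.aic - (2 * self.k_params - 2 * self.loglik)) > 1e-9:
            raise AnalysisError("AIC inconsistent with lnL and k")


def fit_range_model(
    tree: Tree,
    ranges: RangeData,
    model: str = "DEC",
    n_starts: int = 5,
    seed: int | None = 0,
    maxiter: int = 400,
) -> RangeModelFit:
    """Maximize the DEC(+J) likelihood by Nelder-Mead from jittered starts.

    d and e are optimized in log space; j through a logistic transform onto
    [0, 3]. Returns the best start with AIC = 2k - 2 lnL.
    """
    model = model.upper()
    if model == "DECJ":
        model = "DEC+J"
    if model not in ("DEC", "DEC+J"):
        raise ConfigError(f"unknown model {model!r}")
    with_j = model == "DEC+J"
    rng = np.random.default_rng(seed)

    def unpack(x):
        d = float(np.exp(np.clip(x[0], -25, 10)))
        e = float(np.exp(np.clip(x[1], -25, 10)))
        j = float(J_MAX * expit(x[2])) if with_j else 0.0
        return d, e, j

    def objective(x):
        d, e, j = unpack(x)
        try:
            return -dec_loglik(tree, ranges, d, e, j)
        except (AnalysisError, FloatingPointError):
            return 1e12

    base = [np.log(0.1), np.log(0.1)] + ([float(logit(0.1 / J_MAX))] if with_j else [])
    best = None
    start_lnls = []
    any_converged = False
    for s in range(n_starts):
        x0 = np.asarray(base) + (rng.normal(0, 1.0, size=len(base)) if s else 0.0)
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter},
        )
        start_lnls.append(-float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e12:
        raise AnalysisError("all optimizer starts failed; trace: " + repr(start_lnls))
    d, e, j = unpack(best.x)
    lnl = -float(best.fun)
    k = 3 if with_j else 2
    return RangeModelFit(
        model=model,
        d=d,
        e=e,
        j=j,
        loglik=lnl,
        k_params=k,
        aic=2 * k - 2 * lnl,
        start_logliks=tuple(start_lnls),
        converged=any_converged,
        seed=seed,
        max_range_size=ranges.max_range_size,
    )


# ------------------------------------------------------------ range simulator
def simulate_ranges(
    tree: Tree,
    regions: Sequence[str],
    d: float,
    e: float,
    j: float = 0.0,
    max_range_size: int = 2,
    seed: int | None = 0,
    root_range: frozenset | None = None,
) -> RangeData:
    """Forward-simulate ranges under DEC(+J): Gillespie along branches,
    weighted cladogenetic events at nodes."""
    regions = tuple(regions)
    states = _states(regions, max_range_size)
    index = {s: i for i, s in enumerate(states)}
    Q = _anagenetic_q(states, regions, d, e)
    rng = np.random.default_rng(seed)
    if root_range is None:
        root_range = states[int(rng.integers(len(states)))]

    def evolve(state: frozenset, t: float) -> frozenset:
        i = index[state]
        remaining = t
        while True:
            rate = -Q[i, i]
            if rate <= 0:
                return states[i]
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                return states[i]
            remaining -= wait
            probs = np.maximum(Q[i], 0.0)
            probs = probs / probs.sum()
            i = int(rng.choice(len(states), p=probs))

    tip_ranges: dict[str, frozenset] = {}
    state_at: dict[int, frozenset] = {id(tree.root): root_range}
    for node in tree.preorder():
        state = state_at[id(node)]
        if node.is_leaf:
            tip_ranges[node.label] = state
            continue
        if len(node.children) != 2:
            raise AnalysisError("range simulation requires a binary tree")
        events = _cladogenesis_events(state, regions, j)
        weights = np.array([w for _, _, w in events])
        pick = int(rng.choice(len(events), p=weights / weights.sum()))
        left_state, right_state, _ = events[pick]
        for child, st in zip(node.children, (left_state, right_state)):
            state_at[id(child)] = evolve(st, child.length)
    return RangeData(
        regions=regions, tip_ranges=tip_ranges, max_range_size=max_range_size
    )


# ----------------------------------------------------- stochastic mapping (Mk)
@dataclass(frozen=True)
class StochasticMapSummary:
    regions: tuple[str, ...]
    n_maps: int
    mean_counts: np.ndarray = field(repr=False)  # directional, diag 0
    rate: float
    seed: int | None

    def __post_init__(self):
        counts = np.asarray(self.mean_counts)
        if np.any(counts < 0) or np.any(np.diag(counts) != 0):
            raise AnalysisError("mean counts must be >= 0 with a zero diagonal")

    @property
    def mean_total_changes(self) -> float:
        return float(np.asarray(self.mean_counts).sum())


def _mk_transition(k: int, q: float, t) -> np.ndarray:
    """Equal-rates Mk transition probabilities (closed form)."""
    t = np.asarray(t, dtype=float)
    decay = np.exp(-k * q * t)
    same = 1.0 / k + (1.0 - 1.0 / k) * decay
    diff = 1.0 / k * (1.0 - decay)
    P = np.full((*t.shape, k, k), 0.0) + diff[..., None, None]
    idx = np.arange(k)
    P[..., idx, idx] = same[..., None]
    return P


def _mk_partials(tree: Tree, tip_idx: Mapping[str, int], k: int, q: float):
    partial: dict[int, np.ndarray] = {}
    logscale: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(k)
            vec[tip_idx[node.label]] = 1.0
            partial[id(node)] = vec
            logscale[id(node)] = 0.0
        else:
            vec = np.ones(k)
            sc = 0.0
            for child in node.children:
                P = _mk_transition(k, q, np.array(child.length))
                vec = vec * (P @ partial[id(child)])
                sc += logscale[id(child)]
            m = max(vec.max(), 1e-300)
            partial[id(node)] = vec / m
            logscale[id(node)] = sc + float(np.log(m))
    return partial, logscale


def fit_mk_rate(tree: Tree, tip_states: Mapping[str, str], regions: Sequence[str]) -> float:
    """ML single rate of the equal-rates Mk model (uniform root prior)."""
    regions = tuple(regions)
    k = len(regions)
    idx = {r: i for i, r in enumerate(regions)}
    tip_idx = {t: idx[s] for t, s in tip_states.items()}
    if len(set(tip_states.values())) < 2:
        raise AnalysisError("need >= 2 distinct tip states to identify the rate")

    def neg_lnl(log_q):
        q = float(np.exp(log_q))
        partial, logscale = _mk_partials(tree, tip_idx, k, q)
        root = partial[id(tree.root)]
        return -(float(np.log(max(root.sum() / k, 1e-300))) + logscale[id(tree.root)])

    res = minimize_scalar(neg_lnl, bounds=(-12.0, 6.0), method="bounded")
    return float(np.exp(res.x))


class _UniformizedSampler:
    """Endpoint-conditioned path sampler for the equal-rates Mk chain.

    Uniformization with rate lam = k q (>= max exit rate); jump-count
    distributions and within-path step probabilities are cached, since a
    mapping run revisits the same (branch length, endpoints) many times.
    """

    def __init__(self, k: int, q: float):
        self.k = k
        self.q = q
        self.lam = k * q
        R = np.full((k, k), q / self.lam)
        np.fill_diagonal(R, 1.0 - (k - 1) * q / self.lam)
        self.R = R
        self._powers = [np.eye(k)]
        self._jump_cdf: dict[tuple, np.ndarray] = {}
        self._step_cdf: dict[tuple, np.ndarray] = {}

    def _power(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def _jump_count_cdf(self, a: int, b: int, t: float) -> np.ndarray:
        key = (a, b, round(t, 12))
        cdf = self._jump_cdf.get(key)
        if cdf is None:
            mean = self.lam * t
            n_max = int(mean + 12.0 * np.sqrt(mean) + 25)
            log_pois = (
                -mean
                + np.arange(n_max + 1) * np.log(mean)
                - np.cumsum(
                    np.concatenate([[0.0], np.log(np.arange(1, n_max + 1))])
                )
            )
            w = np.exp(log_pois) * np.array(
                [self._power(n)[a, b] for n in range(n_max + 1)]
            )
            total = w.sum()
            if total <= 0:
                raise AnalysisError(
                    "endpoint-conditioned jump distribution is degenerate"
                )
            cdf = np.cumsum(w / total)
            self._jump_cdf[key] = cdf
        return cdf

    def _step(self, current: int, remaining: int, b: int) -> np.ndarray:
        key = (current, remaining, b)
        cdf = self._step_cdf.get(key)
        if cdf is None:
            probs = self.R[current] * self._power(remaining)[:, b]
            cdf = np.cumsum(probs / probs.sum())
            self._step_cdf[key] = cdf
        return cdf

    def sample(
        self, a: int, b: int, t: float, rng: np.random.Generator
    ) -> list[int]:
        if self.lam * t <= 0:
            if a != b:
                raise AnalysisError("zero-length branch cannot change state")
            return [a, a]
        cdf = self._jump_count_cdf(a, b, t)
        n = int(np.searchsorted(cdf, rng.random()))
        states = [a]
        current = a
        for m in range(1, n + 1):
            cdf_m = self._step(current, n - m, b)
            current = int(np.searchsorted(cdf_m, rng.random()))
            states.append(current)
        if states[-1] != b:  # cannot happen; guard for numeric pathology
            raise AnalysisError("uniformization path failed to hit the endpoint")
        return states


def sample_branch_history(
    a: int, b: int, t: float, k: int, q: float, rng: np.random.Generator
) -> list[int]:
    """States visited along a branch conditional on endpoint states (a -> b),
    by uniformization; returns the state sequence including both endpoints."""
    return _UniformizedSampler(k, q).sample(a, b, t, rng)


def mk_stochastic_maps(
    tree: Tree,
    tip_states: Mapping[str, str],
    regions: Sequence[str] | None = None,
    n_maps: int = 3000,
    seed: int | None = 0,
    rate: float | None = None,
) -> StochasticMapSummary:
    """Stochastic character maps under the fitted (or given) equal-rates Mk
    chain; returns the mean directional region-to-region transition counts
    over ``n_maps`` sampled histories."""
    if regions is None:
        regions = tuple(sorted(set(tip_states.values())))
    regions = tuple(regions)
    k = len(regions)
    idx = {r: i for i, r in enumerate(regions)}
    missing = [t for t in tree.tip_labels if t not in tip_states]
    if missing:
        raise AnalysisError(f"tips without states: {missing}")
    if len({tip_states[t] for t in tree.tip_labels}) < 2:
        raise AnalysisError("need >= 2 distinct tip states")
    q = rate if rate is not None else fit_mk_rate(tree, tip_states, regions)
    tip_idx = {t: idx[s] for t, s in tip_states.items()}
    partial, _ = _mk_partials(tree, tip_idx, k, q)
    rng = np.random.default_rng(seed)
    sampler = _UniformizedSampler(k, q)

    nodes = list(tree.preorder())
    P_branch = {
        id(n): _mk_transition(k, q, np.array(n.length))
        for n in nodes
        if n is not tree.root
    }
    counts = np.zeros((k, k))
    for _ in range(n_maps):
        state: dict[int, int] = {}
        for node in nodes:
            if node is tree.root:
                w = partial[id(node)].copy()  # uniform prior x partials
            else:
                w = P_branch[id(node)][state[id(node.parent)]] * partial[id(node)]
            cdf = np.cumsum(w / w.sum())
            state[id(node)] = int(np.searchsorted(cdf, rng.random()))
        for node in nodes:
            if node is tree.root:
                continue
            path = sampler.sample(
                state[id(node.parent)], state[id(node)], node.length, rng
            )
            for x, y in zip(path, path[1:]):
                if x != y:
                    counts[x, y] += 1
    return StochasticMapSummary(
        regions=regions,
        n_maps=n_maps,
        mean_counts=counts / n_maps,
        rate=float(q),
        seed=seed,
    )
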