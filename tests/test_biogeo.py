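"""DEC likelihoods, model fitting, and Mk stochastic mapping."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from yartsa.biogeo import (
    RangeData,
    dec_loglik,
    fit_range_model,
    fit_mk_rate,
    mk_stochastic_maps,
    sample_branch_history,
    simulate_ranges,
)
from yartsa.errors import AnalysisError, ValidationError
from yartsa.synthdata import SimConfig, simulate_host_tree
from yartsa.trees import parse_newick


# ------------------------------------------------------------- DEC oracle
def oracle_dec_loglik(tree, ranges, d, e, j):
    """Exhaustive oracle: enumerate every internal-node state and every
    cladogenetic daughter assignment explicitly, with dense expm transitions.
    Independent re-derivation of the documented event model."""
    regions = list(ranges.regions)
    states = [
        frozenset(c)
        for size in range(1, ranges.max_range_size + 1)
        for c in itertools.combinations(regions, size)
    ]
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for s in states:
        i = idx[s]
        if len(s) < ranges.max_range_size:
            for a in regions:
                if a not in s:
                    Q[i, idx[s | {a}]] += d * len(s)
        if len(s) >= 2:
            for a in s:
                Q[i, idx[s - {a}]] += e
    np.fill_diagonal(Q, -Q.sum(axis=1))

    def events(s):
        out = []
        if len(s) == 1:
            out.append((s, s, 1.0))
        else:
            for a in s:
                one = frozenset([a])
                out.append((one, s, 1.0))
                out.append((s, one, 1.0))
                out.append((one, s - {a}, 1.0))
                if len(s - {a}) > 1:
                    out.append((s - {a}, one, 1.0))
        for a in regions:
            if a not in s and j > 0:
                one = frozenset([a])
                out.append((s, one, j))
                out.append((one, s, j))
        total = sum(w for _, _, w in out)
        return [(l, r, w / total) for l, r, w in out]

    def subtree_prob(node, state):
        """P(tip data below | node carries ``state`` just before splitting)."""
        if node.is_leaf:
            return 1.0 if ranges.tip_ranges[node.label] == state else 0.0
        total = 0.0
        left, right = node.children
        for sl, sr, w in events(state):
            pl = sum(
                expm(Q * left.length)[idx[sl], idx[x]] * subtree_prob(left, x)
                for x in states
            )
            pr = sum(
                expm(Q * right.length)[idx[sr], idx[x]] * subtree_prob(right, x)
                for x in states
            )
            total += w * pl * pr
        return total

    like = sum(subtree_prob(tree.root, s) for s in states) / n
    return float(np.log(like))


def two_area_ranges(tip_ranges):
    return RangeData(regions=("A", "B"), tip_ranges=tip_ranges, max_range_size=2)


class TestDecLoglik:
    def test_single_region_degenerate(self):
        tree = parse_newick("((x:1,y:1):1,z:2);")
        rd = RangeData(
            regions=("A",),
            tip_ranges={t: frozenset("A") for t in "xyz"},
            max_range_size=1,
        )
        assert dec_loglik(tree, rd, 0.5, 0.1) == 0.0

    def test_j_zero_reduces_to_dec(self):
        tree = parse_newick("((x:1,y:1):1,z:2);")
        rd = two_area_ranges(
            {"x": frozenset("A"), "y": frozenset("B"), "z": frozenset("AB")}
        )
        assert dec_loglik(tree, rd, 0.2, 0.1, j=0.0) == pytest.approx(
            dec_loglik(tree, rd, 0.2, 0.1), abs=1e-12
        )

    @pytest.mark.parametrize("d,e,j", [(0.1, 0.1, 0.0), (1.0, 0.01, 0.5)])
    def test_matches_enumeration_oracle_three_tips(self, d, e, j):
        tree = parse_newick("((x:0.6,y:0.4):0.5,z:1.1);")
        rd = two_area_ranges(
            {"x": frozenset("A"), "y": frozenset("AB"), "z": frozenset("B")}
        )
        assert dec_loglik(tree, rd, d, e, j) == pytest.approx(
            oracle_dec_loglik(tree, rd, d, e, j), abs=1e-8
        )

    def test_nonbinary_tree_rejected(self):
        tree = parse_newick("(x:1,y:1,z:1);")
        rd = two_area_ranges(
            {"x": frozenset("A"), "y": frozenset("B"), "z": frozenset("A")}
        )
        with pytest.raises(AnalysisError, match="binary"):
            dec_loglik(tree, rd, 0.1, 0.1)

    def test_tip_range_exceeding_k_rejected(self):
        with pytest.raises(ValidationError, match="max size"):
            RangeData(
                regions=("A", "B"),
                tip_ranges={"x": frozenset("AB")},
                max_range_size=1,
            )

    def test_loglik_nonpositive_and_k_monotone(self):
        cfg = SimConfig(seed=17, n_samples=12)
        tree = simulate_host_tree(cfg)
        regions = ("A", "B", "C")
        rng = np.random.default_rng(0)
        tips = {
            t: frozenset([regions[int(rng.integers(3))]]) for t in tree.tip_labels
        }
        rd1 = RangeData(regions, tips, max_range_size=1)
        rd2 = RangeData(regions, tips, max_range_size=2)
        lnl1 = dec_loglik(tree, rd1, 0.3, 0.1)
        lnl2 = dec_loglik(tree, rd2, 0.3, 0.1)
        assert lnl1 <= 0 and lnl2 <= 0
        f1 = fit_range_model(tree, rd1, "DEC", n_starts=2, seed=0)
        f2 = fit_range_model(tree, rd2, "DEC", n_starts=2, seed=0)
        assert f2.loglik >= f1.loglik - 1e-6


class TestFitRangeModel:
    def test_aic_consistency_and_convergence(self):
        cfg = SimConfig(seed=18, n_samples=15)
        tree = simulate_host_tree(cfg)
        rd = simulate_ranges(tree, ("A", "B", "C", "D"), d=0.3, e=0.05, seed=4)
        fit = fit_range_model(tree, rd, "DEC", seed=0)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik, abs=1e-9)
        assert fit.converged
        fitj = fit_range_model(tree, rd, "DEC+J", seed=0)
        assert fitj.k_params == 3
        assert fitj.loglik >= fit.loglik - 1e-6  # nested models

    def test_permuted_tip_ranges_degrade_fit(self):
        cfg = SimConfig(seed=19, n_samples=20)
        tree = simulate_host_tree(cfg)
        rd = simulate_ranges(tree, ("A", "B", "C", "D"), d=0.15, e=0.02, seed=1)
        true_lnl = fit_range_model(tree, rd, "DEC", n_starts=3, seed=0).loglik
        rng = np.random.default_rng(2)
        worse = 0
        for rep in range(10):
            labels = list(rd.tip_ranges)
            vals = [rd.tip_ranges[l] for l in labels]
            rng.shuffle(vals)
            shuffled = RangeData(rd.regions, dict(zip(labels, vals)), rd.max_range_size)
            lnl = fit_range_model(tree, shuffled, "DEC", n_starts=3, seed=0).loglik
            worse += lnl < true_lnl
        assert worse >= 9


class TestSimulateRanges:
    def test_output_valid_and_deterministic(self):
        cfg = SimConfig(seed=20, n_samples=10)
        tree = simulate_host_tree(cfg)
        r1 = simulate_ranges(tree, ("A", "B"), d=0.4, e=0.1, j=1.0, seed=9)
        r2 = simulate_ranges(tree, ("A", "B"), d=0.4, e=0.1, j=1.0, seed=9)
        assert r1.tip_ranges == r2.tip_ranges
        for rng_ in r1.tip_ranges.values():
            assert 1 <= len(rng_) <= 2


# ---------------------------------------------------- stochastic mapping
def oracle_expected_changes(a, b, t, k, q, n_max=200):
    """Conditional expected number of real state changes on one branch,
    computed exactly from the uniformized chain."""
    lam = k * q
    R = np.full((k, k), q / lam)
    np.fill_diagonal(R, 1.0 - (k - 1) * q / lam)
    powers = [np.eye(k)]
    for _ in range(n_max):
        powers.append(powers[-1] @ R)
    from scipy.stats import poisson

    pois = poisson.pmf(np.arange(n_max + 1), lam * t)
    weights = pois * np.array([powers[n][a, b] for n in range(n_max + 1)])
    weights /= weights.sum()
    total = 0.0
    for n in range(1, n_max + 1):
        if weights[n] == 0:
            continue
        exp_real = 0.0
        for m in range(1, n + 1):
            for x in range(k):
                for y in range(k):
                    if x != y:
                        exp_real += (
                            powers[m - 1][a, x] * R[x, y] * powers[n - m][y, b]
                        ) / powers[n][a, b]
        total += weights[n] * exp_real
    return total


class TestStochasticMapping:
    def test_branch_history_endpoints_always_consistent(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b = int(rng.integers(2)), int(rng.integers(2))
            path = sample_branch_history(a, b, t=0.7, k=2, q=1.3, rng=rng)
            assert path[0] == a and path[-1] == b

    def test_branch_expected_changes_match_uniformization_oracle(self):
        a, b, t, k, q = 0, 1, 0.8, 2, 1.0
        rng = np.random.default_rng(1)
        n_changes = []
        for _ in range(3000):
            path = sample_branch_history(a, b, t, k, q, rng)
            n_changes.append(sum(x != y for x, y in zip(path, path[1:])))
        expected = oracle_expected_changes(a, b, t, k, q)
        assert np.mean(n_changes) == pytest.approx(expected, rel=0.05)

    def test_single_state_tips_rejected(self):
        tree = parse_newick("((x:1,y:1):1,z:2);")
        with pytest.raises(AnalysisError, match="distinct"):
            mk_stochastic_maps(tree, {"x": "A", "y": "A", "z": "A"}, ("A", "B"))

    def test_low_rate_limit_approaches_parsimony(self):
        # in the q -> 0 limit the chain makes only the one change parsimony
        # requires; the ML rate itself just needs to be finite and positive
        tree = parse_newick("((w:1,x:1):3,(y:1,z:1):3);")
        states = {"w": "A", "x": "A", "y": "B", "z": "B"}
        q = fit_mk_rate(tree, states, ("A", "B"))
        assert 0 < q < 1
        summ = mk_stochastic_maps(
            tree, states, ("A", "B"), n_maps=500, seed=0, rate=1e-3
        )
        assert summ.mean_total_changes <= 1.0 + 0.1

    def test_mean_counts_shape_and_diag(self, default_bundle):
        tree = default_bundle.host_tree
        region_of = default_bundle.samples.frame["region"].to_dict()
        summ = mk_stochastic_maps(
            tree, region_of, default_bundle.samples.regions, n_maps=50, seed=0
        )
        assert summ.mean_counts.shape == (4, 4)
        assert np.all(np.diag(summ.mean_counts) == 0)
        assert summ.n_maps == 50
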