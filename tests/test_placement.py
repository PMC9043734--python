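"""Pruning likelihood, per-edge placement, and the origin-assignment rule."""

import itertools
import math

import numpy as np
import pytest

from yartsa.containers import MultiLocusAlignment
from yartsa.errors import AnalysisError
from yartsa.models import BASE_INDEX, SubstitutionModel
from yartsa.placement import (
    assign_origin,
    loci_sensitivity,
    place_query,
    place_query_subsets,
    placement_to_jplace,
    tree_loglik,
)
from yartsa.synthdata import SimConfig, simulate_host_tree, simulate_sequences
from yartsa.trees import parse_newick, reroot_at_edge


def enumeration_loglik(tree, sequences, model):
    """Oracle: sum the site likelihood over every assignment of ancestral
    states to internal nodes (exponential in tree size)."""
    tips = tree.tip_labels
    length = len(sequences[tips[0]])
    internals = [n for n in tree.postorder() if not n.is_leaf]
    pi = np.asarray(model.freqs)
    lnl = 0.0
    for site in range(length):
        site_like = 0.0
        for combo in itertools.product(range(4), repeat=len(internals)):
            state = {id(n): s for n, s in zip(internals, combo)}
            prob = pi[state[id(tree.root)]]
            for node in tree.postorder():
                if node is tree.root:
                    continue
                P = model.transition_matrix(node.length)
                parent_state = state[id(node.parent)]
                if node.is_leaf:
                    char = sequences[node.label][site]
                    if char in BASE_INDEX:
                        prob_node = P[parent_state, BASE_INDEX[char]]
                    else:
                        prob_node = 1.0
                else:
                    prob_node = P[parent_state, state[id(node)]]
                prob *= prob_node
            site_like += prob
        lnl += math.log(site_like)
    return lnl


class TestTreeLoglik:
    def test_invariant_site_zero_branches(self):
        tree = parse_newick("(A:0,B:0);")
        lnl = tree_loglik(tree, {"A": "C", "B": "C"}, SubstitutionModel.jc69())
        assert lnl == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("model", [SubstitutionModel.jc69(), SubstitutionModel.hky85()])
    def test_matches_state_enumeration(self, model):
        # 4 tips x 10 sites against the exhaustive ancestral-state sum
        cfg = SimConfig(seed=13, n_samples=4, n_loci=1, locus_length=10)
        tree = simulate_host_tree(cfg).scaled(0.3)
        aln = simulate_sequences(tree, cfg, rate_scaler=1.0)
        seqs = aln.concatenate()
        assert tree_loglik(tree, seqs, model) == pytest.approx(
            enumeration_loglik(tree, seqs, model), abs=1e-10
        )

    def test_rerooting_invariance(self):
        cfg = SimConfig(seed=14, n_samples=6, n_loci=1, locus_length=40)
        tree = simulate_host_tree(cfg).scaled(0.2)
        aln = simulate_sequences(tree, cfg, rate_scaler=1.0)
        seqs = aln.concatenate()
        model = SubstitutionModel.jc69()
        base = tree_loglik(tree, seqs, model)
        below = tree.tipset_below()
        for node in tree.postorder():
            if node is tree.root or node.parent is tree.root:
                continue
            rerooted = reroot_at_edge(tree, below[node], fraction=0.3)
            assert tree_loglik(rerooted, seqs, model) == pytest.approx(base, abs=1e-8)

    def test_missing_tip_sequence_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        with pytest.raises(AnalysisError, match="without sequences"):
            tree_loglik(tree, {"A": "ACGT"}, SubstitutionModel.jc69())


@pytest.fixture(scope="module")
def instance():
    cfg = SimConfig(seed=21, n_samples=10, n_loci=3, locus_length=250)
    host = simulate_host_tree(cfg)
    molecular = host.scaled(0.08 / host.root_height)
    aln = simulate_sequences(molecular, cfg, rate_scaler=1.0)
    return molecular, aln


class TestPlaceQuery:

    def test_self_placement_recovers_tip(self, instance):
        tree, aln = instance
        tip = tree.tip_labels[3]
        pruned, info = tree.prune_tip(tip)
        query = {l: aln.data[l][tip] for l in aln.loci}
        res = place_query(pruned, aln.subset_samples(pruned.tip_labels), tip, query)
        correct = set(info["child_tipsets"])
        if info["sibling_tipset"] is not None:
            correct.add(info["sibling_tipset"])
        assert res.edge_tipsets[res.best_edge] in correct
        assert res.best_lwr >= 0.99

    def test_per_edge_likelihoods_match_graft_oracle(self, instance):
        tree, aln = instance
        model = SubstitutionModel.jc69()
        tip = tree.tip_labels[0]
        pruned, _ = tree.prune_tip(tip)
        sub = aln.subset_samples(pruned.tip_labels)
        query = {l: aln.data[l][tip] for l in aln.loci}
        res = place_query(pruned, sub, tip, query, model)
        seqs = sub.concatenate()
        qcat = "".join(query[l] for l in aln.loci)
        for edge in res.edges:
            grafted = pruned.graft(
                res.edge_tipsets[edge.edge_id], tip, edge.pendant_length
            )
            oracle = tree_loglik(grafted, {**seqs, tip: qcat}, model)
            assert edge.loglik == pytest.approx(oracle, abs=1e-8)

    def test_lwr_normalization(self, instance):
        tree, aln = instance
        tip = tree.tip_labels[5]
        pruned, _ = tree.prune_tip(tip)
        query = {l: aln.data[l][tip] for l in aln.loci}
        res = place_query(pruned, aln.subset_samples(pruned.tip_labels), tip, query)
        assert sum(e.lwr for e in res.edges) == pytest.approx(1.0, abs=1e-9)

    def test_uninformative_query_spreads_uniformly(self, instance):
        tree, aln = instance
        tip = tree.tip_labels[2]
        pruned, _ = tree.prune_tip(tip)
        length = aln.locus_length(aln.loci[0])
        query = {aln.loci[0]: "N" * length}
        res = place_query(pruned, aln.subset_samples(pruned.tip_labels), "blank", query)
        expected = 1.0 / len(res.edges)
        assert all(e.lwr == pytest.approx(expected, rel=1e-6) for e in res.edges)

    def test_colliding_query_label_rejected(self, instance):
        tree, aln = instance
        tip = tree.tip_labels[0]
        query = {l: aln.data[l][tip] for l in aln.loci}
        with pytest.raises(AnalysisError, match="collides"):
            place_query(tree, aln, tip, query)

    def test_no_shared_loci_rejected(self, instance):
        tree, aln = instance
        with pytest.raises(AnalysisError, match="no loci"):
            place_query(tree, aln, "q", {"unknown_locus": "ACGT"})

    def test_subset_placements_match_single_calls(self, instance):
        tree, aln = instance
        tip = tree.tip_labels[7]
        pruned, _ = tree.prune_tip(tip)
        sub = aln.subset_samples(pruned.tip_labels)
        query = {l: aln.data[l][tip] for l in aln.loci}
        multi = place_query_subsets(
            pruned, sub, tip, query, subsets=[[aln.loci[0]], list(aln.loci)]
        )
        single = place_query(pruned, sub, tip, {aln.loci[0]: query[aln.loci[0]]})
        for a, b in zip(multi[0].edges, single.edges):
            assert a.loglik == pytest.approx(b.loglik, abs=1e-9)


class TestLociSensitivity:
    def test_full_information_places_perfectly(self):
        # well-separated reference, all loci: every replicate lands correctly
        cfg = SimConfig(seed=30, n_samples=10, n_loci=4, locus_length=400)
        host = simulate_host_tree(cfg)
        molecular = host.scaled(0.3 / host.root_height)
        aln = simulate_sequences(molecular, cfg, rate_scaler=1.0)
        table = loci_sensitivity(
            molecular, aln, loci_counts=[4], reps_per_count=10, seed=0
        )
        assert table.loc[0, "frac_correct"] == 1.0
        assert table.loc[0, "mean_confidence"] > 0.95

    def test_requested_count_beyond_available_rejected(self, small_bundle):
        with pytest.raises(AnalysisError, match="loci"):
            loci_sensitivity(
                small_bundle.host_molecular_tree,
                small_bundle.full_alignment,
                loci_counts=[99],
            )


def eight_tip_labelled_tree():
    text = (
        "(((A:0.05,B:0.05):0.05,(C:0.05,(D:0.03,(E:0.02,F:0.02):0.01):0.02)"
        "Himalaya:0.05):0.05,(G:0.1,H:0.1):0.05);"
    )
    return parse_newick(text)


def placement_on_tipset(tree, tipset, lwr=0.9):
    """Synthetic PlacementResult putting ``lwr`` on the edge over ``tipset``."""
    from yartsa.placement import EdgePlacement, PlacementResult

    indexed = tree.copy()
    edge_nodes = indexed.index_edges()
    below = indexed.tipset_below()
    tipsets = tuple(below[n] for n in edge_nodes)
    target = tipsets.index(tipset)
    rest = (1.0 - lwr) / (len(edge_nodes) - 1)
    edges = tuple(
        EdgePlacement(
            edge_id=i,
            loglik=-100.0 if i == target else -200.0,
            pendant_length=0.01,
            lwr=lwr if i == target else rest,
        )
        for i in range(len(edge_nodes))
    )
    return PlacementResult(
        query_id="q", loci_used=("L1",), edges=edges, best_edge=target,
        n_sites=100, edge_tipsets=tipsets,
    )


class TestAssignOrigin:
    def test_nested_placement(self):
        tree = eight_tip_labelled_tree()
        res = placement_on_tipset(tree, frozenset({"E"}))
        report = assign_origin(tree, res)
        assert (report.label, report.relation) == ("Himalaya", "nested")

    def test_sister_placement(self):
        tree = eight_tip_labelled_tree()
        res = placement_on_tipset(tree, frozenset({"C", "D", "E", "F"}))
        report = assign_origin(tree, res)
        assert (report.label, report.relation) == ("Himalaya", "sister")

    def test_outgroup_placement_unassigned(self):
        tree = eight_tip_labelled_tree()
        res = placement_on_tipset(tree, frozenset({"G"}))
        report = assign_origin(tree, res, truth="Himalaya")
        assert report.label is None and report.relation == "none"
        assert report.outcome == "FN"

    def test_outcome_classes(self):
        tree = eight_tip_labelled_tree()
        nested = placement_on_tipset(tree, frozenset({"D"}))
        assert assign_origin(tree, nested, truth="Himalaya").outcome == "TP"
        assert assign_origin(tree, nested, truth="QTP").outcome == "FP"
        out = placement_on_tipset(tree, frozenset({"A"}))
        assert assign_origin(tree, out, truth="QTP").outcome == "TN"

    def test_low_lwr_unassigned(self):
        tree = eight_tip_labelled_tree()
        res = placement_on_tipset(tree, frozenset({"E"}), lwr=0.3)
        report = assign_origin(tree, res, lwr_floor=0.5)
        assert report.label is None

    def test_clade_lwr_mass(self):
        tree = eight_tip_labelled_tree()
        res = placement_on_tipset(tree, frozenset({"E"}), lwr=0.9)
        report = assign_origin(tree, res)
        # mass on the 7 edges inside-or-at the Himalaya clade root
        rest = (1.0 - 0.9) / (len(res.edges) - 1)
        assert report.clade_lwr == pytest.approx(0.9 + 6 * rest)


class TestJplace:
    def test_output_shape(self, small_bundle):
        tree = small_bundle.host_molecular_tree
        aln = small_bundle.full_alignment
        tip = tree.tip_labels[0]
        pruned, _ = tree.prune_tip(tip)
        query = {l: aln.data[l][tip] for l in aln.loci}
        res = place_query(pruned, aln.subset_samples(pruned.tip_labels), tip, query)
        j = placement_to_jplace(pruned, [res])
        assert j["fields"][0] == "edge_num"
        assert "{0}" in j["tree"]
        assert j["placements"][0]["n"] == [tip]
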