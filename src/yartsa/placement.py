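"""Likelihood placement of query samples on a fixed reference tree.

Placement is exhaustive per-edge maximum likelihood: the query is attached
by a new node at each edge's midpoint with a pendant branch whose length is
optimized by golden-section search, and per-edge likelihood weight ratios
(LWRs) normalize the optimized likelihoods. The engine computes "below" and
"outside" conditional likelihoods once per reference tree, after which every
pendant-length evaluation is a cheap spectral contraction — this is what
makes the 1..L-locus sensitivity sweep tractable.

On top of the engine sit the leave-one-out loci-sensitivity experiment and
the monophyly/sister origin-assignment rule (a query is assigned to a
labelled clade if its best placement is nested within it, or sits on the
clade's root edge, i.e. sister to it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MultiLocusAlignment
from .errors import AnalysisError, ValidationError
from .models import BASE_INDEX, SubstitutionModel
from .trees import Tree

__all__ = [
    "PlacementResult",
    "EdgePlacement",
    "AssignmentReport",
    "tree_loglik",
    "place_query",
    "place_query_subsets",
    "loci_sensitivity",
    "assign_origin",
    "placement_to_jplace",
]

_MISSING = 255
_LWR_TOL = 1e-9
PENDANT_BOUNDS = (1e-8, 2.0)
_GOLDEN_TOL = 1e-6


# ----------------------------------------------------------------- encoding
def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, _MISSING, dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _tip_partials(codes: np.ndarray) -> np.ndarray:
    """(n_patterns,) codes -> (n_patterns, 4) partials; missing -> all ones."""
    n = codes.shape[0]
    out = np.zeros((n, 4))
    miss = codes == _MISSING
    out[np.arange(n)[~miss], codes[~miss].astype(int)] = 1.0
    out[miss] = 1.0
    return out


# -------------------------------------------------------------- tree lnL
def tree_loglik(
    tree: Tree, sequences: Mapping[str, str], model: SubstitutionModel
) -> float:
    """Felsenstein pruning log-likelihood over all sites (patterns compressed).

    '-'/'N' are uninformative; every tip must have a sequence.
    """
    tips = tree.tip_labels
    missing = [t for t in tips if t not in sequences]
    if missing:
        raise AnalysisError(f"tips without sequences: {missing}")
    lengths = {len(sequences[t]) for t in tips}
    if len(lengths) != 1:
        raise AnalysisError("sequences must have equal length")
    mat = np.stack([_encode_seq(sequences[t]) for t in tips])
    patterns, counts = np.unique(mat.T, axis=0, return_counts=True)
    patterns = patterns.T  # taxa x n_patterns
    row_of = {label: i for i, label in enumerate(tips)}

    partial: dict[int, np.ndarray] = {}
    scale: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            partial[id(node)] = _tip_partials(patterns[row_of[node.label]])
            scale[id(node)] = np.zeros(counts.shape[0])
        else:
            prod = np.ones((counts.shape[0], 4))
            sc = np.zeros(counts.shape[0])
            for child in node.children:
                P = model.transition_matrix(child.length)
                prod *= partial[id(child)] @ P.T
                sc += scale[id(child)]
            m = np.maximum(prod.max(axis=1), 1e-300)
            partial[id(node)] = prod / m[:, None]
            scale[id(node)] = sc + np.log(m)
    pi = np.asarray(model.freqs)
    site_l = partial[id(tree.root)] @ pi
    return float(counts @ (np.log(np.maximum(site_l, 1e-300)) + scale[id(tree.root)]))


# -------------------------------------------------------------- result types
@dataclass(frozen=True)
class EdgePlacement:
    edge_id: int
    loglik: float
    pendant_length: float
    lwr: float


@dataclass(frozen=True)
class PlacementResult:
    query_id: str
    loci_used: tuple[str, ...]
    edges: tuple[EdgePlacement, ...]
    best_edge: int
    n_sites: int
    edge_tipsets: tuple[frozenset, ...] = field(repr=False)

    def __post_init__(self):
        total = sum(e.lwr for e in self.edges)
        if abs(total - 1.0) > _LWR_TOL:
            raise AnalysisError(f"LWRs must sum to 1 (got {total})")
        best = max(self.edges, key=lambda e: e.loglik)
        if self.edges[self.best_edge].loglik < best.loglik - 1e-9:
            raise AnalysisError("best edge does not have maximal log-likelihood")

    @property
    def best_lwr(self) -> float:
        return self.edges[self.best_edge].lwr

    def lwr_of(self, edge_id: int) -> float:
        return self.edges[edge_id].lwr


# ------------------------------------------------------------------- engine
class _PlacementWorkspace:
    """Per-(reference tree, query) partials shared across locus subsets."""

    def __init__(
        self,
        ref_tree: Tree,
        ref_aln: MultiLocusAlignment,
        query_id: str,
        query_seqs: Mapping[str, str],
        model: SubstitutionModel,
    ):
        if query_id in ref_tree.tip_labels:
            raise AnalysisError(f"query label {query_id!r} collides with a reference tip")
        loci = [l for l in ref_aln.loci if l in query_seqs]
        if not loci:
            raise AnalysisError("query shares no loci with the reference alignment")
        self.query_id = query_id
        self.model = model
        self.loci = loci
        self.tree = ref_tree.copy()
        self.edge_nodes = self.tree.index_edges()
        tips = self.tree.tip_labels

        pattern_blocks, count_blocks, locus_ids = [], [], []
        for li, locus in enumerate(loci):
            length = ref_aln.locus_length(locus)
            if len(query_seqs[locus]) != length:
                raise AnalysisError(
                    f"query sequence length mismatch at locus {locus!r}"
                )
            rows = []
            for t in tips:
                seq = ref_aln.data[locus].get(t, "N" * length)
                rows.append(_encode_seq(seq))
            rows.append(_encode_seq(query_seqs[locus]))
            mat = np.stack(rows)
            pats, counts = np.unique(mat.T, axis=0, return_counts=True)
            pattern_blocks.append(pats.T)
            count_blocks.append(counts.astype(float))
            locus_ids.append(np.full(counts.shape[0], li))
        self.patterns = np.concatenate(pattern_blocks, axis=1)
        self.counts = np.concatenate(count_blocks)
        self.pattern_locus = np.concatenate(locus_ids)
        self.site_totals = {
            locus: int(ref_aln.locus_length(locus)) for locus in loci
        }
        self._build_contexts()

    # ................................................. conditional likelihoods
    def _build_contexts(self) -> None:
        tree, model = self.tree, self.model
        tips = tree.tip_labels
        row_of = {label: i for i, label in enumerate(tips)}
        nP = self.counts.shape[0]

        down: dict[int, np.ndarray] = {}
        dscale: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                down[id(node)] = _tip_partials(self.patterns[row_of[node.label]])
                dscale[id(node)] = np.zeros(nP)
            else:
                prod = np.ones((nP, 4))
                sc = np.zeros(nP)
                for child in node.children:
                    P = model.transition_matrix(child.length)
                    prod *= down[id(child)] @ P.T
                    sc += dscale[id(child)]
                m = np.maximum(prod.max(axis=1), 1e-300)
                down[id(node)] = prod / m[:, None]
                dscale[id(node)] = sc + np.log(m)

        pi = np.asarray(model.freqs)
        up: dict[int, np.ndarray] = {}
        uscale: dict[int, np.ndarray] = {}
        for node in tree.preorder():
            if node is tree.root:
                continue
            parent = node.parent
            if parent is tree.root:
                base = np.tile(pi, (nP, 1))
                bscale = np.zeros(nP)
            else:
                P = model.transition_matrix(parent.length)
                base = up[id(parent)] @ P
                bscale = uscale[id(parent)].copy()
            for sib in parent.children:
                if sib is node:
                    continue
                P = model.transition_matrix(sib.length)
                base = base * (down[id(sib)] @ P.T)
                bscale = bscale + dscale[id(sib)]
            m = np.maximum(base.max(axis=1), 1e-300)
            up[id(node)] = base / m[:, None]
            uscale[id(node)] = bscale + np.log(m)

        # per-edge midpoint context: A (outside) * B (below), both evolved to
        # the midpoint, contracted against the model's spectral basis
        eigval, left, right = model._spectral
        self._eigval = eigval
        q_tip = _tip_partials(self.patterns[-1])
        qk = q_tip @ right.T  # (nP, 4)

        E = len(self.edge_nodes)
        G = np.empty((E, nP, 4))
        CS = np.empty((E, nP))
        for e, node in enumerate(self.edge_nodes):
            half = model.transition_matrix(node.length / 2.0)
            A = up[id(node)] @ half
            B = down[id(node)] @ half.T
            ctx = A * B
            m = np.maximum(ctx.max(axis=1), 1e-300)
            ctx = ctx / m[:, None]
            CS[e] = uscale[id(node)] + dscale[id(node)] + np.log(m)
            G[e] = (ctx @ left) * qk
        self._G = G
        self._CS = CS

    # ........................................................... evaluation
    def place(
        self,
        loci: Sequence[str] | None = None,
        pendant_bounds: tuple[float, float] = PENDANT_BOUNDS,
    ) -> PlacementResult:
        loci = list(loci) if loci is not None else list(self.loci)
        unknown = set(loci) - set(self.loci)
        if unknown:
            raise AnalysisError(f"loci not in workspace: {sorted(unknown)}")
        sel = [self.loci.index(l) for l in loci]
        mask = np.isin(self.pattern_locus, sel)
        G = np.ascontiguousarray(self._G[:, mask, :])
        CS = np.ascontiguousarray(self._CS[:, mask])
        counts = self.counts[mask]
        eigval = self._eigval
        E = len(self.edge_nodes)
        lo, hi = pendant_bounds

        def _loglik(lam: np.ndarray) -> np.ndarray:
            ex = np.exp(np.outer(lam, eigval))  # (E, 4)
            vals = np.einsum("epk,ek->ep", G, ex)
            logs = np.log(np.maximum(vals, 1e-300)) + CS
            return logs @ counts

        gr = (math.sqrt(5.0) - 1.0) / 2.0
        a = np.full(E, lo)
        b = np.full(E, hi)
        c = b - gr * (b - a)
        d = a + gr * (b - a)
        fc = _loglik(c)
        fd = _loglik(d)
        n_iter = int(math.ceil(math.log((hi - lo) / _GOLDEN_TOL) / -math.log(gr)))
        for _ in range(n_iter):
            go_right = fc < fd  # maximum in [c, b]
            a = np.where(go_right, c, a)
            b = np.where(go_right, b, d)
            c_new = np.where(go_right, d, b - gr * (b - a))
            d_new = np.where(go_right, a + gr * (b - a), c)
            f_keep = np.where(go_right, fd, fc)
            x_eval = np.where(go_right, d_new, c_new)
            f_eval = _loglik(x_eval)
            c, d = c_new, d_new
            fc = np.where(go_right, f_keep, f_eval)
            fd = np.where(go_right, f_eval, f_keep)
        lam = 0.5 * (a + b)
        lnl = _loglik(lam)

        shift = lnl - lnl.max()
        w = np.exp(shift)
        lwr = w / w.sum()
        depth = np.array([self._edge_depth(n) for n in self.edge_nodes])
        order = sorted(
            range(E), key=lambda e: (-round(lnl[e] / 1e-9), depth[e], e)
        )
        best = order[0]
        tipsets = self._edge_tipsets()
        edges = tuple(
            EdgePlacement(
                edge_id=e,
                loglik=float(lnl[e]),
                pendant_length=float(lam[e]),
                lwr=float(lwr[e]),
            )
            for e in range(E)
        )
        n_sites = sum(self.site_totals[l] for l in loci)
        return PlacementResult(
            query_id=self.query_id,
            loci_used=tuple(loci),
            edges=edges,
            best_edge=best,
            n_sites=n_sites,
            edge_tipsets=tipsets,
        )

    def _edge_depth(self, node) -> int:
        depth = 0
        while node.parent is not None:
            node = node.parent
            depth += 1
        return depth

    def _edge_tipsets(self) -> tuple[frozenset, ...]:
        below = self.tree.tipset_below()
        return tuple(below[n] for n in self.edge_nodes)


def place_query(
    ref_tree: Tree,
    ref_aln: MultiLocusAlignment,
    query_id: str,
    query_seqs: Mapping[str, str],
    model: SubstitutionModel | None = None,
    pendant_bounds: tuple[float, float] = PENDANT_BOUNDS,
) -> PlacementResult:
    """Exhaustive per-edge ML placement of one query.

    ``query_seqs`` maps locus name -> aligned sequence (same coordinates as
    the reference locus alignments); loci absent from the query are excluded
    from the comparison for all taxa.
    """
    model = model or SubstitutionModel.jc69()
    ws = _PlacementWorkspace(ref_tree, ref_aln, query_id, query_seqs, model)
    return ws.place(pendant_bounds=pendant_bounds)


def place_query_subsets(
    ref_tree: Tree,
    ref_aln: MultiLocusAlignment,
    query_id: str,
    query_seqs: Mapping[str, str],
    subsets: Sequence[Sequence[str]],
    model: SubstitutionModel | None = None,
) -> list[PlacementResult]:
    """Place the same query under several locus subsets, sharing partials."""
    model = model or SubstitutionModel.jc69()
    ws = _PlacementWorkspace(ref_tree, ref_aln, query_id, query_seqs, model)
    return [ws.place(loci=subset) for subset in subsets]


# --------------------------------------------------------- loci sensitivity
def loci_sensitivity(
    ref_tree: Tree,
    ref_aln: MultiLocusAlignment,
    loci_counts: Sequence[int] | None = None,
    reps_per_count: int = 100,
    model: SubstitutionModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-out placement confidence as a function of locus count.

    Each replicate removes one reference tip and re-places it from a
    uniformly drawn subset of k of its loci. Confidence is the LWR mass on
    the edges corresponding to the original attachment (the merged edge
    created by pruning plus that node's child edges). Returns one row per k:
    (k, mean_confidence, frac_correct, n_reps).
    """
    model = model or SubstitutionModel.jc69()
    loci_counts = (
        sorted(loci_counts) if loci_counts is not None
        else list(range(1, len(ref_aln.loci) + 1))
    )
    if max(loci_counts) > len(ref_aln.loci):
        raise AnalysisError(
            f"requested {max(loci_counts)} loci but alignment has {len(ref_aln.loci)}"
        )
    if ref_tree.n_tips < 10:
        raise AnalysisError("reference needs at least 10 tips")
    rng = np.random.default_rng(seed)
    tips = sorted(ref_tree.tip_labels)

    conf: dict[int, list[float]] = {k: [] for k in loci_counts}
    correct: dict[int, list[bool]] = {k: [] for k in loci_counts}
    for _ in range(reps_per_count):
        # a tip with enough loci for the largest k (retry-bounded)
        for _attempt in range(50):
            tip = tips[int(rng.integers(len(tips)))]
            available = ref_aln.loci_of(tip)
            if len(available) >= max(loci_counts):
                break
        else:
            raise AnalysisError("no tip has enough loci for the requested counts")
        pruned, info = ref_tree.prune_tip(tip)
        query_seqs = {l: ref_aln.data[l][tip] for l in available}
        subsets = [
            [available[i] for i in rng.choice(len(available), size=k, replace=False)]
            for k in loci_counts
        ]
        ws = _PlacementWorkspace(
            pruned, ref_aln.subset_samples(pruned.tip_labels), tip, query_seqs, model
        )
        correct_sets = set(info["child_tipsets"])
        if info["sibling_tipset"] is not None:
            correct_sets.add(info["sibling_tipset"])
        for k, subset in zip(loci_counts, subsets):
            res = ws.place(loci=subset)
            mass = sum(
                e.lwr
                for e in res.edges
                if res.edge_tipsets[e.edge_id] in correct_sets
            )
            conf[k].append(mass)
            correct[k].append(res.edge_tipsets[res.best_edge] in correct_sets)
    rows = [
        {
            "n_loci": k,
            "mean_confidence": float(np.mean(conf[k])),
            "frac_correct": float(np.mean(correct[k])),
            "n_reps": len(conf[k]),
        }
        for k in loci_counts
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- assignment
@dataclass(frozen=True)
class AssignmentReport:
    query_id: str
    label: str | None  # None = unassigned
    relation: str  # "nested" | "sister" | "none"
    clade_lwr: float  # LWR mass inside the assigned clade (incl. its root edge)
    best_lwr: float
    truth: str | None = None
    outcome: str | None = None  # TP/FP/FN/TN when truth known

    def __post_init__(self):
        if (self.relation == "none") != (self.label is None):
            raise AnalysisError("relation 'none' iff unassigned")


def assign_origin(
    ref_tree: Tree,
    placement: PlacementResult,
    lwr_floor: float = 0.5,
    truth: str | None = None,
) -> AssignmentReport:
    """Monophyly/sister origin-assignment rule.

    A query is assigned label L if its best edge is strictly inside a clade
    labelled L (nested) or is that clade's root edge (sister). Placements
    whose best-edge LWR falls below ``lwr_floor`` are unassigned. With a
    known truth label the outcome class is reported: assignment to the wrong
    label is a false positive (the usage for "misplaced within Himalayan
    clusters"); an unassigned query whose truth is an assignable label is a
    false negative.
    """
    tree = ref_tree.copy()
    tree.index_edges()
    below = tree.tipset_below()
    labelled = [
        (node.clade_label, below[node])
        for node in tree.preorder()
        if node.clade_label and not node.is_leaf
    ]
    if not labelled:
        raise AnalysisError("reference tree has no labelled clades")
    all_labels = {lab for lab, _ in labelled}

    best_ts = placement.edge_tipsets[placement.best_edge]
    best_lwr = placement.best_lwr

    label: str | None = None
    relation = "none"
    clade_ts: frozenset | None = None
    if best_lwr >= lwr_floor:
        hits = []
        for lab, ts in labelled:
            if best_ts == ts:
                hits.append((lab, "sister", ts))
            elif best_ts < ts:
                hits.append((lab, "nested", ts))
        labels_hit = {lab for lab, _, _ in hits}
        if len(labels_hit) > 1:
            raise AnalysisError(
                f"best edge lies in clades with conflicting labels: {sorted(labels_hit)}"
            )
        if hits:
            # innermost containing clade determines the relation
            hits.sort(key=lambda h: len(h[2]))
            label, relation, clade_ts = hits[0]

    clade_lwr = 0.0
    if clade_ts is not None:
        clade_lwr = sum(
            e.lwr
            for e in placement.edges
            if placement.edge_tipsets[e.edge_id] <= clade_ts
        )

    outcome = None
    if truth is not None:
        if label is not None:
            outcome = "TP" if label == truth else "FP"
        else:
            outcome = "FN" if truth in all_labels else "TN"
    return AssignmentReport(
        query_id=placement.query_id,
        label=label,
        relation=relation,
        clade_lwr=clade_lwr,
        best_lwr=best_lwr,
        truth=truth,
        outcome=outcome,
    )


# -------------------------------------------------------------------- jplace
def placement_to_jplace(
    ref_tree: Tree, placements: Sequence[PlacementResult], top_n: int = 7
) -> dict:
    """jplace-compatible dict (edge-numbered tree + per-query placements)."""
    tree = ref_tree.copy()
    edge_nodes = tree.index_edges()

    def _write(node) -> str:
        if node.is_leaf:
            s = node.label
        else:
            s = "(" + ",".join(_write(c) for c in node.children) + ")"
            if node.clade_label:
                s += node.clade_label
        if node.parent is not None:
            s += f":{node.length:.10g}{{{node.edge_id}}}"
        return s

    tree_str = _write(tree.root) + ";"
    out_placements = []
    for res in placements:
        ranked = sorted(res.edges, key=lambda e: -e.lwr)[:top_n]
        out_placements.append(
            {
                "p": [
                    [e.edge_id, e.loglik, e.lwr, e.pendant_length]
                    for e in ranked
                ],
                "n": [res.query_id],
            }
        )
    return {
        "version": 3,
        "tree": tree_str,
        "placements": out_placements,
        "fields": ["edge_num", "likelihood", "like_weight_ratio", "pendant_length"],
        "metadata": {"software": "yartsa"},
    }
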