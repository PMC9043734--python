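"""Rooted phylogenies: the in-memory tree type and Newick round-tripping.

The tree is the substrate for everything downstream — patristic distances,
likelihood placement, time slices and range models — so it is kept as a
plain parent-pointer node structure rather than a wrapper around a heavier
library object.  Newick *parsing* is delegated to dendropy; serialization is
done here because outputs are canonicalized (children sorted by their
smallest descendant tip label) so that identical trees always produce
identical strings.

Branch lengths are substitutions/site for molecular trees and arbitrary
time units for ultrametric (simulated or dated) trees.  Internal-node labels
carry clade tags (e.g. region names) used by the origin-assignment rule.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator

import dendropy

from .errors import NewickParseError, ValidationError

__all__ = ["TreeNode", "Tree", "parse_newick", "write_newick", "reroot_at_edge"]

_ULTRAMETRIC_RTOL = 1e-6


class TreeNode:
    """A node in a rooted tree. ``length`` is the branch above the node."""

    __slots__ = ("label", "length", "children", "parent", "clade_label", "edge_id")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.clade_label: str | None = None
        self.edge_id: int | None = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} len={self.length:g}>"


class Tree:
    """Rooted phylogeny with unique tip labels and non-negative branch lengths."""

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self.validate()

    # ---------------------------------------------------------------- basics
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.postorder())

    def find_tip(self, label: str) -> TreeNode:
        for t in self.tips():
            if t.label == label:
                return t
        raise ValidationError(f"tip {label!r} not found in tree")

    def scaled(self, factor: float) -> "Tree":
        """Copy with all branch lengths multiplied by ``factor`` (e.g. to
        convert a time tree to expected substitutions/site)."""
        if factor < 0:
            raise ValidationError("scale factor must be >= 0")
        tree = self.copy()
        for node in tree.postorder():
            node.length *= factor
        tree.root.length = 0.0
        return tree

    def copy(self) -> "Tree":
        def _clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            new.clade_label = node.clade_label
            new.edge_id = node.edge_id
            for child in node.children:
                new.add_child(_clone(child))
            return new

        return Tree(_clone(self.root), rooted=self.rooted)

    # ------------------------------------------------------------- invariants
    def validate(self) -> None:
        labels = []
        for node in self.postorder():
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length {node.length} above node {node.label!r}"
                )
            if node.is_leaf:
                if not node.label:
                    raise ValidationError("unlabelled tip")
                labels.append(node.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate tip labels: {sorted(dupes)}")

    # -------------------------------------------------------------- geometry
    def depths(self) -> dict[TreeNode, float]:
        """Root-to-node path length for every node."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                out[node] = out[node.parent] + node.length
        return out

    @property
    def root_height(self) -> float:
        depths = self.depths()
        return max(depths[t] for t in self.tips())

    def is_ultrametric(self, rtol: float = _ULTRAMETRIC_RTOL) -> bool:
        depths = self.depths()
        heights = [depths[t] for t in self.tips()]
        hi = max(heights)
        if hi == 0:
            return True
        return (hi - min(heights)) <= rtol * hi

    def node_ages(self) -> dict[TreeNode, float]:
        """Time before present for every node of an ultrametric tree."""
        depths = self.depths()
        height = max(depths[t] for t in self.tips())
        return {n: max(height - d, 0.0) for n, d in depths.items()}

    def mrca(self, labels: list[str]) -> TreeNode:
        want = set(labels)
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.label}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
            if want <= below[node]:
                return node
        raise ValidationError(f"labels {sorted(want)} not all present in tree")

    def tipset_below(self) -> dict[TreeNode, frozenset]:
        out: dict[TreeNode, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                out[node] = frozenset().union(*(out[c] for c in node.children))
        return out

    # ------------------------------------------------------------------ edges
    def canonical_sort(self) -> None:
        """Order children lexicographically by smallest descendant tip label."""
        min_tip: dict[TreeNode, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                min_tip[node] = node.label
            else:
                node.children.sort(key=lambda c: min_tip[c])
                min_tip[node] = min_tip[node.children[0]]

    def index_edges(self) -> list[TreeNode]:
        """Assign stable integer edge ids (preorder over the canonical tree).

        The edge of a node is the branch connecting it to its parent; the
        root has no edge.  Returns the nodes in edge-id order.
        """
        self.canonical_sort()
        ordered = [n for n in self.preorder() if n is not self.root]
        for i, node in enumerate(ordered):
            node.edge_id = i
        self.root.edge_id = None
        return ordered

    # ----------------------------------------------------------- manipulation
    def prune_tip(self, label: str) -> tuple["Tree", dict]:
        """Remove a tip, suppressing the resulting unary node.

        Returns the pruned tree plus a record of where the tip was attached:
        ``sibling_tipset`` is the descendant tip set of the merged edge in
        the pruned tree (the edge onto which a correct re-placement falls)
        and ``child_tipsets`` are the tip sets of that node's children.
        """
        tree = self.copy()
        tip = tree.find_tip(label)
        parent = tip.parent
        if parent is None:
            raise ValidationError("cannot prune the only node of a tree")
        parent.children.remove(tip)
        if len(parent.children) == 1:
            sibling = parent.children[0]
            grand = parent.parent
            if grand is None:
                # parent was the root: the sibling becomes the new root
                sibling.parent = None
                sibling_length = sibling.length
                sibling.length = 0.0
                new_tree = Tree(sibling, rooted=tree.rooted)
                info = {
                    "sibling_tipset": None,  # attachment was at the root
                    "child_tipsets": [
                        frozenset(_tips_below(c)) for c in sibling.children
                    ],
                    "root_attachment": True,
                    "removed_sibling_length": sibling_length,
                }
                return new_tree, info
            grand.children[grand.children.index(parent)] = sibling
            sibling.parent = grand
            sibling.length += parent.length
            new_tree = Tree(tree.root, rooted=tree.rooted)
            info = {
                "sibling_tipset": frozenset(_tips_below(sibling)),
                "child_tipsets": [frozenset(_tips_below(c)) for c in sibling.children],
                "root_attachment": False,
            }
            return new_tree, info
        # multifurcating parent: no unary suppression needed
        new_tree = Tree(tree.root, rooted=tree.rooted)
        info = {
            "sibling_tipset": frozenset(_tips_below(parent)),
            "child_tipsets": [frozenset(_tips_below(c)) for c in parent.children],
            "root_attachment": parent.parent is None,
        }
        return new_tree, info

    def graft(
        self,
        edge_tipset: frozenset,
        query_label: str,
        pendant_length: float,
        split_fraction: float = 0.5,
    ) -> "Tree":
        """Attach a new tip on the edge above the node subtending ``edge_tipset``.

        The edge is split at ``split_fraction`` from the child end; used by the
        graft-and-score placement oracle and by tests.
        """
        tree = self.copy()
        below = tree.tipset_below()
        target = None
        for node, ts in below.items():
            if node is not tree.root and ts == edge_tipset:
                target = node
                break
        if target is None:
            raise ValidationError(f"no edge subtends tip set {sorted(edge_tipset)}")
        parent = target.parent
        t = target.length
        mid = TreeNode(None, t * (1.0 - split_fraction))
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        target.length = t * split_fraction
        mid.add_child(target)
        mid.add_child(TreeNode(query_label, pendant_length))
        return Tree(tree.root, rooted=tree.rooted)


def _tips_below(node: TreeNode) -> list[str]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        else:
            stack.extend(n.children)
    return out


# ----------------------------------------------------------------- newick io
def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Internal node labels become clade labels.  Raises
    :class:`NewickParseError` on unbalanced parentheses, duplicate tip
    labels or negative branch lengths, naming the offending token.
    """
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    def _convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if label is None:
                raise NewickParseError("unlabelled tip in Newick input")
            node = TreeNode(str(label))
        else:
            node = TreeNode(None)
            node.clade_label = str(dnode.label) if dnode.label else None
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                raise NewickParseError(
                    f"missing branch length above {node.label or node.clade_label or 'internal node'}"
                )
            length = 0.0
        if length < 0:
            raise NewickParseError(
                f"negative branch length {length} above "
                f"{node.label or node.clade_label or 'internal node'}"
            )
        node.length = float(length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dtree.seed_node)
    try:
        return Tree(root)
    except ValidationError as exc:
        raise NewickParseError(str(exc)) from exc


def _fmt_length(x: float) -> str:
    return format(float(x), ".10g")


def write_newick(tree: Tree) -> str:
    """Serialize canonically: children sorted by smallest descendant tip label."""
    tree = tree.copy()
    tree.canonical_sort()

    buf = io.StringIO()

    def _write(node: TreeNode) -> None:
        if node.is_leaf:
            buf.write(node.label)
        else:
            buf.write("(")
            for i, child in enumerate(node.children):
                if i:
                    buf.write(",")
                _write(child)
            buf.write(")")
            if node.clade_label:
                buf.write(node.clade_label)
        if node.parent is not None:
            buf.write(":" + _fmt_length(node.length))

    _write(tree.root)
    buf.write(";")
    return buf.getvalue()


def apply_clade_labels(tree: Tree, labels: dict | str) -> Tree:
    """Attach clade labels from a sidecar table to a tree whose Newick
    carries none.

    ``labels`` is either a mapping {label: iterable of tip labels} — the
    label is applied at the MRCA of the tips — or the path of a CSV with
    columns ``label`` and ``tips`` (semicolon-separated tip labels).
    """
    if not isinstance(labels, dict):
        import csv

        parsed: dict[str, list[str]] = {}
        with open(labels) as fh:
            for row in csv.DictReader(fh):
                parsed[row["label"]] = row["tips"].split(";")
        labels = parsed
    tree = tree.copy()
    for label, tips in labels.items():
        node = tree.mrca(list(tips))
        if node.is_leaf:
            raise ValidationError(
                f"clade label {label!r} resolves to a single tip"
            )
        node.clade_label = label
    return tree


def reroot_at_edge(tree: Tree, tipset: frozenset, fraction: float = 0.5) -> Tree:
    """Re-root on the edge above the node subtending ``tipset``.

    ``fraction`` of the edge stays on the subtended side.  Used to check
    re-rooting invariance of reversible-model likelihoods.
    """
    tree = tree.copy()
    below = tree.tipset_below()
    target = None
    for node, ts in below.items():
        if node is not tree.root and ts == tipset:
            target = node
            break
    if target is None:
        raise ValidationError(f"no edge subtends tip set {sorted(tipset)}")
    if target.parent is tree.root and len(tree.root.children) == 2:
        # already rooted on this edge (up to the split position)
        sibling = [c for c in tree.root.children if c is not target][0]
        total = target.length + sibling.length
        target.length = total * fraction
        sibling.length = total * (1 - fraction)
        return Tree(tree.root, rooted=tree.rooted)

    old_parent = target.parent
    t = target.length
    new_root = TreeNode(None)
    target.parent = None
    target.length = t * fraction
    new_root.add_child(target)

    # walk up the old parent chain, flipping parent->child direction
    def _flip(node: TreeNode, coming_from: TreeNode, carry_length: float) -> TreeNode:
        """Re-hang ``node`` as a child below ``coming_from``'s new position."""
        flipped = TreeNode(None, carry_length)
        flipped.clade_label = node.clade_label
        for child in node.children:
            if child is not coming_from:
                flipped.add_child(child)
                child.parent = flipped
        if node.parent is not None:
            _attach_flipped_parent(flipped, node)
        return flipped

    def _attach_flipped_parent(flipped: TreeNode, node: TreeNode) -> None:
        up = _flip(node.parent, node, node.length)
        flipped.add_child(up)

    up_side = _flip(old_parent, target, t * (1 - fraction))
    new_root.add_child(up_side)
    _suppress_unary(new_root)
    return Tree(new_root, rooted=tree.rooted)


def _suppress_unary(root: TreeNode) -> None:
    """Merge unary internal nodes (child absorbs the parent's branch)."""
    stack = [root]
    while stack:
        node = stack.pop()
        changed = True
        while changed:
            changed = False
            for i, child in enumerate(node.children):
                if not child.is_leaf and len(child.children) == 1:
                    grand = child.children[0]
                    grand.length += child.length
                    grand.parent = node
                    node.children[i] = grand
                    changed = True
        stack.extend(node.children)
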