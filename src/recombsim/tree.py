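"""Phylogeny handling: Newick parsing, branch rescaling and the decomposition
of a rooted tree into *time segments* of co-existing branches.

A time segment is a depth interval of the tree in which the set of living
branches is constant.  Homologous recombination is confined to branches that
share a segment (lineages that overlap in time); each branch contributes an
overlap length ``l`` to every segment its depth interval crosses, and the
Poisson event budgets of the simulation engine are proportional to ``l``.

Segment boundaries are placed at every distinct node depth: this is the
minimal cut rule that yields constant membership within each segment.
Non-ultrametric trees are legal — a leaf shallower than the deepest leaf
simply stops appearing in later segments (the lineage is frozen).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "TreeNode",
    "TimeSegment",
    "NewickError",
    "parse_newick",
    "to_newick",
    "rescale",
    "time_segments",
]

# depths closer than this are considered the same segment boundary
_DEPTH_TOL = 1e-12


class NewickError(ValueError):
    """Raised for malformed Newick input or invalid tree structure."""


@dataclass(eq=False)
class TreeNode:
    """A node of a rooted phylogeny.

    ``branch_length`` is the length of the edge above this node, in expected
    substitutions per site; it is ``None`` only for the root.  ``depth`` is
    the root-to-node distance along branch lengths.  ``label`` is the leaf
    name for leaves and an auto-assigned identifier for internal nodes, so
    every edge of the tree can be referred to by its child node's label.
    """

    name: str | None
    branch_length: float | None
    children: list["TreeNode"] = field(default_factory=list)
    depth: float = 0.0
    label: str = ""

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Yield nodes in preorder (root first)."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf()]

    def max_depth(self) -> float:
        return max(n.depth for n in self.walk())


@dataclass
class TimeSegment:
    """A maximal depth interval [start_depth, end_depth) with constant branch
    membership.  ``members`` pairs each living branch (identified by its child
    node) with its overlap length inside the segment."""

    start_depth: float
    end_depth: float
    members: list[tuple[TreeNode, float]]

    @property
    def width(self) -> float:
        return self.end_depth - self.start_depth


def _finalize(root: TreeNode) -> TreeNode:
    """Assign depths, unique labels; validate leaf names."""
    counter = 0
    seen: set[str] = set()
    # iterative preorder with parent depth
    stack: list[tuple[TreeNode, float]] = [(root, 0.0)]
    root.depth = 0.0
    while stack:
        node, pdepth = stack.pop()
        if node is root:
            node.depth = 0.0
        else:
            node.depth = pdepth + node.branch_length
        if node.is_leaf():
            if not node.name:
                raise NewickError("leaf with empty name")
            if node.name in seen:
                raise NewickError(f"duplicate leaf name: {node.name!r}")
            seen.add(node.name)
            node.label = node.name
        else:
            node.label = node.name or f"node{counter}"
            counter += 1
        for child in node.children:
            stack.append((child, node.depth))
    return root


def parse_newick(text: str) -> TreeNode:
    """Parse a rooted Newick string with branch lengths into a :class:`TreeNode`.

    Every non-root edge must carry an explicit branch length; missing lengths,
    duplicate leaf names and syntax errors raise :class:`NewickError` (syntax
    errors carry dendropy's line/column diagnostics).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = str(dnode.label)
        node = TreeNode(name=name, branch_length=None)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            if dchild.edge.length is None:
                who = child.name or "internal node"
                raise NewickError(
                    f"missing branch length on edge above {who!r}"
                )
            if dchild.edge.length < 0:
                raise NewickError(
                    f"negative branch length on edge above {child.name!r}"
                )
            child.branch_length = float(dchild.edge.length)
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    return _finalize(root)


def to_newick(root: TreeNode) -> str:
    """Serialize back to Newick (labels + branch lengths)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            core = node.name or ""
        else:
            core = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.branch_length is not None:
            return f"{core}:{node.branch_length!r}"
        return core

    return fmt(root) + ";"


def _copy(node: TreeNode) -> TreeNode:
    new = TreeNode(name=node.name, branch_length=node.branch_length,
                   depth=node.depth, label=node.label)
    new.children = [_copy(c) for c in node.children]
    return new


def rescale(tree: TreeNode, coefficient: float) -> TreeNode:
    """Return a copy with all branch lengths multiplied by ``coefficient``.

    A coefficient of 0.5 halves every branch (and therefore the expected
    number of events); topology is unchanged and depths are recomputed.
    """
    if not coefficient > 0:
        raise ValueError(f"rescaling coefficient must be > 0, got {coefficient}")
    new = _copy(tree)
    for node in new.walk():
        if node.branch_length is not None:
            node.branch_length *= coefficient
    return _finalize(new)


def time_segments(tree: TreeNode) -> list[TimeSegment]:
    """Cut the tree into maximal constant-membership depth intervals.

    Boundaries are the sorted unique node depths (0 through the maximum
    depth).  Each branch appears in every segment its interval
    ``[parent.depth, node.depth)`` overlaps, with ``l`` equal to the overlap
    length; zero-overlap branches are excluded.  The per-branch overlaps sum
    to the full branch length.
    """
    nodes = list(tree.walk())
    if len(nodes) < 2:
        raise ValueError("single-node tree: nothing to simulate")

    depths = sorted(n.depth for n in nodes)
    boundaries: list[float] = []
    for d in depths:
        if not boundaries or d - boundaries[-1] > _DEPTH_TOL * max(1.0, d):
            boundaries.append(d)
    if len(boundaries) < 2:
        # all branches have zero length: the empty tiling of [0, 0]
        return []

    # edges as (parent_depth, child_node)
    edges: list[tuple[float, TreeNode]] = []
    stack = [tree]
    while stack:
        node = stack.pop()
        for child in node.children:
            edges.append((node.depth, child))
            stack.append(child)

    segments: list[TimeSegment] = []
    for start, end in zip(boundaries[:-1], boundaries[1:]):
        members: list[tuple[TreeNode, float]] = []
        for pdepth, child in edges:
            overlap = min(child.depth, end) - max(pdepth, start)
            if overlap > _DEPTH_TOL:
                members.append((child, overlap))
        segments.append(TimeSegment(start, end, members))
    return segments
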