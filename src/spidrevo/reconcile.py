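"""Gene-tree/species-tree reconciliation and duplication–loss rooting.

A gene family without an outgroup (spidroins have no non-spider homolog) can
be rooted by parsimony on gene duplications and losses: every edge of the
unrooted gene tree is tried as the root, the tree is reconciled with the
species tree by LCA mapping, and the rooting minimizing duplications plus
losses is preferred.  Ties are reported, never broken silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import LeafMapping, PhyloTree, TreeError, TreeNode, validate_mapping


@dataclass(frozen=True)
class EventCounts:
    duplications: int
    losses: int

    def __post_init__(self) -> None:
        if self.duplications < 0 or self.losses < 0:
            raise ValueError("event counts must be non-negative")

    @property
    def total(self) -> int:
        return self.duplications + self.losses


@dataclass(frozen=True)
class RootingEntry:
    edge_index: int
    counts: EventCounts
    tree: PhyloTree


@dataclass
class RootingReport:
    """All candidate rootings of an unrooted gene tree, ranked by event cost."""

    entries: list[RootingEntry] = field(default_factory=list)

    @property
    def ranked(self) -> list[RootingEntry]:
        return sorted(
            self.entries, key=lambda e: (e.counts.total, e.counts.duplications)
        )

    @property
    def optimal(self) -> list[RootingEntry]:
        """All entries attaining the minimum total cost, in edge-index order."""
        best = min(e.counts.total for e in self.entries)
        return [e for e in self.entries if e.counts.total == best]

    @property
    def best(self) -> RootingEntry:
        return self.ranked[0]


def _require_rooted_binary(tree: PhyloTree, name: str) -> None:
    if not tree.rooted:
        raise TreeError(f"{name} must be rooted")
    for n in tree.postorder():
        if n.children and len(n.children) != 2:
            raise TreeError(f"{name} has a polytomy at {n.label!r}; resolve it first")


def lca_mapping(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: LeafMapping
) -> dict[int, TreeNode]:
    """Standard LCA map of gene-tree nodes onto species-tree nodes.

    Leaves map through ``mapping``; an internal gene node maps to the LCA of
    its children's images.  Returns ``id(gene node) → species node``.
    """
    _require_rooted_binary(gene_tree, "gene tree")
    _require_rooted_binary(species_tree, "species tree")
    validate_mapping(mapping, gene_tree, species_tree)

    species_by_label = {n.label: n for n in species_tree.leaves()}
    parent = species_tree.parent_map()
    depth: dict[int, int] = {}
    for n in species_tree.preorder():
        p = parent[id(n)]
        depth[id(n)] = 0 if p is None else depth[id(p)] + 1

    def lca(a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = parent[id(a)]
            else:
                b = parent[id(b)]
        return a

    M: dict[int, TreeNode] = {}
    for g in gene_tree.postorder():
        if g.is_leaf():
            M[id(g)] = species_by_label[mapping[g.label]]
        else:
            c1, c2 = g.children
            M[id(g)] = lca(M[id(c1)], M[id(c2)])
    return M


def count_events(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: LeafMapping
) -> tuple[EventCounts, dict[int, bool]]:
    """Duplication and loss counts for a rooted gene tree.

    A gene node is a duplication iff its species image equals a child's
    image.  Losses accumulate along species-tree edges skipped by the
    mapping: for each child ``c`` of ``g`` the term is
    ``d(M(g), M(c)) − 1 + [g is duplication]`` where ``d`` is the number of
    species-tree edges from ``M(g)`` down to ``M(c)``.

    Returns the totals and a per-node annotation ``id(gene node) → is_dup``.
    """
    M = lca_mapping(gene_tree, species_tree, mapping)
    parent = species_tree.parent_map()
    depth: dict[int, int] = {}
    for n in species_tree.preorder():
        p = parent[id(n)]
        depth[id(n)] = 0 if p is None else depth[id(p)] + 1

    dups = losses = 0
    is_dup: dict[int, bool] = {}
    for g in gene_tree.postorder():
        if g.is_leaf():
            continue
        c1, c2 = g.children
        dup = M[id(g)] is M[id(c1)] or M[id(g)] is M[id(c2)]
        is_dup[id(g)] = dup
        dups += dup
        for c in (c1, c2):
            d = depth[id(M[id(c)])] - depth[id(M[id(g)])]
            losses += d - 1 + (1 if dup else 0)
    return EventCounts(dups, losses), is_dup


# ---------------------------------------------------------------------------
# Rooting

def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a rooted binary tree to its unrooted (basal trifurcation) form."""
    if not tree.rooted:
        return tree.copy()
    root = tree.root.copy()
    if len(root.children) != 2:
        raise TreeError("can only unroot a bifurcating root")
    a, b = root.children
    if a.is_leaf() and b.is_leaf():
        raise TreeError("cannot unroot a 2-leaf tree")
    keep, other = (a, b) if not a.is_leaf() else (b, a)
    if keep.length is not None and other.length is not None:
        other = TreeNode(other.label, keep.length + other.length, other.children)
    new_root = TreeNode(label=None, length=None, children=list(keep.children) + [other])
    return PhyloTree(new_root, rooted=False)


def _edges(tree: PhyloTree) -> list[tuple[TreeNode, TreeNode]]:
    """(parent, child) edges in stable preorder."""
    out = []
    for n in tree.preorder():
        for c in n.children:
            out.append((n, c))
    return out


def _oriented(node: TreeNode, came_from: TreeNode | None, adj, elen) -> TreeNode:
    children = [
        _oriented(nb, node, adj, elen) for nb in adj[id(node)] if nb is not came_from
    ]
    length = None if came_from is None else elen[frozenset((id(node), id(came_from)))]
    return TreeNode(label=node.label, length=length, children=children)


def root_on_edge(tree: PhyloTree, edge_index: int) -> PhyloTree:
    """Root an unrooted tree at the midpoint of the given edge."""
    if tree.rooted:
        raise TreeError("input must be unrooted; call unroot() first")
    edges = _edges(tree)
    parent, child = edges[edge_index]
    adj: dict[int, list[TreeNode]] = {}
    elen: dict[frozenset, float | None] = {}
    for p, c in edges:
        adj.setdefault(id(p), []).append(c)
        adj.setdefault(id(c), []).append(p)
        elen[frozenset((id(p), id(c)))] = c.length
    half = None if child.length is None else child.length / 2.0
    left = _oriented(child, parent, adj, elen)
    right = _oriented(parent, child, adj, elen)
    left = TreeNode(left.label, half, left.children)
    right = TreeNode(right.label, half, right.children)
    return PhyloTree(TreeNode(children=[left, right]), rooted=True)


def enumerate_rootings(tree: PhyloTree) -> list[PhyloTree]:
    """All rooted trees obtainable by placing the root on each edge (2n−3)."""
    if tree.rooted:
        raise TreeError("input must be unrooted; call unroot() first")
    return [root_on_edge(tree, i) for i in range(len(_edges(tree)))]


def root_by_duploss(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: LeafMapping
) -> RootingReport:
    """Exhaustive duplication–loss rooting of an unrooted gene tree.

    Every edge is tried as the root and reconciled against the species tree;
    the report ranks rootings by total events (then duplications) and exposes
    the full optimal (tied) set.
    """
    if gene_tree.rooted:
        gene_tree = unroot(gene_tree)
    report = RootingReport()
    for i, rooted in enumerate(enumerate_rootings(gene_tree)):
        counts, _ = count_events(rooted, species_tree, mapping)
        report.entries.append(RootingEntry(edge_index=i, counts=counts, tree=rooted))
    return report


def report_table(report: RootingReport):
    """Ranked rooting report as a DataFrame (write with ``.to_csv(sep='\\t')``)."""
    import pandas as pd

    ranked = report.ranked
    return pd.DataFrame(
        {
            "edge_index": [e.edge_index for e in ranked],
            "duplications": [e.counts.duplications for e in ranked],
            "losses": [e.counts.losses for e in ranked],
            "total": [e.counts.total for e in ranked],
        }
    )


def annotate_duplications(
    gene_tree: PhyloTree, species_tree: PhyloTree, mapping: LeafMapping
) -> PhyloTree:
    """Return a copy of the gene tree with duplication nodes labeled ``[D]``."""
    tree = gene_tree.copy()
    _, is_dup = count_events(tree, species_tree, mapping)
    for n in tree.postorder():
        if is_dup.get(id(n)):
            n.label = (n.label or "") + "[D]"
    return tree
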