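"""Phylogenetic tree container, Newick I/O, and leaf→species mappings.

The package uses its own lightweight node type so that reconciliation and the
trait models can annotate and rewire trees freely; parsing and serialisation
of Newick go through dendropy.  Rootedness follows the standard convention:
a tree whose root has exactly two children is rooted, three or more children
mark an unrooted tree (basal polytomy).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Malformed tree or mapping input."""


@dataclass
class TreeNode:
    label: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["TreeNode"]:
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf()]

    def copy(self) -> "TreeNode":
        return TreeNode(self.label, self.length, [c.copy() for c in self.children])


@dataclass
class PhyloTree:
    """A rooted or unrooted tree with labeled leaves and optional lengths ≥ 0."""

    root: TreeNode
    rooted: bool = True

    def __post_init__(self) -> None:
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        for n in self.root.postorder():
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length {n.length} at {n.label!r}")
            if n.is_leaf() and not n.label:
                raise TreeError("unlabeled leaf")

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def preorder(self) -> Iterator[TreeNode]:
        return self.root.preorder()

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def is_binary(self) -> bool:
        """All internal nodes have 2 children (root may have 3 if unrooted)."""
        for n in self.postorder():
            if n.is_leaf():
                continue
            want = (2,) if self.rooted or n is not self.root else (3,)
            if len(n.children) not in want:
                return False
        return True

    def parent_map(self) -> dict[int, Optional[TreeNode]]:
        """Map ``id(node)`` → parent node (root → None)."""
        parents: dict[int, Optional[TreeNode]] = {id(self.root): None}
        for n in self.preorder():
            for c in n.children:
                parents[id(c)] = n
        return parents

    def find(self, label: str) -> TreeNode:
        for n in self.postorder():
            if n.label == label:
                return n
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Newick I/O (via dendropy)

def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    node = TreeNode(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def tree_from_newick(text: str) -> PhyloTree:
    """Parse one Newick string into a :class:`PhyloTree`."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"invalid Newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = None  # a root edge length has no meaning here
    rooted = len(root.children) == 2 or root.is_leaf() or len(root.children) == 1
    return PhyloTree(root, rooted=rooted)


def read_newick(path: str | Path) -> PhyloTree:
    return tree_from_newick(Path(path).read_text())


def _to_dendropy(tree: PhyloTree) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(node: TreeNode, dnode: dendropy.Node) -> None:
        dnode.edge.length = node.length
        if node.is_leaf():
            dnode.taxon = taxa.new_taxon(node.label)
        else:
            dnode.label = node.label
            for c in node.children:
                build(c, dnode.new_child())

    build(tree.root, dtree.seed_node)
    dtree.is_rooted = tree.rooted
    return dtree


def write_newick(tree: PhyloTree) -> str:
    """Serialise to a one-line Newick string."""
    return _to_dendropy(tree).as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def write_newick_file(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def bipartitions(tree: PhyloTree) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions, each as its smaller-side label set.

    Rooting-invariant: used to compare topologies across rootings.
    """
    all_leaves = frozenset(tree.leaf_labels())
    parts: set[frozenset[str]] = set()
    for n in tree.postorder():
        if n is tree.root or n.is_leaf():
            continue
        below = frozenset(l.label for l in n.leaves())
        if 1 < len(below) < len(all_leaves) - 1:
            other = all_leaves - below
            parts.add(min(below, other, key=lambda s: (len(s), sorted(s))))
    return parts


# ---------------------------------------------------------------------------
# Leaf → species mapping

LeafMapping = dict  # gene-leaf label -> species-leaf label


def read_leaf_mapping(path: str | Path) -> LeafMapping:
    """Read a 2-column TSV of gene-leaf → species-leaf labels."""
    mapping: LeafMapping = {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t")):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise TreeError(f"mapping line {i + 1}: need 2 tab-separated columns")
            gene, species = row[0].strip(), row[1].strip()
            if gene in mapping:
                raise TreeError(f"duplicate gene label {gene!r} in mapping")
            mapping[gene] = species
    if not mapping:
        raise TreeError(f"empty mapping file {path}")
    return mapping


def write_leaf_mapping(mapping: LeafMapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, species in mapping.items():
            fh.write(f"{gene}\t{species}\n")


def mapping_from_suffix(gene_labels: list[str], sep: str = "_") -> LeafMapping:
    """Fallback mapping rule: strip the trailing ``_<suffix>`` copy tag.

    ``Liphistius_fib1`` → ``Liphistius``; labels without the separator map to
    themselves.
    """
    out: LeafMapping = {}
    for label in gene_labels:
        out[label] = label.rsplit(sep, 1)[0] if sep in label else label
    return out


def validate_mapping(
    mapping: LeafMapping, gene_tree: PhyloTree, species_tree: PhyloTree
) -> None:
    """Check the mapping is total over gene leaves with species-leaf images."""
    gene_leaves = set(gene_tree.leaf_labels())
    species_leaves = set(species_tree.leaf_labels())
    missing = gene_leaves - set(mapping)
    if missing:
        raise TreeError(f"gene leaves without species mapping: {sorted(missing)}")
    bad = {g: s for g, s in mapping.items() if g in gene_leaves and s not in species_leaves}
    if bad:
        raise TreeError(f"mapped to unknown species: {bad}")
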