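"""Independent oracles and random-instance builders for the test suite.

Everything here re-derives quantities by enumeration or explicit walks,
independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from spidrevo.trees import PhyloTree, TreeNode


def random_rooted_binary(labels: list[str], rng: np.random.Generator) -> PhyloTree:
    """Random rooted binary topology by successive random joins."""
    nodes = [TreeNode(label=l, length=1.0) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(TreeNode(length=1.0, children=[a, b]))
    nodes[0].length = None
    return PhyloTree(nodes[0], rooted=True)


# ---------------------------------------------------------------------------
# Reconciliation oracle: explicit embedding walk

def brute_force_events(gene_tree: PhyloTree, species_tree: PhyloTree, mapping: dict):
    """Duplication/loss counts by explicitly embedding the gene tree.

    Maps each gene node to the smallest species clade containing its species
    set (clade scan, no LCA recursion), then walks each gene edge down the
    species-tree parent chain, counting every species node the lineage
    passes through without branching as one loss.
    """
    clades = {
        id(n): frozenset(l.label for l in n.leaves()) for n in species_tree.postorder()
    }
    parent = species_tree.parent_map()
    nodes = list(species_tree.postorder())

    def smallest_clade(species: frozenset) -> TreeNode:
        best = None
        for n in nodes:
            if species <= clades[id(n)]:
                if best is None or len(clades[id(n)]) < len(clades[id(best)]):
                    best = n
        return best

    M = {}
    for g in gene_tree.postorder():
        species = frozenset(mapping[l.label] for l in g.leaves())
        M[id(g)] = smallest_clade(species)

    dups = losses = 0
    for g in gene_tree.postorder():
        if g.is_leaf():
            continue
        is_dup = any(M[id(g)] is M[id(c)] for c in g.children)
        dups += is_dup
        for c in g.children:
            path = []  # parent-chain walk from M(c) up to M(g)
            v = M[id(c)]
            while v is not M[id(g)]:
                path.append(v)
                v = parent[id(v)]
            # species nodes passed through without branching: all strictly
            # between, plus M(g) itself after a duplication; a lineage that
            # never leaves M(g) (empty path) passes through nothing
            if path:
                losses += len(path) - 1 + (1 if is_dup else 0)
    return dups, losses


def random_reconcile_instance(rng: np.random.Generator, max_gene=8, max_species=6):
    n_species = int(rng.integers(2, max_species + 1))
    species = random_rooted_binary([f"s{i}" for i in range(n_species)], rng)
    n_genes = int(rng.integers(2, max_gene + 1))
    mapping = {f"g{i}": f"s{rng.integers(n_species)}" for i in range(n_genes)}
    gene = random_rooted_binary(list(mapping), rng)
    return gene, species, mapping


# ---------------------------------------------------------------------------
# Linear parsimony oracle: grid brute force

def grid_parsimony_cost(tree: PhyloTree, traits: dict) -> float:
    """Minimum Σ|parent−child| over all internal-node assignments on a grid
    of observed values and their midpoints (exact for linear cost)."""
    values = sorted({float(v) for v in traits.values()})
    grid = sorted(
        set(values) | {(a + b) / 2 for a, b in itertools.combinations(values, 2)}
    )
    internal = [n for n in tree.postorder() if not n.is_leaf()]
    parent = tree.parent_map()
    best = np.inf
    for combo in itertools.product(grid, repeat=len(internal)):
        val = {id(n): v for n, v in zip(internal, combo)}
        for leaf in tree.leaves():
            val[id(leaf)] = float(traits[leaf.label])
        cost = sum(
            abs(val[id(n)] - val[id(parent[id(n)])])
            for n in tree.postorder()
            if n is not tree.root
        )
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# Tandem repeat oracle: exhaustive (period, phase) scan for exact arrays

def brute_force_perfect_arrays(seq: str, min_period=2, min_copies=2):
    """All maximal perfect tandem arrays by scanning every (period, phase).

    Only exact copies count, so this is an oracle for noiseless inputs.
    Returns (start, end, period, copies) tuples of maximal arrays.
    """
    n = len(seq)
    found = set()
    for p in range(min_period, n // min_copies + 1):
        for start in range(n - 2 * p + 1):
            copies = 1
            while (
                start + (copies + 1) * p <= n
                and seq[start + copies * p : start + (copies + 1) * p]
                == seq[start : start + p]
            ):
                copies += 1
            if copies >= min_copies:
                # maximality: not extendable left by one period
                if start >= p and seq[start - p : start] == seq[start : start + p]:
                    continue
                found.add((start, start + copies * p, p, copies))
    return found
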