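"""Seeded generators providing ground truth for every analysis stage.

Each generator emulates the statistical structure one pipeline stage assumes:
Yule species trees; gene families evolving inside them by duplication and
loss; coding sequences built from long Ala/Gly/Ser-rich tandem repeat units
with per-copy mutation; tip traits under gradual, star, or punctuated
(speciational) change; and alignments with planted internal deletions.

Every generator draws from its own named RNG stream derived from the run
seed, so identical seeds give bit-identical output and adding a generator
never shifts another's draws.  Results carry their ground truth and can dump
it as a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .indels import BinaryMatrix, IndelCharacter
from .reconcile import EventCounts
from .sequences import GAP, BioSequence, MultipleAlignment
from .trees import LeafMapping, PhyloTree, TreeNode

# named stream ids, one per generator
_STREAMS = {
    "species_tree": 1,
    "gene_tree": 2,
    "repeat_protein": 3,
    "traits": 4,
    "alignment_indels": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# Species trees (Yule)

def sim_species_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth (Yule) species tree: rooted, binary, ultrametric.

    Starts from the root split (two lineages); while ``k`` lineages are
    active the next speciation waits Exp(k·birth_rate).  A final waiting time
    at ``n_tips`` lineages gives the terminal branches positive length.
    Leaves are labeled ``s1..sn`` in tree order.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = _rng(seed, "species_tree")
    root = TreeNode()
    active = [root.add_child(TreeNode(length=0.0)), root.add_child(TreeNode(length=0.0))]
    while len(active) < n_tips:
        k = len(active)
        w = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.length += w
        i = rng.integers(k)
        split = active[i]
        children = [split.add_child(TreeNode(length=0.0)) for _ in range(2)]
        active[i : i + 1] = children
    w = rng.exponential(1.0 / (n_tips * birth_rate))
    for node in active:
        node.length += w
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.label = f"s{i}"
    return PhyloTree(root, rooted=True)


# ---------------------------------------------------------------------------
# Gene trees (duplication–loss inside the species tree)

@dataclass
class GeneTreeSim:
    gene_tree: PhyloTree
    mapping: LeafMapping
    true_counts: EventCounts

    def truth(self) -> dict:
        return {
            "duplications": self.true_counts.duplications,
            "losses": self.true_counts.losses,
            "mapping": dict(self.mapping),
        }


def sim_gene_tree(
    species_tree: PhyloTree,
    dup_rate: float = 0.3,
    loss_rate: float = 0.0,
    seed: int = 0,
    min_leaves: int = 3,
    max_retries: int = 100,
) -> GeneTreeSim:
    """Evolve one gene family inside the species tree by birth–death.

    A single gene lineage enters at the species root and bifurcates at every
    speciation; along a species branch it duplicates (splitting in place) or
    dies with exponential waiting times.  The returned tree contains only
    surviving lineages; the true duplication count is restricted to
    duplications with surviving descendants on *both* sides (the observable
    ones), while the loss count tallies every loss event drawn.

    Retries with perturbed streams until the surviving family has at least
    ``min_leaves`` leaves, then errors out after ``max_retries``.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")

    for attempt in range(max_retries):
        rng = _rng(seed, "gene_tree") if attempt == 0 else np.random.default_rng(
            [int(seed), _STREAMS["gene_tree"], attempt]
        )
        counter: dict[str, int] = {}
        stats = {"dups": 0, "losses": 0}
        total = dup_rate + loss_rate

        def evolve(s_node: TreeNode, remaining: float) -> TreeNode | None:
            while True:
                w = rng.exponential(1.0 / total) if total > 0 else np.inf
                if w < remaining:
                    remaining -= w
                    if rng.random() < (loss_rate / total):
                        stats["losses"] += 1
                        return None
                    left = evolve(s_node, remaining)
                    right = evolve(s_node, remaining)
                    if left is not None and right is not None:
                        stats["dups"] += 1
                        return TreeNode(children=[left, right])
                    return left if left is not None else right
                break
            if s_node.is_leaf():
                counter[s_node.label] = counter.get(s_node.label, 0) + 1
                return TreeNode(label=f"{s_node.label}_g{counter[s_node.label]}")
            kids = [evolve(c, c.length or 0.0) for c in s_node.children]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return TreeNode(children=kids)

        root = evolve(species_tree.root, 0.0)
        if root is None or len(root.leaves()) < min_leaves or len(root.children) != 2:
            continue
        tree = PhyloTree(root, rooted=True)
        mapping: LeafMapping = {
            label: label.rsplit("_g", 1)[0] for label in tree.leaf_labels()
        }
        return GeneTreeSim(tree, mapping, EventCounts(stats["dups"], stats["losses"]))
    raise RuntimeError(
        f"no surviving gene family with ≥{min_leaves} leaves in {max_retries} tries"
    )


# ---------------------------------------------------------------------------
# Repeat proteins

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_AA20 = sorted(_CODONS_FOR)  # the 20 standard amino acids


def default_aa_weights() -> dict[str, float]:
    """Ala/Gly/Ser-rich unit composition typical of silk repeat regions."""
    weights = {aa: 0.35 / 17 for aa in _AA20 if aa not in "AGS"}
    weights.update({"A": 0.30, "G": 0.10, "S": 0.25})
    return weights


@dataclass
class RepeatProteinSim:
    dna: BioSequence
    protein: BioSequence
    unit_intervals: tuple[tuple[int, int], ...]  # protein coordinates
    ancestral_unit: str  # protein

    def truth(self) -> dict:
        return {
            "unit_intervals": [list(iv) for iv in self.unit_intervals],
            "ancestral_unit": self.ancestral_unit,
            "period": len(self.ancestral_unit),
            "n_units": len(self.unit_intervals),
        }


def _mutate_codon(codon: str, pos: int, rng: np.random.Generator) -> str:
    """Substitute one site, resampling so the codon never becomes a stop."""
    for _ in range(20):
        alt = rng.choice([b for b in "ACGT" if b != codon[pos]])
        cand = codon[:pos] + alt + codon[pos + 1 :]
        if cand not in standard_dna_table.stop_codons:
            return cand
    return codon


def sim_repeat_protein(
    unit_len: int = 180,
    n_units: int = 6,
    sub_rate: float = 0.02,
    indel_rate: float = 0.0,
    flank_len: int = 30,
    aa_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> RepeatProteinSim:
    """Simulate a CDS built from tandem copies of one ancestral repeat unit.

    The ancestral unit is drawn from ``aa_weights`` (A/G/S-rich by default)
    with codons uniform among synonymous options; each copy then receives
    per-nucleotide substitutions at ``sub_rate`` (never creating stops) and,
    at ``indel_rate`` per residue, single-codon deletions.  Random
    uniform-composition flanks are appended on both sides.
    """
    if unit_len < 4 or n_units < 2:
        raise ValueError("need unit_len ≥ 4 and n_units ≥ 2")
    rng = _rng(seed, "repeat_protein")
    weights = aa_weights or default_aa_weights()
    aas = sorted(weights)
    probs = np.array([weights[a] for a in aas], dtype=float)
    probs = probs / probs.sum()

    anc_aa = rng.choice(aas, size=unit_len, p=probs)
    anc_codons = [
        _CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))] for aa in anc_aa
    ]

    def flank() -> list[str]:
        out = []
        for _ in range(flank_len):
            aa = _AA20[rng.integers(20)]
            out.append(_CODONS_FOR[aa][rng.integers(len(_CODONS_FOR[aa]))])
        return out

    left, right = flank(), flank()
    copies: list[list[str]] = []
    for _ in range(n_units):
        codons = list(anc_codons)
        for ci in range(len(codons)):
            for pos in range(3):
                if rng.random() < sub_rate:
                    codons[ci] = _mutate_codon(codons[ci], pos, rng)
        if indel_rate > 0:
            keep = rng.random(len(codons)) >= indel_rate
            codons = [c for c, k in zip(codons, keep) if k]
        copies.append(codons)

    intervals = []
    pos = len(left)
    for codons in copies:
        intervals.append((pos, pos + len(codons)))
        pos += len(codons)

    all_codons = left + [c for codons in copies for c in codons] + right
    dna = "".join(all_codons)
    protein = "".join(standard_dna_table.forward_table[c] for c in all_codons)
    return RepeatProteinSim(
        dna=BioSequence("sim_repeat", dna, "dna"),
        protein=BioSequence("sim_repeat", protein, "protein"),
        unit_intervals=tuple(intervals),
        ancestral_unit="".join(anc_aa),
    )


# ---------------------------------------------------------------------------
# Traits

TRAIT_MODES = ("bm_distance", "star", "speciational")


def sim_traits(
    tree: PhyloTree,
    mode: str = "bm_distance",
    sigma2: float = 1.0,
    z0: float = 0.0,
    seed: int = 0,
) -> dict:
    """Simulate tip trait values on a tree.

    ``bm_distance``: Brownian motion, Gaussian branch increments of variance
    σ²·length; ``star``: tips i.i.d. Normal(z0, σ²); ``speciational``:
    increment variance σ² on every branch regardless of its length.
    """
    if mode not in TRAIT_MODES:
        raise ValueError(f"mode must be one of {TRAIT_MODES}")
    rng = _rng(seed, "traits")
    tips = tree.leaf_labels()
    if mode == "star":
        vals = z0 + np.sqrt(sigma2) * rng.standard_normal(len(tips))
        return dict(zip(tips, vals.tolist()))
    values: dict[int, float] = {id(tree.root): z0}
    parents = tree.parent_map()
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_val = values[id(parents[id(node)])]
        if mode == "bm_distance":
            if node.length is None:
                raise ValueError("bm_distance needs branch lengths")
            var = sigma2 * node.length
        else:
            var = sigma2
        values[id(node)] = parent_val + np.sqrt(var) * rng.standard_normal()
    return {leaf.label: values[id(leaf)] for leaf in tree.leaves()}


# ---------------------------------------------------------------------------
# Alignments with planted indels

@dataclass
class IndelAlignmentSim:
    alignment: MultipleAlignment
    true_matrix: BinaryMatrix

    def truth(self) -> dict:
        return {
            "characters": [[c.start, c.end] for c in self.true_matrix.characters],
            "taxa": list(self.true_matrix.taxa),
            "states": [list(r) for r in self.true_matrix.states],
        }


def sim_alignment_indels(
    n_taxa: int,
    length: int,
    events: list[tuple[list[str] | tuple[str, ...], int, int]],
    seed: int = 0,
    sub_rate: float = 0.05,
) -> IndelAlignmentSim:
    """Plant internal deletion events into a random protein alignment.

    Rows derive from one random ancestral row with per-site substitutions at
    ``sub_rate``; each event ``(taxa, start, end)`` deletes the column
    interval in the listed taxa.  Two events on the same taxon must be
    separated by at least one retained column, or the realized gap runs would
    contradict the planted characters.  The true binary matrix is built from
    the events by the simple-indel-coding rules (exact run → 1, strictly
    subsuming run → ``?``, else 0).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    per_taxon: dict[str, list[tuple[int, int]]] = {t: [] for t in taxa}
    for who, start, end in events:
        if not (0 < start < end < length):
            raise ValueError(f"event ({start}, {end}) must be internal to (0, {length})")
        for t in who:
            if t not in per_taxon:
                raise ValueError(f"unknown taxon {t!r}")
            for s0, e0 in per_taxon[t]:
                if start <= e0 and s0 <= end:  # overlap or abutment
                    raise ValueError(
                        f"contradictory events on {t!r}: ({s0},{e0}) vs ({start},{end})"
                    )
            per_taxon[t].append((start, end))

    rng = _rng(seed, "alignment_indels")
    aas = np.array(_AA20)
    ancestral = aas[rng.integers(20, size=length)]
    rows = []
    for t in taxa:
        row = ancestral.copy()
        mut = rng.random(length) < sub_rate
        row[mut] = aas[rng.integers(20, size=int(mut.sum()))]
        chars = row.tolist()
        for s, e in per_taxon[t]:
            for j in range(s, e):
                chars[j] = GAP
        rows.append((t, "".join(chars)))
    alignment = MultipleAlignment.from_pairs(rows, alphabet="protein")

    intervals = sorted({(s, e) for t in taxa for (s, e) in per_taxon[t]})
    characters = [IndelCharacter(s, e) for s, e in intervals]
    states = []
    for t in taxa:
        own = set(per_taxon[t])
        row_states = []
        for s, e in intervals:
            if (s, e) in own:
                row_states.append("1")
            elif any(s0 <= s and e <= e0 and (s0, e0) != (s, e) for s0, e0 in own):
                row_states.append("?")
            else:
                row_states.append("0")
        states.append(row_states)
    return IndelAlignmentSim(alignment, BinaryMatrix(list(taxa), characters, states))


def write_truth_sidecar(result, path: str | Path) -> None:
    """Dump a generator's ground truth as a JSON sidecar."""
    Path(path).write_text(json.dumps(result.truth(), indent=2) + "\n")
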