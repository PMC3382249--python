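# Methods

`spidrevo` re-implements, as a tested library, the inference chain used to
study the evolution of a silk gene family across the three principal spider
lineages: rooting a gene tree without an outgroup by duplication–loss
reconciliation, profiling tandem repeat arrays and their homogenization in
silk protein repeat regions, modeling the evolution of repeat-region
amino-acid composition, coding alignment gaps as characters, and measuring
conservation in a cysteine-rich protein alignment. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic generators do and do not emulate.

## Reconciliation and duplication–loss rooting

A gene tree `G` and species tree `S` (both rooted, binary) are related by
the standard LCA map `M`: leaves map through the gene→species table, and
`M(g) = lca_S(M(g₁), M(g₂))` for internal `g` with children `g₁, g₂`. A node
is a **duplication** iff `M(g) = M(gᵢ)` for some child. **Losses** accumulate
along skipped species edges: each child contributes
`d(M(g), M(gᵢ)) − 1 + [g is duplication]`, where `d` is the species-tree
edge distance; every term is ≥ 0. Branch lengths never enter the counts.

Gene families without an outgroup are rooted by trying each of the `2n − 3`
edges of the unrooted gene tree as the root, reconciling, and ranking by
total events (then duplications). Ties are reported in full, never broken
silently, because the tie structure is itself informative (many rootings can
share the optimal duplication count while differing in losses). The root is
placed at the edge midpoint; lengths are halved when present but do not
affect counts.

Correctness is established two ways: against an independent embedding-walk
oracle (clade-scan mapping plus explicit parent-chain walks counting
pass-through species nodes) on hundreds of random instances, and against
simulation ground truth — with loss rate 0 the optimal rooting reproduces
the simulated duplication count exactly, and with losses the parsimony
count never exceeds the simulated one.

## Tandem repeat detection

Silk protein repeat regions are arrays of long "ensemble" units (~180
residues in most of the taxa this package is aimed at) homogenized by
concerted evolution. The detector is a self-comparison lag profile:

1. For each candidate period `p` in `[min_period, max_period]` (default
   4–500) mark `m(i) = 1` iff `seq[i] == seq[i+p]`.
2. Seed candidate regions where a `p`-wide window of `m` has match fraction
   ≥ `min_coverage_run` (default 0.5).
3. Snap boundaries to the first/last position opening a locally dense match
   run (≥ 3/4 within a window of `min(2·seed_word, p)`); the window mean
   alone smears up to ~p/2 into the flanks.
4. Require at least `2·seed_word` matched positions in the region — a
   significance floor that removes chance micro-repeats (without it, ~4% of
   length-200 i.i.d. sequences yield a spurious 2-copy array; with it,
   none in 100 seeds).
5. Reduce each candidate to its **primitive period**: if re-segmenting at
   `p/k` keeps mean chunk identity within 2 percentage points, the shorter
   unit is the homogenized repeat and the longer one its harmonic. Without
   this step the detector reports period `2u` about as often as `u`, since
   both lags give identical coverage on a clean array.
6. Segment the region into consecutive `p`-length units (a final partial
   unit is kept if ≥ 0.8·p), iteratively re-align units to a working
   plurality consensus (global alignment, match +1 / mismatch −1 / gap −2,
   via Biopython's PairwiseAligner), and score mean pairwise identity
   (matching columns / columns with at least one non-gap member).
7. Resolve overlapping candidates across periods by greatest coverage, then
   identity, then smallest period.

Phase is inherently ambiguous: a tandem array has no privileged starting
rotation, and when a flank residue happens to match at the lag the reported
array may start a residue or two early. Detected consensus units are
therefore compared to ground truth up to cyclic rotation; unit *intervals*
are recovered within ±2 residues in ≥95% of planted-array replicates.

The reported consensus is the 50%-majority rule: per column, the most
frequent non-gap residue is emitted iff its frequency strictly exceeds half
of the non-gap count, else `X`; columns gapped in more than half the units
are dropped. Ties therefore yield `X`, matching the convention of marking
ambiguities explicitly.

## Synonymous / non-synonymous differences from the consensus

Repeat units are back-translated to a codon alignment (each residue column
expands to its source codon, gaps to `---`; the CDS must translate exactly
to the ungapped protein row, `X` matching anything). The consensus DNA is
the per-column plurality nucleotide (ties broken A<C<G<T). Each nucleotide
of each unit differing from the consensus is classified by substituting it
*singly* into the consensus codon: amino acid change ⇒ non-synonymous, else
synonymous. Multi-hit codons are thus decomposed per site against the
consensus background; the two counts always sum to the nucleotide Hamming
distance between units and consensus (positions gapped on either side are
skipped — indels are not substitutions).

## Composition profiles

Repeat-region composition is computed over the union of detected unit
intervals (or any explicit interval list): `percent(r) = 100·count(r)/n`,
with ambiguous residues (`X`) excluded from the denominator by default
(`count_ambiguous=True` includes them). The comparative Ala/Gly/Ser matrix
holds raw percentages and column-centered values (value − column mean), the
scale used for heat-map style comparisons, plus the panel mean of A+G+S.

## Continuous-trait models

Ancestral states of composition percentages are reconstructed by **linear
(Wagner) parsimony**: the downpass assigns each node the intersection of its
children's intervals, or the closed gap between them while adding the gap
width to the cost. The root interval is exactly the set of optimal root
states; reported non-root intervals are the downpass (subtree-conditional)
intervals. The cost equals the global minimum of Σ|parent − child|, verified
against grid brute force on small trees.

The model comparison fits nine Brownian-motion variants, a mode × lengths
grid, ranked by `AIC = 2k − 2 logL`:

- **mode** — `pure_phylogenetic` (the tree as given); `non_phylogenetic` (a
  unit-length star: tips i.i.d., no phylogenetic covariance);
  `punctuated_average` (change concentrated at branching events: each
  sister-branch pair is reshaped to an asymmetric `T : 1` split of its
  summed length, so one descendant tracks the ancestor while the other
  jumps; asymmetry thresholds `T` of 100 and 1000 by default).
- **lengths** — `distance` (input branch lengths), `equal` (all 1),
  `free` (lengths are fitted parameters).

Under every model the tip vector is multivariate normal with mean `z0` and
covariance `σ²·C`, `C[i,j]` the shared root-to-tip path length. `z0` (GLS
mean) and `σ²` (mean squared scaled residual) are profiled in closed form.
Free lengths are optimized by bounded L-BFGS-B on log lengths in
`[1e-6, 1e3]` from the equal-lengths start, with a bounded iteration budget;
free models carry `k = 2 + #branches` and are AIC-dominated unless the data
truly demand them (a warning flags `k > n`).

Punctuated polarity (which sister is the long side) is chosen by a single
deterministic postorder sweep, each pair's two assignments compared with the
others held fixed, and **each fitted polarity is counted as one discrete
parameter in `k`**. This charge is essential: with ~n/2 uncounted fitted
polarity bits the punctuated models systematically out-fit the true
generating model on Brownian data. With it, model-family recovery on
simulated data is ≥70% (in practice ≥80%) for gradual, star, and
speciational regimes alike. The punctuated construction itself (T:1 reshape
preserving each pair's summed length) is this package's committed,
documented surrogate for a model whose original operational definition is
not fully specified; its threshold semantics — "favored if branching events
carry branches 100/1000× their sisters" — is preserved by construction.
Percent traits are modeled untransformed.

## Simple indel coding

Each distinct **internal** gap run (unique start/end columns) becomes one
binary character. A taxon scores `1` if it has exactly that run, `?` if its
own gap strictly subsumes the run (covers it fully and is longer — equal
intervals score 1), `0` otherwise, including partially overlapping,
non-subsuming gaps. Terminal gap runs mark incomplete sequences: they
produce no characters and score `?` on characters they overlap
(`terminal_gaps="absent"` scores them 0 instead — the choice is exposed
because published practice varies). Export formats: a TSV state matrix and
a NEXUS matrix with the residue data and the binary indel characters as
separate partitions (MIXED datatype plus a SETS block).

## Conservation statistics

Pairwise similarity treats gaps as missing: per pair, % identical columns
among columns where both rows have residues; pairs sharing no columns are
undefined and excluded from group means. Column conservation tiers use an
ordered physiochemical table (Taylor/Venn sets, most specific first —
Proline, Glycine, Negative, Positive, Tiny, Aliphatic, Aromatic, Charged,
Small, Polar, Hydrophobic, then a universal catch-all): `identical_100`
(one residue), `category_100` (one non-universal category covers all),
`majority_gt50` (a residue or category covers >50% strictly), else `none`.
Note the rule is taken literally: a column like {K,R,L,V} is
`majority_gt50` because Hydrophobic covers 3/4 — broad categories qualify.
Cross-group conservation counts columns with at least one residue in each
group and reports the percentage reaching a configurable tier (default
`majority_gt50`) on the pooled column. The cysteine scan returns columns
100% / ≥50% cysteine among non-gap rows — candidate disulfide positions in
egg-case-protein comparisons.

## Synthetic data

Generators draw from named RNG streams derived from the run seed (numpy
`SeedSequence`-style keyed streams), so identical configurations are
bit-reproducible and adding a generator never shifts another's draws. Each
result object carries its ground truth and can write it as a JSON sidecar.

- **Species trees**: Yule process from the root split; waiting times
  Exp(k·λ); ultrametric, strictly positive lengths. Mean tip depth matches
  the analytic Σ 1/(kλ) expectation in Monte-Carlo tests.
- **Gene trees**: a single gene lineage enters at the species root,
  bifurcates at speciations, duplicates/dies with exponential waiting times
  within branches (no duplications on a zero-length root stem). True
  duplication counts are restricted to duplications with surviving
  descendants on both sides — the observable ones; the loss tally counts
  every loss event drawn.
- **Repeat proteins**: an ancestral unit (default 180 residues) drawn from
  an A/G/S-rich composition (A 0.30 / G 0.10 / S 0.25, remainder uniform —
  the regime typical of the silks this models), codons uniform among
  synonymous options; per-copy nucleotide substitutions at `sub_rate`
  (stops resampled away), optional single-codon deletions, random
  uniform-composition flanks (default 30 residues) on both sides.
- **Traits**: `bm_distance` (variance σ²·length per branch), `star`
  (i.i.d. tips), `speciational` (variance σ² per branch regardless of
  length).
- **Indel alignments**: one random ancestral row, per-site substitutions at
  5%, planted internal deletion events; events on the same taxon must not
  overlap or abut (the realized gap runs would contradict the planted
  characters). The true binary matrix is derived from the events alone.

What the generators do **not** emulate: sequence-level evolution along the
gene tree (units mutate from a fixed ancestor, not along a genealogy),
gene conversion between repeat copies, insertion events, rate variation
among sites, and alignment error — so passing recovery tests demonstrates
algorithmic correctness under the stated noise models, not robustness to
every feature of real silk gene data (where repeat boundaries were often
curated by eye).

## Problem sizes and degenerate inputs

The recovery studies run at: 500 random reconciliation instances (≤8 gene
leaves, ≤6 species); 100 rooting replicates per loss regime on an 8-species
tree; 200 planted repeat arrays (unit 180, 6 copies, substitution rate
0.02/0.05) for the test suite and 100 for the acceptance script; 100 (tests)
or 50 (script) trait replicates per generating regime on a 32-tip tree with
a single asymmetry threshold of 100; grid brute force for parsimony on
trees of 4–6 tips. Degenerate inputs error loudly: polytomies in
reconciliation, missing tip traits, singular covariances, frame violations,
contradictory planted indels, out-of-bounds regions. Sequences too short to
hold two repeat units return an empty result rather than an error, matching
how a scan over a protein panel is used.
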