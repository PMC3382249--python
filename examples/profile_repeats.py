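"""Detect tandem repeats in a silk-like protein and profile homogenization.

Simulates a spidroin-style coding sequence (~180-residue A/G/S-rich units in
tandem), detects the array, builds the 50%-majority consensus, and counts
synonymous vs non-synonymous nucleotide differences of each repeat from the
codon consensus — the signature of concerted evolution is high identity and
an excess of shared, recent differences.
"""

from spidrevo import (
    BioSequence,
    MultipleAlignment,
    backtranslate,
    build_consensus,
    classify_differences,
    consensus_dna_from_alignment,
    detect_tandem_repeats,
    residue_composition,
    sim_repeat_protein,
    single_residue_runs,
)

sim = sim_repeat_protein(unit_len=180, n_units=6, sub_rate=0.02, seed=3)
print(f"simulated protein: {len(sim.protein.residues)} residues, "
      f"true units {sim.unit_intervals[0]}..{sim.unit_intervals[-1]}")

arrays = detect_tandem_repeats(sim.protein)
a = arrays[0]
print(f"\ndetected {len(arrays)} array: period {a.period}, {a.n_units} copies, "
      f"mean pairwise identity {a.mean_identity:.1f}%, coverage {a.coverage:.2f}")

consensus = build_consensus(a.aligned_units)
runs = single_residue_runs(consensus)
print(f"consensus unit ({len(consensus)} aa), single-residue tandem runs: "
      f"{[(r, l) for r, s, l in runs]}")

comp = residue_composition(sim.protein, region=list(a.units))
print("repeat-region composition: "
      + ", ".join(f"{r} {comp.get(r):.1f}%" for r in "AGS"))

# codon-level differences from the consensus
rows = [(f"u{i}", sim.protein.residues[s:e]) for i, (s, e) in enumerate(sim.unit_intervals)]
cds = {f"u{i}": BioSequence(f"u{i}", sim.dna.residues[3 * s : 3 * e], "dna")
       for i, (s, e) in enumerate(sim.unit_intervals)}
codon_aln = backtranslate(MultipleAlignment.from_pairs(rows), cds)
diff = classify_differences(codon_aln, consensus_dna_from_alignment(codon_aln))
print(f"\ndifferences from codon consensus over {diff.alignment_length_nt} nt: "
      f"{diff.nonsynonymous} non-synonymous, {diff.synonymous} synonymous")
print("(every differing nucleotide is classified by substituting it singly "
      "into the consensus codon)")
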