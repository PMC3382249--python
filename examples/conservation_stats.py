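"""Similarity and physiochemical conservation of a cysteine-rich alignment.

Builds a small egg-case-protein-like alignment of two sequence groups,
computes pairwise % similarity (gaps as missing), per-column conservation
tiers against the Taylor physiochemical categories, cross-group conservation
of shared sites, and conserved cysteine positions.
"""

from spidrevo import (
    MultipleAlignment,
    column_conservation,
    cross_group_conservation,
    cysteine_conservation,
    pairwise_similarity,
)

aln = MultipleAlignment.from_pairs([
    ("ecpl1", "MCAKSCDE-GC"),
    ("ecpl2", "MCAKTCDD-GC"),
    ("ecpl3", "MCGRSCEE-GC"),
    ("ecp1",  "MCAKSCDEKGC"),
    ("ecp2",  "MCSRTCEDKGC"),
])
groups = {i: ("ecpl" if i.startswith("ecpl") else "ecp") for i in aln.ids}

sim = pairwise_similarity(aln, groups)
print(f"within-ECPL mean similarity : {sim.within_group_mean('ecpl'):.2f}%")
print(f"ECPL vs ECP mean similarity : {sim.between_group_mean('ecpl', 'ecp'):.2f}%")

tiers = column_conservation(aln)
for j, (tier, cat) in enumerate(tiers):
    print(f"col {j:2d}: {tier:14s} {cat or ''}")

cross = cross_group_conservation(aln, ["ecpl1", "ecpl2", "ecpl3"], ["ecp1", "ecp2"])
print(f"\nconserved at sites shared by both groups: {cross:.1f}%")

full, half = cysteine_conservation(aln)
print(f"cysteine columns at 100%: {full} (candidate disulfide positions)")
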