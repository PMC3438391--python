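"""Build the reference gene-content haplotype catalog and inspect it.

The common KIR haplotypes are combinations of a centromeric and a telomeric
motif flanked by four framework genes.  The catalog holds the six common
Cen x Tel combinations, the rarer Cen-B3 ~ Tel-A haplotype, and the
Cen-B1 ~ Tel-B haplotype carrying a KIR3DS1 deletion; expanding the 2DS3S5
slot (one of KIR2DS3/KIR2DS5 per occupied motif) yields marker-level
haplotypes usable in set-union arithmetic.
"""

import kirpop as kp

h7 = kp.build_reference_haplotypes(include_deletion=False, expand_2DS3S5=False)
h8 = kp.build_reference_haplotypes(include_deletion=True, expand_2DS3S5=False)
h18 = h8.expand()

print(f"base catalog: {len(h7)} haplotypes: {', '.join(h7.names)}")
print(f"amended catalog (+3DS1 deletion): {len(h8)} haplotypes")
print(f"marker-level expansion: {len(h18)} variants")

cAtA = h18[0]
print(f"\n{cAtA.name} carries: {', '.join(sorted(cAtA.markers))}")
g = kp.genotype_from_pair(cAtA, cAtA)
print(f"an A/A homozygote therefore types positive for {len(g.present)} loci")
# The 18 variants are what the constrained EM searches over; the counts per
# parent (1/2/4) reflect how many 2DS3S5 slots each motif combination has.
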