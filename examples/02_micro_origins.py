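"""Which small gecko chromosomes are fused microchromosomes?

Classifies each gecko chromosome by where its markers sit in the three
Toxicofera witness species that still carry many microchromosomes, then
compares how the gecko and the sand lizard packaged the shared
micro-derived markers — identical packaging would indicate fusions
inherited from a common ancestor.
"""

from karyosynth import lineage_partition_overlap, load_fixture, micro_origin_profile

cmap = load_fixture().cmap

print("chromosome  classification  chicken-segments")
for prof in micro_origin_profile(cmap, "GHO"):
    print(f"GHO{prof.chromosome:<9} {prof.classification:<15} {prof.segment_count}")

cmp = lineage_partition_overlap(cmap, "GHO", "LAG")
print(f"\nshared micro-derived markers: {len(cmp.markers)}")
print(f"partitions identical between GHO and LAG: {cmp.partitions_identical}")
# all_micro chromosomes (5, 9, 10, 11) are pure microchromosome fusions;
# the partitions differ, so the gecko and lacertid lineages assembled their
# fusion products independently.
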