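"""Conserved avian macrochromosome units in the gecko map.

Loads the packaged 86-marker comparative table and asks which gecko (GHO)
chromosomes carry material from the 11 conserved chicken macrochromosome
units, and which sand-lizard (LAG) macrochromosomes the same units pick
out.
"""

from karyosynth import conserved_macro_chromosomes, hit_units, load_fixture

cmap = load_fixture().cmap

gho = sorted(conserved_macro_chromosomes(cmap, "GHO"), key=lambda x: (len(x), x))
units = sorted(hit_units(cmap, "GHO"))
lag = sorted(conserved_macro_chromosomes(cmap, "LAG"), key=lambda x: (len(x), x))

print(f"gecko chromosomes with conserved avian material ({len(gho)}): {gho}")
print(f"avian units represented ({len(units)}): {units}")
print(f"sand-lizard macrochromosomes reached via the same units ({len(lag)}): {lag}")
# Ten gecko chromosomes cover all eleven chicken units; through those units
# they connect to eight numbered sand-lizard macrochromosomes.
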