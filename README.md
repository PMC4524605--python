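# karyosynth

Comparative cytogenetic analysis of karyotype reorganization in squamate
reptiles: from cross-species gene-location tables to conserved synteny
segments, microchromosome-origin accounting, and phylogenetically
polarized rearrangement scenarios — validated against a karyotype-
evolution simulator with known ground truth.

## The problem

Most squamate reptiles carry two chromosome size classes: large
macrochromosomes and dot-like microchromosomes. Geckos (Gekkota) and
lacertid lizards have few or no microchromosomes, yet Gekkota branches
near the base of the squamate tree. Did microchromosomes arise later by
fission of macrochromosomes, or did they exist ancestrally and disappear
in these two lineages by repeated fusion? FISH-mapping the same set of
functional genes in several species turns this into a computable
question: genes co-located on one chromosome in species A and on one
chromosome in species B define a conserved synteny segment, and the way
segments are packaged into chromosomes across the tree lets one infer
typed events — centric fusion/fission (Robertsonian), tandem fusion
(whose relic is an interstitial telomeric site, ITS), and inversions —
and polarize them by outgroup parsimony.

The package ships, as its test fixture, a comparative table of 86
functional genes mapped in the Hokou gecko (GHO, 2n = 38, no
microchromosomes) with ortholog locations in the sand lizard (LAG), water
monitor (VSA), butterfly lizard (LRE), four-striped rat snake (EQU),
green anole (ACA) and chicken (GGA), plus karyotype definitions, rDNA/ITS
landmarks and the species tree.

## What it computes

* **Synteny segments** — `segment_table(map, A, B)`: maximal co-located
  marker sets linking a chromosome/arm of A to one of B, with support
  counts. Σ support = number of markers mapped in both species.
* **Avian-unit conservation** — `conserved_macro_chromosomes` /
  `hit_units`: which chromosomes carry material from the conserved
  chicken macrochromosome units {1p, 1q, 2p, 2q, 3, 4q, 5, 6, 7, 8, Z}.
* **Micro-origin accounting** — `micro_origin_profile`: classifies each
  chromosome as `all_micro` / `mixed` / `all_macro` / `insufficient` from
  where its genes sit in the Toxicofera witness species (VSA, LRE, EQU),
  and `lineage_partition_overlap` tests whether two microchromosome-poor
  lineages assembled the *same* fusion products (shared descent) or
  different ones (independent loss).
* **Rearrangement scenarios** — `infer_scenario`: classifies chromosome
  correspondences (e.g. the p and q arms of one bi-armed chromosome each
  matching a distinct acrocentric in the other species), polarizes the
  implied centric fusion/fission on the species tree by outgroup
  parsimony, detects tandem fusions from ITS landmarks and micro-fusion
  products, and flags marker-order discrepancies as qualitative inversion
  calls. Exact oracles (`breakpoint_count`, BFS
  `reversal_distance_exact`, n ≤ 8) support inversion reasoning.
* **Simulation** — `evolve(SimConfig, tree)`: evolves an ancestral
  karyotype of acrocentric macro- and microchromosomes under
  fusion/fission/tandem-fusion/inversion events, emits tip tables in the
  exact input formats, and records ground truth for recovery tests.

## Worked example

```bash
python examples/01_homology_counts.py
```

prints

```
gecko chromosomes with conserved avian material (10): ['1', '2', '3', '4', '6', '7', '8', '13', '14', '15']
avian units represented (11): ['1p', '1q', '2p', '2q', '3', '4q', '5', '6', '7', '8', 'Z']
sand-lizard macrochromosomes reached via the same units (8): ['1', '3', '4', '5', '7', '8', '9', '10']
```

— ten gecko chromosome pairs cover all eleven conserved chicken
macrochromosome units, and through those units they correspond to eight
sand-lizard macrochromosomes. `examples/02_micro_origins.py` shows that
gecko chromosomes 5, 9, 10 and 11 are composed purely of
microchromosome-derived segments and that the gecko and the sand lizard
partition the shared micro-derived markers differently — the two lineages
lost their microchromosomes independently. `examples/03_infer_scenario.py`
prints the inferred event list, e.g.

```
tandem_fusion          GHO14p + proto-GHO14q                  [Gekkota]
centric_fusion         proto-GHO1p + proto-GHO1q              [Gekkota]
centric_fusion         proto-GHO15 + proto-GHO13              [Toxicofera]
centric_fusion         proto-GHO7 + proto-GHO14q              [Toxicofera]
...
```

— centric fusions of gecko-like acrocentric proto-chromosomes built the
bi-armed butterfly-lizard chromosomes on the Toxicofera branch, while the
two large bi-armed gecko pairs and the ITS-marked chromosome 14 tandem
fusion are gecko-lineage events. `examples/04_simulate_and_recover.py`
closes the loop: simulated fusions are recovered with correct kind,
operands and branch.

A thin CLI wraps the same calls: `karyosynth report`,
`karyosynth homology segments|conserved|micro-origin`,
`karyosynth rearrange infer`, `karyosynth simulate`.

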