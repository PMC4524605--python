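# Methods

This note documents the models, decision rules and numerical choices
behind `karyosynth`, and what the simulator-based tests do and do not
show about real data.

## Input model

The analysis substrate is a comparative map: gene markers × species, each
cell a cytogenetic location string. The parser accepts the dialect of
published FISH tables: `1p`, `2q12.2–q21.1` (hyphen or en-dash, stray
spaces tolerated), bare chromosome numbers, `Zp`/`Zq`, sex-annotated
labels (`4 (ZW)`, `5 (Z)`), explicit `Micro`, micro-group ranges
(`11–18`, meaning "one of the small chromosomes 11–18, identity
unresolved"), `un` (location undetermined) and `–` (no data). Canonical
output uses a single en-dash, so read→write→read is the identity.

Design choices at this layer:

* **Band labels are ordinal, not metric.** `11.1 < 11.2 < 12 < 21.1`
  orders positions centromere→telomere along an arm; no distance
  semantics are ever attached.
* **Centromere-spanning ranges** (`3p11.1–q11`) are stored with
  `arm="whole"`: the marker cannot be attributed to one arm, and
  downstream arm logic treats it as consistent with either.
* **Anonymous microchromosomes.** Explicit `Micro` cells and micro-group
  ranges both aggregate to a single `Micro` side in segment tables and
  partition blocks, because neither resolves chromosome identity.
* **Sex chromosomes by numeric label.** A gecko location written `4 (ZW)`
  is stored under chromosome `4` with a sex annotation; karyotype
  definitions mark which label carries Z. Display labels substitute `Z`
  (so operands read `proto-GHOZ`).
* **Karyotype bookkeeping.** Each chromosome row carries `copies` (2 for
  an autosome pair, 1 each for Z and W in a ZW female), making the
  2n-consistency check exact for any sex system.
* **Marker order** within a chromosome comes from an explicit rank column
  when present (simulated data), else from band positions when every
  marker has one, else from table row order. Provenance is recorded;
  row-order-based inferences are treated as approximate throughout.

## Synteny segments and avian units

A segment is the marker set shared by one (chromosome, arm) of species A
and one of species B; arms are taken as recorded (a bare label is
`whole`). Minimum support for reporting is 1 gene — single-gene
homology statements are standard in cytogenetic mapping — but support
counts are always attached so callers can threshold. Two invariants are
enforced by tests: symmetry under side swap, and conservation (support
counts sum to the number of markers mapped in both species).

Conserved avian units default to the eleven chicken macrochromosomes/arms
{1p, 1q, 2p, 2q, 3, 4q, 5, 6, 7, 8, Z}. Chicken 4p is deliberately not a
member (its material sits on a micro-derived gecko chromosome), and the
set is configurable. Arm matching is asymmetric on purpose: a gene
recorded on `2p` matches unit `2p` and unit `2`; a gene recorded on bare
`2` matches unit `2` only — arm-level units require arm-level data.

The "eight lacertid macrochromosomes" count is produced by the same
unit-mediated rule (lacertid chromosomes carrying ≥1 gene whose chicken
location falls in the unit set, micro-group cells excluded); no separate
counting rule is defined for it.

## Microchromosome-origin accounting

Witness species are the three Toxicofera maps with dense data (VSA, LRE,
EQU); the anole is excluded by default because its column is sparse and
chromosome-number based. Per gene, each witness votes `micro` (explicit
micro location) or `macro` (identified chromosome); missing/unknown cells
abstain. A gene is *micro-derived* if ≥1 witness votes micro and
*macro-derived* if ≥1 votes macro — a conflicted gene is both, which is
what marks chromosomes carrying inserted micro segments as `mixed`.

Chromosome classification:

* `all_micro` — ≥2 informative genes and **every** informative gene is
  unanimously micro across its witnesses. The two-gene minimum prevents a
  single-marker chromosome from being called a fusion product; the
  unanimity requirement keeps chromosomes with any macro evidence out.
* `mixed` — at least one micro-derived and one macro-derived gene.
* `all_macro` — only macro votes.
* `insufficient` — fewer than 2 informative genes.

Lineage independence is tested on the markers unanimously micro in the
witnesses and mapped in both focal species: each species partitions them
by chromosome; the partitions are *identical* iff every block of one
equals a block of the other. Identity is the signature of fusions
inherited from a common ancestor; on the study panel the gecko and the
sand lizard partition the shared markers differently.

## Rearrangement inference

**Correspondence classification.** For each chromosome of the focal
species, the partner units matched by its p and q arms are computed.
Multiple arms of one partner chromosome collapse to the whole chromosome;
a single-arm match collapses to the whole chromosome when the partner has
no markers elsewhere on it (an effectively one-armed chromosome written
with or without its q); centromere-spanning markers are tolerated when
their partner chromosome already backs an armed unit. If the p and q arms
each match exactly one unit on *distinct* partner chromosomes, the
pattern is `arms_to_two_wholes` — the signature of a centric
fusion/fission relating the two karyotypes.

**Polarization** (joined side J = the bi-armed chromosome, split side S =
the two acrocentrics). Witnesses are ranked by phylogenetic position:

1. the designated outgroup — decisive when the two blocks sit on disjoint
   chromosomes (*split*) or both confined to one single chromosome
   (*joined*); overlapping multi-chromosome patterns are inconclusive;
2. tips attaching rootward of the J–S divergence (unanimous consensus);
3. all remaining tips (unanimous consensus). These may share a side's
   derived state, so they decide only when nothing closer to the root
   does, and they never veto a decisive outgroup.

A decisive outgroup contradicted by a unanimous rootward consensus yields
an *ambiguous* event rather than a forced call. Ancestral split ⇒
`centric_fusion` on J's branch; ancestral joined ⇒ `centric_fission` on
S's branch. This ordering is what allows a fusion in the basal lineage
itself to be polarized (every other lineage holds the split state), and
it makes the inference self-dual: rerooting the tree so the fused lineage
is basal flips the call to the mirrored fission, a property enforced by
test.

**Branch labels.** With a lineage mapping on the tree (the study panel:
Gekkota, Lacertidae, Toxicofera), events are assigned to the stem of the
derived side's major lineage; finer placement inside the Toxicofera
polytomy is not attempted. Without a mapping (simulated trees), the
branch is the largest clade containing the derived tip — excluding the
reference — whose sampled members share the derived state.

**Morphology-based fusion detector.** One biologically real configuration
escapes `arms_to_two_wholes`: a bi-armed chromosome whose entire mapped
content (both arms) lies on a single *acrocentric* chromosome of another
lineage. Chromosome arms do not appear without rearrangement, and the
acrocentric partner shows the one-armed ancestral state of the shared
material, so the focal chromosome gained its second arm by centric fusion
on its own branch. Operands are named `proto-<X>q` (the arm treated as
the fusion host) plus the partner proto-chromosome. On the study panel
exactly one chromosome fires this rule (the second-largest gecko pair
against the acrocentric sand-lizard chromosome 1).

**Tandem fusions and micro-fusion products.** An ITS landmark on a
chromosome with a micro-derived arm yields a `tandem_fusion` naming that
arm and the acrocentric proto-chromosome of the other arm. An `all_micro`
chromosome whose genes span ≥2 distinct chicken chromosomes yields a
`micro_fusion` event with one operand per chicken segment; a single-
segment product (e.g. a chromosome matching only chicken 15) may simply
be an intact ancestral microchromosome grown in size, so no event is
claimed.

**Inversions.** For segments with ≥3 shared markers, order discrepancy is
measured by `breakpoint_count` (adjacencies with free virtual ends; 0 iff
identical or exactly reversed). On the packaged table one side's order is
always row order — a drawn-figure approximation — so inversion calls are
emitted only as qualitative, `ambiguous` flags and never counted as
minimal-event claims. Exact reversal distances (BFS over the permutation
group) are available for explicit-rank or simulated data and are capped
at n ≤ 8, where the search space (n!) is exhaustively tractable; the
oracle satisfies ⌈b/2⌉ ≤ d ≤ n−1, verified over every permutation up to
n = 6.

**Determinism.** All iteration is over sorted structures; events
deduplicate on (kind, operand set, branch) — branch included so that the
same fusion arising independently on two branches remains two events —
and the output ordering is (branch, operands, kind). Two runs on the same
inputs are byte-identical.

`centromere_repositioning` exists as an event kind for annotation but is
never auto-inferred: on this kind of data it is an alternative hypothesis
to pericentric inversion that marker content cannot distinguish.

## Simulator

The generator evolves a pseudo-haploid ancestral karyotype (default 19
acrocentric macrochromosomes and 12 microchromosomes — the true ancestral
counts are unknown; these defaults are illustrative and configurable)
along a given tree. Markers (default 3 per macro, 2 per micro) are placed
in seeded random order per chromosome. Events per branch are applied as
listed; unspecified operands are drawn uniformly from the currently
eligible chromosomes. Centric fusion requires two non-micro acrocentrics
(fusing a bi-armed chromosome is an error); fission splits a bi-armed
chromosome at the centromere; tandem fusion appends a micro to an arm
end, removes exactly one microchromosome, and leaves an ITS with
configurable probability (default 1.0); inversion reverses a contiguous
block of ≥2 markers within an arm. Tips emit maps with explicit rank
columns (so order inference is exact), per-tip karyotypes and ITS
landmarks. The history records every applied event with operand marker
sets, supports exact replay (replaying the log from the ancestor must
reproduce every tip state), and grounds the recovery test: over 50 seeded
replicates with 1–3 fusions per derived branch and 3 markers per operand,
the pipeline recovers ≥95% of fusions with correct branch and operands
(in practice 100% under these conditions).

What the simulator does **not** emulate: band-level resolution,
hybridization failure (missing cells), mapping error, chromosome size or
recombination, translocations, and sex chromosomes. Passing recovery
tests therefore demonstrates the correctness of the inference logic under
clean data, not robustness to the noise sources of real FISH tables —
on real data the support counts and the ambiguous-event class carry that
uncertainty instead.

## Known limitations

* Within-chromosome marker order in the packaged table is row order; the
  original maps depict order graphically, so order-dependent statements
  on the fixture are approximate by construction.
* The gecko chromosome 12 is macro-homologous to partner-arm material yet
  falls outside the default avian unit set's reach (its chicken homolog,
  27, is not a unit); the ten-chromosome conserved set reproduces the
  unit-mediated counting rule, and this asymmetry is inherent to that
  rule rather than resolved by it.
* Polarization treats the four Toxicofera maps as one polytomous lineage;
  events shared by only part of that clade are still labelled with the
  lineage stem.
* The small pericentric inversion hypothesized for the second gecko pair
  has no printed marker support and is represented here in documentation
  only, not asserted by `infer_scenario`.
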