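"""Pairwise synteny segments and chromosome-origin accounting.

Three questions, all answered directly from a :class:`ComparativeMap`:

* which chromosome/arm of species A shares markers with which
  chromosome/arm of species B (:func:`segment_table`);
* which chromosomes of a squamate species carry material homologous to the
  conserved avian macrochromosome units
  (:func:`conserved_macro_chromosomes` / :func:`hit_units`);
* which chromosomes of a species are built from ancestral
  microchromosomes, judged by where their markers sit in the Toxicofera
  species that still carry many microchromosomes
  (:func:`micro_origin_profile`), and whether two microchromosome-poor
  lineages assembled the same fusion products
  (:func:`lineage_partition_overlap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cytomap import ComparativeMap, GeneMarker

__all__ = [
    "AvianMacroUnitSet",
    "SegmentHomology",
    "MicroOriginProfile",
    "PartitionComparison",
    "DEFAULT_TOXICOFERA",
    "segment_table",
    "conserved_macro_chromosomes",
    "hit_units",
    "micro_origin_profile",
    "micro_derived_markers",
    "lineage_partition_overlap",
]

#: Toxicofera species used as microchromosome-state witnesses by default.
#: The anole is excluded: its column is sparse and chromosome-number based.
DEFAULT_TOXICOFERA = ("VSA", "LRE", "EQU")


@dataclass(frozen=True)
class AvianMacroUnitSet:
    """Chicken macrochromosomes / macrochromosome arms treated as conserved
    linkage units.

    A unit is either a whole chromosome token (``"3"``, ``"Z"``) or an arm
    token (``"4q"``).  A gene recorded on ``2p`` matches unit ``2p`` and
    unit ``2``; a gene recorded on bare ``2`` matches unit ``2`` only —
    arm-level units require arm-level data.
    """

    units: frozenset[str] = frozenset(
        {"1p", "1q", "2p", "2q", "3", "4q", "5", "6", "7", "8", "Z"}
    )

    def __post_init__(self) -> None:
        whole = {u for u in self.units if not u.endswith(("p", "q")) or u in ("p", "q")}
        arms = self.units - whole
        clash = {a[:-1] for a in arms} & whole
        if clash:
            raise ValueError(
                f"unit set mixes arm and whole tokens for chromosome(s) {sorted(clash)}"
            )

    def matches(self, chromosome: str, arm: str) -> bool:
        """Does a gene at (chromosome, arm) fall inside the unit set?"""
        if chromosome in self.units:  # whole token matches any arm
            return True
        if arm in ("p", "q") and f"{chromosome}{arm}" in self.units:
            return True
        return False

    def matching_units(self, chromosome: str, arm: str) -> set[str]:
        out = set()
        if chromosome in self.units:
            out.add(chromosome)
        if arm in ("p", "q") and f"{chromosome}{arm}" in self.units:
            out.add(f"{chromosome}{arm}")
        return out


DEFAULT_AVIAN_UNITS = AvianMacroUnitSet()


@dataclass(frozen=True)
class SegmentHomology:
    """A maximal co-located marker set linking one chromosome/arm in
    species A to one in species B."""

    side_a: tuple[str, str, str]  # (species, chromosome, arm)
    side_b: tuple[str, str, str]
    support: tuple[str, ...]

    @property
    def support_count(self) -> int:
        return len(self.support)

    def swapped(self) -> "SegmentHomology":
        return SegmentHomology(side_a=self.side_b, side_b=self.side_a, support=self.support)


def segment_table(
    cmap: ComparativeMap, sp_a: str, sp_b: str
) -> list[SegmentHomology]:
    """All synteny segments between two species, one per distinct
    (chromosome/arm, chromosome/arm) pair with ≥1 shared mapped marker.

    Anonymous microchromosome locations (explicit ``Micro`` and micro-group
    tokens) aggregate into a single ``Micro`` side per species.  Sorted by
    descending support then lexically.
    """
    if sp_a == sp_b:
        raise ValueError("segment_table needs two distinct species")
    cmap.require_species(sp_a, sp_b)
    buckets: dict[tuple[tuple[str, str], tuple[str, str]], list[str]] = {}
    for m in cmap.markers:
        la, lb = m.locations.get(sp_a), m.locations.get(sp_b)
        if la is None or lb is None or not la.mapped or not lb.mapped:
            continue
        buckets.setdefault((la.side(), lb.side()), []).append(m.symbol)
    segments = [
        SegmentHomology(
            side_a=(sp_a,) + sa, side_b=(sp_b,) + sb, support=tuple(symbols)
        )
        for (sa, sb), symbols in buckets.items()
    ]
    segments.sort(key=lambda s: (-s.support_count, s.side_a, s.side_b))
    return segments


def conserved_macro_chromosomes(
    cmap: ComparativeMap,
    species: str,
    units: AvianMacroUnitSet = DEFAULT_AVIAN_UNITS,
    chicken: str = "GGA",
) -> set[str]:
    """Chromosomes of ``species`` carrying ≥1 gene whose chicken location
    falls inside the avian macro-unit set."""
    cmap.require_species(species, chicken)
    out: set[str] = set()
    for m in cmap.markers:
        loc = m.locations.get(species)
        gga = m.locations.get(chicken)
        if loc is None or gga is None or not loc.resolved or not gga.resolved:
            continue
        if units.matches(gga.chromosome, gga.arm):
            out.add(loc.chromosome)
    return out


def hit_units(
    cmap: ComparativeMap,
    species: str,
    units: AvianMacroUnitSet = DEFAULT_AVIAN_UNITS,
    chicken: str = "GGA",
) -> set[str]:
    """The subset of avian units represented on the conserved chromosomes
    of ``species``."""
    conserved = conserved_macro_chromosomes(cmap, species, units, chicken)
    out: set[str] = set()
    for m in cmap.markers:
        loc = m.locations.get(species)
        gga = m.locations.get(chicken)
        if loc is None or gga is None or not loc.resolved or not gga.resolved:
            continue
        if loc.chromosome in conserved:
            out |= units.matching_units(gga.chromosome, gga.arm)
    return out


# ---------------------------------------------------------------------------
# microchromosome-origin accounting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicroOriginProfile:
    """Micro- vs macro-origin classification of one chromosome.

    ``evidence`` records, per gene, the micro/macro vote of each Toxicofera
    witness species with data.  A gene is *micro-derived* if ≥1 witness
    places it on a microchromosome, *macro-derived* if ≥1 witness places it
    on a macrochromosome (a conflicted gene is both), and *unanimously
    micro* if every witness with data says micro.

    classification:
      * ``all_micro`` — ≥2 informative genes, every one unanimously micro;
      * ``mixed`` — ≥1 micro-derived and ≥1 macro-derived gene;
      * ``all_macro`` — every informative gene macro-only;
      * ``insufficient`` — fewer than 2 informative genes.
    """

    species: str
    chromosome: str
    classification: str
    evidence: Mapping[str, Mapping[str, str]]  # gene -> witness -> micro|macro
    segment_count: int  # distinct chicken chromosomes among its genes


def _witness_votes(
    marker: GeneMarker, witnesses: Sequence[str]
) -> dict[str, str]:
    votes: dict[str, str] = {}
    for sp in witnesses:
        loc = marker.locations.get(sp)
        if loc is None or not loc.mapped:
            continue
        if loc.is_micro or loc.is_micro_group:
            votes[sp] = "micro"
        elif loc.chromosome is not None:
            votes[sp] = "macro"
    return votes


def _is_unanimous_micro(votes: Mapping[str, str]) -> bool:
    return bool(votes) and all(v == "micro" for v in votes.values())


def micro_derived_markers(
    cmap: ComparativeMap, toxicofera: Sequence[str] = DEFAULT_TOXICOFERA
) -> list[GeneMarker]:
    """Markers unanimously placed on microchromosomes by the Toxicofera
    witness species with data (the markers used for lineage-independence
    comparisons)."""
    out = []
    for m in cmap.markers:
        if _is_unanimous_micro(_witness_votes(m, toxicofera)):
            out.append(m)
    return out


def micro_origin_profile(
    cmap: ComparativeMap,
    species: str,
    toxicofera: Sequence[str] = DEFAULT_TOXICOFERA,
    chicken: str = "GGA",
) -> list[MicroOriginProfile]:
    """One profile per chromosome of ``species`` with ≥1 informative gene."""
    if not toxicofera:
        raise ValueError("need at least one Toxicofera witness species")
    cmap.require_species(species, *toxicofera)
    by_chrom: dict[str, list[GeneMarker]] = {}
    for m in cmap.markers:
        loc = m.locations.get(species)
        if loc is not None and loc.resolved:
            by_chrom.setdefault(loc.chromosome, []).append(m)

    profiles = []
    for chrom in cmap.chromosomes_of(species):
        markers = by_chrom.get(chrom, [])
        evidence = {}
        informative = []
        for m in markers:
            votes = _witness_votes(m, toxicofera)
            if votes:
                informative.append(m)
                evidence[m.symbol] = votes
        if not informative:
            continue
        n_micro = sum(
            1 for m in informative if "micro" in evidence[m.symbol].values()
        )
        n_macro = sum(
            1 for m in informative if "macro" in evidence[m.symbol].values()
        )
        if len(informative) < 2:
            cls = "insufficient"
        elif all(_is_unanimous_micro(evidence[m.symbol]) for m in informative):
            cls = "all_micro"
        elif n_micro >= 1 and n_macro >= 1:
            cls = "mixed"
        else:
            cls = "all_macro"
        chicken_chroms = {
            m.locations[chicken].chromosome
            for m in markers
            if chicken in m.locations and m.locations[chicken].resolved
        }
        profiles.append(
            MicroOriginProfile(
                species=species,
                chromosome=chrom,
                classification=cls,
                evidence=evidence,
                segment_count=len(chicken_chroms),
            )
        )
    return profiles


@dataclass(frozen=True)
class PartitionComparison:
    """How two species partition a shared marker set into chromosomes."""

    species_a: str
    species_b: str
    markers: tuple[str, ...]
    blocks_a: tuple[frozenset[str], ...]
    blocks_b: tuple[frozenset[str], ...]
    partitions_identical: bool


def lineage_partition_overlap(
    cmap: ComparativeMap,
    sp_a: str,
    sp_b: str,
    toxicofera: Sequence[str] = DEFAULT_TOXICOFERA,
) -> PartitionComparison:
    """Compare how two lineages packaged the ancestral microchromosome
    material into present-day chromosomes.

    Restricted to markers micro-derived in Toxicofera and mapped in both
    species; each species partitions them by chromosome (anonymous micro
    locations pool into one ``Micro`` block).  ``partitions_identical`` is
    True iff every block of one partition equals a block of the other —
    the signature of fusions shared through common descent rather than
    assembled independently.
    """
    cmap.require_species(sp_a, sp_b)
    shared = [
        m
        for m in micro_derived_markers(cmap, toxicofera)
        if sp_a in m.locations
        and sp_b in m.locations
        and m.locations[sp_a].mapped
        and m.locations[sp_b].mapped
    ]
    if not shared:
        raise ValueError(
            f"no shared micro-derived markers between {sp_a} and {sp_b}"
        )

    def blocks(sp: str) -> tuple[frozenset[str], ...]:
        by_chrom: dict[str, set[str]] = {}
        for m in shared:
            label, _ = m.locations[sp].side()
            by_chrom.setdefault(label, set()).add(m.symbol)
        return tuple(
            frozenset(v) for _, v in sorted(by_chrom.items(), key=lambda kv: kv[0])
        )

    ba, bb = blocks(sp_a), blocks(sp_b)
    return PartitionComparison(
        species_a=sp_a,
        species_b=sp_b,
        markers=tuple(m.symbol for m in shared),
        blocks_a=ba,
        blocks_b=bb,
        partitions_identical=set(ba) == set(bb),
    )
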