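"""Inference of typed, phylogenetically polarized karyotype rearrangements.

From pairwise synteny segments this module classifies chromosome
correspondences (e.g. "the p and q arms of a bi-armed chromosome in one
species each match a distinct acrocentric chromosome in the other"),
polarizes the implied centric fusion/fission on a fixed species tree by
outgroup parsimony, detects tandem fusions from interstitial telomeric
sites (ITS) and micro-fusion products from micro-origin profiles, and
assembles the whole event scenario for a comparative map.

Polarity convention.  For a correspondence with a *joined* side J (the
bi-armed chromosome) and a *split* side S (the two acrocentrics), the
ancestral state is taken from the designated outgroup when its data are
decisive (the two blocks on disjoint chromosomes = split; both confined to
the same single chromosome = joined) and otherwise from the unanimous
state of all other sampled lineages.  A decisive outgroup contradicted by
a unanimous inner consensus yields an *ambiguous* event rather than a
forced call.  Ancestral split ⇒ centric fusion on J's branch; ancestral
joined ⇒ centric fission on S's branch.

Exact small-instance oracles (:func:`breakpoint_count`,
:func:`reversal_distance_exact`) support inversion reasoning on marker
orders; on band-free real data orders are row-order approximations and
inversion calls are emitted only as qualitative flags.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .cytomap import ComparativeMap, GeneMarker, KaryotypeDef, Landmark, SpeciesTree
from .homology import (
    DEFAULT_TOXICOFERA,
    MicroOriginProfile,
    SegmentHomology,
    _is_unanimous_micro,
    _witness_votes,
    micro_origin_profile,
    segment_table,
)
from .locations import band_sort_key

__all__ = [
    "ChromUnit",
    "CorrespondenceClass",
    "RearrangementEvent",
    "MarkerOrder",
    "ScenarioConfig",
    "classify_correspondence",
    "polarize_fusion_fission",
    "detect_tandem_fusion",
    "breakpoint_count",
    "reversal_distance_exact",
    "all_reversal_distances",
    "marker_order",
    "infer_scenario",
]


# ---------------------------------------------------------------------------
# units and correspondences
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class ChromUnit:
    """A chromosome or chromosome arm of one species."""

    species: str
    chromosome: str
    arm: str = "whole"  # p | q | whole

    def label(self, karyotypes: Mapping[str, KaryotypeDef] | None = None) -> str:
        """Display label, e.g. ``GHO14q`` or ``GHOZ`` for a Z-bearing label."""
        chrom = self.chromosome
        if karyotypes and self.species in karyotypes:
            entry = karyotypes[self.species].entry(chrom)
            if entry is not None and entry.sex == "Z":
                chrom = "Z"
        return f"{self.species}{chrom}" + ("" if self.arm == "whole" else self.arm)

    def proto_label(self, karyotypes=None) -> str:
        return f"proto-{self.label(karyotypes)}"


@dataclass(frozen=True)
class CorrespondenceClass:
    """How one (focal) chromosome corresponds to the partner species.

    ``arm_detail`` maps each focal arm carrying informative markers to the
    single partner unit it matches (present only when that resolution is
    clean); ``arm_support`` carries the witnessing gene symbols per arm.
    """

    species: str
    chromosome: str
    partner_species: str
    pattern: str  # one_to_one_whole | arms_to_two_wholes | whole_to_arm | segmental | unresolved
    arm_detail: Mapping[str, ChromUnit] = field(default_factory=dict)
    arm_support: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def pair(self) -> tuple[str, str]:
        partners = {u.chromosome for u in self.arm_detail.values()}
        return (self.chromosome, "+".join(sorted(partners)))


def _partner_arm_usage(segments: Sequence[SegmentHomology]) -> dict[str, set[str]]:
    """Which arms of each partner (side_a) chromosome carry markers."""
    usage: dict[str, set[str]] = {}
    for seg in segments:
        _, chrom, arm = seg.side_a
        if chrom != "Micro":
            usage.setdefault(chrom, set()).add(arm)
    return usage


def _collapse_unit(
    species: str, chrom: str, arms: set[str], usage: Mapping[str, set[str]]
) -> ChromUnit | None:
    """Reduce the (chromosome, arms) a focal arm matches to one unit.

    Arms of the same partner chromosome collapse to the whole chromosome;
    a single-arm match collapses to the whole chromosome when the partner
    has no markers anywhere else on it (an effectively one-armed
    chromosome written with or without its q).
    """
    arms = set(arms)
    if len(arms) > 1:
        return ChromUnit(species, chrom, "whole")
    arm = next(iter(arms))
    if arm == "whole":
        return ChromUnit(species, chrom, "whole")
    used_elsewhere = usage.get(chrom, set()) - {arm}
    if used_elsewhere:
        return ChromUnit(species, chrom, arm)
    return ChromUnit(species, chrom, "whole")


def classify_correspondence(
    segments: Sequence[SegmentHomology],
    karyotypes: Mapping[str, KaryotypeDef] | None = None,
) -> list[CorrespondenceClass]:
    """Classify every focal (side_b) chromosome of one species pair.

    ``arms_to_two_wholes``: the focal p and q arms each match exactly one
    partner unit and the two units lie on distinct partner chromosomes —
    the signature of a centric fusion/fission relating the two karyotypes.
    """
    if not segments:
        return []
    focal_sp = segments[0].side_b[0]
    partner_sp = segments[0].side_a[0]
    usage = _partner_arm_usage(segments)

    by_chrom: dict[str, list[SegmentHomology]] = {}
    for seg in segments:
        _, chrom, _ = seg.side_b
        if chrom != "Micro":
            by_chrom.setdefault(chrom, []).append(seg)

    classes = []
    for chrom in sorted(by_chrom, key=str):
        segs = by_chrom[chrom]
        # partner units per focal arm, ignoring anonymous-micro partners
        arm_to_chrom_arms: dict[str, dict[str, set[str]]] = {}
        arm_to_support: dict[str, list[str]] = {}
        for seg in segs:
            _, p_chrom, p_arm = seg.side_a
            _, _, f_arm = seg.side_b
            if p_chrom == "Micro":
                continue
            arm_to_chrom_arms.setdefault(f_arm, {}).setdefault(p_chrom, set()).add(p_arm)
            arm_to_support.setdefault(f_arm, []).extend(seg.support)

        arm_detail: dict[str, ChromUnit] = {}
        clean = True
        for f_arm, chrom_arms in arm_to_chrom_arms.items():
            if len(chrom_arms) == 1:
                (p_chrom, p_arms), = chrom_arms.items()
                unit = _collapse_unit(partner_sp, p_chrom, p_arms, usage)
                if unit is not None:
                    arm_detail[f_arm] = unit
                    continue
            clean = False

        # a centromere-spanning (whole-arm) marker is consistent with either
        # arm: tolerate it when its partner chromosome already backs one of
        # the armed units
        if (
            "whole" in arm_detail
            and len(arm_detail) > 1
            and arm_detail["whole"].chromosome
            in {u.chromosome for a, u in arm_detail.items() if a != "whole"}
        ):
            del arm_detail["whole"]
            arm_to_chrom_arms.pop("whole", None)

        informative_arms = set(arm_to_chrom_arms)
        if not informative_arms:
            pattern = "unresolved"
        elif not clean:
            pattern = "segmental"
        elif informative_arms == {"p", "q"}:
            up, uq = arm_detail["p"], arm_detail["q"]
            if up.chromosome != uq.chromosome:
                pattern = "arms_to_two_wholes"
            else:
                pattern = "whole_to_arm" if (up.arm != "whole" or uq.arm != "whole") else "one_to_one_whole"
        elif informative_arms == {"whole"} or len(informative_arms) == 1:
            unit = next(iter(arm_detail.values()))
            pattern = "one_to_one_whole" if unit.arm == "whole" else "whole_to_arm"
        else:
            pattern = "segmental"

        classes.append(
            CorrespondenceClass(
                species=focal_sp,
                chromosome=chrom,
                partner_species=partner_sp,
                pattern=pattern,
                arm_detail=arm_detail,
                arm_support={
                    a: tuple(sorted(set(s))) for a, s in arm_to_support.items()
                },
            )
        )
    return classes


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

_EVENT_KINDS = (
    "centric_fusion",
    "centric_fission",
    "tandem_fusion",
    "paracentric_inversion",
    "pericentric_inversion",
    "centromere_repositioning",
    "micro_fusion",
)


@dataclass(frozen=True)
class RearrangementEvent:
    """A typed karyotype rearrangement, polarized onto a tree branch when
    the evidence allows and flagged ambiguous (with the alternative
    placements listed) otherwise."""

    kind: str
    operands: tuple[str, ...]
    branch: str | None = None
    evidence: tuple[str, ...] = ()
    confidence: str = "polarized"  # polarized | ambiguous
    alternatives: tuple[str, ...] = ()
    #: marker content of each operand, for content-based identification
    operand_markers: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_KINDS:
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.confidence == "polarized" and self.branch is None:
            raise ValueError("a polarized event needs a branch")
        if self.confidence == "ambiguous" and not self.alternatives:
            raise ValueError("an ambiguous event must list its alternatives")

    def key(self) -> tuple:
        # branch is part of the identity: the same fusion arising
        # independently on two branches is two events, while one event
        # corroborated by several species pairs collapses to one
        return (self.kind, frozenset(self.operands), self.branch)


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------


def _markers_on_unit(cmap: ComparativeMap, unit: ChromUnit) -> list[GeneMarker]:
    out = []
    for m in cmap.markers:
        loc = m.locations.get(unit.species)
        if loc is None or not loc.resolved or loc.chromosome != unit.chromosome:
            continue
        if unit.arm == "whole" or loc.arm in (unit.arm, "whole"):
            out.append(m)
    return out


def _chrom_set(markers: Iterable[GeneMarker], species: str) -> set[str]:
    out = set()
    for m in markers:
        loc = m.locations.get(species)
        if loc is not None and loc.resolved:
            out.add(loc.chromosome)
    return out


def _joint_state(
    markers1: Sequence[GeneMarker], markers2: Sequence[GeneMarker], species: str
) -> str:
    """Witness state of one species for the character "block1 and block2
    joined on one chromosome"."""
    c1, c2 = _chrom_set(markers1, species), _chrom_set(markers2, species)
    if not c1 or not c2:
        return "unknown"
    if c1.isdisjoint(c2):
        return "split"
    if c1 == c2 and len(c1) == 1:
        return "joined"
    return "inconclusive"


def _branch_label(
    tree: SpeciesTree,
    species: str,
    excluding: str,
    tip_state,
    own_state: str,
) -> str:
    """Branch carrying a derived state observed in ``species``.

    With a lineage mapping, the stem of the species' major lineage (finer
    placement inside a polytomous lineage is not attempted).  Otherwise the
    stem of the largest clade containing the species, excluding the
    reference, whose sampled members share the derived state.
    """
    lineage = tree.lineage(species)
    if lineage != species:
        return lineage
    best = species
    for name, tips in tree.clades_toward(species, excluding=excluding):
        states = [tip_state(t) for t in tips if t != species]
        if all(s in (own_state, "unknown", "inconclusive") for s in states):
            best = name
        else:
            break
    return best


def _is_basal_side(tree: SpeciesTree, a: str, b: str) -> bool:
    """True iff species ``a`` attaches to the MRCA(a, b) as a bare tip while
    ``b`` sits inside an internal subclade (i.e. ``a`` is the basal side)."""
    mrca = tree._mrca(a, b)
    a_leaf = b_leaf = None
    for child in mrca.child_nodes():
        tips = tree.tips_under(child)
        if a in tips:
            a_leaf = child.is_leaf()
        if b in tips:
            b_leaf = child.is_leaf()
    return bool(a_leaf) and not b_leaf


def polarize_fusion_fission(
    corr: CorrespondenceClass,
    tree: SpeciesTree,
    cmap: ComparativeMap,
    karyotypes: Mapping[str, KaryotypeDef] | None = None,
    reference_species: str | None = None,
) -> RearrangementEvent:
    """Polarize an ``arms_to_two_wholes`` correspondence into a centric
    fusion (ancestral state split) or fission (ancestral state joined).

    ``reference_species`` controls proto-chromosome naming: when the joined
    side is the reference, operands are named by its own arms
    (``proto-<X>p`` / ``proto-<X>q``); otherwise by the split-side units.
    """
    if corr.pattern != "arms_to_two_wholes":
        raise ValueError(
            f"cannot polarize a {corr.pattern!r} correspondence; "
            "need arms_to_two_wholes"
        )
    j_sp, s_sp = corr.species, corr.partner_species
    unit_p, unit_q = corr.arm_detail["p"], corr.arm_detail["q"]
    block_p = _markers_on_unit(cmap, unit_p)
    block_q = _markers_on_unit(cmap, unit_q)

    def tip_state(sp: str) -> str:
        if sp == j_sp:
            return "joined"
        if sp == s_sp:
            return "split"
        return _joint_state(block_p, block_q, sp)

    out_sp = tree.outgroup
    out_state = tip_state(out_sp)

    def _consensus(species: Iterable[str]) -> str:
        states = {tip_state(sp) for sp in species} & {"split", "joined"}
        return next(iter(states)) if len(states) == 1 else "unknown"

    # witnesses attaching between the root and the pair's MRCA speak
    # directly to the ancestral state; members of either side's own clade
    # may share that side's derived state, so they only decide (by
    # unanimity) when nothing closer to the root does
    basal = [
        sp
        for sp in tree.witnesses_outside(j_sp, s_sp)
        if sp != out_sp
    ]
    peripheral = [
        sp
        for sp in tree.species
        if sp not in basal and sp not in (j_sp, s_sp, out_sp)
    ]
    basal_consensus = _consensus(basal)
    peripheral_consensus = _consensus(peripheral)

    if out_state in ("split", "joined") and basal_consensus in ("split", "joined") \
            and out_state != basal_consensus:
        ancestral = "conflict"
    elif out_state in ("split", "joined"):
        ancestral = out_state
    elif basal_consensus in ("split", "joined"):
        ancestral = basal_consensus
    elif peripheral_consensus in ("split", "joined"):
        ancestral = peripheral_consensus
    else:
        ancestral = "unknown"

    # operand naming and content
    if reference_species is not None and j_sp == reference_species:
        names = (
            ChromUnit(j_sp, corr.chromosome, "p").proto_label(karyotypes),
            ChromUnit(j_sp, corr.chromosome, "q").proto_label(karyotypes),
        )
        contents = (
            frozenset(m.symbol for m in _markers_on_unit(cmap, ChromUnit(j_sp, corr.chromosome, "p"))),
            frozenset(m.symbol for m in _markers_on_unit(cmap, ChromUnit(j_sp, corr.chromosome, "q"))),
        )
    else:
        names = (unit_p.proto_label(karyotypes), unit_q.proto_label(karyotypes))
        contents = (
            frozenset(m.symbol for m in block_p),
            frozenset(m.symbol for m in block_q),
        )
    evidence = tuple(
        sorted(set(corr.arm_support.get("p", ())) | set(corr.arm_support.get("q", ())))
    )

    if ancestral == "split":
        branch = _branch_label(tree, j_sp, s_sp, tip_state, "joined")
        return RearrangementEvent(
            kind="centric_fusion",
            operands=names,
            branch=branch,
            evidence=evidence,
            operand_markers=contents,
        )
    if ancestral == "joined":
        branch = _branch_label(tree, s_sp, j_sp, tip_state, "split")
        return RearrangementEvent(
            kind="centric_fission",
            operands=names,
            branch=branch,
            evidence=evidence,
            operand_markers=contents,
        )
    alts = (
        f"centric_fusion@{tree.lineage(j_sp)}",
        f"centric_fission@{tree.lineage(s_sp)}",
    )
    return RearrangementEvent(
        kind="centric_fusion",
        operands=names,
        branch=None,
        evidence=evidence,
        confidence="ambiguous",
        alternatives=alts,
        operand_markers=contents,
    )


# ---------------------------------------------------------------------------
# tandem fusions and micro-fusion products
# ---------------------------------------------------------------------------


def detect_tandem_fusion(
    landmarks: Sequence[Landmark],
    profiles: Sequence[MicroOriginProfile],
    cmap: ComparativeMap,
    tree: SpeciesTree | None = None,
    toxicofera: Sequence[str] = DEFAULT_TOXICOFERA,
    chicken: str = "GGA",
) -> list[RearrangementEvent]:
    """Tandem-fusion events from ITS relics and micro-fusion products from
    micro-origin profiles, for one focal species.

    An ITS on a chromosome whose other material includes a micro-derived
    arm marks the junction where a microchromosome fused end-on to an
    acrocentric proto-chromosome.  A chromosome classified ``all_micro``
    whose genes span ≥2 distinct chicken chromosomes is itself a fusion
    product of several ancestral microchromosomes.
    """
    events: list[RearrangementEvent] = []
    species = {p.species for p in profiles} | {lm.species for lm in landmarks}
    if len(species) > 1:
        raise ValueError(f"landmarks/profiles span several species: {sorted(species)}")
    if not species:
        return events
    sp = next(iter(species))
    branch = tree.lineage(sp) if tree is not None else sp

    for lm in sorted(
        (lm for lm in landmarks if lm.kind == "ITS"),
        key=lambda lm: str(lm.location.chromosome),
    ):
        chrom = lm.location.chromosome
        for arm, other in (("p", "q"), ("q", "p")):
            arm_markers = [
                m
                for m in _markers_on_unit(cmap, ChromUnit(sp, chrom, arm))
                if m.locations[sp].arm == arm
            ]
            micro_derived = [
                m
                for m in arm_markers
                if _is_unanimous_micro(_witness_votes(m, toxicofera))
            ]
            if micro_derived:
                events.append(
                    RearrangementEvent(
                        kind="tandem_fusion",
                        operands=(
                            f"{sp}{chrom}{arm}",
                            f"proto-{sp}{chrom}{other}",
                        ),
                        branch=branch,
                        evidence=tuple(
                            sorted(m.symbol for m in micro_derived)
                        )
                        + (f"ITS:{sp}{chrom}",),
                        operand_markers=(
                            frozenset(m.symbol for m in micro_derived),
                            frozenset(
                                m.symbol
                                for m in _markers_on_unit(cmap, ChromUnit(sp, chrom, other))
                            ),
                        ),
                    )
                )
                break  # one tandem fusion per ITS

    for prof in sorted(profiles, key=lambda p: str(p.chromosome)):
        if prof.classification != "all_micro" or prof.segment_count < 2:
            continue
        markers = cmap.markers_on(sp, prof.chromosome)
        chicken_chroms = sorted(
            {
                m.locations[chicken].chromosome
                for m in markers
                if chicken in m.locations and m.locations[chicken].resolved
            },
            key=lambda c: (len(c), c),
        )
        events.append(
            RearrangementEvent(
                kind="micro_fusion",
                operands=tuple(f"micro({chicken}{c})" for c in chicken_chroms),
                branch=branch,
                evidence=tuple(sorted(m.symbol for m in markers)),
                operand_markers=tuple(
                    frozenset(
                        m.symbol
                        for m in markers
                        if chicken in m.locations
                        and m.locations[chicken].resolved
                        and m.locations[chicken].chromosome == c
                    )
                    for c in chicken_chroms
                ),
            )
        )
    return events


# ---------------------------------------------------------------------------
# marker orders and inversion oracles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerOrder:
    """Ordered marker symbols along a chromosome (centromere→telomere
    within each arm)."""

    species: str
    chromosome: str
    arm: str
    markers: tuple[str, ...]
    provenance: str  # explicit_rank | band_order | row_order

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate markers in order")
        if self.provenance not in ("explicit_rank", "band_order", "row_order"):
            raise ValueError(f"bad provenance {self.provenance!r}")

    def restrict(self, symbols: Iterable[str]) -> "MarkerOrder":
        keep = set(symbols)
        return replace(self, markers=tuple(m for m in self.markers if m in keep))


def marker_order(
    cmap: ComparativeMap,
    species: str,
    chromosome: str,
    arm: str | None = None,
) -> MarkerOrder:
    """Derive a marker order: explicit rank column if present, else band
    positions when every marker carries one, else fixture row order."""
    entries = []
    for idx, m in enumerate(cmap.markers):
        loc = m.locations.get(species)
        if loc is None or not loc.resolved or loc.chromosome != chromosome:
            continue
        if arm is not None and loc.arm != arm:
            continue
        entries.append((idx, m, loc))
    if not entries:
        return MarkerOrder(species, chromosome, arm or "whole", (), "row_order")

    if all(species in m.ranks for _, m, _ in entries):
        entries.sort(key=lambda e: (e[1].ranks[species], e[0]))
        prov = "explicit_rank"
    elif all(loc.band_start is not None for _, _, loc in entries):
        entries.sort(
            key=lambda e: (
                e[2].arm,
                band_sort_key(e[2].band_start),
                band_sort_key(e[2].band_end) if e[2].band_end else (),
                e[0],
            )
        )
        prov = "band_order"
    else:
        prov = "row_order"
    return MarkerOrder(
        species, chromosome, arm or "whole", tuple(m.symbol for _, m, _ in entries), prov
    )


_END = object()


def _adjacencies(order: Sequence) -> set[frozenset]:
    seq = [_END, *order, _END]
    return {frozenset((seq[i], seq[i + 1])) for i in range(len(seq) - 1)}


def breakpoint_count(order_a: MarkerOrder, order_b: MarkerOrder) -> int:
    """Adjacencies of ``order_a`` (with free virtual ends) absent from
    ``order_b`` in either orientation; 0 iff the orders are identical or
    exactly reversed."""
    if set(order_a.markers) != set(order_b.markers):
        raise ValueError("breakpoint_count needs orders over the same marker set")
    adj_b = _adjacencies(order_b.markers)
    return sum(1 for adj in _adjacencies(order_a.markers) if adj not in adj_b)


_MAX_EXACT_N = 8


def _as_permutation(perm, reference=None) -> tuple[int, ...]:
    if isinstance(perm, MarkerOrder):
        if reference is None:
            raise ValueError("a MarkerOrder needs a reference order")
        ref = reference.markers if isinstance(reference, MarkerOrder) else tuple(reference)
        if set(perm.markers) != set(ref):
            raise ValueError("order and reference cover different markers")
        pos = {sym: i for i, sym in enumerate(ref)}
        return tuple(pos[sym] for sym in perm.markers)
    return tuple(perm)


def reversal_distance_exact(perm, reference=None) -> int:
    """Minimum number of segment reversals sorting an unsigned permutation,
    by breadth-first search over the permutation group (n ≤ 8 only)."""
    p = _as_permutation(perm, reference)
    n = len(p)
    if sorted(p) != list(range(n)):
        raise ValueError("not a permutation of 0..n-1")
    if n > _MAX_EXACT_N:
        raise ValueError(
            f"exact reversal distance is limited to n ≤ {_MAX_EXACT_N} "
            f"(got n = {n}); the search space grows as n!"
        )
    target = tuple(range(n))
    if p == target:
        return 0
    seen = {p}
    frontier = deque([(p, 0)])
    while frontier:
        cur, d = frontier.popleft()
        for i in range(n - 1):
            for j in range(i + 1, n):
                nxt = cur[:i] + cur[i : j + 1][::-1] + cur[j + 1 :]
                if nxt == target:
                    return d + 1
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append((nxt, d + 1))
    raise AssertionError("unreachable: reversals generate the symmetric group")


def all_reversal_distances(n: int) -> dict[tuple[int, ...], int]:
    """Reversal distance from the identity for every permutation of size n
    (single BFS; the distance is symmetric)."""
    if n > _MAX_EXACT_N:
        raise ValueError(f"n ≤ {_MAX_EXACT_N} only")
    start = tuple(range(n))
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        cur = frontier.popleft()
        d = dist[cur]
        for i in range(n - 1):
            for j in range(i + 1, n):
                nxt = cur[:i] + cur[i : j + 1][::-1] + cur[j + 1 :]
                if nxt not in dist:
                    dist[nxt] = d + 1
                    frontier.append(nxt)
    return dist


# ---------------------------------------------------------------------------
# whole-scenario inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Which comparisons feed scenario inference.

    ``pairs`` are (reference-like, derived-like) species pairs; both sides
    of each pair are scanned for fusion products.  ``focal_species`` get
    ITS/micro-fusion detection.  ``reference_species`` fixes the
    proto-chromosome naming frame.
    """

    pairs: tuple[tuple[str, str], ...]
    focal_species: tuple[str, ...] = ()
    toxicofera: tuple[str, ...] = DEFAULT_TOXICOFERA
    reference_species: str | None = None
    chicken: str = "GGA"
    min_inversion_shared: int = 3
    annotate_centromere_repositioning: bool = False


def default_config(cmap: ComparativeMap) -> ScenarioConfig:
    """The study-panel configuration when the roster matches the packaged
    fixture; otherwise a minimal all-vs-first configuration."""
    roster = set(cmap.species_roster)
    if {"GHO", "LAG", "LRE", "GGA"} <= roster:
        return ScenarioConfig(
            pairs=(("GHO", "LRE"), ("GHO", "LAG")),
            focal_species=("GHO",),
            reference_species="GHO",
        )
    ref = cmap.species_roster[0]
    return ScenarioConfig(
        pairs=tuple((ref, sp) for sp in cmap.species_roster[1:]),
        focal_species=(),
    )


def _containment_fusions(
    cmap: ComparativeMap,
    karyotypes: Mapping[str, KaryotypeDef],
    tree: SpeciesTree,
    focal_sp: str,
    partner_sp: str,
    skip_chromosomes: set[str],
) -> list[RearrangementEvent]:
    """Morphology-based fusion detector.

    A metacentric/submetacentric focal chromosome with markers on both arms
    whose entire mapped content lies on a single *acrocentric* partner
    chromosome gained its second arm by centric fusion on the focal branch:
    arms do not appear without a rearrangement, and the acrocentric partner
    shows the ancestral one-armed state of the shared material.
    """
    events = []
    karyo = karyotypes.get(focal_sp)
    if karyo is None:
        return events
    for chrom in sorted(cmap.chromosomes_of(focal_sp), key=str):
        if chrom in skip_chromosomes:
            continue
        entry = karyo.entry(chrom)
        if entry is None or entry.morphology not in ("metacentric", "submetacentric"):
            continue
        markers = cmap.markers_on(focal_sp, chrom)
        arms = {m.locations[focal_sp].arm for m in markers}
        if not {"p", "q"} <= arms:
            continue
        partner_chroms = _chrom_set(markers, partner_sp)
        mapped_in_partner = [
            m
            for m in markers
            if partner_sp in m.locations and m.locations[partner_sp].resolved
        ]
        if len(partner_chroms) != 1 or len(mapped_in_partner) < 2:
            continue
        p_chrom = next(iter(partner_chroms))
        p_entry = karyotypes.get(partner_sp, karyo).entry(p_chrom)
        if p_entry is None or not p_entry.is_acrocentric:
            continue
        partner_unit = ChromUnit(partner_sp, p_chrom, "whole")
        events.append(
            RearrangementEvent(
                kind="centric_fusion",
                operands=(
                    f"proto-{focal_sp}{chrom}q",
                    partner_unit.proto_label(karyotypes),
                ),
                branch=tree.lineage(focal_sp),
                evidence=tuple(sorted(m.symbol for m in mapped_in_partner)),
                operand_markers=(
                    frozenset(
                        m.symbol for m in markers if m.locations[focal_sp].arm == "q"
                    ),
                    frozenset(m.symbol for m in mapped_in_partner),
                ),
            )
        )
    return events


def _inversion_flags(
    cmap: ComparativeMap,
    segments: Sequence[SegmentHomology],
    tree: SpeciesTree,
    min_shared: int,
) -> list[RearrangementEvent]:
    events = []
    for seg in segments:
        sp_a, chrom_a, arm_a = seg.side_a
        sp_b, chrom_b, arm_b = seg.side_b
        if chrom_a == "Micro" or chrom_b == "Micro" or seg.support_count < min_shared:
            continue
        oa = marker_order(cmap, sp_a, chrom_a, None if arm_a == "whole" else arm_a)
        ob = marker_order(cmap, sp_b, chrom_b, None if arm_b == "whole" else arm_b)
        shared = set(seg.support) & set(oa.markers) & set(ob.markers)
        if len(shared) < min_shared:
            continue
        oa_r, ob_r = oa.restrict(shared), ob.restrict(shared)
        if breakpoint_count(oa_r, ob_r) == 0:
            continue
        label_a = ChromUnit(sp_a, chrom_a, arm_a).label()
        label_b = ChromUnit(sp_b, chrom_b, arm_b).label()
        events.append(
            RearrangementEvent(
                kind="paracentric_inversion",
                operands=(label_a, label_b),
                branch=None,
                evidence=tuple(sorted(shared)),
                confidence="ambiguous",
                alternatives=(
                    f"inversion@{tree.lineage(sp_a)}",
                    f"inversion@{tree.lineage(sp_b)}",
                ),
            )
        )
    return events


def infer_scenario(
    cmap: ComparativeMap,
    karyotypes: Mapping[str, KaryotypeDef],
    landmarks: Sequence[Landmark],
    tree: SpeciesTree,
    config: ScenarioConfig | None = None,
) -> list[RearrangementEvent]:
    """Run the full inference pipeline and return the deduplicated,
    deterministically ordered event scenario."""
    if config is None:
        config = default_config(cmap)
    for a, b in config.pairs:
        for sp in (a, b):
            if sp not in cmap.species_roster:
                raise ValueError(f"species {sp!r} required by config is not in the map")
    tree.validate_roster(cmap.species_roster)

    events: list[RearrangementEvent] = []
    for a, b in config.pairs:
        for ref_sp, focal_sp in ((a, b), (b, a)):
            segs = segment_table(cmap, ref_sp, focal_sp)
            classes = classify_correspondence(segs, karyotypes)
            fused_here: set[str] = set()
            for corr in classes:
                if corr.pattern != "arms_to_two_wholes":
                    continue
                fused_here.add(corr.chromosome)
                events.append(
                    polarize_fusion_fission(
                        corr,
                        tree,
                        cmap,
                        karyotypes,
                        reference_species=config.reference_species,
                    )
                )
            events.extend(
                _containment_fusions(
                    cmap, karyotypes, tree, focal_sp, ref_sp, fused_here
                )
            )
        events.extend(
            _inversion_flags(
                cmap, segment_table(cmap, a, b), tree, config.min_inversion_shared
            )
        )

    for sp in config.focal_species:
        profiles = micro_origin_profile(
            cmap, sp, config.toxicofera, chicken=config.chicken
        )
        events.extend(
            detect_tandem_fusion(
                [lm for lm in landmarks if lm.species == sp],
                profiles,
                cmap,
                tree=tree,
                toxicofera=config.toxicofera,
                chicken=config.chicken,
            )
        )

    # deduplicate on (kind, operand set); first occurrence wins
    seen: set = set()
    unique = []
    for ev in events:
        if ev.key() in seen:
            continue
        seen.add(ev.key())
        unique.append(ev)
    unique.sort(key=lambda e: (e.branch or "~", e.operands, e.kind))
    return unique
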