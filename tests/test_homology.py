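"""Synteny segments, avian-unit conservation, micro-origin accounting."""

import pytest

from karyosynth.cytomap import SpeciesTree
from karyosynth.homology import (
    AvianMacroUnitSet,
    conserved_macro_chromosomes,
    hit_units,
    lineage_partition_overlap,
    micro_derived_markers,
    micro_origin_profile,
    segment_table,
)
from karyosynth.simulate import SimConfig, evolve

from conftest import make_sim


# -- segment tables ---------------------------------------------------------


def test_gho7_gga4q_segment(fixture_map):
    segs = segment_table(fixture_map, "GHO", "GGA")
    hit = [s for s in segs if s.side_a[1:] == ("7", "whole")]
    assert len(hit) == 1
    assert hit[0].side_b[1:] == ("4", "q")
    assert hit[0].support_count == 6


def test_gho13_links_lre3q(fixture_map):
    segs = segment_table(fixture_map, "GHO", "LRE")
    assert any(
        s.side_a[1] == "13" and s.side_b[1:] == ("3", "q") for s in segs
    )


def test_segment_table_same_species_rejected(fixture_map):
    with pytest.raises(ValueError, match="distinct"):
        segment_table(fixture_map, "GHO", "GHO")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_segment_symmetry_and_support_conservation(sim_tree, seed):
    """segment_table(A,B) equals segment_table(B,A) with sides swapped, and
    support counts sum to the number of markers mapped in both species."""
    cmap, _, _ = make_sim(
        sim_tree,
        seed=seed,
        branch_events={
            "SPA": [{"kind": "centric_fusion"}, {"kind": "tandem_fusion"}],
            "SPB": [{"kind": "inversion"}, {"kind": "tandem_fusion"}],
        },
    )
    ab = segment_table(cmap, "SPA", "SPB")
    ba = segment_table(cmap, "SPB", "SPA")
    assert {(s.side_a, s.side_b, s.support) for s in ab} == {
        (s.side_b, s.side_a, s.support) for s in ba
    }
    n_both = sum(
        1
        for m in cmap.markers
        if m.locations["SPA"].mapped and m.locations["SPB"].mapped
    )
    assert sum(s.support_count for s in ab) == n_both


def test_fixture_support_conservation(fixture_map):
    segs = segment_table(fixture_map, "GHO", "LRE")
    n_both = sum(
        1
        for m in fixture_map.markers
        if m.locations["GHO"].mapped and m.locations["LRE"].mapped
    )
    assert sum(s.support_count for s in segs) == n_both


# -- avian macro units ------------------------------------------------------


def test_conserved_macro_chromosomes_default(fixture_map):
    assert conserved_macro_chromosomes(fixture_map, "GHO") == {
        "1", "2", "3", "4", "6", "7", "8", "13", "14", "15",
    }


def test_conserved_macro_empty_units(fixture_map):
    assert conserved_macro_chromosomes(
        fixture_map, "GHO", AvianMacroUnitSet(frozenset())
    ) == set()


def test_conserved_macro_single_arm_unit(fixture_map):
    # GGA4p carries only CUL4B/ATRX/AR, all on chromosome 5 of the gecko
    assert conserved_macro_chromosomes(
        fixture_map, "GHO", AvianMacroUnitSet(frozenset({"4p"}))
    ) == {"5"}


def test_unit_set_rejects_arm_whole_clash():
    with pytest.raises(ValueError, match="4"):
        AvianMacroUnitSet(frozenset({"4", "4q"}))


def test_arm_gene_matches_whole_unit_but_not_conversely():
    units = AvianMacroUnitSet(frozenset({"2"}))
    assert units.matches("2", "p")
    assert units.matches("2", "whole")
    arm_units = AvianMacroUnitSet(frozenset({"2p"}))
    assert arm_units.matches("2", "p")
    assert not arm_units.matches("2", "whole")  # arm units need arm data


def test_hit_units_all_eleven(fixture_map):
    assert hit_units(fixture_map, "GHO") == {
        "1p", "1q", "2p", "2q", "3", "4q", "5", "6", "7", "8", "Z",
    }
    assert hit_units(fixture_map, "GHO", AvianMacroUnitSet(frozenset({"Z"}))) == {"Z"}
    assert hit_units(fixture_map, "GHO", AvianMacroUnitSet(frozenset())) == set()


def test_conserved_monotone_in_unit_set(fixture_map):
    default = AvianMacroUnitSet()
    full = conserved_macro_chromosomes(fixture_map, "GHO", default)
    units = sorted(default.units)
    for k in range(len(units)):
        subset = AvianMacroUnitSet(frozenset(units[:k]))
        sub = conserved_macro_chromosomes(fixture_map, "GHO", subset)
        assert sub <= full


# -- micro-origin profiles --------------------------------------------------


def test_micro_origin_classifications(fixture_map):
    profiles = {p.chromosome: p for p in micro_origin_profile(fixture_map, "GHO")}
    all_micro = {c for c, p in profiles.items() if p.classification == "all_micro"}
    assert all_micro == {"5", "9", "10", "11"}
    assert profiles["6"].classification == "mixed"
    assert profiles["16"].classification == "insufficient"
    # segment counts: distinct chicken chromosomes among the genes
    assert profiles["5"].segment_count == 2
    assert profiles["9"].segment_count == 3
    assert profiles["11"].segment_count == 1


def test_all_micro_never_carries_toxicofera_macro_gene(fixture_map):
    """Unanimity invariant: a chromosome classified all_micro has no gene
    located on a macrochromosome in any Toxicofera witness."""
    for prof in micro_origin_profile(fixture_map, "GHO"):
        if prof.classification != "all_micro":
            continue
        for votes in prof.evidence.values():
            assert "macro" not in votes.values(), prof.chromosome


def test_micro_origin_requires_witnesses(fixture_map):
    with pytest.raises(ValueError, match="witness"):
        micro_origin_profile(fixture_map, "GHO", toxicofera=())


def test_lag6_is_micro_composed(fixture_map):
    profiles = {p.chromosome: p for p in micro_origin_profile(fixture_map, "LAG")}
    assert profiles["6"].classification == "all_micro"


# -- lineage partitions -----------------------------------------------------


def test_partition_gecko_vs_lacertid_not_identical(fixture_map):
    cmp = lineage_partition_overlap(fixture_map, "GHO", "LAG")
    assert not cmp.partitions_identical
    # LAG6's markers split over two gecko chromosomes
    lag6 = {"TMEM57", "RNF19B", "ENO1", "DNM1", "PPP2R1A", "GRIN1"}
    assert any(lag6 <= b for b in cmp.blocks_b)
    assert not any(lag6 <= b for b in cmp.blocks_a)


def test_partition_self_identical(fixture_map):
    assert lineage_partition_overlap(fixture_map, "GHO", "GHO").partitions_identical


def test_partition_requires_shared_markers():
    from karyosynth.cytomap import ComparativeMap, GeneMarker
    from karyosynth.locations import parse_location

    markers = tuple(
        GeneMarker(
            symbol=sym,
            origin_species="A",
            seq_lengths=(),
            accessions=(),
            locations={
                "A": parse_location("1", "A"),
                "B": parse_location("2", "B"),
                "W": parse_location("3", "W"),  # macro everywhere: no micros
            },
        )
        for sym in ("g1", "g2")
    )
    cmap = ComparativeMap(species_roster=("A", "B", "W"), markers=markers)
    with pytest.raises(ValueError, match="no shared"):
        lineage_partition_overlap(cmap, "A", "B", toxicofera=("W",))


def test_shared_ancestral_fusion_gives_identical_partitions():
    """Micros fused on a shared internal branch leave identical partitions
    in the two descendant tips; independent fusions do not."""
    tree = SpeciesTree("(OUT,(REF,(SPA,SPB)AB)Inner)Root;", outgroup="OUT")
    shared = SimConfig(
        n_macro=6,
        n_micro=3,
        markers_per_macro=2,
        markers_per_micro=2,
        branch_events={
            "AB": [
                {"kind": "tandem_fusion", "operands": ["m01", "M01"]},
                {"kind": "tandem_fusion", "operands": ["m02", "M03"]},
            ]
        },
        seed=5,
    )
    cmap, _, _ = evolve(shared, tree)
    cmp = lineage_partition_overlap(cmap, "SPA", "SPB", toxicofera=("OUT",))
    assert cmp.partitions_identical

    independent = SimConfig(
        n_macro=6,
        n_micro=3,
        markers_per_macro=2,
        markers_per_micro=2,
        branch_events={
            "SPA": [{"kind": "tandem_fusion", "operands": ["m01", "M01"]}],
            "SPB": [{"kind": "tandem_fusion", "operands": ["m02", "M03"]}],
        },
        seed=5,
    )
    cmap2, _, _ = evolve(independent, tree)
    cmp2 = lineage_partition_overlap(cmap2, "SPA", "SPB", toxicofera=("OUT",))
    assert not cmp2.partitions_identical


def test_micro_derived_filter_matches_discussion_genes(fixture_map):
    symbols = {m.symbol for m in micro_derived_markers(fixture_map)}
    # the LAG6 block and the anonymous micro-group markers are all included
    assert {"TMEM57", "RNF19B", "ENO1", "HSPA8", "ACTN4"} <= symbols
    # genes with a Toxicofera macrochromosome assignment are excluded
    assert "EEF2" not in symbols and "TRIM37" not in symbols
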