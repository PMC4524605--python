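"""Comparative gene-location tables, karyotype definitions, landmarks, trees.

The central container is :class:`ComparativeMap`: an ordered list of gene
markers, each with one parsed :class:`~karyosynth.locations.ChromLocation`
per species.  Everything reads and writes plain TSV so that a map can be
assembled in a spreadsheet, diffed, and round-tripped without loss
(``read_map(write_map(m)) == m`` field for field).

The package ships a fixture map of 86 protein-coding markers FISH-mapped in
the Hokou gecko (GHO) with ortholog locations in the sand lizard (LAG),
water monitor (VSA), butterfly lizard (LRE), four-striped rat snake (EQU),
green anole (ACA) and chicken (GGA), together with karyotype definitions,
rDNA/ITS landmarks and the study species tree.  Loaders: :func:`load_fixture`.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

import dendropy
import pandas as pd

from .locations import (
    ChromLocation,
    LocationParseError,
    format_location,
    parse_location,
)

__all__ = [
    "GeneMarker",
    "ComparativeMap",
    "ChromEntry",
    "KaryotypeDef",
    "Landmark",
    "SpeciesTree",
    "MapFormatError",
    "read_map",
    "write_map",
    "read_karyotypes",
    "read_karyotype",
    "write_karyotypes",
    "read_landmarks",
    "write_landmarks",
    "read_tree",
    "load_fixture",
    "FixtureBundle",
    "SPECIES_TOKENS",
]

#: fixed species tokens of the study panel, in roster order
SPECIES_TOKENS = ("GHO", "LAG", "VSA", "LRE", "EQU", "ACA", "GGA")

_MAP_FIXED_COLS = ("symbol", "origin", "length_bp", "accessions")
_MORPHOLOGIES = (
    "metacentric",
    "submetacentric",
    "subtelocentric",
    "acrocentric",
    "micro",
)


class MapFormatError(ValueError):
    """A structural problem in an input table (not a cell-level parse error)."""


# ---------------------------------------------------------------------------
# comparative map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneMarker:
    """One gene marker row: probe provenance plus per-species locations."""

    symbol: str
    origin_species: str
    seq_lengths: tuple[int, ...]
    accessions: tuple[str, ...]
    locations: Mapping[str, ChromLocation]
    previously_mapped: bool = False
    #: optional explicit within-chromosome ranks (centromere→telomere)
    ranks: Mapping[str, int] = field(default_factory=dict)

    def location(self, species: str) -> ChromLocation:
        return self.locations[species]


@dataclass(frozen=True)
class ComparativeMap:
    """Ordered gene markers × species cytogenetic locations."""

    species_roster: tuple[str, ...]
    markers: tuple[GeneMarker, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for m in self.markers:
            if m.symbol in seen:
                raise MapFormatError(f"duplicate marker symbol {m.symbol!r}")
            seen.add(m.symbol)
            for sp in m.locations:
                if sp not in self.species_roster:
                    raise MapFormatError(
                        f"marker {m.symbol}: location for {sp!r} not in roster"
                    )

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, symbol: str) -> GeneMarker:
        for m in self.markers:
            if m.symbol == symbol:
                return m
        raise KeyError(symbol)

    def require_species(self, *species: str) -> None:
        for sp in species:
            if sp not in self.species_roster:
                raise MapFormatError(f"species {sp!r} not in roster")

    def markers_on(self, species: str, chromosome: str) -> list[GeneMarker]:
        """Markers mapped to an identified chromosome of ``species``."""
        out = []
        for m in self.markers:
            loc = m.locations.get(species)
            if loc is not None and loc.resolved and loc.chromosome == chromosome:
                out.append(m)
        return out

    def chromosomes_of(self, species: str) -> list[str]:
        """Identified chromosome labels of ``species`` carrying ≥1 marker."""
        seen: dict[str, None] = {}
        for m in self.markers:
            loc = m.locations.get(species)
            if loc is not None and loc.resolved:
                seen.setdefault(loc.chromosome, None)
        return list(seen)

    def subset_species(self, species: Iterable[str]) -> "ComparativeMap":
        keep = tuple(sp for sp in self.species_roster if sp in set(species))
        markers = tuple(
            GeneMarker(
                symbol=m.symbol,
                origin_species=m.origin_species,
                seq_lengths=m.seq_lengths,
                accessions=m.accessions,
                locations={sp: m.locations[sp] for sp in keep if sp in m.locations},
                previously_mapped=m.previously_mapped,
                ranks={sp: r for sp, r in m.ranks.items() if sp in keep},
            )
            for m in self.markers
        )
        return ComparativeMap(species_roster=keep, markers=markers)


def _split_ints(cell: str) -> tuple[int, ...]:
    cell = str(cell).strip()
    if not cell or cell.lower() == "nan":
        return ()
    return tuple(int(x.strip().replace(",", "")) for x in re.split(r"[;|]", cell))


def _split_strs(cell: str) -> tuple[str, ...]:
    cell = str(cell).strip()
    if not cell or cell.lower() == "nan":
        return ()
    return tuple(x.strip() for x in re.split(r"[;|,]", cell) if x.strip())


def read_map(source: str | IO[str]) -> ComparativeMap:
    """Read a comparative map TSV.

    Columns: ``symbol, origin, length_bp, accessions`` then one column per
    species token; optional ``previously_mapped`` flag column and optional
    ``rank_<species>`` integer columns (explicit marker order overriding row
    order).  Sequence lengths and accessions are ``;``-separated when a
    marker was sequenced as two clones.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    for c in _MAP_FIXED_COLS:
        if c not in cols:
            raise MapFormatError(f"missing required column {c!r}")
    extra = [c for c in cols if c not in _MAP_FIXED_COLS]
    rank_cols = [c for c in extra if c.startswith("rank_")]
    flag_cols = [c for c in extra if c == "previously_mapped"]
    roster = tuple(c for c in extra if c not in rank_cols and c not in flag_cols)
    if not roster:
        raise MapFormatError("no species columns found")
    for rc in rank_cols:
        if rc[len("rank_"):] not in roster:
            raise MapFormatError(f"rank column {rc!r} names an unknown species")

    markers = []
    for _, row in df.iterrows():
        symbol = row["symbol"].strip()
        locations = {}
        for sp in roster:
            try:
                locations[sp] = parse_location(row[sp], sp, context=f"row {symbol}")
            except LocationParseError:
                raise
        ranks = {}
        for rc in rank_cols:
            val = str(row[rc]).strip()
            if val:
                ranks[rc[len("rank_"):]] = int(val)
        markers.append(
            GeneMarker(
                symbol=symbol,
                origin_species=row["origin"].strip(),
                seq_lengths=_split_ints(row["length_bp"]),
                accessions=_split_strs(row["accessions"]),
                locations=locations,
                previously_mapped=(
                    str(row["previously_mapped"]).strip() in ("1", "true", "True")
                    if flag_cols
                    else False
                ),
                ranks=ranks,
            )
        )
    return ComparativeMap(species_roster=roster, markers=tuple(markers))


def write_map(cmap: ComparativeMap, dest: str | IO[str]) -> None:
    """Write a comparative map as canonical TSV (see :func:`read_map`)."""
    has_ranks = sorted({sp for m in cmap.markers for sp in m.ranks})
    rows = []
    for m in cmap.markers:
        row = {
            "symbol": m.symbol,
            "origin": m.origin_species,
            "length_bp": ";".join(str(x) for x in m.seq_lengths),
            "accessions": ";".join(m.accessions),
            "previously_mapped": "1" if m.previously_mapped else "0",
        }
        for sp in cmap.species_roster:
            loc = m.locations.get(sp)
            row[sp] = format_location(loc) if loc is not None else ""
        for sp in has_ranks:
            row[f"rank_{sp}"] = str(m.ranks[sp]) if sp in m.ranks else ""
        rows.append(row)
    cols = (
        list(_MAP_FIXED_COLS)
        + ["previously_mapped"]
        + list(cmap.species_roster)
        + [f"rank_{sp}" for sp in has_ranks]
    )
    pd.DataFrame(rows, columns=cols).to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# karyotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromEntry:
    """One chromosome of a karyotype definition.

    ``copies`` is the count contributed to 2n: 2 for an autosome pair, 1
    for each of Z and W in a heterogametic (ZW female) karyotype.
    """

    label: str
    morphology: str
    size_class: str  # macro | micro
    copies: int = 2
    sex: str = ""  # "", "Z", "W"

    def __post_init__(self) -> None:
        if self.morphology not in _MORPHOLOGIES:
            raise MapFormatError(f"bad morphology {self.morphology!r}")
        if self.size_class not in ("macro", "micro"):
            raise MapFormatError(f"bad size class {self.size_class!r}")
        if self.morphology == "micro" and self.size_class != "micro":
            raise MapFormatError("morphology=micro implies size_class=micro")

    @property
    def is_biarmed(self) -> bool:
        return self.morphology in ("metacentric", "submetacentric", "subtelocentric")

    @property
    def is_acrocentric(self) -> bool:
        return self.morphology == "acrocentric"


@dataclass(frozen=True)
class KaryotypeDef:
    species: str
    diploid_number: int
    chromosomes: tuple[ChromEntry, ...]
    sex_system: str = "unknown"  # ZW | ZZ-homomorphic | unknown
    fundamental_number: int | None = None

    def __post_init__(self) -> None:
        total = sum(c.copies for c in self.chromosomes)
        if total != self.diploid_number:
            raise MapFormatError(
                f"{self.species}: 2n={self.diploid_number} inconsistent with "
                f"listed chromosomes (sum of copies = {total})"
            )

    def entry(self, label: str) -> ChromEntry | None:
        for c in self.chromosomes:
            if c.label == label:
                return c
        return None

    def morphology_of(self, label: str) -> str | None:
        e = self.entry(label)
        return e.morphology if e else None


def read_karyotypes(source: str | IO[str]) -> dict[str, KaryotypeDef]:
    """Read karyotype definitions for one or more species from TSV.

    Columns: species, diploid_number, fundamental_number, sex_system,
    chromosome, morphology, size_class, copies, sex.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, KaryotypeDef] = {}
    for sp, grp in df.groupby("species", sort=False):
        chroms = tuple(
            ChromEntry(
                label=r["chromosome"].strip(),
                morphology=r["morphology"].strip(),
                size_class=r["size_class"].strip(),
                copies=int(r["copies"]),
                sex=r.get("sex", "").strip() if "sex" in df.columns else "",
            )
            for _, r in grp.iterrows()
        )
        fn_raw = grp.iloc[0].get("fundamental_number", "")
        fn = int(fn_raw) if str(fn_raw).strip() else None
        out[sp] = KaryotypeDef(
            species=sp,
            diploid_number=int(grp.iloc[0]["diploid_number"]),
            chromosomes=chroms,
            sex_system=grp.iloc[0].get("sex_system", "unknown").strip() or "unknown",
            fundamental_number=fn,
        )
    return out


def read_karyotype(source: str | IO[str], species: str) -> KaryotypeDef:
    karyos = read_karyotypes(source)
    if species not in karyos:
        raise MapFormatError(f"no karyotype rows for species {species!r}")
    return karyos[species]


def write_karyotypes(karyos: Mapping[str, KaryotypeDef], dest: str | IO[str]) -> None:
    rows = []
    for sp, k in karyos.items():
        for c in k.chromosomes:
            rows.append(
                {
                    "species": sp,
                    "diploid_number": k.diploid_number,
                    "fundamental_number": (
                        "" if k.fundamental_number is None else k.fundamental_number
                    ),
                    "sex_system": k.sex_system,
                    "chromosome": c.label,
                    "morphology": c.morphology,
                    "size_class": c.size_class,
                    "copies": c.copies,
                    "sex": c.sex,
                }
            )
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

_LANDMARK_KINDS = ("rDNA_18S28S", "rDNA_5S", "ITS", "telomere_terminal")


@dataclass(frozen=True)
class Landmark:
    """A non-gene cytogenetic landmark (rDNA cluster or telomeric signal)."""

    species: str
    kind: str
    location: ChromLocation
    position_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _LANDMARK_KINDS:
            raise MapFormatError(f"bad landmark kind {self.kind!r}")
        if self.kind == "ITS" and self.location.chromosome is None:
            raise MapFormatError("an ITS landmark must name a single chromosome")


def read_landmarks(source: str | IO[str]) -> list[Landmark]:
    """Read a landmark TSV (columns: species, kind, location, note)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        sp = r["species"].strip()
        out.append(
            Landmark(
                species=sp,
                kind=r["kind"].strip(),
                location=parse_location(r["location"], sp, context="landmark"),
                position_note=r.get("note", "").strip() if "note" in df.columns else "",
            )
        )
    return out


def write_landmarks(landmarks: Iterable[Landmark], dest: str | IO[str]) -> None:
    rows = [
        {
            "species": lm.species,
            "kind": lm.kind,
            "location": format_location(lm.location),
            "note": lm.position_note,
        }
        for lm in landmarks
    ]
    pd.DataFrame(rows).to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------


class SpeciesTree:
    """A rooted species tree with a designated outgroup.

    Thin wrapper over a dendropy tree providing the few queries the
    rearrangement polarizer needs: tip sets, MRCA-relative witnesses, and
    an optional ``lineages`` mapping assigning each tip to a named major
    lineage (used to label event branches; defaults to the tip name).
    """

    def __init__(
        self,
        newick_text: str,
        outgroup: str,
        lineages: Mapping[str, str] | None = None,
    ):
        self.newick_text = newick_text.strip()
        self.tree = dendropy.Tree.get(
            data=self.newick_text, schema="newick", preserve_underscores=True
        )
        self.tree.is_rooted = True
        self.species: tuple[str, ...] = tuple(
            leaf.taxon.label for leaf in self.tree.leaf_node_iter()
        )
        if outgroup not in self.species:
            raise MapFormatError(f"outgroup {outgroup!r} is not a tip of the tree")
        self.outgroup = outgroup
        self._lineages = dict(lineages or {})

    def lineage(self, species: str) -> str:
        return self._lineages.get(species, species)

    @property
    def lineages(self) -> dict[str, str]:
        return dict(self._lineages)

    def _leaf(self, species: str):
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label == species:
                return leaf
        raise KeyError(species)

    def _mrca(self, a: str, b: str):
        return self.tree.mrca(taxon_labels=[a, b])

    def tips_under(self, node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}

    def witnesses_outside(self, a: str, b: str) -> list[str]:
        """Tips whose lineages attach rootward of MRCA(a, b)."""
        inside = self.tips_under(self._mrca(a, b))
        return [sp for sp in self.species if sp not in inside]

    def clades_toward(self, tip: str, excluding: str) -> list[tuple[str, set[str]]]:
        """Named nested clades containing ``tip`` but not ``excluding``,
        ordered smallest (the tip itself) to largest.  A clade's name is the
        node label from the Newick text when present, else the sorted tips
        joined with ``+``."""
        node = self._leaf(tip)
        out: list[tuple[str, set[str]]] = []
        while node is not None:
            tips = self.tips_under(node)
            if excluding in tips:
                break
            if node.is_leaf():
                name = node.taxon.label
            else:
                name = node.label or "+".join(sorted(tips))
            out.append((name, tips))
            node = node.parent_node
        return out

    def validate_roster(self, roster: Iterable[str]) -> None:
        missing = [sp for sp in roster if sp not in self.species]
        if missing:
            raise MapFormatError(f"map species missing from tree: {missing}")

    def rerooted(self, new_outgroup: str) -> "SpeciesTree":
        """A copy rerooted so that ``new_outgroup`` is the basal tip."""
        tree = self.tree.clone(depth=1)
        leaf = None
        for lf in tree.leaf_node_iter():
            if lf.taxon.label == new_outgroup:
                leaf = lf
                break
        if leaf is None:
            raise KeyError(new_outgroup)
        tree.reroot_at_edge(leaf.edge, update_bipartitions=False)
        text = tree.as_string(schema="newick", suppress_rooting=True).strip()
        return SpeciesTree(text, outgroup=new_outgroup, lineages=self._lineages)


def read_tree(
    source: str | IO[str],
    outgroup: str,
    lineages: Mapping[str, str] | None = None,
) -> SpeciesTree:
    """Read a Newick species tree from a path or stream."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    return SpeciesTree(text, outgroup=outgroup, lineages=lineages)


# ---------------------------------------------------------------------------
# packaged fixture
# ---------------------------------------------------------------------------

#: major-lineage labels of the study panel (Gekkota basal among the
#: squamates sampled; the four Toxicofera species form a polytomy here)
FIXTURE_LINEAGES = {
    "GHO": "Gekkota",
    "LAG": "Lacertidae",
    "VSA": "Toxicofera",
    "LRE": "Toxicofera",
    "EQU": "Toxicofera",
    "ACA": "Toxicofera",
    "GGA": "Aves",
}


@dataclass(frozen=True)
class FixtureBundle:
    cmap: ComparativeMap
    karyotypes: dict[str, KaryotypeDef]
    landmarks: list[Landmark]
    tree: SpeciesTree


def _data_text(name: str) -> str:
    return (resources.files("karyosynth") / "data" / name).read_text(encoding="utf-8")


def load_fixture_map() -> ComparativeMap:
    return read_map(_io.StringIO(_data_text("comparative_map.tsv")))


def load_fixture_karyotypes() -> dict[str, KaryotypeDef]:
    return read_karyotypes(_io.StringIO(_data_text("karyotypes.tsv")))


def load_fixture_landmarks() -> list[Landmark]:
    return read_landmarks(_io.StringIO(_data_text("landmarks.tsv")))


def load_fixture_tree() -> SpeciesTree:
    return SpeciesTree(
        _data_text("species_tree.nwk"), outgroup="GGA", lineages=FIXTURE_LINEAGES
    )


def load_fixture() -> FixtureBundle:
    """The packaged study fixture: map, karyotypes, landmarks and tree."""
    return FixtureBundle(
        cmap=load_fixture_map(),
        karyotypes=load_fixture_karyotypes(),
        landmarks=load_fixture_landmarks(),
        tree=load_fixture_tree(),
    )
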