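"""Parsing and formatting of cytogenetic location strings.

A location cell in a comparative gene-location table is a compact string
such as ``"1p"``, ``"2q12.2–q21.1"``, ``"4 (ZW)"``, ``"Micro"``,
``"11–18"``, ``"un"`` or ``"–"``.  :func:`parse_location` turns one cell
into a fully flagged :class:`ChromLocation`; :func:`format_location` is its
canonical inverse (hyphens/en-dashes and stray whitespace in the input are
normalized to a single en-dash on output, so ``parse → format → parse`` is
the identity).

Band labels (``12.2``, ``21.1``) are ordinal positions along an arm ordered
centromere→telomere; they carry no physical-distance semantics.  A band
range that crosses the centromere (``3p11.1–q11``) is recorded with
``arm="whole"`` and arm-prefixed band labels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "ChromLocation",
    "LocationParseError",
    "parse_location",
    "format_location",
    "band_sort_key",
]

EN_DASH = "–"

#: tokens that mean "no data" in the table dialect
_MISSING_TOKENS = {"", "-", EN_DASH, "—", "no"}
#: token for "location undetermined"
_UNKNOWN_TOKEN = "un"

_MICRO_GROUP_RE = re.compile(rf"^(\d+)\s*[-{EN_DASH}]\s*(\d+)$")
_SEX_RE = re.compile(r"^(?P<body>.*?)\s*\(\s*(?P<sex>ZW|Z)\s*\)\s*$")
_CHROM_RE = re.compile(r"^(?P<chrom>\d+|[ZW])\s*(?P<rest>.*)$")
_BAND = r"[pq]?\d+(?:\.\d+)?"
_REST_RE = re.compile(
    rf"^(?P<arm>[pq])(?P<start>\d+(?:\.\d+)?)?"
    rf"(?:\s*[-{EN_DASH}]\s*(?P<end>{_BAND}))?$"
)


class LocationParseError(ValueError):
    """Raised for a cell that does not belong to the table dialect."""

    def __init__(self, raw: str, species: str, context: str | None = None):
        self.raw = raw
        self.species = species
        self.context = context
        where = f" ({context})" if context else ""
        super().__init__(
            f"unparseable chromosomal location {raw!r} for species "
            f"{species}{where}"
        )


@dataclass(frozen=True)
class ChromLocation:
    """A parsed cytogenetic location of one gene marker in one species.

    ``status`` is ``"mapped"`` when the cell names a chromosome, a
    microchromosome (``is_micro``) or a micro-group range token such as
    ``11–18`` (``is_micro_group`` — "one of the microchromosomes, identity
    unknown"); ``"unknown"`` for an undetermined location (``un``) and
    ``"missing"`` for an empty / dash cell.
    """

    species: str
    chromosome: str | None = None
    arm: str = "whole"  # p | q | whole
    band_start: str | None = None
    band_end: str | None = None
    is_micro: bool = False
    is_micro_group: bool = False
    sex_annotation: str = "none"  # none | Z | ZW
    status: str = "mapped"  # mapped | unknown | missing

    def __post_init__(self) -> None:
        if self.status not in ("mapped", "unknown", "missing"):
            raise ValueError(f"bad status {self.status!r}")
        if self.arm not in ("p", "q", "whole"):
            raise ValueError(f"bad arm {self.arm!r}")
        if self.sex_annotation not in ("none", "Z", "ZW"):
            raise ValueError(f"bad sex annotation {self.sex_annotation!r}")
        if self.is_micro and self.is_micro_group:
            raise ValueError("is_micro and is_micro_group are exclusive")
        if self.band_end is not None and self.band_start is None:
            raise ValueError("band_end requires band_start")
        if self.status == "mapped" and not (
            self.chromosome or self.is_micro or self.is_micro_group
        ):
            raise ValueError("mapped location needs a chromosome or micro flag")

    # -- convenience predicates -------------------------------------------

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"

    @property
    def resolved(self) -> bool:
        """Mapped to an identified chromosome (not an anonymous micro)."""
        return (
            self.status == "mapped"
            and self.chromosome is not None
            and not self.is_micro_group
        )

    def side(self) -> tuple[str, str]:
        """(chromosome label, arm) used for synteny-segment bookkeeping.

        Anonymous microchromosomes — explicit ``Micro`` cells and
        micro-group ranges — aggregate under the single label ``"Micro"``.
        """
        if not self.mapped:
            raise ValueError("no side for an unmapped location")
        if self.is_micro or self.is_micro_group:
            return ("Micro", "whole")
        assert self.chromosome is not None
        return (self.chromosome, self.arm)


def band_sort_key(band: str) -> tuple:
    """Ordinal key for a band label: 11.1 < 11.2 < 12 < 21.1.

    Arm-prefixed labels (``p11.1``) order p before q, mirroring a
    centromere-crossing range read p→q.
    """
    band = band.strip()
    arm_rank = 0
    if band and band[0] in "pq":
        arm_rank = 1 if band[0] == "q" else 0
        band = band[1:]
    parts = tuple(int(x) for x in band.split(".") if x != "")
    return (arm_rank,) + parts


def parse_location(raw: str, species: str, *, context: str | None = None) -> ChromLocation:
    """Parse one table cell into a :class:`ChromLocation`.

    Tolerates hyphen or en-dash in ranges and stray whitespace.  Raises
    :class:`LocationParseError` for anything outside the dialect.
    """
    if raw is None:
        raw = ""
    text = str(raw).strip()

    if text in _MISSING_TOKENS or text.lower() == "nan":
        return ChromLocation(species=species, status="missing")
    if text == _UNKNOWN_TOKEN:
        return ChromLocation(species=species, status="unknown")
    if text.lower() == "micro":
        return ChromLocation(species=species, is_micro=True)

    m = _MICRO_GROUP_RE.match(text)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo < hi:  # a range like 11–18; a band range never looks like this
            return ChromLocation(
                species=species,
                chromosome=f"{lo}{EN_DASH}{hi}",
                is_micro_group=True,
            )

    sex = "none"
    m = _SEX_RE.match(text)
    if m:
        sex = m.group("sex")
        text = m.group("body").strip()

    m = _CHROM_RE.match(text)
    if not m:
        raise LocationParseError(raw, species, context)
    chrom = m.group("chrom")
    rest = m.group("rest").strip()

    if not rest:
        return ChromLocation(species=species, chromosome=chrom, sex_annotation=sex)

    m = _REST_RE.match(rest)
    if not m:
        raise LocationParseError(raw, species, context)
    arm = m.group("arm")
    start = m.group("start")
    end = m.group("end")

    if end is not None and end[0] in "pq":
        end_arm, end_band = end[0], end[1:]
    else:
        end_arm, end_band = arm, end

    if start is None:
        if end is not None:
            raise LocationParseError(raw, species, context)
        return ChromLocation(
            species=species, chromosome=chrom, arm=arm, sex_annotation=sex
        )

    if end is None:
        return ChromLocation(
            species=species,
            chromosome=chrom,
            arm=arm,
            band_start=start,
            sex_annotation=sex,
        )

    if end_arm == arm:
        loc = ChromLocation(
            species=species,
            chromosome=chrom,
            arm=arm,
            band_start=start,
            band_end=end_band,
            sex_annotation=sex,
        )
    else:
        # range crosses the centromere: the location spans both arms
        loc = ChromLocation(
            species=species,
            chromosome=chrom,
            arm="whole",
            band_start=f"{arm}{start}",
            band_end=f"{end_arm}{end_band}",
            sex_annotation=sex,
        )
    return loc


def format_location(loc: ChromLocation) -> str:
    """Canonical string for a location; inverse of :func:`parse_location`."""
    if loc.status == "missing":
        return EN_DASH
    if loc.status == "unknown":
        return _UNKNOWN_TOKEN
    if loc.is_micro:
        return "Micro"
    if loc.is_micro_group:
        assert loc.chromosome is not None
        return loc.chromosome
    assert loc.chromosome is not None
    out = loc.chromosome
    if loc.arm != "whole":
        out += loc.arm
        if loc.band_start is not None:
            out += loc.band_start
            if loc.band_end is not None:
                out += f"{EN_DASH}{loc.arm}{loc.band_end}"
    elif loc.band_start is not None:
        # centromere-crossing range with arm-prefixed bands
        out += loc.band_start
        if loc.band_end is not None:
            out += f"{EN_DASH}{loc.band_end}"
    if loc.sex_annotation != "none":
        out += f" ({loc.sex_annotation})"
    return out


def strip_bands(loc: ChromLocation) -> ChromLocation:
    """Location with band detail dropped (chromosome/arm resolution only)."""
    return replace(loc, band_start=None, band_end=None)
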