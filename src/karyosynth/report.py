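"""Reproduction report: headline numbers recomputed from the fixture.

Runs the full pipeline on the packaged study fixture and compares every
derived quantity — marker totals, the conserved-chromosome set and avian
unit coverage, per-chromosome marker counts, the microchromosome-composed
set, the lineage-independence check, and the named fusion scenario —
against the expected values shipped alongside the fixture.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources

import yaml

from .cytomap import FixtureBundle, load_fixture
from .homology import (
    conserved_macro_chromosomes,
    hit_units,
    lineage_partition_overlap,
    micro_origin_profile,
    segment_table,
)
from .rearrange import infer_scenario

__all__ = ["CheckResult", "ReproductionReport", "run_reproduction", "load_expected"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    computed: object
    expected: object

    @property
    def passed(self) -> bool:
        return self.computed == self.expected


@dataclass(frozen=True)
class ReproductionReport:
    checks: tuple[CheckResult, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __getitem__(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "checks": {
                c.name: {
                    "computed": c.computed,
                    "expected": c.expected,
                    "passed": c.passed,
                }
                for c in self.checks
            },
            "passed": self.passed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=False)

    def to_text(self) -> str:
        lines = []
        width = max(len(c.name) for c in self.checks)
        for c in self.checks:
            mark = "ok  " if c.passed else "FAIL"
            lines.append(f"[{mark}] {c.name:<{width}}  computed={c.computed!r}")
            if not c.passed:
                lines.append(f"       {'':<{width}}  expected={c.expected!r}")
        lines.append("overall: " + ("PASS" if self.passed else "FAIL"))
        return "\n".join(lines)


def load_expected() -> dict:
    text = (resources.files("karyosynth") / "data" / "expected_checks.yaml").read_text(
        encoding="utf-8"
    )
    return yaml.safe_load(text)


def _sorted_labels(labels) -> list[str]:
    return sorted(labels, key=lambda x: (len(x), x))


def run_reproduction(bundle: FixtureBundle | None = None) -> ReproductionReport:
    """Compute every fixture check and compare with the expected table."""
    if bundle is None:
        bundle = load_fixture()
    expected = load_expected()
    cmap = bundle.cmap

    checks: list[CheckResult] = []

    def add(name: str, computed) -> None:
        checks.append(CheckResult(name=name, computed=computed, expected=expected[name]))

    add("total_markers", len(cmap))
    add("newly_mapped", sum(1 for m in cmap.markers if not m.previously_mapped))
    add(
        "focal_cloned_probes",
        sum(
            1
            for m in cmap.markers
            if m.origin_species == "GHO" and not m.previously_mapped
        ),
    )
    add("origin_counts", dict(Counter(m.origin_species for m in cmap.markers)))

    conserved = conserved_macro_chromosomes(cmap, "GHO")
    add("conserved_macro_chromosomes", _sorted_labels(conserved))
    add("hit_unit_count", len(hit_units(cmap, "GHO")))
    add("lag_macro_count", len(conserved_macro_chromosomes(cmap, "LAG")))

    add(
        "marker_counts",
        {
            chrom: len(cmap.markers_on("GHO", chrom))
            for chrom in expected["marker_counts"]
        },
    )
    gho7_4q = [
        s
        for s in segment_table(cmap, "GHO", "GGA")
        if s.side_a[1] == "7" and s.side_b[1:] == ("4", "q")
    ]
    add("gho7_gga4q_support", gho7_4q[0].support_count if gho7_4q else 0)

    profiles = micro_origin_profile(cmap, "GHO")
    add(
        "micro_composed",
        _sorted_labels(
            p.chromosome for p in profiles if p.classification == "all_micro"
        ),
    )
    add(
        "partitions_identical",
        lineage_partition_overlap(cmap, "GHO", "LAG").partitions_identical,
    )

    events = infer_scenario(cmap, bundle.karyotypes, bundle.landmarks, bundle.tree)
    inferred = {(e.kind, frozenset(e.operands), e.branch) for e in events}
    found = [
        [kind, operands, branch]
        for kind, operands, branch in expected["required_events"]
        if (kind, frozenset(operands), branch) in inferred
    ]
    add("required_events", found)

    return ReproductionReport(checks=tuple(checks))
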