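"""Target-drug cohort construction and event counting.

A *target* case is a deduplicated report listing the drug of interest under an
accepted role code — by default primary suspect (PS) only, so reports where the
drug appears only as concomitant, secondary suspect or interacting are part of
the background. Counting is case-level: at PT level a case contributes one
count per distinct preferred term it reports; at SOC level each case counts at
most once per system organ class, however many of its PTs map there.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import ReportCase, ROLE_CODES

log = logging.getLogger(__name__)

UNMAPPED_SOC = "UNMAPPED"


@dataclass(frozen=True)
class DrugQuery:
    """Synonym set and role filter defining the target cohort."""

    target_names: frozenset[str]
    role_filter: frozenset[str] = frozenset({"PS"})
    substring_match: bool = False

    def __post_init__(self):
        if not self.target_names:
            raise ValueError("target_names must be non-empty")
        if not self.role_filter <= set(ROLE_CODES):
            raise ValueError(f"role_filter must be a subset of {ROLE_CODES}")

    @classmethod
    def from_names(cls, names: Iterable[str], roles: Iterable[str] = ("PS",),
                   substring_match: bool = False) -> "DrugQuery":
        return cls(
            frozenset(n.strip().upper() for n in names if n.strip()),
            frozenset(r.strip().upper() for r in roles),
            substring_match,
        )

    def matches(self, case: ReportCase) -> bool:
        for d in case.drugs:
            if d.role not in self.role_filter:
                continue
            if d.name in self.target_names:
                return True
            if self.substring_match and any(t in d.name for t in self.target_names):
                return True
        return False


@dataclass
class MeddraMap:
    """PT -> SOC mapping (user-supplied; MedDRA itself is licensed).

    PTs not covered by the mapping are routed to the sentinel SOC
    ``UNMAPPED`` rather than dropped.
    """

    pt_to_soc: dict[str, str] = field(default_factory=dict)

    def soc(self, pt: str) -> str:
        return self.pt_to_soc.get(pt.strip().upper(), UNMAPPED_SOC)

    def socs_of(self, pts: Iterable[str]) -> set[str]:
        return {self.soc(pt) for pt in pts}

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str = "\t") -> "MeddraMap":
        """Load a two-column (PT, SOC) delimited text file with a header row."""
        mapping = {}
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                continue
            mapping[parts[0].strip().upper()] = parts[1].strip()
        return cls(mapping)


@dataclass
class CohortCounts:
    """Case-level event counts for the target cohort and its background.

    ``target_pt_counts[pt]`` is the contingency cell *a* for that PT and
    ``background_pt_counts[pt]`` the cell *c*; the SOC-level maps play the same
    roles at SOC granularity.
    """

    n_target_cases: int
    n_background_cases: int
    target_pt_counts: dict[str, int] = field(default_factory=dict)
    background_pt_counts: dict[str, int] = field(default_factory=dict)
    target_soc_counts: dict[str, int] = field(default_factory=dict)
    background_soc_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_target_event_pairs(self) -> int:
        return sum(self.target_pt_counts.values())

    def at_level(self, level: str) -> tuple[dict[str, int], dict[str, int]]:
        if level.upper() == "PT":
            return self.target_pt_counts, self.background_pt_counts
        if level.upper() == "SOC":
            return self.target_soc_counts, self.background_soc_counts
        raise ValueError(f"level must be PT or SOC, got {level!r}")


def select_cohort(
    cases: Sequence[ReportCase], query: DrugQuery
) -> tuple[list[ReportCase], list[ReportCase]]:
    """Partition deduplicated cases into (target, background).

    The partition is exhaustive and disjoint: every case not matching the
    query — including cases naming the target drug under an excluded role —
    goes to the background.
    """
    target, background = [], []
    for c in cases:
        (target if query.matches(c) else background).append(c)
    if not target:
        log.warning("cohort selection matched no cases for %s", sorted(query.target_names))
    return target, background


def count_events(
    target: Sequence[ReportCase],
    background: Sequence[ReportCase],
    meddra: MeddraMap | None = None,
) -> CohortCounts:
    """Case-level PT (and, with a mapping, SOC) counts for both partitions."""

    def pt_counts(cases: Sequence[ReportCase]) -> Counter:
        ctr: Counter = Counter()
        for c in cases:
            ctr.update(c.reactions)
        return ctr

    def soc_counts(cases: Sequence[ReportCase]) -> Counter:
        ctr: Counter = Counter()
        for c in cases:
            ctr.update(meddra.socs_of(c.reactions))  # type: ignore[union-attr]
        return ctr

    counts = CohortCounts(
        n_target_cases=len(target),
        n_background_cases=len(background),
        target_pt_counts=dict(pt_counts(target)),
        background_pt_counts=dict(pt_counts(background)),
    )
    if meddra is not None:
        counts.target_soc_counts = dict(soc_counts(target))
        counts.background_soc_counts = dict(soc_counts(background))
    return counts
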