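"""Reading, normalising and deduplicating FAERS-style quarterly ASCII bundles.

FAERS (the FDA Adverse Event Reporting System) ships each quarter as a set of
"$"-delimited text tables — DEMO (demographics), DRUG, REAC (MedDRA-coded
reactions), THER (therapy dates), OUTC (outcomes), INDI (indications) and RPSR
(report sources) — keyed by PRIMARYID, with CASEID grouping successive versions
of the same case. This module parses those tables into a :class:`RawBundle`,
removes superseded case versions (per CASEID keep the latest FDA receipt date,
ties broken by highest PRIMARYID), and assembles one :class:`ReportCase` per
retained report with demographics converted to canonical units.

Line-level parsing is done by hand (split on the delimiter) rather than through
a CSV reader: FAERS files are unquoted, and the contract here is that every
malformed line is counted and logged with its file, line number and reason —
never silently dropped or NaN-filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

#: The seven FAERS table sections.
TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER", "OUTC", "INDI", "RPSR")

#: Drug role codes: primary suspect, secondary suspect, concomitant, interaction.
ROLE_CODES = ("PS", "SS", "C", "I")

#: FAERS outcome codes (congenital anomaly, death, disability, hospitalisation,
#: life-threatening, other, required intervention).
OUTCOME_CODES = ("CA", "DE", "DS", "HO", "LT", "OT", "RI")

# Age-unit codes to years. Unmappable codes yield a missing age.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

# Weight-unit codes to kilograms.
WEIGHT_UNIT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}

# FAERS occp_cod values to reporter-occupation categories.
DEFAULT_OCCUPATION_MAP = {
    "CN": "consumer",
    "HP": "health_professional",
    "LW": "lawyer",
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
}

AGE_PLAUSIBLE_RANGE = (0.0, 130.0)


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=False)
class PartialDate:
    """A FAERS date of day, month or year precision (YYYYMMDD / YYYYMM / YYYY).

    Ordering comparisons use the *earliest completion* of a partial date
    (missing month/day treated as January/1st), which gives a deterministic
    total order for deduplication.
    """

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def earliest(self) -> date:
        return date(self.year, self.month or 1, self.day or 1)

    def to_date(self) -> date:
        """Exact date; requires day precision."""
        if self.precision != "day":
            raise ValueError(f"date {self} has {self.precision} precision")
        return date(self.year, self.month, self.day)

    def midpoint(self) -> date:
        """Midpoint imputation: day 15 of the month, or July 1 of the year."""
        if self.precision == "day":
            return self.to_date()
        if self.precision == "month":
            return date(self.year, self.month, 15)
        return date(self.year, 7, 1)

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 1, self.day or 1)

    def __lt__(self, other: "PartialDate") -> bool:
        return self.sort_key() < other.sort_key()

    def __le__(self, other: "PartialDate") -> bool:
        return self.sort_key() <= other.sort_key()

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    @classmethod
    def parse(cls, text: str) -> "PartialDate | None":
        """Parse a FAERS date string; returns None for empty/invalid input."""
        text = text.strip()
        if not text or not text.isdigit():
            return None
        try:
            if len(text) == 8:
                d = cls(int(text[:4]), int(text[4:6]), int(text[6:8]))
                d.to_date()  # validate calendar date
                return d
            if len(text) == 6:
                d = cls(int(text[:4]), int(text[4:6]))
                if not 1 <= d.month <= 12:
                    return None
                return d
            if len(text) == 4:
                return cls(int(text))
        except ValueError:
            return None
        return None

    @classmethod
    def from_date(cls, d: date) -> "PartialDate":
        return cls(d.year, d.month, d.day)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportKey:
    """Identity of one report version: PRIMARYID, CASEID, FDA receipt date."""

    primaryid: int
    caseid: int
    fda_dt: PartialDate

    def dedup_rank(self) -> tuple[tuple[int, int, int], int]:
        # Latest FDA_DT wins; ties broken by highest PRIMARYID.
        return (self.fda_dt.sort_key(), self.primaryid)


@dataclass(frozen=True)
class DrugEntry:
    name: str  # uppercased, whitespace-trimmed
    role: str  # one of ROLE_CODES
    start_date: PartialDate | None = None


@dataclass
class ReportCase:
    """One deduplicated adverse-event report."""

    key: ReportKey
    sex: str = "unknown"  # female | male | unknown
    age_years: float | None = None
    weight_kg: float | None = None
    reporter_occupation: str = "missing"
    country: str | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: frozenset[str] = frozenset()
    outcomes: frozenset[str] = frozenset()
    event_date: PartialDate | None = None


@dataclass
class RejectedRow:
    path: str
    line_no: int
    reason: str

    def format(self) -> str:
        return f"{self.path}\t{self.line_no}\t{self.reason}"


@dataclass
class RawBundle:
    """Parsed FAERS tables for one quarter (or one synthetic bundle).

    ``tables`` maps a table name (one of :data:`TABLE_NAMES`) to a list of
    row dicts keyed by uppercased column name. Detail rows whose PRIMARYID is
    absent from DEMO are quarantined into ``rejects``.
    """

    quarter_id: str
    tables: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    source_paths: list[str] = field(default_factory=list)
    rejects: list[RejectedRow] = field(default_factory=list)

    def rows(self, name: str) -> list[dict[str, str]]:
        return self.tables.get(name, [])


@dataclass(frozen=True)
class Dialect:
    """Delimited-text dialect. FAERS is '$'-delimited with one header row."""

    delimiter: str = "$"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


class FaersIOError(RuntimeError):
    pass


def classify_table(path: str | Path) -> str:
    """Infer the FAERS table type from a file name (e.g. ``DEMO12Q3.txt``)."""
    stem = Path(path).stem.upper()
    hits = [name for name in TABLE_NAMES if name in stem]
    if len(hits) != 1:
        raise FaersIOError(
            f"cannot classify table type of {path!r}: matches {hits or 'none'} "
            f"of {TABLE_NAMES}"
        )
    return hits[0]


def _parse_file(
    path: Path, table: str, dialect: Dialect, rejects: list[RejectedRow]
) -> list[dict[str, str]]:
    try:
        text = path.read_text(encoding="utf-8", errors="replace")
    except OSError as exc:
        raise FaersIOError(f"unreadable file: {path}") from exc
    lines = text.splitlines()
    if not lines:
        rejects.append(RejectedRow(str(path), 0, "empty file"))
        return []
    header = [h.strip().upper() for h in lines[0].split(dialect.delimiter)]
    n_cols = len(header)
    rows: list[dict[str, str]] = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(dialect.delimiter)
        if len(fields) != n_cols:
            rejects.append(
                RejectedRow(
                    str(path),
                    i,
                    f"expected {n_cols} fields, got {len(fields)}",
                )
            )
            continue
        rows.append(dict(zip(header, (f.strip() for f in fields))))
    return rows


def read_bundle(
    paths: Sequence[str | Path],
    dialect: Dialect | None = None,
    quarter_id: str = "bundle",
) -> RawBundle:
    """Parse one quarter's table files into a :class:`RawBundle`.

    Each file must declare one of the seven table types in its name. Malformed
    lines and orphan detail rows (PRIMARYID absent from DEMO) are quarantined
    into the bundle's reject log, never silently dropped.
    """
    dialect = dialect or Dialect()
    bundle = RawBundle(quarter_id=quarter_id)
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FaersIOError(f"unreadable file: {p}")
        table = classify_table(p)
        rows = _parse_file(p, table, dialect, bundle.rejects)
        bundle.tables.setdefault(table, []).extend(rows)
        bundle.source_paths.append(str(p))

    demo_ids = {r.get("PRIMARYID", "") for r in bundle.rows("DEMO")}
    for name in TABLE_NAMES:
        if name == "DEMO" or name not in bundle.tables:
            continue
        kept = []
        for r in bundle.tables[name]:
            if r.get("PRIMARYID", "") in demo_ids:
                kept.append(r)
            else:
                bundle.rejects.append(
                    RejectedRow(
                        name, 0, f"orphan PRIMARYID {r.get('PRIMARYID', '?')}"
                    )
                )
        bundle.tables[name] = kept
    if bundle.rejects:
        log.warning(
            "bundle %s: %d rejected rows", bundle.quarter_id, len(bundle.rejects)
        )
    return bundle


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(keys: Iterable[ReportKey]) -> list[ReportKey]:
    """Collapse report versions: per CASEID keep the latest FDA_DT, ties broken
    by the highest PRIMARYID. Output is sorted by CASEID (deterministic)."""
    best: dict[int, ReportKey] = {}
    for k in keys:
        cur = best.get(k.caseid)
        if cur is None or k.dedup_rank() > cur.dedup_rank():
            best[k.caseid] = k
    return [best[c] for c in sorted(best)]


# ---------------------------------------------------------------------------
# Case assembly
# ---------------------------------------------------------------------------


def _parse_int(text: str | None) -> int | None:
    if text is None:
        return None
    text = text.strip()
    try:
        return int(float(text)) if text else None
    except ValueError:
        return None


def _parse_float(text: str | None) -> float | None:
    if text is None:
        return None
    text = text.strip()
    try:
        return float(text) if text else None
    except ValueError:
        return None


def convert_age(value: str | None, unit: str | None) -> float | None:
    """Coded FAERS age to years; implausible (outside [0, 130]) -> missing."""
    v = _parse_float(value)
    if v is None:
        return None
    factor = AGE_UNIT_TO_YEARS.get((unit or "YR").strip().upper() or "YR")
    if factor is None:
        return None
    years = v * factor
    lo, hi = AGE_PLAUSIBLE_RANGE
    if not (lo <= years <= hi):
        log.warning("implausible age %s %s (%.1f years) set missing", value, unit, years)
        return None
    return years


def convert_weight(value: str | None, unit: str | None) -> float | None:
    v = _parse_float(value)
    if v is None or v <= 0:
        return None
    factor = WEIGHT_UNIT_TO_KG.get((unit or "KG").strip().upper() or "KG")
    if factor is None:
        return None
    return v * factor


def _demo_keys(bundles: Sequence[RawBundle]) -> list[tuple[ReportKey, dict[str, str]]]:
    out = []
    for b in bundles:
        for row in b.rows("DEMO"):
            pid = _parse_int(row.get("PRIMARYID"))
            cid = _parse_int(row.get("CASEID"))
            fda = PartialDate.parse(row.get("FDA_DT", ""))
            if pid is None or cid is None or fda is None:
                b.rejects.append(
                    RejectedRow("DEMO", 0, f"unparseable key fields: {row}")
                )
                continue
            out.append((ReportKey(pid, cid, fda), row))
    return out


def assemble_cases(
    bundles: Sequence[RawBundle],
    occupation_map: Mapping[str, str] | None = None,
) -> list[ReportCase]:
    """Deduplicate across *all* bundles jointly and build one
    :class:`ReportCase` per retained PRIMARYID, aggregating its DRUG, REAC,
    THER and OUTC rows and converting age/weight to canonical units.
    """
    occupation_map = dict(occupation_map or DEFAULT_OCCUPATION_MAP)
    demo = _demo_keys(bundles)
    retained = {k.primaryid: k for k in deduplicate(k for k, _ in demo)}
    demo_rows = {k.primaryid: row for k, row in demo if retained.get(k.primaryid) is k}

    drugs: dict[int, list[dict[str, str]]] = {}
    reacs: dict[int, list[dict[str, str]]] = {}
    thers: dict[int, list[dict[str, str]]] = {}
    outcs: dict[int, list[dict[str, str]]] = {}
    for b in bundles:
        for name, store in (("DRUG", drugs), ("REAC", reacs), ("THER", thers), ("OUTC", outcs)):
            for row in b.rows(name):
                pid = _parse_int(row.get("PRIMARYID"))
                if pid in retained:
                    store.setdefault(pid, []).append(row)

    empty_pt = 0
    cases: list[ReportCase] = []
    for key in sorted(retained.values(), key=lambda k: k.caseid):
        row = demo_rows[key.primaryid]
        sex_code = row.get("SEX", row.get("GNDR_COD", "")).strip().upper()
        sex = {"F": "female", "M": "male"}.get(sex_code, "unknown")
        occ = occupation_map.get(row.get("OCCP_COD", "").strip().upper(), "missing")
        country = (
            row.get("OCCR_COUNTRY", "").strip()
            or row.get("REPORTER_COUNTRY", "").strip()
            or None
        )
        # Therapy start dates attach to drug rows via DSG_DRUG_SEQ == DRUG_SEQ.
        starts: dict[str, PartialDate] = {}
        for t in thers.get(key.primaryid, []):
            seq = t.get("DSG_DRUG_SEQ", "").strip()
            d = PartialDate.parse(t.get("START_DT", ""))
            if d is not None and (seq not in starts or d.sort_key() < starts[seq].sort_key()):
                starts[seq] = d
        drug_entries = []
        for dr in drugs.get(key.primaryid, []):
            name = dr.get("DRUGNAME", "").strip().upper()
            role = dr.get("ROLE_COD", "").strip().upper()
            if not name or role not in ROLE_CODES:
                continue
            drug_entries.append(
                DrugEntry(name, role, starts.get(dr.get("DRUG_SEQ", "").strip()))
            )
        pts = set()
        for r in reacs.get(key.primaryid, []):
            pt = r.get("PT", "").strip()
            if pt:
                pts.add(pt.upper())
            else:
                empty_pt += 1
        outcomes = {
            o.get("OUTC_COD", "").strip().upper()
            for o in outcs.get(key.primaryid, [])
        } & set(OUTCOME_CODES)
        cases.append(
            ReportCase(
                key=key,
                sex=sex,
                age_years=convert_age(row.get("AGE"), row.get("AGE_COD")),
                weight_kg=convert_weight(row.get("WT"), row.get("WT_COD")),
                reporter_occupation=occ,
                country=country,
                drugs=drug_entries,
                reactions=frozenset(pts),
                outcomes=frozenset(outcomes),
                event_date=PartialDate.parse(row.get("EVENT_DT", "")),
            )
        )
    if empty_pt:
        log.warning("dropped %d REAC rows with empty PT", empty_pt)
    return cases


def write_reject_log(bundles: Sequence[RawBundle], path: str | Path) -> int:
    """Write one line per rejected row (file, line number, reason)."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\tline\treason\n")
        for b in bundles:
            for r in b.rejects:
                fh.write(r.format() + "\n")
                n += 1
    return n
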