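"""Domain model for catheter-episode registries.

A registry is a flat table with one row per central venous catheter (CVC)
episode: the stratum (center), patient covariates, insertion site, the number
of days the catheter was in situ (dwell time), and — when a catheter-related
bloodstream infection (CRBSI) was adjudicated — its class (definite or
probable), onset day and causative pathogen.  Day 1 is the first day in situ;
``dwell_days`` counts whole days contributed to CVC-day denominators and
``crbsi_onset_day`` is on the same scale.

CRBSI adjudication itself (the clinical definition of definite/probable) is
taken as given labels; this module only enforces structural consistency.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

__all__ = [
    "CVCRecord",
    "Cohort",
    "Violation",
    "ReadAudit",
    "RegistryError",
    "REGISTRY_COLUMNS",
    "SEXES",
    "DISEASES",
    "SITES",
    "CRBSI_CLASSES",
    "PATHOGENS",
    "read_registry",
    "write_registry",
    "validate_cohort",
]

SEXES = ("male", "female")
DISEASES = ("AML", "ALL", "NHL", "MM", "HL", "other")
SITES = ("jugular", "subclavian")
CRBSI_CLASSES = ("none", "definite", "probable")
PATHOGENS = (
    "CoNS",
    "Enterobacteriaceae",
    "other_gram_negative",
    "other_gram_positive",
    "Candida",
    "multibacterial",
)

#: Fixed CSV column order.  Booleans are serialized as 0/1, absent values as
#: empty cells.  UTF-8, comma separated, header required.
REGISTRY_COLUMNS = (
    "record_id",
    "center_id",
    "age_years",
    "sex",
    "disease",
    "insertion_site",
    "antimicrobial_coated",
    "chg_dressing",
    "neutropenic_at_insertion",
    "dwell_days",
    "crbsi_class",
    "crbsi_onset_day",
    "pathogen",
    "platelets_d7",
    "platelets_d14",
    "platelets_d21",
)

PLATELET_DAYS = (7, 14, 21)


class RegistryError(ValueError):
    """Raised for malformed registry files or invalid cohorts."""


@dataclass(frozen=True)
class CVCRecord:
    """One catheter episode (a registry row)."""

    record_id: str
    center_id: str
    age_years: int
    sex: str
    disease: str
    insertion_site: str
    antimicrobial_coated: bool
    chg_dressing: bool
    neutropenic_at_insertion: bool
    dwell_days: int
    crbsi_class: str = "none"
    crbsi_onset_day: Optional[int] = None
    pathogen: Optional[str] = None
    platelets_d7: Optional[int] = None
    platelets_d14: Optional[int] = None
    platelets_d21: Optional[int] = None


@dataclass(frozen=True)
class Violation:
    """A single invariant violation, reported not raised."""

    record_id: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.record_id}: {self.field}: {self.rule}"


@dataclass
class ReadAudit:
    """Audit log of a lenient registry read."""

    n_rows: int = 0
    n_kept: int = 0
    n_dropped: int = 0
    dropped: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)


@dataclass
class Cohort:
    """Ordered collection of :class:`CVCRecord` with schema metadata.

    Ordering is the registry (insertion-date) order and is stable under
    read/write round-trips.  ``audit`` is populated only by lenient reads.
    """

    records: list[CVCRecord]
    schema_version: str = "1"
    audit: Optional[ReadAudit] = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CVCRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _record_violations(rec: CVCRecord) -> list[Violation]:
    v: list[Violation] = []

    def bad(field_: str, rule: str) -> None:
        v.append(Violation(rec.record_id, field_, rule))

    if not isinstance(rec.dwell_days, int) or rec.dwell_days < 1:
        bad("dwell_days", "dwell_days must be an integer >= 1 (CVC >= 1 day in situ)")
    if not isinstance(rec.age_years, int) or rec.age_years < 16:
        bad("age_years", "age_years must be an integer >= 16")
    if rec.sex not in SEXES:
        bad("sex", f"sex must be one of {SEXES}")
    if rec.disease not in DISEASES:
        bad("disease", f"disease must be one of {DISEASES}")
    if rec.insertion_site not in SITES:
        bad("insertion_site", f"insertion_site must be one of {SITES}")
    if rec.crbsi_class not in CRBSI_CLASSES:
        bad("crbsi_class", f"crbsi_class must be one of {CRBSI_CLASSES}")

    has_event = rec.crbsi_class in ("definite", "probable")
    if has_event:
        if rec.crbsi_onset_day is None:
            bad("crbsi_onset_day", "crbsi_onset_day required when crbsi_class != none")
        elif not (1 <= rec.crbsi_onset_day <= max(rec.dwell_days, 1)):
            bad("crbsi_onset_day", "crbsi_onset_day must satisfy 1 <= onset <= dwell_days")
        if rec.pathogen is None:
            bad("pathogen", "pathogen required when crbsi_class != none")
        elif rec.pathogen not in PATHOGENS:
            bad("pathogen", f"pathogen must be one of {PATHOGENS}")
    else:
        if rec.crbsi_onset_day is not None:
            bad("crbsi_onset_day", "crbsi_onset_day must be absent when crbsi_class = none")
        if rec.pathogen is not None:
            bad("pathogen", "pathogen must be absent when crbsi_class = none")

    for day in PLATELET_DAYS:
        val = getattr(rec, f"platelets_d{day}")
        if val is not None and rec.dwell_days < day:
            bad(f"platelets_d{day}",
                f"platelets_d{day} present but CVC removed before day {day}")
        if val is not None and val < 0:
            bad(f"platelets_d{day}", "platelet count must be >= 0")
    return v


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check every record invariant plus record_id uniqueness.

    Pure reporting function: returns an empty list iff the cohort is valid,
    never raises on invalid content.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in cohort:
        if rec.record_id in seen:
            out.append(Violation(rec.record_id, "record_id",
                                 "record_id must be unique within cohort"))
        seen.add(rec.record_id)
        out.extend(_record_violations(rec))
    return out


# ---------------------------------------------------------------------------
# CSV serialization


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    return str(value)


def write_registry(cohort: Cohort, path) -> None:
    """Write a cohort to CSV so that :func:`read_registry` round-trips it."""
    path = Path(path)
    lines = [",".join(REGISTRY_COLUMNS)]
    for rec in cohort:
        lines.append(",".join(_fmt(getattr(rec, c)) for c in REGISTRY_COLUMNS))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_int(raw: str, column: str, row: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise RegistryError(
            f"row {row}: column '{column}': cannot coerce {raw!r} to integer"
        ) from None


def _parse_bool(raw: str, column: str, row: int) -> bool:
    if raw in ("0", "1"):
        return raw == "1"
    raise RegistryError(f"row {row}: column '{column}': expected 0/1, got {raw!r}")


def _parse_row(values: list[str], row: int) -> CVCRecord:
    d = dict(zip(REGISTRY_COLUMNS, values))
    opt_int = lambda c: None if d[c] == "" else _parse_int(d[c], c, row)
    return CVCRecord(
        record_id=d["record_id"],
        center_id=d["center_id"],
        age_years=_parse_int(d["age_years"], "age_years", row),
        sex=d["sex"],
        disease=d["disease"],
        insertion_site=d["insertion_site"],
        antimicrobial_coated=_parse_bool(d["antimicrobial_coated"], "antimicrobial_coated", row),
        chg_dressing=_parse_bool(d["chg_dressing"], "chg_dressing", row),
        neutropenic_at_insertion=_parse_bool(d["neutropenic_at_insertion"],
                                             "neutropenic_at_insertion", row),
        dwell_days=_parse_int(d["dwell_days"], "dwell_days", row),
        crbsi_class=d["crbsi_class"],
        crbsi_onset_day=opt_int("crbsi_onset_day"),
        pathogen=d["pathogen"] if d["pathogen"] != "" else None,
        platelets_d7=opt_int("platelets_d7"),
        platelets_d14=opt_int("platelets_d14"),
        platelets_d21=opt_int("platelets_d21"),
    )


def read_registry(path, strict: bool = True) -> Cohort:
    """Read a registry CSV into a :class:`Cohort`.

    In strict mode any invariant violation (or type-coercion failure) aborts
    with a :class:`RegistryError` naming the offending row.  In lenient mode
    violating rows are dropped and counted in ``cohort.audit``.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryError(f"registry file not found: {path}")
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise RegistryError(f"{path}: empty file (header row required)")
    header = tuple(lines[0].split(","))
    if header != REGISTRY_COLUMNS:
        unknown = set(header) - set(REGISTRY_COLUMNS)
        missing = set(REGISTRY_COLUMNS) - set(header)
        raise RegistryError(
            f"{path}: header mismatch (unknown columns {sorted(unknown)}, "
            f"missing columns {sorted(missing)}, order must be fixed)"
        )

    audit = ReadAudit()
    records: list[CVCRecord] = []
    seen: set[str] = set()
    for row_no, line in enumerate(lines[1:], start=2):
        audit.n_rows += 1
        values = line.split(",")
        if len(values) != len(REGISTRY_COLUMNS):
            msg = f"row {row_no}: expected {len(REGISTRY_COLUMNS)} fields, got {len(values)}"
            if strict:
                raise RegistryError(f"{path}: {msg}")
            audit.n_dropped += 1
            audit.dropped.append((row_no, msg))
            continue
        try:
            rec = _parse_row(values, row_no)
        except RegistryError as exc:
            if strict:
                raise RegistryError(f"{path}: {exc}") from None
            audit.n_dropped += 1
            audit.dropped.append((row_no, str(exc)))
            continue
        problems = _record_violations(rec)
        if rec.record_id in seen:
            problems.append(Violation(rec.record_id, "record_id",
                                      "record_id must be unique within cohort"))
        if problems:
            msg = "; ".join(str(p) for p in problems)
            if strict:
                raise RegistryError(f"{path}: row {row_no}: {msg}")
            audit.n_dropped += 1
            audit.dropped.append((row_no, msg))
            continue
        seen.add(rec.record_id)
        records.append(rec)
        audit.n_kept += 1

    return Cohort(records=records, audit=None if strict else audit)


def cohort_from_records(records: Iterable[CVCRecord]) -> Cohort:
    return Cohort(records=list(records))
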