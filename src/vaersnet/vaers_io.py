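"""Reading, normalising and writing VAERS-style spontaneous report data.

VAERS distributes its data as three comma-separated tables — DATA (one row
per report: receipt date, sex, age, ...), VACCINE (one row per administered
vaccine) and SYMPTOMS (reported MedDRA preferred terms) — joined on the
VAERS_ID report identifier.  This module joins such a triplet into a
normalised, deduplicated :class:`ReportSet` and round-trips that normalised
form through a single flat CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("F", "M", "U")

#: normalised flat-CSV column order
_FLAT_COLUMNS = ["report_id", "year", "sex", "age", "vaccines", "symptoms"]


class SchemaError(ValueError):
    """A required column is missing from one of the input tables."""


def normalize_sex(raw: Optional[str]) -> str:
    """Map a raw sex field to one of ``F``/``M``/``U``.

    F and M are accepted case-insensitively; anything else (including blank
    or missing) collapses to U (unknown).
    """
    if raw is None:
        return "U"
    s = str(raw).strip().upper()
    return s if s in ("F", "M") else "U"


def parse_recv_year(raw: Optional[str]) -> Optional[int]:
    """Parse the year out of an MM/DD/YYYY received-date string.

    Returns ``None`` for unparseable or blank dates.
    """
    if raw is None:
        return None
    s = str(raw).strip()
    if not s:
        return None
    try:
        return datetime.strptime(s, "%m/%d/%Y").year
    except ValueError:
        return None


def _clean_terms(terms: Iterable[str]) -> frozenset[str]:
    out = set()
    for t in terms:
        if t is None:
            continue
        t = str(t).strip()
        if t:
            out.add(t)
    return frozenset(out)


@dataclass(frozen=True)
class Report:
    """One spontaneous report: identifier, demographics and the reported sets.

    ``vaccines`` and ``symptoms`` are deduplicated sets — a term listed twice
    in the raw file counts once.
    """

    report_id: str
    year: Optional[int]
    sex: str
    age: Optional[float]
    vaccines: frozenset[str] = field(default_factory=frozenset)
    symptoms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not str(self.report_id).strip():
            raise ValueError("report_id must be a non-empty string")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValueError("age must be non-negative or None")
        object.__setattr__(self, "vaccines", _clean_terms(self.vaccines))
        object.__setattr__(self, "symptoms", _clean_terms(self.symptoms))


class ReportSet:
    """An ordered collection of :class:`Report` with unique identifiers."""

    def __init__(self, reports: Iterable[Report], provenance: str = "") -> None:
        self._reports: tuple[Report, ...] = tuple(reports)
        self.provenance = provenance
        ids = [r.report_id for r in self._reports]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate report_id {dup!r} in ReportSet")
        self._by_id = {r.report_id: r for r in self._reports}

    def __len__(self) -> int:
        return len(self._reports)

    def __iter__(self) -> Iterator[Report]:
        return iter(self._reports)

    def __getitem__(self, report_id: str) -> Report:
        return self._by_id[report_id]

    def __contains__(self, report_id: str) -> bool:
        return report_id in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        return self._reports == other._reports

    def __repr__(self) -> str:
        return f"ReportSet({len(self)} reports, provenance={self.provenance!r})"

    @property
    def reports(self) -> tuple[Report, ...]:
        return self._reports

    def report_ids(self) -> list[str]:
        return [r.report_id for r in self._reports]


def _read_table(path: Path, table: str, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    # permissive 8-bit decode: raw VAERS files predate consistent encodings
    df = pd.read_csv(
        path,
        dtype=str,
        encoding="cp1252",
        encoding_errors="replace",
        keep_default_na=False,
    )
    df.columns = [c.strip().upper() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} table {path} is missing required column {col!r}")
    return df


def read_reports(
    data_table_path: str | Path,
    vaccine_table_path: str | Path,
    symptom_table_path: str | Path,
) -> ReportSet:
    """Join a VAERS-style CSV triplet into a normalised :class:`ReportSet`.

    One report is emitted per distinct VAERS_ID in the DATA table; vaccine
    codes and symptom terms are aggregated from the other two tables by ID.
    Reports without vaccine or symptom rows are retained (they still count
    in report-total denominators downstream).  Unparseable received dates
    leave the report's year missing and are tallied in a logged skip count.
    """
    data = _read_table(Path(data_table_path), "Data", ["VAERS_ID", "RECVDATE"])
    vax = _read_table(Path(vaccine_table_path), "Vaccine", ["VAERS_ID", "VAX_TYPE"])
    sym = _read_table(Path(symptom_table_path), "Symptom", ["VAERS_ID"])

    sym_cols = [c for c in sym.columns if c.startswith("SYMPTOM")]
    if not sym_cols:
        raise SchemaError(
            f"Symptom table {symptom_table_path} is missing required column 'SYMPTOM*'"
        )

    vax_by_id: dict[str, set[str]] = {}
    for rid, code in zip(vax["VAERS_ID"], vax["VAX_TYPE"]):
        rid = str(rid).strip()
        code = str(code).strip()
        if rid and code:
            vax_by_id.setdefault(rid, set()).add(code)

    sym_by_id: dict[str, set[str]] = {}
    for _, row in sym.iterrows():
        rid = str(row["VAERS_ID"]).strip()
        if not rid:
            continue
        bucket = sym_by_id.setdefault(rid, set())
        for c in sym_cols:
            term = str(row[c]).strip()
            if term:
                bucket.add(term)

    reports: list[Report] = []
    seen: set[str] = set()
    bad_dates = 0
    for _, row in data.iterrows():
        rid = str(row["VAERS_ID"]).strip()
        if not rid:
            continue
        if rid in seen:
            logger.warning("duplicate VAERS_ID %s in Data table; keeping first row", rid)
            continue
        seen.add(rid)
        year = parse_recv_year(row["RECVDATE"])
        if year is None:
            bad_dates += 1
        age_raw = str(row.get("AGE_YRS", "")).strip()
        try:
            age: Optional[float] = float(age_raw) if age_raw else None
            if age is not None and age < 0:
                age = None
        except ValueError:
            age = None
        reports.append(
            Report(
                report_id=rid,
                year=year,
                sex=normalize_sex(row.get("SEX")),
                age=age,
                vaccines=frozenset(vax_by_id.get(rid, set())),
                symptoms=frozenset(sym_by_id.get(rid, set())),
            )
        )
    if bad_dates:
        logger.info("%d report(s) had unparseable received dates; year set to missing", bad_dates)
    return ReportSet(reports, provenance=f"joined from {data_table_path}")


def write_reports(reports: ReportSet, path: str | Path) -> None:
    """Serialise a :class:`ReportSet` as a single flat CSV.

    Vaccine and symptom sets are pipe-delimited (sorted for determinism);
    commas inside terms survive via standard CSV quoting.  The pipe itself
    is reserved as the in-cell delimiter and may not occur in a term.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_FLAT_COLUMNS)
        for r in reports:
            for term in list(r.vaccines) + list(r.symptoms):
                if "|" in term:
                    raise ValueError(f"term {term!r} contains the reserved delimiter '|'")
            w.writerow(
                [
                    r.report_id,
                    "" if r.year is None else r.year,
                    r.sex,
                    "" if r.age is None else repr(r.age),
                    "|".join(sorted(r.vaccines)),
                    "|".join(sorted(r.symptoms)),
                ]
            )


def read_normalized(path: str | Path) -> ReportSet:
    """Read the flat CSV written by :func:`write_reports`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"normalized report file not found: {path}")
    reports: list[Report] = []
    with path.open(newline="", encoding="utf-8") as fh:
        rdr = csv.DictReader(fh)
        missing = [c for c in _FLAT_COLUMNS if c not in (rdr.fieldnames or [])]
        if missing:
            raise SchemaError(f"normalized file {path} is missing column(s) {missing}")
        for row in rdr:
            reports.append(
                Report(
                    report_id=row["report_id"],
                    year=int(row["year"]) if row["year"] else None,
                    sex=row["sex"],
                    age=float(row["age"]) if row["age"] else None,
                    vaccines=frozenset(v for v in row["vaccines"].split("|") if v),
                    symptoms=frozenset(s for s in row["symptoms"].split("|") if s),
                )
            )
    return ReportSet(reports, provenance=str(path))
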