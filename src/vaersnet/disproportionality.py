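"""Stratified pair counting and proportional reporting ratios (PRR).

For a vaccine V and symptom S within a stratum (the whole corpus, a single
reporting year, or one sex) the PRR is

    PRR = (a / b) / (c / d)

where, counting *reports* within the stratum: a = reports for V that contain
S, b = all reports for V, c = all reports containing S, and d = all reports.
The comparator deliberately uses *all* reports — including V's own — rather
than the classic "all other vaccines" variant; an association is called
significant when its stratum PRR is strictly greater than 1.

A PRR is *undefined* (carried as ``None``, never 0 or infinity) when any of
b, c, d is zero in the stratum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .vaers_io import Report, ReportSet

# (lower, upper, label); upper bound exclusive, None = unbounded
DEFAULT_AGE_BINS: tuple[tuple[Optional[float], Optional[float], str], ...] = (
    (None, 2, "<2"),
    (2, 18, "2-17"),
    (18, 65, "18-64"),
    (65, None, "65+"),
)
UNKNOWN_AGE = "unknown"

#: a stratum is "overall", ("year", y) or ("sex", "F"/"M")
Stratum = Union[str, tuple]


def age_group(
    age: Optional[float],
    bins: Sequence[tuple[Optional[float], Optional[float], str]] = DEFAULT_AGE_BINS,
) -> str:
    """Assign an age in years to a surveillance age band."""
    if age is None:
        return UNKNOWN_AGE
    for lo, hi, label in bins:
        if (lo is None or age >= lo) and (hi is None or age < hi):
            return label
    return UNKNOWN_AGE


def age_group_labels(
    bins: Sequence[tuple[Optional[float], Optional[float], str]] = DEFAULT_AGE_BINS,
) -> list[str]:
    return [label for _, _, label in bins] + [UNKNOWN_AGE]


@dataclass
class DemographicDistribution:
    """Sex and age-band counts over the reports containing one pair.

    ``by_year`` holds the same breakdown restricted to each (parseable)
    reporting year.  Sex counts and age counts each sum to the pair's total
    report count.
    """

    sex_counts: dict[str, int]
    age_counts: dict[str, int]
    by_year: dict[int, dict[str, dict[str, int]]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.sex_counts.values())


@dataclass
class AssociationRecord:
    """One vaccine–symptom pair with stratified counts and PRR values."""

    vaccine: str
    symptom: str
    n_pair_total: int = 0
    n_pair_by_year: dict[int, int] = field(default_factory=dict)
    n_pair_by_sex: dict[str, int] = field(default_factory=lambda: {"F": 0, "M": 0})
    prr_overall: Optional[float] = None
    prr_by_year: dict[int, Optional[float]] = field(default_factory=dict)
    prr_by_sex: dict[str, Optional[float]] = field(default_factory=dict)
    demo: Optional[DemographicDistribution] = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.vaccine, self.symptom)

    def prr_for(self, stratum: Stratum) -> Optional[float]:
        """The already-computed PRR for a stratum, or None if undefined/absent."""
        kind, key = resolve_stratum(stratum)
        if kind == "overall":
            return self.prr_overall
        if kind == "year":
            return self.prr_by_year.get(key)
        return self.prr_by_sex.get(key)


@dataclass
class StratumCounts:
    """Report-level denominators within one stratum."""

    n_total: int = 0
    vaccine_counts: Counter = field(default_factory=Counter)
    symptom_counts: Counter = field(default_factory=Counter)


class CountContext:
    """Denominator counts for the overall corpus, each year and each sex.

    Sex strata cover F and M only; unknown-sex reports contribute to the
    overall and yearly strata but to neither sex stratum.  Reports with an
    unparseable year contribute to overall/sex strata only.
    """

    def __init__(self) -> None:
        self.overall = StratumCounts()
        self.by_year: dict[int, StratumCounts] = {}
        self.by_sex: dict[str, StratumCounts] = {"F": StratumCounts(), "M": StratumCounts()}

    def stratum(self, stratum: Stratum) -> Optional[StratumCounts]:
        kind, key = resolve_stratum(stratum)
        if kind == "overall":
            return self.overall
        if kind == "year":
            return self.by_year.get(key)
        return self.by_sex.get(key)

    def years(self) -> list[int]:
        return sorted(self.by_year)


def resolve_stratum(stratum: Stratum) -> tuple[str, Optional[object]]:
    """Normalise the stratum spelling to ('overall'|'year'|'sex', key)."""
    if stratum == "overall":
        return ("overall", None)
    if isinstance(stratum, str) and stratum in ("F", "M"):
        return ("sex", stratum)
    if isinstance(stratum, int):
        return ("year", stratum)
    if isinstance(stratum, tuple) and len(stratum) == 2 and stratum[0] in ("year", "sex"):
        return (stratum[0], stratum[1])
    raise ValueError(f"unrecognised stratum {stratum!r}")


def count_pairs(reports: ReportSet) -> tuple[list[AssociationRecord], CountContext]:
    """Enumerate co-occurring vaccine–symptom pairs and all denominators.

    A report with j vaccines and k symptoms contributes to j×k pairs, once
    each (sets are already deduplicated per report).  Returns one record per
    distinct pair seen in at least one report, sorted by (vaccine, symptom),
    plus the :class:`CountContext` of per-stratum totals.
    """
    if len(reports) == 0:
        raise ValueError("count_pairs requires a non-empty ReportSet")

    ctx = CountContext()
    records: dict[tuple[str, str], AssociationRecord] = {}

    for r in reports:
        strata: list[StratumCounts] = [ctx.overall]
        if r.year is not None:
            strata.append(ctx.by_year.setdefault(r.year, StratumCounts()))
        if r.sex in ("F", "M"):
            strata.append(ctx.by_sex[r.sex])
        for sc in strata:
            sc.n_total += 1
            for v in r.vaccines:
                sc.vaccine_counts[v] += 1
            for s in r.symptoms:
                sc.symptom_counts[s] += 1
        for v in r.vaccines:
            for s in r.symptoms:
                rec = records.get((v, s))
                if rec is None:
                    rec = records[(v, s)] = AssociationRecord(vaccine=v, symptom=s)
                rec.n_pair_total += 1
                if r.year is not None:
                    rec.n_pair_by_year[r.year] = rec.n_pair_by_year.get(r.year, 0) + 1
                if r.sex in ("F", "M"):
                    rec.n_pair_by_sex[r.sex] += 1

    ordered = [records[k] for k in sorted(records)]
    for rec in ordered:
        rec.n_pair_by_year = dict(sorted(rec.n_pair_by_year.items()))
    return ordered, ctx


def prr(
    record: AssociationRecord, context: CountContext, stratum: Stratum = "overall"
) -> Optional[float]:
    """PRR of a pair within one stratum; ``None`` where undefined.

    Undefined means a zero in any denominator (no reports for V, none
    containing S, or an empty stratum); a = 0 with valid denominators gives
    PRR = 0.0, which is defined.
    """
    kind, key = resolve_stratum(stratum)
    sc = context.stratum(stratum)
    if sc is None:
        return None
    if kind == "overall":
        a = record.n_pair_total
    elif kind == "year":
        a = record.n_pair_by_year.get(key, 0)
    else:
        a = record.n_pair_by_sex.get(key, 0)
    b = sc.vaccine_counts.get(record.vaccine, 0)
    c = sc.symptom_counts.get(record.symptom, 0)
    d = sc.n_total
    if b == 0 or c == 0 or d == 0:
        return None
    return (a / b) / (c / d)


def compute_prrs(
    records: Iterable[AssociationRecord], context: CountContext
) -> list[AssociationRecord]:
    """Fill overall, per-year and per-sex PRRs on each record, in place.

    Yearly PRRs are computed for the years in which the pair occurs; sex
    PRRs for both F and M (possibly undefined).
    """
    out = list(records)
    for rec in out:
        rec.prr_overall = prr(rec, context, "overall")
        rec.prr_by_year = {y: prr(rec, context, ("year", y)) for y in rec.n_pair_by_year}
        rec.prr_by_sex = {g: prr(rec, context, ("sex", g)) for g in ("F", "M")}
    return out


def significant_associations(
    records: Iterable[AssociationRecord],
    stratum: Stratum = "overall",
    threshold: float = 1.0,
) -> list[AssociationRecord]:
    """Keep records whose stratum PRR is strictly above ``threshold``.

    Undefined (None) PRRs never pass.  The default threshold of 1 is the
    disproportionate-reporting criterion.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    kept = []
    for rec in records:
        value = rec.prr_for(stratum)
        if value is not None and value > threshold:
            kept.append(rec)
    return kept


def demographic_distribution(
    reports: ReportSet,
    vaccine: str,
    symptom: str,
    bins: Sequence[tuple[Optional[float], Optional[float], str]] = DEFAULT_AGE_BINS,
) -> DemographicDistribution:
    """Sex / age-band counts over the reports containing one pair, total and per-year."""
    labels = age_group_labels(bins)
    sex_counts = {g: 0 for g in ("F", "M", "U")}
    age_counts = {lab: 0 for lab in labels}
    by_year: dict[int, dict[str, dict[str, int]]] = {}
    for r in reports:
        if vaccine not in r.vaccines or symptom not in r.symptoms:
            continue
        band = age_group(r.age, bins)
        sex_counts[r.sex] += 1
        age_counts[band] += 1
        if r.year is not None:
            yr = by_year.setdefault(
                r.year,
                {"sex": {g: 0 for g in ("F", "M", "U")}, "age": {lab: 0 for lab in labels}},
            )
            yr["sex"][r.sex] += 1
            yr["age"][band] += 1
    return DemographicDistribution(
        sex_counts=sex_counts, age_counts=age_counts, by_year=dict(sorted(by_year.items()))
    )


def attach_demographics(
    records: Iterable[AssociationRecord], reports: ReportSet
) -> list[AssociationRecord]:
    """Compute and attach the demographic distribution of every record's pair."""
    out = list(records)
    for rec in out:
        rec.demo = demographic_distribution(reports, rec.vaccine, rec.symptom)
    return out


def associations_to_frame(records: Iterable[AssociationRecord]) -> "pd.DataFrame":
    """Long-format summary table: one row per (pair, stratum) with count and PRR."""
    import pandas as pd

    rows = []
    for rec in records:
        rows.append(
            dict(
                vaccine=rec.vaccine,
                symptom=rec.symptom,
                stratum="overall",
                n_pair=rec.n_pair_total,
                prr=rec.prr_overall,
            )
        )
        for y in sorted(rec.prr_by_year):
            rows.append(
                dict(
                    vaccine=rec.vaccine,
                    symptom=rec.symptom,
                    stratum=str(y),
                    n_pair=rec.n_pair_by_year.get(y, 0),
                    prr=rec.prr_by_year[y],
                )
            )
        for g in ("F", "M"):
            if g in rec.prr_by_sex:
                rows.append(
                    dict(
                        vaccine=rec.vaccine,
                        symptom=rec.symptom,
                        stratum=g,
                        n_pair=rec.n_pair_by_sex.get(g, 0),
                        prr=rec.prr_by_sex[g],
                    )
                )
    return pd.DataFrame(rows, columns=["vaccine", "symptom", "stratum", "n_pair", "prr"])
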