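"""Pair counting, stratified PRR values and the significance filter."""

import numpy as np
import pytest

from vaersnet import (
    AssociationRecord,
    Report,
    ReportSet,
    compute_prrs,
    count_pairs,
    demographic_distribution,
    prr,
    significant_associations,
)
from vaersnet.disproportionality import age_group

from oracles import brute_force_prr, random_report_set


def _record(records, vaccine, symptom):
    return next(r for r in records if r.pair == (vaccine, symptom))


def test_count_pairs_tiny3(tiny3):
    """A report with j vaccines and k symptoms contributes j×k pairs, once each."""
    records, ctx = count_pairs(tiny3)
    pairs = {r.pair: r.n_pair_total for r in records}
    assert pairs == {
        ("DTAP", "Fever"): 1,
        ("MMR", "Fever"): 1,
        ("FLU", "Fever"): 1,
        ("FLU", "Rash"): 1,
    }
    # empty report R3 still counts in the denominators
    assert ctx.overall.n_total == 3
    assert ctx.by_year[1991].n_total == 2


def test_count_pairs_rejects_empty():
    with pytest.raises(ValueError):
        count_pairs(ReportSet([]))


def test_prr_toy_prr_closed_form(toy_prr):
    """a=4, b=10, c=20, d=100 → (4/10)/(20/100) = 2.0 exactly."""
    records, ctx = count_pairs(toy_prr)
    rec = _record(records, "V", "S")
    assert prr(rec, ctx, "overall") == 2.0


def test_prr_is_one_when_vaccine_in_every_report():
    """b = d forces a = c, so the ratio collapses to exactly 1."""
    reports = ReportSet(
        [
            Report(f"R{i}", 2000, "F", None, frozenset({"ALL"}), frozenset({"S"} if i < 3 else {"T"}))
            for i in range(10)
        ]
    )
    records, ctx = count_pairs(reports)
    assert prr(_record(records, "ALL", "S"), ctx, "overall") == 1.0
    assert prr(_record(records, "ALL", "T"), ctx, "overall") == 1.0


def test_prr_undefined_on_zero_denominator():
    """A stratum where the symptom never appears yields a flagged None."""
    reports = ReportSet(
        [
            Report("R1", 2000, "F", None, frozenset({"V"}), frozenset({"S"})),
            Report("R2", 2000, "M", None, frozenset({"W"}), frozenset()),
            Report("R3", 2001, "M", None, frozenset({"W"}), frozenset({"T"})),
        ]
    )
    records, ctx = count_pairs(reports)
    rec = _record(records, "V", "S")
    # S never appears in 2001 (c = 0) and V never appears in the M stratum (b = 0)
    assert prr(rec, ctx, ("year", 2001)) is None
    assert prr(rec, ctx, ("sex", "M")) is None
    assert prr(rec, ctx, "overall") is not None


def test_compute_prrs_fills_strata(toy_prr):
    records, ctx = count_pairs(toy_prr)
    compute_prrs(records, ctx)
    rec = _record(records, "V", "S")
    assert rec.prr_overall == 2.0
    assert set(rec.prr_by_sex) == {"F", "M"}
    assert set(rec.prr_by_year) == set(rec.n_pair_by_year)


def test_significance_is_strict():
    """PRR must be strictly greater than the threshold; undefined never passes."""
    recs = [
        AssociationRecord("V1", "S", prr_overall=0.5),
        AssociationRecord("V2", "S", prr_overall=1.0),
        AssociationRecord("V3", "S", prr_overall=1.0001),
        AssociationRecord("V4", "S", prr_overall=None),
    ]
    kept = significant_associations(recs, "overall")
    assert [r.vaccine for r in kept] == ["V3"]
    with pytest.raises(ValueError):
        significant_associations(recs, "overall", threshold=0)


def test_demographics_tiny3(tiny3):
    demo = demographic_distribution(tiny3, "FLU", "Fever")
    assert demo.sex_counts == {"F": 1, "M": 0, "U": 0}
    assert demo.age_counts["18-64"] == 1 and demo.total == 1
    assert demo.by_year[1991]["sex"]["F"] == 1
    absent = demographic_distribution(tiny3, "FLU", "Nonexistent")
    assert absent.total == 0 and all(v == 0 for v in absent.age_counts.values())


def test_demographics_sum_to_pair_total(small_corpus):
    reports, _ = small_corpus
    records, _ = count_pairs(reports)
    for rec in records[:25]:
        demo = demographic_distribution(reports, rec.vaccine, rec.symptom)
        assert sum(demo.sex_counts.values()) == rec.n_pair_total
        assert sum(demo.age_counts.values()) == rec.n_pair_total


@pytest.mark.parametrize(
    "age,expected",
    [(None, "unknown"), (0.0, "<2"), (1.9, "<2"), (2.0, "2-17"), (17.9, "2-17"),
     (18.0, "18-64"), (64.9, "18-64"), (65.0, "65+"), (90.0, "65+")],
)
def test_age_groups(age, expected):
    assert age_group(age) == expected


def test_yearly_counts_sum_to_total(small_corpus):
    """Stratum additivity: yearly numerators reproduce the overall numerator."""
    reports, _ = small_corpus
    records, _ = count_pairs(reports)
    for rec in records:
        assert sum(rec.n_pair_by_year.values()) == rec.n_pair_total


def test_prr_invariant_under_replication():
    """Replicating every report k times leaves every PRR unchanged."""
    rng = np.random.default_rng(3)
    base = random_report_set(rng, n_reports=60)
    records, ctx = count_pairs(base)
    compute_prrs(records, ctx)
    replicated = ReportSet(
        [
            Report(f"{r.report_id}_{k}", r.year, r.sex, r.age, r.vaccines, r.symptoms)
            for r in base
            for k in range(3)
        ]
    )
    records3, ctx3 = count_pairs(replicated)
    compute_prrs(records3, ctx3)
    by_pair = {r.pair: r for r in records3}
    for rec in records:
        other = by_pair[rec.pair]
        assert other.prr_overall == rec.prr_overall
        assert other.prr_by_sex == rec.prr_by_sex
        assert other.prr_by_year == rec.prr_by_year


@pytest.mark.parametrize("seed", range(6))
def test_prr_matches_brute_force_scan(seed):
    """Formula-based PRR equals exhaustive report scanning, exactly, all strata."""
    rng = np.random.default_rng(seed)
    reports = random_report_set(rng, n_reports=150)
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)
    years = {r.year for r in reports if r.year is not None}
    for rec in records:
        assert rec.prr_overall == brute_force_prr(reports, rec.vaccine, rec.symptom)
        for g in ("F", "M"):
            assert rec.prr_by_sex[g] == brute_force_prr(
                reports, rec.vaccine, rec.symptom, ("sex", g)
            )
        for y in years & set(rec.n_pair_by_year):
            assert rec.prr_by_year[y] == brute_force_prr(
                reports, rec.vaccine, rec.symptom, ("year", y)
            )
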