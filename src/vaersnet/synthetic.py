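"""Synthetic VAERS-like report generation with planted vaccine–AE signals.

The generator emulates the structure of spontaneous vaccine adverse-event
reports: each report carries a reporting year, sex (F/M/U), age, one or more
administered vaccines drawn from a catalog with realistic marginal usage, and
symptom terms drawn independently per report at configurable background
rates.  Planted signals multiply a symptom's probability in reports that
contain a given vaccine (optionally only for one sex), giving a known ground
truth against which PRR recovery can be tested.

The model is deliberately minimal: symptoms are conditionally independent
given the vaccines, risks combine multiplicatively (capped at probability 1),
and reporting rates carry no temporal trend.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .vaers_io import Report, ReportSet

# Default catalogs: a scaled-down spontaneous-reporting corpus.  Marginal
# vaccine usage is skewed (seasonal influenza dominates; several paediatric
# vaccines mid-range; a long tail), and symptom background rates span common
# reactogenicity terms (~per-cent scale) down to rare serious events.
DEFAULT_VACCINES: dict[str, float] = {
    "FLU3": 0.22,
    "VARCEL": 0.10,
    "MMR": 0.10,
    "DTAP": 0.09,
    "HIBV": 0.08,
    "HEP": 0.07,
    "PNC": 0.07,
    "IPV": 0.06,
    "HEPA": 0.05,
    "HPV4": 0.05,
    "TDAP": 0.04,
    "MNQ": 0.03,
    "ROT": 0.02,
    "ZOS": 0.02,
}

DEFAULT_SYMPTOMS: dict[str, float] = {
    "Pyrexia": 0.08,
    "Injection site erythema": 0.07,
    "Rash": 0.06,
    "Headache": 0.05,
    "Injection site swelling": 0.05,
    "Urticaria": 0.04,
    "Vomiting": 0.04,
    "Erythema": 0.035,
    "Pain": 0.035,
    "Dizziness": 0.03,
    "Pruritus": 0.03,
    "Nausea": 0.03,
    "Injection site pain": 0.025,
    "Fatigue": 0.025,
    "Diarrhoea": 0.02,
    "Myalgia": 0.02,
    "Chills": 0.02,
    "Arthralgia": 0.015,
    "Cough": 0.015,
    "Syncope": 0.012,
    "Oedema peripheral": 0.01,
    "Dyspnoea": 0.01,
    "Hypoaesthesia": 0.008,
    "Paraesthesia": 0.008,
    "Somnolence": 0.006,
    "Convulsion": 0.005,
    "Anaphylactic reaction": 0.004,
    "Facial palsy": 0.003,
    "Guillain-Barre syndrome": 0.002,
    "Intussusception": 0.002,
}

# age mixture: infants, children, adults, elderly, missing
_AGE_COMPONENTS = ((0.0, 2.0), (2.0, 18.0), (18.0, 65.0), (65.0, 90.0))
_AGE_WEIGHTS = (0.25, 0.20, 0.45, 0.08, 0.02)  # last = missing age


@dataclass(frozen=True)
class PlantedSignal:
    """One ground-truth association: multiply the symptom's probability by
    ``multiplier`` in reports containing ``vaccine``.

    ``sex`` is "F", "M" or "both"; "both" applies to F and M reports but not
    to unknown-sex reports.  A multiplier of 1 means no planted effect.
    """

    vaccine: str
    symptom: str
    sex: str = "both"
    multiplier: float = 1.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic corpus (all rates per report)."""

    n_reports: int = 50_000
    years: tuple[int, int] = (2010, 2013)
    vaccine_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VACCINES))
    symptom_catalog: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SYMPTOMS))
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"F": 0.56, "M": 0.38, "U": 0.06}
    )
    planted_signals: list[PlantedSignal] = field(default_factory=list)
    vaccines_per_report: dict[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("years range is inverted")
        if not self.vaccine_catalog:
            raise ValueError("vaccine_catalog is empty")
        if not self.symptom_catalog:
            raise ValueError("symptom_catalog is empty")
        for name, table in (
            ("vaccine_catalog", self.vaccine_catalog),
            ("symptom_catalog", self.symptom_catalog),
        ):
            for k, p in table.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{k!r}] probability {p} outside [0, 1]")
        if set(self.sex_probs) != {"F", "M", "U"}:
            raise ValueError("sex_probs must have exactly the keys F, M, U")
        if any(not (0.0 <= p <= 1.0) for p in self.sex_probs.values()):
            raise ValueError("sex probabilities must be in [0, 1]")
        if abs(sum(self.sex_probs.values()) - 1.0) > 1e-9:
            raise ValueError("sex_probs must sum to 1")
        for sig in self.planted_signals:
            if sig.multiplier < 0:
                raise ValueError("planted multiplier must be >= 0")
            if sig.sex not in ("F", "M", "both"):
                raise ValueError("planted sex must be F, M or both")
            if sig.vaccine not in self.vaccine_catalog:
                raise ValueError(f"planted vaccine {sig.vaccine!r} not in catalog")
            if sig.symptom not in self.symptom_catalog:
                raise ValueError(f"planted symptom {sig.symptom!r} not in catalog")
        if not self.vaccines_per_report:
            raise ValueError("vaccines_per_report is empty")
        if any(k < 1 for k in self.vaccines_per_report):
            raise ValueError("vaccines_per_report keys must be positive integers")
        if abs(sum(self.vaccines_per_report.values()) - 1.0) > 1e-9:
            raise ValueError("vaccines_per_report probabilities must sum to 1")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["planted_signals"] = [asdict(s) for s in self.planted_signals]
        d["years"] = list(self.years)
        Path(path).write_text(json.dumps(d, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        d["years"] = tuple(d["years"])
        d["planted_signals"] = [PlantedSignal(**s) for s in d.get("planted_signals", [])]
        d["vaccines_per_report"] = {int(k): v for k, v in d["vaccines_per_report"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """The planted signals plus their realised co-report counts.

    ``realized[(vaccine, symptom)]`` maps stratum labels ("total", "F", "M")
    to the number of emitted reports containing both terms; recountable from
    the emitted ReportSet.
    """

    planted_signals: list[PlantedSignal]
    realized: dict[tuple[str, str], dict[str, int]]


def generate_reports(config: SyntheticConfig) -> tuple[ReportSet, GroundTruth]:
    """Draw a seeded synthetic ReportSet and its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    y0, y1 = config.years
    years = rng.integers(y0, y1 + 1, size=n)
    sexes = rng.choice(
        np.array(["F", "M", "U"]),
        size=n,
        p=[config.sex_probs["F"], config.sex_probs["M"], config.sex_probs["U"]],
    )

    comp = rng.choice(len(_AGE_WEIGHTS), size=n, p=_AGE_WEIGHTS)
    u = rng.random(n)
    ages = np.full(n, np.nan)
    for i, (lo, hi) in enumerate(_AGE_COMPONENTS):
        mask = comp == i
        ages[mask] = np.round(lo + u[mask] * (hi - lo), 1)

    vacc_names = np.array(sorted(config.vaccine_catalog))
    vacc_probs = np.array([config.vaccine_catalog[v] for v in vacc_names], dtype=float)
    if (vacc_probs <= 0).all():
        raise ValueError("at least one vaccine usage probability must be positive")
    n_vacc = len(vacc_names)
    k_choices = np.array(sorted(config.vaccines_per_report))
    k_probs = np.array([config.vaccines_per_report[k] for k in k_choices], dtype=float)
    n_per = np.minimum(rng.choice(k_choices, size=n, p=k_probs), n_vacc)

    # weighted sampling without replacement per report via the Gumbel top-k trick
    with np.errstate(divide="ignore"):
        logp = np.where(vacc_probs > 0, np.log(vacc_probs), -np.inf)
    keys = rng.gumbel(size=(n, n_vacc)) + logp
    order = np.argsort(-keys, axis=1)
    member = np.zeros((n, n_vacc), dtype=bool)
    sel = np.arange(n_vacc)[None, :] < n_per[:, None]
    member[np.repeat(np.arange(n), n_per), order[sel]] = True

    symp_names = np.array(sorted(config.symptom_catalog))
    bg = np.array([config.symptom_catalog[s] for s in symp_names], dtype=float)
    prob = np.tile(bg, (n, 1))
    v_index = {v: i for i, v in enumerate(vacc_names)}
    s_index = {s: i for i, s in enumerate(symp_names)}
    for sig in config.planted_signals:
        if sig.sex == "both":
            sex_mask = (sexes == "F") | (sexes == "M")
        else:
            sex_mask = sexes == sig.sex
        rows = member[:, v_index[sig.vaccine]] & sex_mask
        prob[rows, s_index[sig.symptom]] *= sig.multiplier
    np.clip(prob, 0.0, 1.0, out=prob)
    hits = rng.random((n, len(symp_names))) < prob

    reports = []
    for i in range(n):
        reports.append(
            Report(
                report_id=f"SYN{i + 1:07d}",
                year=int(years[i]),
                sex=str(sexes[i]),
                age=None if np.isnan(ages[i]) else float(ages[i]),
                vaccines=frozenset(vacc_names[member[i]]),
                symptoms=frozenset(symp_names[hits[i]]),
            )
        )
    rs = ReportSet(reports, provenance=f"synthetic(seed={config.seed}, n={n})")

    realized: dict[tuple[str, str], dict[str, int]] = {}
    for sig in config.planted_signals:
        vi, si = v_index[sig.vaccine], s_index[sig.symptom]
        both = member[:, vi] & hits[:, si]
        realized[(sig.vaccine, sig.symptom)] = {
            "total": int(both.sum()),
            "F": int((both & (sexes == "F")).sum()),
            "M": int((both & (sexes == "M")).sum()),
        }
    return rs, GroundTruth(planted_signals=list(config.planted_signals), realized=realized)


def write_vaers_tables(reports: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Emit a ReportSet as a VAERS-style CSV triplet (DATA, VACCINE, SYMPTOMS).

    Lets the full pipeline be exercised from raw-file ingestion.  The receipt
    date is reconstructed as Jan 15 of the report's year (only the year is
    modelled); a missing year yields a blank date.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    import csv

    paths = {
        "data": out_dir / "DATA.csv",
        "vaccine": out_dir / "VACCINE.csv",
        "symptoms": out_dir / "SYMPTOMS.csv",
    }
    with paths["data"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "RECVDATE", "SEX", "AGE_YRS"])
        for r in reports:
            w.writerow(
                [
                    r.report_id,
                    "" if r.year is None else f"01/15/{r.year}",
                    r.sex,
                    "" if r.age is None else r.age,
                ]
            )
    with paths["vaccine"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "VAX_TYPE"])
        for r in reports:
            for v in sorted(r.vaccines):
                w.writerow([r.report_id, v])
    with paths["symptoms"].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "SYMPTOM"])
        for r in reports:
            for s in sorted(r.symptoms):
                w.writerow([r.report_id, s])
    return paths


def make_fixture(name: str) -> ReportSet:
    """Hand-written deterministic fixtures shared across the test suite.

    - ``tiny3``: the 3-report join example (R1 {DTAP,MMR}×{Fever}; R2
      {FLU}×{Rash,Fever} with sex F, age 30; R3 empty sets).
    - ``toy_prr``: 100 reports where vaccine V appears in 10 reports, 4 of
      them with symptom S, and S appears in 20 reports overall, so the
      overall PRR of (V, S) is (4/10)/(20/100) = 2.0.
    - ``toy_star``: 4 reports inducing a 1-vaccine / 4-AE star network.
    """
    if name == "tiny3":
        return ReportSet(
            [
                Report("R1", 1990, "M", 1.0, frozenset({"DTAP", "MMR"}), frozenset({"Fever"})),
                Report("R2", 1991, "F", 30.0, frozenset({"FLU"}), frozenset({"Rash", "Fever"})),
                Report("R3", 1991, "U", None, frozenset(), frozenset()),
            ],
            provenance="fixture:tiny3",
        )
    if name == "toy_prr":
        reports = []
        for i in range(1, 101):
            vaccines = {"V"} if i <= 10 else {"OTHER"}
            symptoms = {"Background"}
            # S in 4 of V's 10 reports and in 16 others: 20 of 100 overall
            if i <= 4 or 11 <= i <= 26:
                symptoms.add("S")
            reports.append(
                Report(
                    f"P{i:03d}",
                    2000 + (i % 2),
                    "F" if i % 2 else "M",
                    float(10 + i % 50),
                    frozenset(vaccines),
                    frozenset(symptoms),
                )
            )
        return ReportSet(reports, provenance="fixture:toy_prr")
    if name == "toy_star":
        aes = ["AE1", "AE2", "AE3", "AE4"]
        return ReportSet(
            [
                Report(
                    f"S{i + 1}",
                    2005,
                    "F" if i % 2 else "M",
                    float(20 + i),
                    frozenset({"STAR_V"}),
                    frozenset({aes[i]}),
                )
                for i in range(4)
            ],
            provenance="fixture:toy_star",
        )
    raise KeyError(f"unknown fixture {name!r}; expected one of tiny3, toy_prr, toy_star")
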