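import csv
from pathlib import Path

import pytest

from vaersnet import PlantedSignal, SyntheticConfig, generate_reports, make_fixture


@pytest.fixture
def tiny3():
    return make_fixture("tiny3")


@pytest.fixture
def toy_prr():
    return make_fixture("toy_prr")


@pytest.fixture
def toy_star():
    return make_fixture("toy_star")


@pytest.fixture(scope="session")
def small_corpus():
    """A seeded 3000-report corpus with one female-specific planted signal."""
    cfg = SyntheticConfig(
        n_reports=3000,
        seed=11,
        planted_signals=[PlantedSignal("MMR", "Rash", "F", 5.0)],
    )
    reports, truth = generate_reports(cfg)
    return reports, truth


def write_triplet(
    out_dir: Path,
    data_rows: list[dict],
    vaccine_rows: list[tuple[str, str]],
    symptom_rows: list[tuple[str, str]],
) -> tuple[Path, Path, Path]:
    """Write a raw VAERS-style CSV triplet for ingestion tests."""
    data = out_dir / "DATA.csv"
    vax = out_dir / "VACCINE.csv"
    sym = out_dir / "SYMPTOMS.csv"
    with data.open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["VAERS_ID", "RECVDATE", "SEX", "AGE_YRS"])
        w.writeheader()
        for row in data_rows:
            w.writerow({k: row.get(k, "") for k in w.fieldnames})
    with vax.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "VAX_TYPE"])
        w.writerows(vaccine_rows)
    with sym.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["VAERS_ID", "SYMPTOM"])
        w.writerows(symptom_rows)
    return data, vax, sym
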