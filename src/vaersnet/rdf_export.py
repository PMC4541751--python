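"""RDF serialisation of vaccine–AE association summaries, and queries over it.

Each distinct (vaccine, symptom) pair becomes one association resource with a
deterministic identifier, linked to its vaccine code, symptom term, report
counts, stratified (per-year / per-sex) PRR nodes and, when available, its
demographic distribution.  No external vocabulary exists for this meta-model,
so a small project namespace is used:

    prefix vaersnet: <http://vaersnet.example.org/ns#>
    predicates: hasVaccine, hasSymptom, reportCount, hasPRR, prrUndefined,
                hasStratum, forYear, forSex,
                hasDemographic, dimension, category, demographicCount

Triple budget per record: 5 base triples (rdf:type, hasVaccine, hasSymptom,
reportCount, hasPRR-or-prrUndefined) + up to 4 per stratum node (hasStratum,
forYear/forSex, reportCount, hasPRR-or-prrUndefined) + 4-5 per demographic
cell.  Stratum and demographic nodes use deterministic URIs (no blank nodes),
so the sorted N-Triples form is canonical.
"""

from __future__ import annotations

import hashlib
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Optional
from urllib.parse import quote

from rdflib import Graph, Literal, Namespace, RDF, URIRef
from rdflib.namespace import XSD

from .disproportionality import AssociationRecord, DemographicDistribution

VN = Namespace("http://vaersnet.example.org/ns#")


class IntegrityError(ValueError):
    """The graph violates the association meta-model (missing mandatory links)."""


def association_uri(vaccine: str, symptom: str) -> URIRef:
    """Deterministic association identifier: encoded vaccine + hashed symptom."""
    tag = hashlib.sha1(symptom.encode("utf-8")).hexdigest()[:16]
    return URIRef(str(VN) + "assoc/" + quote(vaccine, safe="") + "_" + tag)


def _prr_literal(value: float) -> Literal:
    # positional xsd:decimal: repr() is the shortest exact form and Turtle's
    # plain-literal shorthand preserves a decimal lexical verbatim (it
    # reformats xsd:double, losing precision)
    lexical = format(Decimal(repr(float(value))), "f")
    if "." not in lexical:
        lexical += ".0"
    return Literal(lexical, datatype=XSD.decimal)


def _add_prr(g: Graph, node: URIRef, value: Optional[float]) -> None:
    if value is None:
        g.add((node, VN.prrUndefined, Literal(True)))
    else:
        g.add((node, VN.hasPRR, _prr_literal(value)))


def _add_demo(g: Graph, assoc: URIRef, demo: DemographicDistribution) -> None:
    def cell(suffix: str, dimension: str, category: str, count: int, year: Optional[int]) -> None:
        node = URIRef(str(assoc) + "/demo/" + suffix)
        g.add((assoc, VN.hasDemographic, node))
        g.add((node, VN.dimension, Literal(dimension)))
        g.add((node, VN.category, Literal(category)))
        g.add((node, VN.demographicCount, Literal(int(count), datatype=XSD.integer)))
        if year is not None:
            g.add((node, VN.forYear, Literal(int(year), datatype=XSD.integer)))

    for cat, n in demo.sex_counts.items():
        cell(f"sex/{quote(cat, safe='')}", "sex", cat, n, None)
    for cat, n in demo.age_counts.items():
        cell(f"age/{quote(cat, safe='')}", "age", cat, n, None)
    for year, breakdown in demo.by_year.items():
        for cat, n in breakdown["sex"].items():
            cell(f"{year}/sex/{quote(cat, safe='')}", "sex", cat, n, year)
        for cat, n in breakdown["age"].items():
            cell(f"{year}/age/{quote(cat, safe='')}", "age", cat, n, year)


def to_rdf(records: Iterable[AssociationRecord]) -> Graph:
    """Serialise association records into an RDF graph (the Fig.-2-style meta-model).

    Records must be unique per (vaccine, symptom); counts and PRRs are
    expected to be computed already.  Undefined PRRs are marked explicitly
    rather than dropped.
    """
    records = list(records)
    pairs = [r.pair for r in records]
    if len(pairs) != len(set(pairs)):
        raise ValueError("duplicate (vaccine, symptom) records in RDF input")

    g = Graph()
    g.bind("vaersnet", VN)
    for rec in sorted(records, key=lambda r: r.pair):
        assoc = association_uri(rec.vaccine, rec.symptom)
        g.add((assoc, RDF.type, VN.VaccineAEAssociation))
        g.add((assoc, VN.hasVaccine, Literal(rec.vaccine)))
        g.add((assoc, VN.hasSymptom, Literal(rec.symptom)))
        g.add((assoc, VN.reportCount, Literal(int(rec.n_pair_total), datatype=XSD.integer)))
        _add_prr(g, assoc, rec.prr_overall)

        years = sorted(set(rec.n_pair_by_year) | set(rec.prr_by_year))
        for y in years:
            snode = URIRef(str(assoc) + f"/year/{int(y)}")
            g.add((assoc, VN.hasStratum, snode))
            g.add((snode, VN.forYear, Literal(int(y), datatype=XSD.integer)))
            if y in rec.n_pair_by_year:
                g.add((snode, VN.reportCount,
                       Literal(int(rec.n_pair_by_year[y]), datatype=XSD.integer)))
            if y in rec.prr_by_year:
                _add_prr(g, snode, rec.prr_by_year[y])

        for sex in sorted(set(rec.n_pair_by_sex) | set(rec.prr_by_sex)):
            snode = URIRef(str(assoc) + f"/sex/{quote(sex, safe='')}")
            g.add((assoc, VN.hasStratum, snode))
            g.add((snode, VN.forSex, Literal(sex)))
            if sex in rec.n_pair_by_sex:
                g.add((snode, VN.reportCount,
                       Literal(int(rec.n_pair_by_sex[sex]), datatype=XSD.integer)))
            if sex in rec.prr_by_sex:
                _add_prr(g, snode, rec.prr_by_sex[sex])

        if rec.demo is not None:
            _add_demo(g, assoc, rec.demo)
    return g


def _read_prr(g: Graph, node: URIRef) -> tuple[bool, Optional[float]]:
    """(present, value) for a node's PRR; value None when explicitly undefined."""
    lit = g.value(node, VN.hasPRR)
    if lit is not None:
        return True, float(lit)
    if g.value(node, VN.prrUndefined) is not None:
        return True, None
    return False, None


def query_association(graph: Graph, vaccine: str, symptom: str) -> Optional[AssociationRecord]:
    """Reconstruct one association record from the graph; None if absent.

    Raises :class:`IntegrityError` when the matched association resource
    lacks a mandatory link (vaccine, symptom, count, or overall PRR marker).
    """
    with_v = set(graph.subjects(VN.hasVaccine, Literal(vaccine)))
    with_s = set(graph.subjects(VN.hasSymptom, Literal(symptom)))
    matches = with_v & with_s
    if not matches:
        return None
    if len(matches) > 1:
        raise IntegrityError(f"multiple association resources for ({vaccine!r}, {symptom!r})")
    assoc = matches.pop()

    total = graph.value(assoc, VN.reportCount)
    if total is None:
        raise IntegrityError(f"association {assoc} lacks a reportCount")
    present, prr_overall = _read_prr(graph, assoc)
    if not present:
        raise IntegrityError(f"association {assoc} lacks an overall PRR or undefined marker")

    rec = AssociationRecord(
        vaccine=vaccine,
        symptom=symptom,
        n_pair_total=int(total),
        n_pair_by_year={},
        n_pair_by_sex={},
        prr_overall=prr_overall,
        prr_by_year={},
        prr_by_sex={},
    )
    for snode in graph.objects(assoc, VN.hasStratum):
        year = graph.value(snode, VN.forYear)
        sex = graph.value(snode, VN.forSex)
        count = graph.value(snode, VN.reportCount)
        present, value = _read_prr(graph, snode)
        if year is not None:
            y = int(year)
            if count is not None:
                rec.n_pair_by_year[y] = int(count)
            if present:
                rec.prr_by_year[y] = value
        elif sex is not None:
            s = str(sex)
            if count is not None:
                rec.n_pair_by_sex[s] = int(count)
            if present:
                rec.prr_by_sex[s] = value
        else:
            raise IntegrityError(f"stratum node {snode} has neither forYear nor forSex")
    rec.n_pair_by_year = dict(sorted(rec.n_pair_by_year.items()))

    demo_nodes = list(graph.objects(assoc, VN.hasDemographic))
    if demo_nodes:
        sex_counts: dict[str, int] = {}
        age_counts: dict[str, int] = {}
        by_year: dict[int, dict[str, dict[str, int]]] = {}
        for node in demo_nodes:
            dim = str(graph.value(node, VN.dimension))
            cat = str(graph.value(node, VN.category))
            n = int(graph.value(node, VN.demographicCount))
            year = graph.value(node, VN.forYear)
            if year is None:
                (sex_counts if dim == "sex" else age_counts)[cat] = n
            else:
                yr = by_year.setdefault(int(year), {"sex": {}, "age": {}})
                yr[dim][cat] = n
        rec.demo = DemographicDistribution(
            sex_counts=sex_counts,
            age_counts=age_counts,
            by_year=dict(sorted(by_year.items())),
        )
    return rec


def list_pairs(graph: Graph) -> list[tuple[str, str]]:
    """All (vaccine, symptom) pairs with an association resource in the graph."""
    pairs = []
    for assoc in graph.subjects(RDF.type, VN.VaccineAEAssociation):
        v = graph.value(assoc, VN.hasVaccine)
        s = graph.value(assoc, VN.hasSymptom)
        if v is None or s is None:
            raise IntegrityError(f"association {assoc} lacks a vaccine or symptom link")
        pairs.append((str(v), str(s)))
    return sorted(pairs)


def pairs_with_prr_above(graph: Graph, threshold: float = 1.0) -> list[tuple[str, str]]:
    """Pairs whose overall PRR literal is strictly above the threshold."""
    out = []
    for assoc, _, lit in graph.triples((None, VN.hasPRR, None)):
        if (assoc, RDF.type, VN.VaccineAEAssociation) not in graph:
            continue  # skip stratum nodes, which also carry hasPRR
        if float(lit) > threshold:
            v = graph.value(assoc, VN.hasVaccine)
            s = graph.value(assoc, VN.hasSymptom)
            if v is not None and s is not None:
                out.append((str(v), str(s)))
    return sorted(out)


def canonical_ntriples(graph: Graph) -> str:
    """Sorted N-Triples serialisation; identical for isomorphic URI-only graphs."""
    nt = graph.serialize(format="nt")
    lines = sorted(line for line in nt.splitlines() if line.strip())
    return "\n".join(lines) + "\n"


def write_turtle(graph: Graph, path: str | Path) -> None:
    Path(path).write_text(graph.serialize(format="turtle"), encoding="utf-8")


def write_ntriples(graph: Graph, path: str | Path) -> None:
    Path(path).write_text(canonical_ntriples(graph), encoding="utf-8")


def read_rdf(path: str | Path) -> Graph:
    """Parse a Turtle or N-Triples file back into a graph."""
    g = Graph()
    fmt = "turtle" if str(path).endswith((".ttl", ".turtle")) else "nt"
    g.parse(str(path), format=fmt)
    return g
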