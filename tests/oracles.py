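"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: PRR by exhaustive
report scanning, shortest paths by Floyd–Warshall, and the PCC index via the
textbook Pearson correlation of binary incidence vectors.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from vaersnet.association_network import BipartiteNetwork
from vaersnet.vaers_io import Report, ReportSet

_INF = 10**9


def brute_force_prr(
    reports: ReportSet, vaccine: str, symptom: str, stratum="overall"
) -> Optional[float]:
    """PRR recomputed by scanning every report in the stratum."""
    if stratum == "overall":
        sub = list(reports)
    elif isinstance(stratum, tuple) and stratum[0] == "year":
        sub = [r for r in reports if r.year == stratum[1]]
    elif isinstance(stratum, tuple) and stratum[0] == "sex":
        sub = [r for r in reports if r.sex == stratum[1]]
    else:
        raise ValueError(f"bad stratum {stratum!r}")
    a = sum(1 for r in sub if vaccine in r.vaccines and symptom in r.symptoms)
    b = sum(1 for r in sub if vaccine in r.vaccines)
    c = sum(1 for r in sub if symptom in r.symptoms)
    d = len(sub)
    if b == 0 or c == 0 or d == 0:
        return None
    return (a / b) / (c / d)


def floyd_warshall_metrics(net: BipartiteNetwork) -> tuple[float, int]:
    """(average path length, diameter) over reachable unordered pairs.

    Integer distance total accumulated before the single division, so the
    float mean is bit-identical to any implementation summing the same
    multiset of integer distances.
    """
    nodes = sorted(net.vaccine_nodes) + sorted(net.ae_nodes)
    n = len(nodes)
    if n == 0:
        return 0.0, 0
    idx = {name: i for i, name in enumerate(nodes)}
    dist = np.full((n, n), _INF, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    for v, s in net.edges:
        i, j = idx[v], idx[s]
        dist[i, j] = dist[j, i] = 1
    for k in range(n):
        dist = np.minimum(dist, dist[:, k, None] + dist[None, k, :])
    off = (~np.eye(n, dtype=bool)) & (dist < _INF)
    count = int(off.sum())
    if count == 0:
        return 0.0, 0
    total = int(dist[off].sum())
    return total / count, int(dist[off].max())


def binary_vector_pearson(deg_a: int, deg_b: int, shared: int, n_y: int) -> float:
    """Pearson correlation of two materialised binary incidence vectors."""
    x = np.zeros(n_y)
    y = np.zeros(n_y)
    x[:deg_a] = 1
    y[:shared] = 1  # overlap with the start of x
    y[deg_a : deg_a + (deg_b - shared)] = 1
    return float(np.corrcoef(x, y)[0, 1])


def random_report_set(rng: np.random.Generator, n_reports: int = 120) -> ReportSet:
    """A small random ReportSet for oracle comparisons (no planted structure)."""
    vaccines = [f"V{j}" for j in range(5)]
    symptoms = [f"S{j}" for j in range(8)]
    reports = []
    for i in range(n_reports):
        year = int(rng.integers(2000, 2003)) if rng.random() > 0.05 else None
        sex = str(rng.choice(["F", "M", "U"], p=[0.45, 0.45, 0.10]))
        nv = int(rng.integers(0, 4))
        ns = int(rng.integers(0, 4))
        vs = frozenset(rng.choice(vaccines, size=nv, replace=False)) if nv else frozenset()
        ss = frozenset(rng.choice(symptoms, size=ns, replace=False)) if ns else frozenset()
        age = float(rng.integers(0, 90)) if rng.random() > 0.1 else None
        reports.append(Report(f"R{i:04d}", year, sex, age, vs, ss))
    return ReportSet(reports, provenance="random-oracle-fixture")


def random_bipartite_network(rng: np.random.Generator, max_nodes: int = 300) -> BipartiteNetwork:
    """A random bipartite network with at least one edge."""
    nv = int(rng.integers(2, max(3, max_nodes // 4)))
    na = int(rng.integers(2, max(3, max_nodes - nv)))
    p = float(rng.uniform(0.01, 0.2))
    edges = set()
    mask = rng.random((nv, na)) < p
    for i, j in zip(*np.nonzero(mask)):
        edges.add((f"V{i}", f"A{j}"))
    if not edges:
        edges.add(("V0", "A0"))
    from vaersnet.association_network import build_network

    return build_network(edges)
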