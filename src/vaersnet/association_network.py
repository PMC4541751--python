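"""Bipartite vaccine–adverse-event association networks and their metrics.

Significant associations (stratum PRR > 1) become edges of an undirected
bipartite graph with vaccine nodes on one side and adverse-event (AE) terms
on the other.  The summary statistics mirror common network-analyzer output:
average node degree 2E/N, average shortest-path length over reachable
unordered node pairs, and diameter (largest finite eccentricity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx

from .disproportionality import (
    AssociationRecord,
    compute_prrs,
    count_pairs,
    significant_associations,
)
from .vaers_io import ReportSet


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 → 0.01), for table-style presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BipartiteNetwork:
    """Vaccine nodes, AE nodes and the undirected edges between the two types.

    Nodes exist only through edges (no isolated nodes), and every edge joins
    one vaccine to one AE term.
    """

    vaccine_nodes: frozenset[str]
    ae_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]  # (vaccine, symptom)

    def __post_init__(self) -> None:
        overlap = self.vaccine_nodes & self.ae_nodes
        if overlap:
            raise ValueError(f"labels used as both vaccine and AE: {sorted(overlap)[:3]}")
        touched_v, touched_a = set(), set()
        for v, s in self.edges:
            if v not in self.vaccine_nodes or s not in self.ae_nodes:
                raise ValueError(f"edge ({v!r}, {s!r}) does not join a vaccine to an AE")
            touched_v.add(v)
            touched_a.add(s)
        if touched_v != set(self.vaccine_nodes) or touched_a != set(self.ae_nodes):
            raise ValueError("network contains isolated nodes")

    @property
    def n_node(self) -> int:
        return len(self.vaccine_nodes) + len(self.ae_nodes)

    @property
    def n_link(self) -> int:
        return len(self.edges)


@dataclass
class NetworkMetrics:
    """The per-stratum characteristics row: N, E, 2E/N, mean path, diameter."""

    n_node: int
    n_link: int
    average_degree: float
    average_path_length: float
    diameter: int
    empty: bool = False  # flag for a stratum with no significant associations

    def rounded(self, ndigits: int = 2) -> "NetworkMetrics":
        return NetworkMetrics(
            self.n_node,
            self.n_link,
            round_half_up(self.average_degree, ndigits),
            round_half_up(self.average_path_length, ndigits),
            self.diameter,
            self.empty,
        )


def build_network(
    significant: Iterable[Union[AssociationRecord, tuple[str, str]]]
) -> BipartiteNetwork:
    """Build the bipartite network from (pre-filtered) association records.

    Accepts records or bare (vaccine, symptom) tuples; duplicates collapse to
    a single edge.  An empty input yields the (valid) empty network.
    """
    edges: set[tuple[str, str]] = set()
    for item in significant:
        if isinstance(item, AssociationRecord):
            edges.add((item.vaccine, item.symptom))
        else:
            v, s = item
            edges.add((str(v), str(s)))
    return BipartiteNetwork(
        vaccine_nodes=frozenset(v for v, _ in edges),
        ae_nodes=frozenset(s for _, s in edges),
        edges=frozenset(edges),
    )


def to_networkx(net: BipartiteNetwork) -> nx.Graph:
    """Undirected networkx view with a ``type`` node attribute (deterministic order)."""
    g = nx.Graph()
    for v in sorted(net.vaccine_nodes):
        g.add_node(v, type="vaccine")
    for s in sorted(net.ae_nodes):
        g.add_node(s, type="ae")
    g.add_edges_from(sorted(net.edges))
    return g


def network_metrics(net: BipartiteNetwork) -> NetworkMetrics:
    """Degree/path summary of a bipartite network.

    Shortest paths are unweighted (breadth-first).  The mean is taken over
    reachable unordered node pairs, self-pairs excluded; the diameter is the
    largest finite shortest-path length.  For a disconnected network this
    averages within components, the usual network-analyzer convention.
    """
    if net.n_node == 0:
        return NetworkMetrics(0, 0, 0.0, 0.0, 0, empty=True)
    g = to_networkx(net)
    # accumulate the integer distance total first so the single division is
    # reproducible against any oracle that sums the same multiset
    total = 0
    count = 0
    diameter = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                count += 1
                if d > diameter:
                    diameter = d
    apl = total / count if count else 0.0
    return NetworkMetrics(
        n_node=net.n_node,
        n_link=net.n_link,
        average_degree=2 * net.n_link / net.n_node,
        average_path_length=apl,
        diameter=diameter,
        empty=net.n_link == 0,
    )


def yearly_metrics_table(
    reports: ReportSet,
    threshold: float = 1.0,
    strata: Optional[Sequence[str]] = None,
) -> list[tuple[str, NetworkMetrics]]:
    """One metrics row per reporting year plus Female, Male and Overall.

    ``strata`` restricts the rows: any of "years", "F", "M", "overall"
    (default all).  Each row is built from that stratum's PRR>threshold
    associations; a stratum with none yields a zero row flagged ``empty``.
    """
    wanted = set(strata) if strata is not None else {"years", "F", "M", "overall"}
    records, ctx = count_pairs(reports)
    compute_prrs(records, ctx)

    rows: list[tuple[str, NetworkMetrics]] = []

    def row(label: str, stratum) -> None:
        sig = significant_associations(records, stratum, threshold)
        rows.append((label, network_metrics(build_network(sig))))

    if "years" in wanted:
        for y in ctx.years():
            row(str(y), ("year", y))
    if "F" in wanted:
        row("Female", ("sex", "F"))
    if "M" in wanted:
        row("Male", ("sex", "M"))
    if "overall" in wanted:
        row("Overall", "overall")
    return rows


def metrics_table_to_tsv(rows: Iterable[tuple[str, NetworkMetrics]], path: str | Path) -> None:
    """Write the metrics table as TSV in the standard column order."""
    path = Path(path)
    lines = ["stratum\tn_node\tn_link\taverage_degree\taverage_path_length\tdiameter"]
    for label, m in rows:
        r = m.rounded()
        lines.append(
            f"{label}\t{m.n_node}\t{m.n_link}\t{r.average_degree:.2f}"
            f"\t{r.average_path_length:.2f}\t{m.diameter}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """GraphML export with the node ``type`` attribute (vaccine vs ae)."""
    nx.write_graphml(to_networkx(net), str(path))
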