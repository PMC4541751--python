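"""Projection of the bipartite network onto one node type via a PCC index.

For two same-type nodes A and B of a bipartite network, with degree |N(A)|,
|N(B)|, shared opposite-type neighbours |N(A)∩N(B)| and n_y opposite-type
nodes in total, the association index is

    PCC_AB = (|N(A)∩N(B)|·n_y − |N(A)|·|N(B)|)
             / sqrt(|N(A)|·|N(B)|·(n_y−|N(A)|)·(n_y−|N(B)|))

which is exactly the Pearson correlation of the two binary incidence vectors
over the opposite node set: 1 for perfect overlap, 0 for chance overlap, −1
for perfect anti-correlation.  The index is undefined (NaN) for a node
connected to none or all opposite-type nodes.

Vaccines are then clustered agglomeratively on distance 1 − PCC, and the
female/male similarity distributions compared descriptively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import ks_2samp

from .association_network import BipartiteNetwork

logger = logging.getLogger(__name__)

DENSITY_BIN_WIDTH = 0.05  # fixed bins over [-1, 1] so strata overlays align


def pcc_index(deg_a: int, deg_b: int, shared: int, n_y: int) -> float:
    """PCC association index from the two degrees, overlap and n_y.

    Returns NaN (undefined) when either degree is 0 or n_y.  Raises on
    inconsistent counts (overlap exceeding a degree, degree exceeding n_y).
    """
    for name, val in (("deg_a", deg_a), ("deg_b", deg_b), ("shared", shared), ("n_y", n_y)):
        if val < 0:
            raise ValueError(f"{name} must be non-negative, got {val}")
    if shared > min(deg_a, deg_b):
        raise ValueError(f"shared={shared} exceeds min(deg_a, deg_b)={min(deg_a, deg_b)}")
    if max(deg_a, deg_b) > n_y:
        raise ValueError(f"degree exceeds n_y={n_y}")
    if deg_a in (0, n_y) or deg_b in (0, n_y):
        return math.nan
    num = shared * n_y - deg_a * deg_b
    den = math.sqrt(deg_a * deg_b * (n_y - deg_a) * (n_y - deg_b))
    return num / den


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise PCC indexes over one node type.

    ``values[i, j]`` is the index between ``labels[i]`` and ``labels[j]``;
    undefined entries are NaN.  ``n_y`` is the size of the opposite node set
    the indexes were computed against.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    n_y: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.10g")

    def offdiagonal_values(self) -> np.ndarray:
        """Upper-triangle (i < j) index values, NaN entries dropped."""
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]


def similarity_matrix(net: BipartiteNetwork, project_onto: str = "vaccine") -> SimilarityMatrix:
    """All pairwise PCC indexes among the chosen node type of a network."""
    if project_onto == "vaccine":
        labels = sorted(net.vaccine_nodes)
        opposite = sorted(net.ae_nodes)
        nbrs = {v: {s for (vv, s) in net.edges if vv == v} for v in labels}
    elif project_onto == "ae":
        labels = sorted(net.ae_nodes)
        opposite = sorted(net.vaccine_nodes)
        nbrs = {s: {v for (v, ss) in net.edges if ss == s} for s in labels}
    else:
        raise ValueError("project_onto must be 'vaccine' or 'ae'")
    if len(labels) < 2:
        raise ValueError(f"need at least 2 {project_onto} nodes, found {len(labels)}")

    n_y = len(opposite)
    pos = {name: i for i, name in enumerate(opposite)}
    # binary incidence matrix: labels x opposite nodes
    B = np.zeros((len(labels), n_y), dtype=np.int64)
    for i, lab in enumerate(labels):
        for o in nbrs[lab]:
            B[i, pos[o]] = 1
    deg = B.sum(axis=1)
    shared = B @ B.T
    num = shared * n_y - np.outer(deg, deg)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt(np.outer(deg, deg) * np.outer(n_y - deg, n_y - deg)).astype(float)
        vals = np.where(den > 0, num / den, np.nan)
    bad = (deg == 0) | (deg == n_y)
    vals[bad, :] = np.nan
    vals[:, bad] = np.nan
    return SimilarityMatrix(labels=tuple(labels), values=vals, n_y=n_y)


@dataclass
class ClusterTree:
    """Agglomerative merge tree over vaccine labels (scipy linkage encoding)."""

    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix

    def cut(self, k: int) -> dict[str, int]:
        """Flat clustering into k groups; label → cluster id (1-based)."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = merge-height differences."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_").replace(",", "").replace(
                    "(", "").replace(")", "").replace(":", "").replace(";", "")
                return f"{name}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});"


def cluster_vaccines(sim: SimilarityMatrix, method: str = "average") -> ClusterTree:
    """Hierarchical clustering of the similarity profiles on distance 1 − PCC.

    Undefined (NaN) indexes are imputed as 0 — the index's chance reference
    point — with a logged warning.  Labels are processed in lexicographic
    order so ties break deterministically.
    """
    if len(sim.labels) < 2:
        raise ValueError("clustering requires at least 2 labels")
    order = np.argsort(np.array(sim.labels))
    labels = tuple(sim.labels[i] for i in order)
    vals = sim.values[np.ix_(order, order)].astype(float).copy()
    off = ~np.eye(len(labels), dtype=bool)
    if np.isnan(vals[off]).all():
        raise ValueError("all off-diagonal similarities are undefined")
    n_nan = int(np.isnan(vals).sum())
    if n_nan:
        logger.warning("imputing %d undefined PCC entries as 0 for clustering", n_nan)
        vals = np.nan_to_num(vals, nan=0.0)
    dist = 1.0 - vals
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # enforce exact symmetry
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    return ClusterTree(labels=labels, linkage=z)


@dataclass
class StrataComparison:
    """Descriptive comparison of PCC distributions between two strata.

    ``values_a``/``values_b`` are the paired off-diagonal indexes over the
    common label set (pairs undefined in either stratum are dropped);
    ``density`` holds aligned binned counts for overlay plotting; the
    Kolmogorov–Smirnov distance is reported descriptively, with no p-value.
    """

    common_labels: tuple[str, ...]
    values_a: np.ndarray
    values_b: np.ndarray
    density: pd.DataFrame  # bin_left, bin_right, count_a, count_b
    ks_distance: float

    def density_to_tsv(self, path: str | Path) -> None:
        self.density.to_csv(path, sep="\t", index=False)


def compare_strata(sim_a: SimilarityMatrix, sim_b: SimilarityMatrix) -> StrataComparison:
    """Compare two similarity matrices (e.g. female vs male) over common labels."""
    common = sorted(set(sim_a.labels) & set(sim_b.labels))
    if len(common) < 2:
        raise ValueError(f"need at least 2 common labels, found {len(common)}")
    ia = [sim_a.labels.index(c) for c in common]
    ib = [sim_b.labels.index(c) for c in common]
    a = sim_a.values[np.ix_(ia, ia)]
    b = sim_b.values[np.ix_(ib, ib)]
    iu = np.triu_indices(len(common), k=1)
    va, vb = a[iu], b[iu]
    keep = ~(np.isnan(va) | np.isnan(vb))
    va, vb = va[keep], vb[keep]
    if va.size == 0:
        raise ValueError("no defined pairs in common between the two strata")

    edges = np.round(np.arange(-1.0, 1.0 + DENSITY_BIN_WIDTH / 2, DENSITY_BIN_WIDTH), 10)
    count_a, _ = np.histogram(va, bins=edges)
    count_b, _ = np.histogram(vb, bins=edges)
    density = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count_a": count_a,
            "count_b": count_b,
        }
    )
    ks = float(ks_2samp(va, vb).statistic) if (va.size and vb.size) else 0.0
    if np.array_equal(va, vb):
        ks = 0.0
    return StrataComparison(
        common_labels=tuple(common),
        values_a=va,
        values_b=vb,
        density=density,
        ks_distance=ks,
    )
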