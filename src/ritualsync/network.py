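"""Proximity graph, shortest-path node distances, and the five pair categories.

Two worshippers in the same space are adjacent when their recorded mean
distance is within 2 m (closed threshold). Pairs are partitioned into:

* ``imam_colocated`` — the imam with a worshipper sharing his space;
* ``imam_noncolocated`` — the imam with a worshipper in the separated space;
* ``neighbours`` — two non-imam worshippers, adjacent;
* ``distant`` — two non-imam worshippers, same space, not adjacent;
* ``separated`` — two non-imam worshippers in different spaces (the
  reference category in every regression).

Node distance is the unweighted shortest-path length in the adjacency
graph; cross-space pairs have no finite path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

CATEGORIES = ("imam_colocated", "imam_noncolocated", "neighbours", "distant", "separated")
REFERENCE_CATEGORY = "separated"


@dataclass
class PairRecord:
    """One unordered participant pair with its spatial bookkeeping.

    ``id_a`` is the imam whenever the pair contains him (so downstream lag
    sign conventions read "positive = imam leads").
    """

    id_a: str
    id_b: str
    mean_distance_m: float  # NaN when out of radio range (cross-space)
    adjacency: bool
    node_distance: float  # positive integer, or math.inf when unreachable
    category: str
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")

    @property
    def pair_id(self) -> str:
        return f"{self.id_a}|{self.id_b}"


def build_graph(
    proximity: pd.DataFrame, metadata: pd.DataFrame, threshold_m: float = 2.0
) -> nx.Graph:
    """Undirected adjacency graph: edge iff same group and distance <= threshold."""
    ids = list(metadata.index)
    sub = proximity.loc[ids, ids].to_numpy(float)
    diffs = np.abs(sub - sub.T)
    asym = 0.0 if (diffs.size == 0 or np.all(np.isnan(diffs))) else float(np.nanmax(diffs))
    if asym > 1e-6 or not np.array_equal(np.isnan(sub), np.isnan(sub.T)):
        raise DataIntegrityError(f"proximity table asymmetric (max |d_ab - d_ba| = {asym:.3g})")

    g = nx.Graph()
    for pid in ids:
        g.add_node(pid, role=metadata.loc[pid, "role"], group=metadata.loc[pid, "group"])
    for a, b in combinations(ids, 2):
        if metadata.loc[a, "group"] != metadata.loc[b, "group"]:
            continue
        d = proximity.loc[a, b]
        if pd.notna(d) and d <= threshold_m:
            g.add_edge(a, b, distance_m=float(d))
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    if isolated:
        logger.warning("isolated nodes in proximity graph: %s", isolated)
    return g


def shortest_path_distances(graph: nx.Graph) -> pd.DataFrame:
    """Unweighted (BFS) shortest-path length between all pairs; inf if unreachable."""
    ids = list(graph.nodes)
    table = pd.DataFrame(math.inf, index=ids, columns=ids, dtype=float)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for dst, dist in lengths.items():
            table.loc[src, dst] = float(dist)
    return table


def categorize_pairs(
    graph: nx.Graph, metadata: pd.DataFrame, proximity: Optional[pd.DataFrame] = None
) -> list:
    """All unordered pairs as PairRecords with category and node distance."""
    imams = metadata.index[metadata["role"] == "imam"].tolist()
    if len(imams) > 1:
        raise ConfigurationError(f"expected at most one imam, found {imams}")
    imam = imams[0] if imams else None
    node_dist = shortest_path_distances(graph)

    records = []
    for a, b in combinations(metadata.index, 2):
        if b == imam:  # imam always listed first
            a, b = b, a
        same_group = metadata.loc[a, "group"] == metadata.loc[b, "group"]
        adjacent = graph.has_edge(a, b)
        if a == imam:
            category = "imam_colocated" if same_group else "imam_noncolocated"
        elif not same_group:
            category = "separated"
        else:
            category = "neighbours" if adjacent else "distant"
        d = float(proximity.loc[a, b]) if proximity is not None else math.nan
        records.append(
            PairRecord(
                id_a=a,
                id_b=b,
                mean_distance_m=d,
                adjacency=adjacent,
                node_distance=float(node_dist.loc[a, b]),
                category=category,
            )
        )
    counts = pd.Series([r.category for r in records]).value_counts().to_dict()
    logger.info("pair categories: %s", counts)
    return records


def nearest_neighbour_distances(
    proximity: pd.DataFrame, metadata: pd.DataFrame, group: str
) -> pd.Series:
    """Per-worshipper distance to the closest same-group worshipper (imam excluded)."""
    members = metadata.index[(metadata["group"] == group) & (metadata["role"] == "worshipper")]
    if len(members) < 2:
        raise ValueError(f"group {group!r} has fewer than two worshippers")
    sub = proximity.loc[members, members].to_numpy(float).copy()
    np.fill_diagonal(sub, np.nan)
    return pd.Series(np.nanmin(sub, axis=1), index=members, name=f"nn_distance_{group}")
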