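"""Canonical undirected interaction networks and centrality-based role calls.

The topology statistics follow the comparative-disease convention: a *hub* is
a node whose degree exceeds the network mean degree plus ``k_sd`` (default 2)
standard deviations; a *bottleneck* is a node in the top ``fraction`` (default
5%) by normalized betweenness centrality; a *hub-bottleneck* is both at once.

Betweenness is Brandes' algorithm on unweighted shortest paths (networkx
backend), with equal-length paths sharing credit fractionally, normalized by
2/((n-1)(n-2)) for n >= 3 and computed over the full graph — node pairs in
different components simply contribute nothing.  Degrees ignore edge weights.
The degree standard deviation is the population form (divide by n), the
NetworkAnalyzer convention; ``ddof=1`` switches to the sample form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import GeneSet, InteractionRecord

__all__ = [
    "CentralityTable",
    "RoleCall",
    "build_network",
    "induced_subgraph",
    "centrality",
    "call_hubs",
    "call_bottlenecks",
    "call_roles",
    "roles_from_lists",
    "shared_roles",
    "key_genes",
]


@dataclass(frozen=True)
class CentralityTable:
    """Per-node degree and normalized betweenness plus degree summary stats."""

    table: pd.DataFrame  # index: gene; columns: degree (int), betweenness (float)
    n_nodes: int
    mean_degree: float
    sd_degree: float

    def __len__(self) -> int:
        return self.n_nodes


@dataclass(frozen=True)
class RoleCall:
    hubs: frozenset[str]
    bottlenecks: frozenset[str]
    hub_bottlenecks: frozenset[str]
    hub_threshold: float
    bottleneck_rank_cutoff: int


def build_network(
    records: list[InteractionRecord],
    score_min: float,
    *,
    score_scale: float = 1.0,
) -> nx.Graph:
    """Canonicalize raw edge records into a simple weighted undirected graph.

    Scores are divided by ``score_scale`` (1000 for STRING links files) onto
    the [0, 1] weight scale, self-loops dropped, duplicate and reciprocal
    records collapsed keeping the maximum score, edges below ``score_min``
    (on the normalized scale) dropped, and genes left without any surviving
    edge excluded entirely — which is how a submitted gene list can yield a
    smaller network.
    """
    if score_scale <= 0:
        raise ValidationError("score_scale must be positive")
    best: dict[tuple[str, str], float] = {}
    for rec in records:
        a, b = rec.gene_a.strip().upper(), rec.gene_b.strip().upper()
        if not a or not b or a == b:
            continue
        key = (a, b) if a < b else (b, a)
        w = rec.score / score_scale
        if w > best.get(key, -math.inf):
            best[key] = w
    G = nx.Graph()
    for (a, b), w in best.items():
        if w >= score_min:
            G.add_edge(a, b, weight=w)
    return G


def induced_subgraph(network: nx.Graph, genes: GeneSet) -> nx.Graph:
    """Subgraph induced on ``genes``, with resulting isolates removed."""
    keep = set(network.nodes) & set(genes.genes)
    H = nx.Graph(network.subgraph(keep))
    H.remove_nodes_from([v for v in list(H.nodes) if H.degree(v) == 0])
    return H


def centrality(network: nx.Graph, *, ddof: int = 0) -> CentralityTable:
    """Degree and normalized betweenness for every node.

    For n < 3 every betweenness is 0 (the 2/((n-1)(n-2)) normalization is
    undefined).  ``ddof=0`` gives the population degree SD.
    """
    nodes = sorted(network.nodes)
    n = len(nodes)
    degrees = np.array([network.degree(v) for v in nodes], dtype=int)
    if n >= 3:
        bc = nx.betweenness_centrality(network, normalized=True, weight=None)
    else:
        bc = {v: 0.0 for v in nodes}
    table = pd.DataFrame(
        {"degree": degrees, "betweenness": [bc[v] for v in nodes]}, index=pd.Index(nodes, name="gene")
    )
    mean = float(degrees.mean()) if n else 0.0
    sd = float(degrees.std(ddof=ddof)) if n > ddof else 0.0
    return CentralityTable(table=table, n_nodes=n, mean_degree=mean, sd_degree=sd)


def hub_threshold(table: CentralityTable, k_sd: float = 2.0) -> float:
    return table.mean_degree + k_sd * table.sd_degree


def call_hubs(table: CentralityTable, k_sd: float = 2.0) -> frozenset[str]:
    """Genes with degree strictly above mean + k_sd * SD.

    Strict inequality means a regular graph (SD = 0) has no hubs.
    """
    if table.n_nodes == 0:
        return frozenset()
    thr = hub_threshold(table, k_sd)
    deg = table.table["degree"]
    return frozenset(deg.index[deg > thr])


def bottleneck_cutoff(n_nodes: int, fraction: float) -> int:
    # epsilon guards against 0.05*100 -> 5.000000000000001 -> ceil 6
    return int(math.ceil(fraction * n_nodes - 1e-9)) if n_nodes else 0


def call_bottlenecks(table: CentralityTable, fraction: float = 0.05) -> frozenset[str]:
    """Top ceil(fraction * n) genes by betweenness, ties broken by symbol."""
    if not 0 < fraction <= 1:
        raise ValidationError("bottleneck fraction must be in (0, 1]")
    if table.n_nodes == 0:
        return frozenset()
    cutoff = bottleneck_cutoff(table.n_nodes, fraction)
    ranked = sorted(
        table.table["betweenness"].items(), key=lambda kv: (-kv[1], kv[0])
    )
    return frozenset(g for g, _ in ranked[:cutoff])


def call_roles(
    table: CentralityTable, k_sd: float = 2.0, fraction: float = 0.05
) -> RoleCall:
    hubs = call_hubs(table, k_sd)
    bottlenecks = call_bottlenecks(table, fraction) if table.n_nodes else frozenset()
    return RoleCall(
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_bottlenecks=hubs & bottlenecks,
        hub_threshold=hub_threshold(table, k_sd) if table.n_nodes else 0.0,
        bottleneck_rank_cutoff=bottleneck_cutoff(table.n_nodes, fraction),
    )


def roles_from_lists(hubs, bottlenecks) -> RoleCall:
    """Build a RoleCall from externally supplied hub/bottleneck lists.

    Used to push published role tables through the same intersection and
    key-gene logic as computed calls; thresholds are unknown and recorded
    as NaN / the bottleneck list length.
    """
    h, b = frozenset(hubs), frozenset(bottlenecks)
    return RoleCall(
        hubs=h,
        bottlenecks=b,
        hub_bottlenecks=h & b,
        hub_threshold=float("nan"),
        bottleneck_rank_cutoff=len(b),
    )


def shared_roles(
    call_a: RoleCall, call_b: RoleCall
) -> tuple[frozenset[str], frozenset[str]]:
    """Element-wise hub and bottleneck intersections across two networks."""
    return call_a.hubs & call_b.hubs, call_a.bottlenecks & call_b.bottlenecks


def key_genes(
    common_call: RoleCall,
    shared_hubs: frozenset[str] = frozenset(),
    shared_bottlenecks: frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Union of the common network's hubs and bottlenecks, with provenance.

    One row per key gene; boolean columns record hub/bottleneck status in
    the common network and membership in the cross-network shared hub and
    shared bottleneck sets.  Whether every key gene also appears among the
    shared hubs (as observed in the motivating comparison) is reported by
    the flags, never assumed.
    """
    union = sorted(common_call.hubs | common_call.bottlenecks)
    return pd.DataFrame(
        {
            "is_hub": [g in common_call.hubs for g in union],
            "is_bottleneck": [g in common_call.bottlenecks for g in union],
            "in_shared_hubs": [g in shared_hubs for g in union],
            "in_shared_bottlenecks": [g in shared_bottlenecks for g in union],
        },
        index=pd.Index(union, name="gene"),
    )
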