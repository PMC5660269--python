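"""End-to-end two-disease comparison pipeline.

Flow: read the two disease gene lists, intersect them into the common gene
set, induce the disease-A, disease-B and common networks from one supplied
score-filtered interactome, compute centralities and hub/bottleneck role
calls per network, intersect the two disease calls into shared hubs and
bottlenecks, take the common network's hub-or-bottleneck union as the key
gene set, detect overlapping cohesive groups on the common network, enrich
the key genes against the annotation database with kappa grouping, and
write a deterministic report bundle.

All analysis stages are seed-free and deterministic; the config seed only
feeds synthetic-data generation upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import enrichment as enr
from . import io
from .clusterone import Cluster, ClusterOneParams, detect_complexes
from .enrichment import EnrichmentRow, GroupingParams
from .errors import ValidationError
from .io import AnnotationDB, GeneSet
from .network import (
    CentralityTable,
    RoleCall,
    build_network,
    call_roles,
    centrality,
    induced_subgraph,
    key_genes,
    shared_roles,
)

__all__ = ["PipelineConfig", "ComparisonReport", "run_comparison", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genes_a: str | Path
    genes_b: str | Path
    interactome: str | Path
    annotations: str | Path
    score_min: float
    dialect: str = "generic_tsv"
    hub_k_sd: float = 2.0
    bottleneck_fraction: float = 0.05
    cluster_params: ClusterOneParams = field(default_factory=ClusterOneParams)
    grouping_params: GroupingParams = field(default_factory=GroupingParams)
    correction: str = "benjamini_hochberg"
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.score_min <= 1.0:
            raise ValidationError("score_min must be on the normalized [0, 1] scale")
        if self.hub_k_sd < 0:
            raise ValidationError("hub_k_sd must be >= 0")
        if not 0 < self.bottleneck_fraction <= 1:
            raise ValidationError("bottleneck_fraction must be in (0, 1]")
        if self.correction not in enr.ADJUST_METHODS:
            raise ValidationError(f"unknown correction method {self.correction!r}")
        if self.dialect not in io.DIALECTS:
            raise ValidationError(f"unknown dialect {self.dialect!r}")


def load_config(path) -> PipelineConfig:
    """Load a flat YAML config; nested cluster/grouping keys are optional."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cluster = ClusterOneParams(**raw.pop("cluster", {}))
    grouping = GroupingParams(**raw.pop("grouping", {}))
    return PipelineConfig(cluster_params=cluster, grouping_params=grouping, **raw)


@dataclass
class ComparisonReport:
    name_a: str
    name_b: str
    genes_a: GeneSet
    genes_b: GeneSet
    common_genes: GeneSet
    networks: dict[str, nx.Graph]
    centrality_a: CentralityTable
    centrality_b: CentralityTable
    common_centrality: CentralityTable
    roles_a: RoleCall
    roles_b: RoleCall
    common_roles: RoleCall
    shared_hubs: frozenset[str]
    shared_bottlenecks: frozenset[str]
    key_genes: pd.DataFrame
    clusters: list[Cluster]
    enrichment: list[EnrichmentRow]
    term_edges: list
    gene_edges: list

    def summary(self) -> dict:
        """All headline counts, each recomputable from the report tables."""
        nets = {
            name: {"nodes": G.number_of_nodes(), "edges": G.number_of_edges()}
            for name, G in self.networks.items()
        }
        groups = sorted({g for r in self.enrichment for g in r.groups})
        return {
            "size_a": len(self.genes_a),
            "size_b": len(self.genes_b),
            "n_common_genes": len(self.common_genes),
            "networks": nets,
            "n_hubs": {
                self.name_a: len(self.roles_a.hubs),
                self.name_b: len(self.roles_b.hubs),
                "common": len(self.common_roles.hubs),
            },
            "n_bottlenecks": {
                self.name_a: len(self.roles_a.bottlenecks),
                self.name_b: len(self.roles_b.bottlenecks),
                "common": len(self.common_roles.bottlenecks),
            },
            "n_hub_bottlenecks_common": len(self.common_roles.hub_bottlenecks),
            "n_shared_hubs": len(self.shared_hubs),
            "n_shared_bottlenecks": len(self.shared_bottlenecks),
            "n_key_genes": int(len(self.key_genes)),
            "key_genes": sorted(self.key_genes.index),
            "n_clusters": len(self.clusters),
            "cluster_sizes": [len(c.members) for c in self.clusters],
            "cluster_p_values": [float(io.fmt_float(c.p_value)) for c in self.clusters],
            "n_enriched_terms": len(self.enrichment),
            "n_term_groups": len(groups),
        }


def run_comparison(config: PipelineConfig) -> ComparisonReport:
    """Execute the full comparison; writes the report bundle when
    ``config.out_dir`` is set."""
    genes_a = io.read_gene_list(config.genes_a)
    genes_b = io.read_gene_list(config.genes_b)
    if genes_b.name == genes_a.name:  # same stem (or same file twice)
        genes_b = GeneSet(genes_b.name + "_b", genes_b.genes)
    logger.info("gene lists: %s=%d, %s=%d", genes_a.name, len(genes_a), genes_b.name, len(genes_b))

    common = genes_a.intersection(genes_b)
    logger.info("common genes: %d", len(common))
    if len(common) == 0:
        logger.warning("no common genes between %s and %s; downstream sections will be empty",
                       genes_a.name, genes_b.name)

    records = io.read_interactions(config.interactome, config.dialect)
    scale = 1000.0 if config.dialect == "string_links" else 1.0
    base = build_network(records, config.score_min, score_scale=scale)
    logger.info("interactome: %d records -> %d nodes / %d edges at score_min=%g",
                len(records), base.number_of_nodes(), base.number_of_edges(), config.score_min)

    nets = {
        genes_a.name: induced_subgraph(base, genes_a),
        genes_b.name: induced_subgraph(base, genes_b),
        "common": induced_subgraph(base, common),
    }
    for name, G in nets.items():
        logger.info("network %s: %d nodes / %d edges", name, G.number_of_nodes(), G.number_of_edges())

    cent = {name: centrality(G) for name, G in nets.items()}
    roles = {
        name: call_roles(tab, config.hub_k_sd, config.bottleneck_fraction)
        for name, tab in cent.items()
    }
    shared_h, shared_b = shared_roles(roles[genes_a.name], roles[genes_b.name])
    logger.info("shared hubs: %d, shared bottlenecks: %d", len(shared_h), len(shared_b))

    key = key_genes(roles["common"], shared_h, shared_b)
    logger.info("key genes (common hubs | bottlenecks): %d", len(key))

    common_net = nets["common"]
    clusters = detect_complexes(common_net, config.cluster_params) if common_net else []
    logger.info("clusters: %d (sizes %s)", len(clusters), [len(c.members) for c in clusters])

    db = io.read_gmt(config.annotations)
    universe = GeneSet("universe", db.genes() & set(base.nodes)) if (db.genes() & set(base.nodes)) \
        else GeneSet("universe", db.genes())
    query = GeneSet("key_genes", frozenset(key.index)) if len(key) else None
    rows: list[EnrichmentRow] = []
    term_edges: list = []
    gene_edges: list = []
    if query is not None:
        rows = enr.enrich(query, db, universe, config.grouping_params, config.correction)
        if rows:
            rows = enr.group_terms(rows, db, universe, config.grouping_params)
            term_edges, gene_edges = enr.export_term_graph(
                rows, db, universe, config.grouping_params
            )
    logger.info("enriched terms: %d in %d group(s)", len(rows),
                len({g for r in rows for g in r.groups}))

    report = ComparisonReport(
        name_a=genes_a.name,
        name_b=genes_b.name,
        genes_a=genes_a,
        genes_b=genes_b,
        common_genes=common,
        networks=nets,
        centrality_a=cent[genes_a.name],
        centrality_b=cent[genes_b.name],
        common_centrality=cent["common"],
        roles_a=roles[genes_a.name],
        roles_b=roles[genes_b.name],
        common_roles=roles["common"],
        shared_hubs=shared_h,
        shared_bottlenecks=shared_b,
        key_genes=key,
        clusters=clusters,
        enrichment=rows,
        term_edges=term_edges,
        gene_edges=gene_edges,
    )
    if config.out_dir is not None:
        io.write_report(report, config.out_dir)
        logger.info("report written to %s", config.out_dir)
    return report
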