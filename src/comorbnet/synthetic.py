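"""Synthetic gene sets, interactomes and annotation databases with planted
ground truth.

Every generator is a pure function of its spec: the same spec and seed give
byte-identical output.  Gene symbols are synthetic tokens ``G000001``... so
no real gene identity is implied.  The generators stand in for the live
disease-gene, interactome and pathway-annotation databases a real analysis
would query, at desk scale:

* ``make_disease_pair`` — two gene sets with an *exact* configured overlap
  (the motivating comparison worked at 838 / 331 genes with 113 shared).
* ``make_interactome`` — a background random graph with planted dense
  modules (Bernoulli p_in within, p_out elsewhere), optional high-degree
  hubs attached preferentially outside the modules, and an optional
  two-clique bridge motif whose middle node is a guaranteed betweenness
  bottleneck.
* ``make_annotations`` — GMT-writable term database with terms planted to
  over-represent a designated ground-truth gene set.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import io
from .errors import ValidationError
from .io import AnnotationDB, GeneSet

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticDiseasePairSpec",
    "SyntheticAnnotationSpec",
    "GroundTruth",
    "make_interactome",
    "make_bridge_graph",
    "make_disease_pair",
    "make_annotations",
    "make_benchmark_scenario",
    "write_ground_truth",
    "read_ground_truth",
]


def _symbols(start: int, count: int) -> list[str]:
    return [f"G{i:06d}" for i in range(start, start + count)]


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value}")


def _check_count(value: int, name: str, minimum: int = 0) -> None:
    if value < minimum:
        raise ValidationError(f"{name} must be >= {minimum}, got {value}")


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    n_background_nodes: int = 100
    planted_modules: tuple[tuple[int, float], ...] = ()
    p_out: float = 0.01
    planted_hub_count: int = 0
    planted_hub_extra_degree: int = 0
    include_bridge: bool = False
    bridge_clique_size: int = 5
    weight_model: str = "unit"  # "unit" or "uniform" (0.4-1.0, STRING-like)
    seed: int = 0

    def __post_init__(self):
        _check_count(self.n_background_nodes, "n_background_nodes")
        _check_prob(self.p_out, "p_out")
        for i, (size, p_in) in enumerate(self.planted_modules):
            _check_count(size, f"planted_modules[{i}].size")
            _check_prob(p_in, f"planted_modules[{i}].p_in")
        if sum(s for s, _ in self.planted_modules) > self.n_background_nodes:
            raise ValidationError(
                "planted module sizes exceed n_background_nodes"
            )
        _check_count(self.planted_hub_count, "planted_hub_count")
        _check_count(self.planted_hub_extra_degree, "planted_hub_extra_degree")
        if self.include_bridge and self.bridge_clique_size < 3:
            raise ValidationError("bridge_clique_size must be >= 3")
        if self.weight_model not in ("unit", "uniform"):
            raise ValidationError("weight_model must be 'unit' or 'uniform'")


@dataclass(frozen=True)
class SyntheticDiseasePairSpec:
    universe_size: int = 2000
    size_a: int = 838
    size_b: int = 331
    overlap_size: int = 113
    seed: int = 0

    def __post_init__(self):
        _check_count(self.universe_size, "universe_size")
        _check_count(self.size_a, "size_a")
        _check_count(self.size_b, "size_b")
        _check_count(self.overlap_size, "overlap_size")
        if self.overlap_size > min(self.size_a, self.size_b):
            raise ValidationError("overlap_size exceeds min(size_a, size_b)")
        if max(self.size_a, self.size_b) > self.universe_size:
            raise ValidationError("set sizes exceed universe_size")
        if self.size_a + self.size_b - self.overlap_size > self.universe_size:
            raise ValidationError("universe too small for the requested overlap")


@dataclass(frozen=True)
class SyntheticAnnotationSpec:
    n_terms: int = 100
    term_size_range: tuple[int, int] = (5, 40)
    # (term_name, ground-truth target name, fraction of term genes from target)
    planted_terms: tuple[tuple[str, str, float], ...] = ()
    source_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        _check_count(self.n_terms, "n_terms")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            raise ValidationError("term_size_range must satisfy 1 <= min <= max")
        for name, _, frac in self.planted_terms:
            _check_prob(frac, f"planted term {name!r} fraction_from_target")


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery checks."""

    module_memberships: list[frozenset[str]] = field(default_factory=list)
    hub_genes: frozenset[str] = frozenset()
    bridge_gene: str | None = None
    enriched_terms: frozenset[str] = frozenset()

    def resolve(self, name: str) -> frozenset[str]:
        """Resolve a planted-target name: 'module_<i>', 'hubs' or 'bridge'."""
        if name == "hubs":
            return self.hub_genes
        if name == "bridge":
            if self.bridge_gene is None:
                raise ValidationError("no bridge gene planted")
            return frozenset([self.bridge_gene])
        if name.startswith("module_"):
            idx = int(name.split("_", 1)[1])
            if idx >= len(self.module_memberships):
                raise ValidationError(f"no planted module {idx}")
            return self.module_memberships[idx]
        raise ValidationError(f"unresolvable planted target {name!r}")


# ---------------------------------------------------------------------------
# interactome


def _edge_weight(rng: np.random.Generator, model: str) -> float:
    return 1.0 if model == "unit" else float(rng.uniform(0.4, 1.0))


def make_interactome(spec: SyntheticNetworkSpec) -> tuple[nx.Graph, GroundTruth]:
    """Planted-partition interactome with optional hubs and bridge motif.

    Background nodes are partitioned so that the planted modules occupy
    disjoint leading blocks; intra-module pairs get Bernoulli(p_in) edges,
    every other background pair Bernoulli(p_out).  Planted hubs are *extra*
    nodes attached to ``planted_hub_extra_degree`` distinct partners drawn
    preferentially from non-module background nodes, keeping module density
    and hub degree independently tunable.  The optional bridge motif (two
    cliques joined through one new node) is added as its own component.
    """
    rng = np.random.default_rng(spec.seed)
    G = nx.Graph()
    background = _symbols(1, spec.n_background_nodes)
    G.add_nodes_from(background)
    truth = GroundTruth()

    pos = 0
    module_of: dict[str, int] = {}
    for mi, (size, _) in enumerate(spec.planted_modules):
        members = background[pos : pos + size]
        pos += size
        truth.module_memberships.append(frozenset(members))
        for v in members:
            module_of[v] = mi
    p_ins = [p for _, p in spec.planted_modules]

    for u, v in itertools.combinations(background, 2):
        mu, mv = module_of.get(u), module_of.get(v)
        p = p_ins[mu] if (mu is not None and mu == mv) else spec.p_out
        if rng.random() < p:
            G.add_edge(u, v, weight=_edge_weight(rng, spec.weight_model))

    next_id = spec.n_background_nodes + 1
    if spec.planted_hub_count:
        hubs = _symbols(next_id, spec.planted_hub_count)
        next_id += spec.planted_hub_count
        non_module = [v for v in background if v not in module_of]
        for h in hubs:
            G.add_node(h)
            pool = non_module if len(non_module) >= spec.planted_hub_extra_degree else background
            k = min(spec.planted_hub_extra_degree, len(pool))
            partners = rng.choice(len(pool), size=k, replace=False)
            for idx in sorted(partners):
                G.add_edge(h, pool[idx], weight=_edge_weight(rng, spec.weight_model))
        truth.hub_genes = frozenset(hubs)

    if spec.include_bridge:
        motif, motif_truth = make_bridge_graph(spec.bridge_clique_size, start_id=next_id)
        G.add_edges_from(motif.edges(data=True))
        truth.bridge_gene = motif_truth.bridge_gene

    return G, truth


def make_bridge_graph(clique_size: int, start_id: int = 1) -> tuple[nx.Graph, GroundTruth]:
    """Two disjoint cliques joined through a single bridge node.

    The bridge node ``v`` is adjacent to exactly one member of each clique,
    so every cross-clique shortest path runs through it: its raw betweenness
    is exactly clique_size**2, strictly above every other node's.
    """
    if clique_size < 3:
        raise ValidationError("clique_size must be >= 3")
    a = _symbols(start_id, clique_size)
    b = _symbols(start_id + clique_size, clique_size)
    bridge = _symbols(start_id + 2 * clique_size, 1)[0]
    G = nx.Graph()
    for clique in (a, b):
        for u, v in itertools.combinations(clique, 2):
            G.add_edge(u, v, weight=1.0)
    G.add_edge(bridge, a[0], weight=1.0)
    G.add_edge(bridge, b[0], weight=1.0)
    truth = GroundTruth(
        module_memberships=[frozenset(a), frozenset(b)], bridge_gene=bridge
    )
    return G, truth


# ---------------------------------------------------------------------------
# disease gene sets


def make_disease_pair(spec: SyntheticDiseasePairSpec) -> tuple[GeneSet, GeneSet]:
    """Two gene sets with exactly the configured sizes and intersection."""
    rng = np.random.default_rng(spec.seed)
    universe = _symbols(1, spec.universe_size)
    n_a_only = spec.size_a - spec.overlap_size
    n_b_only = spec.size_b - spec.overlap_size
    picked = rng.choice(
        spec.universe_size, size=spec.overlap_size + n_a_only + n_b_only, replace=False
    )
    shared = [universe[i] for i in picked[: spec.overlap_size]]
    a_only = [universe[i] for i in picked[spec.overlap_size : spec.overlap_size + n_a_only]]
    b_only = [universe[i] for i in picked[spec.overlap_size + n_a_only :]]
    return (
        GeneSet("disease_a", frozenset(shared + a_only)),
        GeneSet("disease_b", frozenset(shared + b_only)),
    )


# ---------------------------------------------------------------------------
# annotations


def make_annotations(
    universe: GeneSet, spec: SyntheticAnnotationSpec, ground: GroundTruth | None = None
) -> AnnotationDB:
    """Random background terms plus planted over-represented terms.

    A planted term of size s with fraction f draws ceil(f*s) genes (capped at
    the target size) from its resolved ground-truth target and the remainder
    uniformly from the rest of the universe.  Planted term names are recorded
    in ``ground.enriched_terms``.
    """
    if len(universe) == 0:
        raise ValidationError("universe must be non-empty")
    rng = np.random.default_rng(spec.seed)
    uni = sorted(universe.genes)
    lo, hi = spec.term_size_range
    if hi > len(uni):
        raise ValidationError("term_size_range max exceeds universe size")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(uni), size=size, replace=False)
        terms[f"TERM{i:04d}"] = (
            spec.source_label,
            frozenset(uni[j] for j in members),
        )
    planted_names = []
    for name, target_name, frac in spec.planted_terms:
        if ground is None:
            raise ValidationError("planted terms require a GroundTruth to resolve targets")
        target = sorted(ground.resolve(target_name) & universe.genes)
        if not target:
            raise ValidationError(f"planted target {target_name!r} is empty in the universe")
        size = int(rng.integers(lo, hi + 1))
        n_target = min(int(np.ceil(frac * size)), len(target), size)
        from_target = [target[j] for j in rng.choice(len(target), size=n_target, replace=False)]
        rest_pool = [g for g in uni if g not in set(target)]
        n_rest = min(size - n_target, len(rest_pool))
        from_rest = [rest_pool[j] for j in rng.choice(len(rest_pool), size=n_rest, replace=False)]
        if name in terms:
            raise ValidationError(f"duplicate planted term name {name!r}")
        terms[name] = (spec.source_label, frozenset(from_target + from_rest))
        planted_names.append(name)
    if ground is not None:
        ground.enriched_terms = frozenset(planted_names)
    return AnnotationDB(terms)


# ---------------------------------------------------------------------------
# ground-truth sidecar


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "module_memberships": [sorted(m) for m in truth.module_memberships],
        "hub_genes": sorted(truth.hub_genes),
        "bridge_gene": truth.bridge_gene,
        "enriched_terms": sorted(truth.enriched_terms),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        module_memberships=[frozenset(m) for m in payload["module_memberships"]],
        hub_genes=frozenset(payload["hub_genes"]),
        bridge_gene=payload["bridge_gene"],
        enriched_terms=frozenset(payload["enriched_terms"]),
    )


def make_clustering_benchmark(seed: int) -> tuple[nx.Graph, GroundTruth]:
    """Standard planted-partition benchmark for the clustering stage.

    Two modules of 20 nodes at p_in = 0.95 plus a 20-node sparse background
    fringe at p_out = 0.005.  As in classic community-recovery benchmarks the
    modules dominate the graph; cohesiveness growth with zero node penalty
    deliberately absorbs degree-one satellites hanging off a module, so a
    large sparse background would dilute Jaccard recovery without making the
    modules any less recoverable.
    """
    spec = SyntheticNetworkSpec(
        n_background_nodes=60,
        planted_modules=((20, 0.95), (20, 0.95)),
        p_out=0.005,
        seed=seed,
    )
    return make_interactome(spec)


# ---------------------------------------------------------------------------
# standard two-disease benchmark scenario


@dataclass
class BenchmarkScenario:
    interactome: nx.Graph
    truth: GroundTruth
    genes_a: GeneSet
    genes_b: GeneSet
    annotations: AnnotationDB

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_a": out / "genes_a.txt",
            "genes_b": out / "genes_b.txt",
            "interactome": out / "interactome.tsv",
            "annotations": out / "annotations.gmt",
            "ground_truth": out / "ground_truth.json",
        }
        io.write_gene_list(self.genes_a, paths["genes_a"])
        io.write_gene_list(self.genes_b, paths["genes_b"])
        records = [
            io.InteractionRecord(min(u, v), max(u, v), d.get("weight", 1.0))
            for u, v, d in self.interactome.edges(data=True)
        ]
        records.sort()
        io.write_interactions(records, paths["interactome"])
        io.write_gmt(self.annotations, paths["annotations"])
        write_ground_truth(self.truth, paths["ground_truth"])
        return paths


def make_benchmark_scenario(
    seed: int,
    *,
    n_background: int = 150,
    module_size: int = 20,
    module_p_in: float = 0.95,
    p_out: float = 0.01,
    n_hubs: int = 3,
    hub_extra_degree: int = 40,
    disease_extra: int = 100,
    n_terms: int = 60,
    term_size_range: tuple[int, int] = (5, 20),
) -> BenchmarkScenario:
    """Standard end-to-end benchmark: two diseases sharing a planted dense
    module and ``n_hubs`` planted shared hubs, plus annotation terms planted
    on the hub set.

    Both disease gene sets contain the planted module and hubs plus a random
    sample of ``disease_extra`` remaining background genes, so the induced
    disease networks both retain high hub degrees while the per-disease
    backgrounds differ.
    """
    rng = np.random.default_rng(seed)
    net_spec = SyntheticNetworkSpec(
        n_background_nodes=n_background,
        planted_modules=((module_size, module_p_in),),
        p_out=p_out,
        planted_hub_count=n_hubs,
        planted_hub_extra_degree=hub_extra_degree,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    G, truth = make_interactome(net_spec)
    module = sorted(truth.module_memberships[0])
    hubs = sorted(truth.hub_genes)
    others = sorted(set(G.nodes) - set(module) - set(hubs))

    def sample_extra() -> list[str]:
        k = min(disease_extra, len(others))
        idx = rng.choice(len(others), size=k, replace=False)
        return [others[i] for i in sorted(idx)]

    genes_a = GeneSet("disease_a", frozenset(module + hubs + sample_extra()))
    genes_b = GeneSet("disease_b", frozenset(module + hubs + sample_extra()))

    universe = GeneSet("universe", frozenset(G.nodes))
    ann_spec = SyntheticAnnotationSpec(
        n_terms=n_terms,
        term_size_range=term_size_range,
        planted_terms=(
            ("PLANTED_HUB_TERM_A", "hubs", 0.5),
            ("PLANTED_HUB_TERM_B", "hubs", 0.5),
        ),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    annotations = make_annotations(universe, ann_spec, truth)
    return BenchmarkScenario(G, truth, genes_a, genes_b, annotations)
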