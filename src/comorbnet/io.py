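"""Readers and writers for every external format the pipeline touches.

Formats in scope: plain gene lists (one symbol per line), STRING-links-style
whitespace tables (protein1, protein2, combined_score on the 0-1000 integer
scale), generic two/three-column TSV edge lists, GMT gene-set databases, SIF
edge exports, and the TSV+JSON report bundle.

All writers are deterministic: fixed ordering (lexicographic), fixed number
formatting (6 significant digits for probabilities and centralities), so
identical inputs yield byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import ParseError, ValidationError

__all__ = [
    "GeneSet",
    "InteractionRecord",
    "AnnotationDB",
    "read_gene_list",
    "write_gene_list",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "write_sif",
    "write_report",
    "fmt_float",
]

DIALECTS = ("string_links", "generic_tsv")


def fmt_float(x: float) -> str:
    """Canonical 6-significant-digit rendering used by every writer."""
    return f"{float(x):.6g}"


@dataclass(frozen=True)
class GeneSet:
    """A named, deduplicated set of uppercase gene symbols.

    May be empty (e.g. the intersection of two disjoint disease lists);
    readers, not the container, reject empty input files.
    """

    name: str
    genes: frozenset[str]

    def __post_init__(self):
        if not self.name:
            raise ValidationError("GeneSet name must be non-empty")
        for g in self.genes:
            if not g or g != g.strip().upper():
                raise ValidationError(f"invalid gene symbol {g!r} in set {self.name!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersection(self, other: "GeneSet", name: str = "common") -> "GeneSet":
        return GeneSet(name, self.genes & other.genes)


class InteractionRecord(NamedTuple):
    """One raw edge record as read from disk, score on the file's own scale.

    Self-loops and duplicates are allowed here; canonicalization happens in
    ``network.build_network``.
    """

    gene_a: str
    gene_b: str
    score: float


@dataclass
class AnnotationDB:
    """Term -> (source label, gene set) mapping, GMT-serializable.

    Term names are unique; every term annotates at least one gene.
    """

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for name, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {name!r} annotates no genes")

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self) -> frozenset[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for _, gs in self.terms.values():
            out |= gs
        return frozenset(out)

    def term_genes(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    def source(self, term: str) -> str:
        return self.terms[term][0]


# ---------------------------------------------------------------------------
# gene lists


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list.

    Blank lines and ``#`` comments are skipped; symbols are uppercased,
    stripped and deduplicated.  The set name defaults to the file stem.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seen.setdefault(line.upper(), None)
    if not seen:
        raise ValidationError(f"{path}: gene list contains no symbols")
    return GeneSet(name or path.stem, frozenset(seen))


def write_gene_list(genes: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes.genes)))


# ---------------------------------------------------------------------------
# interaction tables


def _looks_like_header(fields: list[str]) -> bool:
    if len(fields) < 3:
        return True
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def read_interactions(path, dialect: str = "generic_tsv") -> list[InteractionRecord]:
    """Read an edge table in one of the supported dialects.

    ``string_links``: whitespace-separated protein1/protein2/combined_score
    with integer scores on the 0-1000 scale; a header line is auto-detected
    and skipped.  ``generic_tsv``: two or three tab-separated columns, a
    missing third column means score 1.0.  Records are returned verbatim.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    records: list[InteractionRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "string_links":
                fields = line.split()
                if lineno == 1 and _looks_like_header(fields):
                    continue
                if len(fields) < 3:
                    raise ParseError("expected 3 whitespace-separated columns", path, lineno)
                try:
                    score = float(fields[2])
                except ValueError:
                    raise ParseError(f"malformed score {fields[2]!r}", path, lineno) from None
            else:
                fields = line.split("\t")
                if lineno == 1 and len(fields) >= 3 and _looks_like_header(fields):
                    continue
                if len(fields) == 2:
                    score = 1.0
                elif len(fields) >= 3:
                    try:
                        score = float(fields[2])
                    except ValueError:
                        raise ParseError(f"malformed score {fields[2]!r}", path, lineno) from None
                else:
                    raise ParseError("expected 2 or 3 tab-separated columns", path, lineno)
            a, b = fields[0].strip().upper(), fields[1].strip().upper()
            records.append(InteractionRecord(a, b, score))
    return records


def write_interactions(records: Iterable[InteractionRecord], path) -> None:
    """Write a three-column TSV edge list (node1, node2, score)."""
    lines = [f"{r.gene_a}\t{r.gene_b}\t{fmt_float(r.score)}" for r in records]
    Path(path).write_text("".join(f"{l}\n" for l in lines))


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path) -> AnnotationDB:
    """Read a GMT file: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description and >= 1 gene", path, lineno)
            name, source = fields[0], fields[1]
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ParseError(f"term {name!r} lists no genes", path, lineno)
            if name in terms:
                raise ValidationError(f"{path}:{lineno}: duplicate term name {name!r}")
            terms[name] = (source, genes)
    return AnnotationDB(terms)


def write_gmt(db: AnnotationDB, path) -> None:
    lines = []
    for name in sorted(db.terms):
        source, genes = db.terms[name]
        lines.append("\t".join([name, source, *sorted(genes)]))
    Path(path).write_text("".join(f"{l}\n" for l in lines))


# ---------------------------------------------------------------------------
# SIF and report bundle


def write_sif(network, path, relation: str = "pp") -> None:
    """Write one ``A pp B`` line per undirected edge, endpoints and lines
    lexicographically ordered."""
    lines = sorted(f"{min(u, v)}\t{relation}\t{max(u, v)}" for u, v in network.edges())
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def write_term_graph_sif(term_edges, gene_edges, path) -> None:
    """Write the enrichment term map: term-term kappa edges (``tt``) and
    term-gene annotation edges (``tg``)."""
    lines = [f"{a}\ttt\t{b}" for a, b, _w in term_edges]
    lines += [f"{t}\ttg\t{g}" for t, g in gene_edges]
    Path(path).write_text("".join(f"{l}\n" for l in lines))


def write_report(report, out_dir) -> None:
    """Emit the full comparison report bundle into ``out_dir``.

    Files: centrality.tsv (common network, with role flags), roles.tsv (all
    three networks), clusters.tsv, enrichment.tsv, term_graph.sif and
    summary.json.  Byte-deterministic for a fixed report.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create report directory {out}: {e}") from e

    # centrality of the common network, with role flags
    lines = ["gene\tdegree\tbetweenness\tis_hub\tis_bottleneck\tis_hub_bottleneck"]
    table = report.common_centrality.table
    roles = report.common_roles
    for gene in sorted(table.index):
        h = int(gene in roles.hubs)
        b = int(gene in roles.bottlenecks)
        lines.append(
            f"{gene}\t{int(table.at[gene, 'degree'])}\t"
            f"{fmt_float(table.at[gene, 'betweenness'])}\t{h}\t{b}\t{h * b}"
        )
    (out / "centrality.tsv").write_text("".join(f"{l}\n" for l in lines))

    # role calls across all three networks
    lines = ["network\tgene\trole\tin_shared_hubs\tin_shared_bottlenecks\tis_key_gene"]
    named = [
        (report.name_a, report.roles_a),
        (report.name_b, report.roles_b),
        ("common", report.common_roles),
    ]
    key = set(report.key_genes.index)
    for net_name, call in named:
        for role, members in (
            ("hub", call.hubs),
            ("bottleneck", call.bottlenecks),
            ("hub_bottleneck", call.hub_bottlenecks),
        ):
            for gene in sorted(members):
                lines.append(
                    f"{net_name}\t{gene}\t{role}\t"
                    f"{int(gene in report.shared_hubs)}\t"
                    f"{int(gene in report.shared_bottlenecks)}\t"
                    f"{int(gene in key)}"
                )
    (out / "roles.tsv").write_text("".join(f"{l}\n" for l in lines))

    # clusters
    lines = ["cluster_id\tsize\tcohesiveness\tp_value\tmembers"]
    for i, c in enumerate(report.clusters):
        lines.append(
            f"{i}\t{len(c.members)}\t{fmt_float(c.cohesiveness)}\t"
            f"{fmt_float(c.p_value)}\t{';'.join(sorted(c.members))}"
        )
    (out / "clusters.tsv").write_text("".join(f"{l}\n" for l in lines))

    # enrichment
    lines = ["term\tsource\tk\tK\tp_raw\tp_adj\tgenes_found\tgroups"]
    for r in report.enrichment:
        groups = ";".join(str(g) for g in sorted(r.groups))
        lines.append(
            f"{r.term}\t{r.source}\t{r.k}\t{r.K}\t{fmt_float(r.p_raw)}\t"
            f"{fmt_float(r.p_adj)}\t{';'.join(sorted(r.genes_found))}\t{groups}"
        )
    (out / "enrichment.tsv").write_text("".join(f"{l}\n" for l in lines))

    write_term_graph_sif(report.term_edges, report.gene_edges, out / "term_graph.sif")

    (out / "summary.json").write_text(
        json.dumps(report.summary(), indent=2, sort_keys=True) + "\n"
    )


def read_report_summary(out_dir) -> dict:
    return json.loads((Path(out_dir) / "summary.json").read_text())
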