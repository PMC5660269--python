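"""Over-representation analysis and kappa-based term grouping.

A query gene set is tested against each annotation term with the upper-tail
hypergeometric probability P(X >= k) for X ~ Hypergeom(N, K, n) — N the
background universe size, K the term size within the universe, n the query
size, k the number of query genes annotated by the term.  P-values are
corrected across tested terms (Benjamini-Hochberg by default; Bonferroni and
Holm step-down available) and significant terms are grouped by Cohen's kappa
agreement of their gene memberships, ClueGO-style: terms whose kappa reaches
the threshold are linked, each term seeds a group from its closed
neighborhood, and groups sharing at least half of the smaller group's terms
are merged iteratively — so a term bridging two families can belong to more
than one final group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import AnnotationDB, GeneSet

__all__ = [
    "GroupingParams",
    "EnrichmentRow",
    "hypergeom_p",
    "adjust_p",
    "enrich",
    "kappa",
    "group_terms",
    "group_labels",
    "export_term_graph",
]

logger = logging.getLogger(__name__)

ADJUST_METHODS = {
    "benjamini_hochberg": "fdr_bh",
    "bonferroni": "bonferroni",
    "bonferroni_stepdown": "holm",
}


@dataclass(frozen=True)
class GroupingParams:
    kappa_threshold: float = 0.4
    min_genes: int = 2

    def __post_init__(self):
        if not 0.0 <= self.kappa_threshold <= 1.0:
            raise ValidationError("kappa_threshold must be in [0, 1]")
        if self.min_genes < 1:
            raise ValidationError("min_genes must be >= 1")


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    source: str
    k: int  # query genes found in the term
    K: int  # term size within the universe
    p_raw: float
    p_adj: float
    genes_found: frozenset[str]
    groups: frozenset[int] = field(default_factory=frozenset)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValidationError(
            f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def adjust_p(p_values, method: str = "benjamini_hochberg") -> list[float]:
    """Multiple-testing adjustment, output order matching input order."""
    if method not in ADJUST_METHODS:
        raise ValidationError(
            f"unknown method {method!r}; expected one of {sorted(ADJUST_METHODS)}"
        )
    ps = [float(p) for p in p_values]
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value {p} outside [0, 1]")
    if not ps:
        return []
    adjusted = multipletests(ps, method=ADJUST_METHODS[method])[1]
    return [min(1.0, float(p)) for p in adjusted]


def enrich(
    query: GeneSet,
    db: AnnotationDB,
    universe: GeneSet,
    params: GroupingParams | None = None,
    method: str = "benjamini_hochberg",
) -> list[EnrichmentRow]:
    """One row per term with at least ``params.min_genes`` query hits.

    Query genes outside the universe are dropped with a warning; term gene
    sets are intersected with the universe.  Adjustment spans every tested
    (i.e. emitted) term.  Rows sorted by adjusted p, then term name.
    """
    params = params or GroupingParams()
    if len(universe) == 0:
        raise ValidationError("universe must be non-empty")
    uni = universe.genes
    q = query.genes & uni
    dropped = query.genes - uni
    if dropped:
        logger.warning(
            "%d query gene(s) outside the universe dropped: %s",
            len(dropped),
            ", ".join(sorted(dropped)[:10]),
        )
    if not q:
        return []
    N, n = len(uni), len(q)
    tested: list[tuple[str, str, int, int, float, frozenset[str]]] = []
    for term in sorted(db.terms):
        source, genes = db.terms[term]
        tg = genes & uni
        if not tg:
            continue
        found = q & tg
        if len(found) < params.min_genes:
            continue
        p = hypergeom_p(len(found), len(tg), n, N)
        tested.append((term, source, len(found), len(tg), p, frozenset(found)))
    if not tested:
        return []
    adj = adjust_p([t[4] for t in tested], method)
    rows = [
        EnrichmentRow(term=t, source=s, k=k, K=K, p_raw=p, p_adj=pa, genes_found=g)
        for (t, s, k, K, p, g), pa in zip(tested, adj)
    ]
    rows.sort(key=lambda r: (r.p_adj, r.term))
    return rows


def kappa(genes_a, genes_b, universe) -> float:
    """Cohen's kappa of two gene sets' membership over a finite universe.

    The 2x2 agreement table classifies every universe gene as in/out of each
    set; kappa = (p_o - p_e) / (1 - p_e).  Identical sets give 1.0 (covering
    the degenerate p_e = 1 case of two full- or empty-universe sets).
    """
    uni = frozenset(universe.genes if isinstance(universe, GeneSet) else universe)
    if not uni:
        raise ValidationError("universe must be non-empty")
    A = frozenset(genes_a) & uni
    B = frozenset(genes_b) & uni
    if A == B:
        return 1.0
    N = len(uni)
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = N - a - b - c
    p_o = (a + d) / N
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    return (p_o - p_e) / (1.0 - p_e)


def _kappa_edges(rows, db, uni, threshold):
    genes = {r.term: db.terms[r.term][1] & uni for r in rows}
    terms = [r.term for r in rows]
    edges = []
    for i, t in enumerate(terms):
        for u in terms[i + 1 :]:
            kap = kappa(genes[t], genes[u], uni)
            if kap >= threshold:
                edges.append((t, u, kap))
    return edges


def group_terms(
    rows: list[EnrichmentRow],
    db: AnnotationDB,
    universe: GeneSet,
    params: GroupingParams | None = None,
) -> list[EnrichmentRow]:
    """Assign kappa-group ids to enrichment rows.

    Group ids are 0-based in order of each group's best (smallest) adjusted
    p-value; a term may carry several ids when it bridges groups that were
    not merged.  Labels (the lowest-p term of each group) are available via
    :func:`group_labels`.
    """
    if not rows:
        raise ValidationError("group_terms needs at least one enrichment row")
    params = params or GroupingParams()
    uni = frozenset(universe.genes)
    edges = _kappa_edges(rows, db, uni, params.kappa_threshold)
    neighbors: dict[str, set[str]] = {r.term: {r.term} for r in rows}
    for t, u, _ in edges:
        neighbors[t].add(u)
        neighbors[u].add(t)

    groups: list[frozenset[str]] = []
    for r in rows:
        g = frozenset(neighbors[r.term])
        if g not in groups:
            groups.append(g)
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                small = min(len(groups[i]), len(groups[j]))
                if len(groups[i] & groups[j]) >= 0.5 * small:
                    union = groups[i] | groups[j]
                    groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                    if union not in groups:
                        groups.append(union)
                    merged = True
                    break
            if merged:
                break

    p_of = {r.term: r.p_adj for r in rows}
    groups.sort(key=lambda g: (min(p_of[t] for t in g), min(sorted(g))))
    out = []
    for r in rows:
        ids = frozenset(i for i, g in enumerate(groups) if r.term in g)
        out.append(replace(r, groups=ids))
    return out


def group_labels(rows: list[EnrichmentRow]) -> dict[int, str]:
    """Label each group by its lowest-adjusted-p member term."""
    best: dict[int, tuple[float, str]] = {}
    for r in rows:
        for gid in r.groups:
            cand = (r.p_adj, r.term)
            if gid not in best or cand < best[gid]:
                best[gid] = cand
    return {gid: term for gid, (_, term) in sorted(best.items())}


def export_term_graph(
    rows: list[EnrichmentRow],
    db: AnnotationDB,
    universe: GeneSet | None = None,
    params: GroupingParams | None = None,
):
    """Deterministic edge lists for the enrichment map.

    Returns (term_edges, gene_edges): term-term pairs whose kappa reaches the
    grouping threshold, weighted by kappa; and the term-gene bipartite edges
    over each term's universe-restricted gene set.
    """
    if not rows:
        raise ValidationError("export_term_graph needs at least one enrichment row")
    params = params or GroupingParams()
    uni = frozenset(universe.genes) if universe is not None else db.genes()
    term_edges = sorted(
        ((min(t, u), max(t, u), w) for t, u, w in _kappa_edges(rows, db, uni, params.kappa_threshold)),
        key=lambda e: (e[0], e[1]),
    )
    gene_edges = sorted(
        (r.term, g) for r in rows for g in (db.terms[r.term][1] & uni)
    )
    return term_edges, gene_edges
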