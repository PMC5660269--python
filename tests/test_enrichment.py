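"""Hypergeometric ORA, p-value adjustment, kappa, and term grouping."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from comorbnet import enrichment as enr
from comorbnet.enrichment import GroupingParams
from comorbnet.errors import ValidationError
from comorbnet.io import AnnotationDB, GeneSet
from comorbnet.synthetic import SyntheticAnnotationSpec, make_annotations
from oracles import brute_force_hypergeom_tail


class TestHypergeom:
    def test_zero_hits_is_certain(self):
        assert enr.hypergeom_p(0, 4, 5, 10) == 1.0

    def test_closed_form_case(self):
        # C(4,4)*C(6,1)/C(10,5) = 6/252
        assert enr.hypergeom_p(4, 4, 5, 10) == pytest.approx(6 / 252)

    def test_saturated_term(self):
        assert enr.hypergeom_p(5, 10, 5, 10) == pytest.approx(1.0)

    def test_matches_draw_enumeration(self):
        for N, K, n, k in [(8, 3, 4, 2), (10, 5, 5, 4), (12, 6, 4, 3), (7, 2, 5, 1)]:
            assert enr.hypergeom_p(k, K, n, N) == pytest.approx(
                brute_force_hypergeom_tail(k, K, n, N), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            enr.hypergeom_p(5, 4, 5, 10)


class TestAdjustP:
    @pytest.mark.parametrize("method", sorted(enr.ADJUST_METHODS))
    def test_single_p_unchanged(self, method):
        assert enr.adjust_p([0.03], method) == [0.03]

    def test_bh_step_up(self):
        assert enr.adjust_p([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_holm(self):
        assert enr.adjust_p([0.01, 0.04], "bonferroni_stepdown") == pytest.approx([0.02, 0.04])

    def test_bonferroni_clips_at_one(self):
        assert enr.adjust_p([0.6, 0.9], "bonferroni") == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            enr.adjust_p([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_monotone_after_sorting_by_raw(self, ps):
        adj = enr.adjust_p(ps)
        paired = sorted(zip(ps, adj))
        for (_, a1), (_, a2) in zip(paired, paired[1:]):
            assert a2 >= a1 - 1e-12


class TestKappa:
    UNI = GeneSet("u", frozenset(f"G{i:02d}" for i in range(20)))

    def test_identical_sets(self):
        a = {"G00", "G01", "G02"}
        assert enr.kappa(a, set(a), self.UNI) == 1.0

    def test_hand_computed_table(self):
        # |A&B|=5, |A\B|=2, |B\A|=3, neither=10 -> kappa ~ 0.4681
        A = {f"G{i:02d}" for i in range(7)}          # 5 shared + 2 own
        B = {f"G{i:02d}" for i in range(5)} | {"G07", "G08", "G09"}
        assert enr.kappa(A, B, self.UNI) == pytest.approx(0.22 / 0.47, abs=1e-4)

    def test_complete_disagreement(self):
        uni = GeneSet("u", frozenset(f"G{i}" for i in range(10)))
        A = {f"G{i}" for i in range(5)}
        B = {f"G{i}" for i in range(5, 10)}
        assert enr.kappa(A, B, uni) == pytest.approx(-1.0)

    @given(
        a=st.sets(st.integers(0, 19), max_size=20),
        b=st.sets(st.integers(0, 19), max_size=20),
    )
    def test_symmetry(self, a, b):
        A = {f"G{i:02d}" for i in a}
        B = {f"G{i:02d}" for i in b}
        assert enr.kappa(A, B, self.UNI) == enr.kappa(B, A, self.UNI)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enr.kappa({"A"}, {"B"}, frozenset())


def _db(terms: dict[str, set[str]]) -> AnnotationDB:
    return AnnotationDB({t: ("src", frozenset(g)) for t, g in terms.items()})


class TestEnrich:
    UNI = GeneSet("u", frozenset(f"G{i:03d}" for i in range(100)))

    def test_empty_query_gives_empty_result(self):
        db = _db({"T1": {"G001", "G002"}})
        q = GeneSet("q", frozenset({"ZZZ"}))  # entirely outside the universe
        assert enr.enrich(q, db, self.UNI) == []

    def test_min_genes_excludes_single_hits(self):
        db = _db({"ONE": {"G001", "G050", "G051"}, "TWO": {"G001", "G002", "G052"}})
        q = GeneSet("q", frozenset({"G001", "G002"}))
        rows = enr.enrich(q, db, self.UNI, GroupingParams(min_genes=2))
        assert [r.term for r in rows] == ["TWO"]
        assert rows[0].k == 2 and rows[0].genes_found == frozenset({"G001", "G002"})

    def test_planted_term_ranks_first(self):
        uni = self.UNI
        hits = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            query = frozenset(rng.choice(sorted(uni.genes), 10, replace=False))
            db_terms = {}
            db = make_annotations(
                uni,
                SyntheticAnnotationSpec(n_terms=100, term_size_range=(5, 20), seed=seed),
            )
            db_terms = dict(db.terms)
            db_terms["PLANTED"] = ("src", frozenset(list(query)[:10]))
            rows = enr.enrich(GeneSet("q", query), AnnotationDB(db_terms), uni)
            total += 1
            if rows and rows[0].term == "PLANTED":
                hits += 1
        assert hits >= 0.95 * total

    def test_row_invariants(self):
        db = _db({"T": {"G001", "G002", "G003"}})
        q = GeneSet("q", frozenset({"G001", "G002", "G099"}))
        (row,) = enr.enrich(q, db, self.UNI)
        assert row.k == len(row.genes_found) <= row.K
        assert row.p_adj >= row.p_raw

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            enr.enrich(GeneSet("q", frozenset({"A"})), _db({"T": {"A"}}),
                       GeneSet("u", frozenset()))


class TestGroupTerms:
    UNI = GeneSet("u", frozenset(f"G{i:03d}" for i in range(80)))

    def _rows(self, db, query_genes):
        q = GeneSet("q", frozenset(query_genes))
        return enr.enrich(q, db, self.UNI, GroupingParams(min_genes=1))

    def test_single_row_single_group(self):
        db = _db({"T": {"G001", "G002"}})
        rows = enr.group_terms(self._rows(db, {"G001", "G002"}), db, self.UNI)
        assert rows[0].groups == frozenset({0})
        assert enr.group_labels(rows) == {0: "T"}

    def test_identical_terms_share_group(self):
        db = _db({"T1": {"G001", "G002"}, "T2": {"G001", "G002"}})
        rows = enr.group_terms(self._rows(db, {"G001", "G002"}), db, self.UNI)
        assert rows[0].groups == rows[1].groups == frozenset({0})

    def test_four_planted_families_recovered(self):
        # 4 families of 3 terms; near-identical gene sets within a family,
        # disjoint across families
        db_terms = {}
        for fam in range(4):
            base = {f"G{fam * 20 + i:03d}" for i in range(10)}
            for j in range(3):
                genes = set(base)
                genes.discard(f"G{fam * 20 + j:03d}")  # drop one gene per variant
                db_terms[f"F{fam}_{j}"] = genes
        db = _db(db_terms)
        query = {f"G{fam * 20 + i:03d}" for fam in range(4) for i in range(5, 8)}
        rows = enr.group_terms(self._rows(db, query), db, self.UNI)
        groups = {g for r in rows for g in r.groups}
        assert len(groups) == 4
        for fam in range(4):
            fam_groups = {g for r in rows if r.term.startswith(f"F{fam}_") for g in r.groups}
            assert len(fam_groups) == 1

    def test_group_ids_ordered_by_best_p(self):
        db = _db({
            "STRONG": {f"G{i:03d}" for i in range(4)},
            "WEAK": {f"G{i:03d}" for i in range(40, 70)},
        })
        rows = enr.group_terms(self._rows(db, {"G000", "G001", "G002", "G003", "G040", "G041"}),
                               db, self.UNI)
        by_term = {r.term: r for r in rows}
        assert by_term["STRONG"].p_adj < by_term["WEAK"].p_adj
        assert by_term["STRONG"].groups == frozenset({0})
        assert by_term["WEAK"].groups == frozenset({1})

    def test_empty_rows_rejected(self):
        with pytest.raises(ValidationError):
            enr.group_terms([], _db({"T": {"G001"}}), self.UNI)


class TestExportTermGraph:
    UNI = GeneSet("u", frozenset(f"G{i:03d}" for i in range(50)))

    def test_single_term_has_only_gene_edges(self):
        db = _db({"T": {"G001", "G002", "G003"}})
        q = GeneSet("q", frozenset({"G001", "G002"}))
        rows = enr.enrich(q, db, self.UNI)
        tt, tg = enr.export_term_graph(rows, db, self.UNI)
        assert tt == []
        assert tg == [("T", "G001"), ("T", "G002"), ("T", "G003")]

    def test_identical_terms_link_with_weight_one(self):
        db = _db({"T1": {"G001", "G002"}, "T2": {"G001", "G002"}})
        q = GeneSet("q", frozenset({"G001", "G002"}))
        rows = enr.enrich(q, db, self.UNI)
        tt, _ = enr.export_term_graph(rows, db, self.UNI)
        assert tt == [("T1", "T2", 1.0)]

    def test_sif_round_trip(self, tmp_path):
        from comorbnet.io import write_term_graph_sif

        db = _db({"T1": {"G001", "G002"}, "T2": {"G001", "G002"}})
        q = GeneSet("q", frozenset({"G001", "G002"}))
        rows = enr.enrich(q, db, self.UNI)
        tt, tg = enr.export_term_graph(rows, db, self.UNI)
        write_term_graph_sif(tt, tg, tmp_path / "g.sif")
        lines = (tmp_path / "g.sif").read_text().splitlines()
        back_tt = [tuple(l.split("\t")) for l in lines if "\ttt\t" in l]
        back_tg = [tuple(l.split("\t")) for l in lines if "\ttg\t" in l]
        assert [(a, b) for a, _, b in back_tt] == [(a, b) for a, b, _ in tt]
        assert [(a, b) for a, _, b in back_tg] == tg
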