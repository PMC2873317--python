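"""Annotation parsing, Fisher over-representation and BH correction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from helpers import hypergeom_upper_tail
from lcrscape.enrichment import (
    AnnotationTable,
    adjust_rows,
    bh_adjust,
    enrichment_report,
    fisher_enrichment,
    go_enrichment,
    read_annotations,
)
from lcrscape.simulate import SyntheticConfig, generate_annotations, generate_proteome


def small_table():
    return AnnotationTable(
        term_genes={
            "GO:1": {"g1", "g2", "g3"},
            "GO:2": {"g2", "g4"},
            "GO:3": {"g5"},
        },
        term_branch={"GO:1": "P", "GO:2": "F", "GO:3": "C"},
    )


class TestReadAnnotations:
    def test_tsv_duplicates_collapse(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\tGO:X\tP\ng1\tGO:X\tP\ng2\tGO:X\tP\n")
        table = read_annotations(path)
        assert table.term_genes["GO:X"] == {"g1", "g2"}

    def test_tsv_branch_defaults(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("g1\tGO:X\n")
        assert read_annotations(path).term_branch["GO:X"] == "P"

    def test_gaf_not_qualifier_dropped(self, tmp_path):
        header = "!gaf-version: 2.2\n"
        row = "SGD\t{gene}\tSYM\t{qual}\t{term}\tPMID:1\tIDA\t\t{aspect}\tname\t\tprotein\ttaxon:559292\t20100413\tSGD\n"
        path = tmp_path / "ann.gaf"
        path.write_text(
            header
            + row.format(gene="g1", qual="", term="GO:0006950", aspect="P")
            + row.format(gene="g2", qual="NOT", term="GO:0006950", aspect="P")
            + row.format(gene="g3", qual="NOT|contributes_to", term="GO:0006950", aspect="P")
        )
        table = read_annotations(path)
        assert table.term_genes["GO:0006950"] == {"g1"}
        assert table.term_branch["GO:0006950"] == "P"

    def test_hand_counted_fixture(self, tmp_path):
        path = tmp_path / "ann.tsv"
        rows = [("g1", "GO:A"), ("g2", "GO:A"), ("g3", "GO:A"),
                ("g1", "GO:B"), ("g4", "GO:B"), ("g5", "GO:C")]
        path.write_text("".join(f"{g}\t{t}\tP\n" for g, t in rows))
        table = read_annotations(path)
        assert {t: len(s) for t, s in table.term_genes.items()} == {
            "GO:A": 3, "GO:B": 2, "GO:C": 1,
        }

    def test_errors(self, tmp_path):
        empty = tmp_path / "empty.tsv"
        empty.write_text("# nothing\n")
        with pytest.raises(ValueError, match="no annotations"):
            read_annotations(empty)
        with pytest.raises(ValueError, match="unknown annotation format"):
            read_annotations(empty, fmt="xml")


class TestFisher:
    def test_matches_exact_tail_sum(self):
        background = {f"g{i}" for i in range(100)}
        annotated = {f"g{i}" for i in range(10)}
        study = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 55)}
        table = AnnotationTable(term_genes={"GO:T": annotated}, term_branch={"GO:T": "P"})
        row = fisher_enrichment(study, background, table)[0]
        assert (row.k, row.n, row.K, row.N) == (5, 10, 10, 100)
        exact = float(hypergeom_upper_tail(5, 100, 10, 10))
        assert abs(row.p - exact) <= 1e-12

    def test_term_covering_background_gives_p_one(self):
        background = {f"g{i}" for i in range(20)}
        table = AnnotationTable(term_genes={"GO:T": set(background)}, term_branch={"GO:T": "P"})
        row = fisher_enrichment({"g0", "g1"}, background, table)[0]
        assert row.p == pytest.approx(1.0)

    def test_study_equals_background(self):
        background = {f"g{i}" for i in range(20)}
        table = AnnotationTable(
            term_genes={"GO:T": {"g0", "g1", "g2"}}, term_branch={"GO:T": "P"}
        )
        rows = fisher_enrichment(background, background, table)
        assert rows[0].k == rows[0].K
        assert rows[0].p == pytest.approx(1.0)

    def test_absent_term_reports_p_one(self):
        table = AnnotationTable(term_genes={"GO:T": {"zz"}}, term_branch={"GO:T": "P"})
        row = fisher_enrichment({"g1"}, {"g1", "g2", "zz"} - {"zz"} | {"g3"}, table)[0]
        assert row.k == 0 and row.p == 1.0

    def test_study_outside_background_raises(self):
        with pytest.raises(ValueError, match="stranger"):
            fisher_enrichment({"stranger"}, {"g1"}, small_table())

    def test_exact_tail_grid(self, rng):
        """Hypergeometric tail agreement to 1e-12 over random small tables."""
        for _ in range(40):
            N = int(rng.integers(5, 31))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(1, N + 1))
            background = {f"g{i}" for i in range(N)}
            study = set(list(background)[:n])
            annotated = set(rng.choice(sorted(background), size=K, replace=False))
            table = AnnotationTable(term_genes={"GO:T": annotated}, term_branch={"GO:T": "P"})
            row = fisher_enrichment(study, background, table)[0]
            exact = float(hypergeom_upper_tail(row.k, N, K, n))
            assert abs(row.p - exact) <= 1e-12


class TestBH:
    def test_step_up_by_hand(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        expected = [0.02, 0.05333333333333334, 0.05333333333333334, 0.2]
        assert bh_adjust([0.005, 0.04, 0.04, 0.2]) == pytest.approx(expected)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_monotone_and_dominating(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_per_branch_vs_pooled(self):
        background = {f"g{i}" for i in range(40)}
        table = AnnotationTable(
            term_genes={"GO:p1": {"g0", "g1"}, "GO:f1": {"g0", "g1"}, "GO:p2": {"g5"}},
            term_branch={"GO:p1": "P", "GO:f1": "F", "GO:p2": "P"},
        )
        rows = fisher_enrichment({"g0", "g1", "g2"}, background, table)
        per_branch = {r.term: r.q for r in adjust_rows([r for r in rows], per_branch=True)}
        pooled = {r.term: r.q for r in adjust_rows([r for r in rows], per_branch=False)}
        # identical p-values, but the F branch has a single test when split
        assert per_branch["GO:f1"] <= pooled["GO:f1"]


def test_report_threshold_and_sorting():
    background = {f"g{i}" for i in range(200)}
    study = {f"g{i}" for i in range(20)}
    table = AnnotationTable(
        term_genes={
            "GO:hit": {f"g{i}" for i in range(15)},
            "GO:miss": {f"g{i}" for i in range(100, 120)},
        },
        term_branch={"GO:hit": "P", "GO:miss": "P"},
    )
    rows, report = go_enrichment(study, background, table, q_threshold=1.1)
    assert len(report) == 2
    assert list(report["term"]) == ["GO:hit", "GO:miss"]  # sorted by p within branch
    assert enrichment_report(rows, q_threshold=1e-30).empty
    _, tight = go_enrichment(study, background, table, q_threshold=0.01)
    assert list(tight["term"]) == ["GO:hit"]


def test_planted_enrichment_is_recovered(rng):
    """A term present in 40% of a 150-gene study vs 5% of a 3000-gene
    background must surface at q < 0.01."""
    background = [f"g{i}" for i in range(3000)]
    study = background[:150]
    carriers = set(
        g for g in study if rng.random() < 0.4
    ) | set(g for g in background[150:] if rng.random() < 0.05)
    table = AnnotationTable(
        term_genes={"GO:planted": carriers, "GO:noise": set(background[::7])},
        term_branch={"GO:planted": "P", "GO:noise": "P"},
    )
    _, report = go_enrichment(study, background, table, q_threshold=0.01)
    assert "GO:planted" in set(report["term"])


def test_disjoint_subsets_recover_disjoint_terms():
    """Terms planted for the terminal and central subsets respectively are
    each significant only for their own subset."""
    config = SyntheticConfig(seed=42, n_proteins=900, fraction_with_lcr=0.5)
    _, truth = generate_proteome(config)
    table, _ = generate_annotations(truth, config, np.random.default_rng(43))
    background = sorted(truth.protein_lengths)
    sig = {}
    for subset in ("terminal", "central"):
        study = sorted(truth.ids_by_class(subset))
        _, report = go_enrichment(study, background, table, q_threshold=0.01)
        sig[subset] = set(report["term"])
    planted = {t.subset: t.term for t in truth.planted_terms}
    assert planted["terminal"] in sig["terminal"]
    assert planted["central"] in sig["central"]
    assert planted["terminal"] not in sig["central"]
    assert planted["central"] not in sig["terminal"]
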