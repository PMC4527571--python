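"""Module pairing, hub ranking, enrichment and report arithmetic."""

import math

import pytest
from scipy.special import comb

from mirmodule import integrate
from mirmodule.quant_de import ExpressionRecord
from mirmodule.target_predict import TargetSite


def _rec(mid, status):
    r = ExpressionRecord(mid, "known", 10, 10, 10**5, 10**5)
    r.status = status
    return r


def _site(mid, gene):
    return TargetSite(mid, gene, 0, 21, 0.0, 11, "")


class TestSummarizePercentages:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(265, 336, 78.87), (178, 265, 67.17), (221, 277, 79.78),
         (134, 221, 60.63), (336, 351, 95.73), (275, 1059, 25.97), (0, 7, 0.0)],
    )
    def test_rounding(self, num, den, expected):
        assert integrate.summarize_percentages(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            integrate.summarize_percentages(1, 0)


class TestPairModules:
    def test_relation_labels(self):
        mirnas = [_rec("m1", "up"), _rec("m2", "down"), _rec("m3", "up")]
        sites = [_site("m1", "g1"), _site("m2", "g2"), _site("m3", "g3"), _site("m1", "g4")]
        gene_de = {"g1": "down", "g2": "up", "g3": "up", "g4": "unDE"}
        modules, summary = integrate.pair_modules(mirnas, sites, gene_de)
        by_pair = {(m.mirna_id, m.gene_id): m for m in modules}
        assert by_pair[("m1", "g1")].relation == "up-down" and by_pair[("m1", "g1")].inverse
        assert by_pair[("m2", "g2")].relation == "down-up" and by_pair[("m2", "g2")].inverse
        assert by_pair[("m3", "g3")].relation == "up-up" and not by_pair[("m3", "g3")].inverse
        assert by_pair[("m1", "g4")].relation == "de-unDE"
        assert summary["n_inverse"] == 2 and summary["inverse_pct"] == 50.0

    def test_unde_mirnas_excluded(self):
        modules, _ = integrate.pair_modules(
            [_rec("m1", "unDE")], [_site("m1", "g1")], {"g1": "down"}
        )
        assert modules == []

    def test_duplicate_pairs_collapse(self):
        modules, _ = integrate.pair_modules(
            [_rec("m1", "up")], [_site("m1", "g1"), _site("m1", "g1")], {"g1": "down"}
        )
        assert len(modules) == 1

    def test_unresolved_gene_carried_as_unde(self):
        modules, summary = integrate.pair_modules(
            [_rec("m1", "up")], [_site("m1", "missing")], {}
        )
        assert modules[0].gene_status == "unDE"
        assert summary["unresolved_genes"] == 1

    def test_relation_classes_partition(self, pipeline_result):
        summary = pipeline_result.module_summary
        if not summary:
            pytest.skip("no modules in fixture")
        assert sum(summary["by_relation"].values()) == summary["n_modules"]

    def test_inverse_fraction_label_independent(self):
        mirnas = [_rec("m1", "up")]
        sites = [_site("m1", "gA"), _site("m1", "gB")]
        gene_de = {"gA": "down", "gB": "up"}
        _, s1 = integrate.pair_modules(mirnas, sites, gene_de)
        renamed_sites = [_site("m1", "x1"), _site("m1", "x2")]
        _, s2 = integrate.pair_modules(mirnas, renamed_sites, {"x1": "down", "x2": "up"})
        assert s1["inverse_pct"] == s2["inverse_pct"]


class TestRankHubs:
    def test_single_mirna(self):
        modules, _ = integrate.pair_modules(
            [_rec("m1", "up")],
            [_site("m1", f"g{i}") for i in range(3)],
            {f"g{i}": "down" for i in range(3)},
        )
        hubs = integrate.rank_hubs(modules)
        assert hubs[0].n_inverse == 3 and hubs[0].mirna_id == "m1"

    def test_tie_breaks_lexicographically(self):
        mirnas = [_rec("mB", "up"), _rec("mA", "up")]
        sites = [_site("mB", "g1"), _site("mA", "g2")]
        gene_de = {"g1": "down", "g2": "down"}
        modules, _ = integrate.pair_modules(mirnas, sites, gene_de)
        hubs = integrate.rank_hubs(modules)
        assert [h.mirna_id for h in hubs] == ["mA", "mB"]

    def test_invariant_chain(self, pipeline_result):
        for h in pipeline_result.hubs:
            assert h.n_inverse <= h.n_de_targets <= h.n_targets

    def test_graph_export_structure(self, tmp_path):
        modules, _ = integrate.pair_modules(
            [_rec("m1", "up")], [_site("m1", "g1")], {"g1": "down"}
        )
        g = integrate.modules_graph(modules)
        assert g.nodes["m1"]["kind"] == "miRNA" and g.nodes["g1"]["kind"] == "gene"
        assert g.edges["m1", "g1"]["inverse"]
        integrate.export_graph(modules, tmp_path / "n.graphml", tmp_path / "e.tsv")
        assert (tmp_path / "n.graphml").exists()


class TestEnrich:
    def test_target_equals_background_gives_p_one(self):
        genes = {f"g{i}" for i in range(30)}
        term_map = {"T1": ("term one", {f"g{i}" for i in range(10)})}
        results = integrate.enrich(genes, genes, term_map)
        assert results[0].p == 1.0

    def test_matches_exhaustive_hypergeometric_sum(self):
        # n=20 targets from N=1000; the term covers all 20 targets and 100 genes
        N, K, n, k = 1000, 100, 20, 20
        background = [f"g{i}" for i in range(N)]
        term_genes = set(background[:K])
        targets = background[:k]
        results = integrate.enrich(targets, background, {"T": ("t", term_genes)})
        direct = sum(
            comb(K, i, exact=True) * comb(N - K, n - i, exact=True)
            for i in range(k, min(K, n) + 1)
        ) / comb(N, n, exact=True)
        assert results[0].p == pytest.approx(direct, rel=1e-9)
        assert results[0].k == k and results[0].K == K

    def test_empty_term_map(self):
        assert integrate.enrich(["g1"], ["g1", "g2"], {}) == []

    def test_term_without_background_genes_skipped(self):
        results = integrate.enrich(["g1"], ["g1", "g2"], {"T": ("t", {"zz"})})
        assert results == []

    def test_target_outside_background_rejected(self):
        with pytest.raises(ValueError):
            integrate.enrich(["g3"], ["g1", "g2"], {})

    def test_fdr_spans_terms(self):
        background = [f"g{i}" for i in range(100)]
        term_map = {
            "T1": ("a", set(background[:10])),
            "T2": ("b", set(background[50:])),
        }
        results = integrate.enrich(background[:10], background, term_map)
        assert all(0 < r.p <= 1 and r.fdr >= r.p - 1e-12 for r in results)


def test_planted_inverse_pairs_recovered(small_dataset, pipeline_result):
    """Modules recover the generator's inverse couplings for correctly
    called miRNAs, and recovered inverse modules never contradict truth."""
    ds, res = small_dataset, pipeline_result
    truth_by_seq = {t.mature_seq: t for t in ds.truth}
    rep = dict(res.family_reference.sequences())
    rep.update({nm.mirna_id: nm.mature_seq for nm in res.novel})
    status_of = {
        r.mirna_id: r.status for r in res.known_records + res.novel_records
    }
    inverse_found = {(m.mirna_id, m.gene_id) for m in res.modules if m.inverse}
    for mid, gene in inverse_found:
        t = truth_by_seq[rep[mid]]
        assert gene in t.target_gene_ids
        assert t.target_relation == "inverse"
    # every inverse truth pair whose miRNA was called correctly is found
    for t in ds.truth:
        if t.target_relation != "inverse" or t.direction == "unDE":
            continue
        called = [mid for mid, seq in rep.items() if seq == t.mature_seq]
        if not called or status_of.get(called[0]) != t.direction:
            continue
        for gene in t.target_gene_ids:
            assert (called[0], gene) in inverse_found
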