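"""Region merging, target-gene assignment, enrichment and specificity."""

import numpy as np
import pytest

from epom.assoc import AssociationResult
from epom.downstream import (
    assign_target_genes,
    count_gene_sharing,
    gene_set_enrichment,
    merge_adjacent,
    snp_enrichment,
    specificity_summary,
    target_gene_sets,
    TargetAssignment,
)
from epom.io import (
    GeneAnnotation,
    GeneRecord,
    GeneSetCollection,
    GenomicWindow,
    SNPCatalog,
    SNPRecord,
)
from epom.overlap import OverlapTestInput, overlap_log_pvalue


def W(start, end=None, chrom="chr1"):
    return GenomicWindow(chrom, start, end if end is not None else start + 200)


class TestMergeAdjacent:
    def test_book_ended_windows_merge(self):
        assert merge_adjacent([W(0), W(200)]) == [W(0, 400)]

    def test_gapped_windows_stay_separate(self):
        assert merge_adjacent([W(0), W(400)]) == [W(0), W(400)]

    def test_run_of_k_windows_becomes_one_region(self):
        for k in (1, 3, 7):
            merged = merge_adjacent([W(200 * i) for i in range(k)])
            assert merged == [W(0, 200 * k)]

    def test_idempotent_and_conserves_coverage(self, rng):
        wins = {W(200 * int(i)) for i in rng.choice(100, 40, replace=False)}
        merged = merge_adjacent(wins)
        assert merge_adjacent(merged) == merged
        assert sum(r.end - r.start for r in merged) == 200 * len(wins)

    def test_chromosomes_never_merge(self):
        assert merge_adjacent([W(0), W(0, chrom="chr2")]) == [
            W(0), W(0, chrom="chr2")]


class TestTargetGenes:
    ann = GeneAnnotation([
        GeneRecord("GA", "chr1", 150_100, "+"),   # 150 kb right of mid 100
        GeneRecord("GB", "chr1", 300_000, "-"),
        GeneRecord("GC", "chr2", 500, "+"),
    ])

    def test_enhancer_takes_nearest_tss_either_direction(self):
        [a] = assign_target_genes([W(0)], "G1", "enhancer", self.ann)
        assert a.gene_id == "GA"
        assert a.distance == 150_000

    def test_promoter_rejects_gene_running_toward_region(self):
        # region midpoint sits 1 kb downstream of a '+' TSS
        ann = GeneAnnotation([GeneRecord("GA", "chr1", 0, "+")])
        [a] = assign_target_genes([W(900, 1100)], "G1", "promoter", ann)
        assert a.gene_id is None
        # the same region is fine for an enhancer
        [e] = assign_target_genes([W(900, 1100)], "G1", "enhancer", ann)
        assert e.gene_id == "GA"

    def test_promoter_accepts_minus_strand_gene_upstream(self):
        ann = GeneAnnotation([GeneRecord("GA", "chr1", 100, "-")])
        [a] = assign_target_genes([W(200, 400)], "G1", "promoter", ann)
        assert a.gene_id == "GA"  # TSS <= midpoint for '-' genes

    def test_beyond_max_distance_unassigned(self):
        ann = GeneAnnotation([GeneRecord("GA", "chr1", 250_100, "+")])
        [a] = assign_target_genes([W(0)], "G1", "enhancer", ann)
        assert a.gene_id is None

    def test_equidistant_tie_resolves_lexicographically(self):
        ann = GeneAnnotation([
            GeneRecord("GZ", "chr1", 0, "+"),
            GeneRecord("GA", "chr1", 200, "+"),
        ])
        [a] = assign_target_genes([W(0)], "G1", "enhancer", ann)
        assert a.gene_id == "GA"  # both 100 bp from midpoint

    def test_enhancer_assignments_superset_of_promoter_rule(self, rng):
        genes = [GeneRecord(f"G{i:03d}", "chr1",
                            int(rng.integers(0, 400_000)),
                            rng.choice(["+", "-"])) for i in range(50)]
        ann = GeneAnnotation(genes)
        regions = [W(200 * int(k)) for k in rng.choice(1000, 100,
                                                       replace=False)]
        enh = assign_target_genes(regions, "G", "enhancer", ann)
        prom = assign_target_genes(regions, "G", "promoter", ann)
        prom_genes = {a.gene_id for a in prom if a.gene_id}
        enh_genes = {a.gene_id for a in enh if a.gene_id}
        for a_p, a_e in zip(prom, enh):
            if a_p.gene_id is not None:
                assert a_e.gene_id is not None
        assert len(enh_genes) >= 0  # sanity; superset holds region-wise
        assert prom_genes <= {g.gene_id for g in genes}


class TestGeneSharing:
    def _assignments(self, per_group):
        out = {}
        for g, genes in per_group.items():
            out[g] = [TargetAssignment(W(200 * i), g, "enhancer", gene, 0)
                      for i, gene in enumerate(genes)]
        return out

    def test_unique_gene_lands_in_n1_bin(self):
        table = count_gene_sharing(self._assignments(
            {"G1": ["A"], "G2": ["B"]}))
        assert table.set_index("group").loc["G1", "n=1"] == 1

    def test_universal_gene_counted_in_top_bin_everywhere(self):
        groups = {f"G{i}": ["A"] for i in range(7)}
        table = count_gene_sharing(self._assignments(groups))
        assert (table["n>5"] == 1).all()

    def test_identical_gene_lists_give_identical_histograms(self):
        table = count_gene_sharing(self._assignments(
            {"G1": ["A", "B"], "G2": ["A", "B"]}))
        rows = table.drop(columns="group").drop_duplicates()
        assert len(rows) == 1

    def test_proportion_is_genes_over_regions(self):
        assignments = self._assignments({"G1": ["A", "B", "A"]})
        table = count_gene_sharing(assignments)
        assert table.loc[0, "proportion"] == pytest.approx(2 / 3)


class TestGeneSetEnrichment:
    def test_reduces_to_overlap_engine(self):
        targets = {"G1": {"a", "b", "c", "d"}, "G2": {"e", "f"}}
        coll = GeneSetCollection({"T1": ("t", frozenset({"a", "b", "e"}))})
        res = gene_set_enrichment(targets, coll)
        row = res.table[(res.table.group == "G1")].iloc[0]
        expected = overlap_log_pvalue(OverlapTestInput(6, 4, 3, 2))
        assert row.log10_p == pytest.approx(expected, rel=1e-12)

    def test_term_equal_to_gene_list_is_top_hit(self):
        genes = frozenset(f"g{i}" for i in range(20))
        targets = {"G1": set(genes), "G2": {f"h{i}" for i in range(20)}}
        coll = GeneSetCollection({
            "SELF": ("t", genes),
            "OTHER": ("t", frozenset({"h0", "h1"})),
        })
        res = gene_set_enrichment(targets, coll)
        top = res.top_terms("G1", k=1)
        assert top.iloc[0].term == "SELF"
        assert top.iloc[0].score > 0

    def test_disjoint_term_scores_zero(self):
        targets = {"G1": {"a", "b"}, "G2": {"c", "d"}}
        coll = GeneSetCollection({"T": ("t", frozenset({"c", "d"}))})
        res = gene_set_enrichment(targets, coll)
        row = res.table[res.table.group == "G1"].iloc[0]
        assert row.log10_p == 0.0 and row.score == 0.0

    def test_planted_term_recovered_only_in_planted_group(self, rng):
        term_genes = frozenset(f"t{i}" for i in range(50))
        decoys = [f"d{i}" for i in range(200)]
        targets = {
            "G1": set(term_genes) | set(decoys[:20]),
            "G2": set(decoys[50:120]),
            "G3": set(decoys[120:190]),
        }
        coll = GeneSetCollection({
            "PLANTED": ("t", term_genes),
            "DECOY": ("t", frozenset(decoys[:40])),
        })
        res = gene_set_enrichment(targets, coll)
        assert res.top_terms("G1", 1).iloc[0].term == "PLANTED"
        planted = res.table[res.table.term == "PLANTED"].set_index("group")
        assert planted.loc["G2", "score"] == 0.0
        assert planted.loc["G3", "score"] == 0.0

    def test_empty_population_raises(self):
        with pytest.raises(ValueError):
            gene_set_enrichment({"G1": set()}, GeneSetCollection(
                {"T": ("t", frozenset({"x"}))}), population=set())


class TestSpecificity:
    def _enrichment(self, log10_ps):
        import pandas as pd

        from epom.downstream import EnrichmentResult
        rows = [{"group": g, "term": t, "log10_p": lp, "score": max(0.0, -lp)}
                for (g, t), lp in log10_ps.items()]
        return EnrichmentResult(unit="gene-set", table=pd.DataFrame(rows))

    def test_all_unique_terms_give_proportion_one(self):
        res = self._enrichment({("G1", "T1"): -5, ("G2", "T2"): -5,
                                ("G1", "T2"): -1, ("G2", "T1"): -1})
        table = specificity_summary(res).set_index("group")
        assert (table["proportion"] == 1.0).all()

    def test_all_shared_terms_give_proportion_zero(self):
        res = self._enrichment({("G1", "T1"): -5, ("G2", "T1"): -5})
        table = specificity_summary(res).set_index("group")
        assert (table["proportion"] == 0.0).all()

    def test_matches_brute_force_count(self, rng):
        groups = [f"G{i}" for i in range(4)]
        terms = [f"T{i}" for i in range(30)]
        log10_ps = {(g, t): float(-rng.uniform(0, 6))
                    for g in groups for t in terms}
        res = self._enrichment(log10_ps)
        table = specificity_summary(res, p_threshold=1e-3).set_index("group")
        enriched = {(g, t) for (g, t), lp in log10_ps.items() if lp < -3}
        for g in groups:
            mine = {t for (gg, t) in enriched if gg == g}
            specific = {t for t in mine
                        if sum(1 for (gg, tt) in enriched if tt == t) == 1}
            expected = len(specific) / len(mine) if mine else 0.0
            assert table.loc[g, "proportion"] == pytest.approx(expected)


class TestSnpEnrichment:
    def _assoc(self, sets):
        return AssociationResult(marks=[], region_class="enhancer",
                                 associated=sets)

    def test_no_snp_in_background_scores_zero(self):
        bg = [W(200 * i) for i in range(20)]
        assoc = self._assoc({"G1": set(bg[:5]), "G2": set(bg[5:10])})
        snps = SNPCatalog([SNPRecord("chr9", 10, "rs1", "T")])
        res = snp_enrichment(assoc, snps, bg)
        assert (res.table["score"] == 0).all()

    def test_snps_planted_in_one_group_dominate(self):
        bg = [W(200 * i) for i in range(100)]
        assoc = self._assoc({"G1": set(bg[:20]), "G2": set(bg[40:60])})
        snps = SNPCatalog([SNPRecord("chr1", w.start + 1, f"rs{i}", "T")
                           for i, w in enumerate(bg[:20])])
        res = snp_enrichment(assoc, snps, bg)
        t = res.table.set_index("group")
        assert t.loc["G1", "score"] > t.loc["G2", "score"]
        assert t.loc["G2", "overlap"] == 0

    def test_half_open_membership(self):
        bg = [W(0), W(200)]
        assoc = self._assoc({"G1": {W(0)}, "G2": {W(200)}})
        snps = SNPCatalog([SNPRecord("chr1", 200, "rs1", "T")])  # in W(200)
        res = snp_enrichment(assoc, snps, bg).table.set_index("group")
        assert res.loc["G2", "overlap"] == 1
        assert res.loc["G1", "overlap"] == 0

    def test_by_term_mode_restricts_b(self):
        bg = [W(200 * i) for i in range(50)]
        assoc = self._assoc({"G1": set(bg[:10]), "G2": set(bg[10:20])})
        snps = SNPCatalog(
            [SNPRecord("chr1", w.start, f"a{i}", "TRAIT_A")
             for i, w in enumerate(bg[:10])]
            + [SNPRecord("chr1", w.start, f"b{i}", "TRAIT_B")
               for i, w in enumerate(bg[10:20])]
        )
        res = snp_enrichment(assoc, snps, bg, by_term=True)
        t = res.table.set_index(["group", "term"])
        assert t.loc[("G1", "TRAIT_A"), "overlap"] == 10
        assert t.loc[("G1", "TRAIT_B"), "overlap"] == 0
        assert t.loc[("G1", "TRAIT_A"), "score"] > t.loc[("G2", "TRAIT_A"), "score"]

    def test_associated_outside_background_raises(self):
        assoc = self._assoc({"G1": {W(5000)}, "G2": {W(0)}})
        with pytest.raises(ValueError, match="outside"):
            snp_enrichment(assoc, SNPCatalog([]), [W(0)])
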