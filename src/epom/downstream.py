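"""Downstream analyses on associated regions.

Covers merging of book-ended windows, nearest-TSS target-gene assignment
(with the promoter directionality rule), gene-sharing summaries, gene-set
(GO/DO) enrichment, specificity proportions, and SNP enrichment. All
enrichment p-values come from the same log-space overlap-test engine used
for the EPOM score, so every analysis shares one statistical core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import AssociationResult
from .io import GeneAnnotation, GenomicWindow, GeneSetCollection, SNPCatalog
from .overlap import OverlapTestInput, epom_score, overlap_log_pvalue

logger = logging.getLogger(__name__)

DEFAULT_MAX_DISTANCE = 200_000


def merge_adjacent(windows: set[GenomicWindow] | list[GenomicWindow]
                   ) -> list[GenomicWindow]:
    """Merge maximal runs of book-ended (0 bp gap) windows per chromosome.

    Idempotent; conserves total covered bp. Real enhancers and promoters
    span far more than one 200 bp window, so runs of adjacent associated
    windows are treated as single regulatory regions.
    """
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    merged: list[GenomicWindow] = []
    for w in ordered:
        if merged and merged[-1].chrom == w.chrom and merged[-1].end == w.start:
            merged[-1] = GenomicWindow(w.chrom, merged[-1].start, w.end)
        else:
            merged.append(w)
    return merged


@dataclass(frozen=True)
class TargetAssignment:
    region: GenomicWindow
    group: str
    region_class: str
    gene_id: str | None
    distance: int | None  # signed TSS - region midpoint, bp


def assign_target_genes(
    regions: list[GenomicWindow],
    group: str,
    region_class: str,
    annotation: GeneAnnotation,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[TargetAssignment]:
    """Assign each region to its nearest TSS within ``max_distance``.

    Distances are measured from the region midpoint. Enhancers take the
    nearest TSS in either direction. Promoters only take a gene
    transcribed away from the region — the region must lie 5' of the TSS
    on the gene's strand (TSS >= midpoint for '+' genes, TSS <= midpoint
    for '-' genes), where a promoter would sit. Equidistant ties resolve
    to the lexicographically smallest gene id.
    """
    if not annotation.records:
        raise ValueError("empty gene annotation")
    if region_class not in ("enhancer", "promoter"):
        raise ValueError(f"unknown region class {region_class!r}")
    by_chrom: dict[str, list] = {}
    for r in annotation.records:
        by_chrom.setdefault(r.chrom, []).append(r)
    index: dict[str, tuple[np.ndarray, list]] = {}
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r.tss, r.gene_id))
        index[chrom] = (np.array([r.tss for r in recs]), recs)

    out: list[TargetAssignment] = []
    for region in regions:
        entry = index.get(region.chrom)
        best = None  # (abs distance, gene_id, signed distance)
        if entry is not None:
            tss_arr, recs = entry
            mid = region.midpoint
            lo = np.searchsorted(tss_arr, mid - max_distance, side="left")
            hi = np.searchsorted(tss_arr, mid + max_distance, side="right")
            for r in recs[lo:hi]:
                d = r.tss - mid
                if abs(d) > max_distance:
                    continue
                if region_class == "promoter":
                    # gene must run away from the region
                    if (r.strand == "+" and d < 0) or (r.strand == "-" and d > 0):
                        continue
                key = (abs(d), r.gene_id)
                if best is None or key < best[0]:
                    best = (key, r.gene_id, d)
        if best is None:
            out.append(TargetAssignment(region, group, region_class, None, None))
        else:
            out.append(TargetAssignment(region, group, region_class,
                                        best[1], best[2]))
    return out


def target_gene_sets(
    assignments: dict[str, list[TargetAssignment]]
) -> dict[str, set[str]]:
    """Per-group set of assigned target genes (regions without a gene drop)."""
    return {
        g: {a.gene_id for a in alist if a.gene_id is not None}
        for g, alist in assignments.items()
    }


def count_gene_sharing(
    assignments: dict[str, list[TargetAssignment]],
    bins: tuple[tuple[int, int], ...] = ((1, 1), (2, 5), (6, 10**9)),
) -> pd.DataFrame:
    """Per-group histogram of genes by how many groups share each gene.

    A gene's n is the number of groups in which it is assigned to at least
    one region; each group's genes are then binned by n (defaults: n=1,
    2-5, >5). ``proportion`` is distinct genes / associated-region count.
    """
    gene_sets = target_gene_sets(assignments)
    n_groups_per_gene: dict[str, int] = {}
    for genes in gene_sets.values():
        for gene in genes:
            n_groups_per_gene[gene] = n_groups_per_gene.get(gene, 0) + 1
    rows = []
    for g, genes in gene_sets.items():
        row: dict[str, object] = {"group": g, "n_genes": len(genes)}
        for lo, hi in bins:
            label = f"n={lo}" if lo == hi else (
                f"n={lo}-{hi}" if hi < 10**9 else f"n>{lo - 1}")
            row[label] = sum(1 for gene in genes
                             if lo <= n_groups_per_gene[gene] <= hi)
        n_regions = len(assignments[g])
        row["proportion"] = len(genes) / n_regions if n_regions else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EnrichmentResult:
    """Per-(group, term) enrichment table; score = -log10(corrected p)."""

    unit: str  # "gene-set" or "snp"
    table: pd.DataFrame  # columns: group, term, overlap, size_a, size_b,
    #                       population, log10_p, score

    def top_terms(self, group: str, k: int = 10) -> pd.DataFrame:
        sub = self.table[self.table["group"] == group]
        return sub.sort_values(["log10_p", "term"]).head(k)


def gene_set_enrichment(
    target_genes: dict[str, set[str]],
    collection: GeneSetCollection,
    population: set[str] | None = None,
    top_k: int | None = None,
) -> EnrichmentResult:
    """Overlap-test enrichment of each term in each group's target genes.

    Population defaults to the union of all groups' target genes (the
    same convention as the EPOM population); terms are restricted to it.
    Bonferroni correction is over the number of terms tested per group.
    """
    if population is None:
        population = set()
        for s in target_genes.values():
            population |= s
    if not population:
        raise ValueError("empty gene population")
    n = len(population)
    terms = collection.terms
    n_tests = len(terms)
    rows = []
    for group, genes in target_genes.items():
        A = genes & population
        for term in terms:
            B = collection.genes_of(term) & population
            ov = len(A & B)
            if A and B:
                lp = overlap_log_pvalue(OverlapTestInput(n, len(A), len(B), ov))
            else:
                lp = 0.0
            rows.append({
                "group": group, "term": term, "overlap": ov,
                "size_a": len(A), "size_b": len(B), "population": n,
                "log10_p": lp, "score": epom_score(lp, max(1, n_tests)),
            })
    table = pd.DataFrame(rows)
    if top_k is not None:
        table = (
            table.sort_values(["group", "log10_p", "term"])
            .groupby("group", group_keys=False)
            .head(top_k)
            .reset_index(drop=True)
        )
    return EnrichmentResult(unit="gene-set", table=table)


def specificity_summary(
    enrichment: EnrichmentResult, p_threshold: float = 1e-3
) -> pd.DataFrame:
    """Per-group proportion of enriched terms that are group-specific.

    A term is enriched in a group when its raw p < p_threshold, and
    specific when enriched in exactly one group. Proportion is
    specific / enriched (0 when a group has no enriched terms).
    """
    t = enrichment.table
    groups = sorted(t["group"].unique())
    if len(groups) < 2:
        raise ValueError("specificity needs >= 2 groups")
    log10_thr = np.log10(p_threshold)
    enriched = t[t["log10_p"] < log10_thr]
    n_groups_per_term = enriched.groupby("term")["group"].nunique()
    rows = []
    for g in groups:
        terms_g = enriched.loc[enriched["group"] == g, "term"]
        n_enriched = len(terms_g)
        n_specific = int((n_groups_per_term.loc[terms_g] == 1).sum()) if n_enriched else 0
        rows.append({
            "group": g,
            "enriched": n_enriched,
            "specific": n_specific,
            "proportion": n_specific / n_enriched if n_enriched else 0.0,
        })
    return pd.DataFrame(rows)


def _windows_with_snps(
    background: list[GenomicWindow], snps: SNPCatalog,
    trait: str | None = None,
) -> set[GenomicWindow]:
    """Background windows containing >= 1 SNP (of ``trait`` if given).

    Membership is half-open: position P is inside (start, end] iff
    start <= P < end. SNPs on chromosomes absent from the background are
    logged and skipped.
    """
    starts_tmp: dict[str, list[int]] = {}
    wins_tmp: dict[str, list[GenomicWindow]] = {}
    for w in sorted(background, key=lambda w: (w.chrom, w.start)):
        starts_tmp.setdefault(w.chrom, []).append(w.start)
        wins_tmp.setdefault(w.chrom, []).append(w)
    index = {c: (np.array(starts_tmp[c]), wins_tmp[c]) for c in starts_tmp}
    hit: set[GenomicWindow] = set()
    skipped = 0
    for rec in snps.records:
        if trait is not None and rec.trait != trait:
            continue
        entry = index.get(rec.chrom)
        if entry is None:
            skipped += 1
            continue
        starts, wins = entry
        k = int(np.searchsorted(starts, rec.position, side="right")) - 1
        if k >= 0 and wins[k].start <= rec.position < wins[k].end:
            hit.add(wins[k])
    if skipped:
        logger.info("skipped %d SNP record(s) on chromosomes absent from "
                    "the background", skipped)
    return hit


def snp_enrichment(
    assoc: AssociationResult,
    snps: SNPCatalog,
    background_windows: list[GenomicWindow],
    by_term: bool = False,
) -> EnrichmentResult:
    """Enrichment of trait/disease SNPs in each group's associated windows.

    Global mode (default): one overlap test per group, with population =
    the background (candidate) windows, A = the group's associated
    windows, B = background windows containing any SNP; Bonferroni over
    the number of groups. Per-term mode: B restricted to windows with a
    SNP of each trait term, Bonferroni over the number of terms.
    """
    bg_set = set(background_windows)
    for g, s in assoc.associated.items():
        if not s <= bg_set:
            raise ValueError(f"group {g!r} has associated windows outside "
                             "the background")
    n = len(bg_set)
    terms = snps.traits if by_term else [None]
    n_tests = len(terms) if by_term else max(1, len(assoc.groups))
    rows = []
    for term in terms:
        B = _windows_with_snps(background_windows, snps, trait=term)
        for g in assoc.groups:
            A = assoc.associated[g]
            ov = len(A & B)
            if A and B:
                lp = overlap_log_pvalue(OverlapTestInput(n, len(A), len(B), ov))
            else:
                lp = 0.0
            rows.append({
                "group": g, "term": term if term is not None else "global",
                "overlap": ov, "size_a": len(A), "size_b": len(B),
                "population": n, "log10_p": lp,
                "score": epom_score(lp, n_tests),
            })
    return EnrichmentResult(unit="snp", table=pd.DataFrame(rows))
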