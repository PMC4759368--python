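"""Enhancer-signature linkage of differential DHS to genes and gene sets.

The method: condition-unique DHS outside promoter windows are operationally
enhancers; each is paired with every gene whose TSS lies within 50 kb of the
site border; the signed change in normalized MaxD ("intensity") weights the
link; the linked gene list is then tested for over-representation in
user-supplied gene sets (hypergeometric with Benjamini–Hochberg FDR — an
open replacement for the proprietary pathway knowledge base the approach
was originally run through) and overlaid with expression ratios.
"""
from __future__ import annotations

import pandas as pd
from scipy import stats

from .types import AnnotatedSite, EnhancerGeneLink, EnrichmentResult, GeneModel

MAX_LINK_DIST = 50_000


def define_enhancers(annotated_sites: list[AnnotatedSite]) -> list[AnnotatedSite]:
    """Drop promoter-category sites; exon/intron/intergenic sites remain."""
    return [s for s in annotated_sites if s.category != "promoter"]


def _border_distance(tss: int, start: int, end: int) -> int:
    """bp from a TSS to the nearest covered base of [start, end); 0 inside."""
    if tss < start:
        return start - tss
    if tss >= end:
        return tss - (end - 1)
    return 0


def link_enhancers_to_genes(
    enhancers: list[AnnotatedSite],
    genes: list[GeneModel],
    max_dist: int = MAX_LINK_DIST,
) -> list[EnhancerGeneLink]:
    """Pair each enhancer with all genes with a TSS within ``max_dist`` bp.

    Distance is TSS to the nearest site border, inclusive at the boundary;
    one enhancer may link many genes and vice versa. The link carries the
    site's signed intensity (delta of normalized MaxD, falling back to the
    site's own normalized MaxD for sites without a comparison delta).
    """
    if not genes:
        raise ValueError("no genes to link against")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links = []
    for s in enhancers:
        intensity = (
            s.delta_norm_maxd if s.delta_norm_maxd is not None else s.norm_maxd
        )
        for g in by_chrom.get(s.chrom, []):
            d = _border_distance(g.tss, s.start, s.end)
            if d <= max_dist:
                links.append(
                    EnhancerGeneLink(
                        site_id=s.site_id,
                        chrom=s.chrom,
                        start=s.start,
                        end=s.end,
                        category=s.category,
                        gene_id=g.gene_id,
                        distance=d,
                        intensity=intensity,
                    )
                )
    return links


def gene_intensity_table(
    links: list[EnhancerGeneLink], aggregate: str = "max_abs"
) -> pd.DataFrame:
    """Collapse multi-enhancer genes to one signed intensity per gene.

    ``max_abs`` (default) keeps the signed value of the link with the
    largest |intensity|; ``sum`` adds the signed intensities. The full link
    list stays available separately — this table only feeds the overlay.
    """
    if aggregate not in ("max_abs", "sum"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    rows: dict[str, list[float]] = {}
    for ln in links:
        rows.setdefault(ln.gene_id, []).append(ln.intensity)
    records = []
    for gene_id in sorted(rows):
        vals = rows[gene_id]
        if aggregate == "max_abs":
            intensity = max(vals, key=lambda v: (abs(v), v))
        else:
            intensity = sum(vals)
        records.append(
            {"gene_id": gene_id, "intensity": intensity, "n_links": len(vals)}
        )
    return pd.DataFrame(records, columns=["gene_id", "intensity", "n_links"])


def hypergeom_pvalue(overlap: int, background: int, set_size: int, query: int) -> float:
    """One-sided over-representation tail P(X >= overlap)."""
    return float(stats.hypergeom.sf(overlap - 1, background, set_size, query))


def enrich_gene_sets(
    query_genes: set[str],
    background_genes: set[str],
    collection: dict[str, set[str]],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each gene set.

    Sets are intersected with the background before testing; p-values are
    one-sided upper tails, adjusted across sets by Benjamini–Hochberg, and
    results come back sorted by ascending p (ties by set name).
    """
    if not background_genes:
        raise ValueError("empty background")
    if not query_genes <= background_genes:
        raise ValueError("query genes must be a subset of the background")
    names = sorted(collection)
    results = []
    for name in names:
        members = collection[name] & background_genes
        k = len(members & query_genes)
        p = hypergeom_pvalue(k, len(background_genes), len(members), len(query_genes))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=k,
                set_size=len(members),
                query_size=len(query_genes),
                background_size=len(background_genes),
                p_value=p,
                bh_fdr=1.0,
            )
        )
    fdr = stats.false_discovery_control([r.p_value for r in results], method="bh")
    for r, q in zip(results, fdr):
        r.bh_fdr = float(q)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def overlay_expression(
    gene_table: pd.DataFrame, expression_ratios: pd.DataFrame, column: str | None = None
) -> pd.DataFrame:
    """Join per-gene intensities with log2 expression ratios.

    ``expression_ratios`` is indexed by gene_id; ``column`` selects the
    condition/time column to overlay (default: all ratio columns). Genes
    missing from the expression table are flagged (``in_expression`` False)
    rather than dropped.
    """
    cols = [column] if column else list(expression_ratios.columns)
    missing_cols = [c for c in cols if c not in expression_ratios.columns]
    if missing_cols:
        raise ValueError(f"expression table lacks columns {missing_cols}")
    shared = set(gene_table["gene_id"]) & set(expression_ratios.index)
    if gene_table.shape[0] and not shared:
        raise ValueError(
            "no shared genes between links and expression — check that both "
            "use the same gene-id namespace"
        )
    joined = gene_table.merge(
        expression_ratios[cols], left_on="gene_id", right_index=True, how="left"
    )
    joined["in_expression"] = joined["gene_id"].isin(expression_ratios.index)
    return joined
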