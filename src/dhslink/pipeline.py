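"""End-to-end composition: replicate concordance through gene-set enrichment.

This wires the stages the way the study ran them: per-condition replicate
concordant (RC) sets, a pairwise comparison, annotation of the sites gained
in the second condition, promoter exclusion to get enhancers, 50 kb TSS
pairing, per-gene intensity collapse, and hypergeometric enrichment of the
linked genes against user gene sets.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import accessibility, annotation, linkage
from .types import (
    AnnotatedSite,
    DifferentialSite,
    EnhancerGeneLink,
    EnrichmentResult,
    GenomeAnnotation,
    HotspotSet,
    VennPartition,
)


@dataclass
class LinkageResult:
    rc_a: HotspotSet
    rc_b: HotspotSet
    venn: VennPartition
    diff_sites: list[DifferentialSite]
    gained_annotated: list[AnnotatedSite]
    category_fractions: annotation.CategoryFractions
    enhancers: list[AnnotatedSite]
    links: list[EnhancerGeneLink]
    gene_table: pd.DataFrame
    enrichment: list[EnrichmentResult]

    @property
    def query_genes(self) -> set[str]:
        return set(self.gene_table["gene_id"])


def run_linkage_pipeline(
    rep_a: tuple[HotspotSet, HotspotSet],
    rep_b: tuple[HotspotSet, HotspotSet],
    genome: GenomeAnnotation,
    gene_sets: dict[str, set[str]],
    alpha: float = 0.05,
    max_dist: int = linkage.MAX_LINK_DIST,
    statuses: tuple[str, ...] = ("unique_b",),
) -> LinkageResult:
    """Full enhancer-signature analysis for one condition pair.

    ``statuses`` selects which differential classes count as "gained"
    sites for the enhancer definition — by default the sites unique to
    condition b (those that appeared), the study's primary reading;
    ``("unique_b", "common_modified")`` widens it to intensified sites.
    """
    rc_a = accessibility.replicate_concordant(*rep_a)
    rc_b = accessibility.replicate_concordant(*rep_b)
    venn, diffs = accessibility.compare_two(rc_a, rc_b, alpha=alpha)
    gained = [d for d in diffs if d.status in statuses]
    annotated, fractions = annotation.annotate_all(
        gained, genome.genes, condition=rc_b.condition
    )
    enhancers = linkage.define_enhancers(annotated)
    links = linkage.link_enhancers_to_genes(enhancers, genome.genes, max_dist=max_dist)
    gene_table = linkage.gene_intensity_table(links)
    background = {g.gene_id for g in genome.genes}
    query = set(gene_table["gene_id"])
    enrichment = (
        linkage.enrich_gene_sets(query, background, gene_sets) if query else []
    )
    return LinkageResult(
        rc_a=rc_a,
        rc_b=rc_b,
        venn=venn,
        diff_sites=diffs,
        gained_annotated=annotated,
        category_fractions=fractions,
        enhancers=enhancers,
        links=links,
        gene_table=gene_table,
        enrichment=enrichment,
    )
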