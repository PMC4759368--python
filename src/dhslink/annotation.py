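"""Priority genomic annotation of DHS sites and TSS-centred summaries.

Each site gets exactly one category with priority promoter > exon > intron;
what remains is intergenic and is split into distal upstream / downstream by
its position relative to the nearest gene's TSS, strand-aware. The promoter
window is TSS +/- 2.5 kb (half-open), matching the definition used when the
sites were called.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .types import CATEGORIES, AnnotatedSite, GeneModel
from .accessibility import NORM_DEPTH

PROMOTER_HALFWIDTH = 2500


@dataclass
class CategoryFractions:
    condition: str
    counts: dict[str, int]
    fractions: dict[str, float]


@dataclass
class AggregationProfile:
    """Mean depth-normalized tag density in bins around the TSS.

    Offsets are bin left edges relative to the TSS, oriented 5'->3' (minus
    strand windows are flipped before averaging).
    """

    bin_offsets: np.ndarray
    density: np.ndarray
    n_tss: int
    bin_size: int


class GeneIndex:
    """Interval indexes over promoter windows, exons and gene bodies."""

    def __init__(self, genes: list[GeneModel], promoter_halfwidth: int = PROMOTER_HALFWIDTH):
        if not genes:
            raise ValueError("empty gene list: categories undefined")
        self.genes = {g.gene_id: g for g in genes}
        self.promoter_halfwidth = promoter_halfwidth
        self.promoters: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exons: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.bodies: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.tss_by_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
        for g in genes:
            lo = max(0, g.tss - promoter_halfwidth)
            self.promoters[g.chrom].addi(lo, g.tss + promoter_halfwidth, g.gene_id)
            for s, e in g.exons:
                self.exons[g.chrom].addi(s, e, g.gene_id)
            self.bodies[g.chrom].addi(g.tx_start, g.tx_end, g.gene_id)
            self.tss_by_chrom[g.chrom].append((g.tss, g.gene_id))
        for chrom in self.tss_by_chrom:
            self.tss_by_chrom[chrom].sort()

    def hits(self, tree: dict[str, IntervalTree], chrom: str, start: int, end: int):
        if chrom not in tree:
            return []
        return sorted(iv.data for iv in tree[chrom].overlap(start, end))


def _signed_tss_distance(midpoint: int, gene: GeneModel) -> int:
    """Signed offset of a position from the TSS, positive downstream."""
    if gene.strand == "+":
        return midpoint - gene.tss
    return gene.tss - midpoint


def _nearest_gene(index: GeneIndex, chrom: str, midpoint: int,
                  candidates: list[str] | None = None) -> GeneModel:
    """Nearest gene by midpoint-to-TSS distance; ties to the smaller id."""
    pool = (
        [index.genes[g] for g in candidates]
        if candidates
        else [index.genes[g] for _tss, g in index.tss_by_chrom.get(chrom, [])]
    )
    if not pool:
        # no gene on this chromosome: deterministic fallback over all genes
        pool = list(index.genes.values())
    return min(pool, key=lambda g: (abs(midpoint - g.tss), g.gene_id))


def classify_site(
    chrom: str,
    start: int,
    end: int,
    index: GeneIndex,
    site_id: str = "",
    norm_maxd: float = 0.0,
    delta_norm_maxd: float | None = None,
    peak_pos: int | None = None,
) -> AnnotatedSite:
    """Assign the single highest-priority category to one site.

    A site intersecting any promoter window is a promoter regardless of
    other overlaps; otherwise any exon overlap wins over intron (gene body);
    purely intergenic sites are distal_upstream when 5' of the nearest
    gene's TSS in that gene's orientation, downstream otherwise.
    """
    midpoint = (start + end) // 2
    for category, tree in (
        ("promoter", index.promoters),
        ("exon", index.exons),
        ("intron", index.bodies),
    ):
        hit_ids = index.hits(tree, chrom, start, end)
        if hit_ids:
            gene = _nearest_gene(index, chrom, midpoint, candidates=hit_ids)
            return AnnotatedSite(
                chrom=chrom, start=start, end=end, site_id=site_id,
                category=category, nearest_gene_id=gene.gene_id,
                distance_to_tss=_signed_tss_distance(midpoint, gene),
                norm_maxd=norm_maxd, delta_norm_maxd=delta_norm_maxd,
                peak_pos=peak_pos,
            )
    gene = _nearest_gene(index, chrom, midpoint)
    dist = _signed_tss_distance(midpoint, gene)
    category = "distal_upstream" if dist < 0 else "downstream"
    return AnnotatedSite(
        chrom=chrom, start=start, end=end, site_id=site_id,
        category=category, nearest_gene_id=gene.gene_id,
        distance_to_tss=dist, norm_maxd=norm_maxd,
        delta_norm_maxd=delta_norm_maxd, peak_pos=peak_pos,
    )


def annotate_all(
    sites,
    genes: list[GeneModel],
    condition: str = "",
    promoter_halfwidth: int = PROMOTER_HALFWIDTH,
) -> tuple[list[AnnotatedSite], CategoryFractions]:
    """Classify every site and report the per-category count fractions.

    ``sites`` may be Hotspot or DifferentialSite records (anything with
    chrom/start/end plus optional site_id / norm_maxd / delta_norm_maxd).
    An empty site list yields zero counts rather than an error.
    """
    index = GeneIndex(genes, promoter_halfwidth=promoter_halfwidth)
    annotated = []
    for s in sites:
        annotated.append(
            classify_site(
                s.chrom, s.start, s.end, index,
                site_id=getattr(s, "site_id", "") or "|".join(
                    getattr(s, "site_ids_a", ()) + getattr(s, "site_ids_b", ())
                ),
                norm_maxd=getattr(s, "norm_maxd", 0.0)
                if hasattr(s, "norm_maxd")
                else max(getattr(s, "norm_a", 0.0), getattr(s, "norm_b", 0.0)),
                delta_norm_maxd=getattr(s, "delta_norm_maxd", None),
                peak_pos=getattr(s, "peak_pos", None),
            )
        )
    counts = {c: 0 for c in CATEGORIES}
    for a in annotated:
        counts[a.category] += 1
    total = len(annotated)
    fractions = {c: (counts[c] / total if total else 0.0) for c in CATEGORIES}
    return annotated, CategoryFractions(
        condition=condition, counts=counts, fractions=fractions
    )


def aggregation_profile(
    tag_track: dict[str, np.ndarray],
    genes: list[GeneModel],
    total_reads: int,
    flank: int = 5000,
    bin_size: int = 50,
) -> AggregationProfile:
    """Average depth-normalized tag density around TSSs.

    For every TSS the per-bp cut counts in [TSS - flank, TSS + flank) are
    taken strand-oriented (minus-strand windows reversed), summed into
    ``bin_size`` bins, scaled to 10 million reads, and averaged over TSSs.
    Windows truncated by a chromosome edge are zero-padded.
    """
    if not genes:
        raise ValueError("no genes: nothing to aggregate")
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide 2*flank")
    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins, dtype=float)
    n_tss = 0
    for g in genes:
        if g.chrom not in tag_track:
            continue
        counts = tag_track[g.chrom]
        lo, hi = g.tss - flank, g.tss + flank
        window = np.zeros(2 * flank, dtype=float)
        src_lo, src_hi = max(0, lo), min(len(counts), hi)
        if src_hi > src_lo:
            window[src_lo - lo: src_hi - lo] = counts[src_lo:src_hi]
        if g.strand == "-":
            window = window[::-1]
        acc += window.reshape(n_bins, bin_size).sum(axis=1)
        n_tss += 1
    if n_tss == 0:
        raise ValueError("no gene lies on a chromosome present in the track")
    density = acc * NORM_DEPTH / total_reads / n_tss
    offsets = np.arange(-flank, flank, bin_size)
    return AggregationProfile(
        bin_offsets=offsets, density=density, n_tss=n_tss, bin_size=bin_size
    )


def maxd_distribution(annotated: list[AnnotatedSite]):
    """Per-category empirical distribution of normalized MaxD.

    Returns ``(values, ecdf)`` per category: sorted support values and a
    right-continuous step function reaching 1; empty categories map to an
    empty support with a flag entry.
    """
    out: dict[str, dict] = {}
    by_cat: dict[str, list[float]] = {c: [] for c in CATEGORIES}
    for a in annotated:
        by_cat[a.category].append(a.norm_maxd)
    for cat, vals in by_cat.items():
        values = np.sort(np.asarray(vals, dtype=float))

        def ecdf(x, values=values):
            if values.size == 0:
                return np.nan
            return np.searchsorted(values, x, side="right") / values.size

        out[cat] = {
            "values": values,
            "ecdf": ecdf,
            "flags": [] if values.size else ["empty category"],
        }
    return out
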