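"""Differential chromatin accessibility from DHS hotspot calls.

The per-site statistic is MaxD — the maximal per-bp tag count inside a DHS —
normalized to 10 million reads so libraries of different depth compare.
Replicate-concordant (RC) sets keep only sites supported by both biological
replicas; pairwise and three-way comparisons partition sites into
common/unique Venn regions, and an exact conditional binomial test scores
MaxD differences between conditions.

Overlap means >= 1 shared bp under half-open coordinates throughout.
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .types import DifferentialSite, GeneModel, Hotspot, HotspotSet, VennPartition

NORM_DEPTH = 1e7  # MaxD reference depth: per 10 million reads


def normalize_maxd(raw_maxd: float, total_reads: int) -> float:
    """Scale a raw peak tag count to the 10-million-read reference depth."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return raw_maxd * NORM_DEPTH / total_reads


def _trees(sites: list[Hotspot]) -> dict[str, IntervalTree]:
    by_chrom: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, h in enumerate(sites):
        by_chrom[h.chrom].addi(h.start, h.end, i)
    return by_chrom


def _overlapping(trees: dict[str, IntervalTree], h: Hotspot) -> list[int]:
    if h.chrom not in trees:
        return []
    return sorted(iv.data for iv in trees[h.chrom].overlap(h.start, h.end))


def replicate_concordant(rep1: HotspotSet, rep2: HotspotSet) -> HotspotSet:
    """Sites supported by both biological replicas.

    Cross-replicate overlapping intervals are merged into their union
    (connected components of the overlap graph, so chained overlaps collapse
    into one site). The merged site's normalized MaxD is the mean of the two
    per-replicate values (the per-bp maximum within the merged span on each
    side); raw counts and depths are kept as pairs for downstream testing.
    """
    if rep1.condition != rep2.condition:
        raise ValueError(
            f"replicates from different conditions: "
            f"{rep1.condition!r} vs {rep2.condition!r}"
        )
    trees2 = _trees(rep2.sites)
    # union-find over (rep index, site index)
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(len(rep1.sites)):
        parent[(0, i)] = (0, i)
    for j in range(len(rep2.sites)):
        parent[(1, j)] = (1, j)
    for i, h in enumerate(rep1.sites):
        for j in _overlapping(trees2, h):
            union((0, i), (1, j))

    components: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for node in parent:
        components[find(node)].append(node)

    merged: list[Hotspot] = []
    for members in components.values():
        side1 = [rep1.sites[i] for r, i in members if r == 0]
        side2 = [rep2.sites[j] for r, j in members if r == 1]
        if not side1 or not side2:
            continue  # not replicate-concordant
        allsites = side1 + side2
        raw1 = max(h.raw_maxd for h in side1)
        raw2 = max(h.raw_maxd for h in side2)
        norm1 = normalize_maxd(raw1, rep1.total_reads)
        norm2 = normalize_maxd(raw2, rep2.total_reads)
        peak_candidates = [h.peak_pos for h in allsites if h.peak_pos is not None]
        merged.append(
            Hotspot(
                chrom=allsites[0].chrom,
                start=min(h.start for h in allsites),
                end=max(h.end for h in allsites),
                raw_maxd=raw1 + raw2,
                norm_maxd=(norm1 + norm2) / 2.0,
                site_id="+".join(sorted({h.site_id for h in allsites})),
                peak_pos=peak_candidates[0] if peak_candidates else None,
                raw_pair=(raw1, raw2),
                depth_pair=(rep1.total_reads, rep2.total_reads),
            )
        )
    return HotspotSet(
        sample_id=f"{rep1.sample_id}+{rep2.sample_id}",
        condition=rep1.condition,
        total_reads=rep1.total_reads + rep2.total_reads,
        sites=merged,
    )


def maxd_difference_test(
    count_a: int,
    depth_a: int,
    count_b: int,
    depth_b: int,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """Exact conditional binomial test on peak-bp tag counts.

    Conditional on the total ``n = count_a + count_b``, ``count_a`` is
    Binomial(n, depth_a / (depth_a + depth_b)) when the underlying per-bp
    rates are equal; the two-sided exact p-value against that null scores
    the MaxD difference. ``n = 0`` gives p = 1. Exactness keeps the test
    valid at the small counts typical of single-bp densities.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    n = count_a + count_b
    if n == 0:
        return 1.0, False
    p0 = depth_a / (depth_a + depth_b)
    p = stats.binomtest(count_a, n, p0, alternative="two-sided").pvalue
    return float(p), bool(p < alpha)


def _site_count_depth(h: Hotspot, default_depth: int) -> tuple[int, int]:
    """Raw count and depth for testing: summed replicate pairs when present."""
    if h.raw_pair is not None and h.depth_pair is not None:
        return sum(h.raw_pair), sum(h.depth_pair)
    return h.raw_maxd, default_depth


def compare_two(
    set_a: HotspotSet,
    set_b: HotspotSet,
    alpha: float = 0.05,
) -> tuple[VennPartition, list[DifferentialSite]]:
    """Pairwise comparison of two (replicate-concordant) DHS sets.

    Sites with no cross-set overlap are unique to their side; overlapping
    groups (connected components, so one-to-many chains merge) become a
    single differential site spanning their union, with per-side counts
    summed, signed delta of normalized MaxD (b minus a) and an exact
    binomial p-value. Unique sites are also emitted as differential records
    with the absent side at count 0.
    """
    trees_b = _trees(set_b.sites)
    trees_a = _trees(set_a.sites)
    parent: dict[tuple[int, int], tuple[int, int]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for i in range(len(set_a.sites)):
        parent[(0, i)] = (0, i)
    for j in range(len(set_b.sites)):
        parent[(1, j)] = (1, j)
    for i, h in enumerate(set_a.sites):
        for j in _overlapping(trees_b, h):
            union((0, i), (1, j))

    assignments: dict[tuple[int, str], str] = {}
    for i, h in enumerate(set_a.sites):
        assignments[(0, h.site_id)] = "11" if _overlapping(trees_b, h) else "10"
    for j, h in enumerate(set_b.sites):
        assignments[(1, h.site_id)] = "11" if _overlapping(trees_a, h) else "01"
    venn = VennPartition(
        set_names=(set_a.condition, set_b.condition), assignments=assignments
    )

    components: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for node in parent:
        components[find(node)].append(node)

    diffs: list[DifferentialSite] = []
    for members in components.values():
        side_a = [set_a.sites[i] for r, i in members if r == 0]
        side_b = [set_b.sites[j] for r, j in members if r == 1]
        allsites = side_a + side_b
        chrom = allsites[0].chrom
        start = min(h.start for h in allsites)
        end = max(h.end for h in allsites)
        ca = sum(_site_count_depth(h, set_a.total_reads)[0] for h in side_a)
        cb = sum(_site_count_depth(h, set_b.total_reads)[0] for h in side_b)
        da = (
            _site_count_depth(side_a[0], set_a.total_reads)[1]
            if side_a
            else set_a.total_reads * 1
        )
        db = (
            _site_count_depth(side_b[0], set_b.total_reads)[1]
            if side_b
            else set_b.total_reads * 1
        )
        norm_a = max((h.norm_maxd for h in side_a), default=0.0)
        norm_b = max((h.norm_maxd for h in side_b), default=0.0)
        p, sig = maxd_difference_test(ca, da, cb, db, alpha=alpha)
        if not side_b:
            status = "unique_a"
        elif not side_a:
            status = "unique_b"
        else:
            status = "common_modified" if sig else "common_unchanged"
        peaks = [h.peak_pos for h in allsites if h.peak_pos is not None]
        diffs.append(
            DifferentialSite(
                chrom=chrom,
                start=start,
                end=end,
                condition_a=set_a.condition,
                condition_b=set_b.condition,
                count_a=ca,
                count_b=cb,
                depth_a=da,
                depth_b=db,
                norm_a=norm_a,
                norm_b=norm_b,
                delta_norm_maxd=norm_b - norm_a,
                p_value=p,
                status=status,
                site_ids_a=tuple(h.site_id for h in side_a),
                site_ids_b=tuple(h.site_id for h in side_b),
                peak_pos=peaks[0] if peaks else None,
            )
        )
    diffs.sort(key=lambda d: (d.chrom, d.start, d.end))
    return venn, diffs


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (optional follow-up to alpha)."""
    return list(stats.false_discovery_control(np.asarray(pvalues), method="bh"))


def compare_three(
    set_a: HotspotSet,
    set_b: HotspotSet,
    set_c: HotspotSet,
    alpha: float = 0.05,
) -> tuple[VennPartition, dict[str, list[Hotspot]]]:
    """Three-way Venn partition of DHS sets by cross-set overlap.

    Every site lands in exactly one of 7 regions according to which of the
    other two sets it overlaps (mask order a, b, c). Returns the partition
    plus the per-condition unique site lists.
    """
    sets = (set_a, set_b, set_c)
    trees = [_trees(s.sites) for s in sets]
    assignments: dict[tuple[int, str], str] = {}
    uniques: dict[str, list[Hotspot]] = {s.condition: [] for s in sets}
    for idx, s in enumerate(sets):
        for h in s.sites:
            mask = ""
            for other in range(3):
                if other == idx:
                    mask += "1"
                else:
                    mask += "1" if _overlapping(trees[other], h) else "0"
            assignments[(idx, h.site_id)] = mask
            if mask.count("1") == 1:
                uniques[s.condition].append(h)
    venn = VennPartition(
        set_names=tuple(s.condition for s in sets), assignments=assignments
    )
    return venn, uniques


def top_changed_sites(
    diff_sites: list[DifferentialSite],
    genes: list[GeneModel],
    n: int = 1500,
    tss_flank: int = 1000,
) -> list[DifferentialSite]:
    """Top-n TSS-proximal sites ranked by absolute MaxD change.

    Restricted to sites whose interval intersects any TSS +/- ``tss_flank``
    window; ranked by |delta| descending, ties broken by genomic position.
    """
    tss_tree: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        lo = max(0, g.tss - tss_flank)
        tss_tree[g.chrom].addi(lo, g.tss + tss_flank, g.gene_id)
    near = [
        d
        for d in diff_sites
        if d.chrom in tss_tree and tss_tree[d.chrom].overlap(d.start, d.end)
    ]
    near.sort(key=lambda d: (-abs(d.delta_norm_maxd), d.chrom, d.start))
    return near[:n]


def export_motif_windows(
    sites: list[DifferentialSite],
    chroms: dict[str, int],
    width: int = 200,
) -> list[tuple[str, int, int, str, bool]]:
    """Fixed-width windows around site peaks for motif discovery export.

    Each window is centered on the site's peak bp (interval midpoint when no
    peak is recorded), clipped at chromosome bounds; rows are
    (chrom, start, end, site_label, clipped).
    """
    if not sites:
        raise ValueError("no sites to export")
    if width % 2 != 0:
        raise ValueError("window width must be even")
    half = width // 2
    rows = []
    for d in sites:
        if d.chrom not in chroms:
            raise ValueError(f"unknown chromosome {d.chrom!r}")
        center = d.peak_pos if d.peak_pos is not None else (d.start + d.end) // 2
        start, end = center - half, center + half
        clipped = False
        if start < 0:
            start, end, clipped = 0, width, True
        limit = chroms[d.chrom]
        if end > limit:
            start, end, clipped = max(0, limit - width), limit, True
        label = "|".join(d.site_ids_a + d.site_ids_b) or f"{d.chrom}:{d.start}"
        rows.append((d.chrom, start, end, label, clipped))
    return rows
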