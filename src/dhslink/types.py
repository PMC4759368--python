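"""Core domain types for the DHS analysis pipeline.

All genomic coordinates are 0-based half-open (BED convention). A hotspot's
MaxD is the maximal per-base-pair tag count within the site; its normalized
form is expressed per 10 million sequenced reads.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with exon structure.

    The TSS is ``tx_start`` on the + strand and ``tx_end - 1`` on the −
    strand (the last covered base under half-open coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"gene {self.gene_id}: tx_start must be < tx_end "
                f"({self.tx_start} >= {self.tx_end})"
            )
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, "
                    f"non-overlapping and within the transcript"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus gene models (a stand-in reference annotation)."""

    chroms: dict[str, int]
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        for name, length in self.chroms.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        for g in self.genes:
            if g.chrom not in self.chroms:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.tx_end > self.chroms[g.chrom]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom}"
                )


@dataclass
class Hotspot:
    """A DHS interval with raw and depth-normalized maximal tag density.

    ``raw_maxd`` may be carried as a per-replicate pair after replicate
    merging; ``raw_pair``/``depth_pair`` hold those components so exact count
    tests remain possible downstream.
    """

    chrom: str
    start: int
    end: int
    raw_maxd: int
    norm_maxd: float
    site_id: str
    peak_pos: int | None = None
    raw_pair: tuple[int, int] | None = None
    depth_pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"site {self.site_id}: start must be < end")
        if self.raw_maxd < 0:
            raise ValueError(f"site {self.site_id}: raw_maxd must be >= 0")

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class HotspotSet:
    """All DHS calls of one sample/condition plus library metadata."""

    sample_id: str
    condition: str
    total_reads: int
    sites: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        self.sites = sorted(self.sites, key=lambda h: (h.chrom, h.start, h.end))
        ids = [h.site_id for h in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate site_id in sample {self.sample_id}")

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class DifferentialSite:
    """A condition-pair comparison record at one (possibly merged) interval.

    ``delta_norm_maxd`` is condition-b minus condition-a normalized MaxD —
    the signed "Intensity" used to weight linked genes. Status is
    ``unique_a``/``unique_b`` when the site has no overlap on the other side,
    otherwise ``common_modified`` (p below alpha) or ``common_unchanged``.
    """

    chrom: str
    start: int
    end: int
    condition_a: str
    condition_b: str
    count_a: int
    count_b: int
    depth_a: int
    depth_b: int
    norm_a: float
    norm_b: float
    delta_norm_maxd: float
    p_value: float
    status: str
    site_ids_a: tuple[str, ...] = ()
    site_ids_b: tuple[str, ...] = ()
    peak_pos: int | None = None

    STATUSES = ("unique_a", "unique_b", "common_modified", "common_unchanged")

    def __post_init__(self) -> None:
        if self.status not in self.STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class VennPartition:
    """Exact partition of input sites into Venn regions.

    Region labels are membership masks over the compared sets in order
    (e.g. ``"10"``/``"01"``/``"11"`` for a pair; ``"110"`` etc. for three).
    ``assignments`` maps every input site to its single region, keyed by
    (set-index, site_id), so per-set counts always sum to set sizes.
    """

    set_names: tuple[str, ...]
    assignments: dict[tuple[int, str], str]

    @property
    def region_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for region in self.assignments.values():
            counts[region] = counts.get(region, 0) + 1
        return counts

    def sites_in(self, region: str) -> list[tuple[int, str]]:
        return [k for k, r in self.assignments.items() if r == region]

    def per_set_total(self, set_index: int) -> int:
        return sum(1 for (i, _sid) in self.assignments if i == set_index)


CATEGORIES = ("promoter", "exon", "intron", "distal_upstream", "downstream")


@dataclass
class AnnotatedSite:
    """A hotspot-like record with its priority genomic category.

    Priority is promoter > exon > intron; remaining sites are distal
    upstream/downstream of the nearest gene's TSS. ``distance_to_tss`` is
    signed and strand-oriented: positive downstream of the TSS in the gene's
    reading direction.
    """

    chrom: str
    start: int
    end: int
    site_id: str
    category: str
    nearest_gene_id: str
    distance_to_tss: int
    norm_maxd: float = 0.0
    delta_norm_maxd: float | None = None
    peak_pos: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class EnhancerGeneLink:
    """A non-promoter differential site paired with a nearby gene.

    ``distance`` is from the gene's TSS to the nearest site border in bp
    (0 when the TSS falls inside the site); ``intensity`` is the signed
    delta of normalized MaxD carried over from the comparison.
    """

    site_id: str
    chrom: str
    start: int
    end: int
    category: str
    gene_id: str
    distance: int
    intensity: float


@dataclass
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    bh_fdr: float
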