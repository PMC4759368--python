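"""Synthetic fixtures with known ground truth for the whole pipeline.

The generator emulates the study design: a small multi-chromosome genome
with exon-structured gene models; per-condition DHS site sets sharing a
common backbone plus condition-unique sites; "gained enhancer" sites
planted outside promoter windows but within linking range of a chosen gene
set; Poisson tag pileups at a controlled sequencing depth with two jittered
replicate peak calls per condition; qPCR digestion titrations with known
digested fractions; and an expression matrix in which the planted genes
carry a log2 effect in the induced condition.

Everything is driven by one integer seed through numpy SeedSequence spawns:
a fixed seed reproduces the fixture byte for byte.
"""
from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .annotation import GeneIndex, classify_site
from .types import GeneModel, GenomeAnnotation, Hotspot, HotspotSet

PLANTED_SET_NAME = "planted_gained_enhancer_targets"


# ------------------------------------------------------------------- genome

def make_genome(
    n_chroms: int, chrom_length: int, n_genes: int, seed: int
) -> GenomeAnnotation:
    """A genome of equal-length chromosomes with non-overlapping genes.

    Genes are 2–20 kb with 2–10 exons each, both strands represented.
    Raises when the requested gene count cannot be placed without overlap
    at the implied density.
    """
    chrom_length = int(chrom_length)
    if n_chroms < 1 or chrom_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    budget = n_chroms * chrom_length
    # gene lengths adapt to the requested density: at most half the genome
    # is genic, capped at 20 kb per gene
    per_gene = budget // (2 * n_genes) if n_genes else budget
    max_gene_len = min(20_000, per_gene)
    min_gene_len = max(100, max_gene_len // 10)
    if n_genes and max_gene_len < 200:
        raise ValueError(
            f"cannot place {n_genes} non-overlapping genes in {budget} bp "
            f"of genome: density infeasible"
        )
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes % n_chroms):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for ci, (chrom, clen) in enumerate(chroms.items()):
        placed: list[tuple[int, int]] = []
        for _ in range(per_chrom[ci]):
            length = int(rng.integers(min_gene_len, max_gene_len + 1))
            for _attempt in range(200):
                start = int(rng.integers(0, clen - length))
                end = start + length
                i = bisect.bisect_left(placed, (start, end))
                ok = True
                if i > 0 and placed[i - 1][1] + 500 > start:
                    ok = False
                if i < len(placed) and end + 500 > placed[i][0]:
                    ok = False
                if ok:
                    bisect.insort(placed, (start, end))
                    break
            else:
                raise ValueError(
                    f"failed to place gene {gid} on {chrom} after 200 tries: "
                    "density infeasible"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 11))
            # cut the transcript into 2*n_exons-1 alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                                      replace=False))
            bounds = np.concatenate(([0], cuts, [length]))
            exons = tuple(
                (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
                for k in range(n_exons)
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
            gid += 1
    return GenomeAnnotation(chroms=chroms, genes=genes)


# ---------------------------------------------------------------- site truth

@dataclass(frozen=True)
class TrueSite:
    site_id: str
    chrom: str
    start: int
    end: int
    peak_pos: int
    maxd: float  # expected normalized MaxD (per 10M reads)
    shared: bool
    modified: bool = False  # shared site with a condition-specific shift
    planted_gene: str | None = None
    category: str = ""


@dataclass
class TruthSpec:
    """Study-design parameters for the synthetic site truth.

    Defaults describe the desk-scale rendition of the compared conditions:
    a common backbone of accessible sites, condition-unique sites, a subset
    of shared sites with a condition-specific MaxD shift, and gained
    enhancers planted near a target gene set in the induced condition.
    MaxD values and shift factors are log-normal (site intensities span
    orders of magnitude in real data).
    """

    conditions: tuple[str, ...] = ("B34", "B39d1", "OIMd1")
    n_shared: int = 200
    n_unique: dict[str, int] = field(
        default_factory=lambda: {"B34": 20, "B39d1": 25, "OIMd1": 25}
    )
    base_maxd_log_mean: float = math.log(60.0)
    base_maxd_log_sd: float = 0.5
    shift_log_mean: float = math.log(2.5)
    shift_log_sd: float = 0.35
    shared_modified_fraction: float = 0.15
    modified_condition: str = "OIMd1"
    planted_condition: str = "OIMd1"
    planted_genes: tuple[str, ...] = ()
    n_planted_enhancers: int = 10
    planted_maxd_log_mean: float = math.log(150.0)
    planted_maxd_log_sd: float = 0.25
    expression_effect: float = 2.0
    site_width_range: tuple[int, int] = (150, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared < 0 or any(v < 0 for v in self.n_unique.values()):
            raise ValueError("site counts must be >= 0")
        for c in self.n_unique:
            if c not in self.conditions:
                raise ValueError(f"n_unique names unknown condition {c!r}")


@dataclass
class HotspotTruth:
    spec: TruthSpec
    sites_by_condition: dict[str, list[TrueSite]]
    planted_genes: tuple[str, ...]

    def unique_counts(self) -> dict[str, int]:
        return {
            cond: sum(1 for s in sites if not s.shared)
            for cond, sites in self.sites_by_condition.items()
        }

    def shared_count(self) -> int:
        any_cond = next(iter(self.sites_by_condition.values()))
        return sum(1 for s in any_cond if s.shared)


class _Placer:
    """Non-overlapping interval placement with a safety margin."""

    def __init__(self, chroms: dict[str, int], margin: int = 100):
        self.chroms = chroms
        self.margin = margin
        self.placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def try_place(self, chrom: str, start: int, end: int) -> bool:
        lst = self.placed[chrom]
        if start < 0 or end > self.chroms[chrom]:
            return False
        i = bisect.bisect_left(lst, (start, end))
        if i > 0 and lst[i - 1][1] + self.margin > start:
            return False
        if i < len(lst) and end + self.margin > lst[i][0]:
            return False
        bisect.insort(lst, (start, end))
        return True

    def place_random(self, rng, width: int) -> tuple[str, int, int]:
        names = list(self.chroms)
        for _ in range(500):
            chrom = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, self.chroms[chrom] - width))
            if self.try_place(chrom, start, start + width):
                return chrom, start, start + width
        raise ValueError("could not place site: genome too crowded")


def make_hotspot_truth(genome: GenomeAnnotation, spec: TruthSpec) -> HotspotTruth:
    """Per-condition true site lists with known category and MaxD.

    Shared backbone sites have identical intervals across conditions; a
    fraction of them carry a multiplicative MaxD shift in the modified
    condition. Unique sites are private intervals. Planted gained enhancers
    are unique to the planted condition, sit outside every promoter window
    and within 50 kb of a planted gene's TSS.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    gene_ids = {g.gene_id for g in genome.genes}
    planted = spec.planted_genes
    if not planted and spec.n_planted_enhancers > 0:
        if not genome.genes:
            raise ValueError("planted enhancers need a genome with genes")
        order = sorted(gene_ids)
        take = min(spec.n_planted_enhancers, len(order))
        idx = rng.choice(len(order), size=take, replace=False)
        planted = tuple(order[i] for i in sorted(idx))
    unknown = [g for g in planted if g not in gene_ids]
    if unknown:
        raise ValueError(f"planted genes not in genome: {unknown}")

    index = GeneIndex(genome.genes) if genome.genes else None
    placer = _Placer(genome.chroms)
    wlo, whi = spec.site_width_range

    def draw_width() -> int:
        return int(rng.integers(wlo, whi + 1))

    def peak_of(start: int, end: int) -> int:
        return int(rng.integers(start + (end - start) // 4,
                                end - (end - start) // 4))

    def categorize(chrom: str, start: int, end: int) -> str:
        if index is None:
            return "downstream"
        return classify_site(chrom, start, end, index).category

    shared: list[TrueSite] = []
    n_modified = int(round(spec.shared_modified_fraction * spec.n_shared))
    for i in range(spec.n_shared):
        w = draw_width()
        chrom, start, end = placer.place_random(rng, w)
        maxd = float(rng.lognormal(spec.base_maxd_log_mean, spec.base_maxd_log_sd))
        shared.append(
            TrueSite(
                site_id=f"shared_{i:04d}",
                chrom=chrom, start=start, end=end,
                peak_pos=peak_of(start, end),
                maxd=maxd, shared=True, modified=i < n_modified,
                category=categorize(chrom, start, end),
            )
        )

    uniques: dict[str, list[TrueSite]] = {c: [] for c in spec.conditions}
    for cond in spec.conditions:
        for i in range(spec.n_unique.get(cond, 0)):
            w = draw_width()
            chrom, start, end = placer.place_random(rng, w)
            maxd = float(
                rng.lognormal(spec.base_maxd_log_mean, spec.base_maxd_log_sd)
            )
            uniques[cond].append(
                TrueSite(
                    site_id=f"{cond}_u{i:04d}",
                    chrom=chrom, start=start, end=end,
                    peak_pos=peak_of(start, end),
                    maxd=maxd, shared=False,
                    category=categorize(chrom, start, end),
                )
            )

    # planted gained enhancers: near a planted gene's TSS, never in a promoter
    if spec.n_planted_enhancers > 0 and planted:
        if index is None:
            raise ValueError("planted enhancers need a non-empty genome")
        genes_by_id = {g.gene_id: g for g in genome.genes}
        for i in range(spec.n_planted_enhancers):
            gene = genes_by_id[planted[i % len(planted)]]
            w = draw_width()
            for _attempt in range(500):
                offset = int(rng.integers(3000, 48_000 - w))
                sign = -1 if rng.random() < 0.5 else 1
                start = gene.tss + sign * offset - (w // 2)
                end = start + w
                if start < 0 or end > genome.chroms[gene.chrom]:
                    continue
                if index.hits(index.promoters, gene.chrom, start, end):
                    continue
                if placer.try_place(gene.chrom, start, end):
                    break
            else:
                raise ValueError(
                    f"could not place planted enhancer near {gene.gene_id}"
                )
            maxd = float(
                rng.lognormal(spec.planted_maxd_log_mean, spec.planted_maxd_log_sd)
            )
            uniques[spec.planted_condition].append(
                TrueSite(
                    site_id=f"planted_{i:04d}",
                    chrom=gene.chrom, start=start, end=end,
                    peak_pos=peak_of(start, end),
                    maxd=maxd, shared=False, planted_gene=gene.gene_id,
                    category=categorize(gene.chrom, start, end),
                )
            )

    shift = {
        s.site_id: float(rng.lognormal(spec.shift_log_mean, spec.shift_log_sd))
        for s in shared if s.modified
    }
    sites_by_condition: dict[str, list[TrueSite]] = {}
    for cond in spec.conditions:
        rows = []
        for s in shared:
            maxd = s.maxd * shift[s.site_id] if (
                s.modified and cond == spec.modified_condition
            ) else s.maxd
            rows.append(
                TrueSite(
                    site_id=s.site_id, chrom=s.chrom, start=s.start, end=s.end,
                    peak_pos=s.peak_pos, maxd=maxd, shared=True,
                    modified=s.modified, category=s.category,
                )
            )
        rows.extend(uniques[cond])
        rows.sort(key=lambda s: (s.chrom, s.start))
        sites_by_condition[cond] = rows
    return HotspotTruth(
        spec=spec, sites_by_condition=sites_by_condition, planted_genes=planted
    )


# ----------------------------------------------------------------- tag piles

def simulate_tags(
    truth_sites: list[TrueSite],
    genome: GenomeAnnotation,
    total_reads: int,
    seed: int,
    condition: str = "cond",
    jitter: int = 10,
    background_fraction: float | None = None,
) -> tuple[dict[str, np.ndarray], tuple[HotspotSet, HotspotSet]]:
    """Poisson cut-count tracks plus two jittered replicate peak calls.

    Per-bp counts inside a site follow a triangular profile whose peak mean
    equals the site's true MaxD scaled to the library depth (so at 10M reads
    the expected raw peak count equals the normalized MaxD). Reads not
    consumed by sites are spread uniformly as background so the track total
    matches the library size within Poisson error; ``background_fraction``
    overrides that (0 disables background, leaving only site tags).
    Replicate boundaries jitter by up to ``jitter`` bp each side; each
    replicate draws its own Poisson realization at the same depth. The
    returned track is replicate 1's.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    ss = np.random.SeedSequence(seed).spawn(3)
    depth_scale = total_reads / 1e7
    rate = {c: np.zeros(n, dtype=float) for c, n in genome.chroms.items()}
    for s in truth_sites:
        pos = np.arange(s.start, s.end)
        left = max(s.peak_pos - s.start, 1)
        right = max(s.end - 1 - s.peak_pos, 1)
        tri = np.where(
            pos <= s.peak_pos,
            1.0 - (s.peak_pos - pos) / (left + 1),
            1.0 - (pos - s.peak_pos) / (right + 1),
        )
        rate[s.chrom][s.start: s.end] += s.maxd * depth_scale * np.clip(tri, 0, 1)
    site_mass = sum(r.sum() for r in rate.values())
    genome_len = sum(genome.chroms.values())
    if background_fraction is None:
        bg = max(0.0, total_reads - site_mass) / genome_len
    else:
        bg = background_fraction * total_reads / genome_len
    for c in rate:
        rate[c] += bg

    reps = []
    for k in range(2):
        rng = np.random.default_rng(ss[k])
        track = {c: rng.poisson(r).astype(np.int64) for c, r in rate.items()}
        sites = []
        for s in truth_sites:
            d1 = int(rng.integers(-jitter, jitter + 1))
            d2 = int(rng.integers(-jitter, jitter + 1))
            start = max(0, s.start + d1)
            end = min(genome.chroms[s.chrom], s.end + d2)
            if end <= start:
                start, end = s.start, s.end
            window = track[s.chrom][start:end]
            raw = int(window.max()) if window.size else 0
            peak = start + int(window.argmax()) if window.size else start
            sites.append(
                Hotspot(
                    chrom=s.chrom, start=start, end=end, raw_maxd=raw,
                    norm_maxd=raw * 1e7 / total_reads,
                    site_id=s.site_id, peak_pos=peak,
                )
            )
        reps.append(
            (
                track,
                HotspotSet(
                    sample_id=f"{condition}_rep{k + 1}",
                    condition=condition,
                    total_reads=total_reads,
                    sites=sites,
                ),
            )
        )
    (track1, rep1), (_track2, rep2) = reps
    return track1, (rep1, rep2)


# ----------------------------------------------------------------- titration

def simulate_titration(
    true_fractions: dict[float, float],
    efficiency: float = 2.0,
    cq0: float = 20.0,
    sd_noise: float = 0.0,
    seed: int = 0,
    n_sensitive: int = 2,
    n_resistant: int = 2,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """A qPCR titration table with known digested fractions.

    ``true_fractions`` maps DNase concentration (U per 1e6 nuclei) to the
    digested fraction at sensitive sites; resistant sites stay undigested.
    Cq at fraction f is ``cq0 - log_efficiency(1 - f)`` plus Gaussian noise.
    Fractions of exactly 1 are rejected (Cq undefined).
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    for u, f in true_fractions.items():
        if not 0.0 <= f < 1.0:
            raise ValueError(f"fraction at {u} U must be in [0, 1), got {f}")
    rng = np.random.default_rng(seed)
    log_eff = math.log(efficiency)
    rows = []
    sites = [(f"sens_{i + 1}", "sensitive") for i in range(n_sensitive)]
    sites += [(f"resist_{i + 1}", "resistant") for i in range(n_resistant)]
    for site_id, cls in sites:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"site_id": site_id, "site_class": cls, "dnase_units": 0.0,
                 "replicate": rep,
                 "cq": cq0 + float(rng.normal(0, sd_noise)) if sd_noise else cq0}
            )
            for units in sorted(true_fractions):
                f = true_fractions[units] if cls == "sensitive" else 0.0
                cq = cq0 - math.log(1.0 - f) / log_eff
                if sd_noise:
                    cq += float(rng.normal(0, sd_noise))
                rows.append(
                    {"site_id": site_id, "site_class": cls,
                     "dnase_units": float(units), "replicate": rep, "cq": cq}
                )
    return pd.DataFrame(rows, columns=[
        "site_id", "site_class", "dnase_units", "replicate", "cq"
    ])


# ---------------------------------------------------------------- expression

EXPR_CONDITIONS = ("B39", "OIM")
EXPR_TIMES = ("d1", "d2")


def simulate_expression(
    genome: GenomeAnnotation,
    planted_genes: tuple[str, ...],
    n_replicates: int = 3,
    effect: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-by-sample intensity matrix with a planted log2 effect.

    Planted genes carry an additive ``effect`` on the log2 scale in every
    induced ("OIM") column; all other variation is log-normal noise around
    a per-gene baseline. Columns are ``<condition>:<time>:<replicate>``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    planted_set = set(planted_genes)
    base = 2.0 ** rng.normal(8.0, 1.0, size=len(gene_ids))
    cols = {}
    for cond in EXPR_CONDITIONS:
        for time in EXPR_TIMES:
            for rep in range(1, n_replicates + 1):
                shift = np.array(
                    [effect if (cond == "OIM" and g in planted_set) else 0.0
                     for g in gene_ids]
                )
                noise = rng.normal(0.0, noise_sd, size=len(gene_ids)) if noise_sd else 0.0
                cols[f"{cond}:{time}:{rep}"] = base * 2.0 ** (shift + noise)
    return pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))


# ----------------------------------------------------------------- gene sets

def make_gene_sets(
    genome: GenomeAnnotation,
    planted_genes: tuple[str, ...],
    n_decoys: int = 20,
    seed: int = 0,
) -> dict[str, set[str]]:
    """The planted target set plus size-matched decoy sets of other genes."""
    rng = np.random.default_rng(seed)
    others = sorted(set(g.gene_id for g in genome.genes) - set(planted_genes))
    size = len(planted_genes)
    if size == 0:
        raise ValueError("no planted genes to build sets around")
    if size > len(others):
        raise ValueError("not enough non-planted genes for size-matched decoys")
    sets = {PLANTED_SET_NAME: set(planted_genes)}
    for d in range(n_decoys):
        pick = rng.choice(len(others), size=size, replace=False)
        sets[f"decoy_{d + 1:02d}"] = {others[i] for i in sorted(pick)}
    return sets


# ------------------------------------------------------------------- fixture

@dataclass
class FixtureConfig:
    """End-to-end fixture at desk scale: 2 chromosomes x 2 Mb, 50 genes,
    2M-read libraries — roughly 1/1000 of a human DNase-seq experiment with
    the site-to-gene geometry preserved."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 50
    total_reads: int = 2_000_000
    truth: TruthSpec = field(default_factory=TruthSpec)
    titration_fractions: dict[float, float] = field(
        default_factory=lambda: {20.0: 0.50, 40.0: 0.75, 80.0: 0.93}
    )
    titration_noise_sd: float = 0.05
    expression_replicates: int = 3
    expression_noise_sd: float = 0.25
    n_decoy_sets: int = 20
    seed: int = 0


@dataclass
class Fixture:
    config: FixtureConfig
    genome: GenomeAnnotation
    truth: HotspotTruth
    replicates: dict[str, tuple[HotspotSet, HotspotSet]]
    tracks: dict[str, dict[str, np.ndarray]]
    titration: pd.DataFrame
    expression: pd.DataFrame
    gene_sets: dict[str, set[str]]


def generate_fixture(seed: int = 0, config: FixtureConfig | None = None) -> Fixture:
    """Build the full in-memory fixture from one master seed."""
    cfg = config or FixtureConfig()
    cfg.seed = seed
    ss = np.random.SeedSequence(seed).spawn(8)

    def subseed(i: int) -> int:
        return int(ss[i].generate_state(1)[0] % (2**31))

    genome = make_genome(cfg.n_chroms, cfg.chrom_length, cfg.n_genes, subseed(0))
    truth_spec = cfg.truth
    truth_spec.seed = subseed(1)
    truth = make_hotspot_truth(genome, truth_spec)
    replicates = {}
    tracks = {}
    for i, cond in enumerate(truth_spec.conditions):
        track, (rep1, rep2) = simulate_tags(
            truth.sites_by_condition[cond], genome, cfg.total_reads,
            seed=subseed(2) + i, condition=cond,
        )
        tracks[cond] = track
        replicates[cond] = (rep1, rep2)
    titration = simulate_titration(
        cfg.titration_fractions, sd_noise=cfg.titration_noise_sd, seed=subseed(3)
    )
    expression = simulate_expression(
        genome, truth.planted_genes,
        n_replicates=cfg.expression_replicates,
        effect=truth_spec.expression_effect,
        noise_sd=cfg.expression_noise_sd,
        seed=subseed(4),
    )
    gene_sets = make_gene_sets(
        genome, truth.planted_genes, n_decoys=cfg.n_decoy_sets, seed=subseed(5)
    )
    return Fixture(
        config=cfg, genome=genome, truth=truth, replicates=replicates,
        tracks=tracks, titration=titration, expression=expression,
        gene_sets=gene_sets,
    )


def truth_to_dict(truth: HotspotTruth) -> dict:
    return {
        "planted_genes": list(truth.planted_genes),
        "conditions": list(truth.spec.conditions),
        "n_shared": truth.shared_count(),
        "n_unique": truth.unique_counts(),
        "sites": {
            cond: [asdict(s) for s in sites]
            for cond, sites in truth.sites_by_condition.items()
        },
    }


def write_fixture(fixture: Fixture, outdir: str | Path) -> list[str]:
    """Write the fixture as plain-text files; returns the manifest.

    Files: chrom.sizes, genes.bed (BED12), per-condition replicate BED6
    hotspot calls, bedGraph tag tracks, titration.tsv, expression.tsv,
    sets.gmt, truth.json, samples.tsv (library metadata), manifest.json.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def emit(name: str) -> Path:
        manifest.append(name)
        return out / name

    dio.write_chrom_sizes(fixture.genome.chroms, emit("chrom.sizes"))
    dio.write_genes_bed12(fixture.genome.genes, emit("genes.bed"))
    meta_rows = []
    for cond, (rep1, rep2) in fixture.replicates.items():
        for k, rep in enumerate((rep1, rep2), start=1):
            dio.write_hotspots_bed(rep, emit(f"hotspots_{cond}_rep{k}.bed"))
            meta_rows.append(
                {"sample_id": rep.sample_id, "condition": cond,
                 "total_reads": rep.total_reads}
            )
        dio.write_bedgraph(fixture.tracks[cond], emit(f"tags_{cond}.bedGraph"))
    pd.DataFrame(meta_rows).to_csv(emit("samples.tsv"), sep="\t", index=False)
    dio.write_titration_tsv(fixture.titration, emit("titration.tsv"))
    dio.write_expression_tsv(fixture.expression, emit("expression.tsv"))
    dio.write_gmt(fixture.gene_sets, emit("sets.gmt"))
    dio.write_json(truth_to_dict(fixture.truth), emit("truth.json"))
    dio.write_json({"files": sorted(manifest)}, out / "manifest.json")
    manifest.append("manifest.json")
    return sorted(manifest)
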