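"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: chrom.sizes TSV, BED6 hotspot calls (name = site id, score = raw
MaxD), BED12 gene models, bedGraph cut-count tracks, GMT gene sets, and the
titration / expression TSVs. Everything is 0-based half-open.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import GeneModel, GenomeAnnotation, Hotspot, HotspotSet


# ---------------------------------------------------------------- chrom sizes

def write_chrom_sizes(chroms: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in chroms.items():
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split("\t")
            out[name] = int(length)
    return out


# ----------------------------------------------------------------- BED6 sites

def write_hotspots_bed(hset: HotspotSet, path: str | Path) -> None:
    """BED6 with name = site_id and score = raw MaxD.

    The peak position, when known, is appended as a 7th column so that
    round-trips keep it; standard BED readers ignore extra columns.
    """
    with open(path, "w") as fh:
        for h in hset.sites:
            peak = h.peak_pos if h.peak_pos is not None else "."
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.site_id}\t"
                f"{h.raw_maxd}\t.\t{peak}\n"
            )


def read_hotspots_bed(
    path: str | Path, sample_id: str, condition: str, total_reads: int
) -> HotspotSet:
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name, score = parts[:5]
            peak = (
                int(parts[6])
                if len(parts) > 6 and parts[6] not in ("", ".")
                else None
            )
            raw = int(score)
            sites.append(
                Hotspot(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    raw_maxd=raw,
                    norm_maxd=raw * 1e7 / total_reads,
                    site_id=name,
                    peak_pos=peak,
                )
            )
    return HotspotSet(
        sample_id=sample_id, condition=condition, total_reads=total_reads, sites=sites
    )


# ---------------------------------------------------------------- BED12 genes

def write_genes_bed12(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t"
                f"{g.strand}\t{g.tx_start}\t{g.tx_end}\t0\t"
                f"{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            p = line.rstrip("\n").split("\t")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            strand = p[5]
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offsets = [int(x) for x in p[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + sz) for off, sz in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    exons=exons,
                )
            )
    return genes


# ------------------------------------------------------------------- bedGraph

def write_bedgraph(track: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length encode per-bp counts; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in track:
            counts = np.asarray(track[chrom])
            if counts.size == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(counts)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [counts.size]))
            vals = counts[starts]
            for s, e, v in zip(starts, ends, vals):
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str | Path, chroms: dict[str, int]) -> dict[str, np.ndarray]:
    track = {name: np.zeros(length, dtype=np.int64) for name, length in chroms.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, val = line.rstrip("\n").split("\t")
            track[chrom][int(start): int(end)] = int(val)
    return track


# ------------------------------------------------------------------------ GMT

def write_gmt(collection: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            name, members = parts[0], set(parts[2:])
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            out[name] = members
    return out


# ------------------------------------------------------------------ TSV / JSON

def write_titration_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_titration_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_genome(chrom_sizes_path: str | Path, genes_bed_path: str | Path) -> GenomeAnnotation:
    return GenomeAnnotation(
        chroms=read_chrom_sizes(chrom_sizes_path),
        genes=read_genes_bed12(genes_bed_path),
    )
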