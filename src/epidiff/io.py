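"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph are 0-based half-open and pass through unchanged; GTF is
1-based closed and is converted to the internal half-open convention here, at
the reader boundary.  bedGraph values are written with ``repr`` (shortest
round-trip representation), so write -> read -> write is byte-identical.
"""

from __future__ import annotations

import re
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomicDistribution, GenomicInterval

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_gtf_genes",
    "write_distribution_tsv",
]

ANNOTATION_COLUMNS = ["gene_id", "name", "chrom", "start", "end", "strand", "biotype"]


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 peaks; strand (column 6) is kept when present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) >= 6 and row[5] in ("+", "-") else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(path, intervals: Sequence[GenomicInterval], names=None, scores=None) -> None:
    """Write BED3 (or BED6+ when names/scores given)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(str(names[i]) if names is not None else ".")
                cols.append(repr(scores[i]) if scores is not None else "0")
                cols.append(iv.strand)
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-base coverage arrays, one per chromosome.

    The array for each chromosome extends to the largest end coordinate seen;
    uncovered bases are 0.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        float_precision="round_trip",  # bit-exact write -> read -> write
    )
    out: dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom", sort=True):
        arr = np.zeros(int(sub["end"].max()), dtype=float)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s): int(e)] = v
        out[str(chrom)] = arr
    return out


def write_bedgraph(path, coverage: Mapping[str, np.ndarray]) -> None:
    """Write dense coverage as run-length-encoded bedGraph (zero runs omitted).

    Values are formatted with ``repr`` so the file round-trips bit-exactly
    through :func:`read_bedgraph` and a rewrite.
    """
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            arr = np.asarray(coverage[chrom], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{repr(float(v))}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return dict(zip(df["chrom"], df["size"].astype(int)))


def read_annotation_tsv(path) -> list[GeneAnnotation]:
    """7/8-column TSV: gene_id, name, chrom, start, end, strand, biotype
    [, chromatin_associated].  Coordinates are 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation TSV missing columns: {missing}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                name=str(row.name),
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end), str(row.strand)),
                biotype=str(row.biotype),
                chromatin_associated=bool(getattr(row, "chromatin_associated", False)),
            )
        )
    return genes


def write_annotation_tsv(path, genes: Sequence[GeneAnnotation]) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "name": g.name,
            "chrom": g.interval.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
            "biotype": g.biotype,
            "chromatin_associated": g.chromatin_associated,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["chromatin_associated"]).to_csv(
        path, sep="\t", index=False
    )


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf_genes(path) -> list[GeneAnnotation]:
    """Extract gene records from a GTF; 1-based closed coordinates become
    0-based half-open.  Any gene_biotype/gene_type other than protein_coding
    collapses onto the internal non_coding class."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            raw_bt = attrs.get("gene_biotype", attrs.get("gene_type", "protein_coding"))
            biotype = "protein_coding" if raw_bt == "protein_coding" else "non_coding"
            gid = attrs.get("gene_id", f"{f[0]}:{f[3]}-{f[4]}")
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    name=attrs.get("gene_name", gid),
                    interval=GenomicInterval(f[0], int(f[3]) - 1, int(f[4]), f[6]),
                    biotype=biotype,
                )
            )
    return genes


def write_distribution_tsv(path, dist: GenomicDistribution) -> None:
    """Class, fractional count, fraction of total — one row per feature class."""
    with open(path, "w") as fh:
        fh.write("class\tfractional_count\tfraction_of_total\n")
        for cls, cnt in dist.as_dict().items():
            fh.write(f"{cls}\t{repr(float(cnt))}\t{repr(float(dist.fraction_of_total(cls)))}\n")
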