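"""Genomic coordinate conventions, interval arithmetic, and feature annotation.

All coordinates are 0-based half-open (BED convention) internally; readers for
1-based formats (GTF) convert at the boundary.  A gene's TSS is ``start`` on
the + strand and ``end - 1`` on the - strand.  The genome is partitioned into
three feature classes:

* **promoter** — TSS +/- ``promoter_halfwidth`` (default 2.5 kb), unioned over
  genes and clipped to chromosome bounds;
* **genic** — gene bodies minus all promoter windows;
* **intergenic** — everything else.

A peak is assigned the set of classes it overlaps by at least one base, and a
peak overlapping k classes contributes 1/k to each, so fractional class counts
always sum to the number of peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "FeatureModel",
    "GenomicDistribution",
    "merge_intervals",
    "subtract_intervals",
    "overlap_length",
    "promoter_of",
    "classify_peak_features",
    "genomic_distribution",
]

FEATURE_CLASSES = ("promoter", "genic", "intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body with biotype, strand-resolved TSS, and a literature flag
    marking whether the gene product is known to be chromatin-associated."""

    gene_id: str
    name: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    chromatin_associated: bool = False

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )
        if self.biotype not in ("protein_coding", "non_coding"):
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: start on +, end - 1 on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Single-linkage merge: intervals overlapping by >= 1 bp collapse into one.

    Book-ended intervals ([a,b) and [b,c)) are also joined — their union is
    contiguous, matching base-mask semantics and ``bedtools merge``.  Output
    is sorted and strictly separated; the operation is idempotent and
    order-invariant.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlapping or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


def _as_arrays(merged: Sequence[GenomicInterval]) -> tuple[np.ndarray, np.ndarray]:
    starts = np.fromiter((iv.start for iv in merged), dtype=np.int64, count=len(merged))
    ends = np.fromiter((iv.end for iv in merged), dtype=np.int64, count=len(merged))
    return starts, ends


def overlap_length(
    chrom: str, start: int, end: int, merged: Sequence[GenomicInterval]
) -> int:
    """Total bases of [start, end) on ``chrom`` covered by a merged interval set."""
    total = 0
    for iv in merged:
        if iv.chrom != chrom:
            continue
        lo = max(start, iv.start)
        hi = min(end, iv.end)
        if lo < hi:
            total += hi - lo
    return total


def subtract_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference a \\ b over merged interval lists (per chromosome)."""
    a_merged = merge_intervals(a) if a else []
    b_merged = merge_intervals(b) if b else []
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cuts = [c for c in b_merged if c.chrom == iv.chrom and c.start < iv.end and iv.start < c.end]
        pos = iv.start
        for c in sorted(cuts, key=lambda x: x.start):
            if c.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, c.start))
            pos = max(pos, c.end)
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


@dataclass
class FeatureModel:
    """Promoter/genic/intergenic partition of a genome.

    Parameters
    ----------
    genes
        Gene annotations; may be empty (everything is then intergenic).
    chrom_sizes
        Chromosome name -> length in bp.  Promoter windows are clipped to
        [0, length).
    promoter_halfwidth
        Half-width of the promoter window around the TSS, bp (default 2500,
        i.e. a 5 kb window).
    """

    genes: list[GeneAnnotation]
    chrom_sizes: Mapping[str, int]
    promoter_halfwidth: int = 2500
    _promoters: list[GenomicInterval] = field(init=False, repr=False)
    _genic: list[GenomicInterval] = field(init=False, repr=False)
    _covered: list[GenomicInterval] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        proms = [promoter_of(g, self) for g in self.genes]
        bodies = [g.interval for g in self.genes]
        self._promoters = merge_intervals(proms) if proms else []
        self._genic = subtract_intervals(bodies, self._promoters)
        self._covered = merge_intervals(proms + bodies) if self.genes else []

    @property
    def promoter_intervals(self) -> list[GenomicInterval]:
        """Merged promoter windows of all genes."""
        return self._promoters

    @property
    def genic_intervals(self) -> list[GenomicInterval]:
        """Gene bodies minus promoter windows, merged."""
        return self._genic


def promoter_of(gene: GeneAnnotation, model: "FeatureModel") -> GenomicInterval:
    """Promoter window [tss - h, tss + h) clipped to the chromosome.

    The window is strand-independent in width; only the TSS position depends
    on strand.  Raises KeyError if the gene's chromosome is not in the model.
    """
    chrom = gene.interval.chrom
    if chrom not in model.chrom_sizes:
        raise KeyError(f"unknown chromosome {chrom!r} for gene {gene.gene_id}")
    h = model.promoter_halfwidth
    start = max(0, gene.tss - h)
    end = min(model.chrom_sizes[chrom], gene.tss + h)
    return GenomicInterval(chrom, start, end, gene.interval.strand)


def classify_peak_features(
    peak: GenomicInterval, model: FeatureModel
) -> frozenset[str]:
    """Feature classes (promoter/genic/intergenic) a peak overlaps by >= 1 bp.

    Promoter takes precedence inside promoter windows: genic means the part of
    a gene body not classified as promoter.  Intergenic is present iff some
    part of the peak lies outside all promoters and gene bodies.  With an
    empty annotation every peak is intergenic.
    """
    classes: set[str] = set()
    if overlap_length(peak.chrom, peak.start, peak.end, model._promoters) > 0:
        classes.add("promoter")
    if overlap_length(peak.chrom, peak.start, peak.end, model._genic) > 0:
        classes.add("genic")
    covered = overlap_length(peak.chrom, peak.start, peak.end, model._covered)
    if covered < peak.length:
        classes.add("intergenic")
    return frozenset(classes)


@dataclass(frozen=True)
class GenomicDistribution:
    """Fractional counts of peaks per feature class; counts sum to total_peaks."""

    promoter_count: float
    genic_count: float
    intergenic_count: float
    total_peaks: int

    def fraction_of_total(self, cls: str) -> float:
        if self.total_peaks == 0:
            return 0.0
        return getattr(self, f"{cls}_count") / self.total_peaks

    def as_dict(self) -> dict[str, float]:
        return {
            "promoter": self.promoter_count,
            "genic": self.genic_count,
            "intergenic": self.intergenic_count,
        }


def genomic_distribution(
    peaks: Sequence[GenomicInterval],
    model: FeatureModel,
    weighting: str = "fractional",
) -> GenomicDistribution:
    """Distribute peaks over promoter/genic/intergenic classes.

    ``weighting="fractional"`` (default) gives each peak total weight 1, split
    1/k over the k classes it overlaps, so counts sum exactly to the number of
    peaks.  ``weighting="per_class"`` counts a peak once in every class it
    overlaps (the alternative reading of proportional counting; totals then
    exceed the peak count for multi-class peaks).
    """
    if weighting not in ("fractional", "per_class"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = {c: 0.0 for c in FEATURE_CLASSES}
    for peak in peaks:
        classes = classify_peak_features(peak, model)
        w = 1.0 / len(classes) if weighting == "fractional" else 1.0
        for c in classes:
            counts[c] += w
    return GenomicDistribution(
        promoter_count=counts["promoter"],
        genic_count=counts["genic"],
        intergenic_count=counts["intergenic"],
        total_peaks=len(peaks),
    )
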