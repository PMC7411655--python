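"""Spike-in (exogenous genome) normalization of ChIP-seq and TSS metaprofiles.

With a constant amount of exogenous (e.g. fruit-fly) chromatin added per cell,
reads mapping to the exogenous genome calibrate immunoprecipitation efficiency
and sequencing depth between samples, so genome-wide occupancy shifts that
per-million scaling would erase survive normalization.  The aggregate profile
sums endogenous coverage in fixed bins around each target gene's TSS and
divides by the exogenous read count and the number of targets:

    value(b) = per * sum_genes covsum(gene, b) / (exogenous_reads * n_targets)

``per`` (default 1e6) only rescales to readable magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atac import SignalTrack
from .core import GeneAnnotation

__all__ = ["SpikeInSample", "TSSProfile", "spikein_scale_factor", "tss_aggregate_profile"]


@dataclass
class SpikeInSample:
    """A ChIP sample: endogenous coverage track plus the two mapped read counts
    from the composite-genome alignment."""

    track: SignalTrack
    exogenous_reads: int
    endogenous_reads: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.exogenous_reads < 0 or self.endogenous_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class TSSProfile:
    """Spike-in-normalized aggregate signal in bins around the TSS.

    ``bin_offsets`` are bin centers relative to the TSS (bp, signed, 5'->3'
    of the gene when strand-aware); ``values`` are per ``per`` exogenous reads
    per target gene.
    """

    bin_offsets: np.ndarray
    values: np.ndarray
    n_targets: int
    window: int
    bin_width: int
    clipped_genes: list[str] = field(default_factory=list)
    skipped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != 2 * self.window // self.bin_width:
            raise ValueError("profile length must equal 2*window/bin_width")
        if (np.asarray(self.values) < 0).any():
            raise ValueError("profile values must be non-negative")


def spikein_scale_factor(sample: SpikeInSample, per: int = 1_000_000) -> float:
    """Multiplier that puts endogenous coverage on the per-``per``-exogenous-reads
    scale; errors when the sample has no exogenous reads to normalize by."""
    if sample.exogenous_reads <= 0:
        raise ValueError(f"sample {sample.label!r} not normalizable: no exogenous reads")
    return per / sample.exogenous_reads


def tss_aggregate_profile(
    sample: SpikeInSample,
    genes: Sequence[GeneAnnotation],
    window: int = 2500,
    bin_width: int = 50,
    strand_aware: bool = True,
    per: int = 1_000_000,
) -> TSSProfile:
    """Aggregate spike-in-normalized coverage around the TSSs of a gene list.

    Each gene contributes the per-base coverage sum inside each ``bin_width``
    bin of [TSS - window, TSS + window); minus-strand genes have their bin
    axis reversed when ``strand_aware`` so upstream is always left.  Windows
    reaching past chromosome bounds are clipped (gene flagged); genes on
    chromosomes absent from the track are skipped with a warning and excluded
    from ``n_targets``.
    """
    if not genes:
        raise ValueError("gene list is empty")
    if window % bin_width != 0:
        raise ValueError("window must be a multiple of bin_width")
    scale = spikein_scale_factor(sample, per=per)
    n_bins = 2 * window // bin_width
    acc = np.zeros(n_bins, dtype=float)
    clipped: list[str] = []
    skipped: list[str] = []
    n_used = 0
    for gene in genes:
        chrom = gene.interval.chrom
        if chrom not in sample.track.coverage:
            warnings.warn(
                f"gene {gene.gene_id} on {chrom} absent from track; skipped",
                stacklevel=2,
            )
            skipped.append(gene.gene_id)
            continue
        sums = _gene_bin_sums(sample.track, chrom, gene.tss, window, bin_width, n_bins)
        if sums is None:
            sums, was_clipped = _gene_bin_sums_clipped(
                sample.track, chrom, gene.tss, window, bin_width, n_bins
            )
            if was_clipped:
                clipped.append(gene.gene_id)
        if strand_aware and gene.interval.strand == "-":
            sums = sums[::-1]
        acc += sums
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene in the list overlaps the track")
    values = scale * acc / n_used
    offsets = -window + (np.arange(n_bins) + 0.5) * bin_width
    return TSSProfile(
        bin_offsets=offsets,
        values=values,
        n_targets=n_used,
        window=window,
        bin_width=bin_width,
        clipped_genes=clipped,
        skipped_genes=skipped,
    )


def _gene_bin_sums(track, chrom, tss, window, bin_width, n_bins):
    """Fast path: per-base track and window fully inside the chromosome."""
    if track.bin_width != 1:
        return None
    lo, hi = tss - window, tss + window
    arr = track.coverage[chrom]
    if lo < 0 or hi > len(arr):
        return None
    return arr[lo:hi].reshape(n_bins, bin_width).sum(axis=1)


def _gene_bin_sums_clipped(track, chrom, tss, window, bin_width, n_bins):
    """General path: binned tracks and/or windows clipped at chromosome bounds.

    The per-base coverage sum in a profile bin is the sum over track bins of
    value * bases-of-overlap.
    """
    arr = track.coverage[chrom]
    tw = track.bin_width
    extent = len(arr) * tw
    out = np.zeros(n_bins, dtype=float)
    was_clipped = False
    for b in range(n_bins):
        lo = tss - window + b * bin_width
        hi = lo + bin_width
        clo, chi = max(0, lo), min(extent, hi)
        if clo != lo or chi != hi:
            was_clipped = True
        if clo >= chi:
            continue
        first, last = clo // tw, (chi - 1) // tw
        for t in range(first, last + 1):
            ov = min(chi, (t + 1) * tw) - max(clo, t * tw)
            out[b] += arr[t] * ov
    return out, was_clipped
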