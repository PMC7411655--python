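"""Two-condition chromatin accessibility comparison.

The workflow mirrors a standard two-condition open-chromatin analysis: library
depths are equalized (seeded down-sampling, or deterministic per-million
scaling), peaks called per condition are merged into a single union set, each
union peak is summarized by the maximum normalized coverage it contains in
each condition, and a peak is called differential when

1. one condition is enriched at least ``fold_min``-fold over the other
   (``fold_min`` = 2 by default), and
2. the maximum normalized value across the two conditions exceeds
   ``value_min`` (2 by default).

The same per-peak maxima feed the between-condition scatterplot and the
replicate-correlation QC, so every downstream view shares one quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import GeneAnnotation, GenomicInterval, merge_intervals

__all__ = [
    "SignalTrack",
    "FragmentSet",
    "UnionPeak",
    "DifferentialCall",
    "CorrelationResult",
    "FragmentSizeHistogram",
    "downsample_fragments",
    "build_union_peaks",
    "quantify_union_peaks",
    "classify_differential",
    "call_differential_peaks",
    "locus_peak_count",
    "replicate_correlation",
    "fragment_size_histogram",
]

UP = "up_in_case"
DOWN = "down_in_case"
NS = "not_differential"


@dataclass
class SignalTrack:
    """Binned non-negative coverage per chromosome at a fixed bin width.

    ``coverage[chrom][i]`` is the signal over bases
    ``[i * bin_width, (i+1) * bin_width)``; bin_width 1 means per-base.
    """

    coverage: dict[str, np.ndarray]
    total_fragments: int
    label: str = ""
    bin_width: int = 1

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        for chrom, arr in self.coverage.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.coverage[chrom] = arr

    def extent(self, chrom: str) -> int:
        """Rightmost covered coordinate (bp) on a chromosome."""
        return len(self.coverage[chrom]) * self.bin_width

    def max_in(self, interval: GenomicInterval) -> float:
        """Maximum coverage over bins intersecting the half-open interval."""
        if interval.chrom not in self.coverage:
            raise KeyError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"on chromosome absent from track {self.label!r}"
            )
        if interval.end > self.extent(interval.chrom):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"outside track extent {self.extent(interval.chrom)}"
            )
        lo = interval.start // self.bin_width
        hi = -(-interval.end // self.bin_width)  # ceil division
        return float(self.coverage[interval.chrom][lo:hi].max())


@dataclass
class FragmentSet:
    """Paired-end fragments as intervals; insert size = end - start."""

    fragments: list[GenomicInterval]
    label: str = ""

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def insert_sizes(self) -> np.ndarray:
        return np.fromiter(
            (f.end - f.start for f in self.fragments), dtype=np.int64, count=len(self.fragments)
        )


@dataclass(frozen=True)
class UnionPeak:
    """A merged two-condition peak with per-condition max normalized signal."""

    interval: GenomicInterval
    v: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.v.values()):
            raise ValueError("normalized signal must be non-negative")


@dataclass(frozen=True)
class DifferentialCall:
    """Classification of a union peak under the two-clause differential rule."""

    peak: UnionPeak | None
    status: str
    fold: float
    passed_value_filter: bool


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    n: int
    defined: bool
    reason: str = ""


@dataclass(frozen=True)
class FragmentSizeHistogram:
    """Counts per 1-bp insert size in [1, max_size]; larger sizes pool in overflow."""

    counts: np.ndarray  # counts[s-1] = number of fragments of size s
    overflow: int
    max_size: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.overflow


def downsample_fragments(fs: FragmentSet, target_n: int, seed: int) -> FragmentSet:
    """Sample exactly ``target_n`` fragments uniformly without replacement.

    Depth equalization across libraries; reproducible for a fixed seed.  No
    up-sampling: target_n may not exceed the library size.
    """
    n = len(fs)
    if not (0 < target_n <= n):
        raise ValueError(f"target_n={target_n} not in (0, {n}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=target_n, replace=False))
    return FragmentSet([fs.fragments[i] for i in idx], label=fs.label)


def build_union_peaks(
    peaks_a: Sequence[GenomicInterval], peaks_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Merge both conditions' peak calls into one sorted non-overlapping set.

    Single-linkage: any chain of >= 1 bp overlaps collapses into one interval,
    so every input peak is contained in exactly one output interval.
    """
    pooled = list(peaks_a) + list(peaks_b)
    if not pooled:
        return []
    return merge_intervals(pooled)


def quantify_union_peaks(
    union: Sequence[GenomicInterval],
    track_a: SignalTrack,
    track_b: SignalTrack,
    mode: str = "per_million",
) -> list[UnionPeak]:
    """Per-peak, per-condition max normalized signal over the union set.

    ``per_million`` scales each track's max by 1e6 / total_fragments;
    ``downsampled`` assumes depths were equalized upstream and uses raw maxima.
    """
    if mode not in ("per_million", "downsampled"):
        raise ValueError(f"unknown mode {mode!r}")
    scales = {}
    for t in (track_a, track_b):
        if mode == "per_million":
            if t.total_fragments <= 0:
                raise ValueError(f"track {t.label!r}: total_fragments must be > 0")
            scales[t.label] = 1e6 / t.total_fragments
        else:
            scales[t.label] = 1.0
    if track_a.label == track_b.label:
        raise ValueError("tracks must carry distinct condition labels")
    out = []
    for iv in union:
        v = {t.label: t.max_in(iv) * scales[t.label] for t in (track_a, track_b)}
        out.append(UnionPeak(interval=iv, v=v))
    return out


def _fold(v_control: float, v_case: float) -> float:
    if v_control == 0.0 and v_case == 0.0:
        return 1.0
    if v_control == 0.0 or v_case == 0.0:
        return math.inf
    return max(v_case / v_control, v_control / v_case)


def classify_differential(
    v_control: float,
    v_case: float,
    fold_min: float = 2.0,
    value_min: float = 2.0,
) -> DifferentialCall:
    """Apply the two-clause differential rule to one peak's signal pair.

    fold is the symmetric ratio max(case/control, control/case), with x/0 = inf
    for x > 0 and 0/0 = 1.  Status is up_in_case iff case >= fold_min * control
    and max(v) > value_min (strict); down_in_case symmetrically.  The fold
    comparison is inclusive ("at least"), the value filter strict.
    """
    if v_control < 0 or v_case < 0:
        raise ValueError("signal values must be non-negative")
    fold = _fold(v_control, v_case)
    passed_value = max(v_control, v_case) > value_min
    status = NS
    if passed_value:
        # fold_min > 1 makes the two clauses mutually exclusive whenever the
        # value filter passes (both hold only at v_control = v_case = 0)
        if v_case >= fold_min * v_control:
            status = UP
        elif v_control >= fold_min * v_case:
            status = DOWN
    return DifferentialCall(peak=None, status=status, fold=fold, passed_value_filter=passed_value)


def call_differential_peaks(
    union_peaks: Sequence[UnionPeak],
    control_label: str,
    case_label: str,
    fold_min: float = 2.0,
    value_min: float = 2.0,
) -> list[DifferentialCall]:
    """Classify every union peak, attaching the peak to each call."""
    out = []
    for up in union_peaks:
        call = classify_differential(
            up.v[control_label], up.v[case_label], fold_min=fold_min, value_min=value_min
        )
        out.append(DifferentialCall(peak=up, status=call.status, fold=call.fold,
                                    passed_value_filter=call.passed_value_filter))
    return out


def locus_peak_count(
    peaks: Sequence[GenomicInterval],
    gene: GeneAnnotation,
    flank: int = 50_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> int:
    """Number of peaks overlapping the gene body extended by ``flank`` bp.

    The window [start - flank, end + flank) is clipped at chromosome bounds
    when sizes are given; overlap is >= 1 bp on the same chromosome.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    iv = gene.interval
    lo = max(0, iv.start - flank)
    hi = iv.end + flank
    if chrom_sizes is not None and iv.chrom in chrom_sizes:
        hi = min(hi, chrom_sizes[iv.chrom])
    window = GenomicInterval(iv.chrom, lo, hi)
    return sum(1 for p in peaks if p.overlaps(window))


def replicate_correlation(
    values_rep1: Sequence[float], values_rep2: Sequence[float]
) -> CorrelationResult:
    """Pearson correlation of per-union-peak signals between two replicates.

    Requires >= 3 paired peaks.  A zero-variance vector makes the coefficient
    undefined; that is reported explicitly rather than propagating NaN.
    """
    x = np.asarray(values_rep1, dtype=float)
    y = np.asarray(values_rep2, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 peaks for a correlation")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult(r=None, n=n, defined=False, reason="zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n=n, defined=True)


def fragment_size_histogram(fs: FragmentSet, max_size: int = 2000) -> FragmentSizeHistogram:
    """Insert-size spectrum: 1-bp bins in [1, max_size] plus an overflow bin."""
    if len(fs) == 0:
        raise ValueError("fragment set is empty")
    sizes = fs.insert_sizes
    counts = np.bincount(sizes[sizes <= max_size], minlength=max_size + 1)[1:]
    overflow = int((sizes > max_size).sum())
    return FragmentSizeHistogram(counts=counts, overflow=overflow, max_size=max_size)
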