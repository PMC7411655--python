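"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's interval arithmetic: they
label every base of a small chromosome (or scan every base of an interval)
and are used to cross-check the production implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from epidiff.core import FeatureModel, GeneAnnotation, GenomicInterval


@pytest.fixture
def simple_model() -> FeatureModel:
    """One 100 kb chromosome, one + gene [10000, 30000) with TSS 10000."""
    gene = GeneAnnotation(
        gene_id="g1",
        name="gene1",
        interval=GenomicInterval("chr1", 10_000, 30_000, "+"),
    )
    return FeatureModel(genes=[gene], chrom_sizes={"chr1": 100_000})


def random_annotation(rng: np.random.Generator, length: int = 100_000, n_genes: int = 6):
    """A random non-overlapping annotation on one chromosome."""
    slot = length // n_genes
    genes = []
    for i in range(n_genes):
        lo = i * slot + int(rng.integers(0, slot // 3))
        hi = lo + int(rng.integers(slot // 4, slot // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i}", name=f"g{i}",
                interval=GenomicInterval("chr1", lo, min(hi, length - 1), strand),
            )
        )
    return FeatureModel(genes=genes, chrom_sizes={"chr1": length})


def base_labels(model: FeatureModel, chrom: str, length: int) -> np.ndarray:
    """Per-base feature labels (0=intergenic, 1=genic, 2=promoter), computed
    directly from gene records without the package's interval arithmetic."""
    lab = np.zeros(length, dtype=np.int8)
    h = model.promoter_halfwidth
    for g in model.genes:
        if g.interval.chrom != chrom:
            continue
        lab[g.interval.start: g.interval.end] = np.maximum(
            lab[g.interval.start: g.interval.end], 1
        )
    for g in model.genes:
        if g.interval.chrom != chrom:
            continue
        lo = max(0, g.tss - h)
        hi = min(length, g.tss + h)
        lab[lo:hi] = 2
    return lab


LABEL_NAMES = {0: "intergenic", 1: "genic", 2: "promoter"}


def oracle_classify(peak: GenomicInterval, labels: np.ndarray) -> frozenset[str]:
    """Set of per-base labels under the peak."""
    return frozenset(LABEL_NAMES[v] for v in np.unique(labels[peak.start: peak.end]))


def oracle_merge(intervals, length: int) -> list[tuple[int, int]]:
    """Single-linkage merge via a boolean base mask (maximal covered runs;
    book-ended intervals form one run)."""
    mask = np.zeros(length, dtype=bool)
    for iv in intervals:
        mask[iv.start: iv.end] = True
    out = []
    in_run = False
    for i in range(length):
        if mask[i] and not in_run:
            start, in_run = i, True
        elif not mask[i] and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, length))
    return out


def oracle_max_coverage(arr: np.ndarray, start: int, end: int) -> float:
    """Max coverage by explicit per-base enumeration."""
    best = -np.inf
    for i in range(start, end):
        if arr[i] > best:
            best = arr[i]
    return float(best)


def oracle_differential(v_control: float, v_case: float, fold_min=2.0, value_min=2.0) -> str:
    """Clause-by-clause re-evaluation of the two-part differential rule."""
    clause_value = max(v_control, v_case) > value_min
    up = v_case >= fold_min * v_control and clause_value
    down = v_control >= fold_min * v_case and clause_value
    if up and down:  # both hold only when v_control = v_case = 0, blocked above
        return "not_differential"
    if up:
        return "up_in_case"
    if down:
        return "down_in_case"
    return "not_differential"
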