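"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure each analysis assumes — a
two-condition accessibility experiment with planted differential regions, a
spike-in ChIP pair with a known genome-wide occupancy shift, DE tables with
planted case-specific non-coding genes and decoys for every failure mode, and
qPCR plates with planted expression folds under Gaussian Ct noise — on a toy
genome small enough for exhaustive per-base oracles.

Noise models are the minimal conventional ones per data type: multiplicative
lognormal on accessibility signal, Poisson on ChIP coverage, Gaussian on the
Ct scale.  Every generator is a pure function of its parameters and seed
(byte-identical reruns); one experiment seed spawns independent sub-streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .assays import CtMeasurement
from .atac import FragmentSet, SignalTrack
from .chip import SpikeInSample
from .core import GeneAnnotation, GenomicInterval
from .funnel import DETable

import pandas as pd

__all__ = [
    "ToyGenome",
    "PlantedRegion",
    "SyntheticTruth",
    "default_toy_genome",
    "generate_accessibility_pair",
    "generate_fragment_set",
    "generate_spikein_experiment",
    "generate_de_tables",
    "generate_qpcr_plate",
    "generate_chip_qpcr_plate",
]


@dataclass
class ToyGenome:
    """A small genome with non-overlapping annotated genes."""

    chrom_sizes: dict[str, int]
    genes: list[GeneAnnotation]


@dataclass(frozen=True)
class PlantedRegion:
    """A planted enriched region with its true differential direction."""

    interval: GenomicInterval
    direction: str  # up | down | none (relative to the case condition)
    fold: float


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, for recovery assertions."""

    seed: int
    planted_differential_regions: list[PlantedRegion] = field(default_factory=list)
    true_occupancy_ratio: float | None = None
    planted_candidates: list[str] = field(default_factory=list)
    planted_chromatin_associated: list[str] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    planted_expression_folds: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_differential_regions"] = [
            PlantedRegion(GenomicInterval(**r["interval"]), r["direction"], r["fold"])
            for r in d.get("planted_differential_regions", [])
        ]
        return cls(**d)


def default_toy_genome(
    seed: int = 0,
    length: int = 1_000_000,
    n_coding: int = 40,
    n_noncoding: int = 20,
    chrom: str = "chrS",
) -> ToyGenome:
    """One 1 Mb chromosome with 60 non-overlapping genes (40 coding, 20 non-coding).

    Genes are placed in evenly spaced slots with randomized spans and strands,
    so promoters, bodies, and intergenic gaps all occur.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    n_genes = n_coding + n_noncoding
    slot = length // n_genes
    biotypes = np.array(["protein_coding"] * n_coding + ["non_coding"] * n_noncoding)
    rng.shuffle(biotypes)
    genes = []
    for i in range(n_genes):
        lo = i * slot + int(rng.integers(200, slot // 4))
        body = int(rng.integers(slot // 4, slot // 2))
        hi = min(lo + body, (i + 1) * slot - 100)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"G{i:04d}",
                name=f"gene{i}",
                interval=GenomicInterval(chrom, lo, hi, strand),
                biotype=str(biotypes[i]),
            )
        )
    return ToyGenome(chrom_sizes={chrom: length}, genes=genes)


def generate_accessibility_pair(
    genome: ToyGenome,
    n_peaks: int = 200,
    frac_differential: float = 0.2,
    fold: float = 4.0,
    depth: int = 1_000_000,
    noise_cv: float = 0.0,
    peak_width: int = 300,
    base_height: float = 10.0,
    height_spread: float = 7.0,
    background: float = 0.2,
    boundary_jitter: int = 20,
    seed: int = 0,
    noise_seed: int | None = None,
):
    """Two-condition accessibility tracks and peak calls with planted truth.

    Places ``n_peaks`` non-overlapping enriched regions on the toy genome; a
    ``frac_differential`` subset carries a true case/control ratio of
    ``fold`` (half up in the case, half down).  Peak strengths are on the
    per-million normalized scale: each region draws a strength log-uniformly
    in [``base_height``, ``base_height * height_spread``] (real peak sets
    span about an order of magnitude), shared between conditions so it
    cancels from the fold ratio; the floor ``base_height`` (default 10) keeps
    every region above the value-filter threshold.  Raw coverage is scaled to
    ``depth`` fragments.  Strengths get independent multiplicative lognormal
    noise of coefficient of variation ``noise_cv`` per condition; passing a
    ``noise_seed`` redraws only that noise, giving replicate draws of the
    same planted experiment.  Per-condition peak calls jitter the region
    boundaries by up to ``boundary_jitter`` bp to exercise the union merge.

    Returns (track_control, track_case, peaks_control, peaks_case, truth).
    """
    if not (0 <= frac_differential <= 1):
        raise ValueError("frac_differential must be in [0, 1]")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    chrom, length = next(iter(genome.chrom_sizes.items()))
    slot = length // n_peaks
    if slot <= peak_width + 2 * boundary_jitter + 2:
        raise ValueError(
            f"cannot place {n_peaks} non-overlapping peaks of width {peak_width} "
            f"on a {length} bp genome; use a larger genome or fewer peaks"
        )
    if height_spread < 1:
        raise ValueError("height_spread must be >= 1")
    ss = np.random.SeedSequence([seed, 0xACC])
    rng_place, rng_noise, rng_jit = (np.random.default_rng(s) for s in ss.spawn(3))
    if noise_seed is not None:
        rng_noise = np.random.default_rng(np.random.SeedSequence([seed, 0xACC, noise_seed]))

    starts = np.array(
        [i * slot + int(rng_place.integers(boundary_jitter + 1, slot - peak_width - boundary_jitter - 1))
         for i in range(n_peaks)]
    )
    n_diff = int(round(frac_differential * n_peaks))
    diff_idx = rng_place.choice(n_peaks, size=n_diff, replace=False)
    directions = np.array(["none"] * n_peaks, dtype=object)
    directions[diff_idx[: n_diff // 2]] = "up"
    directions[diff_idx[n_diff // 2:]] = "down"

    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    strengths = base_height * height_spread ** rng_place.random(n_peaks)

    def heights(i: int, direction: str) -> tuple[float, float]:
        ctrl = float(strengths[i])
        if direction == "up":
            case = ctrl * fold
        elif direction == "down":
            case = ctrl / fold
        else:
            case = ctrl
        return ctrl, case

    cov_ctrl = np.full(length, background)
    cov_case = np.full(length, background)
    regions, truth_regions = [], []
    for i in range(n_peaks):
        s, e = int(starts[i]), int(starts[i]) + peak_width
        ctrl_h, case_h = heights(i, directions[i])
        if sigma > 0:
            ctrl_h *= float(np.exp(rng_noise.normal(-sigma**2 / 2, sigma)))
            case_h *= float(np.exp(rng_noise.normal(-sigma**2 / 2, sigma)))
        cov_ctrl[s:e] = ctrl_h
        cov_case[s:e] = case_h
        iv = GenomicInterval(chrom, s, e)
        regions.append(iv)
        truth_regions.append(
            PlantedRegion(interval=iv, direction=str(directions[i]),
                          fold=fold if directions[i] != "none" else 1.0)
        )

    scale = depth / 1e6  # normalized height -> raw coverage at the given depth
    track_ctrl = SignalTrack({chrom: cov_ctrl * scale}, total_fragments=depth, label="control")
    track_case = SignalTrack({chrom: cov_case * scale}, total_fragments=depth, label="case")

    def jittered(rng) -> list[GenomicInterval]:
        out = []
        for iv in regions:
            a = int(rng.integers(0, boundary_jitter + 1))
            b = int(rng.integers(0, boundary_jitter + 1))
            out.append(GenomicInterval(chrom, max(0, iv.start - a), min(length, iv.end + b)))
        return out

    peaks_ctrl = jittered(rng_jit)
    peaks_case = jittered(rng_jit)
    truth = SyntheticTruth(
        seed=seed,
        planted_differential_regions=truth_regions,
        params={
            "n_peaks": n_peaks, "frac_differential": frac_differential, "fold": fold,
            "depth": depth, "noise_cv": noise_cv, "peak_width": peak_width,
            "base_height": base_height, "height_spread": height_spread,
            "background": background,
        },
    )
    return track_ctrl, track_case, peaks_ctrl, peaks_case, truth


def generate_fragment_set(
    n: int = 10_000,
    genome: ToyGenome | None = None,
    seed: int = 0,
    label: str = "",
) -> FragmentSet:
    """Paired-end fragments with the bimodal insert-size spectrum typical of
    transposase libraries (sub-nucleosomal ~80 bp and mono-nucleosomal ~200 bp
    modes), uniformly positioned on the toy genome."""
    genome = genome or default_toy_genome()
    chrom, length = next(iter(genome.chrom_sizes.items()))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF1A9]))
    mode = rng.random(n) < 0.6
    sizes = np.where(
        mode,
        rng.lognormal(np.log(80), 0.25, n),
        rng.lognormal(np.log(200), 0.15, n),
    ).astype(int)
    sizes = np.clip(sizes, 1, 2500)
    starts = rng.integers(0, length - 2500, n)
    frags = [GenomicInterval(chrom, int(s), int(s + sz)) for s, sz in zip(starts, sizes)]
    return FragmentSet(frags, label=label)


def generate_spikein_experiment(
    genome: ToyGenome,
    genes: Sequence[GeneAnnotation] | None = None,
    true_ratio: float = 2.0,
    depth: int = 2_000_000,
    spikein_fraction: float = 0.1,
    peak_height: float = 5.0,
    peak_sd: float = 400.0,
    background: float = 0.2,
    seed: int = 0,
):
    """A spike-in ChIP pair with a planted genome-wide occupancy shift.

    Sample A's expected endogenous coverage is a background plus a Gaussian
    bump at every target TSS, scaled so total expected endogenous reads equal
    ``depth``; sample B's expectation is ``true_ratio`` times A's at every
    base.  Spike-in chromatin is constant per cell, so both samples share the
    same expected exogenous read count, fixed so the exogenous fraction of
    sample A's reads is ``spikein_fraction``.  Coverage is Poisson per base;
    exogenous counts are Poisson.

    Returns (sample_a, sample_b, truth).
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    if not (0 < spikein_fraction < 1):
        raise ValueError("spikein_fraction must be in (0, 1)")
    genes = list(genes) if genes is not None else genome.genes
    chrom, length = next(iter(genome.chrom_sizes.items()))
    ss = np.random.SeedSequence([seed, 0xC41])
    rng_a, rng_b, rng_exo = (np.random.default_rng(s) for s in ss.spawn(3))

    x = np.arange(length, dtype=float)
    expected = np.full(length, background)
    for g in genes:
        if g.interval.chrom != chrom:
            continue
        lo = max(0, g.tss - 4 * int(peak_sd))
        hi = min(length, g.tss + 4 * int(peak_sd))
        expected[lo:hi] += peak_height * np.exp(-0.5 * ((x[lo:hi] - g.tss) / peak_sd) ** 2)
    expected *= depth / expected.sum()

    cov_a = rng_a.poisson(expected).astype(float)
    cov_b = rng_b.poisson(true_ratio * expected).astype(float)
    exo_expected = spikein_fraction / (1.0 - spikein_fraction) * depth
    exo_a = int(rng_exo.poisson(exo_expected))
    exo_b = int(rng_exo.poisson(exo_expected))

    sample_a = SpikeInSample(
        track=SignalTrack({chrom: cov_a}, total_fragments=int(cov_a.sum()), label="A"),
        exogenous_reads=exo_a,
        endogenous_reads=int(cov_a.sum()),
        label="A",
    )
    sample_b = SpikeInSample(
        track=SignalTrack({chrom: cov_b}, total_fragments=int(cov_b.sum()), label="B"),
        exogenous_reads=exo_b,
        endogenous_reads=int(cov_b.sum()),
        label="B",
    )
    truth = SyntheticTruth(
        seed=seed,
        true_occupancy_ratio=true_ratio,
        params={
            "depth": depth, "spikein_fraction": spikein_fraction,
            "peak_height": peak_height, "peak_sd": peak_sd, "background": background,
        },
    )
    return sample_a, sample_b, truth


_DECOY_MODES = (
    "coding_significant",      # right q and expression, wrong biotype
    "not_significant",         # non-coding, case-specific, but q >= 0.05
    "expressed_in_control",    # significant non-coding, detectable in control
    "expressed_in_other",      # significant non-coding, detectable in the other background
    "below_tau_in_case",       # significant non-coding, under the detection floor in case
)


def generate_de_tables(
    genome: ToyGenome | None = None,
    n_genes: int = 500,
    n_planted_candidates: int = 3,
    n_chromatin: int = 1,
    q_max: float = 0.05,
    tau: float = 1.0,
    tau_margin: float = 1.0,
    noncoding_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[DETable, SyntheticTruth]:
    """DE tables for two comparisons with planted candidates and staged decoys.

    Planted candidates are non-coding, significant (q < q_max) in the case
    comparison, expressed at >= tau + tau_margin in the case and 0 in both
    control conditions; ``n_chromatin`` of them carry the chromatin literature
    flag.  One decoy per failure mode is planted so each funnel stage
    demonstrably rejects something; the rest of the table is background with
    uniform q-values and mixed expression.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE7]))
    gene_pool: list[tuple[str, str]] = []
    if genome is not None:
        gene_pool = [(g.gene_id, g.biotype) for g in genome.genes]
    while len(gene_pool) < n_genes:
        i = len(gene_pool)
        bt = "non_coding" if rng.random() < noncoding_fraction else "protein_coding"
        gene_pool.append((f"g{i:05d}", bt))
    gene_pool = gene_pool[:n_genes]

    nc_ids = [g for g, bt in gene_pool if bt == "non_coding"]
    n_special = n_planted_candidates + len(_DECOY_MODES) - 1  # coding decoy is separate
    if n_planted_candidates > len(nc_ids) or n_special > len(nc_ids):
        raise ValueError("not enough non-coding genes for the requested plants")
    if n_chromatin > n_planted_candidates:
        raise ValueError("n_chromatin cannot exceed n_planted_candidates")
    coding_ids = [g for g, bt in gene_pool if bt == "protein_coding"]

    picked_nc = list(rng.choice(nc_ids, size=n_special, replace=False))
    planted = picked_nc[:n_planted_candidates]
    decoy_nc = picked_nc[n_planted_candidates:]
    decoys = {
        "coding_significant": [str(rng.choice(coding_ids))],
        "not_significant": [decoy_nc[0]],
        "expressed_in_control": [decoy_nc[1]],
        "expressed_in_other": [decoy_nc[2]],
        "below_tau_in_case": [decoy_nc[3]],
    }
    def q_sig() -> float:
        return float(rng.uniform(1e-4, 0.8 * q_max))

    def q_ns() -> float:
        return float(rng.uniform(q_max, 1.0))

    rows = []
    for gid, bt in gene_pool:
        chrom_flag = gid in planted[:n_chromatin]
        if gid in planted:
            qc, qo = q_sig(), q_ns()
            e_case = tau + tau_margin + float(rng.uniform(0, 5))
            e_ctrl, e_other = 0.0, 0.0
        elif gid in decoys["coding_significant"] or gid in decoys["not_significant"]:
            qc = q_sig() if gid in decoys["coding_significant"] else q_ns()
            qo = q_ns()
            e_case = tau + tau_margin + float(rng.uniform(0, 5))
            e_ctrl, e_other = 0.0, 0.0
        elif gid in decoys["expressed_in_control"]:
            qc, qo = q_sig(), q_ns()
            e_case = tau + tau_margin + float(rng.uniform(0, 5))
            e_ctrl, e_other = tau + float(rng.uniform(0, 2)), 0.0
        elif gid in decoys["expressed_in_other"]:
            qc, qo = q_sig(), q_ns()
            e_case = tau + tau_margin + float(rng.uniform(0, 5))
            e_ctrl, e_other = 0.0, tau + float(rng.uniform(0, 2))
        elif gid in decoys["below_tau_in_case"]:
            qc, qo = q_sig(), q_ns()
            e_case = float(rng.uniform(0, 0.8 * tau))
            e_ctrl, e_other = 0.0, 0.0
        else:
            qc = float(rng.uniform(0, 1))
            # ~30% of background deregulation is shared between comparisons,
            # so the Venn overlap of the two non-coding sets is non-trivial
            qo = qc if rng.random() < 0.3 else float(rng.uniform(0, 1))
            # background expression is condition-correlated (not case-specific):
            # control expression >= case expression guarantees the expression
            # filter rejects every background gene, so the planted candidates
            # are the only case-specific loci by construction
            b = float(rng.exponential(2.0))
            e_case = b * float(rng.lognormal(0, 0.2))
            e_ctrl = e_case * float(rng.uniform(1.0, 1.5))
            e_other = b * float(rng.lognormal(0, 0.2))
        for comparison, q in (("case_vs_control", qc), ("other_vs_control", qo)):
            rows.append({
                "gene_id": gid, "biotype": bt, "comparison": comparison,
                "q_value": q, "expr_case": e_case, "expr_control": e_ctrl,
                "expr_other": e_other, "chromatin_associated": chrom_flag,
            })
    table = DETable(pd.DataFrame(rows))
    truth = SyntheticTruth(
        seed=seed,
        planted_candidates=[str(g) for g in planted],
        planted_chromatin_associated=[str(g) for g in planted[:n_chromatin]],
        decoys={k: [str(g) for g in v] for k, v in decoys.items()},
        params={"n_genes": n_genes, "q_max": q_max, "tau": tau, "tau_margin": tau_margin},
    )
    return table, truth


def generate_qpcr_plate(
    design: Mapping[tuple[str, str], float],
    calibrator: str,
    reference_target: str = "REF",
    ct_base: float = 20.0,
    sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[CtMeasurement], SyntheticTruth]:
    """Expression qPCR wells with planted fold changes.

    ``design`` maps (sample, target) to the true quantity relative to the
    calibrator sample (where every fold is taken as 1).  Each well's
    Ct = ct_base - log2(quantity) + N(0, sigma); the reference target is added
    at fold 1 for every sample.
    """
    if sigma < 0 or replicates < 1:
        raise ValueError("sigma must be >= 0 and replicates >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9BC2]))
    samples = sorted({s for s, _ in design} | {calibrator})
    targets = sorted({t for _, t in design})
    wells: list[CtMeasurement] = []
    folds: dict[str, float] = {}
    for s in samples:
        for t in targets + [reference_target]:
            if t == reference_target or s == calibrator:
                fold = 1.0
            else:
                fold = float(design.get((s, t), 1.0))
            folds[f"{s}|{t}"] = fold
            for rep in range(1, replicates + 1):
                ct = ct_base - np.log2(fold) + (rng.normal(0, sigma) if sigma > 0 else 0.0)
                wells.append(CtMeasurement(sample=s, target=t, ct=float(ct), replicate=rep))
    truth = SyntheticTruth(
        seed=seed,
        planted_expression_folds=folds,
        params={"ct_base": ct_base, "sigma": sigma, "replicates": replicates,
                "calibrator": calibrator, "reference_target": reference_target},
    )
    return wells, truth


def generate_chip_qpcr_plate(
    true_percent_input: Mapping[tuple[str, str], float],
    input_fraction: float = 0.01,
    ct_input_base: float = 20.0,
    sigma: float = 0.0,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[list[CtMeasurement], SyntheticTruth]:
    """ChIP-qPCR wells (IP + input) with planted percent-input recoveries.

    ``true_percent_input`` maps (sample, locus) to the true recovery in
    percent; IP Cts are derived by inverting the percent-input formula at the
    given ``input_fraction`` and then perturbed with N(0, sigma), as are the
    input wells.
    """
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC4B9]))
    wells: list[CtMeasurement] = []
    truths: dict[str, float] = {}
    for (sample, locus), pct in sorted(true_percent_input.items()):
        if pct <= 0:
            raise ValueError("true percent input must be positive")
        truths[f"{sample}|{locus}"] = float(pct)
        adjusted = ct_input_base - np.log2(1.0 / input_fraction)
        ct_ip_true = adjusted - np.log2(pct / 100.0)
        for rep in range(1, replicates + 1):
            noise_ip = rng.normal(0, sigma) if sigma > 0 else 0.0
            noise_in = rng.normal(0, sigma) if sigma > 0 else 0.0
            wells.append(CtMeasurement(sample=sample, target=locus, ct=float(ct_ip_true + noise_ip),
                                       replicate=rep, role="IP"))
            wells.append(CtMeasurement(sample=sample, target=locus, ct=float(ct_input_base + noise_in),
                                       replicate=rep, role="input", input_fraction=input_fraction))
    truth = SyntheticTruth(
        seed=seed,
        planted_expression_folds=truths,
        params={"input_fraction": input_fraction, "ct_input_base": ct_input_base,
                "sigma": sigma, "replicates": replicates},
    )
    return wells, truth
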