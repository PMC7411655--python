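"""Closed-form assay quantification: ddCt, ChIP-qPCR percent input and fold
enrichment, and the myotube fusion index.

Amplification efficiency defaults to perfect doubling (2.0 per cycle); an
efficiency parameter is exposed for instruments calibrated otherwise.
Replicate Cts are averaged on the Ct scale before any delta is taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMeasurement",
    "RelativeQuantity",
    "FusionField",
    "FusionIndexResult",
    "ddct_relative_expression",
    "ddct_from_table",
    "percent_input",
    "fold_enrichment",
    "fusion_index",
    "read_ct_table",
    "read_fusion_table",
]


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR well: threshold cycle for a (sample, target) pair."""

    sample: str
    target: str
    ct: float
    replicate: int = 1
    role: str = "cDNA"  # IP | input | cDNA
    input_fraction: float | None = None  # fraction of chromatin used as input

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"Ct must be positive, got {self.ct}")
        if self.role not in ("IP", "input", "cDNA"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "input":
            f = self.input_fraction
            if f is None or not (0 < f <= 1):
                raise ValueError("input wells need input_fraction in (0, 1]")


@dataclass(frozen=True)
class RelativeQuantity:
    """A ddCt fold change of target vs reference, relative to a calibrator."""

    value: float
    target: str = ""
    reference: str = ""
    calibrator: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("relative quantity must be positive")


@dataclass(frozen=True)
class FusionField:
    """Nuclei counts in one microscope field: nuclei inside myotubes
    (cells with >= 2 nuclei) out of all nuclei."""

    nuclei_in_myotubes: int
    total_nuclei: int

    def __post_init__(self) -> None:
        if self.total_nuclei <= 0:
            raise ValueError("total_nuclei must be positive")
        if not (0 <= self.nuclei_in_myotubes <= self.total_nuclei):
            raise ValueError("nuclei_in_myotubes outside [0, total_nuclei]")


@dataclass(frozen=True)
class FusionIndexResult:
    per_field: tuple[float, ...]  # percentage per field
    mean: float
    sd: float  # sample SD (n-1); NaN for a single field
    n_fields: int


def _check_ct(*cts: float) -> None:
    for ct in cts:
        if ct <= 0:
            raise ValueError(f"Ct must be positive, got {ct}")


def ddct_relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
    efficiency: float = 2.0,
) -> float:
    """ddCt fold change: E^-[(Ct_t,s - Ct_r,s) - (Ct_t,cal - Ct_r,cal)].

    Equals 1 when sample and calibrator have identical target/reference
    deltas; each cycle of advantage doubles the value at efficiency 2.
    """
    _check_ct(ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return float(efficiency ** (-ddct))


def ddct_from_table(
    measurements: Sequence[CtMeasurement],
    target: str,
    reference: str,
    sample: str,
    calibrator: str,
    efficiency: float = 2.0,
) -> RelativeQuantity:
    """ddCt from a plate of replicate wells: mean Ct per (sample, target)
    first, then the double delta."""

    def mean_ct(s: str, t: str) -> float:
        cts = [m.ct for m in measurements if m.sample == s and m.target == t]
        if not cts:
            raise ValueError(f"no Ct wells for sample {s!r}, target {t!r}")
        return float(np.mean(cts))

    value = ddct_relative_expression(
        mean_ct(sample, target),
        mean_ct(sample, reference),
        mean_ct(calibrator, target),
        mean_ct(calibrator, reference),
        efficiency=efficiency,
    )
    return RelativeQuantity(value=value, target=target, reference=reference, calibrator=calibrator)


def percent_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float,
    efficiency: float = 2.0,
) -> float:
    """ChIP-qPCR recovery as a percentage of (dilution-adjusted) input.

    The input Ct is first shifted to the 100%-input equivalent
    (ct_input - log_E(1/input_fraction)); recovery is then
    100 * E^(adjusted - ct_ip).  The input dilution is kit-defined and must
    be supplied explicitly.
    """
    _check_ct(ct_ip, ct_input)
    if not (0 < input_fraction <= 1):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    if efficiency <= 1:
        raise ValueError("efficiency must exceed 1")
    adjusted = ct_input - math.log(1.0 / input_fraction, efficiency)
    return 100.0 * efficiency ** (adjusted - ct_ip)


def fold_enrichment(pct_target: float, pct_control_locus: float) -> float:
    """Percent-input at the locus of interest over percent-input at a positive
    control locus, within one sample; compare samples as a ratio of ratios."""
    if pct_control_locus <= 0:
        raise ValueError("control locus percent input must be positive")
    if pct_target < 0:
        raise ValueError("target percent input must be non-negative")
    return pct_target / pct_control_locus


def fusion_index(fields: Sequence[FusionField]) -> FusionIndexResult:
    """Per-field fusion percentages and their mean +/- sample SD.

    A field's index is 100 * nuclei-in-myotubes / total nuclei; the summary
    is across whatever fields/replicates are supplied (count recorded).
    """
    if not fields:
        raise ValueError("need at least one field")
    per = tuple(100.0 * f.nuclei_in_myotubes / f.total_nuclei for f in fields)
    mean = float(np.mean(per))
    sd = float(np.std(per, ddof=1)) if len(per) > 1 else float("nan")
    return FusionIndexResult(per_field=per, mean=mean, sd=sd, n_fields=len(per))


def read_ct_table(path) -> list[CtMeasurement]:
    """Long-format TSV: sample, target, role, replicate, Ct[, input_fraction]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        frac = getattr(row, "input_fraction", None)
        if frac is not None and pd.isna(frac):
            frac = None
        out.append(
            CtMeasurement(
                sample=str(row.sample),
                target=str(row.target),
                ct=float(row.Ct),
                replicate=int(getattr(row, "replicate", 1)),
                role=str(getattr(row, "role", "cDNA")),
                input_fraction=float(frac) if frac is not None else None,
            )
        )
    return out


def read_fusion_table(path) -> dict[str, list[FusionField]]:
    """TSV: sample, field, nuclei_in_myotubes, total_nuclei -> fields per sample."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[FusionField]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            FusionField(int(row.nuclei_in_myotubes), int(row.total_nuclei))
        )
    return out
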