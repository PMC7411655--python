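"""Multi-stage selection of case-specific non-coding candidate genes.

Starting from differential-expression tables for two comparisons against the
same control (the affected case vs control, and an unrelated disease
background vs control), the funnel narrows:

1. loci deregulated in the case comparison (q < q_max, strict);
2. the non-coding subset (biotype filter);
3. genes expressed only in the case condition (abundance >= tau in the case,
   < tau in every control condition);
4. genes flagged in the literature as chromatin-associated.

The overlap of the two comparisons' non-coding deregulated sets (the Venn
view) is reported alongside; an alternative funnel that restricts stage 3 to
that overlap is also computed, since either starting set is defensible.
DE estimation itself is upstream: the tables are inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DETable",
    "CandidateFunnelResult",
    "read_de_table",
    "deregulated_set",
    "noncoding_subset",
    "case_specific_expressed",
    "run_funnel",
]

REQUIRED_COLUMNS = ("gene_id", "biotype", "comparison", "q_value")
EXPR_PREFIX = "expr_"


@dataclass
class DETable:
    """Long-format differential-expression records, one row per
    (gene, comparison).

    Columns: gene_id, biotype (protein_coding | non_coding), comparison,
    q_value in [0, 1], one ``expr_<condition>`` abundance column per
    condition (FPKM-like, >= 0), and optionally chromatin_associated (bool).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"DE table missing columns: {missing}")
        q = self.df["q_value"]
        if ((q < 0) | (q > 1)).any():
            raise ValueError("q_value outside [0, 1]")
        for c in self.expression_columns:
            if (self.df[c].dropna() < 0).any():
                raise ValueError(f"negative abundance in {c}")
        if "chromatin_associated" not in self.df.columns:
            self.df = self.df.assign(chromatin_associated=False)
        dup = self.df.duplicated(subset=["gene_id", "comparison"])
        if dup.any():
            raise ValueError("more than one row per (gene, comparison)")

    @property
    def expression_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(EXPR_PREFIX)]

    @property
    def conditions(self) -> list[str]:
        return [c[len(EXPR_PREFIX):] for c in self.expression_columns]

    def comparisons(self) -> list[str]:
        return sorted(self.df["comparison"].unique())

    def expression(self, gene: str, condition: str) -> float:
        """Abundance of a gene in a condition (consistent across that gene's rows)."""
        col = EXPR_PREFIX + condition
        if col not in self.df.columns:
            raise KeyError(f"gene {gene}: no expression column for condition {condition!r}")
        vals = self.df.loc[self.df["gene_id"] == gene, col].dropna()
        if vals.empty:
            raise KeyError(f"gene {gene}: missing expression for condition {condition!r}")
        return float(vals.iloc[0])


def read_de_table(path) -> DETable:
    """Read a long-format DE table TSV (see :class:`DETable` for columns)."""
    return DETable(pd.read_csv(path, sep="\t", dtype={"gene_id": str}))


def deregulated_set(table: DETable, comparison: str, q_max: float = 0.05) -> frozenset[str]:
    """Genes with q_value strictly below q_max in the named comparison."""
    df = table.df
    if comparison not in set(df["comparison"]):
        raise ValueError(f"unknown comparison {comparison!r}; have {table.comparisons()}")
    sub = df[(df["comparison"] == comparison) & (df["q_value"] < q_max)]
    return frozenset(sub["gene_id"])


def noncoding_subset(table: DETable, genes: frozenset[str]) -> frozenset[str]:
    """Restrict a gene set to non_coding biotype."""
    nc = set(table.df.loc[table.df["biotype"] == "non_coding", "gene_id"])
    return frozenset(genes & nc)


def case_specific_expressed(
    genes: frozenset[str],
    table: DETable,
    case: str,
    controls: Sequence[str],
    tau: float = 1.0,
) -> frozenset[str]:
    """Genes expressed in the case condition and in no control condition.

    Expressed means abundance >= tau; a single control at or above tau
    excludes the gene.  Missing expression for a required condition is an
    error naming the gene and condition.
    """
    kept = []
    for g in sorted(genes):
        if table.expression(g, case) >= tau and all(
            table.expression(g, c) < tau for c in controls
        ):
            kept.append(g)
    return frozenset(kept)


@dataclass(frozen=True)
class CandidateFunnelResult:
    """Stage sets and counts of the candidate-selection funnel."""

    deregulated_case: frozenset[str]
    deregulated_other: frozenset[str]
    noncoding_case: frozenset[str]
    noncoding_other: frozenset[str]
    overlap: frozenset[str]
    case_specific_expressed: frozenset[str]
    chromatin_associated_final: frozenset[str]
    case_specific_from_overlap: frozenset[str]
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "deregulated_case": len(self.deregulated_case),
            "deregulated_other": len(self.deregulated_other),
            "noncoding_case": len(self.noncoding_case),
            "noncoding_other": len(self.noncoding_other),
            "overlap": len(self.overlap),
            "case_specific_expressed": len(self.case_specific_expressed),
            "chromatin_associated_final": len(self.chromatin_associated_final),
            "case_specific_from_overlap": len(self.case_specific_from_overlap),
        }


def run_funnel(
    table: DETable,
    q_max: float = 0.05,
    tau: float = 1.0,
    case_comparison: str = "case_vs_control",
    other_comparison: str = "other_vs_control",
    case_condition: str = "case",
    control_conditions: Sequence[str] = ("control", "other"),
) -> CandidateFunnelResult:
    """Run the full funnel and the Venn overlap of the two comparisons.

    The expression filter runs on the case-deregulated non-coding set; the
    variant restricted to the Venn overlap is reported as
    ``case_specific_from_overlap``.  The final stage keeps genes whose
    chromatin_associated flag is set.
    """
    dereg_case = deregulated_set(table, case_comparison, q_max)
    dereg_other = deregulated_set(table, other_comparison, q_max)
    nc_case = noncoding_subset(table, dereg_case)
    nc_other = noncoding_subset(table, dereg_other)
    overlap = nc_case & nc_other
    specific = case_specific_expressed(nc_case, table, case_condition, control_conditions, tau)
    specific_overlap = case_specific_expressed(
        frozenset(overlap), table, case_condition, control_conditions, tau
    )
    chrom_flag = set(
        table.df.loc[table.df["chromatin_associated"].astype(bool), "gene_id"]
    )
    final = frozenset(specific & chrom_flag)
    return CandidateFunnelResult(
        deregulated_case=dereg_case,
        deregulated_other=dereg_other,
        noncoding_case=nc_case,
        noncoding_other=nc_other,
        overlap=frozenset(overlap),
        case_specific_expressed=specific,
        chromatin_associated_final=final,
        case_specific_from_overlap=specific_overlap,
        params={
            "q_max": q_max,
            "tau": tau,
            "case_comparison": case_comparison,
            "other_comparison": other_comparison,
            "case_condition": case_condition,
            "control_conditions": tuple(control_conditions),
        },
    )
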