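#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes two-condition accessibility tracks and peak calls, a spike-in ChIP
pair, differential-expression tables, and qPCR plates — each with its
truth.json — under results/data/.  One seed governs everything.
"""

from pathlib import Path

from epidiff import io
from epidiff.simulate import (
    default_toy_genome,
    generate_accessibility_pair,
    generate_de_tables,
    generate_qpcr_plate,
    generate_spikein_experiment,
)

SEED = 20240901
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = default_toy_genome(seed=SEED)
    io.write_annotation_tsv(OUT / "genes.tsv", genome.genes)
    with open(OUT / "chrom.sizes", "w") as fh:
        for c, n in genome.chrom_sizes.items():
            fh.write(f"{c}\t{n}\n")

    tc, tk, pc, pk, truth = generate_accessibility_pair(
        genome, n_peaks=200, frac_differential=0.2, fold=4.0, noise_cv=0.1, seed=SEED)
    io.write_bedgraph(OUT / "atac.control.bedgraph", tc.coverage)
    io.write_bedgraph(OUT / "atac.case.bedgraph", tk.coverage)
    io.write_bed(OUT / "atac.control.bed", pc)
    io.write_bed(OUT / "atac.case.bed", pk)
    truth.to_json(OUT / "atac.truth.json")
    print(f"accessibility pair: {len(pc)} peaks/condition, 20% differential at 4-fold, "
          f"10% signal noise -> {OUT}/atac.*")

    sa, sb, truth = generate_spikein_experiment(genome, true_ratio=2.0,
                                                depth=300_000, seed=SEED)
    io.write_bedgraph(OUT / "chip.A.bedgraph", sa.track.coverage)
    io.write_bedgraph(OUT / "chip.B.bedgraph", sb.track.coverage)
    with open(OUT / "chip.reads.tsv", "w") as fh:
        fh.write("sample\tendogenous_reads\texogenous_reads\n")
        fh.write(f"A\t{sa.endogenous_reads}\t{sa.exogenous_reads}\n")
        fh.write(f"B\t{sb.endogenous_reads}\t{sb.exogenous_reads}\n")
    truth.to_json(OUT / "chip.truth.json")
    print(f"spike-in ChIP pair: true 2x occupancy shift, exo reads "
          f"{sa.exogenous_reads}/{sb.exogenous_reads} -> {OUT}/chip.*")

    table, truth = generate_de_tables(n_genes=500, n_planted_candidates=3, seed=SEED)
    table.df.to_csv(OUT / "rnaseq.de.tsv", sep="\t", index=False)
    truth.to_json(OUT / "rnaseq.truth.json")
    print(f"DE tables: 500 genes x 2 comparisons, planted candidates "
          f"{truth.planted_candidates} -> {OUT}/rnaseq.*")

    wells, truth = generate_qpcr_plate(
        {("case", "TARGET"): 2.0, ("other", "TARGET"): 1.0},
        calibrator="control", sigma=0.1, replicates=3, seed=SEED)
    with open(OUT / "qpcr.ct.tsv", "w") as fh:
        fh.write("sample\ttarget\trole\treplicate\tCt\tinput_fraction\n")
        for w in wells:
            fh.write(f"{w.sample}\t{w.target}\t{w.role}\t{w.replicate}\t{w.ct!r}\t\n")
    truth.to_json(OUT / "qpcr.truth.json")
    print(f"qPCR plate: {len(wells)} wells, planted 2-fold target -> {OUT}/qpcr.*")


if __name__ == "__main__":
    main()
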