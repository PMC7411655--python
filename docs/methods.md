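# Methods

## Coordinate conventions and the feature partition

All coordinates are 0-based, half-open (BED convention) throughout the
library; the GTF reader converts 1-based closed gene records at the boundary.
A gene's TSS is `start` on the + strand and `end − 1` on the − strand.

The genome is partitioned into three feature classes:

* **promoter** — TSS ± `promoter_halfwidth` (default 2,500 bp, i.e. a 5 kb
  window), unioned over genes and clipped to chromosome bounds;
* **genic** — gene bodies minus all promoter windows (promoter takes
  precedence wherever the two overlap);
* **intergenic** — everything else.

A peak belongs to every class it overlaps by at least one base; there is no
minimum-overlap fraction. In the distribution summary each peak contributes
total weight 1, split 1/k over the k classes it touches, so fractional class
counts always sum to the number of peaks. The alternative reading — counting
a multi-class peak once per class — is available as
`weighting="per_class"`; it is reported per class but no longer conserves the
peak count. Interval merging is single-linkage and joins book-ended
intervals (their union is contiguous, matching base-mask semantics and
`bedtools merge`); it is idempotent and order-invariant.

## Differential accessibility

The two-condition comparison quantifies a merged **union peak set**: peaks
called in either condition are pooled and single-linkage merged, and each
union interval is summarized by the maximum normalized coverage it contains
per condition. Two normalization modes are provided:

* `per_million` (default): max coverage × 10⁶ / total mapped fragments —
  deterministic;
* `downsampled`: raw maxima after seeded down-sampling of each library to a
  common fragment count (`downsample_fragments`, uniform without
  replacement, no up-sampling).

The threshold `value_min` applies on whichever scale is selected and the
choice is recorded in output provenance.

A union peak is **differential** when

1. one condition is enriched at least `fold_min`-fold over the other
   (inclusive comparison, default 2), with the symmetric fold
   `max(v_case/v_control, v_control/v_case)`, and
2. `max(v_control, v_case) > value_min` (strict, default 2).

Degenerate folds are explicit: `x/0 = ∞` for `x > 0` (differential if the
value filter passes) and `0/0 = 1` (never differential). No pseudocount is
added. With `fold_min > 1` the up and down clauses are mutually exclusive
whenever the value filter passes, so ties are impossible. Scatter points,
differential calls, and replicate-correlation QC all read the same per-peak
quantification. Pearson correlation requires ≥ 3 peaks and reports a
zero-variance input as "undefined" rather than propagating NaN.

`locus_peak_count` counts peaks overlapping a gene body extended by a flank
(default ± 50 kb, clipped at chromosome ends); insert-size spectra are 1-bp
bins over [1, 2000] with an overflow bin, conserving the fragment count.

## Spike-in ChIP normalization and TSS profiles

With a constant amount of exogenous chromatin added per cell, reads mapping
to the exogenous genome calibrate IP efficiency and sequencing depth, so a
genome-wide occupancy shift — invisible to per-million scaling — survives
normalization. The scale factor is `per / exogenous_reads` (`per` = 10⁶ by
default; it only sets readable magnitudes and is config-exposed).

The aggregate TSS profile sums endogenous coverage in `bin_width` bins over
`[TSS − window, TSS + window)` (defaults 50 bp and 2,500 bp) across a gene
list and normalizes by exogenous reads and target count:

    value(b) = per · Σ_genes covsum(gene, b) / (exogenous_reads · n_targets)

Bins hold the per-base coverage sum (binned input tracks are expanded by
overlap weighting), not read 5′ ends: the library uses one signal
representation everywhere, and read-level inputs are converted to coverage by
the readers. Minus-strand genes have their bin axis reversed by default so
upstream is always left (metagene convention; disable with
`strand_aware=False`). Windows crossing chromosome ends are clipped and the
gene flagged; genes on chromosomes absent from the track are skipped with a
warning and excluded from `n_targets`.

## Candidate non-coding gene selection

Inputs are long-format differential-expression tables (one row per gene ×
comparison; DE estimation itself is upstream). The funnel:

1. deregulated in the case comparison: `q < q_max`, strict (default 0.05);
2. non-coding biotype;
3. expressed only in the case: abundance ≥ τ in the case and < τ in every
   control condition;
4. flagged chromatin-associated (a literature annotation supplied as input,
   never computed).

τ defaults to 1.0 FPKM — a conventional detection floor; it is
config-exposed and recorded in output provenance because it changes the
candidate list. The Venn overlap of the two comparisons' non-coding
deregulated sets is reported alongside, and the variant funnel that restricts
stage 3 to that overlap is also computed (`case_specific_from_overlap`),
since either starting set is a defensible reading of the design; the
case-deregulated set is the default path.

Note the expression filter is two-sided in τ: raising the floor shrinks the
case clause but relaxes the control clause, so the stage set is only
guaranteed monotone in τ on genes whose control abundances sit below both
floors. Monotonicity in `q_max` is unconditional.

## Assay formulas

* **ddCt**: `E^−[(Ct_t,s − Ct_r,s) − (Ct_t,cal − Ct_r,cal)]` with
  amplification efficiency E fixed at 2.0 (perfect doubling; an efficiency
  parameter exists for calibrated instruments). Replicate Cts are averaged
  on the Ct scale before any delta.
* **Percent input**: the input Ct is shifted to its 100%-input equivalent,
  `Ct_input − log_E(1/input_fraction)`, and recovery is
  `100 · E^(adjusted − Ct_IP)`. The input dilution is kit-defined and must
  be supplied; it is never defaulted.
* **Fold enrichment**: percent-input at the locus of interest over
  percent-input at a positive-control locus, within one sample; samples are
  compared as a ratio of ratios.
* **Fusion index**: per microscope field, 100 × nuclei-in-myotubes (cells
  with ≥ 2 nuclei) / total nuclei; summarized as mean ± sample SD (n − 1
  denominator). A single field reports SD as NaN.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, plus a `SyntheticTruth` record, so the whole pipeline is testable
without any external download. Noise models are the minimal conventional
ones per data type: multiplicative lognormal on accessibility signal,
Poisson on ChIP coverage, Gaussian on the Ct scale. Every generator is a
pure function of its parameters and seed (byte-identical reruns); one
experiment seed spawns independent sub-streams via `SeedSequence`.

* **Toy genome**: one 1 Mb chromosome, 60 non-overlapping genes (40 coding,
  20 non-coding) with random strands — small enough for exhaustive per-base
  oracles.
* **Accessibility pair**: 200 non-overlapping 300 bp regions; 20% planted
  differential at 4-fold (half up, half down). Region strengths are drawn
  log-uniformly over [10, 70] normalized units, shared between conditions
  (so the shared factor cancels from the fold ratio and the floor keeps
  every region above the value filter); per-condition lognormal noise of CV
  `noise_cv` sits on top, and a `noise_seed` redraws only the noise,
  yielding replicate draws of the same planted experiment. Per-condition
  peak calls jitter region boundaries by ≤ 20 bp to exercise the union
  merge.
* **Spike-in pair**: expected coverage is a background plus Gaussian bumps
  at every TSS, scaled to the requested endogenous depth; sample B's
  expectation is `true_ratio` × sample A's at every base. Spike-in chromatin
  is constant per cell, so both samples share the same expected exogenous
  count, set so the exogenous fraction of the reference sample's reads is
  `spikein_fraction`. Halving depth halves endogenous and exogenous reads
  together and leaves the normalized profile unchanged in expectation.
* **DE tables**: planted candidates are non-coding, significant in the case
  comparison, expressed at ≥ τ + margin in the case and 0 in controls, with
  a configurable subset carrying the chromatin flag. One decoy per failure
  mode (coding, non-significant, expressed-in-control, expressed-in-other,
  below-floor-in-case) guarantees every stage demonstrably rejects
  something. Background genes draw condition-correlated expression (control
  ≥ case) so planted candidates are the only case-specific loci by
  construction, and ~30% of background deregulation is shared between
  comparisons so the Venn overlap is non-trivial.
* **qPCR plates**: `Ct = ct_base − log₂(true quantity) + N(0, σ)` per well;
  reference targets and calibrator samples are planted at fold 1. The
  ChIP-qPCR variant inverts the percent-input formula at a given input
  fraction to place IP wells, then perturbs IP and input wells alike.

What the generators do **not** emulate: read-level sequences (no FASTQ, no
alignment artifacts), GC or insertion bias, overdispersion beyond the stated
noise models, correlated q-values along the genome, or biotype
misannotation. Passing recovery tests therefore demonstrates the
correctness of the downstream arithmetic and decision rules under the stated
noise models — not robustness to upstream artifacts these models exclude.

## Problem sizes and numerical choices

The bundled analyses and acceptance checks run on the 1 Mb toy genome with
the generator defaults above: 200 accessibility peaks per condition at 10⁶
fragments depth; spike-in pairs at 3 × 10⁵ endogenous reads with a 10%
spike-in fraction, 100 seeded replicates; DE tables of 400–500 genes, 100
seeded replicates; qPCR plates of 3 replicates at σ = 0.1, 100 seeds. Oracle
equivalence checks use 1,000 random cases per operation on a 100 kb
chromosome. Comparisons between floats derived from identical arithmetic are
exact; conservation is asserted to 10⁻⁹; stochastic recovery checks use the
tolerance stated with each check (5% for the spike-in ratio, 10% for qPCR
fold recovery).

Output files write floats with `repr` (shortest round-trip representation),
and the bedGraph reader parses with round-trip precision, so write → read →
write is byte-identical; provenance headers record parameters and seeds,
never timestamps, making every CLI artifact byte-identical across reruns.

## Known limitations

* Peak calling, alignment, and DE estimation are out of scope: peaks,
  coverage tracks, and DE tables are inputs.
* The per-class weighting of multi-class peaks is a design choice (1/k);
  base-pair-proportional weighting is not implemented.
* The spike-in profile uses coverage sums per bin; if upstream tracks encode
  something other than per-base read pileup the `per`-scale values change
  meaning (ratios between samples do not).
* `replicate_correlation` operates on per-union-peak maxima; genome-wide
  binned correlation is not implemented.
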