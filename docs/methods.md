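# Methods

This note documents the models, parameter choices and numerical decisions
behind `ribostall`, and what the synthetic studies do and do not establish
about real data.

## Coordinate conventions and formats

All internal intervals are 0-based half-open, the native convention of BED
and bedGraph; GFF3/GTF 1-based inclusive coordinates are converted once on
read (via an in-memory gffutils database) and nowhere else. A gene's
"transcript region" is the merged exon union over all of its isoforms;
when several isoforms exist the first encountered supplies the CDS used
for tract projection. Coverage is stored per base as floats because 30-bp
tile means are fractional after aggregation. bedGraph and FASTA round-trips
are lossless at per-base resolution (runs of equal value are merged on
write).

## Peak calling

* **Tile statistic.** Tile value is the *mean* per-base coverage (a
  `stat="sum"` option exists). The mean makes the truncated final tile of
  a chromosome comparable to full tiles and matches the behaviour of
  standard bin-coverage tools; with 1-bp expansion the two statistics
  differ only by the constant factor 30, which the per-gene z-score
  cancels anyway.
* **Expansion order.** 30-bp tiles are broken into 1-bp tiles *before*
  gene assignment (a flag allows 30-bp-level assignment). Peak positions
  are therefore defined at 1-bp granularity throughout the consensus
  stage.
* **The fit.** Per gene, μ is the sample mean and σ the maximum-likelihood
  SD (divisor n) of the tile values — the estimator a distribution-fitting
  routine returns; for the ≥ 30 tiles a typical gene has, the difference
  from the n−1 estimator is negligible. Zero-coverage tiles are included
  in the fit (they are part of the gene's coverage distribution); a
  drop-zeros option offers the alternative reading.
* **Peak threshold.** A tile is a peak when its upper-tail probability
  under N(μ, σ) is below α, default α = 0.001. α is a genuinely free
  parameter of this method — there is no canonical value — so it is
  exposed prominently and recorded in every output header. Genes with
  σ = 0 (constant coverage) or fewer than `min_tiles` (default 10) tiles
  are skipped: a normal fit on a handful of tiles is meaningless, and the
  σ = 0 rule avoids division by zero.
* **Calibration caveat.** Real footprint coverage is counts, not Gaussian;
  the 30-base tile mean is approximately normal by the central limit
  theorem at moderate depth (the synthetic default, 20× with NB size 10),
  which is why the null per-tile peak rate tracks α in the calibration
  test. At very low depth or extreme overdispersion the normal
  approximation — and hence the nominal α — degrades; that is a property
  of the method being implemented, not of this implementation.

## Consensus and control subtraction

Positions are compared at exact 1-bp identity; "corresponding positions"
means identical (chromosome, start). Defaults require support in ≥ 2
libraries and exclude a position present in *any* control library (the
strictest reading); `control_min_support` can instead require control
consensus. Surviving positions are merged into maximal contiguous runs,
each keeping the maximum per-position support, and a run overlapping two
genes is reported once per gene. Context sequence is the ± 30 nt genomic
window, clipped at chromosome ends and reverse-complemented for
minus-strand genes. The consensus result is invariant to library input
order and monotone non-increasing in `min_support` and in control-set
size.

## Codon tracts and motif scanning

* polyQ defaults to strict CAG-only runs (the disease-repeat definition);
  a relaxed mode admits CAA. polyS uses all six serine codons and polyA
  all four alanine codons, since those classes are defined by amino acid,
  not codon.
* Tracts are maximal in-frame runs of ≥ `min_codons` (default 4) target
  codons; maximality is property-tested against a regex oracle.
* The motif model is consensus-derived: the consensus letter gets
  probability 1 − ε with ε = 0.01 spread evenly over the other letters.
  Scores are log2 odds against a 0-order background (estimated from the
  scanned sequence set by default), discretized at 10⁻³ bits. The null
  score distribution is built by exact convolution of the per-position
  distributions, and observed windows are scored with the *same*
  discretized integers, so DP p-values equal brute-force enumeration over
  all |Σ|^L windows exactly. Scanning is single-strand, and no
  multiple-testing correction is applied to scan p-values (targets are
  filtered on raw p < 10⁻⁴).
* Peak-tract association: a gene is peak-associated when a consensus peak
  and a tract interval are within 30 nt (gap ≤ window; overlap = 0). The
  boundary is strict: gap 31 does not associate at window 30.
* TPM is the standard length-normalized rate scaled to 10⁶ per library;
  the expressed background is genes with mean TPM ≥ 1.

## Occupancy

The denominator for "rest of transcript" is the CDS minus the tract
(`--denominator transcript` substitutes the full exon union): footprint
density is CDS-borne, and including UTRs would dilute the denominator
unpredictably. Both classification thresholds are strict inequalities —
ratio 1.2 does *not* pass ">20 % increase" and ratio 2.0 does *not* pass
">2-fold" — so the 2-fold class is always nested in the 20 % class. A
gene with several tracts is summarized by its maximum-ratio tract; the
per-tract table is also emitted. Ratios are scale-invariant in the track.

## Polysome target calling

The classifier is deliberately simple and calibrated: per-library counts
are scaled to the mean library depth, TE = log2((polysome + 0.5)/(input +
0.5)) per replicate, and the p-value is a pooled two-sample t-test on
replicate TEs. Pooled rather than Welch because the design is a balanced
two-group comparison at very small n (two replicates, the realistic
minimum for gradient experiments), where Welch's degrees of freedom are
degenerate. "Lowly associated" means log2FC ≤ −1 (a ≥ 2-fold *drop* in
polysome association) with p < 0.05; "highly" the mirror image —
classification is exactly antisymmetric under swapping condition labels.
No multiple-testing correction is applied (targets are filtered on raw
p < 0.05). At n = 2 the test has 2 degrees of freedom; the caller warns
but proceeds. Overlap significance uses the upper-tail hypergeometric
computed via log-gamma and logsumexp, exact in log space for p-values far
below double-precision underflow of the naive sum.

## AvP profiling

AvP_x = ai_x / Σ cr_i × 100 is exactly scale-invariant (multiplying all
intensities of a spectrum by c > 0 changes nothing) and additive in ai_x.
All 9–15 analyses (biological × technical replicates) of a stage are
pooled into one t-test sample by default, matching common practice for
such profiling tables; `--collapse-technical` averages technical
replicates within biological replicates first, which is statistically
cleaner but changes n. The stage-vs-baseline test is Welch by default
(pooled by flag), two-sided, at p < 0.05, uncorrected. The rendered
gradient covers AvP 0–3 % with values above the maximum clipped into the
top bin; binning is monotone in AvP.

## Synthetic data: what it emulates and what it does not

The generator plants exact ground truth so that sensitivity and precision
are well-defined:

* **Genome/annotation**: single-exon, plus-strand coding genes (ATG +
  uniform sense codons + stop) separated by ≥ 100 bp intergenic gaps;
  default 50 genes of 200–600 codons. A planted tract replaces interior
  codons in-frame, so the tract sequence is literally present and
  detectable by an independent oracle. Multi-exon and minus-strand
  handling is exercised by unit tests rather than by the generator
  defaults.
* **Coverage**: per-base negative binomial (mean 20, size 10 — var = μ +
  μ²/size, i.e. moderately overdispersed sequencing-like noise) inside
  exons, zero outside; in Ribo-Seq (not RNA-seq) libraries, tract bases
  get mean × stall_factor (default 5). Stalls as multiplicative mean
  shifts exactly on tract bases give unambiguous truth but ignore real
  features: codon-level periodicity, P-site offsets, ramp effects,
  sequence bias, and spill-over of stalled ribosomes upstream of the
  repeat. Passing recovery tests therefore shows the *pipeline logic* is
  correct, not that real stalls of this magnitude exist.
* **Polysome counts**: gene baseline abundances log-normal (σ = 0.5)
  around mean 500; NB size 50 (dispersion 0.02, typical of
  well-correlated replicate libraries); 2 replicates per
  condition/fraction; planted genes shift the mutant polysome mean by
  2^log2FC (default −3).
* **Spectra**: canonical intensities ~2.5 × 10⁷ with log-normal
  multiplicative noise (CV 1 %) and PTM intensities set so the expected
  AvP equals the generating value.

Everything is deterministic given the seed; distinct libraries use
distinct child seeds.

## Problem sizes

The shipped analyses and checks use 50-gene genomes (~64 kb) for
end-to-end recovery, 120 genes for null calibration, 1000 genes for
polysome calibration/recovery, and motifs of length ≤ 8 for enumeration
oracles — sizes at which every expected value is computable exactly or
with tight Monte-Carlo bands while the whole suite runs in seconds.

## Known limitations

* The peak caller models tile coverage as normal; alternatives (Poisson/NB
  tests) are intentionally out of scope.
* The polysome t-test is a calibrated stand-in for more elaborate
  TE-modeling frameworks; it does not shrink variances across genes.
* The motif scanner handles consensus motifs, not arbitrary PWMs learned
  elsewhere, and 0-order backgrounds only.
* Isomer apportioning of MS intensities (e.g. uridine vs pseudouridine)
  must happen upstream; the AvP module takes already-apportioned
  intensities.
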