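# Methods

`exodys` implements an exon-level dysregulation scan for small case/control
RNA-seq cohorts, together with the counting, normalization, enrichment and
signature-comparison steps that surround it, and a synthetic-data generator
that makes every stage testable without external data. This note records
the statistical model, the conventions and defaults, what the generator
does and does not emulate, and the design choices made where the procedure
was genuinely open.

## The exon scan

For each sample and transcript, exon counts `c_i` are standardized within
the transcript:

    s_i = (c_i − μ) / σ

where μ and σ are the mean and standard deviation of the exon counts of
that transcript in that sample. This removes overall transcript abundance
(and with it the sample's library depth) and leaves each exon's position
within its transcript's expression profile. For every exon, each case
sample's scaled value is then compared to the reference distribution of
scaled values in the control samples:

    z(exon, case) = (s_case − mean(s_controls)) / sd(s_controls)

An exon is called **upregulated** when it has strictly more than
`min_control_reads` (default 50) raw reads summed over the control samples
and at least `min_cases` (default 5) case samples with `z > z_threshold`
(default 4); **downregulated** symmetrically with `z < −z_threshold`. An
exon meeting both rules is reported separately as *ambiguous* rather than
silently assigned; the total selection count treats it as one selection.

Conventions that the formula itself leaves open:

* **σ within the transcript** uses the population convention (ddof 0),
  since it describes the transcript's own count distribution, not an
  estimate of a larger population. `sd_mode="sample"` switches to ddof 1.
* **The control-reference SD** uses the sample convention (ddof 1), since
  eight controls are a small sample from the reference population.
  Configurable via `reference_ddof`.
* **The read filter** sums raw (unscaled) reads over all control samples
  and is a strict inequality; a per-sample-minimum variant is available
  (`control_reads_mode="per_sample"`).
* Transcripts with fewer than two exons, or with zero count variance in a
  sample, have no defined scaling there; exons whose control reference has
  fewer than two defined values or zero SD are excluded and reported with a
  reason (`zero_variance`, `control_sd_zero`, `read_filter`).
* Exons shared by several transcripts are scanned once per (transcript,
  exon) pair, because the scaling is inherently per transcript.

## Permutation null

Significance of the *number* of selected exons is assessed by permuting
condition labels across all samples, preserving the 8/11 group sizes, and
re-running the selection. Within-transcript scaling does not involve the
labels, so the scaled matrix is computed once and reused — an optimization
that is exact, not approximate. The empirical p-value uses the plug-in
convention r/R (the fraction of permutations whose selection count reaches
the observed count); `(r+1)/(R+1)` is available via
`p_convention="add_one"`. Default 1000 permutations. For small designs an
exhaustive mode enumerates all C(n, n_controls) distinct labelings (capped,
default 200,000); the identity labeling is among them and reproduces the
observed count exactly.

## Counting and RPKM

Reads are single aligned segments (paired-end mates count independently)
with MAPQ ≥ 1; the library size of a sample is its number of such reads,
exonic or not. Gene-level "exon hits" count a read once per gene whose
merged exon model it overlaps by at least 1 bp on the matching strand; a
read overlapping merged exons of two genes increments both (logged). At
exon level a read counts only if it overlaps exactly one exon of a
transcript; junction-spanning alignments (two or more exons of the same
transcript) are excluded from that transcript. Whether that exclusion is
per transcript or global across transcripts is configurable
(`multi_exon_rule`), defaulting to per transcript. RPKM is

    RPKM = count / (merged exon length / 10^3) / (library size / 10^6)

with the merged length the total bases of the union of the gene's exons
across transcripts. FPKM is accepted as a synonym — one quantity, two
spellings. Genes with zero merged length are flagged and excluded. There is
no CIGAR-aware spliced-overlap resolution, duplicate marking or
multi-mapper handling; the counter consumes a lightweight alignment table
(TSV/BED6-like), not BAM.

Internally all coordinates are 0-based half-open; the GTF reader converts
from 1-based inclusive, the BED reader passes through. The chromosome
allow-list defaults to 1–22, X, Y, M (with or without a `chr` prefix) in
the library reader; the command-line tools keep all chromosomes unless
`--standard-chromosomes-only` is given, because simulated data lives on
synthetic chromosomes.

## Synthetic data

The generator emulates the design of a strand-specific peripheral-blood
case/control study: 8 controls and 11 cases, transcript/exon structure on
synthetic chromosomes (genes laid out without overlap; additional
transcripts of a gene reuse jittered slices of the first transcript's
exons so merged models genuinely merge), and negative-binomial exon counts

    c_ej ~ NB(mean = μ_e · s_j · effect(e, j),  var = m + α m²)

with a single shared dispersion α (default 0.05), per-exon baseline means
μ_e log-uniform over `baseline_mean` (default 100–8000), and log-normal
library-size factors s_j (CV 0.15). Defaults are chosen as a desk-scale
stand-in for a genome-wide annotation of ~197k exons in ~26k transcripts
(about 7.6 exons per transcript; the default draws 4–10) and clinical-scale
sequencing depth.

**Planted effects.** A configurable fraction of exons receives a
multiplicative case-specific effect (× f for "up", × 1/f for "down",
default f = 8), recorded in a truth table. Planting is restricted, by
design, to effects the scan is built to detect: at most one exon per
transcript, the perturbed mean must stay inside the baseline range, and a
first-order (delta-method) prediction of the within-transcript scaling must
show the planted exon moving by at least 6 times its own noise SD while no
sibling exon moves by more than 2 times its noise SD. The reason for the
last rule is a genuine property of the statistic, not a convenience: a fold
change that pushes one exon far outside its transcript's dynamic range
inflates the transcript's μ and σ in every case sample, which shifts the
*other* exons' scaled values systematically and makes sibling exons of a
true hit light up as false positives. Such profile-rescaling effects are
real biology (amplification, whole-transcript shifts) but are precisely
what within-transcript scaling is designed to cancel; the planted truth
therefore emulates exon-usage shifts, and the sibling-contamination
behaviour is documented here as a known limitation of the method on other
effect types. When eligibility caps the number of planted exons below the
requested fraction, the generator plants what is eligible and logs the
shortfall; the truth table always lists exactly what was planted.

The alignment simulator emits one single-exon read per unit of count, fully
inside the exon, matching strand, MAPQ 60, so re-counting recovers the
generating counts exactly (for single-transcript genes; overlapping
transcripts share genomic intervals, so exon-level recovery across
transcripts is inherently ambiguous there, as in real data). Optional decoy
reads — antisense, MAPQ 0, intergenic, junction-spanning — must leave
exon-level counts unchanged; junction decoys raise the gene-level count
only. There is no sequence-level simulation (no FASTQ), no fragment-length
or GC model, and no isoform-switching truth.

What passing tests on this generator do **not** show about real data: no
batch effects, no per-gene dispersion variation, no correlated exons beyond
the transcript structure, no mappability artifacts, no annotation errors.
The recovery numbers (sensitivity, false-positive rate) characterize the
selection machinery under the stated noise model, not expected performance
on a real cohort.

## Null calibration

With `planted_fraction=0` the condition labels are exchangeable by
construction, so permutation p-values must be uniform. The calibration
check runs 200 replicate simulations (~240 exons each, 8+11 design, 500
permutations) and measures the Kolmogorov–Smirnov distance to uniform. Two
calibration-specific choices: the selection thresholds are relaxed
(z-threshold 1.5, at least 3 cases) so the selection count is
non-degenerate — at the canonical thresholds the null count is almost
surely zero, every plug-in p-value is exactly 1, and uniformity is
meaningless rather than violated; and the plug-in convention's discreteness
leaves small ties, so the KS distance hovers at the pure-sampling level
(~0.06 at n = 200) rather than at zero.

## Enrichment

One-sided hypergeometric over-representation of a study gene set against a
detected-gene background: `p_raw = P(X ≥ k)` for X hypergeometric(N, K, n),
via the closed-form tail (verified against exhaustive enumeration in the
tests). Bonferroni multiplies by the number of terms that still annotate at
least one background gene after intersection; results sort by corrected
p-value, then term id. Annotations are used as given — no ontology-graph
propagation (a pre-propagated annotation file is accepted); gene symbols
are canonicalized by upper-casing and whitespace-stripping only. Study
genes absent from the background are an error by default, droppable with a
warning under `lenient`.

## Heatmap normalization and signatures

Heatmap values are per-gene z-scores of log2(FPKM) with zero FPKM floored
at 0.01 before the log. "Adjusted for outliers" is implemented as: detect
outlying entries per gene by the Iglewicz–Hoaglin modified z-score
`M = 0.6745 (x − median)/MAD` with the conventional cutoff 3.5, winsorize
them to the most extreme non-outlying value on their side, then recompute
the per-gene z-scores. This is an interpretation — trimming or fully robust
standardization would also fit the phrase — so a `robust=True` mode (direct
median/MAD standardization) is provided as the alternative. The 0.6745
constant (the 0.75 normal quantile) is fixed. Genes with zero MAD skip the
adjustment; genes with zero variance become zero rows, are excluded from
clustering and placed last. Genes are ordered by average-linkage
hierarchical clustering on Euclidean distance (neither is dictated by the
problem; both are the common heatmap defaults); samples stay in sheet
order, controls left.

Signature overlap intersects up-with-up and down-with-down (`matched`) or
the direction-blind unions (`any`); a Venn-style region count over several
signatures is available. A symbol appearing in both directions of one
signature is an input error.

## Problem sizes and numerics

The test suite and the acceptance script run entirely on simulated data at
desk scale, chosen as the package's own working sizes: oracle equivalence
on 100 random matrices of ≤5 transcripts × ≤6 samples; recovery on ~2000
exons (250 single-transcript genes, dispersion 0.02, fold 8); calibration
as above; the end-to-end alignment pipeline on ~250 exons. Numerical
details: all randomness flows through `numpy.random.default_rng` with
explicit seeds (operations within one simulation derive distinct streams
from the config seed, so the annotation is identical whether or not counts
are drawn); undefined scaled values and z-scores are NaN and never compare
true against thresholds; enrichment ties break on term id; permutation
labelings enumerate in `itertools.combinations` order with the identity
first when controls lead the sheet.

## Known limitations

* Sibling-exon contamination for out-of-range effects, as discussed above.
* The exon-level exclusion rule needs the transcript structure; on
  annotations where exons are pre-merged across transcripts the scan
  operates on merged units instead.
* Paired mates are treated as independent reads; fragment-level counting
  would roughly halve counts and tighten the NB variance.
* Bonferroni is the only multiplicity correction offered here; gene-level
  q-values are consumed from external tools, not computed.
* The heatmap outlier treatment is an interpretation (winsorize +
  restandardize); figures produced with a different robustification will
  differ in the tails.
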