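# Methods

This note documents the model, the conventions and the numerical choices
behind `epidex`, and what the synthetic benchmark does and does not show.

## Segment model

Protein-coding transcripts are decomposed into up to 14 named segment
categories. Coordinates are 0-based half-open internally (BED convention);
1-based coordinates appear only in formatted output.

* **Promoter windows.** TSS200 covers bases [0, 200) upstream of the
  transcription start on the transcript strand; TSS1500 covers (200, 1500]
  — 1300 bases — so the two windows are disjoint, following the Illumina
  450K manifest convention that the methylation features inherit. Windows
  extending past the chromosome start are truncated at 0 with a warning.
  Because their nominal widths are constants, the promoter windows carry no
  length feature, and their nominal widths (200 / 1300) are used as the
  length denominator for read densities even when truncated.
* **Exons and introns.** First and last exon are the 5'- and 3'-most exons
  on the transcript strand and are *removed* from the exon-body category
  (likewise introns); a single-exon transcript gets the `single_exon`
  designation *instead of* any other exon category, and a transcript with
  exactly one intron gets `single_intron` instead of first/last/body
  introns. This keeps the exon-derived (and intron-derived) categories
  pairwise disjoint, which matters for the drop-off designs: no feature
  family would otherwise be partially removed twice.
* **UTRs and CDS.** UTR5/UTR3 are the exonic bases strand-upstream /
  -downstream of the CDS. They deliberately *may overlap* the first/last
  exon segments (a first exon often contains the entire 5'UTR); every
  category's features are computed independently on its own intervals, so a
  CpG probe in the overlap contributes to both.
* **fullTranscript** is the union of exon intervals (equivalently UTRs +
  CDS for a coding transcript).

## Feature catalog

The default catalog enumerates exactly 1424 named features: 14 segments ×
{avgMval, avglogFC, numHyper, numHypo} = 56 methylation aggregates; 14 ×
(4 + 16 + 64) = 1176 k-mer composition fractions; 12 segment lengths; 14 ×
6 histone densities = 84; 14 × 3 histone contrasts = 42; 14 × 3
conservation means = 42; and 12 junction-distance features. Names are
machine-parsable (`segment_measure`, e.g. `first_exon_A4_minus_S4_divavg`),
and the drop-off plans select features by parsing them.

## Per-family conventions

**Methylation.** Per-probe differential methylation uses a paired two-sided
t-test on per-pair M-value differences (an unpaired Welch option exists),
with Benjamini–Hochberg adjustment across probes. A probe is called
hyper-/hypomethylated when adj. p < 0.05 and logFC is positive/negative
(threshold configurable). Probes with fewer than three complete pairs, or a
degenerate zero-variance difference, keep their effect estimates but get no
call. Probe-to-segment assignment uses the single manifest coordinate.
Junction distances are measured in transcript coordinates (introns
excised); the first base 3' of a junction is at distance 0 from that
junction on its 5' side, and symmetrically the last base 5' of a junction is
at distance 0 on its 3' side. Only exonic probes qualify; statistics are
taken over hyper- and hypo-called probes separately and are missing when no
qualifying probe or junction exists.

**Histone.** A read counts toward a segment when it overlaps any of the
segment's intervals by ≥ 1 base, once per segment (bedtools-multicov
semantics). Densities are count / (segment kb) / (library millions).
The cancer-vs-normal contrast (a − s) / ((a + s)/2) is computed on
*normalized densities*, not raw counts, because the two libraries differ in
depth; it is defined as 0 when both densities are 0 so that unmarked
segments stay dense rather than missing.

**Nucleotide.** Composition uses overlapping k-mer windows on the
strand-oriented (5'→3', reverse-complemented on minus strand) segment
sequence; windows containing an ambiguous base are excluded from numerator
and denominator, so fractions always sum to 1 over valid windows.

**Conservation.** The mean is taken over bases the track covers; uncovered
bases are excluded rather than imputed as 0, since phastCons-style files
omit unalignable bases and zero-imputation would bias means downward.

## Expression response

Transcript-level DE results are aggregated per gene: per-condition mean
counts are combined by a geometric mean with a +1/−1 shift applied only
when a zero is present; the gene log2FC is recomputed from the aggregated
condition means (an alternative mode aggregates the per-transcript fold
changes instead); the gene p-value is the minimum raw transcript p,
adjusted across genes by Holm's step-down procedure. Labels use strict
thresholds: *up* iff adj. p < 0.05 and log2FC > 1, *down* iff adj. p < 0.05
and log2FC < −1, everything else excluded from modeling.

## Feature selection

* **Discretization.** CFS and Gain Ratio run on Fayyad–Irani MDL-discretized
  features (recursive entropy-minimizing binary splits accepted while
  gain > (log(N−1) + Δ)/N). Missing values form their own category, so the
  information-theoretic selectors see missingness directly.
* **CFS** uses best-first forward search over subset merit
  k·mean SU(f,class)/√(k + k(k−1)·mean SU(f,f')), stopping after 5
  consecutive non-improving expansions; it is the only selector with an
  intrinsic subset size.
* **Gain Ratio** = information gain / feature entropy; features with zero
  entropy score 0.
* **ReliefF** uses all training instances, k = 10 nearest hits and misses
  under Manhattan distance on range-normalized values, class-prior-weighted
  miss contributions. Missing entries are filled with the feature mean
  before distance computation: the canonical probabilistic diff is defined
  for nominal attributes only, and a *class-conditional* fill (the nearest
  continuous analogue) turned out to fabricate systematically positive
  weights for mostly-missing noise features — the two class fills differ by
  sampling noise while hit-diffs are exactly zero — so the neutral
  unconditional fill is used and missingness is deliberately not treated as
  signal by this selector.
* **Size matching.** The rankers' selections are cut to the CFS subset size
  so the three methods are compared at equal capacity. Ties are broken
  everywhere by catalog order, which makes every selection deterministic.
* Selection runs once on the full training split (the per-fold option is
  exposed). Held-out test metrics are therefore unbiased; pooled CV metrics
  on the training split share the split with selection and can be
  optimistic on null data, which is why the null check below reads the
  held-out estimate.

## Classification and evaluation

The stratified 80/20 split allocates floor(n_class × 0.2) genes per class to
the test set. Classifiers: SVC (RBF and linear, Platt-calibrated
probabilities so all five classifiers score on [0, 1] and share the 0.5
threshold), logistic regression, Gaussian naive Bayes, random forest (100
trees); standardization for the scale-sensitive learners and median
imputation are fitted on each training fold only. Headline metrics are
pooled out-of-fold (AUC by rank statistic with ties at 1/2, F for the
positive class *up*, MCC defined 0 on degenerate marginals); fold-level
metrics are retained alongside. Selected-feature analyses: average-linkage
hierarchical clustering on 1 − |Pearson r| (pairwise-complete, zero-variance
features excluded) and a top-15 ranking by absolute point-biserial
correlation with the ±1 class encoding.

## Drop-off designs

The data-type design removes one family at a time from the full catalog
(nucleotide = composition + lengths, 1188 features; histone = densities +
contrasts, 126; methylation = aggregates + junction, 68; plus the combined
nucleotide+histone removal); conservation is never dropped. The segment
design operates on the methylation-only sub-model and removes features
sequentially: first exon + first intron, then all gene-body segments
(including UTRs, CDS, fullTranscript aggregates and the exon-defined
junction features), then TSS1500, leaving the four TSS200 aggregates.
Selection and classification are re-run per condition.

## Synthetic benchmark

The generator emulates the study's input stack end to end: random-sequence
chromosomes; genes of 1–10 exons (~10% single-exon) with CDS and UTRs;
Poisson-placed CpG probes (expected 2 in TSS200, 3 in TSS1500, 3/kb over
the gene body); M-values with probe baseline N(0, 2), per-pair effects
N(0, 0.3) and within-sample noise N(0, 0.5); six read libraries of 100k
fixed-length reads (70% placed over promoter/body regions with
mark-specific base rates, 30% uniform background); blockwise conservation
tracks with 10% coverage gaps; and a DE table whose planted genes carry
|log2FC| = 1.2 + Exp(0.6) and p ∈ 10^−U(6,10) (small enough to survive Holm
at the default gene count), alongside non-DE background genes.

Planted associations: every gene's promoter receives a random
cancer-vs-normal methylation change N(0, 0.5), with the systematic
+δ (default 1.0 M-units) added for down-regulated genes — so at δ = 0 the
two classes are exchangeable by construction; up-regulated genes receive
promoter H3K4me3 (fold 3.0) and gene-body H3K36me3 (fold 2.0) enrichment in
the cancer line, on top of a shared per-gene lognormal activity (sd 0.4).
The default sizes (2000 labeled genes, 20 pairs) keep the full pipeline in
the minutes range on one CPU while leaving the planted single-feature
separation at Φ(δ/(σ√2)) ≈ 0.92 AUC — strong but not degenerate. The
optional interaction mode draws two balanced binary states per gene whose
XOR equals the label and lets each state drive one histone mark, removing
all marginal signal; it exercises the advantage of non-linear classifiers.

What the benchmark does **not** emulate: co-methylation block structure,
copy-number or batch confounding, realistic k-mer composition or
CpG-island placement, read-length/fragment-size distributions, or
cell-line-vs-tissue heterogeneity. Passing tests therefore demonstrate
that the extraction, selection and evaluation machinery recovers planted
effects of realistic magnitude and stays at chance without them — not that
any particular real-data accuracy would be attained.

## Verified behavior (computed by the test suite)

* Catalog structure: exactly 1424 features with the stated per-family
  counts.
* Closed-form oracles: shifted geometric mean, Holm adjustment, density
  normalization, difference/average contrast and confusion-matrix metrics
  against hand arithmetic; interval counts, junction distances and
  conservation means against exhaustive brute-force scans.
* Selector oracles: SU/Gain Ratio against plug-in entropy arithmetic; CFS
  selects a planted perfect predictor and rejects its duplicate; ReliefF
  ranks a planted XOR pair above univariate noise.
* End-to-end: at default effect sizes the ReliefF + random-forest pipeline
  reaches held-out AUC ≥ 0.80 (observed ≈ 0.99); at zero effect both the
  held-out and pooled-CV AUC stay within [0.45, 0.55]. Removing the planted
  methylation+histone families degrades held-out AUC monotonically across
  effect scales 0.25/0.5/1.0 (the drop-off acceptance check runs at 800
  genes / 10 pairs), while removing the never-planted
  nucleotide+conservation families changes the training-CV AUC by less
  than its fold-level standard error.

## Known limitations

* The per-probe test is an ordinary paired t-test, not a moderated
  (shrinkage) statistic; with few pairs its calls are noisier than
  limma-style calls on real arrays.
* CFS subset sizes on strongly separable synthetic data are small (~10),
  so size-matched comparisons exercise fewer features than a weaker-signal
  real-data setting would.
* ReliefF is O(n²·p); at the default scale this is seconds, but much larger
  gene universes would need the `m_samples` subsampling parameter.
* The generator plants only the documented effect directions; it does not
  model promoter hypomethylation of up-regulated genes or repressive
  H3K27me3 dynamics (H3K27me3 libraries are generated but carry no planted
  association).
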