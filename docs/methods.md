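# Methods

This note records the models, conventions and numerical choices behind
`domainscape`, and what the synthetic-data validation does and does not
establish about real genomes.

## Coordinates and formats

All internal coordinates are 0-based half-open. Converters sit at the
file boundaries: RepeatMasker `.out` and GFF3 are 1-based inclusive,
BED and bedGraph already 0-based half-open. A single internal
convention eliminates off-by-one drift between the interval-algebra
modules.

## Repeat ledger

Repeat fragments are merged per sequence with a boundary sweep. Bases
covered by fragments of one canonical class keep that class; bases
covered by two or more distinct classes become "Overlapping". Only the
overlap bases are reclassified — the non-overlapping flanks of a
partially overlapping fragment keep their class — because this variant
conserves class-specific bp; reclassifying whole merged intervals
would move flank bases into "Overlapping" and make per-class densities
depend on fragment geometry. Three-or-more-way overlaps generalize the
pairwise rule by base-level voting: any base under ≥2 distinct classes
is Overlapping. Abutting same-class segments are coalesced.

Density reports use merged (non-redundant) bp; top-repeat tables use
unmerged cumulative fragment sizes and row counts, because that is the
arithmetic of the usual "10 most common transposons" tables, whose
"% of all repeats" denominator is the sum over all fragments. Both
conventions are labelled in the output. Rows flagged `*` by the
annotator (overridden by a higher-scoring match) are kept and marked;
dropping them is a caller-side filter. Score cutoffs for cross-genome
match filtering (e.g. endosymbiont-vs-host forensics) are always
user-supplied per comparison; the package ships no magic score.

## Gene architecture

Only CDS features are consumed; a transcript is its ordered coding
exons and the coding span runs from start to stop codon, introns
included. Per gene, the most comprehensive isoform — largest total
coding-exon size, ties broken by lexicographically smallest isoform id
— represents the gene, which avoids double-counting alternative
splicing. Introns are only the gaps between coding exons. Intronless
genes have an undefined median intron size and are excluded from
intron-size distributions (but kept in all other tables). Metric
tables carry log10(x+1) companions for plotting-scale comparisons.
Region partitioning resolves overlap as coding > intronic >
intergenic, so the three sets always partition the region exactly.

## Codon bias

Nc follows Wright: family homozygosity F = Σp² in proportions mode or
the finite-sample estimator (nΣp² − 1)/(n − 1), averaged within
degeneracy classes (9 twofold, Ile as the single threefold, 5
fourfold, Leu/Ser/Arg as whole sixfold families; Met and Trp
contribute the constant 2). Keeping sixfold families whole is the
convention under which the printed bounds are exact:
20 = 2+9+1+5+3 and 61 = 2+18+3+20+18. Families that are absent — or
unusable in finite-sample mode (n < 2 or a non-positive estimate) —
are imputed by the mean F of their observed class, or by 1/k when the
whole class is missing, per Wright's recommendation. Note that the
plug-in Σp̂² is biased upward at finite n, so proportions-mode Nc of a
*sampled* unbiased gene sits noticeably below 61 (≈59.5 at ~170 codons
per family); the finite-sample estimator corrects exactly this and is
the default for real genes, while the proportions mode reproduces the
exact 61/20 bounds on constructed equal-count inputs.

CAI uses w = count/max within each family from a reference count
table, zero-count reference codons floored at w = 0.01 (common
practice; avoids log 0), reference-absent families treated as neutral
(w = 1). The equal-usage threshold is the codon-weighted geometric
mean of the weights (each included sense codon once); an
amino-acid-weighted variant exists and the choice is configurable —
reference sets differ enough between studies that neither convention
is privileged. Codons containing N are excluded from every statistic
and counted separately.

GC partitions are computed over non-stop codons; 4D-site GC uses the
third positions of Ala/Gly/Pro/Thr/Val only, where every substitution
is synonymous.

## Profiles and metagenes

Window Tm uses nearest-neighbor thermodynamics,
Tm(°C) = ΔH/(ΔS + R ln(Cₜ/4)) − 273.15 + 16.6·log₁₀[Na⁺], with the
Breslauer 1986 stack parameters and duplex-initiation terms; defaults
are a 9-bp window, step 1, 50 nM total strand and 50 mM Na⁺. The table
is pluggable (Sugimoto, SantaLucia). Values match
`Bio.SeqUtils.MeltingTemp.Tm_NN` to numerical precision; the rolling
reimplementation exists because per-window calls are impractically
slow at megabase scale. Windows containing N are missing. Absolute Tm
values from different parameter sets differ by several °C, so all
profile comparisons here are within-run contrasts, never absolute
temperature claims.

Enrichment tracks are the signed Poisson log₁₀ likelihood ratio of two
pileups with symmetric pseudocount (default 1e-5): the observation is
the larger of the two values, the sign records which track is larger.
This is the peak-caller logLR convention; it is antisymmetric under
swapping treatment and control and reduces to
(x ln(x/y) − x + y)/ln 10 wherever treatment exceeds control.

Metagenes rescale each coding span to 3 kb by linear interpolation
(endpoints preserved; missing values propagate, never interpolated
across) and attach 2-kb flanks in transcript orientation. Aggregation
is the per-position median, missing values excluded position-wise,
with the contributing-gene count recorded. Bin-averaging was rejected
for span rescaling because it does not preserve endpoints.

Smoothing uses a natural cubic smoothing spline in Reinsch's banded
form. The penalty λ is selected by exact leave-one-out ordinary
cross-validation over a log-spaced grid (14 points spanning 13 decades,
scaled by the cube of the mean point spacing); the LOO residuals use
the exact hat diagonal, obtained in O(n) from a selected (Takahashi)
inversion of the pentadiagonal system, so cross-validating a 7001-point
metagene costs well under a second. Profiles with fewer than 10
defined points pass through unsmoothed with a warning.

LOESS (for the Nc-vs-CAI trend) is degree-1 local regression with
tricube weights and four bisquare robustness iterations; the span is
chosen by generalized cross-validation, n·RSS/(n − tr S)², with the
smoother trace from the closed-form local-linear self-influence. The
span is selected on the initial non-robust pass and the robust
iterations run at the chosen span — selecting under robustness
iterations would make the criterion depend on the very outliers the
iterations are meant to discount.

## Statistics

Kruskal–Wallis uses the tie-corrected H with a chi-square reference.
Dunn z uses pooled midranks with the tie-corrected variance; pairwise
p-values are two-sided normal. Holm step-down controls the family-wise
error rate and its rejections form a prefix of the p-ordered pairs by
construction. The post hoc stage runs only when the omnibus test
rejects at α (default 0.05), a gatekeeping workflow; a flag overrides
it. The hypergeometric enrichment is one-tailed (upper) and exact —
integer combinatorics up to N = 1000, log-gamma beyond. All other
tests are two-sided. Spearman uses midranks and the t approximation;
constant input returns an explicit "undefined" status, not NaN.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with exact bookkeeping:

- Background sequence is i.i.d. at a configured GC (default 0.40) —
  no higher-order Markov structure, which no consumer here needs.
- Transposon copies are planted with uniform 5′/3′ truncation (a
  U(0.2, 1) surviving fraction of the consensus) until per-class
  visible-bp targets are met; defaults 40% LTR + 20% LINE + 5% DNA
  mirror a strongly repeat-dense domain against which a sparse
  reference is contrasted. With nesting enabled, a later insertion
  occludes the bases it covers and the annotation writer emits the
  *visible* pieces of each fragment — what an annotator of the final
  sequence could see — so planted density truth is exact and the
  ±0.02 recovery tolerance is honest headroom, not slack in the
  bookkeeping. Scores are fragment length × a U(2.0, 3.5) quality
  factor, with optional fixed-score decoy matches for cutoff tests.
- Genes are placed in repeat-free windows; intron sizes come from a
  two-component log-normal mixture (medians ≈65 bp and ≈3.5 kb,
  60% short), the short/long bimodality characteristic of Drosophila
  gene models. CDS sequence is sampled codon-wise: by explicit
  frequency vector, by GC3 target (wobble-position choice, the
  mutational-bias regime), or shifted toward reference-optimal codons
  (the selection regime).
- Signals are step functions (10-bp bins, as pileups are): background
  1.0 with Gaussian noise (σ 0.3), plus a promoter Gaussian peak
  (height 8, σ 150 bp) at each 5′ CDS end for the "active" mark and a
  uniform +3.0 over each coding span for the "silencing" mark.
- Ortholog pairs copy species A's exon structure into species B and
  inflate a configured fraction of the *long-component* introns by a
  configured factor (default 8.6), so total CDS differences are zero
  by construction and the intron-inflation truth is recorded per gene.

Everything is a pure function of (config, seed); identical seeds give
byte-identical files.

**What passing tests show — and don't.** Recovery of planted densities,
GC3 targets, bimodality, metagene shapes and enrichment directions
validates the *bookkeeping and statistics* of the pipeline under known
truth. It does not validate repeat annotation itself (no aligner is
run), divergence structure, isochores, alternative splicing, or any
biological effect size: synthetic effect magnitudes are configuration,
not findings.

## Problem sizes

Tests and examples run regions of 40–300 kb with 4–15 genes and codon
sets of ~20–60 genes at 900–3000 codons; the pipeline default
configuration targets 1 Mb per region with 60 genes, which the full
run completes in well under a minute on one core. These sizes give the
rank tests and recovery checks comfortable power while keeping the
whole suite interactive.

## Known limitations

- Only the standard genetic code is wired into the codon machinery.
- The Tm parameter set of the historical profile tools is not
  published alongside them; our Breslauer default is declared, not
  matched to any specific tool's output, and Tm comparisons should be
  read as contrasts.
- Foreign-genome match attribution consumes match intervals; it does
  not run or emulate the underlying homology search, and score-cutoff
  selection procedures are out of scope.
- Expression values are consumed as a precomputed matrix (e.g.
  variance-stabilized counts); no expression modeling is performed.
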