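# Methods

This note documents the models, rules and numerical choices behind
lncflow, and what the synthetic study does and does not establish.

## Coordinates and geometry

All intervals are 0-based half-open internally; GTF (1-based inclusive)
is converted at the I/O boundary.  Every positional decision — overlap,
gap distance, the six-way classification, the cis window — operates on
transcript *spans* (first exon start to last exon end), not exon unions:
the classification scheme is defined pictorially on whole-transcript
boxes, and span semantics keep intron-containing overlaps classified the
way those pictures read.  An exon-union mode is deliberately not offered.
Book-ended intervals share no bases, so they count as non-overlapping
(gap 0): "overlap" always means shared bases.

## Discovery cascade

Steps run in a fixed order (dedup → length → coverage → known-gene
overlap → known-lncRNA identity → coding potential) and each rejected
transcript is attributed to the *first* violated step, which makes drop
counts additive and planted-violation attribution testable.  Boundary
semantics follow the printed inequalities literally: length exactly
200 bp is kept ("shorter than 200" removed), coverage exactly 3 kept,
identity exactly 90% kept (strictly greater removed), coding-potential
score exactly 0 removed (strictly negative kept).  Survivors equal the
intersection of per-step pass sets, so the cascade is order-invariant
for the surviving set and monotone in every threshold.

Coding-potential scores, domain hits, coverage and identity are consumed
as an evidence table; recomputing them (CPC-style classifiers, profile
HMM scans, alignments) is outside scope, which isolates the decision
logic from third-party scorers.  "Read coverage" is treated as an opaque
non-negative real compared against 3, since assembler coverage
attributes and mean per-base depth are interchangeable for the rule.

ORFs are sought on the sense strand only (strand-specific libraries
yield oriented transcripts), ATG-initiated and in-frame stop-terminated,
length including the stop codon.

## Classification

The partner of an lncRNA is the gene with maximal span overlap, else the
nearest gene within a window defaulting to the 100-kb cis window; ties
break to the smaller start coordinate then lexicographic id, making the
assignment deterministic.  The partner-selection rule when several genes
overlap or flank is this package's choice — the six-class scheme itself
does not dictate one.

Genic subtypes are purely geometric: containment is non-strict, and
exact span equality classifies as *containing* (the tie against *nested*
is resolved deterministically; both readings are defensible, one had to
be picked).  Strand is ignored for genic subtypes — an antisense overlap
is still overlapping/containing/nested.  For intergenic pairs, with the
left/right order taken from genomic position, left `+` with right `-`
transcribe toward each other (*convergent*), left `-` with right `+`
away from each other (*divergent*), equal strands are *same_strand*.

## Expression and differential expression

RPKM(A) = 10⁹·C/(N·L) with N the per-sample column sum — the total count
assigned to annotated features, not raw sequenced reads.  "Expressed in
a tissue" means mean replicate RPKM ≥ 1 (inclusive); the mean is the
default aggregation because it is robust to a single noisy replicate,
with a max-rule flag for sensitivity analyses.

The DE screen — fold change ≥ 2 and BH Q ≤ 0.01 — is the contract; the
p-value generator is pluggable.  The default `pooled_z` statistic pools
replicate counts per tissue and tests the binomial split of the pooled
total against the library-size expectation with a normal approximation;
`binomial_exact` replaces the approximation with an exact binomial test.
This is the classic MA-plot-style test for count data: it models
counting (Poisson-level) noise and is well calibrated in that regime,
but is anti-conservative under strong biological overdispersion — the
known trade-off of pooled-sample tests, accepted here because the screen
itself (FC and Q thresholds) is the reproduced object.  Dispersion-aware
models (negative-binomial GLMs with shrinkage) are intentionally not
re-implemented.  Fold changes are computed on counts-per-million with a
pseudo-count of 1 CPM, so zero counts yield finite, shrunk log-ratios;
note that per-million normalization is compositional: a large change in
one feature slightly shifts the apparent ratio of flat features.

Hierarchical clustering for heatmap ordering defaults to average linkage
on 1 − Pearson distance across samples; a constant row has no defined
correlation and is assigned distance 1 to everything (including another
constant row), which parks such rows at the periphery instead of
crashing.

## Cis targets and enrichment

Correlation is computed across all nine samples rather than three tissue
means: n = 3 gives essentially no power at p < 0.01, and replicate-level
correlation is what a co-expression screen sees in practice.  Both
correlation signs are accepted by default (repression by a nearby lncRNA
is as plausible as activation); a positive-only flag exists.  The window
is measured between spans (gap distance), not TSS anchors.

The hypergeometric tail is evaluated with exact integer binomial
coefficients for backgrounds up to 500 genes — the sum is then exact to
the last floating-point digit — and with the log-space survival function
beyond that.  No ontology-graph propagation and no length-bias
correction are applied; the statistic is the plain tail sum.

## ceRNA rule

A candidate triplet needs one miRNA with predicted sites on both the
lncRNA and the mRNA (tables from multiple predictors are unioned by
default; an intersection mode exists for conservative site support).
Acceptance requires at least one contrast where the lncRNA is DE, the
mRNA sign matches and the miRNA sign is opposite; a strict mode requires
every lncRNA-DE contrast to qualify.  Requiring the lncRNA itself to be
DE in the qualifying contrast is a documented choice — the sponging
signature is read from the lncRNA outward.  The rule depends only on
relative signs, so globally flipping all trends leaves the accepted set
unchanged.

## Synthetic study

The generator plants every structure the pipeline is supposed to find,
each in an isolated 250-kb genomic slot so that proximity-based stages
cannot couple unrelated plants (features occupy ≤ 80 kb of a slot,
hence > 100 kb separates features of adjacent slots).  Defaults: 3
chromosomes × 15 Mb; 3 tissues × 3 replicates; 60 class-planted lncRNAs
(10 per class) each with its partner gene; 30 standalone coding genes
(20 planted DE); 20 known lncRNAs (6 tissue-specific, 4 below the RPKM
threshold); 8 cis pairs placed ~40 kb apart sharing a tissue-weight
profile; 6 ceRNA triplets plus 6 concordant-trend decoy triplets; one
cascade decoy per step per 20 planted novels (5% per step).  Library
size 2 × 10⁶ expected counts per sample spread over ~230 features keeps
per-feature counts in the thousands, the regime of well-covered
transcripts.

Counts are negative binomial, variance μ + αμ² with dispersion α = 0.1
(a typical bulk RNA-seq biological-replicate value); α = 0 degenerates
to Poisson, and `exact_counts` replaces sampling with rounded means —
the zero-noise limit in which cis and ceRNA recovery are exact by
construction and used as such in the recovery tests.  Planted effects
are mean ratios of 2^de_log2fc (default 4-fold).  Planted trend truth
marks a contrast ± only where the planted mean ratio itself reaches the
fold-change threshold.  miRNA expression is simulated directly as a
small separate matrix; no claim is made about how real miRNA
quantification behaves.

What the synthetic study does **not** emulate: sequence homology (the
identity column is planted, not aligned), overlapping gene models and
ambiguous multi-partner neighborhoods, read-level artifacts, GC/length
bias, and correlated library-size effects.  Passing tests therefore
demonstrate the correctness of the decision logic under its stated
model, not performance on real tomato libraries.

## Problem sizes and determinism

The test suite and the acceptance script run the default study
(~230 features), a 500-decoy cascade study, a 2,000-feature null and
power simulation for the DE screen, 1,000 random geometries for the
classifier oracle, and exhaustive hypergeometric enumeration to N = 12 —
sizes chosen so every property is measured in seconds while keeping
planted-structure counts large enough to be meaningful.  All randomness
flows from a single integer seed through one `numpy` generator per
study; placements are integer arithmetic, outputs are sorted before
writing, and the run manifest contains no timestamps, so a seed pins
every output byte.

## Known limitations

* The pooled-count DE statistic ignores biological overdispersion (see
  above); its type-I calibration statement applies at counting-noise
  level.
* Single-transcript genes throughout the simulation; isoform-level
  partner choice is untested against real multi-isoform loci.
* The hypergeometric test treats genes as exchangeable — no annotation
  length bias correction.
* The ceRNA rule is sign-based; it does not weigh binding-site counts,
  site accessibility or expression magnitude.
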