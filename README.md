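# lncflow

Downstream analysis of long non-coding RNAs (lncRNAs) from multi-tissue
bulk RNA-seq, packaged as a tested, reusable pipeline.  It covers the
standard post-assembly stages of a plant lncRNA profiling study — here
shaped after a three-tissue (flower / leaf / root), three-replicate
design — without touching reads or assembly: transcript models,
coding-evidence scores and miRNA-target tables are consumed as inputs.

Intended users are bioinformaticians who have assembled transcripts (GTF)
and a count matrix in hand and want the downstream decision logic —
filtering, classification, screening, network construction — as
composable, unit-tested functions rather than a one-off script.

## What it computes

**Novel-lncRNA filter cascade.** Assembled transcripts survive, in order:
deduplication; length ≥ 200 bp; read coverage ≥ 3; no overlap with known
coding genes and ≤ 90% identity to known lncRNAs; coding-potential score
< 0 with no protein-domain hit.  Each failure is attributed to the first
violated step.

**Positional classification.** Each lncRNA is paired with a partner gene
(maximal span overlap, else nearest gene within 100 kb) and assigned one
of six classes: genic *overlapping* / *containing* / *nested* (by span
containment) or intergenic *same_strand* / *convergent* / *divergent*
(by strand and transcription direction relative to the gap).

**Quantification and screening.** RPKM(A) = 10⁹·C / (N·L) for C reads on
feature A, N total assigned reads in the sample and L the feature length;
features with mean tissue RPKM < 1 are dropped; per-tissue presence sets
yield Venn partitions and tissue-specific lists.  Differential expression
between tissue pairs uses a pooled library-size-normalized two-sided
z-test (exact binomial variant available) and calls a feature DE when
fold change ≥ 2 and BH-adjusted Q ≤ 0.01.

**Cis targets and enrichment.** A gene is a cis-target candidate of a DE
lncRNA when it overlaps the lncRNA span or lies within 100 kb and their
expression correlates (Pearson, two-sided p < 0.01).  Term enrichment of
target genes uses the exact hypergeometric upper tail
P = 1 − Σᵢ₌₀^{m−1} C(M,i)·C(N−M,n−i)/C(N,n) with BH Q-values.

**ceRNA network.** An (lncRNA, miRNA, mRNA) triplet with a shared miRNA
response element on both targets is accepted when, in at least one
contrast, the lncRNA is DE, the mRNA trends with it and the miRNA trends
against it — the expression signature of miRNA sponging.  The accepted
network is exported as SIF plus node attributes for network viewers.

A synthetic-study generator (`lncflow.simulate`) produces a complete toy
study — genome, annotation, sequences, negative-binomial counts, evidence
table, miRNA targets and expression — with planted, recoverable ground
truth for every stage, and is the substrate of the test suite.

## Worked example

```bash
lncflow run --outdir demo --seed 1
```

```
pipeline complete; manifest at demo/manifest.json
  simulate: {'transcripts': 230, 'expression_features': 230, 'mirnas': 16}
  discover: {'assembled': 100, 'after_dedup': 100, 'novel_lncRNA': 80,
             'dropped': {'coding_potential': 4, 'coverage': 4,
             'known_lnc_similarity': 4, 'known_overlap': 4, 'length': 4}}
  classify: {'lncRNAs': 100, 'classified': 68}
  quantify: {'features': 230, 'expressed_per_tissue': {'flower': 222,
             'leaf': 222, 'root': 222}, 'expressed_lncRNA': 96}
  de: {'tested': 226, 'significant': 157, 'mirna_significant': 27}
  cis: {'de_lncRNA': 30, 'de_genes': 42, 'cis_pairs': 5}
  enrich: {'terms': 13, 'target_genes': 5}
  cerna: {'candidate_triplets': 12, 'accepted_triplets': 6,
          'mirnas': 6, 'lncRNAs': 6, 'mRNAs': 6}
```

Reading the run: of 100 assembled transcripts, the cascade keeps 80 as
novel lncRNAs and attributes each of the 20 removals to one step (4 per
step here).  All 60 lncRNAs planted with a positional class plus the 8
cis-pair lncRNAs get a partner within 100 kb (68 classified).  The DE
screen then feeds 30 DE lncRNAs × 42 DE genes into cis-target
prediction, which keeps 5 proximal correlated pairs under the default
noise level.  The ceRNA stage accepts exactly the 6 planted sponge-like
triplets out of 12 shared-miRNA candidates, rejecting the 6 decoys whose
miRNA trends with its targets.  The top enrichment line shows the term
planted on the cis-target genes:

```
term_id    term_name                   M  m  P          q
TERM:CIS   planted cis-target process  8  5  4.58e-07   5.95e-06
```

Each stage writes a plain TSV (`discovery.tsv`, `classification.tsv`,
`rpkm.tsv`, `de.tsv`, `cis_targets.tsv`, `enrichment.tsv`,
`cerna_triplets.tsv`) plus `network.sif` / `network_nodes.tsv`, and
`manifest.json` records the config hash, seed and per-stage row counts.
Every stage is also available standalone (`lncflow discover|classify|
quantify|de|cis|enrich|cerna`) on externally produced files, and as
plain library functions.

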