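# Methods

`orthotx` implements a cross-species transcriptome comparison pipeline of
the kind used to contrast a long-lived focal mammal (e.g. the bowhead
whale) against a panel of related species: representative coding-sequence
selection, 1:1 ortholog identification by reciprocal best hit, detection
of focal-lineage-unique amino-acid class changes, and thresholded
differential expression. Every stage is driven and verified by a seeded
synthetic-data generator that plants recoverable ground truth.

## Reference-ORF selection

For each gene the *longest transcript* (by nucleotide length) is kept;
within it the longest complete ORF — ATG through an in-frame stop with no
internal stops — becomes the gene's reference coding sequence. The choice
of transcript by transcript length rather than ORF length is deliberate:
it reproduces the convention of keeping one representative isoform before
ORF extraction, and the test suite pins a case where a shorter transcript
holds a longer ORF.

ORF discovery scans all six frames (de novo assembled transcripts have
unknown orientation) and reports every ATG paired with its next in-frame
stop, nested starts included. A codon containing N is treated as
untranslatable: it can be neither start nor stop, and no reported ORF may
span it. Coordinates are 0-based half-open on the reported strand
(minus-strand coordinates index the reverse complement); human-facing
tables are 1-based.

Ties are totally ordered for reproducibility: equal transcript lengths
fall back to the lexicographically smaller transcript id; equal ORF
lengths to the smaller start coordinate, `+` strand before `-`. Only ATG
is accepted as a start, under the standard genetic code; the minimum
protein length defaults to 100 aa and is configurable (the threshold is a
package default, not an inherited convention).

A gene whose chosen transcript holds no qualifying ORF yields a rejection
*value* carrying the reason, never an exception, so batch runs report
rather than abort.

## Ortholog pairs, sets, and refinement

An **ortholog pair** links a reference gene to one species' transcript
when each is the other's single best-scoring match (reciprocal/
bidirectional best hit). An **ortholog set** is declared when a pair
exists in every species of the panel; incomplete sets are retained for
reporting but excluded downstream.

Similarity can come from either of two sources behind the same decision
rules:

* a **built-in deterministic scorer**: semi-global (free end-gap) affine
  dynamic-programming alignment — BLOSUM62 with gap open −11 / extend −1
  for protein, +2/−3 match/mismatch with −5/−2 gaps for nucleotide. Free
  end gaps matter because transcripts carry UTRs around the homologous
  core. Identity is matches over all alignment columns; query coverage is
  the fraction of query residues aligned to subject residues.
* **ingested 12-column tabular search output** (qseqid … bitscore), where
  "best" is by descending bit score.

Best-hit ties break to the lexicographically smaller subject id — any
total order works; this one is stable under input permutation.

Declared sets pass two refinement filters, both pinned by boundary tests:

1. **start/stop**: at least 80% of member sequences must carry both a
   start and a stop codon (the 80% boundary is inclusive);
2. **length window**: every member's coding length (nucleotides) must lie
   within ±50% of the set's median length, bounds inclusive; the median
   of an even member count is the mean of the two central values.

Members are extracted from transcripts by the longest coding candidate:
complete ORFs compete with open-ended readings (ATG to frame end without
a stop; frame start to first stop without an ATG), so corrupted
transcripts still contribute a member carrying honest `has_start`/
`has_stop` flags — this is what makes the start/stop filter exercisable.

Peptides are annotated against a reference proteome by the best hit with
E-value ≤ 1e−5 (when present), identity strictly > 50% and query coverage
strictly > 75%; anything else is unassigned. The strict inequalities are
intentional and tested at the boundary.

## Lineage-unique residue scanning

The 20 standard amino acids are partitioned into four chemical classes:
acidic (E, D), basic (K, H, R), cysteine (C), and "other" (the remaining
14). A column of a cross-species protein alignment is **called** when

* the focal species holds a standard residue there,
* at least `min_informative_others` non-focal residues are informative
  (not gap, not X; default floor 30, sized for a ~68-species panel),
* no informative non-focal residue shares the focal residue's class, and
* the designated reference species is ungapped at the column (calls are
  reported in 1-based coordinates of the reference protein's ungapped
  sequence).

Gaps and X among non-focal species are ignored rather than disqualifying
the column (configurable): heterogeneous multi-genome panels are never
gap-free, and a hard disqualification would silently discard most of the
alignment. A gap or X in the focal row skips the column.

Calls carry a compact change string — distinct non-focal residues, the
reference position, the focal residue, e.g. `STQ174R`. The residue prefix
is ordered by descending frequency among informative others, ties
alphabetical. This ordering is a package convention chosen for
determinism; published tables of this kind do not document their
ordering, and the parser accepts any order.

A neutral false-positive simulation evolves independent columns along a
phylogeny with unrestricted residue replacement (no planted cross-group
events) and reports the scanner's chance-call count and rate with a 95%
Jeffreys binomial interval. It characterizes this scanner on synthetic
panels only; it is not an estimate of any empirical panel's rate.

## Differential expression

Counts are normalized by **trimmed mean of M-values (TMM)**: the
reference sample is the one whose upper quartile of library-scaled counts
is closest to the mean upper quartile; per sample, genes zero in either
the sample or the reference are dropped, M (log2 ratio of proportions)
and A (average log2 abundance) are computed, the central 40% by M-rank
and 90% by A-rank are retained (30%/5% two-sided trims, the algorithm's
standard defaults), and the factor is 2 to the precision-weighted mean of
retained M with inverse binomial-variance weights, all factors rescaled
to geometric mean 1. The implementation was written from the algorithm's
definition; the test oracle is an independent direct-formula
recomputation (agreement < 1e−9).

Expression is log-CPM on effective library sizes,
`log2((count + 0.5) / (libsize·factor + 1) × 1e6)` — the conventional
pseudocounts, stated because nothing upstream fixes them.

The focal-vs-rest contrast is a two-sample t on log-CPM. With moderation
(default), the pooled per-gene variance s² is shrunk toward a prior:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), with prior df d₀ = 4 and s₀² estimated as
the mean per-gene variance unless supplied; t then has d₀ + d degrees of
freedom. `moderation="none"` is the ordinary pooled t and refuses
zero-variance genes. Raw p-values are Benjamini–Hochberg step-up
adjusted.

A gene is **flagged** only when it clears all three thresholds:
|log2FC| ≥ 2, BH-adjusted P ≤ 0.05, and B ≥ 2.945. B is the log posterior
odds that the gene is differentially expressed; 2.945 = ⌈ln 19⌉₃ is the
smallest three-decimal log-odds corresponding to ≥ 95% posterior
probability, and the package computes this transform rather than
hard-coding it. The exact empirical-Bayes B of hierarchical linear-model
pipelines is out of scope; when no B column is supplied an
**approximate-B** is computed as the log posterior odds under a
two-component mixture on the moderated t — null t(df) versus a scaled
alternative t(df)/c — with prior DE proportion 0.01 and scale c = 5.
These hyperparameters control how conservative the third threshold is on
synthetic data; published B values can always be supplied as an input
column instead, and the decision rule is identical either way.

Note that re-running the full BH adjustment on already-adjusted values is
*not* an identity (the m/rank inflation applies again); what is invariant
is the step-up stage itself — adjusted values are rank-monotone and ≤ 1.
The tests pin exactly that.

Term enrichment of a flagged list against a background universe reports
fold enrichment, (list frequency)/(background frequency), and a one-sided
Fisher's exact p per term; zero-overlap terms report fold 0 and p 1. The
term map is a flat term → gene-set mapping; no ontology-graph handling.

## Synthetic-data generator

The generator's role is verification: it makes no evolutionary-realism
claim (no codon models, no dN/dS, no indels, no read-level simulation).

* **CDS evolution**: nucleotide substitutions are proposed uniformly
  along each branch, with the per-branch event count
  Poisson(branch length × rate × sequence length); with frame
  preservation on, proposals that would create an internal stop or
  destroy the start/stop codon are rejected. Proposal-level rejection is
  the simplest process that maintains the codon invariants exactly, which
  is what downstream filters consume.
* **Random streams** are derived by stable hashing of (seed, gene, node),
  so generators are pure functions of (inputs, seed) and adding a gene
  never perturbs the others' sequences.
* **Planted substitutions**: a column is given a focal residue from a
  requested class absent from all other species (homogenizing the column
  to a single non-target class first when necessary, recorded in the
  truth record). Within-group-only protein evolution provides the
  guaranteed-negative background: every replacement stays inside the
  residue's class, so no column can acquire a unique class by chance.
* **Transcripts** wrap each CDS in uniform-random UTRs of 20–150 nt
  (long enough to exercise ORF search without dominating runtime) and
  apply per-transcript corruptions: start-codon loss (ATG→GTG), stop
  loss (stop→sense, with the 3′ UTR continued stop-free in frame so the
  loss is real), or truncation to a fraction of the CDS (the transcript
  then ends mid-CDS, with no 3′ UTR, like a fragmented assembly).
  Uncorrupted transcripts are guaranteed by redraw to return their
  embedded CDS under the longest-candidate rule.
* **Counts** are negative-binomial with variance μ + φμ². Baseline
  relative abundances are log-normal (σ = 1.5), drawn once per run;
  focal samples multiply planted genes' abundance by 2^effect, and
  abundances are renormalized per sample so the expected column sum
  equals the library size. The renormalization is deliberate: planted
  effects then induce exactly the composition bias TMM exists to
  correct, so the power checks exercise the normalizer honestly.

## Problem sizes and defaults used in verification

The shipped checks run at desk scale, chosen so the whole suite verifies
the logic rather than the throughput: 1,000 random 68-species columns for
the scanner-vs-oracle identity; 50 substitutions planted across 20
twelve-species alignments of 150 residues; 20×20 toy proteomes for the
reciprocal-best-hit enumeration; a 50-gene fixture for TMM and 1,000
random vectors for BH; and 100 simulation seeds of a 200-gene, 4-vs-4
count matrix (library size 3×10⁵, dispersion 0.01, ten genes planted at
|log2FC| = 5) for the power and null checks.

## What passing tests do and do not show

Synthetic panels are gapless unless corrupted, substitution processes are
site-independent and homogeneous, and planted effects are large and
clean. Passing therefore demonstrates that the decision rules — filters,
mutual-best logic, class-uniqueness detection, thresholds — are
implemented exactly, and that the pipeline recovers planted truth with
full sensitivity under its stated conditions. It does not demonstrate
robustness to alignment error, paralogy, assembly artifacts, or count
overdispersion beyond the NB model, none of which the generator emulates.

## Known limitations

* The built-in scorer is exhaustive dynamic programming: right for
  desk-scale verification, not a substitute for a heuristic search engine
  at proteome scale (use the tabular-ingest path there).
* Strictly 1:1 orthology; no paralogy or synteny reasoning.
* Approximate-B is a calibrated stand-in for a fitted empirical-Bayes
  lods; treat its absolute values as a decision statistic, not a
  posterior from a fitted hierarchy.
* The one-vs-rest contrast ignores phylogenetic non-independence among
  the "other" species; so does the design it reproduces.
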