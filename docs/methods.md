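# Methods

This note records the models, parameter choices and numerical conventions
behind `atlasforge`, and what the synthetic tests do and do not establish
about real data.

## The abundance model

Transcript abundance in a healthy library is modelled as Zipf's law: the
gene of rank r has baseline abundance r^(-α) with α = 1, multiplied by
lognormal noise with log-sd σ = 0.25 (the noise avoids ties and mimics
between-gene dispersion without disturbing the global power law).
Consequently the reverse cumulative distribution of TPM — the number of
genes at or above each expression level — is itself a power law with
log–log slope −1/α = −1, which is the quantity the QC stage fits. A
"corrupted" library is planted by overriding α per sample (e.g. α = 2
yields a fitted slope of −1/2).

Tissue identity is a single multiplicative effect: each planted cluster
is a disjoint gene subset up-regulated `fold_up` = 8 in one tissue, after
which each tissue's abundance vector is renormalised to proportions.
Per-library replicate noise is lognormal (log-sd 0.25) on the expected
proportions, drawn from a stream split by sample id, so that adding
samples never changes existing ones. Reads are i.i.d. multinomial draws
with probability proportional to abundance × effective length; the
default "abstract-read" mode returns the exact multinomial counts and is
used for all large-depth work, while sequence mode (capped at 200,000
reads) synthesises reads with uniform starts and an optional uniform
substitution rate for k-mer robustness checks.

What the generator does *not* emulate: 3'-end quality decay and
sequencer-specific error profiles, positional/GC bias, strand
artefacts, paired-end insert-size distributions, isoform switching
within genes, and batch structure beyond the BioProject label. Passing
tests therefore demonstrate correctness of the pipeline's logic and its
statistical behaviour under the stated model, not robustness to every
artefact of real libraries.

## Reference construction

mRNA records are trimmed to their longest ORF (ATG…stop), scanning the
three forward frames only — mRNAs are sense-strand — with ties broken to
the 5'-most start. "Incorporates a CDS" is exact substring containment
of the curated CDS in the *untrimmed* mRNA; no alignment tolerance is
applied, which keeps the rule deterministic and matches the worked
merge example the rule derives from. Duplicate sequences are unified
under the curated identifier. The 300 nt CDS floor, the detection level
(average TPM > 1), and the single-tissue filter are all configurable;
the single-tissue filter defaults to on. RefSeq records lacking any
gene assignment are treated as singleton genes named by their
transcript id and flagged, since no mapping rule is defined for them.

## Quantification

k is the odd integer nearest the midpoint of [max_read_len/3,
min_read_len/2] (ties broken downward, favouring sensitivity), default
21 when the interval is empty. Effective length is ℓ_eff = max(ℓ − 100 +
1, 1), the single-end mean-fragment assumption. Reads map to the
equivalence class of transcripts compatible with all their indexed
k-mers, with a majority-compatibility fallback; class counts are
resolved by EM from uniform starting abundances, at most 200 iterations,
stopping when the largest change in the abundance fractions falls below
1e-8. Gene TPM is the sum of member-transcript TPM, which preserves the
10⁶ column total. Down-sampling of abstract libraries uses the
multivariate hypergeometric distribution — the exact law of seeded
without-replacement read sampling — so sequence and abstract modes are
statistically interchangeable.

## Zipf QC

The fit is unweighted OLS of log10(count) on log10(level) over unique
levels, after dropping levels below TPM 5 and then all points in the
lowest and highest remaining log10 decade (robustness trimming; decade
= floor(log10 level), endpoints closed on the kept side). Fewer than 10
surviving points is an indeterminate fit and fails QC with reason
`unfittable`. The acceptance band is the closed interval [−1.2, −0.8]:
the exclusion rule is deviation of more than 20% from the optimum of −1,
read on the magnitude scale (its literal signed-inequality phrasing
would exclude every sample).

## Atlas, PEM, networks

Replicates aggregate as the median per (BioProject, tissue); the even-
count median is the mean of the central pair. PEM collapses BioProjects
to one value per tissue (median), clamps TPM < 1 to 1, log2-transforms
and centres each gene's row, so rows sum to 0 and undetectable genes
score 0 everywhere. Gene–gene Pearson correlation is computed on
aggregated TPM without transformation (a log2 option is exposed);
constant profiles have undefined correlation, recorded as absent and
warned about, never as 0.

MCL is implemented from scratch on the weighted thresholded graph (a
binary option exists): self-loops equal to each node's maximum incident
weight, column normalisation, then alternating expansion (matrix
squaring) and inflation (entry-wise power 2.2, renormalisation), with
entries below 1e-5 pruned (never a column's maximum) until the maximum
matrix change falls below 1e-6 or 200 iterations (non-convergence is
flagged and the current matrix interpreted). Attractors are nodes with
positive return probability; attractors sharing a served node merge
into one cluster, other nodes join the cluster of strongest total
attachment (ties to the lower cluster index), and cluster ids are
assigned by decreasing size then lexicographic member order. These
internals (loop weighting, pruning, tolerances) are canonical-practice
choices, exposed in the API, since the clustering tool the atlas
protocol uses does not document its own.

## Enrichment and annotation

Enrichment is the one-sided upper-tail hypergeometric test; the
weight-propagation algorithm of hierarchy-aware GO tools is out of
scope, but an elim-style mode removes the genes of significant child
terms from ancestors before testing them (children first via
topological order; cycles are an error). No multiple-testing correction
is applied by default, matching the raw p < 0.05, fold ≥ 2 reporting
rule; Benjamini–Hochberg is available.

Annotation categories follow the 8-tier cascade documented in the
module. Open choices, decided as follows: the ≥ 4 genera rule is counted
over the high-quality hits only; the human protein for the category 1–4
coverage grades is that of the best (lowest E-value) qualifying human
hit, with ties broken by higher identity then subject id; a gene
reaching the genera tier whose best human hit has no known protein
length stays category 5. Description agreement for name transfer uses
exact string match after lowercasing, whitespace collapsing and
stripping isoform/variant suffixes (the normaliser is exposed).
Third-party-annotation hits are recognised by TPA markers in the
description. The enrichment universe defaults to the atlas genes
present in the GO reference.

## Pipeline and problem sizes

The orchestrated run is hard-wired to exactly two quantification
iterations. The default synthetic cohort is 500 genes × 6 tissues × 3
BioProjects × 2 replicates (36 libraries) with six planted 25-gene
clusters at 8-fold, a common depth of 10 million abstract reads per
library, and stream-per-sample seeding; the down-sampling concordance
computation uses one 40-million-read library over 20,000 genes,
down-sampled to 10 million reads twenty times. These sizes run the full
suite in seconds on one CPU while keeping every statistical behaviour —
slope recovery, concordance above 0.96, cluster recovery — comfortably
measurable. All outputs are TSV/FASTA/JSON with fixed float formatting,
so identical configurations reproduce byte-identical output trees.

## Known limitations

- The quantifier is a compact pseudo-aligner: no bootstrap uncertainty,
  bias correction, or strand-awareness; paired-end support is limited
  to abstract mode.
- Zipf fitting follows the OLS-on-log-log convention of the atlas
  protocol rather than maximum-likelihood power-law estimation, and
  inherits its small-sample bias at low gene counts.
- Under the default desk-scale conditions (500 genes), a minority of
  healthy libraries can fall just outside the QC band — the fitted
  slope steepens as gene count shrinks — which the pipeline treats as
  it would real failures; at 2,000+ genes recovered exponents
  concentrate tightly around −1.
- The elim-style decorrelation approximates, but is not, the weight
  algorithm used by hierarchy-aware GO tools.
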