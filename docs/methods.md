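# Methods

`mirmodule` implements the classical two-library small-RNA-seq analysis
for paired plant samples: one reference library (called CA by default)
and one treatment library (NA), each a single pooled sample without
biological replicates. This note documents the models and procedures,
their assumptions, the parameters that matter, and what the synthetic
benchmark does and does not establish.

## Read cleaning and tags

Reads are cleaned by 3' adapter removal (leftmost exact match of the
adapter's first 6 nt), optional 5' adapter removal, an N filter
(default: no N allowed) and an 18–30 nt insert-length window. Surviving
identical sequences collapse into *clean tags* carrying per-library
counts; all downstream work is on tags. U is normalised to T internally
so one alphabet serves hashing, matching and folding. Quality-window
trimming is deliberately omitted: for short inserts the adapter position
dominates, and collapsed tags do not retain per-base qualities.

Adapter sequences and quality cutoffs are conventions of the sequencing
provider; defaults here (no adapters, max_n = 0) assume pre-trimmed
input unless the caller supplies adapters.

## Annotation cascade

Tags are partitioned into miRNA > rRNA > snRNA > snoRNA > tRNA >
unannotated, in that fixed priority, so category totals partition the
clean reads exactly. Mature-miRNA matching is gapless with at most two
substitutions and a terminal overhang of up to 2 nt (overlap at least
tag length − 2); the best hit wins (fewest mismatches, ties to the
lexicographically smallest reference id). Gapped alignment is not
meaningful at 21 nt, so "free gaps" readings of legacy pipelines are
resolved as gap-free. Structural RNAs are matched by exact substring
containment, since those references are full-length molecules much
longer than any tag.

The matcher seeds candidate alignments on shared 6-mers, with an
exhaustive-offset fallback for tags under 20 nt where the pigeonhole
guarantee weakens; it is tested for exact equivalence against an
all-offset Hamming scan.

From quantified hits a family-representative database is built: per
miRNA family (id parsed by stripping the species prefix, -5p/-3p arm
suffix and variant letters), the mature sequence with the highest summed
tag count represents the family. Known-miRNA expression is then counted
against representatives only, best hit per tag, which conserves read
mass.

## Novel miRNA discovery

Unannotated tags are mapped exactly (full length, both strands) to the
genome; tags with more than 20 loci are treated as repeats and dropped.
Around each locus two candidate precursor windows are excised — 160 nt
up/20 nt down and 20 nt up/160 nt down, strand-resolved — reflecting
that the mature may sit on either arm.

Windows are folded by **weighted base-pair maximisation** (Nussinov
dynamic programming) with weights G:C = 3, A:U = 2, G:U = 1 and a
minimum loop of 3 nt, rather than a thermodynamic free-energy model.
This choice is self-contained and oracle-testable: the DP is verified
against exhaustive enumeration of all nested pairings on short strings
and against an independent cubic-time implementation. The traceback is
deterministic (5'-most optimal partner for each closing base). A hook
for an external thermodynamic folder can replace `fold` but is off by
default.

A window is called a hairpin (miRNA) only if all criteria hold:

1. mature length 18–26 nt;
2. every paired mature base pairs outside the mature interval, all on
   one side (mature on one arm, no overlap with the terminal loop);
3. at least 14 mature bases pair into a *compact* opposite arm — the
   densest window of partner positions no wider than mature length
   + 5 nt, which defines the miRNA*;
4. pair score per nucleotide ≥ 0.5 (fold-quality proxy for a minimum
   free energy cutoff);
5. precursor 60–400 nt.

The compactness clause in (3) is essential with a pair-maximisation
objective: random 200 nt windows fold into multibranched structures in
which a 21-mer's partners, though on one side, scatter across several
helices; counting only the densest partner window rejects ~95% of
shuffled controls while keeping ≥0.9 recall on planted precursors. The
residual misses (~3–5% of planted precursors) occur when the global
optimum pairs part of the mature into flanking sequence in both
excised windows; a thermodynamic folder would recover most of these.

A tag is a novel miRNA if at least one locus passes; the best-scoring
passing window is its reported precursor. Windows overlapping
known-miRNA loci are excluded before folding. Known miRNAs are
genome-verified with the same machinery but retained regardless
(cross-species references need not map); they are flagged
`not_genome_verified` instead.

## Quantification and differential expression

- **Counting.** Known: best-hit accrual onto family representatives,
  ≤ 2 substitutions. Novel: a tag accrues to a novel mature when the
  interior (beyond 3 nt from each end) aligns exactly and total end
  differences (terminal substitutions plus overhangs) ≤ 3.
- **TPM** = count / total clean reads × 10⁶. Over a full tag set TPM
  sums to exactly 10⁶ per library.
- **Fold change** = log2(TPM_B / TPM_A) with both TPMs floored at 0.01,
  the detection floor at which a miRNA is "hardly detected"; the floor
  removes zero singularities and is configurable.
- **Significance.** The Audic–Claverie exact tag-count test: conditional
  on the reference count x, the treatment count under the null follows
  a negative binomial with x+1 successes and success probability
  N1/(N1+N2) (equal per-read rates), and the two-sided p doubles the
  smaller tail at the observed count, capped at 1. It is computed
  through scipy's log-space negative binomial and verified against
  direct log-gamma tail summation. This test is the appropriate exact
  choice for one pooled library per condition; it is *not* exactly
  symmetric under exchanging the two libraries (the conditioning count
  changes) — exchange symmetry holds asymptotically, and Fisher's exact
  test on the 2×2 count-vs-rest table, which is exactly symmetric, is
  available behind a config switch. On a Poisson null the empirical
  type-I rate at nominal 0.05 is ≈0.05 (acceptance bound ≤ 0.07).
- **DE call.** |log2FC| > 1 and p < 0.05 and BH FDR ≤ 0.05, adjusted
  within the known and novel classes separately to match the class-wise
  accounting; p < 0.01 flags the strict tier. Whether the original
  FDR procedure was BH is unstated; BH is the standard default.
- **qPCR utility.** 2^−ΔΔCt relative expression for paired
  target/reference cycle thresholds.

No replicate-aware dispersion modelling is attempted: with one pooled
library per condition there is nothing to estimate a biological
variance from, and the exact test quantifies sampling noise only.

## Target prediction

Plant-style expectation scoring: each transcript window is paired in
reverse orientation against the miRNA, charged +1 per mismatch, +0.5
per G:U wobble and +2 per single-nucleotide bulge, with penalties
doubled at miRNA positions 2–13. Sites require expectation ≤ 4.0 and
≤ 2 core mismatches. The penalty constants follow the common plant
target-prediction convention and are config keys. The scanner slides
ungapped windows (one window length, equal to the miRNA); single-bulge
variants (window ± 1 nt, bulge disallowed at positions 10–11) are
scored at the duplex level by `score_duplex`. The predicted cleavage
position is the transcript base opposite miRNA position 10. No
hybridisation energies and no UTR/CDS weighting are computed.

## Module integration

Modules are distinct (DE miRNA, predicted target gene) pairs labelled
up–down, down–up, up–up, down–down or de–unDE from the two DE statuses;
inverse = up–down or down–up, the signature of cleavage-mode
regulation. With a single pair of libraries no correlation coefficient
is defined, so "inverse" is strict sign opposition. Hub miRNAs are
ranked by inverse-module count (then DE-target count, then id) in the
bipartite miRNA–gene network, which is exported as GraphML for any
viewer. Enrichment of target sets is a hypergeometric upper tail
against a user-supplied flat gene→term map with BH FDR across terms; no
ontology DAG propagation is performed.

## Synthetic data: what it emulates and what it does not

The generator plants known and novel precursors (21 nt mature, 8–15 nt
loop, reverse-complement star with 0–2 mutations) on both strands of a
uniform random genome, draws per-miRNA counts from a negative binomial
(dispersion 0.05; Poisson available for calibration checks) around
log-normal abundances normalised so miRNAs carry 4% of reads, fills the
remaining depth with structural-RNA fragments (rRNA 35%, tRNA 3%,
snRNA 0.2%, snoRNA 0.1%) and unannotated background tags drawn from a
bimodal 21/24 nt length mixture (49% at 21 nt). Fold changes follow an
up/down/null mixture (45%/30%/25%, magnitudes 1.5–4), chosen to mirror
a deeply perturbed two-condition design in which most miRNAs change and
more go up than down. Target transcripts carry exact
reverse-complement sites; coupled genes move opposite (inverse), with
(positive) or not at all (none) relative to their miRNA. ε = 0.01 in
the truth-table log2FC mirrors the pipeline's TPM floor. Background
tags colliding with planted matures are re-sampled so truth stays
unambiguous.

Defaults are desk-scale: 60 known + 20 novel miRNAs, 120 kb genome,
10⁵ reads per library. All randomness flows from one integer seed;
fixed seed gives byte-identical outputs. Replicate pooling is exposed
only as the two-pooled-library design; per-cycle error profiles,
adapter-ligation bias and isomiR distributions are not simulated.
Consequently, passing benchmarks demonstrate correctness of the
algorithms under the stated statistical model — they do not certify
performance on real libraries with sequencing error, isomiR clouds or
repeat-rich genomes.

## Numerical and procedural choices

- Deterministic orderings everywhere: tags, loci, records and sites are
  processed and emitted in sorted order; ties break lexicographically.
- Genome mapping seeds on 18-mers (the minimum tag length) with full
  verification, so mapping is exact, not heuristic.
- GFF3 output is 1-based inclusive; all internal coordinates are
  0-based half-open, converted only at I/O.
- Percentages in reports are `round(100·num/den, 2)` throughout.
- Degenerate inputs: empty tag sets, empty term maps and missing report
  sections yield defined empty results, not errors; empty genomes,
  zero denominators and negative counts raise `ValueError`.

## Benchmark problem sizes

The validation suite uses 10⁵-read libraries with 80 planted miRNAs
for recovery checks, 10 seeded replicates of 20 planted precursors for
recall/precision, 10 × 1000 Poisson-null pairs for type-I calibration,
200 short random strings for the folding oracle and 50 random
miRNA–transcript pairs for the scanner oracle. These sizes give stable
estimates (binomial standard errors well under the margins tested)
while keeping a full run in minutes on one core.
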