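# Methods

This note documents the models and procedures implemented in `svcohort`,
the defaults that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## SV representation and typing

Internally an SV call is a sequence-resolved allele pair on 0-based
half-open coordinates (`end − start = len(ref)`); VCF I/O converts to the
1-based convention with the leading shared base in both alleles, the
standard dialect for indel-style records. `svlen` is the absolute allele
length difference for deletions/insertions and the reference span for
inversions (an inversion does not change allele lengths, so the span is
the only meaningful size).

Type inference applies the inversion rule first: with both alleles
≥ 50 bp, a call is INV when
`seq_similarity(ref, revcomp(alt)) ≥ 0.80`. Otherwise a signed length
difference of ≥ 50 bp gives DEL/INS, and anything else is unresolved and
dropped at ingestion. `N` bases participate in edit distance as ordinary
mismatching symbols. Symbolic ALT alleles (`<DEL>` etc.) are skipped with a
logged count rather than erroring, because upstream callers legitimately
emit them; multi-allelic sites are split per ALT before filtering. The
per-record quality score is treated as an opaque monotone score — nothing
assumes it is phred-scaled.

One htslib detail: END equal to the VCF default `POS + len(REF) − 1` is
normalized away on write, which for fully sequence-resolved alleles is
always; the writer restores the key so interval tools see it.

## Pairwise similarity and collapsing

Sequence similarity is `1 − editdistance/max(len)` (edit distance via
edlib; a quadratic DP oracle verifies it in tests). The measure is
deterministic, symmetric, and bounded in [0, 1]; both empty strings have
similarity 1. Size similarity is the min/max length ratio. For same-type
pairs the comparison is over the *variant* sequence — deleted bases,
inserted bases (shared prefix stripped), or the inverted span — so an
insertion's similarity does not depend on flanking context. Distances are
start-to-start; insertion anchors are their start positions.

Matching requires **both** similarities to clear their thresholds within
the positional window (similarity conjunction; replicate concordance uses
strictly-greater-than 0.70, collapsing ≥ 0.95 within 1000 bp). Collapsing
is greedy *star* clustering: records processed in descending quality join
the first existing seed they match (always compared against the seed, never
chained through members), otherwise found a new site. This prevents
transitive drift, makes the representative the maximal-quality record of
its cluster by construction, and yields a deterministic result given the
documented tie-breaks (quality desc, then chrom/start/record-id). A
post-condition checked in tests: no two surviving same-type seeds within
the window still match each other.

One-to-one callset matching ranks candidate pairs by (seq similarity desc,
size similarity desc, distance asc, record ids) and assigns greedily. On
well-separated callsets this equals the exhaustive assignment maximizing
(match count, total similarity); adversarially overlapping candidates could
in principle make the greedy choice sub-optimal, which we accept for
determinism and speed.

## Replicate QC and quality calibration

Technical replicates of the same individual act as an internal truth set.
Every call of both callsets is classified exactly once: matched with both
similarities > 0.70 → consistent, otherwise inconsistent. When an
individual has k > 2 replicate samples, all C(k, 2) pairs contribute. The
quality threshold is the grid value t maximizing Youden's
J(t) = P(consistent ≥ t) − P(inconsistent ≥ t), ties toward the smallest t
(a two-sample KS variant is available behind a flag). For symmetric
true/false score distributions (the generator's default,
Normal(70, 10) vs Normal(30, 10)) the optimum is the midpoint, so the
calibration is validated by recovering the planted boundary of 50.

## Sample and study QC

Per-sample DEL/INS/INV counts are log1p-transformed and scored by a robust
Mahalanobis distance (coordinate-wise median center; covariance from the
rank correlation rescaled by the MAD); the most extreme 2% are flagged.
This is a deterministic replacement for a trained one-class classifier at
the same flagged fraction: the stage's contract is "flag the configured
tail", and a closed-form rule keeps it reproducible and dependency-free.
Studies are dropped wholesale when their flagged-sample count is
binomially enriched over the global rate (one-sided test, BH-adjusted
q < 0.05, at least 2 flags) — a formalization of "outliers concentrate in
a study", which has no canonical rule.

## Cohort matrix and site summaries

Collapsing defines sites; each sample's dosage at a site comes from its
member record (absent → 0; two same-sample records in one cluster resolve
to the higher quality, with a warning). Allele frequencies exclude missing
genotypes from the denominator. Size bins are left-closed right-open at
{50, 100, 300, 1000, 2500, 5000, ∞}; AF bins are log-scaled; a singleton
is allele count 1. The Hardy–Weinberg test is the exact conditional test
(heterozygote count given the allele count), summing the probabilities of
configurations no more probable than observed; it matches full enumeration
to 1e-12 for n ≤ 20 and is conservative by construction.

## LD, pruning, PCA

Two-locus LD uses composite-phase EM over the 3×3 genotype table: only the
double-heterozygote cell is phase-ambiguous and is split by the current
estimate of `f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB)`; convergence at
max-change < 1e-8 or 1000 iterations. D′ and r² follow from the converged
frequencies; monomorphic input is an error since r² is undefined. LD
*pruning* (a filter, not an estimate) uses squared dosage correlation in
sliding windows (50 sites, step 5), dropping the lower-MAF member of any
pair above r² = 0.1.

PCA operates on sites passing MAF > 1% and the exact HWE test at the
Bonferroni level 0.05/(MAF-passing sites), then LD pruning. Dosages are
centered at 2p̂ and scaled by √(2p̂(1−p̂)); missing values are
mean-imputed (i.e., zero after centering); truncated SVD with a
deterministic sign convention (largest-magnitude loading positive). Note
the filters make the degenerate all-identical-samples input unreachable:
every column is then constant, so the empty-post-filter error fires before
any score could be computed. Relatedness-aware PCA is deliberately not
implemented — the generator produces unrelated samples, and the fixed-PC
adjustment is the intended stand-in for a mixed model (see Limitations).

The batch screen reports a Kruskal–Wallis p per PC across batch labels
plus a complete-separation flag (disjoint score ranges between two
batches), the signature of a PC encoding a technical covariate; the
pipeline's read-length restriction is the downstream remedy.

## Single-variant association

Fixed-effects logistic regression by Newton–Raphson (log-likelihood change
< 1e-10, ≤ 50 iterations), Wald z and two-sided p for the dosage term,
covariates: intercept, sex, sequencing-center indicators, and the leading
PCs (5 by default). Under quasi-complete separation — non-convergence or
|β| > 15 — the p-value falls back to the Rao score test in the null model,
which needs no per-variant fit and is stable on degenerate rare-variant
inputs; such results are flagged. Conditional models append the partner
variant's dosage to the covariates after a collinearity check. PCs are held
fixed across conditional models.

Per-ancestry analyses are independent sub-runs over the shared collapsed
callset (MAF > 0.5% and HWE within the group), combined by the
sample-size-weighted Stouffer method
`z_meta = Σ √n_i z_i / √Σ n_i`. The tag-SNP scan reports pairs with EM
r² strictly above 0.4; the haplotype verdict orients D to the SV-alternate
and risk alleles and requires |D′| > 0.5 — a formalization of a
qualitative same-haplotype claim, configurable.

## Gene-based rare-variant tests

All set tests are score tests under one null logistic fit per
phenotype/covariate configuration. With `G̃ = G·diag(w)` and
`P = W − WX(X'WX)⁻¹X'W`:

* burden: `U = (G̃1)'(y − μ̂)`, `χ²₁ = U²/Var(U)`;
* SKAT: `Q = ‖G̃'(y − μ̂)‖²`, null `Σ λ_k χ²₁` with λ the eigenvalues of
  `G̃'PG̃`, tail probability by Liu-type moment matching (skewness/kurtosis
  matched to a (non-central) chi-square; verified against 100,000-draw
  Monte-Carlo mixtures within 10% relative error);
* hybrid: Fisher's combination (χ²₄) of the burden p and the SKAT p on
  genotypes orthogonalized against the burden direction in the P-metric,
  which makes the two score statistics asymptotically independent.

On a single-variant set all three reduce to the same score test
(verified to 1e-8). Weights default to the Beta(1, 25) density of the MAF,
the convention of the standard rare-variant toolchain; a literal-MAF weight
mode is provided because "MAF as weight" is also a defensible reading, and
neither is asserted as the other's substitute. Sets need cMAC ≥ 10;
members need MAF < 1%; SVs enter only with a pathogenicity score ≥ 0.5
from the supplied table (scores are inputs, not computed here — SVs absent
from the table are treated as benign with a warning). Coding status is
≥ 1 bp exon overlap of the representative transcript; non-coding SVs are
evaluated against genes within 1 Mb. Conditional set tests append the
weighted SNV burden to the covariates and re-test the SV members. BH FDR
within each analysis group; gene meta-analysis is one-sided Stouffer on
Φ⁻¹(1−p), consistent with directionless set statistics.

## Synthetic-data generator

The generator emulates the *structure* of a multi-ancestry short-read SV
study, not its biology: a random reference genome (default 2 × 1.5 Mb);
sites spaced > 2.5 kb so collapsing cannot merge distinct sites; base AFs
from Beta(0.3, 3) (rare-skewed); per-population AFs by Balding–Nichols
with Fst 0.1; genotypes in HWE within population; type mix
55.78/41.78/2.44% DEL/INS/INV and a ~300 bp insertion mode seeded from a
shared motif, mirroring the emulated call set's composition and its
ALU-like size peak; phenotypes from a logistic model with configured
per-site odds ratios plus sex and batch effects, intercept solved by
bisection to hit the configured case fraction (0.47). Replicates duplicate
a sample's calls with dropout, breakpoint jitter, per-base sequence error,
and Poisson-injected false calls; true and false calls draw quality from
Normal(70, 10) and Normal(30, 10). Tag-SNP loci are built from explicit
haplotype frequencies achieving a target r² (with a feasibility check
against the D² bound, naming the attainable maximum). Everything is a pure
function of the config and seed; truth (genotypes, causal effects,
per-call labels) is serialized with every bundle.

What it does **not** emulate: read-level errors, genotyping uncertainty
correlated with depth, segmental-duplication artifacts, relatedness,
admixture LD structure, or realistic gene density. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its stated
model, not robustness to every artifact of real sequencing data.

## Problem sizes and determinism

Default test and acceptance problem sizes are chosen for quick, repeatable
runs on a single core: cohorts of a few hundred samples and a few hundred
to two thousand sites, 2000-replicate null calibrations, 200-replicate
effect-recovery simulations, n = 6000 for single-variant power-scale
checks. All randomness flows through explicit seeds; the pipeline writes a
manifest with per-output SHA-256 hashes, and two runs over the same bundle
are byte-identical.

## Known limitations

* No mixed-model (GRM) association or relatedness-aware PCA; fixed-effect
  PC adjustment assumes unrelated samples.
* Greedy collapse and matching are deterministic approximations; they do
  not reproduce any external merging tool's internal scoring.
* Duplication and translocation classes are out of scope (the call sets
  this targets contain DEL/INS/INV only); DUP↔INS type swaps are not
  resolved.
* The Liu tail approximation for chi-square mixtures is accurate to a few
  percent in the regions tested; extreme far-tail p-values (< 1e-10) from
  SKAT should be treated as order-of-magnitude.
* Catalog AFs and pathogenicity scores are consumed as given; no
  annotation is computed from sequence.
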