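# Methods

## Problem and approach

Generative protein models (GANs, masked-language-model samplers, ancestral
reconstruction, autoregressive language models) emit far more candidate
enzyme sequences than a wet lab can express and assay. `compss` implements a
composite, calibrated triage for such candidates: cheap sequence-level
checks first, a likelihood threshold calibrated on natural sequences next,
and an expensive structure-conditioned score only for the survivors. The
package also carries the statistics used to measure whether a metric or a
filter actually enriches active enzymes, and the assay-analysis formulas
used to decide "active" in the first place.

## Metrics

**Tandem repeats.** For unit length k ∈ {1..4}, the repeat score is
−1 × the maximal number of contiguous exact copies of any k-mer, scanning
every start offset and counting only complete copies. AAAAAA → −6/−3/−2/−1
for k = 1..4; LALALALA → −1/−4/−1/−2. The quality check fails a sequence
whose single-residue run exceeds 3 residues or whose residue-pair tandem
spans more than 4 residues. Because a 2-mer tandem has even span, the
smallest failing span is 6 residues (≥ 3 units); this is the reading of
"pair repeat longer than four" we adopt. Limits for 3-/4-mers can be added
through `QualityPolicy.extra_kmer_limits` but are off by default.

**Charge.** Net charge = (#K + #R) − (#D + #E); histidine, cysteine and
tyrosine are deliberately excluded — the definition is a residue count, not
a pKa model. `charged_fraction` counts the same four residue types over the
length.

**Alignment metrics.** Candidates are compared against a training set by
optimal global alignment (BLOSUM62; gap open 10, extend 2; a length-L gap
costs open + L·extend, so a single-residue gap costs 12 — the FASTA-package
convention). Identity = matching columns / full alignment length, gap
columns (terminal ones included) counting as mismatches; an
`include_terminal_gaps=False` variant exists for the other convention. The
mutant-position mean averages the substitution-matrix score over mismatched
gap-free columns and is reported as missing when no such column exists.
`topk_mean_homology` averages the k = 30 best per-reference scores, either
from global-alignment raw scores (internal backend) or phmmer bit scores
(pyhmmer backend); the two scales are never mixed in one table. The
dynamic programming itself is Biopython's `PairwiseAligner`; co-optimal
alignments resolve to the library's first traceback, which is deterministic
across runs — we rely on that stability rather than imposing a bespoke
diagonal-first rule, since no metric here depends on which co-optimal path
is chosen (scores and gap-free column sets are tie-invariant in practice).

**Likelihood scoring.** Scorers implement one method: log-probability of
the observed residue at requested (masked) positions, optionally with MSA
context. Unmasked scoring is one pass; with masking interval m, pass j
masks positions ≡ j (mod m), m passes cover every position exactly once,
and the pooled per-position values are averaged. The MSA-context score uses
the query's 31 nearest training sequences and interval 6 by default. The
internal MSA fallback is a query-anchored star alignment (each neighbor
globally aligned to the query, insertions relative to the query dropped):
columns index query positions, which is exactly what scoring the query row
requires; it is not a general MSA. Real models (single-sequence or
MSA-transformer masked LMs, inverse-folding models) attach as adapters; for
ensembles of checkpoints the default is the mean of per-checkpoint average
log-probabilities. The shipped `PssmScorer` (position probability matrix
with pseudocount α, default 1) is deterministic and context-free, which
gives the test suite a sharp invariant: masked and unmasked averages must
agree exactly.

**Generation.** `iterative_mask_sample` re-draws masked positions from the
scorer's distribution until every position of the target row has been
resampled once; positions are visited in a seeded random order (the visit
order is not externally specified, so we make it explicit and
reproducible). Whole-alignment mode resamples every row; single-sequence
mode resamples one row and rebuilds its context from the training
sequences nearest the current state after each pass. Temperature scales the
sampling distribution as p^(1/T); T → 0 degenerates to the per-column
argmax.

**Structure metrics.** SASA uses the Shrake–Rupley construction: each
atom's van der Waals sphere (Bondi radii) is inflated by the 1.4 Å probe
and covered with a Fibonacci lattice (default 960 points; doubling changes
fixture totals by < 1%); points inside any neighbor's inflated sphere are
buried. Polar area sums atoms with element N, O or S — the element-based
convention; which polar classifier the upstream SASA literature intends is
ambiguous, so the classification is exposed as data
(`struct_metrics.POLAR_ELEMENTS`). Percent polar = 100 × polar/total.
Exactly coincident equal-radius atoms are collapsed to one surface before
the computation (otherwise lattice points lying exactly on the twin sphere
are never classified as buried). Hydrogens, absent from predicted
structures, are simply absent — no united-atom inflation. Per-residue
confidence (pLDDT convention, B-factor column) averages a residue's atom
values by default; a first-atom policy is available since prediction
pipelines write identical values per residue and either reading is then
exact. Inverse-folding and Rosetta-style energies are adapter contracts
with results cached per (structure, sequence) hash.

## Calibration and the selection filter

The cutoff for the likelihood metric is the "top p-th percentile" of
natural-sequence scores (default p = 10): with n calibration scores the
cutoff is the ⌈np/100⌉-th largest, i.e. the lower-value order statistic, so
at most p% of the calibration set passes — the stringent reading. On scores
1..10 with p = 10 the cutoff is 10 and exactly one calibration sequence
meets it.

The filter runs per model–family stratum: (1) sequence stage — identity to
the closest training sequence within [0.50, 0.80] (both endpoints pass,
since the exclusion is "less than 50% or greater than 80%"), likelihood
score ≥ cutoff, quality checks pass; all violated criteria are recorded,
not only the first. When no transmembrane-predictor adapter is attached
that check reports unknown and is not held against the sequence (logged).
(2) structure stage — a seeded sample of 200 passing sequences, ranked by
the structure-conditioned score; 18 drawn at random from the top 40.
Sampled candidates lacking a structure score are dropped and back-filled
from rank 41 onward, with a report entry. (3) controls — each selection is
paired, without replacement, with a random filter-failing sequence whose
identity-to-training is within 0.01; unmatched selections are reported as
such. A single named seed drives every draw, so runs are bit-reproducible.

## Evaluation statistics

AUC-ROC via the rank-sum identity U/(n₁n₀) with mid-ranks (ties = ½ per
pair); orientation flags are data, carried by the score table, because
which direction of a metric "predicts active" is an empirical property of
the dataset, not of the code. Fisher's exact test is two-tailed in the
probability-mass sense (sum of tables as-or-less probable), matching
mainstream software; Spearman is the Pearson correlation of mid-ranks;
Wilcoxon rank-sum uses the exact null for small tie-free samples and the
tie-corrected normal approximation otherwise; group comparisons of assay
endpoints use Welch's t-test. The quadrant analysis splits the plane of two
metrics at their medians (boundary points to the upper/right quadrant) and
reports per-quadrant counts, active fractions and within-quadrant Spearman.

## Assay analysis

MDH: absorbance at 340 nm converts to NADH concentration via Beer–Lambert
c = A/(d·ε), ε = 6.22 mM⁻¹cm⁻¹, d = 0.29 cm; unspecific oxidation is
subtracted per timepoint using the no-substrate control mean before
endpoints are extracted; a sample is active when its endpoint absorbance is
significantly lower than the negative control's (one-sided Welch test,
p ≤ 0.05 — the direction is dictated by "lower", the Welch variant is our
choice since the test family is not pinned down further). SOD: percent
inhibition ((A−B)−(C−D))/(A−B)×100 at the 20-min read; values outside
[0, 100] are reported as-is. Semiquantitative specific activity: MDH mode
uses the mean concentration drop between the 0 s and 90 s reads, with
replicate t₀ values below 275 µM replaced by the negative-control t₀ mean
(fast enzymes exhaust substrate before the first read), averaged over
replicates and divided by the wild-type mean; SOD mode divides the mean
inhibition rate by the wild-type controls' mean. The floor rule applies
only at t = 0 and only in MDH mode.

## Synthetic data

The fixture generator builds a family from a random consensus: natural
train/test sequences at ~95% identity to it, candidates mutated from random
training sequences to land in a target identity band (default 0.60–0.75 to
the closest training sequence, asserted within ±0.05). Half of the
candidates (configurable) receive one injected defect — missing start
methionine, a 4-residue homopolymer, a 6-residue dimer tandem, a
lysine-heavy charge shift, or out-of-band identity — recorded in a
manifest; injection is rejection-sampled so a defect never smuggles in a
second one. Mock scores are coupled to the manifest: clean candidates draw
their likelihood score from N(−1.8, 0.15) and structure score from
N(−0.9, 0.12), defective ones from N(−2.6, 0.15) and N(−1.5, 0.12);
natural calibration scores draw from N(−2.1, 0.12), placed so the
top-decile natural cutoff is attainable by clean candidates — the regime a
selection filter exists for. The planted activity label is 1 with
probability 0.85 for clean, in-band, high-scoring candidates and 0.25
otherwise. Toy structures put backbone + Cβ atoms on idealized helical
geometry (2.3 Å radius, 100°/1.5 Å per residue) — plausible enough for
surface-area sanity checks, nothing more. Synthetic plates follow an
exponential-decay (MDH) or linear-formation (SOD) signal model with
Gaussian noise.

What passing tests show, and what they do not: the fixtures exercise every
code path and make the enrichment property (selected set beats
identity-matched controls on planted activity, across 5 seeds) a theorem
of the coupled generator — they say nothing about how well any real
generative model or scorer performs on real enzymes.

## Numerical and scale choices

Test problem sizes are chosen so the whole suite runs in seconds on one
core: families of 30–80 candidates of length 40–80, alignment oracles on
pairs of length ≤ 15, the Fisher enumeration oracle over all tables with
total ≤ 12, SASA fixtures of ≤ 100 atoms. The PFASUM15 substitution matrix
is not redistributable here; the loader accepts any NCBI-format matrix
file, and the shipped `data/pfasum15_synthetic.mat` is a clearly-labelled
synthetic stand-in used only to test the loading path. Known limitations:
no pKa-based charge model; no approximate (imperfect) tandem repeats; the
internal star alignment drops query-relative insertions; one control per
selection (many-to-one matching unsupported); no multiple-testing
correction (raw p-values are reported by design).
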