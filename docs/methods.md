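# Methods

## Multi-taxonomy assignment

An ASV is scored against every reference 16S sequence and the best
fractional identity is denoted *M*. All references with identity
strictly greater than τ = M − (1 − M)/4 are accepted; references tied at
*M* are always accepted, as an explicit rule: at M = 1 the threshold
equals M, so the strict inequality alone would reject even a perfect
match, and an ASV must keep at least its best hit. Hits exactly at τ are
excluded ("higher than" is read strictly). The window narrows as the
best match improves — at M = 0.98 references down to 0.975 are kept, at
M = 1.0 only perfect ties — which makes the assignment adaptively
conservative: a mediocre best hit admits a broad set of plausible taxa,
an excellent one admits only near-identical references. For M below 0.8
the threshold can fall below zero and every hit is accepted; such
assignments are taxonomically meaningless and callers should treat very
low M as effectively unassigned.

Accepted lineages are merged rank-by-rank: at each rank the distinct
constituent names are deduplicated, sorted alphabetically (the ordering
is a presentation choice; no order is semantically meaningful) and
joined by `/`. Merging splits existing multi-names first, so it is
idempotent and order-invariant. No cap is applied to the number of
accepted references.

**Identity dialect.** Identity is matches / alignment length under
global (Needleman–Wunsch) alignment with unit mismatch and gap costs,
computed with edlib; gap columns count against identity. Other dialects
(e.g. identity over the shorter sequence, or BLAST local identity) give
different numbers; this one is fixed and symmetric. For large references
a precomputed identity table (`asv_id`, `strain_id`, `identity`) can be
supplied in place of the built-in aligner — the thresholding and merging
logic is identical either way.

## Abundance tables

Counts are closed to relative abundances per sample. 16S copy-number
correction divides each taxon's relative abundance by its mean gene
copy number at a stated rank (default: species) and re-closes; because
the correction is a per-taxon rescaling followed by closure, multiplying
all copy numbers by a constant is a no-op, and correcting before or
after aggregation at the same rank gives the same table. `/`-joined
multi-name taxa use the unweighted mean of their constituents' copy
numbers — the multi-name encodes ambiguity among candidates, not a
mixture, so no weighting is defensible. Taxa absent from the
copy-number table fall back to the table's grand mean and are recorded
in the output (`fallback` can be set to raise instead).

Phylotype-level differential analyses run on uncorrected relative
abundances (fold ratios are invariant to a per-taxon rescaling that is
constant across conditions, so this choice does not affect fold
classification); CPI always uses the corrected table because CPI is a
statement about fractions of cells, not of 16S reads.

Detection ("observed" phylotypes) counts taxa whose mean relative
abundance over a sample subset is strictly above a threshold, default 0:
a zero count is "below the limit of detection", anything else is
observed.

## Community phenotype index

The BPM assigns each reference genome a binary state per metabolic
phenotype (complete pathway present/absent). The probability that a
taxon carries a phenotype is the unweighted mean of the bit over the
pooled set of genomes matching the taxon — for a `/`-joined multi-name,
genomes matching any constituent at the analysis rank. Two matching
routes exist:

- **by rank name** (default, rank = species): genome lineages are
  matched against the taxon's constituent names;
- **by accepted references** (phylotype-level): each ASV pools the
  genomes linked to its accepted reference strains. This route keeps
  strain-resolved phenotype differences that species-level pooling
  averages away, and is what makes phylotype-level CPIs commensurable
  with strain-level ground truth in the synthetic experiments.

Taxa with zero supporting genomes carry an explicit missing marker
(NaN), never a silent 0. When computing CPI these taxa are excluded and
the remaining abundances re-closed, and the excluded mass is reported
per sample; treating unmapped taxa as P = 0 would bias CPI toward zero
and break the "fraction of cells" interpretation. CPI is linear in the
abundance vector and bounded in [0, 100] by construction.

The pooled-mean definition of P is deliberately isolated in a single
operation (`phenotype_probability` / the two `probability_table_*`
builders) so that a differently weighted estimator can replace it
without touching anything else.

## Differential statistics

The two-tailed Mann–Whitney test is exact for small samples: for
n₁ + n₂ ≤ 12 the null distribution of U (rank-sum form, mid-ranks for
ties) is built by enumerating all C(n₁+n₂, n₁) group labelings of the
observed values, and the two-tailed p doubles the probability of a U at
least as extreme as observed toward its nearer tail, capped at 1. The
doubling convention (rather than summing both tails of an asymmetric
tie distribution) is a documented dialect; for tie-free data the two
agree. At 4 vs 4 the attainable floor is p = 2/70 ≈ 0.0286, reached
exactly when the groups separate completely — reported as "0.03" at two
decimals in human-readable output, at full precision in TSVs. Larger
samples fall back to scipy's tie-corrected normal approximation.
Comparisons within the enumeration use a 1e−9 tolerance so that
mid-rank halves compare exactly.

Fold classification compares arithmetic means of replicate relative
abundances: ratio > 5 in either direction is increased/decreased
(together: altered), a feature undetected in control but detected under
treatment is "new" (counted as increased), the reverse "lost"
(decreased), and exactly fivefold is unaltered (strict inequality). No
multiple-testing correction gates any output; a Benjamini–Hochberg
column is emitted per condition for convenience only.

PCoA uses Gower double-centering and a dense symmetric
eigendecomposition. Negative eigenvalues — expected, since Bray–Curtis
is not generally Euclidean — are retained in the reported spectrum;
coordinates span only the axes with eigenvalues above 1e−8, and
explained-variance fractions are taken over the positive part.

## Synthetic experiments

The generator emulates the statistical structure of a pooled-inoculum
supplementation study: one control plus nine SCFA conditions, four
technical replicates each, at a sequencing depth of 100,000 reads per
sample.

- **Reference.** 450-nt amplicon-like sequences (V3–V4 scale). Species
  consensi derive from one ancestral sequence by ~30 random
  substitutions and are redrawn until every pair differs at ≥ 3% of
  positions plus a 10-substitution margin; strains differ from their
  consensus by 1–5 substitutions and are pairwise distinct, so each
  strain is its own unique best match at identity 1.0 while sibling
  strains sit at ≥ 97.8%. Species are grouped two-per-genus (and so on
  up the ranks) purely to give the lineage structure; sequence
  divergence is not rank-calibrated. Copy numbers are uniform on
  {1, …, 7} per species, shared by its strains, mirroring species-scale
  averages. One genome per strain carries the phenotypes; per phenotype
  a species-level majority state is drawn at the configured prevalence
  (default 0.5) and each genome follows it with probability `coherence`
  (default 0.9).
- **Counts.** Baseline strain abundances are log-normal (default
  log-mean 0, log-sd 1.5 — a spread of roughly two to three orders of
  magnitude across 30 strains, typical of a cultured community).
  Planted effects multiply chosen strains' abundances per condition;
  the control is always exactly 1.0. A strain's sampling weight is its
  cell abundance × its 16S copy number, so the simulated reads carry
  the copy-number bias the pipeline must remove. Per replicate, counts
  are multinomial at the configured depth (so they sum to depth
  exactly); a Dirichlet layer with scale θ (weights ~ Dirichlet(p/θ))
  adds replicate-level overdispersion when θ > 0. The default θ = 0
  reflects technical replicates of a single culture protocol;
  biological replication would need θ > 0.
- **Ground truth.** Cell-level (pre-copy-number) relative abundances
  and planted multipliers are returned alongside the counts; the
  expected CPI per sample is 100 × Σ strain abundance × genome bit,
  computable without touching the pipeline.

What the generator does **not** model: sequencing error and chimeras
(the pipeline starts at denoised ASVs), inter-individual variation (a
pooled inoculum is a single community), growth dynamics over the culture
period (effects are static per-strain multipliers), and correlated
responses among related strains. Passing tests therefore demonstrate
the correctness of the computations under a known compositional model,
not robustness to real-data artifacts.

**Direction of planted effects.** Relative abundance is compositional:
a 10-fold *increase* planted on strains holding total share *s* inflates
every sample's denominator by 1 + 9s, so the observed fold of the
planted strains is 10/(1 + 9s) — with three strains at typical shares
this sits near the fivefold classification boundary, and no generator
setting avoids it because the damping depends only on the planted
share. A 10-fold *reduction* shrinks the denominator by at most a
factor (1 − 0.9s) and is recovered essentially always. The verification
experiments therefore plant 10-fold fitness reductions — also the
biologically central case for SCFA supplementation, where reduced
fitness of many taxa is the dominant observed response — while the
general-purpose default draws multipliers log-uniformly on [0.1, 10],
covering both directions.

## Problem sizes and tolerances

The verification experiments use a 10-species × 3-strain reference
(30 phylotypes), depth 100,000, 4 replicates, 10-fold reductions on 10%
of strains per condition — small enough to re-run in seconds, large
enough that multinomial noise is far from the planted effect sizes.
Under these conditions planted effects are recovered as altered with
the exact-floor p at ≥ 90% sensitivity, null experiments flag ≤ 10% of
features (observed: ~0%), and pipeline CPIs agree with planted ground
truth to better than 2 percentage points (observed: < 0.7). Closure is
asserted to 1e−9; relative-mode tables are validated to 1e−6 on read.
All randomness flows from explicit integer seeds; equal seeds reproduce
every artifact byte-for-byte, and the pipeline manifest records SHA-256
hashes of all inputs and outputs to make this checkable.

## Known limitations

- The probabilistic phenotype estimate is an unweighted pooled mean;
  published estimators may weight genomes or ranks differently.
- The exact test enumerates up to n₁ + n₂ = 12; beyond that the normal
  approximation is used without a continuity-corrected exact option.
- The built-in aligner is quadratic per pair and intended for reference
  sets up to a few thousand sequences; larger studies should precompute
  identities with a dedicated search tool and pass the identity table.
- Copy-number correction assumes the copy-number table's rank matches
  the taxonomy used for assignment; cross-database name mismatches fall
  back to the grand mean rather than being resolved.
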