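# Methods

This note documents the statistical model behind `cqnorm`: what each stage
computes, the estimators chosen where several renderings exist, the
defaults and their rationale, and what the simulator does and does not
emulate.

## Cq data model

A quantification cycle (Cq) is inversely and logarithmically related to
template abundance: one cycle ≈ one doubling at 100% efficiency.  All Cq
values are carried per replicate; "Undetermined" instrument output is a
distinct undetected state (NaN in memory, the literal token on disk).  We
deliberately never encode censoring as Cq 40: the ceiling is
instrument-dependent, and conflating "not detected" with a measured value
biases every downstream mean.  The canonical on-disk format is long/tidy
CSV (`sample_id, assay_id, replicate, plate_id, cq`); wide sample-by-assay
matrices are an import convenience (replicate index 1), since replicates
and plates have no wide representation.

## Preprocessing

Replicates of a (sample, assay, plate) reaction are averaged over their
detected members; the n−1 SD is compared to a reproducibility threshold of
0.3 cycles.  The comparison is strict (`>`), so an SD of exactly 0.3
passes; the threshold is a boundary of acceptability, and the boundary
value is admissible.  Reactions exceeding it are flagged
`high_replicate_sd` but retained — whether to exclude flagged wells is an
analysis decision, exposed as an option, not something aggregation should
silently do.  Fewer than `min_detected` (default 2) detected replicates
marks the reaction undetected.

Inter-plate calibration subtracts, per (plate, assay), the calibrator
sample's deviation from its cross-plate mean.  Calibration is additive on
the Cq scale (equivalently multiplicative on the linear scale, which is the
physics of amplification); it exactly preserves within-plate Cq
differences.  A calibrator missing on any plate carrying the assay is an
error, not a silent skip.

## Amplification efficiency

A dilution series (log10 input, Cq) is fitted by ordinary least squares;
the efficiency in percent is E = (10^(−1/slope) − 1) × 100, so a slope of
−1/log10 2 ≈ −3.3219 cycles per decade gives E = 100 and amplification
factor AF = 1 + E/100 = 2.  E is invariant to constant Cq offsets
(intercept only).  A non-negative slope means no amplification signal and
is a fit error.  When no series is available an assay defaults to AF = 2;
measured efficiencies for well-behaved miRNA assays cluster tightly around
100 ± 2%, so the default is a serviceable stand-in, and every ratio-based
statistic downstream is unaffected by small AF errors common to all assays.

## Relative quantification and error propagation

RQ(i, s) = AF_i^(Cq_ref(i) − Cq(i, s)), with the per-assay reference point
Cq_ref either the minimum Cq over samples (default; the highest expressor
gets RQ 1, the classic geNorm input convention) or the mean Cq (geometric
mean RQ of 1).  The choice rescales each assay's column by a constant and
provably cancels from geNorm's M and V, NormFinder's stability, and all
group statistics on normalized quantities — it is cosmetic, and both are
offered.

Standard errors are propagated on the log2 scale assuming independence
between assays:

* se(log2 RQ) = replicate_sd/√n_used × log2 AF,
* se(log2 NF) = (1/m)·√Σ se², for m reference assays,
* se(log2 NRQ) = √(se_target² + se_NF²).

Quadrature on the log scale is the standard treatment for multiplicative
quantities; covariances between assays within a sample (shared pipetting)
are not modelled.

The normalization factor NF(s) is the geometric mean of the reference
assays' RQs in sample s, defined only where every member is detected.
NRQ = RQ_target/NF.  When all amplification factors are equal, a
sample-wide Cq shift moves target and NF identically and cancels exactly
in NRQ — the defining property of normalization, and a construction-level
test in the suite.

## Global-mean selection

For large panels, the per-sample arithmetic mean Cq over expressed assays
(equal to the geometric mean of linear quantities at equal efficiencies) is
itself one of the most stable normalizers available.  Two qualifying rules
are computed: every detected assay, and only assays with Cq strictly below
35 ("expressed below cycle 35"); the cutoff rule guards the mean against
near-ceiling noise.  Candidates are ranked by the n−1 SD over samples of
(Cq_i(s) − global mean(s)); a gene tracking the global mean up to a
constant offset scores 0.  SD was chosen over mean absolute deviation for
continuity with geNorm's variance framing (MAD is available by option).
Candidates must be detected in every retained sample — a reference gene
that drops out is no reference gene.  Ties rank lexicographically for
deterministic output.

Composite "virtual assays" (per-sample mean Cq of a member set — the
geometric mean of their linear quantities) can be entered into any stage
in place of a single gene, e.g. to compare a snoRNA geometric mean against
the global mean inside geNorm.

## geNorm

For genes j, k: V_jk = SD_s(log2 RQ_j/RQ_k) (n−1 convention throughout;
the original algorithm's choice is not normative, so ours is documented).
M_j is the mean of V_jk over the other genes in the current set.  The gene
with the largest M is excluded step by step until two remain; those two
share one M, the SD of their mutual log-ratio.  Ties in M break
lexicographically (the alphabetically last of the tied genes is removed).
Both the full-panel M values and each gene's M at its exclusion step are
reported — they answer different questions (how unstable among all, vs at
the point of elimination).

The number of references to use comes from the V series: NF_n is the
geometric mean of the top-n ranked genes, and V(n, n+1) = SD_s(log2
NF_n/NF_{n+1}).  The recommended n is the smallest n with V below 0.15
(the canonical guidance); if none passes, the n minimizing V (adding
further genes is unnecessary once V bottoms out).  Both numbers are
reported.  Pairwise computations use pairwise-complete samples; the NF
series requires complete cases across the ranked genes, dropping (and
counting) samples that miss any.

## NormFinder-style stability

On y = log2 RQ, each sample is centered across genes, removing sample-wide
variation.  Per gene i and group g with n_g samples (G genes, K = 2
groups):

1. group means z̄_ig and residual variances s²_ig (n−1);
2. de-biased variance σ̂²_ig = max(0, [s²_ig − Σ_i' s²_i'g/(G(G−1))]/(1 − 2/G))
   — centering leaks a 1/G share of every gene's variance into every other
   gene's residuals; this inverts the leakage, clamped at zero (an epsilon
   floor would fabricate precision where there is none);
3. group difference d̂_ig = z̄_ig − mean_g z̄_ig;
4. γ̂² = max(0, Σ d̂²/((G−1)(K−1)) − mean(σ̂²_ig/n_g)), the between-gene
   variance of group differences;
5. shrinkage d̃_ig = d̂_ig·γ̂²/(γ̂² + σ̂²_ig/n_g), with the factor defined as 0
   when γ̂² = 0 (no evidence of real group effects ⇒ no group-difference
   penalty);
6. stability ρ_i = mean_g[|d̃_ig| + √((σ̂²_ig/n_g)·γ̂²/(γ̂² + σ̂²_ig/n_g))].

When γ̂² clamps to 0 every ρ collapses to 0; ranking then falls through to
the mean intra-group variance (then the assay name), so the ordering
degrades gracefully to "least noisy first" rather than to an arbitrary
tie.

**Best pair.**  Every pair's composite series c = (z_i + z_i')/2 is pushed
through the same chain with γ̂² held at the panel value.  The composite's
variance is estimated as (σ̂²_i + σ̂²_i')/4 + côv(y_i, y_i')/2, where the
covariance estimate côv = cov(z_i, z_i') + (σ̂²_i + σ̂²_i')/G − correction
inverts the centering-induced negative covariance.  This estimator is
algebraically exact for a gene paired with an identical copy of itself
(the pair then scores precisely the single-gene ρ) and unbiased for
independent genes.  A naive re-estimate from the composite series with the
single-gene correction term would understate pair variances by a factor
(1 − 4/G)/(1 − 2/G) and systematically favour pairs containing one noisy
gene.  Two genes with opposite group effects legitimately score better
together than alone — their composite cancels the group difference — which
is the model's argument for multi-gene normalizers.

log2 is used throughout (not natural log) for consistency with the rest of
the pipeline; stability orderings are unaffected by the base.

## Validation statistics

* **Differential pre-check**: per-assay two-sample t-test between groups,
  Welch (unequal-variance) variant by default since equal group variances
  cannot be assumed for tumour tissue.  The default transform is log10 of
  the Cq value; raw Cq is available, and the two are not interchangeable
  (the double-log transform compresses high-Cq differences), so the
  transform used is recorded in every output row.  Candidates failing the
  pre-check violate the stability models' assumption of non-differential
  reference expression.  No multiple-testing correction is applied to a
  handful of candidate tests; raw p-values are reported.
* **Variance homogeneity**: Bartlett's test across the genes' per-sample
  Cq distributions; a small p-value demonstrates the candidates differ in
  dispersion, i.e. in stability.  A zero-variance gene makes the statistic
  undefined and is reported as an error naming the gene.
* **Equivalence**: mean log2 expression difference between groups with a
  symmetric t-based CI (Welch–Satterthwaite df unpaired; one-sample on
  per-patient differences in paired mode).  Equivalent ⇔ the CI lies
  strictly inside ±log2(fold-change cutoff): cutoff 3 → ±1.58, cutoff 2 →
  ±1.00.  The CI level defaults to 90%, the two-one-sided-tests
  correspondence at α = 0.05, and is recorded in the output.  Shrinking
  the cutoff or widening the CI can only revoke equivalence, never grant
  it.
* **Normality**: one-sample Kolmogorov–Smirnov against a Normal with
  estimated mean/SD, advisory only (estimated parameters make the test
  conservative; it flags, never blocks).  Constant or tiny cells are
  marked untested.

## Target analysis

For each normalizer set: NF → NRQ → Welch t-test on log10 NRQ per target,
with direction (sign of the mean log2 difference, up/down in the case
group) and median fold change.  The side-by-side grid across normalizer
sets makes normalizer-induced masking visible: a "reference" sharing a
target's group shift cancels that target's effect in NRQ, driving the
detected difference toward null regardless of sample size.  Fold changes
are reported alongside p-values because a significant-but-tiny effect and
a masked-but-real one look identical on p alone.

## The simulator

Measured Cq of replicate r, gene i, sample s:

Cq_isr = base_i − shift_i·[s tumour] + u_s + p_plate(s) + e_is + ε_isr

with u_s ~ N(0, sample_shift_sd²) a sample-wide technical shift, p ~
N(0, plate_shift_sd²) a per-plate run effect (plates assigned round-robin
for balance and reproducibility), e_is ~ N(0, intra_sd_i²) the gene's
biological variation per sample, and ε ~ N(0, replicate_sd²) pipetting
noise.  All noise is Normal on the Cq (= log2 abundance) scale, where qPCR
dispersion is approximately scale-free; a positive shift (log2
up-regulation in tumours) lowers tumour Cq.  Values at or above the
detection ceiling (default cycle 40) are emitted as undetected, matching
instrument semantics — a hard censor, not truncation.  Identical
(config, seed) pairs yield byte-identical datasets.

**Default study** (`default_study_config`): 35 tumour vs 39 normal
samples, triplicates, sample shift SD 0.5 cycles, replicate SD 0.15
cycles.  Eight reference candidates span baseline Cq 23.6–31.2 with
intra-group SDs 0.25–1.2 cycles (miRNAs tighter than the snoRNAs, which
serve as the less-stable end of the panel); four targets carry planted
log2 shifts +2, +3, −1, −1 with intra-group SD 0.8 cycles.  These
dispersions are biological variation after technical sample effects are
modelled separately, hence smaller than pooled whole-cohort SDs, which
also absorb group shifts and sample-wide technical scatter.

**Planted-recovery panel** (`planted_recovery_config`): two stable genes
(intra SD 0.2, no shift) among six unstable ones, 20 + 20 samples.  Each
unstable gene is both noisy (intra SD 1.2) and dysregulated (±1.5 log2),
with shifts balanced three up / three down.  The balance matters: the
model-based stability measures deviation from the panel-average group
contrast, so an unbalanced panel penalizes genuinely stable genes, and a
single low-noise up/down pair would itself be the model-true best
normalizer (its effects cancel).  With the balanced design the planted
pair is the true optimum, and both algorithms recover it in ≥95% of
seeded runs.

**What the simulator does not emulate**: probe chemistry and primer
effects, amplification-efficiency variation between samples, spatial
plate effects, correlated biological co-regulation between genes, RNA
quality gradients, and non-Normal heavy-tailed outliers.  Passing tests
therefore demonstrate correctness of the estimators under the declared
noise model, not robustness to every artefact of real instruments.

## Numerical conventions

n−1 SDs everywhere; strict inequalities at declared thresholds (replicate
SD 0.3, Cq < 35, V < 0.15, CI strictly inside the bound); variance
estimates clamped at 0, never at an epsilon; all ties broken by documented
keys ending in the assay name, so every ranking is deterministic;
undetected values propagate as undefined (NaN), never as zeros, and
complete-case rules are stated per stage.  Problem sizes in the test suite
(20–100 seeds for Monte-Carlo properties, 1000 for the type-I calibration,
panels of 3–8 genes) were chosen to make sampling error comfortably
smaller than the margins being asserted.
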