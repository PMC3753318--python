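# Methods

## Model

The scan detects positive selection at candidate loci by contrasting
within-species polymorphism with divergence to an outgroup across loci
(the multilocus HKA framework), in a maximum-likelihood form.  For locus
*i* with `n_i` sampled sequences, `L_i` analysable sites, `S_i` segregating
sites and mean outgroup divergence `D_i` (rounded to the nearest integer for
the Poisson likelihood; the exact mean is retained on the data object):

    S_i ~ Poisson(k_i · θ_i · a_{n_i}),    a_n = Σ_{j=1}^{n-1} 1/j
    D_i ~ Poisson(θ_i · (T + (1 + k_i)/2))

`θ_i` is the whole-locus population mutation parameter (per-site θ × L_i
folded into one free parameter per locus), `T` the species divergence time
in units of 2N generations shared across loci, and `k_i` a dimensionless
selection parameter scaling the focal population's coalescent depth; the
`(1 + k_i)/2` term carries the ancestral-polymorphism contribution to
divergence.  The neutral model fixes all `k_i = 1` (free parameters:
θ_1..θ_m, T); the selection model frees `k` at one focal locus within
[1e-4, 100].  The likelihood-ratio statistic `2(lnL1 − lnL0)` is referred to
χ² with `df = 2` by default.  A single free selection parameter would argue
for `df = 1`; `df = 2` is the convention of the study design this package
reproduces, and makes the test conservative (measured null rejection ~0.02
at α = 0.05).  `lrt_df` is a configuration knob.

Assumptions: infinite-sites mutation (indel/missing columns removed before
counting), free recombination between loci, independence of S and D given
the parameters, a single outgroup sequence, and pools analysed separately
(each pool's test re-estimates its own T, since each pool is a separate
dataset).

## Fitting

Given `(T, k)`, each `θ_i` has a closed-form Poisson MLE
`θ̂_i = (S_i + D_i) / (k_i a_{n_i} + T + (1 + k_i)/2)`, so the likelihood is
maximized on its 1-D (neutral) or 2-D (selection) profile surface in log
space: a moment-based start plus seeded random restarts (default 8),
L-BFGS-B with a Nelder–Mead polish on non-success, `ftol` 1e-12.  θ is
floored at 1e-8 so expected counts stay positive at S = D = 0.  Restarts
make the fit deterministic for a fixed seed.  Standard errors come from the
numerical observed-information matrix on the log scale, delta-mapped back;
they are NaN when `k̂` sits on a bound.  A selection fit falling below its
nested neutral fit by more than 1e-6 draws a warning and the LRT clamps at
zero.  An exhaustive refined grid search over all free parameters is kept in
the test suite as the optimizer's oracle.

## Diversity statistics

S, π (mean pairwise difference per site), Watterson's θ_W = S/(a_n·L_net),
haplotype counts and outgroup divergence are computed after *complete
deletion*: every column carrying a gap or N in any sequence of the analysis
set is dropped.  Whether the original per-locus tables used complete or
pairwise deletion is not documented in the source study; complete deletion
(the DnaSP default) is adopted, with the site set for one HKA test taken
jointly over the pool *plus* the outgroup so that S and D share a common
L_net.  Per-pool summary statistics (the Table-style TSV) use pool-only
deletion.  Multi-allelic columns count once in S; divergence counts raw
mismatches (a Jukes–Cantor correction is available as `jc_correction`,
default off, since the likelihood operates on raw counts).  IUPAC ambiguity
codes other than N are read as missing rather than rejected — Sanger data
routinely contain them.

## Scan pipeline

1. **Panel validation.** Each putatively neutral locus is tested leave-one-
   out against the rest of the panel; the panel passes when no locus has
   p < α.  Failures are warnings by default (`strict_panel` raises).
2. **Candidate tests.** Each candidate × pool test fits the 7 neutral loci
   plus the focal candidate.  Fit failures produce NA rows, never abort.
3. **FDR.** Storey q-values across all candidate tests jointly (81 in the
   default design).  Per-pool stratification is available; joint correction
   is the default because it reproduces the published significant-locus
   count.
4. **Timing.** With α = 0.05 on raw p-values (q-value-based classification
   available): landrace AND improved significant → domestication; improved
   only → improvement; wild significant → flagged as an anomaly (selection
   is measured relative to wild ancestry); anything else → none.  A pool
   only contributes when its `k̂ < 1`: timing dates *positive* selection, so
   significant diversity excess does not date a sweep.  The marginal band
   0.05 < p ≤ 0.10 is annotated separately.
5. **Variant screen.** At FDR-significant loci, fixed non-synonymous
   differences involving the cultivated pools are listed with the cultivated
   allele's frequency among wild sequences; "fixed" requires monomorphism
   over at least `min_called` (default 4) non-missing calls per pool.
   Codon effects use the standard genetic code on the majority-base codon
   context; gap columns are reported structurally as indels, never
   classified synonymous/non-synonymous.

## FDR estimation

π0 is estimated as `π̂0(λ) = #{p > λ}/(m(1 − λ))` on λ = 0.05…0.90 step
0.05, smoothed by a cubic polynomial fit and evaluated at λ = 0.90, clamped
to (0, 1] (with m < 10 the smoother is unreliable and a fixed λ = 0.5
estimator is used, with a warning).  q-values are the step-up minima
`q_(i) = min_{j ≥ i} π̂0 · m · p_(j)/j`; with π0 = 1 they equal
Benjamini–Hochberg adjusted p-values exactly.  On the bundled 81 published
P-values the smoother exceeds 1 and clamps to π0 = 1.0.  Printed "0.0000"
P-values are floored at 1e-5 when re-analysed: a χ² tail probability cannot
be exactly zero, and four printed decimals bound the truncation at 5e-5.

## Synthetic data

`simulate_counts` draws (S, D) directly from the Poisson model above with
θ_i = θ_site·L·bottleneck(pool) — the exact generative twin of the fitted
likelihood, used for calibration (type-I error, power, parameter-recovery)
experiments.

`simulate_alignment` builds sequence alignments under a standard
n-coalescent with infinite-sites mutation.  Conventions are fixed in one
place: θ = 4Nμ per site, time in units of 2N generations, mutation rate
θ_site·L/2 per lineage per unit time.  Within-pool genealogies are drawn
independently per pool with branch lengths scaled by bottleneck(pool) × k —
the same per-pool independence the likelihood assumes.  Above the pool MRCAs
the pools share one ancestral lineage (pool stems join at the deepest pool
root) which meets the outgroup lineage at height T + Exp(1); all stem and
outgroup mutations accrue at the locus's ancestral (wild-scale) rate.  Two
consequences, both deliberate:

* E[D] = θ_site·L·(T + 1) for every pool, *not* scaled by the bottleneck.
  Within one pool the resulting uniform divergence scale is absorbed into
  that pool's T̂, leaving the across-locus contrast — what the test uses —
  intact.
* Fixed differences *between* ingroup pools arise only on the short
  pool-specific stems and stay rare, as in real derived gene pools.

Sweeps are modelled as coalescent-depth scaling (k < 1), not explicit
hitchhiking trajectories — matching what the test detects.  Every mutation
consumes a distinct alignment column (a hard error suggests increasing L if
columns run out), so all segregating columns are bi-allelic.  Optionally a
fixed non-synonymous difference (AAA→AGA, Lys→Arg) is planted in a CDS
codon: fixed in the improved pool, at 1/8 frequency in the wild.  All
randomness flows from `SimConfig.seed` through `SeedSequence` spawns;
outputs are bit-identical across runs.

Default study conditions mirror the target design: 7 neutral + 13
domestication + 14 improvement loci, 8/6/6 wild/landrace/improved samples
plus one outgroup, L = 700 bp (the surveyed amplicons span ~500–1,000 bp),
θ_site = 0.01 in the wild (the neutral wild mean in the published table is
~0.016; 0.01 is a round per-site value in the observed range), T = 8
(divergence ~9× wild diversity, matching the observed D/θ scale), genome-
wide bottleneck factors 0.6 (landrace) and 0.5 (improved) from the observed
neutral landrace/wild and improved/wild diversity ratios, and sweep factor
k = 0.05 at selected loci (domestication loci swept in landrace + improved,
improvement loci in improved only).

What the generator does **not** emulate: recombination within loci,
migration/introgression, shared standing variation between derived pools
(each pool's genealogy is independent below its MRCA), sequencing error and
missing data.  Passing recovery tests therefore demonstrate that the
pipeline detects coalescent-depth reductions under its own modelling
assumptions, not robustness to demographic misspecification.  On coalescent
sequence data the Poisson likelihood ignores genealogical variance in S and
D, so per-test p-values are anti-conservative relative to the count-twin
calibration — a property shared with the original method; the conservative
df = 2 convention and FDR control absorb part of it, and the end-to-end
recovery experiment quantifies the rest.

## Experiment sizes

Calibration and recovery experiments use 500 null count datasets (type-I
error), 200 swept count datasets (power), and 15–20 replicate full studies
(~400–540 planted sweeps) for end-to-end timing recovery; per-study recovery
varies substantially (sd ≈ 0.12) because all tests within a pool share one
neutral panel, so aggregate rates are reported over replicate studies.

## Known limitations

* D is rounded to an integer for the Poisson likelihood (single-outgroup
  design); sub-integer information is discarded.
* The timing rule has no class for landrace-only significance; such loci
  report `none`.
* π0 smoothing uses a cubic polynomial rather than a smoothing spline with
  df = 3; on the 81-test design both saturate at the clamp.
* The original study's "novel variant" screen is not operationalized; only
  the two stated filters (fixed non-synonymous; wild frequency < 20%) are
  implemented.
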