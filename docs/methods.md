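# Methods

This note documents the models, estimators and numerical choices behind
`endopop`, and what the synthetic-data generators do and do not emulate.

## Haplotype copying model (painting)

A recipient haplotype is modelled as an imperfect mosaic of a panel of `D`
donor haplotypes (Li–Stephens). The hidden state at site `t` is the donor
being copied; between adjacent sites separated by `g` cM the donor is
retained with probability `exp(-ρ g / 100)` and otherwise a new donor is
drawn uniformly from the panel (a "switch" may land on the same donor).
The observed allele differs from the copied donor's allele with probability
`θ` per site. The two parameters are:

* `switch_rate` (ρ) — switch intensity per Morgan. Larger values produce
  shorter copied segments. Default 50/Morgan when not fitted.
* `emission_mismatch` (θ) — per-site copying error, in [0, 0.5). Default
  0.01.

Posteriors come from the forward–backward algorithm with per-site
rescaling; the scale factors accumulate the log-likelihood, so no recursion
underflows even at 10⁵ sites (unit-tested). Recipients sharing a donor
panel are processed as a single batch, which is what makes the dating
pipeline tractable on one CPU.

Per recipient and donor group the engine reports the expected copied length
(posterior mass × half-interval cM site weights) and the expected segment
count: one segment opens at the first site of each chromosome, and every
posterior switch expectation that lands on a *different* donor haplotype
opens another. A switch that re-selects the current haplotype is invisible
in the copy path and is therefore not counted as a segment boundary,
although it does count toward the E-M switch-rate statistic (it is a
realization of the transition process). `average_segment_size` = total
copied cM / total expected segments; within-group paintings of a
low-diversity group yield larger values.

Both parameters are re-estimated jointly by E-M (default 10 steps): the
E-step accumulates expected switch counts per inter-site gap and expected
allele mismatches; the M-step solves the one-dimensional switch-rate
likelihood by bounded scalar optimization (log₁₀ ρ ∈ [−3, 4]) and sets θ to
the expected mismatch fraction. The observed-data log-likelihood is
non-decreasing across steps (tested). Initialization is deterministic:
ρ₀ = 100 · D / total cM, θ₀ = 0.01. This parameterization is deliberately
simpler than CHROMOPAINTER's; fitted values are internally consistent but
not directly comparable to CHROMOPAINTER's Mut/Ne parameter scales.

Leave-one-out protocol: a recipient is never its own donor, so when its
group is among the donor groups that group contributes `n_k − 1`
individuals; a singleton recipient group disappears from the donor set
(logged) rather than erroring, so self-copying can never inflate profiles.

Posterior path samples are drawn by standard backward sampling from the
stored forward messages; empirical per-site group frequencies converge to
the forward–backward marginals (tested at 5,000 samples against exact
marginals, and both are tested against exhaustive path enumeration on
instances with ≤ 4 donors × ≤ 6 sites).

## Profile distances

Painting profiles `f_k` are copied-length shares per donor group (rows sum
to 1; individual profiles are renormalized after self-exclusion). For
groups X, Y over the same donor set:

* `TVD_XY = 0.5 Σ_k |f_kX − f_kY|` — half L1 distance, a metric on the
  simplex (property-tested).
* `TVD~_X = 0.5 Σ_i (L_i/L) Σ_k |f_ikX − f_kY|` — X's per-chromosome
  profiles against Y's genome-wide profile, weighted by chromosome SNP
  counts L_i. The cross-group form (X's chromosome slices against Y's
  genome-wide profile) is the statistic's standard definition and is kept
  even though a within-group form might be intuited.
* `F_XY = TVD_XY / (0.5 (TVD~_X + TVD~_Y))` — because each chromosome
  drifts independently, within-group chromosome scatter measures how much
  distance recent drift alone could generate; dividing by it attenuates
  differences due to isolation rather than distinct ancestry. F = 0 for
  identical profiles; F = 1 when both groups' chromosomes are internally
  homogeneous.

`fit_surrogate_mixture` decomposes a target profile as a convex combination
of surrogate profiles by non-negative least squares with a strongly
weighted sum-to-one row (weight 10⁴); weights below 0.001 are zeroed and
the rest renormalized. This replaces a Bayesian mixture posterior whose
role is only to select contributing surrogates; the sparsity pass
reproduces that selection behaviour deterministically.

`f3_statistic(X; A, B)` = mean over sites of `(x−a)(x−b) − h_x/(2n_x−1)`
with `h_x = x(1−x)` and `n_x` diploid target individuals — the correction
is the unbiased estimator of Var(x̂), removing the finite-sample bias that
otherwise makes f3 spuriously positive. Standard errors come from a
leave-one-block-out jackknife over contiguous cM windows (default 5 cM;
equal-weight jackknife formula, adequate for near-equal blocks), and
Z = f3/SE. Z < −2 with f3 < 0 is the admixture signal.

## Coancestry curves and admixture dating

For sampled painting paths, the curve for surrogate pair (a, b) bins every
ordered within-chromosome site pair by cM separation (default 1–50 cM,
0.1 cM bins → 490 bins) and accumulates the symmetrized indicator that one
site copies a and the other copies b, divided by the expectation under
independence (product of genome-wide marginal copying rates). Empty bins
are flagged missing and excluded. All path samples are weighted equally.

After a single admixture pulse g generations ago, ancestry-block sharing
decays as `exp(−g d)` in d Morgans, so the curve follows
`y(d) = A · exp(−λ d/100) + c` with λ (per Morgan) read directly as the age
in generations. Cross-source pairs (a ≠ b) are *depressed* at short range —
nearby segments tend to share a source — so their amplitude A is negative;
the decay rate is unaffected. Fitting is conditional-linear least squares
over a λ grid (1…200, step 1) followed by Levenberg–Marquardt refinement;
deterministic. If refinement fails the grid solution is reported with a
non-convergence flag.

"No admixture signal" is declared when λ ≤ 0, when |A| is numerically zero,
or when |A| < 2 standard errors of A — a flat noisy curve yields a
sign-indefinite amplitude about half the time, so a pure sign test cannot
deliver the required specificity; the 2-SE gate flags ≥ 95% of unadmixed
replicates while never flagging clear signals (tested).

Dates above 60 generations trigger an automatic refit on a 1–10 cM curve
with 0.05 cM bins (short-range bins carry the information about fast
decays); the refit is reported and marked.

Confidence intervals use a hierarchical bootstrap (default 100 resamples):
whole chromosomes *and* recipient haplotypes are independently resampled
with replacement, the curve re-binned from stored per-chromosome,
per-recipient components, and refit; the interval is
`date ± t₀.₉₇₅,(n_chrom−1) × SD` of the bootstrap dates. Two design points
were driven by measured coverage on simulated truth: a plain 2.5/97.5
percentile interval over chromosome-only resamples covered the true age
only ~82–90% of the time (chromosome-only resampling holds the sampled
individuals and their paths fixed and so understates the variance, and
percentile intervals are themselves anti-conservative with ~10 resampling
units); resampling both axes with the t-interval restores nominal-or-better
coverage. λ is invariant to rescaling the curve and to bin width on
noiseless input (both tested).

The `paint_and_date` pipeline chains E-M parameter fitting (on a 5-recipient
subset), path sampling (10 samples per haploid genome), curve construction
and the fit. Fitting the painting parameters matters: a switch rate fixed
too high (120/Morgan) inflates the recovered date by ~2.5 generations,
because spurious fast label switches add a fast-decaying component to the
curve; E-M settles near the generative rate and removes most of that bias.

## Uniparental statistics

* **Gene diversity**: Nei's unbiased `h = n/(n−1)(1 − Σp²)` with sampling
  variance `V(h) = 2/(n(n−1)) {2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²}`
  (validated against a bootstrap at n = 500 within 20%); two-tailed z test
  helper for comparing populations.
* **Φ_ST**: AMOVA variance components on identity (0/1) distances between
  haplotypes or haplogroup labels, computed directly from count vectors.
  Negative values are reported as computed. The permutation p (default
  10,000 relabellings, +1 smoothing) shuffles individuals across
  populations; table columns are first put in a canonical order so the
  permutation stream — and hence p — is invariant to category relabelling.
* **Exact test of differentiation**: Markov chain over contingency tables
  with fixed margins. The proposal swaps the categories of two individuals
  drawn from different populations; for this proposal the
  Metropolis–Hastings ratio against the multivariate hypergeometric target
  is exactly 1, so every move is accepted. Burn-in 1,000 steps, no
  thinning, default 10,000 steps; p = fraction of visited tables whose
  conditional probability (tracked incrementally via log-factorials) does
  not exceed the observed table's. Agrees with Fisher's two-sided exact p
  on every 2×2 table with total ≤ 20 (acceptance-tested) and is
  approximately uniform under a multinomial null.
* **PCO**: classical principal coordinates of the similarity matrix
  S = 1 − F_ST with diagonal `n_i/(n_i − 1)` (the Φ_ST self-similarity of a
  sample against a copy of itself); double-centering + eigendecomposition;
  negative eigenvalues are reported but their axes excluded from the
  default coordinates.
* **Admixture posterior**: the hybrid's counts are multinomial with
  frequencies `p f_A + (1−p) f_B`, parental frequencies Jeffreys-smoothed
  (+0.5), uniform prior on a 1,001-point grid over p; mode, median, mean
  and central 95% credible interval are reported. Post-admixture drift is
  *not* modelled (a deliberate simplification of coalescent-based
  likelihood methods): credible intervals are calibrated under the drift-free
  generative model (coverage-tested) but will undercover when strong drift
  separates the hybrid from its parental frequency sources.
* **Modal haplotype / ASD TMRCA**: the modal (most frequent) full STR
  haplotype within a haplogroup is the inferred ancestral state; a tie is a
  hard error and a winning frequency ≤ 0.5 is flagged so callers can apply
  the high-frequency-modal restriction. ASD is the mean squared repeat
  difference over all chromosome × locus cells (equivalent to per-locus
  averaging for complete data); under the single-step stepwise mutation
  model on a star genealogy E[ASD] = μt, so `t̂ = ASD/μ` with
  μ = 15/7,856 per locus per generation by default. The 95% CI is a
  parametric Monte-Carlo (default 50,000 iterations): datasets of the same
  shape are simulated at t̂ (mutation counts Poisson(μt̂) per cell, ±1 steps
  symmetric) and the 2.5/97.5 percentiles of the re-estimated dates are
  reported. Pooled mode: squared differences from both clusters' own modals
  are averaged into one joint date. Mutation-rate-uncertainty mode divides
  each simulated ASD by a rate drawn from Beta(15.5, 7841.5), the Jeffreys
  posterior for 15 mutations in 7,856 meioses. Generations convert to years
  by exact multiplication with a 28-year generation time.

## Selection scans

EHH at distance d from a core site is the probability that two haplotypes
drawn without replacement are identical over the whole stretch core→d
(classes at the core itself are the core-allele classes). iHH integrates
EHH outward by the trapezoid rule in genetic distance until EHH < 0.05
(cutoff default); a site whose integration runs off the chromosome edge or
crosses an inter-site gap > 0.2 cM is flagged and excluded. XP-EHH =
ln(iHH_A/iHH_B), normalized to mean 0/SD 1 over the scan's valid sites
(single genome-wide bin, the statistic's original construction; no
frequency binning). The cutoff and gap guard are package defaults, chosen
as conventional scan guards; they are not tuned to reproduce any particular
cohort's thresholds.

Significance thresholds are permutation-based: diploid individuals (both
haplotypes moving together) are repeatedly re-partitioned at random into
two groups of the original sizes, the scan re-run, and all permuted
normalized scores pooled; thresholds are the ⌈qN⌉-th smallest pooled values
at q = 0.0001 and 0.9999 (defaults). On exchangeable data the observed and
permuted score distributions coincide, and the procedure declares ~0.02% of
sites significant (calibration-tested).

## Synthetic data

Generators are pure functions of (arguments, seed) — bit-identical under
the same seed — and every generated object satisfies its container's
invariants (tested).

* **Source panels**: ancestral frequencies uniform(0.05, 0.95); population
  frequencies are Balding–Nichols Beta deviates with F = `divergence`, so
  two panels have pairwise F_ST ≈ F (checked against a Hudson estimator at
  F = 0.1 ± 0.02). Haplotypes are drawn site-independently and smoothed by
  a copying pass — each final haplotype is a recombinant mosaic of the
  independent founders at 20 switches/Morgan — which induces the local
  haplotype sharing that painting and EHH statistics require. No external
  coalescent simulator is used: this construction controls differentiation
  and haplotype-sharing scale directly at desk scale.
* **Admixed chromosomes**: Poisson(g per Morgan) breakpoints placed
  uniformly in genetic distance; each segment is labelled source A with
  probability α independently and copies one random haplotype of that
  panel. Expected A-fraction = α; segment lengths exponential(g/Morgan).
* **STR sets**: per generation × locus, mutation with probability μ moves
  the repeat ±1 (reflected upward at repeat 1, logged); E[ASD from the
  ancestor] = μt (tested at t = 35 within 10%).
* **Haplogroup counts**: multinomial draws from `p f_A + (1−p) f_B`.

What the generators do **not** emulate: demographic history (growth,
migration, bottleneck timing), array ascertainment, genotyping error,
phasing error, multi-step STR mutations, or post-admixture drift. Passing
recovery tests therefore demonstrates correctness of the estimators under
their own model assumptions — not robustness to the violations real cohort
data would add.

## Problem sizes and defaults used in the shipped checks

The recovery and calibration suites run at sizes chosen to exercise every
code path on a single CPU: admixture dating at g = 30, α = 0.25, 100
admixed haplotypes, 10 chromosomes of 100 cM with 800 sites each (8
sites/cM; denser maps reduce painting label noise and its small upward
date bias), 2 × 40 donor haplotypes, divergence 0.3 (the dated sources in
this kind of analysis are strongly diverged surrogates), 30–40 replicates;
XP-EHH calibration at 60 haplotypes × 300 sites × 40 permutations; exact
test at 4,000 chain steps per table over all ~2,600 canonical 2×2 tables;
posterior coverage at 200 replicates of n = 200. Larger inputs are
generated at run time, never stored.

## Known limitations

* Painting-based dates carry a small upward bias (≲ 1 generation at the
  sizes above) from residual label-switch noise; the full
  GLOBETROTTER-style null-individual standardization that removes it is
  out of scope.
* The copying model is a simplification of CHROMOPAINTER (no per-donor
  rates, no recipient-specific normalization); fitted parameters are not
  comparable across tools.
* The exact-test p and Φ_ST permutation p are Monte-Carlo estimates;
  their precision is set by the step/permutation counts.
* The admixture posterior ignores drift since admixture and treats parental
  frequencies as estimated from the given samples only.
* Multi-allelic sites, missing genotypes and unphased data are rejected by
  design; the package never imputes.
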