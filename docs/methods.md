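# Methods

## Sampling frame and null model

All computations condition on a 2×2 table with fixed margins: `N` sites,
of which `m_A` hold entity A and `m_B` hold entity B, with co-occurrence
count `X = a` supported on `max(m_A + m_B − N, 0) … min(m_A, m_B)`.  The
modelling assumptions are: sites are exchangeable, the two entities select
sites independently under the null, margins are fixed by design, and
occurrences are observed without error.  Under those assumptions the null
law of `X` is hypergeometric(`N`, `m_A`, `m_B`); the package takes this
from `scipy.stats.hypergeom`.  The null mean is `m_A·m_B/N`; the null sd is
computed by direct summation over the support rather than a closed form,
so degenerate margins need no special-casing.

## Affinity model

The alternative family tilts the null by `e^{αk}` (the extended, or Fisher
noncentral, hypergeometric).  All masses are computed in log space:
log-binomials via `gammaln`, normalisation by `logsumexp`, which keeps the
computation stable for `N` in the hundreds and `|α|` up to the truncation
cap.  The margin pair is put in canonical (sorted) order before the
weights are formed; the family is provably role-symmetric, and
canonical ordering makes that symmetry hold bit-for-bit.  Requests outside
the support return probability 0 rather than raising, which simplifies
vectorised callers; degenerate margins (an entity everywhere or nowhere)
give a single-point support, flagged so that estimation can refuse
cleanly.  Moments are computed by exact summation only; no closed-form or
normal approximations are used anywhere.

## Estimation

The log-likelihood is a natural exponential family in α, hence log-concave,
and the MLE for an interior count solves `E_α(X) = k`.  The solver is
Brent root-finding on `[−log(4N²), +log(4N²)]` with default tolerance
1e−10 on α; strict monotonicity of the mean guarantees the bracket.
Boundary counts (`k = k_min` or `k_max`) have no finite maximiser and are
reported as `± log(4N²)` — twice the `log(2N)` cap that a Jeffreys
beta(½, ½) prior implies for a single binomial log-odds — with an explicit
`is_boundary` flag.  Downstream code must not average truncated and
interior estimates without consulting that flag; the pipeline propagates
it into its output schema.  No prior-based shrinkage is applied to
interior estimates.

Interior estimates additionally obey the finite-estimate cap

    |α̂| ≤ log(2 (N − min(m_A, m_B) − 1) · min(m_A, m_B)) ≤ log(2N²).

A commonly quoted variant of this cap uses `N − max(m_A, m_B) − 1` in the
first factor; that version is false — for `N = 9, m_A = 2, m_B = 7, X = 1`
the MLE is exactly `−½·log 21 ≈ −1.522`, exceeding its `log 4 ≈ 1.386` —
so the package uses the `min`-based form, which we verified for every
interior table with `N ≤ 30` (exhaustively) and on ~11,000 randomised
tables up to `N = 500` (worst observed tightness ratio 0.885).

### Confidence intervals

Three methods, labelled in `method_info`:

* `midp` (default): Cornfield-style tail inversion with the observed
  point's mass half-weighted.  Strict exact inversion is guaranteed
  conservative on a discrete support and its exact coverage at, e.g.,
  `N = 200, m_A = m_B = 80, α = 0` is 0.973 for a nominal 0.95; the mid-P
  variant's exact coverage at the same margins is 0.944–0.964 across
  `α ∈ [−2, 2]`, tracking the nominal level much more closely.  That is
  why mid-P is the default.
* `tail`: the strict exact inversion, for users who require guaranteed
  ≥ nominal coverage.
* `lrt`: profile-likelihood inversion at the χ²₁ critical value.

All intervals are clamped to `± log(4N²)`, matching the point-estimate
truncation convention; boundary counts give one-sided intervals ending at
the truncation value.

### Exact test

`null_p_value` defaults to the minimum-likelihood two-sided rule (sum of
null masses not exceeding the observed mass, with a `1 + 1e−7` relative
tie tolerance, as in standard exact-test implementations); doubling of the
smaller tail is available as `method="doubled"`.  The two conventions
differ on asymmetric supports; neither is canonical, so both are exposed.

## Similarity indices and their null distributions

`J = a/(a+b+c)`, `Dice = 2a/(2a+b+c)` and the Simpson overlap
`a/(a + min(b, c))` are the standard forms.  Indices at `0/0` (neither
entity occurs, or for Simpson a rarer entity that occurs nowhere) are
typed-undefined errors, never silently 0.  Because each index is monotone
in `a` at fixed margins, its exact null distribution is the image of the
hypergeometric under the index map; `index_null_distribution` tabulates
it, with the CDF using the `≤ t` convention, and derives the exact null
mean/sd (for standardized indices), attainable range, and the
median-crossing value — the smallest attained index value whose null CDF
reaches 0.5.  The `median_crossing_bracket` helper returns the two
attained values straddling the 0.5 crossing; for the affinity estimate
used as an index this bracket straddles 0 at every prevalence, while for
Jaccard the crossing wanders by more than 0.2 across prevalence regimes —
the package's core demonstration.

The centering algebra: substituting the null mean `m_A·m_B/N` into
`a/(m_A + m_B − a)` gives a value near `h` exactly when
`N/m_A + N/m_B ≈ (1 + h)/h`.  `centering_pairs` enumerates all margin
pairs (canonical order `m_A ≤ m_B`) within a tolerance of that target,
sorted by deviation.  For `h = 0.5` the target is 3, hit at `N = 100` by
(65, 67), (56, 82), (58, 80), (64, 71), (53, 91) among others.

## All-pairs pipeline

Input orientation is fixed as sites-in-rows, entities-in-columns, with a
`transpose` escape hatch — what plays the role of a "site" is
application-specific, so orientation is never guessed.  Non-binary cells
are an error naming the offending cell, or thresholded at 0.5 on request.
Degenerate entities are kept and flagged (`degenerate` column, NaN
estimates) rather than dropped: in low-prevalence applications boundary
and degenerate pairs are common, and silently dropping them biases any
summary.  No multiple-testing correction is applied by default; a
Benjamini–Hochberg column (`p_null_bh`, via statsmodels) can be requested.
The pair-table CSV schema is versioned (`PAIR_TABLE_VERSION = 1`) with a
fixed column order.  A `max(α̂) − α̂` dissimilarity transform is exported
for downstream clustering tools as labelled plumbing; clustering itself is
out of scope.

## Simulator

`simulate_occupancy` realises the generative story directly: A occupies
`m_A` uniformly chosen sites; B occupies each site independently with
probability `p₁` (A present) or `p₂` (A absent), implying
`α = log[p₁(1−p₂)/(p₂(1−p₁))]`.  With `conditioning_m_b` set, B's total is
fixed by exact two-stage sampling — draw `k` from the extended
hypergeometric at the implied α, then place `k` occurrences uniformly
among A-sites and `m_B − k` among the rest.  This is the exact conditional
law, so no rejection loop is needed and extreme α costs nothing.
`sample_cooccurrence_count` draws counts by inverse-CDF over the tabulated
support.  All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, one independent substream per
replicate, so results are bit-reproducible.

What the simulator emulates is exactly the model's assumptions: no spatial
autocorrelation, no detection error, no more than two entities per
generative run.  Tests passing against it therefore validate the
estimation machinery, not the fit of the model to any field data.

## Problem sizes and tolerances in the test suite

Exhaustive sweeps use `N ≤ 25` (null reduction, to 1e−12 absolute),
`N ≤ 20` (MLE vs dense-grid likelihood search, step 1e−4 over [−15, 15],
agreement 1e−3; and p-values vs exact rational enumeration), `N ≤ 30`
(finite-estimate cap) and `N ≤ 50` (null-centering sandwich).  Stochastic
checks use fixed seeds with tolerances stated beside each assertion:
50,000-draw goodness-of-fit at the 0.001 level, 20,000-replicate
two-sample equivalence of the two conditional constructions, and
2,000-replicate recovery at `N = 200, m_A = m_B = 80` for
`α ∈ {−2, 0, 2}` (median error ≤ 0.15, 95% CI coverage within
[0.93, 0.97]).  The arbitrary-precision summation oracle (mpmath, 60
digits) lives in the test suite only.

## Known limitations

* Estimation conditions on both margins; it does not model margin
  uncertainty (no unconditional MLE).
* The truncation value `log(4N²)` is a reporting convention for infinite
  estimates, not a statistical estimate; comparisons between truncated
  values carry no likelihood meaning beyond their sign.
* Mid-P intervals do not guarantee ≥ nominal coverage for every
  configuration (use `ci_method="tail"` when that guarantee matters).
* The `min`-based finite-estimate cap is verified exhaustively at small N
  and by large randomised sweeps, not by a published proof.
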