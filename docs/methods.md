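# Methods

## The statistic

For a community `C` of richness `k` resolved against a regional pool of
`n` scored species, the permutational DBI potential is

```
potential(C) = P( DBI_sum(R) < DBI_sum(C) )
```

where `R` is a random `k`-subset of the pool drawn **without
replacement** with per-species probability weights `w_i = x^(−DBI_i)`.
It is estimated by Monte Carlo with `n_perm = 10,000` draws by default;
draws whose sum *ties* the observed sum are tallied (`n_equal`) but are
excluded from the numerator. The strict inequality makes the boundary
behavior exact rather than statistical: a community attaining the
minimum possible `DBI_sum` for its richness has potential exactly 0
under every seed. A mid-p variant (`mid_p=True`, adding half the ties)
is available but is not the default.

## The sampling scheme

"Weighted sampling without replacement" is ambiguous in general; this
package uses the *successive* scheme: species are drawn one at a time,
each draw with probability proportional to the weights of the species
still remaining. This is the behavior of the standard unequal-probability
sampling routines in statistical environments. Internally the draw is
vectorized through the exponential-race equivalence: with independent
`E_i ~ Exponential(rate = w_i)`, the `k` smallest arrival times are
distributed exactly as a successive weighted draw, so all 10,000
permutations reduce to one `(n_perm × n)` array operation. The
alternative reading (conditional Poisson sampling) would assign different
subset probabilities; the choice here is pinned by an exact oracle
(`exact_potential_oracle`) that enumerates all ordered draws — summing
`∏ w_i / (remaining weight)` over every ordering of every subset — on
pools of ≤ 10 species and richness ≤ 4. The test suite requires the
Monte-Carlo estimator to agree with the oracle within three binomial
standard errors at 10,000 permutations on 20 random tiny instances.

With `x = 1` the weights are uniform and the draw reduces to simple
random subsets (verified by a chi-square test over all C(5,3) subsets of
an equal-score pool).

## The weight base x

The weight function presumes species frequency falls by a constant
factor per DBI step. The calibration procedure estimates that factor
from quadrat-occupancy data: each species' occupancy rate is its
occupied-quadrat count divided by the most common species' count; rates
are averaged within distribution-subindex classes 0, 1 and 2 (class 3 is
excluded — such range-edge species occur at atypical frequencies and the
class correlates strongly with the other two subindices); the reciprocal
of the geometric mean of the successive class-ratio pair `R1/R0, R2/R1`
is the estimated base, reported both exactly and rounded to the nearest
integer (round-half-up). Class means of 0.80/0.38/0.18 — occupancy
roughly halving per class — give ratios ≈ 0.475/0.474, an exact base of
2.108, and the default integer recommendation `x = 2`. The
geometric-mean-then-round rule is one defensible operationalization of
"halves per step" and is flagged as a package decision; the exact value
is always reported so users can keep a fractional base.

## Synthetic pool generator

`synthetic_pool(n_species=68, seed, decay=2.0)` emulates a
Central-European-like regional checklist: 68 scored species by default,
with the species count per total DBI value proportional to
`decay^(−value)` and at least one species at every value 0–9. The
per-value counts are apportioned deterministically (largest remainder),
so the rarity gradient is a structural property of the generator rather
than of one random draw; only the subindex splits of each total are
sampled. What it does **not** emulate: real pools have irregular score
histograms, taxonomic structure, and spatial/phenological correlation
between species — so tests passing on synthetic pools demonstrate the
*statistical machinery* (boundary exactness, oracle agreement,
reproducibility), not the numerical values any real checklist would
produce. Scenario sums and potentials on depletion-affected rows are
explicitly pool-dependent.

## Scenario engine

Thirteen benchmark scenarios combine four composition bands — 'A'
(DBI 8–9), 'B' (4–5), 'C' (2–3), 'D' (0–1) — with four richness tiers:
small (2), medium (10), large (20; 21 for the mixed
large-'A'-plus-one-'B' case, forced by its mean of 167/21) and giant
(38). Blocks are filled greedily and deterministically: high bands from
the top of the band downward, 'D' from the bottom upward, ties within a
DBI value broken by checklist order. When a band is depleted the builder
substitutes unused species with DBI values nearest the boundary just
crossed — downward for A/B/C (e.g. DBI 7 species extending a depleted
'A' block), upward for 'D' (the only direction that can make a pure-'D'
community's sum exceed its richness), with above-band values as a last
resort for the high bands. Every substitution is recorded as a
(band, value, count) triple in the results. Ranks over an evaluated
scenario set are dense and descending (1 = most valuable, ties share a
rank) and are computed on full-precision metrics.

## Stability diagnostic

Because the potential is a Monte-Carlo estimate, the reliability check
recomputes it `reps = 100` times per site (default), each repetition
using `n_perm = 10,000` fresh permutations from an independently spawned
child RNG stream, then compares every site pair with a two-sided
two-sample Kolmogorov–Smirnov test (asymptotic p-values; standard at 100
observations per side) Bonferroni-corrected over all `n(n−1)/2` pairs. A
pair is flagged indistinguishable when the adjusted p-value is not below
`alpha` (default 0.05, configurable) **or** when both distributions are
degenerate at the same point — e.g. two sites saturated at potential 1.0
on every repetition — where the asymptotic KS p-value is uninformative.
Raw and adjusted p-values are always reported so users can apply their
own threshold.

## Numerical and design choices

* **RNG.** All stochastic operations accept a seed or a
  `numpy.random.Generator`; one generator can be threaded through a whole
  analysis (`DBIAssessment.fit` does this across sites), and repetition
  streams are spawned via `SeedSequence` so results are exactly
  reproducible from the master seed.
* **Degenerate richness.** A community spanning the entire pool is
  permitted with a warning; every permutation then equals the community
  and the potential is exactly 0.
* **Display precision.** `DBI_mean` is displayed to 2 decimals and the
  potential to 3 (`summary()`, CLI); computation and ranking always use
  full precision.
* **Missing checklist scores** are excluded with a warning and a count,
  never imputed; a 73-row checklist with 5 unscored species yields a
  68-species pool.
* **Name matching** trims and collapses whitespace and is
  case-insensitive; original spellings are preserved in output.
  Non-numeric abundance cells are an error rather than silent absence.
* **Vagrant filtering** is deliberately out of scope: no operational
  vagrancy rule exists, so excluding non-resident species is the user's
  responsibility before input.
* **Problem sizes.** Unit tests run reduced Monte-Carlo sizes (hundreds
  to thousands of permutations) where only structural behavior is
  checked; the boundary, oracle-agreement and acceptance computations use
  the full `n_perm = 10,000`. The whole suite completes in a few seconds.

## Known limitations

* The potential saturates at 1.000 for many high-quality scenarios (by
  design — combinatorially few communities outscore them under rarity
  weighting), so it discriminates poorly *among* top-tier sites; the
  stability diagnostic makes this visible via degenerate-pair flags.
* Only the DBI score table ships (via user checklists or the synthetic
  generator); other scoring systems require the user to supply their own
  checklist and, ideally, recalibrate `x`.
* The exact oracle is an enumeration test fixture, not a large-pool
  analytical method.
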