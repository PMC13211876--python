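# Methods

## The route-fusion model

The package models the *route-to-route* map of paired flight, not
moment-to-moment flocking dynamics: when two birds fly together, their joint
route is taken to be a per-time-step convex combination of their preferred
routes, with the experienced bird's share `w ∈ [0, 1]`. Before fusion the
shorter track is linearly resampled to the longer one's point count,
uniformly over its own time span (index-aligned fusion). This abstraction is
deliberate — the available geospatial data cannot separate perceptual,
decision and environmental noise, so the fusion weight is the only behavioural
parameter.

A transmission chain iterates this map: generation 1 is a founder's solo
route; in each generation 2–5 the current experienced route is fused with a
freshly sampled naive bird (sampling with replacement from the population)
and the result propagates. Because every fusion is affine, the share of each
founding bird in any later route follows `c_new = w·c_E + (1 − w)·e_N`
exactly; the package tracks these shares alongside the routes. For
per-time-step weight vectors the time-averaged weight is used in the share
recursion, so vector-weight shares are summaries, not coordinate identities.
Under plain 0.5-averaging the generation-5 shares are 1/16, 1/16, 1/8, 1/4,
1/2 in chain order. Note these sum to one by construction; the popular
intuition that the founder keeps 1/2⁵ = 1/32 double-counts the first fusion —
the first *two* birds each keep 1/16.

## Route efficiency

Efficiency = adjusted beeline / trimmed path length. Trimming removes
circling near the endpoints: the kept segment runs from the **last** exit of
the release-site circle (radius 800 m) to the **first subsequent** entry of
the home-site circle (radius 200 m), with boundary crossing points computed
by exact segment–circle intersection (which makes trimming idempotent). The
adjusted beeline subtracts both radii from the release–home distance — the
unique choice that scores a perfectly straight flight at exactly 1. For
paired flights, efficiency is computed on whichever trajectory is supplied
(typically the fused/joint route).

## Synthetic routes

The generator emulates a population of birds that have already settled on
idiosyncratic routes between sites 8.4 km apart, sampled at 1 Hz at a nominal
20 m/s. Each route's perpendicular displacement field is

* **bird-level bias**: half-sine modes `Σ_k a_k sin(kπ s/B)` with bird-specific
  amplitudes `a_k ~ N(0, (σ_bias/k)²)` — endpoint-anchored, repeatable,
  independent and zero-mean across birds, so averaging cancels error;
* **flight wiggle**: an Ornstein–Uhlenbeck bridge (correlation length 400 m)
  pinned to zero at both sites, giving realistic small-scale tortuosity.

Both scales are calibrated by bisection so the population mean solo
efficiency hits `target_mean_efficiency` (default 0.75 — solo efficiencies of
settled birds are not published as numbers, so this is a configuration
choice, not an empirical one). Per-bird RNG substreams are derived from
`(seed, crc32(bird_id))`, making any chain reproducible regardless of
execution order.

What the generator deliberately does **not** emulate: landmark attraction,
wind, release-site circling (excluded by the trimming zones anyway), GPS
dropouts, and between-bird heterogeneity in route quality beyond what the
random amplitudes produce. Consequences: tests passing on synthetic data
validate the machinery and the qualitative orderings (averaging improves with
generations; the (M−1)/M weight pattern; chains underperform flocks), but
strategy contrasts that depend on the *spread* of real solo efficiencies —
notably how close `all_or_nothing` comes to `averaging` — are not reproduced
quantitatively by a homogeneous synthetic population.

## Weight optimization

Free weights live on a 0.01 grid (`[0.5, 1]` for the nearer-the-beeline
advantage `w_near`), with ties broken toward the smaller weight for
reproducibility. Constant weights are fitted against mean generation-5
efficiency over a fixed set of sampled chains. The per-generation weights of
`maximize_generation` are fitted greedily — generation M is optimized with
earlier generations frozen — which matches the printed 1/M pattern; on
independent zero-mean routes the optimum approaches (M−1)/M because the
experienced route entering generation M is an equal average of M−1 routes and
inverse-variance weighting favours it (M−1):1. A joint four-weight search was
considered and left out: the greedy optimum is the fixed point the iterative
experimental design itself implements.

## Leadership

For synchronized paired tracks, `d_EN(t)` projects the experienced-minus-naive
position onto the pair centroid's next-step direction of motion; the
flight's leadership fraction is the share of steps with `d_EN > 0`. Steps
where the centroid moves less than 0.5 m are dropped (unstable direction) and
exact zeros count half, making the statistic exactly antisymmetric under
swapping the birds. The motion threshold and the zero rule are implementation
choices; only the sign of `d_EN` carries meaning.

## Effective group size

Democratic flocks of size n (equal-weight averages of n distinct routes) give
a mean-efficiency curve fitted as `E(n) = c0 − c1/n` by nonlinear least
squares — the simplest two-parameter hyperbola, consistent with error
variance ∝ 1/n for averaged independent errors, and closed-form invertible:
`n_eff = c1/(c0 − E)`. A Michaelis–Menten-style saturating alternative is
selectable (`form="michaelis_menten"`) for fit comparison. Efficiencies at or
above the asymptote `c0` have no finite equivalent and raise; values beyond
the pool size are flagged as extrapolation.

## Statistical comparison

Route efficiencies are modeled with a fixed-effects beta regression (logit
mean link, constant precision, `generation * dataset` mean structure) via
maximum likelihood; social weights with the analogous linear model.
Strategy-vs-reference effects are Wald contrasts averaged over the observed
generations, reported as odds ratios (efficiency) or mean differences
(weights). Efficiencies at the unit-interval boundary are shrunk with the
standard `(y(n−1)+0.5)/n` transform before fitting.

The dependence induced by reusing the same source birds across simulated
chains is handled by **bird-level bootstrap** contrasts rather than random
effects: birds are resampled with replacement within each dataset ×
generation cell (sample sizes matched to the reference dataset), and
per-generation contrasts get percentile intervals. Two finite-sample
refinements keep the error rates honest at realistic sample sizes:

* intervals use Hesterberg's *expanded percentile* levels — the nominal 2.5 %
  tails widened by the t-quantile and n/(n−1) factors — repairing the plain
  percentile method's narrowness;
* the Dunnett-style familywise adjustment compares each contrast, mapped to
  the normal scale through the t→normal quantile transform at its residual
  df, against the resampled null distribution of the maximum |z| across the
  strategy family (the shared reference draws preserve the many-to-one
  correlation). Simultaneous CIs use the 95th percentile of that max-|z|
  distribution; Bonferroni is available as a conservative fallback, and
  adjusted p-values are never below raw ones.

In null simulations (six strategies vs. one reference, 40 birds per cell,
2000 repetitions) the familywise type-I error of the full
bootstrap-plus-Dunnett pipeline measures ≈ 0.06 at a nominal 0.05, and
the 95 % intervals cover the null in ≈ 95 % of repetitions — both checked in
the test suite.

## Numerical and design choices

* Geographic input is projected to UTM with an in-package WGS84 transverse
  Mercator (zone fixed by the release-site longitude; points more than one
  zone away are rejected). Agreement with independent distance oracles is
  better than 0.1 % at ≤ 20 km.
* Downsampling interpolates linearly onto the 1/f grid and always keeps both
  endpoints; resampling to a longer length is uniform in the track's own time
  span, so upsampling by an integer multiple of the segment count preserves
  path length exactly.
* Exhaustive chain enumeration refuses above 10⁵ sequences and directs the
  caller to seeded sampling; all sampling goes through explicit integer
  seeds, and the pipeline writes identical artifacts for identical configs.
* Degenerate inputs: populations of identical routes make weight objectives
  flat (0.5 is returned with a warning); stationary paired tracks have no
  motion direction and raise; trajectories that never leave the release zone
  or never reach the home zone are trim errors.

## Problem sizes

Default analysis sizes — nine birds, 500 sampled chains for weight fitting,
10,000 bootstrap draws — run in minutes on one core. The test suite and the
acceptance script use these same sizes for the headline checks and smaller
ones (tens to hundreds of chains, hundreds of bootstrap draws) for property
tests, chosen so the full suite completes in about two minutes.

## Known limitations

* Fixed-effects-plus-bootstrap replaces the original random-effects GLMM;
  printed odds ratios from the field data are reproducible only with the
  deposited GPS dataset and that heavier model.
* The `maximize_time_steps` strategy is one admissible reading of
  "the bird nearer the beeline exerts greater influence on average": a single
  fitted advantage `w_near`, not a distance-proportional weight.
* Contribution fractions are exact only for scalar per-flight weights.
* The synthetic population is homogeneous by design; see the synthetic-routes
  section for what that implies about which results transfer to real data.
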