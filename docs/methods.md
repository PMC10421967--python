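# Methods

## The observation problem

A meiotic non-crossover (NCO) event copies a short segment from one
homologous chromosome into the other. It is observable only where the
transmitting parent is heterozygous: each *informative marker* the event
overlaps is converted independently with probability `p` (the
*penetrance*), and the set of converted markers from one event is a *gene
conversion tract*. Events that convert no marker are invisible, so the
observed tracts are a length-biased, incomplete sample of the underlying
events, and neither the number of NCO events nor their length
distribution can be read off the tracts directly.

## Model

An event is `(L, M, C, R)`: integer length `L >= 1`, start `M` uniform
over every placement that keeps the event inside one chromosome, and a
transmitting parent `R` drawn proportionally to per-parent meiosis
counts. Conditional on the placement, each overlapped informative marker
converts independently with probability `p`. Two tabulated functions
summarise the observation process:

* the **detection function** `D(x) = Pr(S != 0 | L = x)` — the average
  over placements of `1 - (1-p)^n`, `n` the number of overlapped markers;
* the **tract function** `T_t(x) = Pr(O = o_t | L = x)` — the placement
  average of `p^|s_t| (1-p)^(n - |s_t|)` over windows containing the
  tract `t`.

Conditioning on detection gives, for any length pmf `f`,

    Pr(O = o_t | S != 0) = sum_x T_t(x) f(x) / sum_x D(x) f(x),

and the likelihood of a tract set is the product of these ratios. `L` is
modelled as a mixture of `n` negative binomials on `{1, 2, ...}`
(`L - 1 ~ NB(size r_i, mean m_i - 1)`; `r = 1` is the shifted geometric).
The weights among *detected* events, `alpha_hat`, are what the likelihood
identifies directly; the underlying weights follow from the
per-component detection masses `d_i = sum_x D(x) f_i(x)` via
`alpha_i ∝ alpha_hat_i / d_i`. The reported mean NCO length is the mean
of the underlying mixture, and the number of events behind `T` observed
tracts is the inverse-detection plug-in `T / Pr(S != 0)` with
`Pr(S != 0) = sum_i alpha_i d_i`, divided by the number of meioses for a
per-meiosis rate.

## Exact kernel computation

`D` and every `T_t` are computed exactly, not by sampling. For a window
of length `x` the contained markers form a consecutive run of the sorted
marker list, and the number of start positions yielding a given run is a
trapezoid-shaped piecewise-linear function of `x` with integer
breakpoints. Summing runs weighted by `(1-p)^(run size)` therefore
reduces to accumulating trapezoids through difference arrays, `O(K * c)`
for `K` markers and maximum contributing run size `c` (runs with
`(1-p)^size < 1e-15` are dropped — an error far below the documented
1e-12 accuracy, which is verified against brute-force enumeration over
all placements on randomized small genomes). The same decomposition
gives each tract function from the runs containing the tract's markers.
The trapezoid parameter set fully determines a tract's function at every
length, so it also serves as a grouping key: tracts with identical
parameters share one row in the fit, which is what makes bootstrap
resampling (a pure reweighting of rows) cheap.

Infinite sums over lengths are truncated where every component's tail
mass falls below `tail_tol` (default 1e-9), re-evaluated whenever the
optimiser moves; the kernel table extends itself on demand. Lengths at
or beyond the shortest chromosome have no placement distribution and are
a hard error; fits additionally carry a `length_cap` (by default a
generous multiple of the initial truncation point and the largest span)
acting as a soft barrier against pathological excursions of the
optimiser.

## EM fit

The E-step computes membership weights
`w_it ∝ alpha_hat_i * Pr(O = o_t | theta_i, S != 0)`; the M-step sets
`alpha_hat_i` to the mean membership and re-optimises each component by
Nelder–Mead over `(log(m - 1), log r)` within
`log(m-1) in [log 1e-3, log 1e8]`, `log r in [log 1e-3, log 1e3]`. A
candidate that fails to improve the weighted objective is discarded in
favour of the previous value, preserving the generalized-EM guarantee of
a nondecreasing log-likelihood (asserted in tests with 1e-8 slack).
Iteration stops when the Euclidean norm of the changes in
`(alpha_hat, log m, log r)` — absolute changes of the logs being
relative changes of the parameters — drops below `tol = 1e-7`, or on a
log-likelihood plateau (< 1e-6 gain per iteration over 8 consecutive
iterations, which an overfit redundant component otherwise stretches to
the iteration cap), or at `max_iter` (500). The inner optimiser's
tolerances scale with the outer step size and tighten to 1e-10 on the
objective as the EM approaches convergence, so warm restarts do not
re-explore the whole basin.

Initialisation: component means at the `(2i+1)/2n` quantiles of observed
tract spans inflated by `1/p` (spans lower-bound event lengths), sizes at
`r = 1`, uniform `alpha_hat`; additional restarts jitter this seedily.
Components whose weight falls below 1e-6 are dropped and the fit
continues with the smaller mixture, flagged in the result. All
randomness flows from the single `FitConfig.seed`; results are
bit-reproducible.

## Model selection and uncertainty

The component count is chosen by a likelihood-ratio ladder: geometric
(`r` fixed at 1) vs one negative binomial (1 df), then `n` vs `n + 1`
components (3 df: one weight, two parameters), adding components while
`p < 0.05` against the chi-squared reference. The chi-squared
approximation at mixture boundaries is known to be conservative in
places; it is adopted deliberately as the standard practice.

A caveat of the gated ladder: the first rung compares geometric to a
single negative binomial, and components are only added once that test
rejects. On data where *no* single-component model captures anything —
e.g. a mixture of two strongly underdispersed components — a single NB
can fit exactly as badly as a single geometric, the first rung fails to
reject, and the ladder stops before ever fitting two components. With
moderately dispersed components the gate is unproblematic (the single-NB
rung picks up the variance excess immediately). When in doubt, fit a
fixed two-component model directly and compare.

Confidence intervals are percentile bootstrap: `B = 200` (tests use 100)
resamples of the tracts with replacement, each refit with EM
warm-started at the full-data estimate — resampling never changes `D` or
any `T_t`, so replicates only reweight kernel rows — and the 2.5th/97.5th
percentiles of the replicate summaries. Penetrance is held at the
full-data estimate across replicates.

Penetrance, when not supplied, is estimated as the fraction of converted
markers among the informative markers strictly between each tract's
outermost converted markers; boundary markers are converted by
construction and would bias `p` upward. Single-marker tracts carry no
interior information and are skipped; if no tract has an interior, the
estimate is refused and the caller must supply `p`.

## Simulator

The generator reproduces the assumed observation process exactly: events
drawn from a specified mixture, placed uniformly among fitting starts,
per-marker Bernoulli conversion, and an exact event count recorded up to
the event that met the tract quota. Marker maps come as explicit
positions, a homogeneous map with a target mean gap (drawn as geometric
gaps; the human-like default is 1465 bp), a clustered map with lognormal
gaps matching a mean and median (human informative-marker maps have
median gap roughly half the mean — on desk-scale genomes this clustering
measurably *increases* estimator variance, so the experiment grids
default to the homogeneous map), or candidate sites kept with
heterozygosity probability `2f(1-f)` from allele frequencies.

The experiment grids cover means {100, 300, 1000} bp, penetrances
{0.5, 0.75, 1.0} and seven dispersion levels `k` with
`variance = mean^2 * k`, `k in {1/16, 1/8, 1/4, 1/2, 1, 2, 4}` (63
single-component conditions; 147 two-component conditions pairing the
mean-100 and mean-1000 components with 1000 tracts from each, i.e. equal
probability of producing a tract from either component). `k = 1`
reproduces the geometric variance; the shifted-NB floor `var > mean - 1`
bounds `k` from below at roughly `1/mean`.

What the generator does not emulate: recombination hotspots or any
non-uniform event placement, length-dependent penetrance, tract calling
errors or merged tracts from overlapping events, and real marker
ascertainment. Passing tests therefore demonstrate correctness of the
inference under its own assumptions, not robustness to their violation.

## Test problem sizes and power

The statistical tests run desk-scale versions of the reference
experiments on a 5 Mb (recovery/variance) or sub-Mb (coverage,
selection) single-chromosome genome:

* *Recovery*: 1000-tract datasets, human-like spacing 1465 bp, means
  {100, 300, 1000} × penetrance {0.5, 1.0}, `k = 1/16`, medians over 40
  (p = 0.5) or 20 (p = 1) replicates, bands 5% (mean) and 10% (count).
  The dispersion and replicate counts follow a power analysis: at
  `k = 1/4` the per-replicate dispersion of the fitted mean reaches ~34%
  in the lowest-information cell (mean 100, p = 0.5; most tracts are
  single-marker there), making a 5% median band at 20 replicates a coin
  flip even for an unbiased estimator; at `k = 1/16` dispersion is
  7–16% and the stated bands are adequately powered. A 60-replicate
  check in the hard cell gives median 100.1 bp (truth 100) and median
  count ratio 0.991.
* *Variance scaling*: variance of the fitted mean at 4000 vs 1000
  tracts, 48 replicates per size (the ratio estimate at 30 replicates
  has only ~74% power for a true ratio of 1/4), band 0.25 ± 0.1. One
  fixed marker map underlies all replicates — redrawing the map per
  replicate adds map-sampling variance that does not scale with the
  tract count and distorts the ratio.
* *Coverage*: the single-component invariant configuration — dense
  markers, p = 1, 500 tracts — 100 datasets × 100 bootstrap replicates,
  99% exact-binomial acceptance band around 0.95. With full detection
  the event-count estimate equals the recorded truth exactly, so the
  count-coverage check is trivially satisfied in this configuration;
  the mean-coverage check is the substantive one.
* *Selection*: 100 geometric-data replicates (the ladder should keep
  the geometric rung ~95% of the time) and 50 two-component replicates
  (means 100/1000, p = 1, dense markers, 2000 tracts; more than 80%
  should select two components). Multi-component likelihoods are
  multimodal — roughly a third of two-component fits on this data land
  in a local optimum ~150 log-likelihood units short without restarts —
  so ladder fits use one jittered restart and cap EM at 100 iterations;
  the LRT margins at the decision rungs are orders of magnitude away
  from the 0.05 threshold, so the cap does not affect decisions.

## Known limitations

* The chi-squared reference for boundary-adjacent nestings is
  approximate.
* The inverse-detection count estimator is a plug-in; its bootstrap CI
  inherits the skew of `1/Pr(S != 0)` when detection is poorly
  identified (small `r`, low penetrance).
* Exact kernels are quadratic-free but still `O(K * c + X_max)` per
  chromosome and `O(pairs * 1) + O(X_max)` per tract; genome-scale maps
  with millions of markers are feasible, but fits whose optimiser
  wanders to means far beyond the data scale pay for kernel extension.
* Very long events (comparable to a chromosome) fall outside the
  placement model and are capped.
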