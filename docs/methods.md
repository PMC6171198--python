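# Methods

## Scope and data model

`packscr` estimates the density of territorial, group-living carnivores from
camera-trap detections of one recognizable focal animal per pack. The unit
of inference is the **pack**: a capture event (CE) is one detection of a
focal animal at one trap in one sampling occasion, regardless of how many
videos were recorded. Occasions are 24-h windows anchored at 15:00 local
time so that a single night's activity falls in one occasion; an event at or
after 15:00 belongs to the occasion opening that day. The encounter model is
Bernoulli: the binary history `y[i, j, k]` records whether pack *i* was
detected at trap *j* in occasion *k*, and repeated videos within a
pack–trap–occasion collapse to one CE. Captures logged at inactive
trap-occasions are dropped with a warning, and packs left with no captures
are removed — SCR conditions on detected individuals, so all-zero rows are
never carried.

Inputs are three plain CSV files (trap deployment with per-occasion activity
flags, animal captures, state space) plus raw event tables with timestamps.
Coordinates are planar metres in any projected CRS; no reprojection is done
(distances are Euclidean — study extents of tens of km make curvature
negligible). A two-block design (blocks surveyed in separate windows) is
encoded through per-trap activity flags, so one session is always one
rectangular trap × occasion array.

## State space

Activity centres live on a discrete habitat mask: an axis-aligned square
lattice (default spacing 666 m) anchored at the trap centroid and clipped to
the union of discs of radius 15 km around the traps. The buffer is around
the traps, not a convex hull — the standard SCR trap buffer; the anchor
choice is immaterial at spacings well below σ and is fixed for
reproducibility. Habitat classification is an input (a 0/1 flag per point),
not computed: land-cover judgement belongs upstream. Non-habitat points are
removed and the habitat area is `A = n_points · (spacing/1000)²` km².
A buffer of zero degenerates to lattice points coincident with traps and is
warned about; a positive buffer smaller than the spacing is rejected.

## Detection model

Two kernels: half-normal `k(d) = exp(−d²/2σ²)` and negative exponential
`k(d) = exp(−d/σ)`; two links for the zero-distance level: direct
`p = g0·k` and cloglog `p = 1 − exp(−λ0·k)` (λ0 is the expected encounter
rate of a pack whose centre sits on the trap). Both engines accept either
kernel; the NE kernel uses `exp(−d/σ)` identically in both engines, so σ is
comparable across estimators. The optional trap-specific behavioural
response ("TRAP") switches the zero-distance parameter per pack × trap after
the first capture **at that trap** — a site-level trap-happiness/shyness
effect; the pre-capture parameter applies up to and including the first
capture.

For both engines, per-pack × trap sufficient statistics are precomputed
(zeros before first capture, the first capture, captures/non-captures after
it, per-trap effort); for NULL models these reduce to binomial counts. This
makes likelihood evaluations over the whole mask a handful of matrix
products.

## Maximum-likelihood estimator

The full (unconditional) likelihood is used rather than conditional
likelihood plus Horvitz–Thompson, so density is a direct parameter: with
homogeneous density D (packs/100 km²) over the mask,
`p·(s) = 1 − Π_{j,k active}(1 − p(s,j))`, `p̄ = mean_s p·(s)`, the number of
detected packs is Poisson(D·A·p̄/100) and each detected history contributes
`log[(1/P)·Σ_s Pr(y_i|s)] − log p̄`. Estimation scales are log D, log σ and
logit g0 / log λ0 (positivity and Wald intervals); optimization is L-BFGS-B
from a default start (σ from half the mean maximum distance moved, D from
the detected count over A) plus two jittered restarts, with a loglik
tolerance of 1e−12. Standard errors come from the inverse observed
information (central-difference Hessian); 95% CIs are Wald intervals on the
estimation scale, back-transformed; natural-scale SEs by the delta method.
Fits require ≥ 2 detected packs and warn when there are no spatial
recaptures (σ weakly identified). Model ranking uses AICc with n = number of
detected packs; AICc is NaN (with a warning) when n ≤ k+1.

## Bayesian estimator

Data augmentation to M pseudo-individuals (default `max(10·n_detected,
100)`, giving headroom over the Ψ ≈ 0.22 regime of the motivating study):
`z_i ~ Bernoulli(Ψ)`, centres uniform on the mask, `Nsuper = Σz`,
`D = 100·Nsuper/A` per draw, exactly. Sampling is Metropolis-within-Gibbs:

- `z_i | rest` Gibbs for undetected rows (odds `Ψ·Pr(all-zero | s_i)` to
  `1 − Ψ`); detected rows have z ≡ 1;
- `Ψ | z` Gibbs, Beta(1 + Σz, 1 + M − Σz);
- `s_i` Metropolis to a mask point drawn uniformly within 3 lattice spacings
  (global uniform fallback for isolated points), with the neighbour-count
  Hastings correction; rows with z = 0 move by prior alone;
- σ, λ0 (and λ0_post) random-walk Metropolis on the log scale with priors
  flat on the natural scale up to explicit wide bounds (σ ≤ 50 km,
  λ0 ≤ 10) that keep the posterior proper on the discrete mask.

Proposal scales adapt toward a 0.2–0.5 acceptance rate during burn-in only,
preserving detailed balance of retained draws; runs are seeded and
bit-reproducible (the seed is mandatory). Defaults mirror the motivating
analysis: 100 000 iterations, 5 000 burn-in, thinning 10. The Bayesian
engine uses the cloglog (λ0) parameterization — the natural scale for a
rate-based Bernoulli model and the one whose σ, λ0 are directly comparable
with the ML cloglog fit.

Convergence: Geweke z per parameter (difference of the means of the first
10% and last 50% of the chain, scaled by Bartlett-window
spectral-density-at-zero estimates per segment; flagged at |z| > 1.6, with
an optional automatic chain extension). Note the calibration ceiling: on a
perfectly mixed chain the statistic is ~N(0, 1), so the two-sided 1.6 rule
passes about 89% of truly converged chains by construction; in finite
samples the spectral estimator's own noise costs a few more points. Constant
(degenerate) chains carry no drift evidence and are reported as NaN rather
than flagged.

Goodness of fit: a posterior-predictive p-value on individual encounter
frequencies. For each retained draw, replicate data are simulated for the
z = 1 individuals at their sampled centres and the Freeman–Tukey discrepancy
`T = Σ_i (√f_i − √e_i)²` of individual total encounter counts (against
their expectations under the draw, computed in closed form, including the
trap-response case) is compared between replicate and observed data;
p ≈ 0.5 indicates adequate fit and the best model is the one closest
to 0.5. The Freeman–Tukey form is this package's documented choice of
discrepancy within the individual-encounter-frequency family. The
trap-response decision combines three signals: overlap of the 95% HPD
intervals of `p1 = 1 − e^{−λ0}` and `p2 = 1 − e^{−λ0_post}`, the relative
density shift against the matching NULL model (≤ 1% treated as negligible),
and the recommendation to drop TRAP when both hold. DIC is deliberately not
computed.

## Derived quantities

- HPD intervals by the sorted-window (shortest-interval) method.
- Total density = pack density × mean pack size, a point conversion; pack
  size is the maximum number of individuals seen in a single CE per pack.
  Pack-size uncertainty is not propagated (matching the conversion's use as
  a reported point product); a delta-method variant would be straightforward
  but is not enabled.
- Home-range summaries from σ: the HN kernel implies a bivariate-normal use
  distribution, so the 95% radius is `σ·sqrt(χ²₂(0.95)) = 2.4477σ`; NE
  solves `1 − e^{−r/σ}(1 + r/σ) = mass` numerically. The "95% use area" is
  the circle of that radius.

## Survey-design analyses

- **Trap subsetting** drops captures at removed traps (and emptied packs,
  logged), enabling reduced-array refits.
- **Session truncation** keeps occasions 1..n (anchored at session start,
  matching an increasing-duration design) and reports recapture counts; trap
  activity vectors are truncated alongside.
- **Inter-observer agreement**: pairwise percent of videos with identical
  pack assignment (indeterminate counts as a label, so joint-indeterminate
  is a match — this convention reproduces the published 85.0/80.0/97.5/92.5
  percentages from the published column counts), per-observer distinct-pack
  and assigned-CE counts, and a concordant-history filter keeping only
  videos all selected observers assign identically and determinately.
- **Misidentification injection** relabels captures between a merge pair
  with a given probability, emulating the observed failure mode of two
  adjacent packs being conflated.

## Synthetic data

The generator draws `N ~ Poisson(D·A/100)` pack centres uniformly over the
habitat mask (a fixed-N switch exists for sampler tests, matching the
binomial prior form of data augmentation) and simulates Bernoulli encounters
at each active trap-occasion, sequentially per occasion when a trap response
is present. Two named designs encode the study conditions of the motivating
surveys: "2014-like" (26 traps at 3.69 km ≈ 1.7σ nearest-neighbour spacing)
and "2015-like" (48 traps at 2.74 km ≈ 1.1σ), both with 71 daily occasions,
a 15-km buffer and a 666-m mask lattice; trap grids are compact square
lattices trimmed to the target count (only the spacing/σ geometry matters
for the properties tested, not the original coordinates). Default parameters
anchor to the published 2015 estimates: σ = 2424 m, λ0 = 0.122, D = 1.21
packs/100 km². The generator emulates the statistical structure the
estimators assume — it has no camera downtime, placement bias, terrain
anisotropy or diel detection heterogeneity, so passing recovery tests
demonstrates estimator correctness under the model, not robustness to those
real-data features (the misidentification and design analyses probe two of
them explicitly).

Under the default scenario the generator yields detected-pack counts
(typically 6–15) and focal capture rates in the field-observed range,
though per-pack CE counts run somewhat higher than the field's 3–18 because
effort is gapless and placement unbiased.

## Problem sizes and numerical choices

Simulation-heavy checks (parameter recovery, cross-estimator consistency,
design properties) run the 2015-like design with a 1 500-m fit mask —
0.62σ, comfortably below the mask-spacing ≲ σ rule, and fine enough that
density estimates change negligibly against the 666-m lattice — with 200
ML replicates and 20 Bayesian chains of 20 000 iterations (burn-in 5 000,
thinning 10). Under these conditions the ML density shows ≈ +3% relative
bias with 96–97% Wald coverage, Bayesian posterior means sit 2–12% above
the MLE (the documented small-sample pattern of data augmentation versus
maximum likelihood), and posterior-predictive p-values on well-specified
data stay within [0.2, 0.8].

Probabilities are clipped away from 0/1 before logs; inactive trap-occasions
contribute nothing to any likelihood (padding a session with inactive
occasions is a no-op); AICc ties rank the smaller model first; degenerate
inputs (no detections possible, all points non-habitat, single detected
pack) raise informative errors rather than returning numbers.

## Limitations and optional checks

Density is homogeneous over the mask (no density surfaces or covariates
beyond the behavioural response); populations are closed within a session;
pack sizes convert density as a point estimate. The original study's raw
capture/trap/state-space files are not redistributed with this package, so
refitting the published Table-4-style estimates (Bayesian 2015 HN density
1.21 ± 0.27; ML 1.15 ± 0.34 with σ ≈ 2428 m, g0 ≈ 0.116) is an optional
check for users holding those files — agreement within one posterior SD
(Bayesian) and two SE (ML) is the expected outcome; the bundled acceptance
script instead verifies the pipeline on the published summary inputs and on
synthetic surveys at the same design.
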