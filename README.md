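# packscr

Pack-based **spatially explicit capture–recapture (SCR)** density estimation
for camera-trap surveys of group-living carnivores.

Estimating the density of wolves (and similar social carnivores) from camera
traps is hard: individuals lack unambiguous natural marks and pack members'
detections are strongly correlated, violating the independence assumptions of
individual-level capture–recapture. The pack-based approach sidesteps both
problems by building the encounter history of **one recognizable focal animal
per pack** (typically an alpha), estimating **pack density**, and converting
to total density with mean pack size. `packscr` implements this pipeline end
to end: raw detection events → binary pack-level capture histories → a
habitat-masked state space → pack density by maximum likelihood and by
Bayesian data-augmentation MCMC → diagnostics, home-range summaries, and
survey-design robustness analyses, plus a synthetic-data generator that
reproduces the statistical structure of the motivating two-session wolf
survey (Arezzo province, Italy).

## The model

Each pack *i* has a latent activity centre *s\_i* on a discrete habitat mask
(a regular lattice buffering the trap array). Detection of the focal animal
at trap *j* on a 24-h occasion *k* is Bernoulli — at most one capture event
(CE) per pack, trap and occasion — with probability decaying in the
centre-to-trap distance *d*:

- half-normal kernel (HN): *k(d) = exp(−d²/2σ²)*;
- negative exponential (NE): *k(d) = exp(−d/σ)*;
- direct link: *p = g₀·k(d)*, or cloglog link: *p = 1 − exp(−λ₀·k(d))*,
  where λ₀ is the expected encounter rate at the centre;
- optional trap-specific behavioural response (*TRAP*): the zero-distance
  parameter switches after a pack's first capture at that trap.

**Maximum likelihood** uses the full (unconditional) likelihood: the number
of detected packs is Poisson(*D·A·p̄*/100) with *A* the habitat area (km²)
and *p̄* the mask-average probability of at least one detection, and each
history contributes its mask-marginal probability. Model choice is by AICc.

**Bayesian estimation** augments the data to *M* pseudo-individuals with
inclusion indicators *z\_i* ~ Bernoulli(Ψ); *N* = Σ*z*, *D* = 100·*N*/*A*.
A seeded Metropolis-within-Gibbs sampler updates *z* and Ψ by Gibbs, the
activity centres by local-window Metropolis moves, and σ, λ₀ by random-walk
Metropolis with flat priors. Convergence is assessed with Geweke z-scores
(|z| ≤ 1.6) and fit with a posterior-predictive (Bayes) p-value on the
Freeman–Tukey discrepancy of individual encounter frequencies (best fit ≈
0.5).

Occasions run 3 p.m. to 2.59 p.m. so nocturnal activity is not split across
occasions (the "midnight problem").

## Worked example

```python
import packscr as p

design = p.make_design("2015-like")          # 48 traps, 2.74 km apart, 71 nights
mask = design.mask(spacing_m=1500.0)         # habitat lattice, 15-km buffer
traps = design.traps()

scenario = p.study_scenario(seed=7, mask=mask)
history, truth = p.simulate(scenario)        # ground truth: 1.21 packs/100 km2

summary = p.summarize(history, traps)
print(f"detected packs: {history.n_animals}, capture events: {summary.n_ce}")
print(f"CE per 100 trap-days: {summary.ce_rate:.2f}")
print(f"MMDM: {summary.mmdm.mean/1000:.2f} km over {summary.mmdm.n} packs")

spec = p.ModelSpec(detfn="HN", response=None, parameterization="cloglog")
ml = p.fit_ml(history, mask, traps, spec, seed=1)
print(f"ML:    D = {ml.D_hat:.2f} packs/100 km2 (SE {ml.se['D']:.2f}), "
      f"sigma = {ml.params.sigma:.0f} m")

config = p.MCMCConfig(n_iter=20_000, burn_in=5_000, thin=10, seed=11)
chain = p.mcmc_fit(history, mask, traps, spec, config)
bp = p.bayes_p_value(chain, history, mask, traps)
print(f"Bayes: D = {chain.D.mean():.2f} packs/100 km2 (SD {chain.D.std(ddof=1):.2f}), "
      f"sigma = {chain.sigma.mean():.0f} m, Bayes p = {bp:.2f}")

total = p.wolves_per_100km2(chain.D.mean(), 4.17)
radius = p.range_radius(chain.sigma.mean(), "HN", 0.95)
print(f"total density at mean pack size 4.17: {total:.2f} wolves/100 km2")
print(f"95% range radius: {radius/1000:.1f} km ({p.use_area(radius):.0f} km2 use area)")
```

Output:

```text
detected packs: 12, capture events: 169
CE per 100 trap-days: 4.96
MMDM: 8.16 km over 7 packs
ML:    D = 1.58 packs/100 km2 (SE 0.46), sigma = 2383 m
Bayes: D = 1.65 packs/100 km2 (SD 0.37), sigma = 2394 m, Bayes p = 0.44
total density at mean pack size 4.17: 6.88 wolves/100 km2
95% range radius: 5.9 km (108 km2 use area)
```

Reading it: this seed detected 12 packs (the 2015 field season found 12) and
both estimators put pack density well within their uncertainty of the true
1.21 packs/100 km², with the Bayesian mean sitting a few percent above the
MLE as expected for a small detected sample; σ ≈ 2.4 km implies a 95% range
radius of 5.9 km. The focal-animal capture rate (4.96 CE/100 trap-days) and
mean maximum distance moved (8.2 km) land in the field-observed range.

A `packscr` CLI wraps the same operations (`packscr simulate`, `packscr
history`, `packscr statespace`, `packscr fit-ml`, `packscr fit-bayes`,
`packscr design agreement`); run `packscr --help`.

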