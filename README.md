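# coxhawk

Maximum-likelihood fitting and simulation of point-process models for
event data that cluster in time, space, or both — the kind of data
ecologists and epidemiologists meet as sighting records, case reports,
or geocoded incidents.

Ecological sightings data often exhibit two distinct kinds of structure
that call for different model families. Events may be *contagious in
time* — one sighting incites another shortly after — which is the domain
of the Hawkes process, with conditional intensity

    λ(t) = μ + α Σ_{i: τᵢ < t} m(τᵢ) exp(−β (t − τᵢ)),

where μ is the background rate, α the jump in intensity after each event
and β the exponential decay rate; α/β is the branching ratio (expected
directly triggered events per event). Events may also be *clustered in
space*, which is the domain of the log-Gaussian Cox process (LGCP),

    Λ(s) = exp(Xβ + G(s)),

an inhomogeneous Poisson process whose log-intensity contains a latent
Matérn Gaussian field G, represented here as a Gaussian Markov random
field on a Delaunay mesh via the SPDE finite-element construction.
`coxhawk` fits both families and their combinations:

- univariate Hawkes processes, with marks, self-inhibition (α < 0), or a
  user-defined time-varying background μ(t; θ);
- N-stream mutually exciting Hawkes processes with an N×N excitation
  matrix (within- vs between-stream excitement);
- spatial and AR(1)-spatiotemporal LGCPs, fitted by Laplace-approximated
  maximum likelihood over the sparse GMRF, with Voronoi dual-mesh
  integration weights, node-level covariates, intensity prediction and
  expected-total estimation Σₖ wₖ exp(β₀ + gₖ);
- marked LGCPs: joint models of a point pattern and a point-referenced
  mark (normal / Poisson / binomial / gamma) sharing the latent field
  through a loading αₘ — the preferential-sampling construction;
- a spatiotemporal self-exciting model whose triggering decays
  exponentially in time and spreads as a bivariate Gaussian kernel in
  space (optionally widening with elapsed time), with an optional
  additive GMRF background.

All fits return natural-scale estimates, delta-method standard errors
from the observed information, the log-likelihood, and convergence
metadata; all simulators (Ogata thinning, branching construction, GMRF
sampling) are exact and seed-reproducible. See `docs/methods.md` for the
model details, parameterisations and numerical choices.

## Worked example

Simulate seven years (T = 2188 days) of daily-scale sightings from a
Hawkes process with a weak self-exciting component, refit it, and read
off the interpretable summaries:

```python
import coxhawk as ch

truth = ch.HawkesParams(mu=0.12, alpha=0.06, beta=0.09)
series = ch.simulate_hawkes(truth, T=2188, seed=1)
print("n events:", series.n)

fit = ch.fit_hawkes(series, init=ch.HawkesParams(0.1, 0.05, 0.1))
for name in ("mu", "alpha", "beta"):
    print(f"{name:>5s} = {fit.estimates[name]:.3f} (SE {fit.std_errors[name]:.3f})")
print(f"loglik = {fit.loglik:.2f}")

for k, v in ch.derived_quantities(fit, T=2188).items():
    print(f"{k} = {v:.2f}")
```

prints

```
n events: 699
   mu = 0.132 (SE 0.023)
alpha = 0.056 (SE 0.011)
 beta = 0.095 (SE 0.021)
loglik = -1456.25
expected_background = 288.52
triggered_per_event = 0.59
descendants_per_event = 2.45
decay_time = 10.54
```

Each true parameter is recovered well within one standard error. The
derived quantities say: about 289 of the 699 events were background
("principal") events and the rest arose from self-excitement; each event
directly triggers 0.59 further events on average (the branching ratio
α̂/β̂); each background event founds a cluster of about 2.45 events
including itself (β̂/(β̂−α̂)); and the excitement decays on a ~10.5-day
timescale (1/β̂), after which an event is effectively independent of
history. The goodness-of-fit transform `ch.gof_transform(series, ...)`
returns the time-changed inter-arrival gaps, which pass a
Kolmogorov–Smirnov test against Exp(1) at the fitted parameters
(p = 1.0 here).

The spatial models follow the same pattern, e.g.

```python
domain = ch.Domain.from_wkt("POLYGON((0 0,10 0,10 10,0 10,0 0))")
mesh = ch.build_mesh(domain, max_edge=1.2)
pattern = ch.simulate_lgcp(ch.SpdeParams.from_range_sigma(3.0, 1.0),
                           beta=[1.0], mesh=mesh, domain=domain, seed=5)
fit = ch.fit_lgcp(pattern, domain, mesh)   # -> beta0, range, sigma + SEs
total = ch.expected_total(fit, ch.dual_mesh_weights(mesh, domain))
```

## Command line

A thin CLI wraps the library for shell pipelines:

```
coxhawk simulate-hawkes --mu 0.5 --alpha 0.5 --beta 1.0 --t-max 2000 --seed 1 --out events.csv
coxhawk fit-hawkes --events events.csv --t-max 2000 --init mu=0.4,alpha=0.4,beta=1.2 --out fit.json
coxhawk build-mesh --domain poly.geojson --max-edge 1.0 --out mesh.json
coxhawk fit-lgcp --locs locs.csv --domain poly.geojson --mesh mesh.json --out fit.json
coxhawk fit-stelfi --events ev.csv --domain poly.geojson --time-independent --out fit.json
```

Events are plain CSV (`t` / `x,y` / `t,x,y` / `t,stream`, optional
`mark`), domains are GeoJSON or WKT, meshes and fit reports are JSON.
Exit codes: 0 success, 2 validation error, 3 non-convergence.

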