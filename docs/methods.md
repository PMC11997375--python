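# Methods

`continuum` simulates eco-evolutionary dynamics of individuals living at
real-valued positions on a rectangular 2D landscape, with kernel-mediated
local interactions, decomposed density-dependent regulation of birth and
death, raster-map habitat heterogeneity, and a minimal diploid genetics
layer. This note records the model, the parameter conventions, the
numerical choices, and what the synthetic test scenarios do and do not
establish.

## The model

**Local density.** The density experienced by an individual at x is the
kernel-smoothed count

    n(x) = (1/sigma_X^2) * sum_i rho((x - x_i)/sigma_X),

in individuals per unit area, summed over *all* individuals including the
focal one (an individual counts toward its own density). Interactions are
truncated at `max_distance` (default 3 sigma) with **no renormalization**:
for a Gaussian kernel about 1.1% of the mass is deliberately lost, keeping
density values directly interpretable. Tests and expectations carry a ~1%
tolerance for this.

**Regulation.** Vital rates depend on position only through the scaled
density u = n(x)/K, where K (individuals per unit area) is the tunable
carrying-capacity parameter. The per-capita net reproductive rate is
F(u) = f(u)(1 - mu(u)) - mu(u); every built-in family satisfies F(1) = 0
and F'(1) < 0, so the equilibrium density is *roughly* K — realized density
is emergent and typically a few percent off (see "Census calibration").
Four families decompose the same net response into different mechanisms:
mortality-regulated, fecundity-regulated and compensatory Beverton–Holt,
and fecundity-regulated Ricker. Validity constraints (a <= f;
0 < alpha <= mu0 < 1; f0 >= a*alpha; 0 < mu < 1) are enforced at
construction so survival probabilities can never leave [0, 1]. The
discrete logistic is refused outright: F(u) = r(1 - u) is unbounded below
and random density fluctuations would eventually produce negative
survival probabilities.

The Ricker family uses f(u) = exp(-(u-1)) * mu/(1-mu) with mu the constant
*death* probability. A description of this form sometimes labels mu the
"probability of survival", but the balance F(1) = 0 holds for all mu only
when mu is the death probability (the two readings coincide at mu = 1/2);
we implement the death-probability reading and default to mu = 1/2 in the
mountain scenario, which also gives f(1) = 1, the fecundity used in the
package's other standard examples. The plain exp(-u) variant (differing by
a factor of e) is available via `shifted=False`.

**Tick cycle.** Each tick executes, in order: (1) mate choice,
reproduction (offspring counts Poisson with mean f(u) evaluated at the
scaled density cached from the previous survival phase), inheritance and
juvenile dispersal; (2) adult movement (individuals of age >= 1, if a
movement kernel is set); (3) density computation over all individuals
including the new juveniles; (4) survival as an independent coin per
individual. Because density for survival is measured after reproduction,
it is divided by (1 + f_bar) * K_local, with f_bar = f(1), so that u
reflects *pre*-reproduction density and the census before reproduction
equilibrates near K * area. Census statistics (census, mean age, allele
frequency) are recorded at the start of each tick, i.e. before
reproduction. Alternative orderings change the equilibria and are out of
scope.

**Sexes and mating.** Mate choice weights each eligible candidate within
the mating kernel's truncation radius by rho(d/sigma_M); no candidate in
range means no offspring that tick — mate failure is a real stochastic
effect, not an error, and there is no global fallback mate. In dioecious
populations females choose males and draw Poisson(2 f(u)) offspring so the
*population-mean* fecundity stays f(u) and the equilibrium census is
unchanged; offspring sexes are assigned 50/50. Monoecious populations
exclude self-mating. With no mating kernel reproduction is clonal.

**Boundaries.** Reflecting (iterated folding, so arbitrarily long
excursions terminate), absorbing (removal), stopping (coordinate clamp),
and reprising (the displacement is *redrawn* from the same kernel until the
destination is inside — conditioning, never clipping; a cap of 1000
redraws converts a degenerate kernel/domain combination into an error).

**Kernels.** Gaussian, flat (uniform on the truncation disc), and the
fat-tailed "t cross-section" kernel with density proportional to
(1 + ||x/sigma||^2/df)^(-(df+1)/2), i.e. the 1D Student-t profile rotated
about the origin (not the bivariate t). Its normalizing constant has the
closed form (df-1)/(2 pi df sigma^2), requiring df > 1 in 2D; construction
rejects df <= 1. Displacement sampling is rotationally symmetric by
construction — angle uniform, radius by exact inverse CDF of the radial
marginal (sampling each coordinate from a 1D t would concentrate mass on
the axes). Sampling draws from the *untruncated* kernel (dispersal is not
clipped at 3 sigma); `truncate=True` conditions draws on the disc and is
used for map-weighted proposals.

**Maps.** Rasters span the domain with row 0 at the top (image
convention); CSV values are taken verbatim, 8-bit monochrome PNG is mapped
affinely onto a target range. Lookup offers pixel-rectangle semantics
(`nearest`) and pixel-center anchored `bilinear`/`bicubic` interpolation
(B-spline; near edges it is clamped, which can differ from other bicubic
conventions at the sub-percent level). **Out-of-bounds queries clamp to the
edge value** — deliberate, to avoid NaN cascades at boundaries, but note a
map is thereby implicitly extended beyond its support; map-weighted point
*sampling* does treat everything outside the domain as zero mass.

**Genetics.** Genotypes are allele-count vectors over L unlinked loci;
locus 0 is selected, the rest neutral with symmetric per-transmission
mutation. The selection coefficient s is per *tick* (rare-allele growth
1 + hs per step at equilibrium; default h = 1/2); it is not a per-generation
Wright–Fisher s and we make no establishment-probability claims with it.
Mortality-mode selection multiplies survival by {1, 1+hs, 1+s}·...
(1 + k s/2 per copy in the additive case); fecundity-mode selection uses
f_k = (1 + f)(1 + ks) - 1. Both give the same allelic growth rate
G(u) = (1 - mu_1)(1 + (f_0 + f_1)/2) - 1 at every density, with
G(1) = s/2, but different post-fixation densities:
u* = 1 + s(1 + 1/f) under mortality selection versus 1 + 2s(1 + 1/f)
under fecundity selection (Beverton–Holt mortality regulation with a = f),
and only fecundity selection depresses the mean age.

## Grid acceleration

When the number of neighbors is large, per-pair sums are replaced by a
raster pipeline: deposit individuals on a grid of cells at most
sigma_X/2 across, smooth with the interaction kernel, and interpolate at
each individual's position. Two choices matter:

* **Deposition is bilinear (cloud-in-cell),** not nearest-cell binning:
  splitting each individual over the four nearest cell centers removes
  most position-quantization noise. With nearest binning the 95th
  percentile relative error against the exact sum is ~9% at cell =
  sigma_X/2; with bilinear deposition it is ~3.5% (pooled over 50 random
  uniform and clustered configurations).
* **Smoothing for density is a zero-padded convolution** (weights =
  kernel density x cell area): the density field genuinely decays near
  boundaries because nobody lives outside, and per-cell weight
  renormalization would erase that and inflate edge densities about
  twofold. Map smoothing for *habitat* fields uses per-cell
  renormalization instead (`edge="renormalize"`, the default), for which
  a constant map is an exact fixed point.

Grid mate choice samples a point near the chooser with density
proportional to (eligible-density map x mating kernel) and takes the
nearest eligible individual. The eligible-count map is smoothed only
enough to fill inter-individual gaps (Gaussian of scale
max(cell, sigma_M/4)); smoothing with the full mating kernel would
convolve the kernel with itself and effectively double the mating scale
(empirically a 10–15% inflation of short mate distances). With dense
eligibles the mate-distance deciles agree with exact kernel-weighted
choice within 5%.

## Determinism

All randomness flows through `numpy` Generators seeded from
(seed, tick, stage), so a configuration and seed reproduce a trajectory
bit for bit, and computing extra diagnostics never perturbs the
trajectory. Two runs with the same seed produce byte-identical CSV
outputs.

## Census calibration and the adaptive tuner

Realized density differs from K for well-understood reasons: density is
measured at a particular phase of the cycle, individuals oversample
high-density regions (they count toward their own density), and
stochasticity (mate failure at small N_M, local extinction at small N_X)
usually pushes density down. In the homogeneous baseline
(sigma_X = sigma_D = sigma_M = 1, K = 5, Beverton–Holt mortality with
a = f = 1) the pre-reproduction census settles ~5–8% above K x area with
these conventions. The neighborhood sizes N_M = 4 pi sigma_M^2 K and
N_X = 4 pi sigma_X^2 K are order-of-magnitude diagnostics; config
validation warns below 5.

Where an exact match to an observed density is wanted, the adaptive tuner
multiplies the regulation strength by `adj`, updated each tick by
exp(alpha (observed - K)) — the printed Beverton–Holt survival form
1/(1 + adj f u) — until a configured burn-in tick, after which `adj`
freezes. Left on, the tuner would cancel genuine responses to changing
conditions (habitat loss should change the population size).

## Spatial statistics

The pair correlation function uses the translation edge correction
(unbiased on rectangles; verified by Monte Carlo against the CSR null and
against an O(n^2) enumeration), with a torus option for periodic test
patterns. The per-bin `mc_sd` is a Poisson approximation from pair counts;
on a single pattern, bin values share a common fluctuation component that
this underestimates by roughly a factor of two at n = 10^4 — comparisons
of single patterns should use an absolute band (~1–2%) alongside it. Mark
connection proportions are reported in the ordered-pair convention, so
2 x cross + FF + MM = 1 exactly (at the count level; the float rendering
agrees to a few ulps) and random labeling yields p(1-p), p^2, (1-p)^2.
Default binning is 30 equal bins to 5 sigma_D, which resolves the
clumping structure that extends to ~3 sigma_D. Isolation by distance is
the mean pairwise proportion of neutral-allele differences per
geographic-distance bin, subsampled to 1000 individuals for large
snapshots.

## Case-study scenarios

The four vignettes are configured pipelines over the engine, at desk
scale, with synthetic landscapes (cone, river mask, gradient) — they are
illustrations of mechanism, not calibrated models of any species.

* **Alpine range shift (pika-style).** T(x,t) = T_elev(x) + T_fluct(t) +
  0.016 t, with an affine lapse model T_elev = T0 - lapse*elevation (the
  original fitted coefficients are not available, so the lapse is a
  config parameter), AR(1) fluctuations (persistence p_fluct, shock
  s_fluct, T_fluct(0) = 0), and survival gated to zero outside
  [-5 + s_seas/2, 28 - s_seas/2] degC. Extinction-risk contrasts use a
  steep synthetic cone so the viable band is a narrow elevation annulus
  that a single bad year can displace.
* **Stage structure (mosquito-style).** Ten immobile daily larval
  classes regulated by Beverton–Holt survival in *total* larval density
  against K(x,t) = K_base(x) + K_rain(t) (sinusoid, period 365, minimum
  0); adults survive at 0.875/day (mean lifespan 8 days), move, mate
  within a maximum distance, and lay eggs at K-weighted points within a
  dispersal radius. The larval regulation strength theta is solved
  numerically from the stationary ten-class recursion
  s_L^10 = 2(1 - s_A)/(s_A lambda), a re-derivation; with default
  lambda = 10 eggs/female/day only ~3% of eggs reach adulthood, so adult
  density is a small fraction of larval K — scenario configurations must
  budget for that.
* **Range expansion (cane-toad-style).** Survival multiplied by the
  logistic suitability 1/(1 + exp(-(alpha_t + beta_t P(x)))) of a
  synthetic precipitation gradient; fat-tailed (t, df = 3) dispersal
  advances the front visibly faster than Gaussian dispersal at the same
  scale. Desk scale only; no real raster, no continental run.
* **Resource-explicit regulation (monarch-style).** Discrete patches each
  deliver a fixed number of resource units per tick, split equally among
  consumers in range (shares add across patches); individuals at or above
  the check age survive with probability min(1, tally). Reproduction
  starts strictly *after* the first cull (check age + 1): if doomed
  individuals could reproduce first, growth would be resource-independent
  and unbounded. Equilibrium census scales linearly with the total
  resource delivered.

## Problem sizes in the test suite

The integrative suites run at sizes chosen to make their signals clearly
resolvable while keeping the whole test run desk-scale: equilibrium
census uses 10 seeds of 300 ticks at K x area = 3125 (N_X ~ 63); the
mountain scenario uses 3 seeds x 1400 ticks (the reproduction script uses
5 seeds x 2000 ticks); sweep contrasts use 15x15–25x25 domains; the
dioecy contrast averages 20 recorded ticks after a 150-tick burn-in.
Results quoted in the README come from these runs.

## Known limitations

* Interactions, mating and movement are isotropic; no
  landscape-resistance-weighted movement, no anisotropy, no 1D/3D.
* Genetics is deliberately minimal: unlinked loci, no recombination maps
  or tree-sequence recording; IBD signals rely on many independent
  neutral loci.
* The grid acceleration assumes the density field varies on the scale of
  sigma_X; it degrades (with a warning) for cells larger than sigma_X/2
  and for populations with atom-like piles of individuals at identical
  positions.
* The per-tick selection coefficient does not plug into per-generation
  diffusion formulas.
* Synthetic landscapes are smooth and low-resolution; conclusions about
  collapse thresholds on real, rugged habitat maps (where low-K habitat
  can lie far from sources rather than adjacent to them) need the real
  rasters — on the smooth cone, low-K rings sit next to productive slopes
  and are partly maintained by source–sink subsidy, which raises realized
  density in marginal habitat relative to an isolated patch of the same K.
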