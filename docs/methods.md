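# Methods

This note documents the models implemented in `stepstone`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a maintainer would want written
down.

## Particle transport

Transport is two-dimensional (depth-averaged) Lagrangian advection–
dispersion. Per time step `dt` each particle receives the interpolated
velocity displacement plus an isotropic Gaussian step of standard
deviation `sqrt(2 D dt)` per axis, the exact discretization of a
diffusion with coefficient `D`. Velocities are interpolated bilinearly
in space and linearly in time from a gridded field carried in an
xarray dataset (`x`, `y` in km on an equirectangular plane at
111.19 km/degree; `t` in hours; `u`, `v` in m/s).

Defaults follow a spring spawning pulse: releases start on day-of-year
59, 1,489 particles per origin every 30 minutes for 14 days (672
release events), tracked for 70 days at 30-minute steps. Note the
schedule arithmetic gives 672 × 1,489 = 1,000,608 particles per origin;
the package always reports the schedule numbers. Tests and the
acceptance script run the same machinery scaled down (tens of particles
per release, days-long windows); the physics checks (exact advection,
diffusion variance within 5% of `2DT` at 10⁴ particles) are
scale-independent.

Choices that were genuinely open:

- **Arrival criterion.** A particle is counted at a destination at its
  first entry into that site's capture radius (default 2 km;
  5 km in the scaled experiment, commensurate with its 10 km grid),
  at most once per destination, and keeps moving. This makes counts
  monotone in the radius and robust to step size.
- **Dispersion.** `D = 10 m²/s`, a typical shelf-sea horizontal
  dispersion magnitude; configurable.
- **Boundaries.** Reflecting by default, preserving particle count (no
  larval mortality is modelled — the arrival matrix measures maximum
  settlement potential); absorbing boundaries optional.
- **What is not modelled.** Vertical structure (sigma layers),
  meteorological forcing, river plumes, larval behaviour, mortality.
  The synthetic flow field is a steady residual (uniform, callable, or
  an anticlockwise gyre) plus a spatially uniform M2 tidal oscillation
  (period 12.42 h); it has the right magnitudes and asymmetry but none
  of the mesoscale structure of a real shelf sea, so passing tests show
  the machinery is correct, not that any particular sea is represented.

## Wright–Fisher metapopulation

`simulate_metapopulation` is a forward diploid Wright–Fisher model.
Migration is *backward*: entry `m[i, j]` is the probability that an
offspring born in deme `j` draws its parents from deme `i` (columns
renormalized to 1). This matches how an arrival matrix converts to
migration: `migration_from_arrivals` sets column `j` proportional to
the particle flux into `j` plus a self-recruitment mass on the diagonal
(default 2.0 in arrival-proportion units — local spawning dominates
but immigration from well-connected sites reaches tens of percent,
plausible for broadcast-spawning bivalves and numerically safe for
sites that receive nothing).

Microsatellites mutate under the strict one-step stepwise model:
each transmitted allele moves ±1 repeat with probability `mu`
(default 0.001564 per gamete per generation, a literature rate for
these loci), reflecting at a floor of one repeat. Founders default to
20 equifrequent alleles per locus so the initial FST is ≈ 0 and any
differentiation is generated by drift and migration — this isolates
the estimators under test. Deme sizes are constant (census
conservation) and selfing is allowed (parents drawn with replacement).

The island-model check uses the equilibrium approximation
`FST = 1/(1 + 4 Nem)`; with `d` demes the finite-island correction
multiplies `Nem` by `(d/(d−1))²`, so at `d = 25`, `Nem = 1` the
expectation is ≈ 0.187 rather than 0.2 — comfortably inside the ±0.05
acceptance band, which is why the band is that wide.

## AMOVA and F-statistics

Sums of squares are computed per locus over allele copies under the
allele-identity metric (group SS = pair-difference count divided by
group size), at three strata: among samples, among individuals within
samples, within individuals. Missing genotypes are dropped per locus
(pairwise deletion; nothing is imputed). Locus SS are summed; degrees
of freedom come from the design sizes (`k−1`, `N−k`, `N` for `N`
diploids in `k` samples — so a 579-in-25 design gives 24/554/579,
total 1,157). Variance components use the unequal-n coefficient
`n0 = (N − Σnᵢ²/N)/(k−1)`; the F-statistics are component ratios and
satisfy `(1−FIS)(1−FST) = 1−FIT` to machine precision on the unclamped
components. Negative pairwise FST values are clamped to 0 in reports
(the raw values are kept on the result object).

Permutation tests use the add-one rule `p = (count+1)/(n+1)`:
individuals are permuted among samples for FST, allele copies among
individuals within samples for FIS. `f_statistics_from_components`
accepts externally published variance components so a printed AMOVA
table can be turned into its implied F-statistics and stratum
percentages.

Null alleles: `brookfield1` `(He−Ho)/(1+He)` and `chakraborty`
`(He−Ho)/(He+Ho)`; under the generator's silencing mechanism (each
copy silenced independently; half-silenced genotypes read as
homozygotes) the Chakraborty estimator is exactly consistent and
Brookfield-1 is mildly conservative — the recovery test reflects this.
Allelic richness is exact hypergeometric rarefaction
`Ar = Σ[1 − C(N−Nᵢ, g)/C(N, g)]`, default `g` twice the smallest
per-sample count of complete genotypes.

## Hybrid index

The likelihood of hybrid index `h` (1 = pure species A) is
`Σ log[h p_A(a) + (1−h) p_B(a)]` over the allele copies of the called
panel loci. Each term is log-concave in `h`, so the log-likelihood is
concave and has a single maximizer. Alleles absent from a finite
reference panel receive a floor frequency `1/(2·panel_size + 1)` before
renormalization, so finite panels never produce −∞ likelihoods.

The maximizer is found by hierarchical refinement on a fixed 10⁻⁶
lattice over [0, 1]: a coarse 10⁻³ grid, then ±2-step windows at each
tenfold refinement. Because the likelihood is concave this equals the
global lattice argmax, and evaluating the mixture weights as
`k/10⁶` and `(10⁶−k)/10⁶` makes panel exchange map the evaluation at
`k` bitwise onto the evaluation at `10⁶−k`: swapping panels A and B
sends ĥ to 1−ĥ exactly at the estimator's resolution. A golden-section
refinement would be marginally faster but cannot guarantee that
symmetry, which the purity filter relies on.

Purity means ĥ at the upper boundary within an explicit tolerance
(default threshold 1.0, tolerance 10⁻⁶) — a grid optimizer legitimately
returns exactly 1.0 for individuals carrying only A-panel alleles, but
the tolerance keeps the filter well-defined if thresholds are moved.
Loci with heavy missingness can be excluded by name (a config list).

The hybrid generator draws each allele copy independently given the
individual's true `h` (no linkage), mirroring the likelihood, so
recovery is exact in expectation. Injected hybrids default to
`h ~ Beta(2, 2)` — a wide swarm centred on intermediate ancestry.
An individual whose 2L copies all happen to come from panel A is
indistinguishable from pure (probability `E[h^2L]` ≈ 2% for Beta(2,2)
at 7 loci), which bounds how precisely a mixing fraction can be
recovered by filtering.

## Geography and migration conversion

The default distance metric is degree-euclidean
(`111.19 km/deg × sqrt(Δlat² + Δlon²)` on raw coordinates) because it
is the study area's linear-distance convention and reproduces the
printed summary distances; haversine is provided as the geodetically
correct alternative (they differ by hundreds of km on long east–west
pairs at 55°N). `distance_summary` can collapse sites closer than a
threshold into one location: the bundled site table contains two
Wadden Sea mussel beds ~6 km apart which the study's printed
min/mean distances treat as a single location (any threshold between
those 6 km and the next-smallest 17 km pair gives the same result;
10 km is used).

Wright's infinite-island conversion `2Nem = (1−FST)/(2 FST)` is defined
for `FST > 0` only; non-positive values map to NaN and are excluded
from correlations.

## Mantel test for asymmetric matrices

A permutation is one random relabelling of sites applied simultaneously
to the rows and columns of the second matrix, preserving asymmetric
structure; the statistic is the Pearson (or Spearman) correlation over
all off-diagonal cells, both triangles. The diagonal is excluded
(FST's diagonal is structurally zero; local retention is reported
separately). All three alternatives are always computed with the
add-one rule; `p_two_sided` uses |r|. The observed statistic is
computed through the same code path as the permuted ones so the
identity relabelling ties exactly (otherwise one-ulp differences bias
small-n p-values — visible against the exhaustive 3! enumeration
oracle). Zero-arrival cells are genuine zeros, not missing data.

## Scaled experiment defaults

`stepping_stone_experiment` runs the whole chain at desk scale: 10
sites 25 km apart in a channel, residual 0.05 m/s along-channel flow
plus a 0.4 m/s M2 tide, 500 particles per site over a 10-day release
and 18-day tracking window, demes of 50 diploids, 7 loci at
`mu = 10⁻³`, 200 generations, 999 Mantel permutations. These sizes
keep a full run around one second while leaving a strong directional
exchange gradient. The expected outcome is a negative FST–arrivals
correlation; with only 45 site pairs and 7 loci the per-replicate power
is not 100% — occasional replicates show a weak correlation, which is
an honest property of a Mantel test at this problem size, not a defect
of the machinery.

## Known limitations

- The synthetic flow has no spatial velocity structure beyond the
  residual pattern; eddies, fronts and bathymetric steering are absent.
- AMOVA degrees of freedom follow the design sizes even with missing
  data (locus SS use pairwise deletion), matching common practice in
  descriptive software rather than per-locus df accounting.
- The hybrid model ignores linkage and genotyping error; panels are
  treated as known up to the floor correction.
- Migration conversion assumes island-model equilibrium; the package
  deliberately does not implement coalescent (non-equilibrium)
  migration estimation — external migration matrices can be compared
  generically through `offdiag_pearson`/`mantel_test`.
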