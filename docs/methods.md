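# Methods

This note records the statistical model, the concrete algorithmic and
numerical choices, and what the synthetic studies used in the test suite
do and do not establish.

## Probability model and standardisation

All analyses condition on the examinee table `pop[i, k]` (region *i*,
stratum *k* = sex × 5-year age band at examination; 10 strata) and assume
regional case counts are independent Poisson,
`o_i ~ Poisson(r_i e_i)`, with `e_i = Σ_k pop[i,k] pr_k` the indirectly
standardised expectation and `r_i` the regional relative risk.  The null
hypothesis everywhere is homogeneous risk, `r_i ≡ 1`: prevalence is
determined by the sex/age composition of examinees alone.

`pr_k` defaults to the internal marginal rate (stratum case total over
stratum examinee total), which enforces `Σ e_i = Σ o_i` exactly (checked
to 1e-10 relative).  Externally supplied reference rates are accepted for
reuse against a standard population; conservation then does not hold and
is not asserted.  `spr_i = o_i / e_i` is reported as missing when
`e_i = 0` (flagged as undefined when `o_i > 0` rather than infinite).

Ages are supplied pre-binned; the package never computes ages from dates.
Coordinates are taken as already-projected planar km (representative
points such as town halls); adjacency is an explicit edge list.  Both
choices keep GIS concerns out of the statistics.  Distinct regions at
zero distance are accepted with a warning (merged administrative offices
exist); an edge list mixing once-per-edge and both-directions conventions
is rejected as ambiguous.

## Flexible and circular scan

Windows for the flexible scan are, for each seed region, every connected
subset (under the supplied contiguity graph) of the seed plus its
K_max − 1 nearest neighbours by Euclidean distance that contains the
seed, up to size K_max.  This is the classic bounded enumeration for
irregularly shaped scans; subsets are enumerated duplicate-free by a
binary include/forbid recursion over bitmasks and deduplicated across
seeds.  Circular windows are the nested nearest-neighbour sets of each
seed (sizes 1..K_max).  Distance ties are broken by lexicographic region
id, so window sets are deterministic.

The statistic is the one-sided (high-risk only) Poisson log likelihood
ratio; windows whose inside rate does not exceed the outside rate score
zero, with 0·ln 0 := 0.  Windows with `e_Z = 0` or `e_Z ≥ E` carry no
comparison and score zero.  The restricted-likelihood ("risk-threshold
pre-filtered") scan variant is deliberately not implemented.

The null distribution is Monte Carlo: R replicates of a multinomial
allocation of the O observed cases across regions with probabilities
`e_i / E` (independent Poissons conditioned on their total), and
`p = (1 + #{replicate max LLR ≥ observed max LLR}) / (R + 1)`.  Ties on
the maximal LLR are broken toward the smaller window, then lexicographic
member ids.  Secondary clusters are reported greedily in decreasing LLR
order among windows disjoint from all previously reported ones, each with
a p-value against the same replicate maxima (conservative).  Defaults:
K_max = 15, R = 999, explicit integer seed.  Replicate evaluation is
vectorised as a sparse window-indicator matrix times the replicate count
matrix, chunked to bound memory.

With every case count zero the scan is degenerate and returns LLR 0 and
p = 1 rather than an error.

## C-index and MEET

The clustering index at scale λ (km) is
`C(λ) = z' A(λ) z` with `z_i = (o_i − e_i)/O` and
`A_ij = exp(−4 (d_ij/λ)²)` — weights fall to e⁻⁴ ≈ 0.018 at distance λ.
The Gaussian kernel is positive semi-definite, so with the diagonal
included C(λ) ≥ 0.  No asymptotic reference distribution is used: with
~100 cases over ~60 units the chi-square approximations are unreliable,
so inference is Monte Carlo only.

MEET shares one multinomial replicate set across the whole scale grid
(one draw per replicate serves every λ), preserving the cross-scale
dependence that the adjustment needs.  Per scale, the observed p is
`(1 + #{C_r ≥ C_obs})/(R + 1)`.  For the adjustment, each replicate is
ranked against all replicates at every scale, the per-replicate minimum p
over scales forms the null distribution of the best-scale p, and
`p_adjusted = (1 + #{min-p_r ≤ min-p_obs})/(R + 1)`.  The profile scale
`λ*` is the grid point minimising the unadjusted p (smallest λ on ties).

Default grid: 5 to 100 km in 5 km steps.  This covers scales from
single-neighbour contiguity to most of a 165 × 132 km study extent; a
grid whose top exceeds twice the map diameter triggers a degeneracy
warning (all weights ≈ 1).  The grid is a configuration choice, not a
fitted quantity.

Monte Carlo p-values are permutation-invariant in distribution but not
realisation-by-realisation (the replicate draws see relabelled bins), so
the relabelling test asserts exact invariance of C and agreement of the
p-values within Monte Carlo error.

## Ecological regression

`o_i ~ Poisson(r_i e_i)`, `ln r_i = β0 + β1 x_i`, fitted by IRLS
(statsmodels GLM, gradient tolerance 1e-8, max 100 iterations;
non-convergence raises with diagnostics).  The offset `ln e_i` makes
`exp(β)` rate ratios against the standardised expectation; with internal
standardisation the null model has `exp(β0) = 1` exactly.  Wald p-values
use the normal approximation; 95 % CIs are `exp(β̂ ± 1.96 SE)`.  AIC uses
the full Poisson log likelihood (including the ln o! terms), so
`AIC(null) − AIC(alt) = dev(null) − dev(alt) − 2` for one added
parameter — an identity the tests check, which pins the constant
convention without external data.

Quartile categories use linear-interpolation percentiles at 25/50/75 of
the region values (each region weighted equally); ties sit in the lower
category; an empty category is an error.  With 59 distinct values the
category sizes are 15/15/14/15.  Q1 is always the reference.  The trend
test refits with integer scores 1–4 as one continuous covariate and
reports that coefficient's Wald p — the conventional epidemiological
p-for-trend.  Models are strictly univariate: one covariate per model.

An independent check fits the same likelihood with a generic BFGS
optimiser; coefficients agree to 1e-6 on fixtures.

## Sensitivity analysis for undiagnosed screen-positives

Stratum diagnosis rates `q_k = diagnosed_k / tested_k` are computed among
confirmatory-tested positives, assumed regionally constant; strata with
zero tested positives get q = 0 with a warning.  Each run draws
`Binomial(u[i,k], q_k)` extra cases independently per region × stratum,
adds them to both the regional and the stratum case totals, re-runs the
standardisation (so `Σ e = Σ o'` holds inside every run), and re-runs the
enabled analyses.  T = 100 runs by default.

Seeding: the analysis seed is derived once from the master seed and
shared by the observed analysis and all runs; only the imputation seed
varies per run.  Consequences: (a) with an empty pool every simulated
p-value equals the observed one exactly — a structural identity the tests
assert; (b) run-to-run differences reflect imputation variability only,
not resampled null tables (paired comparisons).  The report carries the
full per-run p-value table plus box-plot summaries (min, quartiles,
median, max) next to the observed p-values.

When the undiagnosed pool is known only as regional totals, a documented
fallback allocates the totals to strata proportionally to the
screen-positive composition.

## Synthetic studies

The generator emulates the structure the analyses assume, at these
defaults: 59 regions on a jittered hexagonal lattice scaled to
165 × 132 km with Delaunay-derived adjacency (typical neighbour counts
≈ 6, as for real municipality maps, without polygon data); log-normal
region populations (σ = 1) normalised to 295,032 examinees; per-region
stratum shares Dirichlet-perturbed (concentration 80) around a uniform
composition; stratum prevalence rates proportional to a fixed age/sex
profile (rising steeply with age band, female ≈ 2:1) scaled so the
homogeneous-risk expected case total is 115; screen-positive rate
2246/295032 and confirmatory uptake 2051/2246, giving ≈195 undiagnosed
positives.  Embedded clusters set `r_i = RR` on a connected member set
chosen contiguously around a seed or within a radius; disconnected
requests are rejected.  Covariates are a distance-to-point-source field
plus smooth Gaussian-bump fields mapped to plausible ranges.

Cases are drawn `o_ik ~ Poisson(r_i pop_ik pr_k)` cell-wise, so the case
total is itself random (≈115 ± 11); calibration experiments that need a
fixed total instead draw multinomial case vectors conditional on O = 115,
matching the tests' null samplers.  The generator is bit-reproducible
from its seed, and the truth record (risk surface, cluster membership,
rates, totals) round-trips through the written CSV bundle.

What the synthetic studies do **not** emulate: participation differences
across regions, time-varying examination practice, within-municipality
heterogeneity, spatially structured confirmatory-uptake, or any real
dose surface.  Passing calibration and recovery tests therefore shows the
estimators and their Monte Carlo machinery are correct under the model's
own assumptions — not that those assumptions hold for any particular
registry.

## Problem sizes in the test suite

Monte Carlo experiments in the suite are sized for tight feedback while
keeping binomial error useful: null calibration uses one fixed geography,
300 studies × 199 replicates with K_max = 10 (rejection-rate standard
error ≈ 0.013 at α = 0.05); regression coverage uses 200 fits; cluster
recovery uses 30 studies with the window bound set to the designed
cluster size (5), as a power study would choose it.  Production defaults
remain K_max = 15 and R = 999.

## Known limitations

* The scan's secondary-cluster p-values are conservative (ranked against
  the primary's null maxima), the standard practice.
* The flexible enumeration is exponential in K_max on dense graphs; on
  planar contiguity at K_max = 15 it is ≈3×10⁵ windows for 59 regions,
  which is fine, but K_max near n on a dense graph is not intended use.
* MEET's adjusted p is itself a Monte Carlo rank of ranks; with R = 999
  its resolution is 1/1000 and small adjusted p-values saturate.
* Quartile conventions differ across software; results for heavily tied
  covariates depend on the documented lower-category tie rule.
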