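# Methods

This note documents the models implemented in `foragemap`, the choices made
where the procedure left room, and what the synthetic-data generators do and
do not emulate. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## GPS screening

Fixes are resampled to a common interval (default 14 400 s = 4 h) by keeping,
for each grid time counted from the first fix, the nearest fix within half an
interval; each fix is used at most once, so already-gridded data pass through
unchanged and the operation is idempotent. Capture-day trimming removes the
first and last UTC calendar days of the record plus the day of any capture
event (the timezone is a convention; the data carry no local-time semantics).

Error screening is two-staged. Stage 1 flags a fix farther than μ (default
50 km) from the median location of the *other* fixes inside a centred 20 h
window (truncated at the record ends), or farther than Δ (default 200 km)
from the whole-trajectory median. Stage 2 flags interior fixes whose inbound
and outbound speeds both exceed α (default 1.5 km h⁻¹) while the cosine of
the turn between the displacement vectors into and out of the fix is below
cos θ (default −0.97) — the geometric signature of an out-and-back spike.
Flagged fixes are retained with boolean flags rather than deleted, so the
screening is auditable; downstream stages drop them. The collar location
error of a stationary test site is √(sd(x)² + sd(y)²) with sample (n−1)
standard deviations.

## Time-local convex hulls

The time-scaled distance between fixes i and j is

    TSD(i, j) = sqrt(Δx² + Δy² + (s · v_max · Δt)²),

where v_max is the trajectory's maximum observed speed over consecutive
fixes and s ≥ 0 weights time against space. TSD is symmetric, non-negative
and never below the Euclidean distance, with equality at s = 0 or Δt = 0.

**Choosing s.** A point counts as *time-selected* when its k = 10
nearest-neighbour set under TSD(s) differs from the set under s = 0. The
proportion of time-selected points (ptsh) is evaluated on a log-spaced grid
s ∈ [10⁻⁴, 10] and refined by bisection between the bracketing candidates;
the returned s achieves a ptsh as close as possible to the 0.60 target.
The probe size k = 10 decouples this diagnostic from the hull-size
parameter. Neighbour ties are broken by point index, so the diagnostic and
everything downstream are deterministic.

**Neighbour rules.** The a-method adds neighbours in ascending TSD while
the running TSD sum stays within `a` (the parent is always included); the
k-method takes the k nearest points counting the parent itself; the
r-method takes all points with TSD ≤ r. Hulls are the convex hulls of the
parent-plus-neighbour coordinates; degenerate hulls (fewer than three
distinct positions) are retained with zero area, and a segment's perimeter
is counted out-and-back. Enclosed points are all fixes inside *or on* the
hull boundary.

**Revisitation.** The number of separate visits (NSV) of a hull is the
number of maximal runs of its enclosed timestamps with consecutive gaps at
most the inter-visit gap (IVG, default 43 200 s = 12 h). NNSV rescales NSV
by the maximum NSV in the hull set. This normalisation preserves the NSV
sort order exactly, so the isopleths are unaffected by the plausible
alternative normalisation (per enclosed point), which could reorder hulls.

**Isopleths.** Hulls are sorted by the metric descending (ties: smaller
area first, then lower parent index) and unioned progressively; the level-L
isopleth is the first union enclosing at least fraction L of all fixes. By
construction isopleths at ascending levels are nested. The 30% isopleth of
the NNSV-sorted hulls is exported as the core foraging area (CFA); a
species-level CFA is the union of its individuals' polygons with the
individuals retained as metadata.

**Choosing a.** For each candidate the 30%-level area and edge:area ratio
are computed; the selected `a` is the smallest whose relative edge:area
change against the previous candidate falls below `tol_ratio` (default
0.05) while the relative area increase at the next candidate stays within
`jump_tol` (default 0.50). The thresholds are configuration, not doctrine —
the underlying criterion (stabilised boundary complexity before the area
jump that bridges separate cores) fixes no numbers. When no candidate
qualifies, the fallback returns the candidate just before the largest
relative area jump; returning the minimum edge:area change instead would
systematically pick the largest candidate on smoothly decaying curves and
produce over-smoothed hulls that swallow the space between revisitation
cores. One caveat the tests encode: the area of the 30% isopleth is not
strictly monotone in `a`, because a larger `a` can reach the 30% level with
a single big hull slightly smaller than the union of several smaller ones;
the diagnostic curve grows with `a` up to that discreteness.

## Spectral resource models

Plot spectra are 3 × 3-cell means around each plot centre (plots are 6 m
squares on a 2 m grid). All ordered band pairs with strictly positive
denominators are ranked by the squared Pearson correlation of SRI = band
i / band j with the response; the top 100 enter model fitting. Forms:
linear (OLS), second-order polynomial (OLS), exponential
y = b₀·exp(b₁·x) by nonlinear least squares initialised from the
log-linear fit (skipped with a warning when any response is non-positive).
Leave-one-out predictions for the linear-in-parameters forms use the exact
leverage identity e_i/(1 − h_ii) — algebraically identical to refitting on
every n−1 subset, which the tests verify; the exponential form refits
explicitly. AIC = n·ln(RSS/n) + 2(p+1) on the full fit selects the model;
ties go to lower Theil's U, then fewer coefficients.

Theil's U = RMS(p−o) / (RMS(o) + RMS(p)) lies in [0, 1], is 0 exactly for
identical series, and is invariant to common positive rescaling. The
"share of samples predicted within 20%" statistic defaults to the
relative-error reading |error| < 0.2·|observed|; the alternative reading
|error| < 0.2·RMSE is available via `pct_mode="rmse"` but is nearly a
constant ≈ 16% for roughly Gaussian errors (2Φ(0.2)−1) and therefore
carries no information about fit quality. Both a calibration and a
cross-validated adjusted R² are reported on the model card, since either
convention is found in practice.

Non-grassland masking uses fully constrained linear spectral unmixing:
per-cell fractions minimise the squared spectral residual subject to
non-negativity and sum-to-one. The solver first solves the
equality-constrained least-squares (KKT) system for all cells at once and
falls back to sum-to-one-augmented NNLS wherever a fraction goes negative;
fractions are renormalised to the exact simplex and the grass mask is
fraction ≥ 0.5 (boundary in, robust to float round-off). Collinear
endmember spectra are rejected naming the offending pair. Predictions are
applied per masked-in cell and floor-clipped at zero; masked-out cells are
NaN.

## Species comparison

The sampling unit is the raster cell inside a species' CFA, pooled across
individuals within species (duplicate cells within a species count once;
cells under two species count in each — CFAs may overlap). BiomRS =
biomass/100 exactly. The three-class baseline-category logit fixes chamois
as reference (logit 1: ibex, logit 2: red deer) and is fitted by maximum
likelihood (Newton, BFGS fallback); standard errors come from the inverse
observed information. Reported degrees of freedom count all estimated
parameters across both logits (interaction 8, main effects 6, single
predictor 4, intercept 2). Non-convergence or coefficients beyond 10³ in
magnitude raise an error suggesting a separation check — genuinely
separated classes have no ML estimate.

Model selection fits the five candidate forms, reports each form's ΔAIC
against the minimum-AIC model and the likelihood-ratio test of each nested
form against the interaction model. Hosmer–Lemeshow groups each logit's
conditional probabilities into deciles (χ² = Σ(o−e)²/(e(1−e/n_g)),
df = groups − 2, degenerate groups merged with a neighbour); AUC is the
rank-based Mann–Whitney form with ties counted half, invariant under
monotone transforms of the scores. Buffer sensitivity re-extracts and
refits after buffering all CFAs by ±6 m and tests per-coefficient equality
with z = (b − b′)/√(se² + se′²), treating the two fits as independent —
conservative, since they share most of their data.

An interpretation caveat carried deliberately: interaction-model
main-effect coefficients are conditional slopes at zero of the other
predictor, and their signs are fragile under the strong BiomRS–BiomRS:N
collinearity even when the species ordering is unambiguous. The package
therefore also reports fitted-probability contrasts
(`probability_surface_ordering`): the change of P(species) between the low
and high quantiles of one predictor at the median of the other. These
contrasts summarise which species dominates where, robustly.

## Synthetic data: what is emulated, and what is not

**Trajectories** follow a scheduled patch itinerary — a biased correlated
random walk toward the currently scheduled patch, wandering inside it — so
revisitation is ground truth rather than emergent. Dwell times guarantee
that successive visits to a patch are separated by more than the configured
revisit period (24 h default, against the 12 h IVG); an explicit
`dwell_time` lengthens bouts so that commuting, whose corridors are
themselves revisited and would otherwise accumulate visit counts comparable
to the patches, stays a small share of the fixes. Per-fix displacement is
hard-capped at `step_scale`, keeping clean speeds far below the screening
threshold. Defaults: 43 days at 4 h fixes (259 fixes).

**Scenes** are 2 m grids whose biomass and nitrogen truths are
Gaussian-smoothed white-noise fields affinely mapped to configured
mean/sd (defaults 295 ± 110 g m⁻² and 2.1 ± 0.5%, floored at small
positive values; the biomass sd is kept below the heavily skewed spread of
real alpine grassland so a Gaussian field stays positive). Grass-cell
spectra start from a smooth grass endmember, receive smooth per-band
multiplicative variability (default 5%) — without which every band pair
sharing the planted numerator would be exactly collinear with the response
and the planted pair unrecoverable — and then the numerator bands are
overwritten so band i/band j equals the inverse of the planted relation.
The planted relations default to second-order polynomials: a planted
*linear* truth cannot be form-identified at the ≥95% level by any
AIC-style selector, because a quadratic overfits with the well-known ~16%
probability, whereas a genuinely curved truth is identifiable. Cells mix
the grass spectrum with forest/rock/snow/water endmembers on a softmax
simplex with grass dominance, then receive additive white noise floored at
zero reflectance. None of this is radiative transfer: no topography, no
anisotropy, no atmosphere, no sensor PSF.

**Species usage** samples grass cells with probability proportional to
exp(intercept + b_B·BiomRS + b_N·N + b_BN·BiomRS·N) per species.

**Study conditions of `run_study`.** The full chain runs at a deliberately
scaled problem size — a 200 × 200-cell (400 m) scene, 60 plots, 5 chamois /
7 ibex / 3 red deer individuals with 3 patches each — chosen by a
power-analysis argument: the variance of a species' mean resource use is
dominated by the number of *independent* patch sites its CFAs sample, not
by the number of cells. Hence patches are placed by the preference logit
evaluated on patch-scale (disc-averaged) resources, individuals of one
species keep distinct patch sets, patch dwell is weighted by preference
(animals revisit preferred patches more — the premise of
revisitation-based foraging maps), and a 0.2 availability floor mixes in
ordinary sites so the species' resource clouds overlap as real ones do.
Under these conditions the planted ordering (chamois at low biomass, ibex
at high nitrogen, red deer at high biomass) is recovered by the fitted
probability surfaces across seeds.

**Buffer invariance conditions.** `buffer_invariance_experiment` builds
the regime in which a ±6 m boundary shift cannot change conclusions:
resource fields varying at the regional scale (100 m correlation length,
far above the buffer), maps carrying white prediction noise at the accuracy
real band-ratio models achieve (biomass RMSE ≈ 230 g m⁻², N ≈ 0.45%), and
hectare-scale CFAs placed independently of the resource fields. Use-areas
centred tightly on resource optima genuinely attenuate their coefficients
when expanded and sharpen them when shrunk — a property of such data, not
an artifact of buffering, and one that grows with map precision because the
equality z-statistic scales like (buffer/size)·√n. The experiment
deliberately excludes that regime; the trajectory-based pipeline, whose
patches sit on preferred sites, can and does show the attenuation.

## Numerical conventions

- All randomness flows from `numpy.random.default_rng` seeds; child seeds
  stay below 2³¹. Identical config + seed reproduces every table.
- Hull union and point-in-polygon tests use planar shapely predicates;
  boundary points count as enclosed. Nesting assertions in tests compare
  difference areas rather than exact `covers`, which is brittle to
  float-boundary noise.
- The augmented-NNLS unmixing weight is 10⁴ on the sum-to-one row with a
  10⁻⁸ tolerance before the exact renormalisation.
- Coordinates are planar metres in an arbitrary local CRS; timestamps UTC.

## Limitations

- The movement model has no behavioural states beyond
  travel-versus-wander, no diurnal rhythm, and no memory beyond the fixed
  itinerary; passing tests show the hull machinery recovers *planted*
  revisitation, not that real behaviour is this simple.
- Spectral truth is planted in exactly two band ratios; real canopies
  spread information across many correlated bands, so the uniqueness of
  the selected pair is an artefact of the construction.
- Cell-level pooling treats raster cells as independent observations, as
  the large-n z-statistics of the source analysis imply; spatial
  autocorrelation within CFAs makes all standard errors optimistic, which
  is visible in the buffer-sensitivity behaviour of precise maps.
- Single scene, single season: no phenology, no between-year comparisons.
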