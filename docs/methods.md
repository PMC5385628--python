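# Methods

`legrange` models where plant species establish outside their native
range. The motivating system is the legume family: most legume species
depend on symbiosis with nitrogen-fixing rhizobia acquired from soil, and
the question is whether that dependency limits establishment in new
regions once confounding species traits and human-mediated introduction
effort are controlled for. The package provides the full chain — synthetic
data generation, range geoprocessing, covariate construction, model
fitting and bootstrap inference — so that every stage is testable without
any external download.

## The occupancy model

The response is a complete species × region binary matrix $Y_{ij}$: 1 if
species $i$ is recorded non-natively in region $j$, 0 otherwise (cells
where the species is native carry 0 — the response is "found
non-natively", not "present"). The model is a binomial GLMM with logit
link and crossed random intercepts,

$$Y_{ij} \sim \mathrm{Bernoulli}(P_{ij}), \qquad
\mathrm{logit}(P_{ij}) = \alpha + \beta_{SS}\,SS_i + \textstyle\sum_k \beta_k x_{ik}
 + \beta_z x_{jz} + \beta_{int}\,SS_i u_i + SP_i + RE_j,$$

with $SP_i \sim N(0, V_{species})$, $RE_j \sim N(0, V_{region})$.
$SS_i$ is the binary symbiosis trait (1 = symbiotic), $x_{ik}$ are the
species covariates (absolute native-range centroid latitude, total native
area — both centred and scaled; woody and annual, possibly fractional
after imputation; human-use count $u_i$ on its raw 0–11 scale), and
$x_{jz}$ is the centred/scaled region area. $u_i$ is deliberately left
unscaled because zero uses is the meaningful reference point at which the
symbiosis main effect is read. A third crossed intercept for continent
can be switched on; `continent_check` fits it and recommends removal when
its variance is negligible.

Two variants are fitted: all species, and only species occurring in at
least one non-native region (rows restricted, all region columns kept).

## Estimation

The marginal likelihood integrates over $(SP, RE)$; with crossed effects
it does not factorise, so the package maximises the Laplace approximation

$$\log L(\beta, \theta) \approx \log f(y \mid \beta, \hat u)
 - \tfrac12 \hat u^\top P \hat u - \tfrac12 \log\det H_u(\hat u)
 + \tfrac12 \log\det P,$$

where $\hat u$ is the penalised mode, $P$ the precision of the random
effects and $H_u$ the penalised information in the random effects.
Because every cell couples exactly one species with one region, $H_u$ has
an arrow structure — the species block is diagonal — and each inner
Newton solve (PIRLS, with step halving) reduces via a Schur complement to
a dense system of size $n_{regions}$ (+ continents). The determinant uses
the same factorisation. This makes a full 3,530 × 51 fit take seconds in
pure NumPy.

The outer optimisation runs over the fixed effects *jointly* with the log
standard deviations of the variance components (L-BFGS-B, forward
differences), exactly as lme4's Laplace scheme carries $\beta$ in its
outer optimiser. This matters: profiling $\beta$ at the joint penalised
mode instead is appreciably biased for rare-event data, because the
log-determinant term depends strongly on $\beta$ there. A cheap profile
pass (Nelder–Mead over the log-SDs with $\beta$ at the joint mode)
supplies the starting point. On identical simulated data the fit agrees
with `lme4::glmer` to four decimal places in all coefficients, variance
components and log-likelihood (checked at 600 × 30 and 3,530 × 51; a unit
test re-runs the comparison through `Rscript` at small scale).

Numerical choices: log-SD floor at $e^{-12}$ with boundary flagging;
working weights floored at $10^{-10}$; inner gradient tolerance
$10^{-10}$, outer `ftol` $10^{-10}$, at most 200 outer iterations;
suspected complete separation flagged when $|\hat\eta| > 30$ or any
$|\hat\beta| > 20$. With both variances pinned to zero the fit reduces
exactly to IRLS logistic regression (tested against statsmodels to
$10^{-6}$). Reported standard errors are conditional (fixed-effect block
of the inverse penalised information at the mode); the primary inference
route is the bootstrap.

## Parametric bootstrap

Significance testing simulates $B = 1000$ (default) response matrices
from the fitted model, refits the full model to each, and takes empirical
type-7 (linear-interpolation) quantiles of the refitted coefficients at
95/99/99.9%; an effect is starred when its interval excludes zero. Per
the source procedure, simulation *conditions on the random-effect
modes* (`conditional=True`, the default); a flag switches to fresh
random-effect draws from the fitted variances.

The two schemes answer different questions. The conditional scheme
reproduces the published procedure and measures uncertainty given this
world's species and regions; measured across repeated synthetic studies
it badly undercovers the generating fixed effects (≈67% pooled at
nominal 95% on 200 × 20 studies, worst for the region-level covariate,
because random-effect variability is held fixed). The unconditional
scheme is the standard parametric bootstrap for mixed models and is the
one whose across-study coverage is validated in the acceptance suite.

Refits warm-start from the original optimum and use a quasi-Newton
iteration that reuses the original fit's finite-difference Hessian, with
a relaxed gradient tolerance (2×10⁻²) far below bootstrap Monte-Carlo
noise; spot checks agree with fully converged refits to four decimals.
Replicate seeds spawn from a master seed via `SeedSequence`, so results
are independent of execution order.

Two bootstrap-based summaries translate coefficients into region counts:

- **Group means** (`effect_summary`): simulate with every covariate at
  zero (symbiosis at observed values), average the per-species row sums
  by symbiosis group — model-based group means in the manner of
  least-squares means.
- **Interaction profile** (`interaction_profile`): at each human-use
  level $u$, predict per-group expected numbers of non-native regions and
  report $(N_s - N_{ns})/N_{ns}$, negative when symbiotic species occupy
  fewer regions. On the fixed-effects-only path the sign flips where
  $\beta_{SS} + u\,\beta_{int} = 0$; at the published all-species
  coefficients that is $u = 0.523/0.152 \approx 3.4$, i.e. between 3 and
  4 uses.

## Synthetic worlds

`generate_world` draws a complete dataset with known ground truth.
Defaults reproduce the published study's structure: 3,530 species (812
for the non-native-only variant), 51 regions, 91.0% symbiotic species
(3,213/3,530), human-use counts from a zero-inflated Poisson solved to
match $P(0)=0.70$ and mean 0.77 and truncated at 11, woody/annual
prevalences 0.5/0.2 with correlation −0.49 (an antithetic-coupling
mixture; −0.49 sits near the attainable bound −0.5 at these prevalences),
and occupancy drawn from the GLMM above with the published fitted
coefficients and variances (4.83/0.85 all-species; 0.9/1.43
non-native-only). Continuous covariates are emitted already standardised
so the fitting stage's scaling is a near-identity and fitted coefficients
compare directly to the generating ones.

Native ranges (1–5 regions per species, uniform — the source does not
state this distribution, so it is a stand-in) are assigned *after*
drawing $Y$, among each species' zero cells; this keeps "native cells
carry $Y=0$" true by construction without altering the generating
likelihood. In the vanishingly rare case of an all-ones row the smallest-
$\eta$ cell is zeroed and counted in `n_forced_native`.

Geography is deliberately schematic: regions are non-overlapping
rectangles tiling a lon/lat grid between ±63° latitude, each split into
two areas, grouped into six continents. This exercises every geometry
path (touching polygons, hierarchy rollup, promotion) deterministically,
but does not emulate coastlines, realistic region shapes, antimeridian
wraps, taxonomically structured traits or temporal spread — so passing
tests certify the statistical machinery, not realism of any particular
map. The export path (`emit_occurrence_records`) can down-code records to
area level (half under names absent from the gazetteer, exercising the
one-level fallback), inject "unknown" statuses and blank trait values at
configured rates; with all rates at zero, ingestion reproduces the
generator's occupancy matrix exactly (round-trip tested, including under
down-coding).

## Range processing

Occurrence records name a gazetteer unit at one of four levels
(continent > region > area > country) with its parent. Matching is exact
on (level, name), else the parent name one level up ("promoted"), else an
error. Per species, only records at the lowest available level are kept
and unknown-status records are dropped (species with only unknowns
disappear). Same-status polygons that touch are merged with a union-find
pass into non-contiguous ranges; occupancy rolls sub-region records up to
their region ancestor through the gazetteer's parent chain, never by
spatial containment.

Geometry conventions: WGS84 lon/lat degrees; polygons crossing the
antimeridian must be pre-split at ±180°; areas via the
Chamberlain–Duquette line integral on a sphere of radius 6371 km (within
1% of closed forms on test cells); centroids are planar per polygon,
area-weighted across polygons; distances are haversine; containment is
boundary-inclusive. Range dispersion — the source names the concept but
not the formula — is implemented as the mean pairwise great-circle
distance between non-native range centroids, and is undefined (raised,
not 0) below two ranges. The figure-data path merges non-native ranges
closer than 5 degrees, read as great-circle arc between nearest boundary
points (the caption's "Latitude-Longitude" is ambiguous; configurable).

## Covariates

Missing woody/annual values are filled by taxonomic mean imputation:
the mean over observed congeners, else observed tribe members, recorded
in a provenance column; donors are only observed values (single pass, no
chaining) and an empty tribe raises. Human uses are the cardinality of a
species' subset of the 11 recognised use categories. Scaling uses the
sample SD ($n-1$); scaling metadata is retained for exact inverse
transforms.

## Known limitations

- At the paper-calibrated all-species configuration (intercept −8.055
  with $V_{species} = 4.83$: an extreme rare-event regime), Laplace ML is
  not self-consistent: refitting data simulated at those values
  systematically overestimates the species variance (≈7.8) and the
  human-use coefficient (≈1.11 vs 0.964), while the symbiosis, annual
  and interaction coefficients recover well. This is a property of the
  estimator itself — `lme4::glmer` returns the same optimum on identical
  data — not of this implementation; the corresponding acceptance checks
  are left failing rather than widened.
- Conditional (mode-fixed) bootstrap CIs undercover across repeated
  studies, as discussed above; they are nevertheless the default because
  they reproduce the source procedure.
- The generator's latitude/area covariates are standardised stand-ins
  drawn independently of the synthetic map; the geometry-derived
  covariate path exists (`covariate_source="geometry"`) but then the
  generating coefficients no longer apply to the latitude/area columns.
- Phylogenetic structure, alternative imputation schemes and live data
  acquisition are out of scope.

## Problem sizes used in the shipped checks

Full-calibration recovery runs 5 seeds at 3,530 × 51 and 5 at 812 × 51
(seconds per fit). Bootstrap coverage uses 50 studies at 200 × 20 with
B = 200; oracle and geometry checks run on toy fixtures in milliseconds.
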