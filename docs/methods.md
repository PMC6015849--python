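# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `nichetime`, and what the test suite does and does not
establish about real data.

## Activity scoring and shifter definitions

Each species carries integer usage classes for day, twilight and night:
0 (not used), 1 (primary/frequent), 2 (occasional/rare); at least one period
must be primary. Strictness is order-specific: hawks and falcons are strict
when exclusively day-active (any twilight or night use, even occasional,
breaks strictness), while owls are strict when they use the night and not the
day — twilight belongs to the owl night, so night+twilight owls are strict
and exclusively crepuscular owls are not. Time-shifters are hawks with any
twilight/night use and owls that are not strict; for both orders the shifter
call is exactly the complement of strictness. Falcons are rejected from
shifter calls because their ancestral state is mixed, which leaves the
direction of a shift undefined. Occasional (class 2) use counts for shifter
calls but **not** for interference indices, which count class-1 competitors
only.

The packaged worked-example table (`synthdata.paper_fixture`) is synthetic in
its species identities and body sizes; only its marginal category counts are
faithful to the published tallies (158/192/46 species; 38 and 71 shifters;
day-active shares 91% and 65%; night-active share 92%; 43 small and 28 large
owl shifters; 48 migratory). Two published counts cannot hold
simultaneously with "all 38 hawk shifters also day-active" (that would make
158/158 day-active, not 144/158), so the fixture gives 14 of the 34
twilight-active hawks no day use; similarly 9 of the 33 day-active owls get
no night use so that 177/192 are night-active.

## Mk ancestral states

The strict/non-strict character follows a 2-state continuous-time Markov
model with a single rate q (equal rates):
P(stay) = (1 + e^{−2qt})/2 per branch of length t. The likelihood is
computed by Felsenstein pruning with per-node rescaling; q is maximized by
bounded scalar search over log-spaced brackets between 0.01/h and 100/h
(h = mean tip depth), because the likelihood often has an interior peak that
a single wide bracket loses against the saturation plateau at large q.
The root prior is flat (½, ½), so the root posterior equals the scaled root
conditional likelihoods — the common ML convention; the prior is an argument
for sensitivity analyses. Over a tree sample the consensus averages root
posteriors (majority vote over per-tree argmax calls is available); the two
rules can differ only when per-tree posteriors straddle ½. Monomorphic tip
data yield q̂ = 0 and a point-mass root posterior, flagged on the result.

## Pagel's λ and PGLS

The Brownian covariance C has entries equal to the shared root-to-MRCA path
length; V(λ) multiplies off-diagonal entries by λ ∈ [0, 1] and keeps tip
variances. λ is estimated by bounded search over three sub-intervals of
[0, 1] (plus the λ = 1 endpoint) on the REML profile likelihood; REML rather
than ML because the regression variants use the estimated residual variance
for standard errors, and REML keeps their type-I error near nominal. With
λ = 0 on an ultrametric tree the model collapses to i.i.d. regression and
PGLS reproduces OLS exactly; with λ = 1 the slope equals the
independent-contrasts slope. Star trees make λ unidentifiable: flagged,
λ set to 0. Non-ultrametric trees only trigger a warning since λ-GLS assumes
comparable tip heights. The representative tree of a sample is the one whose
λ̂ is the sample median (lower median for even counts).

## Grid, ranges, competition indices

The analysis grid is an axis-aligned square tiling (default 112.5 km) of the
spherical Mollweide plane (authalic radius 6371.007 km); forward projection
solves the auxiliary angle by Newton iteration to 1e−12, and cells are
retained when their centroid inverts to valid geography. A species occupies
every cell its projected breeding-range polygon intersects (boundary touch
counts; a minimum-area fraction is available but defaults to 0). Polygon
edges are densified to ~25 km before projection so straight projected edges
track the curved image of long geographic edges. Polygons crossing the
antimeridian are split automatically on read.

Exploitation pressure = total predator richness of the cell; interference
pressure = richness of species with class-1 use of the focal order's typical
period (day for hawks, night for owls), counted across all three orders.
For the large-owl model both counts keep only competitors > 30 cm. The focal
species is not excluded from its own cell's counts (an exclude-self option
exists). Time-shifter richness is zero only where the order — or, for the
small/large owl models, the subgroup — occurs at all; cells without it are
missing for that model. Realms are assigned by cell-centroid containment.

## Photoperiod

Day length uses the standard sunrise equation with solar declination from
Spencer's Fourier series (|error| ≈ 0.03°); night length replaces the
horizon by a 6° depression (civil night) and can reach zero in polar summer.
No refraction or solar-disc correction is applied: the "centre of the solar
disc" convention is geometric. Under that convention the sun at 60°N still
dips 6.56° below the horizon at the June solstice, so civil night reaches
zero only poleward of ≈ 60.6°; the white-night check therefore sits at 62°.
Each cell is evaluated at its local hemisphere's summer solstice (June 21 /
December 21; a fixed-date mode is available for sensitivity). Against an
independent NOAA/Meeus-style oracle the day and night lengths agree to
within 1.5 minutes for |φ| ≤ 80°.

## Hartigan's dip

The dip — the sup-distance from the empirical CDF to the nearest unimodal
CDF — is computed exactly by the iterative greatest-convex-minorant /
least-concave-majorant algorithm in count units: the minorant fits the
ECDF's left limits, the majorant its right limits, the modal interval is
narrowed at the largest majorant-minorant gap, deviations over discarded
flanks accumulate, and the result is half the largest deviation, floored at
1/(2n) (the value taken for equally spaced samples and for the degenerate
all-equal case). The implementation is validated against an independent
linear-programming oracle (minimal sup-distance over piecewise-linear
unimodal CDFs, every peak segment enumerated) to 1e−9 for n ≤ 12.
p-values are Monte-Carlo under the uniform null with a plus-one correction
(default 9999 draws, seeded) rather than interpolation tables; a shared null
table can be passed in for calibration studies.

Size ties at exactly 30 cm go to the *large* group (the published split
states only greater/less than 30, leaving 30 unassigned).

## Spatial realm mixed model

The assemblage model is y = Xβ + Zb + ε with z-scored response and fixed
effects (interference, exploitation, day/night length), a realm random
intercept and random slope on the scaled total-richness predictor
(unstructured 2 × 2 Ψ; diagonal option), and within-realm residual
correlation r(d) = (1 − c)·f(d/ρ) with f exponential (default), gaussian or
spherical, plus nugget proportion c ∈ [0, 1]; r(0) = 1, no cross-realm
correlation. Distances are Euclidean in projected Mollweide km. The count
response is modelled as Gaussian after scaling — a deliberate reproduction
choice, not a claim that a Poisson model would be wrong.

Estimation profiles β and σ² out of the (restricted) likelihood and
optimizes the remaining parameters (log ρ, logit c, log-Cholesky of Ψ/σ²)
by L-BFGS-B from three starts with different initial ranges (quarter, one
and two times the median pairwise distance); convergence tolerance 1e−10 on
the criterion. Structure comparison always refits by ML so AICs are
comparable; REML likelihoods are never mixed. The implementation is checked
against R nlme (`gls`/`lme` with `corExp(nugget=TRUE)`) on frozen fixtures:
coefficients agree to ~1e−5 and the REML optimum is at least as good as
nlme's. Simultaneous 95% intervals use the single-step max-|z| critical
value, a seeded Monte-Carlo quantile (default 1e5 draws) under the fitted
coefficient correlation; with one coefficient this reduces to 1.96, with
independent coefficients to the Šidák value.

Per-realm subsampling draws round(fraction·n_realm) cells without
replacement (default 40%), seeded and deterministic.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their seed. Yule trees start at the root
split and run until the waiting time after the n-th lineage (expected height
Σ_{k=2..n} 1/(kλ_b)); heights are normalized to 1 where rates are quoted
per unit height. Activity states evolve under the Mk model, or — for
ancestral-state experiments — whole clades holding 2–10% of tips are marked
non-strict until a target fraction is reached, mimicking the strongly
clade-concentrated shifters of the real orders (most small owl shifters
belong to a single genus) rather than the scattered pattern a stationary Mk
draw produces. Log10 sizes are Brownian draws on V(λ) plus a shifter offset
(default −0.15, the direction and rough magnitude of the reported contrast).
Ranges are discs with log-normal radii (median 400 km) centred uniformly in
a regional window (default ±1200 km, ≈ 440 cells, four longitude-band
realms); species counts default to the compiled totals (158/192/46).
Responses for recovery experiments come from the spatial model itself with
β = (0.5, 0.3, −0.2), ρ = 200 km, nugget 0.3, σ² = 1 and realm RE standard
deviations (0.2, 0.1).

Problem sizes in the tests are desk-scale by design: recovery experiments
use 4 realms × 100 cells (bias of each coefficient < 0.05, simultaneous
coverage ≥ 90% over 100 replicates), and correlation-structure selection
uses 2 realms × 300 *randomly placed* locations (span 1500 km, ρ = 150 km,
nugget 0.05). The random layout is essential there: on a 112.5 km lattice
the smallest observable distance is one cell width, and with a free nugget
the exponential, gaussian and spherical families are nearly unidentifiable —
the information that separates them sits at distances well below the lattice
spacing. This is a real limitation for lattice data, not an implementation
artefact.

Passing tests show the estimators recover known truths under the model's own
assumptions (Yule topology, disc ranges, Gaussian responses, band realms).
They do not establish behaviour under real-world features the generator
omits: range-shape irregularity, richness gradients, non-Gaussian counts,
realm shapes, or tree uncertainty beyond Yule samples.

## Known limitations

- Two-state characters only; no rate heterogeneity or Bayesian ASR.
- The Gaussian response ignores the count nature of richness.
- λ-GLS assumes ultrametric-like tip heights (warned, not enforced).
- The dip's Monte-Carlo p-values are exchangeable with, but not identical
  to, the classical interpolated tables.
- Global grids carry ~49,000 cells; REML fits at that scale need the
  per-realm subsampling step (as in the original design) to stay tractable.
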