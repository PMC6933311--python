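# Methods

This note documents the models, parameter choices and numerical behaviour of
sealflux, in the order the pipeline runs. It is the package's account of its
own science: everything quantitative stated here is computed by the test
suite or the example scripts.

## Study table

The packaged dataset (`load_study_table("table1")`) holds one row per seal
foraging trip: at-sea FMR (W kg⁻¹), fasting-adjusted mass change (kg), water
influx (ml kg⁻¹ day⁻¹), trip duration (days), percent of at-sea time diving,
mean maximum dive depth (m), milk fatty-acid diet cluster (1–3) and the
frontal surface area of the carried instruments (cm², a drag proxy). Seals
measured in both summer and fall contribute two rows (summer first); 48
measurements from 33 seals in total. One seal has a single FMR value printed
against two seasons of behavioural data; the value is stored with the summer
row and the fall FMR is left missing (a second number cannot be invented),
so FMR models use 47 complete cases. Where a single diet-cluster label or
tag area spans both of a seal's rows, both rows inherit it. Values are
stored exactly as printed, including mixed precision in the tag areas.

## DLW energetics

*Total body water.* The plateau (initial) estimate divides the moles of
excess ¹⁸O delivered — dose mass × atom-percent enrichment / 18.015 — by the
background-corrected atom-fraction excess at equilibration, and shrinks the
resulting dilution space by a configurable factor, default **1.007**, the
conventional allowance for the ¹⁸O space exceeding true body water. The
scaling (final) estimate assumes constant fractional water content:
`TBW_final = TBW_initial × mass_final / mass_initial`. A ³H-dilution
alternative is supported through the 2.22 × 10⁹ dpm mCi⁻¹ conversion, but
¹⁸O is the default tracer for pool size.

*Turnover.* `k = [ln(C_eq − C_bg) − ln(C_final − C_bg)] / Δt` per label,
with Δt in decimal days. A final concentration at or below background raises
`WashoutError`: the label has decayed into the assay noise and the
measurement is unusable (nearly half of the original field measurements were
lost this way; the synthetic generator reproduces the mechanism with a
configurable exclusion threshold, default 2 ppm final ¹⁸O excess).

*CO₂ production.* Default is the two-pool form
`rCO2 = (N/2.078)(k_o − k_d) − 0.0062 k_d N` (mol day⁻¹, ×22.4 to litres).
A single-pool form, `(N/2.078)(k_o − k_d) − 0.0246·1.05·N(k_o − k_d)`, is
selectable by configuration. Which exact published equation the original
analysis used cannot be determined from its text alone, so the forward
simulator is the arbiter: each form is inverted exactly by the generator
configured to match.

*Partitioning.* Mass-specific FMR uses 23.9 kJ L⁻¹ CO₂ and the mean of
initial and final body mass (a symmetric choice; the reference mass is not
otherwise specified). At-sea FMR is
`(FMR_total × interval − MR_onshore × t_onshore) / t_at_sea`. The onshore
metabolic rate is a **required** configuration parameter with no hidden
default; values near 4–5 W kg⁻¹ are typical of lactating otariids ashore,
and the synthetic generator uses 4.4 W kg⁻¹. At-sea FMR decreases strictly
as the assumed onshore rate increases, so this assumption should always be
reported alongside results.

*Water influx and mass gain.* With the pool changing linearly, efflux is
`k_d` times the mean pool and influx adds the pool's net change per day,
reported in ml per kg of reference mass. Mass change is adjusted for fasting
loss ashore by adding `fasting_rate[season] × t_ashore`; the rates come from
fur-seal fasting literature and default to 0.5 (summer) and 0.6 (fall)
kg day⁻¹ in the generator — they are configuration, not constants.

## Dive processing

Depth is sampled at 5 or 10 s with 1 m resolution. The zero-offset
correction estimates the surface baseline as a centred rolling 10th
percentile over a 2 h window, median-smoothed over the same window, and
subtracts it, flooring corrected depths at −1 m (one unit of sensor
resolution). The original tag-vendor software is undocumented, so this
behaviour is fixed and tested rather than claimed equivalent. Dives are
maximal runs of samples **strictly** deeper than the 3 m threshold — samples
at exactly 3 m are surface — with start/end at the first/last supra-
threshold sample (no crossing interpolation, consistent with the sensor
resolution). Trip summaries report dive count, mean of per-dive maximum
depths (undefined without dives), percent of trip time diving, and — when
night windows are supplied as time intervals — the percentage of dives whose
midpoint falls at night. Day/night is an input, not an ephemeris
computation.

## Track processing

Distances are haversine on a spherical Earth (R = 6371 km), adequate at the
3 m s⁻¹ filtering scale. Quality classes B and Z are dropped. The speed
filter iteratively removes the interior fix whose removal most reduces its
local implied speed (current worst adjacent speed minus the post-removal
bridge speed) until all adjacent speeds are admissible; this distinguishes a
genuine spike (fast on both sides, bridging to a slow segment) from its
innocent neighbours, and on small tracks removes exactly the minimal number
of fixes (verified against exhaustive search). With only two fixes nothing
is removed: their mutual speed cannot identify the bad one. Hourly positions
default to great-circle (slerp) interpolation; a correlated-velocity Kalman
smoother on a local planar projection (`ctcrw_lite`) is provided for users
who want a continuous-time random-walk flavour without the full state-space
machinery, which is out of scope. Habitat classification takes
**user-supplied** bathymetry and mixed-layer-depth grids (regular lon/lat,
nearest-cell lookup): shelf means local depth shallower than a configurable
isobath (default 200 m, the outer-shelf contour; the defining contour is a
user decision), below-MLD means dive depth exceeds the local mixed layer.
Positions outside a grid are labelled unknown rather than extrapolated.

## Fatty-acid clustering

Profiles are restricted to a configurable dietary-FA list (19 marine dietary
FAs by default) whose study-wide mean abundance is ≥ 0.5%, re-closed to
100%, and CLR-transformed after multiplicative zero replacement (zeros →
0.65 × smallest nonzero, rows re-closed). Ward clustering reports heights in
squared-Euclidean units — the dialect that applies the Lance–Williams Ward
update directly to squared distances; the merge order is identical to the
plain-distance dialect, whose heights are the square roots, and a flag
toggles the reporting.

The dynamic tree cut is branch-adaptive rather than a single height cut. A
branch is split where its sorted merge-height profile shows a significant
gap, judged by two conditions: the join above the gap must exceed 2.5× the
height just below (a clear local jump), **and** its joining cost must stand
out against the branch's internal structure,
`d · h_join / Σ(heights below) > 2.5`, where d is the dimensionality of the
clustered vectors. The sum of a subtree's squared-unit heights is
proportional to its within-cluster sum of squares, and dividing the
split's cost by the per-dimension within-SS makes the statistic invariant
to both branch size and dimensionality: across simulated homogeneous
Gaussian branches (15–300 members, 2–19 dimensions) it stays below ~1.7,
while true cluster joins in Dirichlet mixtures of the study's kind sit
above ~4 regardless of sample size. The branch is cut at the geometric
mean of the lowest significant gap and the procedure recurses into each
component. Components smaller than `min_cluster_size` (default 20) are
fringe and are merged into the neighbour they join lowest in the tree. The
procedure is deterministic given the tree; identical profiles yield one
cluster. Height factors are expressed in squared-height units.

Discriminant loadings come from a multiclass LDA on the CLR vectors (SVD
solver, which tolerates the CLR's structural rank deficiency — rows sum to
zero), standardized by pooled within-class SD and ranked by largest absolute
loading across the discriminant axes.

## Model selection and averaging

All `2^p` main-effect subsets (no interactions) are fit by **ML**, not REML,
so likelihoods are comparable across fixed-effect structures. Categorical
codings: season with summer as reference; diet cluster with cluster 1 as
reference. Where a random intercept is requested, a linear mixed model is
attempted first; a boundary variance estimate (≤ 10⁻⁶), a singular fit, or
non-finite standard errors trigger a refit as a plain linear model — on the
packaged table every candidate lands in this regime or very close to it,
matching the original report that the individual-effect variance was
estimated at exactly zero. Parameters are counted as fixed effects +
residual variance (+ random-intercept variance when retained), and
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`. Candidates with `n ≤ k+1` are dropped
with a warning. Coefficients are averaged **conditionally** (over models
containing the term, weights renormalized) within the 95% cumulative-weight
confidence set — the minimal weight-sorted prefix reaching 0.95 — with
Burnham–Anderson unconditional SEs and normal-based 95% CIs (±1.96 SE; no
degrees-of-freedom correction). Percent effects divide the averaged
coefficient by the averaged intercept.

Reproduction caveat: the packaged table stores the printed, rounded values
(1–2 decimals), while the original models were fit to unrounded data. The
refitted averaged intercept (7.47 vs 7.36 W kg⁻¹) and fall effect (+7.1% vs
+7.2%) agree to within ~1.5%, but the trip-duration effect lands at −2.1%
per day against the published −1.9%; the discrepancy is stable across every
defensible convention (mixed vs plain fits, parameter counting, averaging
over all candidates vs the confidence set) and is attributed to input
rounding. The foraging-success candidate set originally included initial
body mass, which the trip table does not record; refits omit it and the
reports say so.

## Synthetic data

The generator's defaults are the study conditions: 33 seals with a 15/33
chance of being measured in both seasons; at-sea FMR intercept 7.36 W kg⁻¹,
+7.2% fall effect, −1.9% per trip day, zero individual SD (the repeated
measures carried no detectable individual signal) and 0.8 W kg⁻¹ residual
SD; trip durations 6.5 ± 1.6 days with ~1.8 days ashore; masses 36 ± 5 kg
clipped to the observed 26.0–47.6 kg range; at-sea mass gain 4.6 ± 2.7 kg;
body water 60% of mass; per-cluster water-influx means (187.7, 158.1,
144.3, 165.0 ml kg⁻¹ day⁻¹) taken from the packaged table's cluster means.
Milk FA profiles are Dirichlet draws (concentration 400) around four
centroids styled on squid-dominated, age-0 pollock, adult pollock and a
fourth mixed diet; cluster probabilities (0.38, 0.27, 0.23, 0.12). Dive
records are nocturnal bouts (21:00–06:00, ~18 dives per night hour, depths
lognormal around 26 m, 1 m s⁻¹ vertical speed, quantized to 1 m); tracks
are correlated random walks from the colony observed through ARGOS-like
class-dependent error. A single `numpy` Generator seeded from the
configuration drives all randomness, so runs are byte-reproducible.

The generator is forward-consistent by construction: `simulate_washout`
computes the `k_d`, `k_o` implied by the configured CO₂ and water-budget
equations and emits the concentrations they predict, so the analysis chain
recovers the true CO₂ production, influx, FMR and mass gain to ~10⁻¹⁴
relative without noise, and without bias under 1% lognormal assay noise.
What the generator does **not** emulate: analytical drift between assay
batches, isotope fractionation corrections, real oceanography or prey
fields, haul-out behaviour within trips, and individual heterogeneity in
the FMR model beyond a configurable Gaussian intercept. Passing tests on
synthetic data therefore validate the estimators' algebra and the
pipeline's plumbing, not the field method's biological assumptions.

## Problem sizes and runtime

The test suite fits ~64-model candidate sets on the 48-row table in a few
seconds; Monte-Carlo checks use 200–500 replicates of small candidate sets
at n = 48, 30–40 replicate synthetic studies for effect recovery, and
291-profile clustering runs. The full suite completes in well under a
minute on one core; a complete synthetic study with dive series runs end to
end in a few seconds.
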