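# Methods

## Scope and model structure

`basinopt` finds Pareto-optimal programmes of measures for a river basin
described at two nested scales: hydrologic catchments (the units of the
environmental indicator) and administrative regions (the units of decision).
A strategy assigns one reduction rate to every (region, sector) pair — the
*drivers*.  The quality module has four nitrogen sectors (manure and mineral
fertilization on the diffuse pathway; point sources and scattered dwellings
on the point pathway); the quantity module has five abstraction sectors
(domestic, energy, livestock, irrigation, industrial).  Both objectives are
minimized: weighted total effort, and an aggregation of the per-unit
indicator.

## Environmental engines

**Nitrogen routing (quality).**  Large-scale conceptual nutrient models
distinguish diffuse emissions, which are partly retained on land before
reaching the stream, from point emissions discharged directly, and attenuate
the accumulated load in the river network.  We keep exactly that structure
in linear form.  For catchment `c` in region `a`:

    L_c = Σ_{s diffuse} src[c,s] (1 − r[a,s]) (1 − B_c)
        + Σ_{s point}   src[c,s] (1 − r[a,s])
    O_c = (L_c + Σ_{u upstream of c} O_u) (1 − R_c)
    TN_c = O_c / Q_c

with basin retention `B_c ∈ [0, 1)`, river retention `R_c ∈ [0, 1)`, and
mean annual discharge `Q_c > 0`.  Units are fixed — loads in t N/yr, volumes
in Mm³/yr — so TN is directly mg N/L (1 t / 1 Mm³ = 1 mg/L).  Discharge is
not affected by quality strategies (nitrogen reductions do not change flow).
The diffuse/point assignment of each sector is data, not code: a `Basin` can
reassign, e.g., scattered dwellings to the diffuse pathway, since the
empirical literature is not unanimous on whether such emissions undergo land
retention.

**Water exploitation (quantity).**  `WEI_a = Σ_s abst[a,s](1 − r[a,s]) /
avail_a`, computed region-locally; upstream–downstream water transfers
between regions are deliberately out of scope.  Class boundaries follow the
conventional readings: WEI ≥ 20% water-stressed, > 40% severe; TN < 1.5 mg/L
good, > 20 mg/L very bad.  The strict-inequality phrases fix only one side
of each boundary; we resolve the other side by making the middle class
closed (0.20 and 0.40 inside `water_stress`; 1.5 and 20 inside
`intermediate`) and test the boundaries explicitly.

## The sensitivity metamodel

The optimizer never calls the environmental engine directly.  A metamodel is
built once: the baseline `v0 = engine(zero strategy)` and, per driver `d`, a
column `S[·, d] = (v0 − engine(step on d)) / step`, with `step = 0.01`
mirroring the 1%-probe convention (any step in (0, 1] gives the same matrix
for the linear engines; a property test asserts step invariance).
Prediction is `v = max(0, v0 − S r)`, clamped after summation because
concentrations cannot be negative.  For the bundled linear engines the
surrogate is exact to floating-point accuracy for *any* strategy — the
acceptance suite verifies ≤ 1e−9 relative error over random basins and
strategies.  For a nonlinear engine the same interface would yield a
first-order approximation; we make no accuracy claim in that case.  The
driver index is serialized with the matrix (regions sorted by id, sectors in
canonical module order) so strategies and matrices cannot misalign.

## Objectives

Effort is `E = Σ w[a,s] r[a,s]`, reported raw and normalized by the maximum
attainable within bounds (`Σ w·rmax`) for cross-run comparability.  Weights
default to 1 everywhere.  Pairwise elicitation uses the analytic hierarchy
process: normalized principal right eigenvector of the reciprocal comparison
matrix, `CR = ((λmax − n)/(n − 1)) / RI(n)` with Saaty's random-index table,
and a warning above the conventional CR = 0.1.  Region-wise and sector-wise
weight vectors combine multiplicatively into cell weights, rescaled to mean
1 so effort magnitudes stay comparable across weightings.

The environmental objective aggregates per-unit values with one of five
operators: mean, median, q3 (linear-interpolation quantile at 0.75 — the
convention is fixed because quantile definitions differ across software),
max, or threshold.  The threshold operator sums the *values* of units
strictly exceeding T; summing exceedances `(v − T)` instead is available as
`threshold_mode="excess"`, since both readings are defensible.

## NSGA-II

The search is the classic elitist non-dominated sorting GA with binary
crowded-tournament selection, simulated binary crossover (η = 15,
probability 0.9), polynomial mutation (η = 20, per-gene probability 1/n),
and (μ+λ) environmental selection.  Population size equals the requested
front size (default 50; generations default 200).  Two choices worth noting:

* the initial population always contains the two corners of the search box
  (zero strategy, maximum-reduction strategy); with elitism this pins the
  front's endpoints — the current situation and the maximum attainable
  improvement — from generation zero;
* all tie-breaks (crowding ties, tournament ties, final dedup) are resolved
  by index or by strategy bytes, so a run is bit-reproducible from its seed.

The final front is the non-dominated set of the last population,
deduplicated on identical objective vectors and sorted by effort.  Crowding
distance gives boundary members +inf; an objective with zero range
contributes nothing, so fully degenerate fronts resolve to the documented
stable-sort tie rule.

For verification the package includes a 2-D hypervolume routine; GA fronts
on 21-level discretized 2–3-driver problems reach ≥ 99% of the exhaustive
Pareto set's hypervolume, provided the population is at least as large as
the discretized reference front (a smaller population measures front
resolution, not search quality).

## Reference families and appraisal

*Uniform sweep*: `r[a,s] = min(u, rmax)` for u on an even grid over [0, 1]
(both ends included).  *Random strategies*: rates uniform on [0, rmax] per
driver.  On converged runs no random strategy strictly dominates a front
member, and nearly all sweep points are matched environmentally at strictly
lower effort — the two sweep endpoints cannot be, because zero effort and
the full-box corner are themselves efficient.

*Prior appraisal* runs the median-metric GA repeatedly (default 20 runs at
desk scale; 100 is the documented full setting) with equal weights, and at
each reference level (90/75/50% of the baseline median) selects the
minimum-effort front member achieving it, recording effort shares by sector
and region.  Unattainable levels are counted per run, never silently
dropped; a level satisfied by the zero strategy is reported as degenerate
(shares undefined).  The selection rule — minimum effort achieving the level
— is our documented choice.

## Synthetic basins

The generator emulates the structure the method assumes: a single-outlet
tree (catchment i > 1 drains into a uniformly chosen earlier catchment),
contiguous region blocks standing in for spatial contiguity, log-normal
sectoral sources (defaults sized for catchments of a few km², i.e. a few
t N/yr per sector), uniform retentions (B in 0.1–0.6, R in 0–0.3), and
discharge accumulated from local runoff (0.5–5 Mm³/yr), hence non-decreasing
downstream.  Region water tables cycle per-region WEI targets through the
three stress windows so any fixture with ≥ 3 regions spans all classes at
baseline.  What the generator does *not* emulate: real hydrography, braided
networks, seasonal dynamics, calibrated retention, spatial correlation of
sources.  Passing tests therefore demonstrate correctness of the machinery
and the qualitative patterns, not predictive skill on a real basin.

The checked-in hotspot fixture (12 catchments, 2 regions, two chains joining
at a well-diluted outlet) concentrates ≥ 80% of sources and every TN > 5
mg/L catchment in region r2, while region r1's catchments control the basin
median.  On it, a threshold-metric (T = 5) optimization allocates almost all
effort to r2 and a median-metric optimization almost none — the clearest
possible form of the metric-choice effect.

## Numerical and I/O conventions

Study problem sizes are kept at desk scale (tens of catchments, populations
of 40–100, 150–200 generations), which the convergence checks above show to
be sufficient for these problem dimensions.  CSV writes use shortest-repr /
`%.17g` floats so write-then-read is exact; reads parse numerics with
Python's round-trip-exact `float`.  All run outputs are timestamp-free and
derive every random draw from the run seed, so repeated runs are
byte-identical.  Validation is strict: missing columns, dangling downstream
references, cycles, negative sources, non-positive discharge or
availability, and out-of-bounds rates are all fatal with named offenders;
unknown CSV columns only warn.

## Known limitations

- The linear routing engine is a structural stand-in calibrated to nothing;
  absolute TN values in synthetic basins are only order-of-magnitude
  realistic.
- Region-local WEI ignores inter-regional water transfers.
- The metamodel's exactness claim holds only for linear engines.
- Only box bounds are supported as constraints; two objectives only.
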