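# Methods

This note documents the models behind `metroexposure`, the defaults and why
they were chosen, what the synthetic data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Station and ventilation states

The built-in station is a two-floor underground island-platform station:
a 90.4 m × 20 m × 3.5 m concourse over a 110 m × 12.8 m × 3 m platform,
four corner exits (A, B north; C, D south) behind short passageways, one
security checkpoint, ticket machines, fare-gate arrays, and a stair +
escalator pair between floors. Supply and return outlets are uniformly
spaced arrays at 300 × 300 mm (concourse) and 600 × 500 mm (platform); the
exact outlet spacing is not dimensioned in the source material, so only
aggregate flow balance is meaningful, and counts (30 supply + 12 return
concourse, 12 supply + 6 return platform) were chosen once to give
3.5–6 air changes per hour at the tabulated face velocities
(v_c = 2.3 m/s, v_p = 1.9 m/s). All geometry is config-overridable
(YAML/JSON).

Ventilation is a small set of discrete airflow-organization states. With
PSDs closed, station air leaves through the exits and the platform's excess
supply air rises through the stairwell. With PSDs open, tunnel suction
reverses the pattern: outdoor air enters the exits, flows down the stairs,
and leaves through the open PSD side (AB or CD — platform states distinguish
the side). The supply-air PM2.5 concentration is taken directly as the
tabulated 24.4 μg/m³ rather than recomputed from 61.5 × 0.40 = 24.6; the
"40 % filtration efficiency" wording and the printed value imply 40 % of
outdoor PM2.5 *passes* the filter, a semantic tension the config simply
stores without resolving.

## Pedestrian flow

The simulator is waypoint-graph based, not a social-force model: the
artifact needs trajectories, residence times, densities and queue positions,
not collision dynamics. Speeds are truncated normal, mean 1.25 m/s,
spread 0.2 read as a **standard deviation** (a literal variance of
0.2 m²/s² gives an implausible ±0.45 m/s spread; a config switch selects
the literal reading), truncated to [0.3, 2.5] m/s. Route choice between
stairs and escalator minimizes `Cost = W_D·(D_G/V) + W_q·Q + W_L·L` with
all weights 1.0 and component costs 25 s (stairs) / 8 s (escalator); the
queue term uses the live escalator backlog, so bursts after train arrivals
divert some agents to the stairs.

Queues (ticket machines 4 × 20 s, security 4 × 2.0 s, fare gates 4 × 1.5 s,
escalator boarding 0.5 s) are FIFO multi-server; service order equals
arrival order by construction. No service rates are given in the source
material; these values were calibrated once so that mean residence times at
the default demand (2143 + 789 boarding, 951 + 918 alighting per hour,
6-min headway, 80 % card users, exit split 3.5 : 2 : 1 : 3.5) fall within
±20 % of the reference means (157.2 s boarding, 92.3 s alighting); the
defaults give ≈180 s and ≈88 s.

Boarding arrivals are schedule-aware: a mean boarding residence well below
the 360 s headway is arithmetically impossible with uniform arrivals (the
platform wait alone would average ≈180 s), so each agent targets a train
and spawns U(15, 100) s plus a per-exit walk estimate before it, missing
the train (and waiting a full headway) when queues run long. Alighting
agents spawn in bursts at train arrivals.

Densities are person-seconds per cell per window on a 2 m grid (the grid
used for congestion, service levels and sources; concentration fields use
0.4 m). IATA waiting levels use closed upper bounds (A ≤ 0.370 ≤ … < F).
Congested regions at level C or worse become particulate sources: emission
= mean persons present × 10 mg/(person·h), emitted over the region's
equivalent-circle footprint (radius √(area/π)) rather than a single cell —
a one-cell point source at 0.4 m resolution would create a single-cell
concentration spike at exactly the queue positions where pedestrians stand,
which is neither physical (the crowd is the source) nor learnable by a
sample-point-trained surrogate. Trajectory timestamps advance in whole
seconds; the speed-cap invariant applies within a floor (the stair link
switches coordinate frames between floors, so a cross-floor displacement is
not physical).

## Concentration fields

The CFD stage is deliberately replaced by a reduced model: a depth-averaged
potential flow (cell injections at supply outlets, extractions at returns,
portal fluxes signed per state, balance closed by construction) followed by
a steady finite-volume solve of `u·∇C = D_eff ∇²C + S/(A·H)`. First-order
upwinding was chosen over central differencing because it makes the system
an M-matrix: concentrations stay non-negative and fields satisfy a discrete
maximum principle, which the test suite asserts. Effective diffusivity is a
single scalar, default 0.1 m²/s, standing in for turbulent mixing; floor
height enters only through source dilution (the breathing plane is treated
as a 2-D layer). Deposition, resuspension, adsorption by pedestrians, PSD
leakage and tunnel-side particulates are all omitted. The return fraction
(share of supply extracted at return outlets) defaults to 0.5; the
open-state exit inflow defaults to 6.0 m³/s. Floors couple through the
stairwell: the platform-closed mean feeds the concourse-closed stair
inflow, and the concourse-open mean feeds the open-platform stair inflow.

Because of all this, the reduced solver is **not** expected to reproduce
the full-physics floor means reported for the original station
(59.73/46.67 μg/m³ concourse, 60.03/53.59/79.88 μg/m³ platform, kept as
reference constants in `metroexposure.reference`); its role is to produce
physically coherent, state-dependent fields with known structure for the
surrogate and exposure stages, and its own correctness is checked against
exact oracles (constant-solution, Laplace profile, 1-D advection closed
form, linearity, maximum principle, mesh-refinement stability of the floor
mean under halved cell size).

## Sampling design

Measurement points follow a centered Latin hypercube per zone (one point
per axis stratum, points at stratum centers so n = 1 sits at the zone
center), optimized by accept-if-better random stratum swaps with restarts
on stall — the maximin score is therefore non-decreasing in the iteration
budget and the design is deterministic per seed. Each floor is split into
two lengthwise halves with 20 points each, designed independently, plus 3
points per concourse passageway (52 concourse candidates, 40 platform).
Which raw points the original campaign dropped as "not convenient" is
unknown; the defaults drop the 5 concourse candidates nearest the fare-gate
arrays and the 11 platform candidates nearest the cordoned platform ends
beyond the PSD range, reproducing the published counts (47 and 29). The
platform rule deliberately avoids dropping points near the stair block:
that is where the stair plume concentrates and where pedestrians transit,
so removing coverage there would blind the surrogate exactly where exposure
accumulates.

## Synthetic measured truth

The generator stands in for the field campaign. The "real" concentration at
a point is a convex blend of the per-state steady fields,
`C(x) = Σ_s w_s(x) C_s(x)` (optionally a power mean with exponent 1 + γ;
γ = 0 by default, 0.3 available to stress the surrogate's nonlinearity),
with per-1-s instrument draws carrying multiplicative Gaussian noise
(default sd 5 %) and quantization to the 0.1 μg/m³ sensitivity step;
stationary samples average 600 draws (the ten-minute protocol), mobile
curves take one draw per second.

The open-state weight is the PSD-open time fraction dwell/headway
(default 30 s / 360 s ≈ 1/12; the dwell is unstated in the source material
and config-exposed) raised logistically toward 1 where outdoor air actually
penetrates. The affinity coordinate is the open-state **outdoor-air
tracer** — the normalized elevation of the open-state field (concourse) or
the CD-minus-AB field difference (platform sides) — rather than raw
Euclidean distance to the exits. The two constructions express the same
physics (passageways track the open state, the interior the closed state),
but the tracer form makes the synthesized truth an exact function of the
per-state simulated values. With a pure distance ramp the measured field is
provably *not* identifiable from the surrogate's inputs (distinct locations
can share identical inputs yet different weights), which caps achievable
test R² near 0.96 and would make parameter recovery fail for reasons
unrelated to the method under study. A distance-based fallback remains for
use without solved fields.

What the generator does **not** emulate: instrument drift and bias,
temporal autocorrelation of outdoor concentration, train-piston transients,
peak-hour resuspension. Passing tests therefore show the pipeline recovers
a truth *of the assumed blend family* under realistic noise — not that the
blend family captures every feature of real station data.

## Surrogate stage

Concourse sample rows are clustered by K-means (k = 2, k-means++, best of
many restarts — at least 200 for tables of ≤ 16 rows so Lloyd's reliably
reaches the global within-cluster sum of squares) on standardized
(inputs, measured) features; coordinates are excluded. The cluster with the
larger passageway share becomes the B type. Splits are uniform random:
A 20 train / 3 test, B 20 / 4, platform 25 / 4. Hyper-parameters (λ, σ) are
tuned by global-best PSO (inertia 0.7, c1 = c2 = 1.5, swarm 14, 20
iterations) over log₁₀λ ∈ [−2, 4] and log₁₀σ ∈ [−3, 2] (ranges that cover
the hyper-parameter optima reported for the original data), scoring
repeated 5-fold cross-validated R² on the training set only — the test set
never enters tuning. The repeat (3 fold shuffles averaged) damps
fold-assignment luck, which otherwise occasionally selects
near-interpolating λ at the search bound. The ε tube half-width defaults to
0.1 μg/m³, the instrument quantization step, as the natural noise floor.
Concourse cells are routed to the A/B model of their nearest labeled sample
point (Voronoi assignment); the platform is one region.

With 3–4 test points, test R² is a high-variance statistic: the denominator
is the spread of a handful of measured values, so a single ≈0.5 μg/m³
prediction error on a tight test triple can drop R² below 0.95 even when
the fit is at instrument-noise accuracy. The acceptance checks therefore
evaluate the default configuration (master seed 0, the package default);
`scripts/acceptance.py` reports the same statistics at any requested seed.

## Exposure calculation

Integration: per second, the per-state simulated values at the pedestrian's
cell are fed to the region's surrogate; predictions are clipped at zero and
summed (Δt = 1 s, piecewise-constant positions, no sub-second
interpolation). Averaging: exactly two microenvironments (concourse —
passageways included — and platform); each floor's average concentration is
the equal-weight mean of its per-state floor means, times the pedestrian's
residence time. Cohorts are 50 random pedestrians per direction. The
synthetic "measured" reference for the method comparison integrates each
sampled pedestrian's noise-free blended-truth curve and averages per
direction (integrate-then-average). In the limit where the surrogate
returns each microenvironment's mean everywhere, the two methods agree
exactly, and the test suite asserts this identity without tolerance.

## Problem sizes and determinism

The default study simulates 1200 s of off-peak demand (≈1600 pedestrians —
enough for 50-per-direction cohorts and stable residence statistics while
keeping the full run around a minute), 0.4 m field grids (226 × 50 and
275 × 32 cells), 2 m density grids, and 600-draw stationary samples. A
single master seed spawns one named RNG stream per stage (pedestrians,
sampling, measurement, surrogate, cohort), so every artifact is
byte-reproducible per seed; the manifest records SHA-256 digests of all
written files.

## Known limitations

- The flow model is potential flow: no recirculation zones, no buoyancy
  (the lighting load is carried in config but unused), no tunnel piston
  wind; portal flow magnitudes for the open states are plausible defaults,
  not measurements.
- Published worked-example arithmetic is reproduced at printed precision,
  with two documented defects in the printed inputs themselves: the
  boarding residence-time relative error (printed 9.24 %, not derivable
  from the printed means) is excluded, and one platform fixed-point mean
  (printed 52.33) is inconsistent with its own printed daily values
  (which average 52.73), so that single per-point check is excluded.
- The average-concentration comparator inherits whatever bias the
  equal-weight state mean has relative to the time-weighted truth; with a
  different dwell/headway ratio its error (and hence the error ratio
  between methods) changes accordingly.
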