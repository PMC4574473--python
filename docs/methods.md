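# Methods

This note documents the models and numerical conventions implemented in
`epishear`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real data.

## Coordinates, units, data model

Positions are in µm with x along the proximal–distal (PD) axis pointing
distally and y along the anterior–posterior (AP) axis pointing
anteriorly; time is in hours after puparium formation (hAPF), frames
5 min apart by default.  A tracked tissue is a sequence of cell-network
frames (cells with centers and areas, vertices with ordered incident
cells, counter-clockwise neighbor lists, polygon rings) plus lineage,
extrusion and T1 records and named regions of interest.  On disk this is
a directory of tidy CSV tables or one SQLite file with identical tables;
reading validates neighbor symmetry, polygon orientation, vertex valence
and the consistency of every event record with the topology difference
of its adjacent frames.  Event records carry the index of the first
frame showing the post-event topology.

Nematics (elongation, shear) are symmetric traceless 2×2 tensors stored
as `(n_xx, n_xy)`; positive `n_xx` means elongation along PD.

## Triangle method

Each interior vertex touching three cells defines one triangle of cell
centers; a k-fold vertex (k > 3) is fanned from its lowest incident cell
id, which is deterministic and tiles the same area.  The reference
triangle is a unit-area equilateral with one edge along +x; any fixed
reference yields identical shear statistics, only the orientation gauge
θ changes.  The map `S` from reference to triangle is factored
`S = sqrt(A) · exp(Q) · R(θ)` with `exp(2Q) = S Sᵀ / det S` (the
elongation is measured in the lab frame, so a rigid rotation rotates the
nematic axis and an affine stretch shifts every triangle's Q equally).
Degenerate (collinear-center) triangles are flagged and excluded from
averages.  All tissue averages are area-weighted, which makes the
triangle mean equal the tissue-scale deformation of the tiled region and
is required for the closure property.

### Per-interval kinematics

For a triangle persisting across an interval, the corner map `M` is
factored through its principal matrix logarithm: `v = tr(log M)/δt`
(area expansion), `ω` = antisymmetric part (rotation rate), `s` =
symmetric traceless part (pure shear rate).  This velocity-gradient
definition is exact for the canonical cases: rigid rotation gives
`s = 0`, and a simple-shear map gives `s_xx = 0` exactly — which is what
makes the alternating sliding-row pattern produce zero net tissue shear.
Alongside, the corotational elongation-change rate
`dq = (rotate(Q₂, −ωδt) − Q₁)/δt` is reported; `s = dq` for triangles
that start isotropic and to first order generally, and the area-weighted
mean of their difference is exactly what the correlation term absorbs.
A superposed finite rotation is removed from `s` only to second order in
(rotation × per-interval strain); per-frame deformations of a few
percent make this negligible.

### Decomposition bookkeeping and closure

Per interval the pipeline computes: the tissue shear rate (area-weighted
mean `s` over persistent triangles); the cell-shape term `DQ/Dt` (the
corotational change of the full-triangulation mean elongation, corotated
by the mean rotation); the event terms; and the correlation term `D`,
defined as the **exact residual** of the topology-free identity on the
persistent-triangle set, `D = ⟨s⟩ − DQ/Dt|persistent`.  The covariance
estimates (area part `−cov(v, Q)`, rotation part `2 cov(ω, εQ)`) are
computed alongside as a diagnostic split; they agree with the exact `D`
to first order in the fluctuations and vanish identically for uniform
rates.

Each event's retriangulation jump uses the intermediate-state
convention: the triangles an event destroys enter with their last
(pre-frame) state and those it creates with their first (post-frame)
state, each mean-centered on the persistent-triangle average of its own
frame, normalized by that frame's triangulated area, the post side
corotated by the mean rotation.  With this convention the event
contributions are exactly additive, so the residual
`ṽ − (DQ/Dt + T + C + E + D)` is zero to round-off whenever every
triangle that appears or disappears is attributed to an event; any
unattributed turnover (boundary churn, ambiguous clusters) surfaces in
the reported residual rather than being redistributed.  Events sharing
triangles are resolved in record order (first match wins) and flagged.
The divided mother's triangles are located by her id; the daughters'
appearance (including the mother→daughters jump) is netted into the
division term.  Events touching cells outside the ROI triangulation are
skipped and reported.

The isotropic balance uses log-rates: `k_d = ln((N+n_d)/N)/δt`,
`k_e = ln((N+n_d)/(N+n_d−n_e))/δt`, `dln(a)/δt` from the mean-area log
difference — under this discretization `v = dln(a)/dt + k_d − k_e`
closes identically.

### Other statistics

Bond orientation is the angle (mod π) of the connector of the two
triangle centroids adjacent to a bond — a robust proxy for short-bond
orientation, orthogonal to a straight bond.  Gain/loss angular
statistics subtract the pooled all-connection distribution from the
event-connection distributions (15° bins by default, ±45 min windows).
The rotation-rate power spectrum bins triangle rotation rates onto a
regular grid (spacing d₀/2, d₀ = 4 µm a typical cell diameter), mean
subtracts, applies a Hann window and reports the 2-D FFT power with the
largest non-DC local maximum; wave numbers are rad/µm with the
dimensionless `q·d₀/2π` convention exposed.  The correlation-attribution
partition splits the weighted covariance with shared means, so subset
plus remainder equals the total exactly.  The region shape nematic is
`½ log(M/√det M)` of the polygon's centered second-area-moment tensor;
a rectangle of aspect ratio `ar` along x has `Q_xx = ln(ar)/2`
(`ar = exp(2Q_xx)`), and isotropic outlines give zero.

## Synthetic tissues

The generator is kinematic by design — polygons moved by prescribed
maps, no force balance — because its purpose is to provide inputs whose
true decomposition is known analytically.  Cells are hexagons on a
(optionally jittered) lattice; an affine map `expm(δt·L)` is applied
per frame; T1s flip a bond into the perpendicular bond between the two
common neighbors, divisions split a polygon through its centroid
perpendicular to the stated division axis, extrusions collapse a cell to
its centroid producing a k-fold vertex.  T1s and extrusions are
choreographed over a ~3-frame ramp (bond/cell shrinks quadratically
before the change, the gained bond regrows after), mirroring how
junctional remodeling proceeds continuously in real tissue; this keeps
cell centers continuous so the retriangulation jump is purely
topological.  Each generated video carries a ground-truth budget: the
integrated applied shear and per-event jumps evaluated by direct
recomputation of the mean elongation immediately before/after the
surgery.  The sliding-row generator builds a brick lattice whose rows
translate rigidly in alternating directions with jittered cell
boundaries (staggering the T1 flips); its analysis region must span an
even number of row pairs for the alternating simple-shear bands to
cancel, and measurements discard a warm-up transient and cover whole T1
cycles.

What passing these tests shows: the decomposition is exact for the
event classes and deformations the generator can express.  What it does
not show: robustness to segmentation/tracking noise, curved-surface
projection artifacts, simultaneous overlapping events, or boundary-cell
churn of real movies — real-data residuals of a few percent are
expected, as opposed to the round-off-level residuals here.

## Ablation recoil

The module ingests already-measured ellipse tuples (V∥, V⊥, r∥, r⊥, θ);
kymograph segmentation is out of scope.  The velocity-gradient tensor is
`R(θ) diag(V∥/r∥, V⊥/r⊥) R(−θ)`; its half-trace is the isotropic
expansion rate, the traceless part the recoil shear.  Fits are
unweighted ordinary least squares with standard errors;
`ζ_xx/K = 2·intercept/slope` with first-order uncertainty propagation
(independent-errors assumption).  The estimate is invariant under
rescaling all recoil rates, so the unknown proportionality between
recoil rate and stress drops out.  The isotropic fit against
`ln(a/a_ref)` reports slope/intercept and the sign of inferred tension
only; the preferred area and area modulus are deliberately not derived
from it — the cell-area spread is too small for a reliable estimate.
`a_ref` is a configurable reference affecting only the intercept.

## Two-rectangle model

State per region: length L, height h (normalized by the initial wing
length), elongation Q, rearrangement rate R, cell area a and preferred
area a₀ (blade).  Constitutive laws: `σ̃ = 2KQ + ζ`,
`P = −K̄ ln(a/a₀_eff) − η̄ v` with `a₀_eff = a₀(1 − ζ̄/K̄)`,
`Q̇ = ṽ − R`, and `(1 + τ_d d/dt) R = Q/τ_r + λ` (τ_d = 0 falls back to
the algebraic branch).  Preferred area follows divisions,
`dln a₀/dt = −k_d + k_e`.

The boundary coupling is this package's own minimal closure of the
force balance (the detailed spring geometry was an open design choice):

* friction enters as a stress γ times the **log-strain rate** of each
  region dimension — the only form dimensionally consistent with a
  friction coefficient in units K·h;
* elastic links are linear in normalized displacement: AP springs on
  each region's height, a PD spring on the hinge–blade interface, and a
  PD spring on the blade length;
* the distal attachment is a hard constraint pinning the wing tip
  (`L̇_blade = −L̇_hinge`); removing it (`distal_attachment=False`)
  leaves the tip force balance with friction and the PD spring only;
* the hinge pressure is the Lagrange multiplier that makes the hinge
  area track its imposed input; the blade area follows from the
  isotropic balance and feeds the cell-area equation
  `dln a/dt = v − k_d + k_e`.

Each step solves the resulting 5×5 (two regions) or 2×2 (single region)
linear system for the strain rates and advances the state with fixed-step
RK4 (δt = 0.01 h default; halving δt changes trajectories at the 1e-9
level).  With constant inputs the simulation converges to the fixed
point R = 0, Q = −τ_r λ to machine precision, and the spring-free,
friction-only single region matches the closed-form linear (Q, R) system
to 1e-6.  Wild-type-like inputs (imposed hinge contraction, pinned tip,
λ_xx < 0) reproduce the two-phase signature — elongation rises then
relaxes while cumulative shear keeps rising — and detaching the tip
reverses the net shear direction.  These are self-consistency and
sign/shape checks; the model is not validated against experimental wing
series, which are not distributed.

Fitting: the delayed law is discretized exactly for piecewise-linear
Q(t) (per segment, particular solution plus `exp(−δt/τ_d)` decay),
avoiding derivative-of-noise artifacts; single-series, joint
(shared τ_r, τ_d, per-wing λ) and full-model fits use
Levenberg–Marquardt with standard errors.  A monotonic, short elongation
episode leaves τ_d weakly identified; the fit flags this when the
relative standard error of τ_d exceeds one.  A delayed transient winds
around its fixed point in the (Q, R) plane (reported via a winding-angle
utility); without delay the points are collinear.

## Default parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| τ_r | elongation relaxation time | 1.8 | h |
| τ_d | rearrangement delay | 3.7 | h |
| λ_xx | autonomous rearrangement drive | −0.10 | 1/h |
| ζ_xx | cell-autonomous anisotropic stress | 0.333·K (blade) | K |
| K̄ | area modulus | 2.07 | K |
| η̄ | area viscosity | 49 (wing fits) / 0 (unit tests) | K·h |
| γ | friction coefficient | 21.3 | K·h |
| d₀ | typical cell diameter | 4 | µm |
| grid box | coarse-graining element | 26 | µm |
| smoothing | pattern time window | 45 | min |

Defaults are the wild-type estimates; every value is a constructor
argument.  Test problem sizes (≈2000 cells × 100 frames for the closure
check, 9×32 brick rows × 136 frames for the sliding check) were chosen
so each scenario contains enough events and full T1 cycles for its
statistic while the whole suite runs in about a minute.

## Known limitations

* Single events per triangle per interval are assumed; overlapping
  events are applied sequentially and flagged, not modeled jointly.
* The generator's polygons stay star-shaped; extreme jitter or very
  elongated cells are outside its envelope.
* The rotation-invariance of per-interval rates is exact only to second
  order in (rotation × strain) per interval (matrix-log convention).
* The rectangle model is spatially lumped (no PDE continuum) and its
  boundary-spring geometry is a modeling choice validated by
  self-consistency, not by tissue data.
* Real-wing quantities (experimental shear curves, fitted boundary
  constants, the ~20–25 reproducibility variance ratios) are not
  reproduced here; no tracking data is distributed with the package.
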