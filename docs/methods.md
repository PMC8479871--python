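# Methods

## Cell model and coordinates

Actin-inhibited adherent cells are modeled as a sphere of radius R truncated
by the substrate plane at the contact angle Ω ∈ [0, π/2].  The free membrane
is the spherical zone above the latitude θ_adh = −π/2 + Ω; the ventral
membrane is the flat closing disc of radius R·sin Ω.  Every node carries a
latitude θ ∈ [−π/2, π/2] (θ = −π/2 at the ventral center) and a periodic
azimuth φ ∈ [−π, π].  Ventral-disc nodes are assigned latitude linearly in
radial position from −π/2 at the disc center to θ_adh at the rim, so the
equal-area Mollweide map covers the entire closed surface; this disc
parameterization is a design choice — any monotone radial map would serve —
and it is applied identically by the generator and by the reconstruction, so
round trips are self-consistent.

Two area conventions exist for the ventral membrane.  Barycentric node-area
lumping (one third of each incident triangle per vertex) leaks roughly half
of the mixed rim-band triangles into A_adh, an error of order one rim band
(~10% for small discs).  `CellMesh.area_adherent` therefore sums the area of
triangles all of whose vertices are adherent; with the generator's explicit
contact-perimeter ring this tiles the ventral disc exactly, and on
reconstructed meshes it errs by less than one rim band.

The printed area-ratio model r_a = sin²Ω/(3 + cos Ω) is canonical for
converting areas to contact angles.  It is not the exact truncated-sphere
ratio (free zone + disc), which it matches only at Ω = 0 and Ω = π/2; the
relative discrepancy in between peaks near 8–12% and is exposed through
`kinematics.area_ratio_exact` rather than hidden.  The inverse is computed
by bracketed root finding to 10⁻¹⁰; the algebraic inverse
cos Ω = (−r_a + √(r_a² − 12 r_a + 4))/2 (the root of the quadratic in cos Ω)
is implemented as a cross-check.  For small angles Ω ≈ 2√r_a.

## Synthetic scenes

`SceneSpec` defaults define the study conditions: R = 3 µm (volumes of order
0.1–0.5 pL), frame interval dt = 10 s, pattern period 200 s (inside the
2–5 min oscillation band), activity amplitude 1 over a baseline of 1,
additive Gaussian noise of SD 0.2, duration 1800 s.  Patterns:

- **horizontal_wave** — a Gaussian domain (angular width `wave_width`,
  default 0.5 rad) circulating about the vertical axis at a fixed latitude
  band; period-T periodic by construction.
- **vertical_wave** — the domain rotates about a horizontal axis starting at
  the ventral pole, crossing the contact perimeter twice per period.
- **transient_spots** — Poisson births (default one per minute), uniform
  area-weighted positions restricted above the contact perimeter, fixed
  60 s lifetime with a fast-rise/exponential-decay ("exponential shoulder")
  profile.  The spot statistics are qualitative by design; the real process
  is only described as spots appearing and disappearing at random positions.
- **pinned_spiral** — a rotating phase field about an axis piercing the
  contact perimeter, activity a·(0.3 + 0.7·sin θ′)·cos(φ′ − 2πt/T).  The
  amplitude floor of 0.3 keeps the ridge amplitude above the low-amplitude
  guard near the singular points so the winding analysis sees well-defined
  phases; the counter-singularity required by closed-surface topology sits
  at the antipode.
- **white_noise / quiet** — noise only / baseline only.
- **isotropic_domain** — a domain moving a fixed angular step per frame
  about a fresh random tangent direction each step.  This is the isotropy
  baseline: with uniformly distributed step directions the expected
  azimuthal and polar component speeds are equal, so v_a ≈ 1.

All randomness flows from one integer seed through a counter-based Philox
generator; identical specs give bit-identical signals.

Node layout: Fibonacci lattice on the cap (uniform in sin θ), sunflower
lattice on the disc, and an explicit double-density ring on the contact
perimeter.  Cap radii are inflated by half the piecewise-flat area deficit
(~0.21·(ℓ/R)²) and the rim ring is placed on the equal-polygon-area circle,
so mesh areas track the analytic values to ≲0.2% at the default resolution
and the r_a convergence contract (<1% relative error at 0.3 µm²/node,
R ≥ 2 µm) holds.

Voxel rendering splats node intensities onto nearest voxels, adds a uniform
cytosolic interior at 15% of the median membrane intensity, and convolves
with an isotropic Gaussian PSF (default 0.3 µm).  The cytosol fraction is
kept below ~0.2: the PSF dilutes the thin membrane shell, and a brighter
interior would move the radial intensity maximum off the membrane.  What the
generator does **not** emulate: photobleaching, shot noise (noise is
additive Gaussian, matching the white-noise DFA baseline α = 0.5),
camera-specific noise, membrane deformation over time, and realistic spot
kinetics.  Tests passing on these scenes validate the analysis chain, not
the biology of real recordings.

## Reconstruction

The membrane is located per ray (Fibonacci directions from the intensity
centroid) as the argmax of the temporal standard deviation sampled by
trilinear interpolation, with subvoxel refinement by a local quadratic fit
and ties broken toward the larger radius (the membrane, not the cytosol,
fluctuates).  Rays with no interior maximum are filled from the nearest
good direction; reconstruction fails if more than 20% are flagged.

Triangulation builds the spherical Delaunay mesh as the convex hull of unit
ray directions, resamples to area/0.3 µm² Fibonacci directions
(inverse-distance radius interpolation, k = 4), smooths node positions by
one pass of a 1-ring Gaussian kernel (width = mean edge length), and
rescales radially to undo the few-percent Laplacian shrinkage.  A corrective
second resampling re-picks the node count from the realized area, landing
the mean node area within ~1% of the 0.3 µm² target.  Repeated smoothing
monotonically shrinks the surface; a single pass is the default.

Adherence: nodes within one axial voxel (0.5 µm) of the lowest supporting
plane are adherent; θ_adh is the area-weighted mean latitude of the
perimeter ring (adherent nodes with a free neighbor).  A larger tolerance
systematically inflates the adherent band and biases the recovered Ω high.

Signal sampling averages trilinear samples at each node and one minimal
voxel step inward/outward along its ray (a ±1-voxel radial window).

## DFA

Classic first-order detrended fluctuation analysis: cumulate the
mean-removed series, split into non-overlapping windows from the series
start (the short tail is discarded), remove the per-window least-squares
line, and define F²(τ) as the mean squared residual over covered samples.
The window set is every integer τ from 4 to ⌊T_max/dt⌋ = 18 samples
(T_max = 180 s); with only 15 scales the log–log fit is unweighted, and
decimating the grid further would destabilize the slope.  α is the
least-squares slope of log F vs log τ; the fit r² is reported per node.
Stored α values are never clipped to [0, 2].

Finite-size behavior worth knowing: at these short windows white noise reads
α ≈ 0.56 rather than 0.50 (the known small-τ DFA1 bias), and a pure
sinusoid's exponent depends on its phase relative to the segment grid — a
zero-phase sine whose zeros align with window boundaries reads ≈1.7 while
generic phases read ≈2.05.  The calibrations use the ensemble mean over 500
series (white noise) and cosine phase (oscillation peak at t = 0, the
wave-front convention).

The latitude profile bins α by node latitude (24 bins), takes per-bin
medians, and fits a degree-4 polynomial weighted by bin occupancy (summed
node area); α_min and α_adh are the fit values at θ = −π/2 and θ_adh, and
Δα = α_adh − α_min.  Degree 4 follows the smooth single-inflection shape of
observed profiles; the fit weights and bin count are free choices exposed as
parameters.  A polynomial of this order cannot represent a hard spatial step
in α — profiles are meaningful for smoothly graded fields, which is what
real maps show.

## Phase analysis

The Morlet kernel is implemented exactly as written,
ψ(t) = ω^(−1/2)·e^(iωt)·e^(−t²/2) with ω = 2π, so a scale of s seconds
probes period s; the 1/√ω normalization differs from common CWT conventions
but only amplitude *ratios* (ridge selection, the low-amplitude guard) enter
any decision.  Scales: 40 log-spaced periods over 60–600 s, covering the
2–5 min band; analysis window 60–330 s (hence the ≥34-sample requirement).
Per time point the ridge is the amplitude-maximizing scale, ties broken
toward the lower frequency; phase is stored mod 2π with the intensity peak
at the 0/2π wrap (the wave front).  No temporal unwrapping and no spatial
smoothing are applied anywhere.

Singularities are faces whose oriented vertex loop accumulates ±2π of
wrapped phase difference; on a closed mesh the charges telescope to zero,
which is asserted every frame.  Nodes whose median ridge amplitude falls
below 10% of the cell median are excluded as quiescent (threshold exposed as
`amp_guard`).  Tracking is greedy nearest-neighbor with a gate of
2·`pin_dist` per frame, no gap bridging, and a 3-frame minimum lifetime to
reject flicker pairs.  A track is **pinned** when ≥80% of its lifetime lies
within `pin_dist` (default 1 µm) of the contact-perimeter ring; distances
use the Euclidean proxy to the nearest ring node, which differs from the
geodesic by <2% at these gates on R ≥ 2 µm cells.  The pinned thresholds
are engineering choices — the phenomenon is defined qualitatively — and all
are parameters.

Guidance events are frames where the isophase line of near-perimeter
wave-front nodes runs parallel to the perimeter: the per-node phase gradient
is estimated from wrapped 1-ring differences by least squares in the tangent
plane, the front line is the gradient rotated 90° about the surface normal,
and a frame counts as aligned when the median angle to the local perimeter
tangent is <20°; runs of ≥3 frames form events.  Under this definition
perimeter-crossing (vertical) waves generate guidance frames while azimuthal
band waves do not.

## Kinematics

Domain tracking projects each frame onto real spherical harmonics up to
degree 3 (least squares on scattered node directions — quadrature is
inappropriate on irregular meshes, and degree ≤3 keeps the 16-coefficient
system strongly overdetermined), reconstructs the smoothed field, and takes
an intensity-weighted centroid of the top 20% of the reconstructed range,
projected back to the membrane radius.  Frames below 5% of the best frame's
contrast are skipped; centroids collapsing toward the cell center (antipodal
ties, ring-like domains) fall back to the first-index argmax and are flagged
ambiguous.

Step speeds use the Euclidean chord between successive peaks over one frame
(chord vs arc differs by <1.2% at the largest step angles probed);
components are absolute projections on the local latitude/azimuth unit
vectors at the step midpoint, and v_a = ⟨v_φ⟩/⟨v_θ⟩ with an infinity flag
when ⟨v_θ⟩ vanishes (exactly azimuthal circulation).  Ω is always derived
from r_a through the printed model, not from direct rim-angle fitting; the
maximal discrete mean curvature (cotangent Laplacian) over perimeter-ring
nodes is reported as κ_max but drives no headline statistic.

Population reduction bins Δα, fits per-bin medians of r_a and of v_a
linearly against the bin-median Δα, and eliminates Δα to obtain
v_a = m·r_a + n₀.  Median-based bin summaries make the composition exact for
exactly linear populations and robust to the flagged-infinite v_a rows,
which are excluded.

## Problem sizes and determinism

Default test and calibration scenes use R = 2–3 µm cells (≈150–400 nodes),
40–180 frames, 500-series DFA ensembles, and 50-seed isotropy ensembles —
sizes at which every quantity reported here is stable to well within its
stated tolerance while the full suite runs in seconds.  All stochastic
stages are keyed by a single seed (Philox counter-based), so reruns are
bit-identical, including CSV outputs of the pipeline.

## Known limitations

- One static mesh per cell: deformable membranes are out of scope (the
  target preparation is actin-inhibited and immobile).
- The printed area-ratio model, not exact truncated-sphere geometry, defines
  Ω; recovered angles inherit its few-degree bias at intermediate Ω.
- DFA exponents at the prescribed 15-scale grid carry the documented
  finite-size biases; comparisons should use the same grid.
- Phase is meaningless in quiescent regions; the amplitude guard excludes
  them rather than reporting noise-driven singularities.
- The guidance detector classifies front orientation only; it does not
  distinguish a guided traveling front from a stationary front lying along
  the perimeter.
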