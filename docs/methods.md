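# Methods

This note records the models, numerical choices and known limitations behind
`cerebmeg`, in the order the pipeline uses them.

## Forward model

The magnetic field outside a spherically symmetric conductor due to an
internal current dipole is computed with the closed-form (Sarvas) expression

    B(r) = μ₀ / (4π F²) · [ F (Q × r₀) − ((Q × r₀) · r) ∇F ],

with r₀ the dipole position relative to the conductor center, F = a(ra + r²
− r₀·r), a = r − r₀. Two properties of this model carry the physics that the
array metrics depend on: a radially oriented dipole is externally silent,
and field strength decays quickly with source depth. The model is
independent of the conductivity profile and conductor radius, so no
conductivities are parameterized.

Numerical choices:

- **Radial silence cutoff.** When the moment is numerically parallel to the
  dipole position (‖Q × r₀‖ ≤ 1e-12 ‖Q‖‖r₀‖) the field is returned as
  exactly zero rather than ~1e-21 T of floating-point noise; radial dipoles
  are exactly silent in this model and downstream silence checks rely on it.
- **Validity domain.** Field points must lie strictly outside the sphere
  through the dipole; violations raise instead of returning the (wrong)
  formula value.
- The test suite cross-checks the closed form against an independent
  single-layer quadrature oracle: the boundary potential of a homogeneous
  conductor sphere is obtained by solving the interior Neumann problem
  numerically in spherical harmonics (azimuthal orders 0/±1 in the
  dipole-aligned frame) and integrated with the single-layer (Geselowitz)
  formula over a Gauss–Legendre surface grid. The two agree to ~1e-12
  relative at the default oracle resolution.

Channel models: SQUID magnetometers integrate the radial field over a
4-point square pickup loop (edge 21 mm, weights ¼ — a knob on
`SensorArray`); axial gradiometers are a proximal-minus-distal point pair
with a 50 mm baseline; OPM channels are single points at the sensitive
element. The true integration rules of commercial sensors are not public at
this fidelity; imported lead fields should be preferred when exact sensor
models matter. Internally everything is SI (T, A·m, m); presentation layers
convert to pT and nAm.

Lead fields computed elsewhere can be imported from HDF5 or dense NPY/text
with a JSON sidecar; the container must declare its gain unit and values are
rescaled to T/(A·m) (e.g. fT/(nA·m) → factor 1e-6).

Sources within 3 mm of the inner conductor boundary are excluded before any
metric, using exact point-to-triangle distances (the threshold is comparable
to mesh edge lengths, so vertex-only distances would misclassify).

## Synthetic head fixture

The fixture supplies the geometric structure the analyses assume, not
anatomy:

| element | default | why |
| --- | --- | --- |
| scalp sphere | radius 0.09 m, icosphere level 4 (2562 vertices) | adult head scale; sensitivities land in the pT range |
| inner boundary | radius 0.083 m | leaves a realistic scalp/skull gap; hosts the 3 mm exclusion |
| cortex-like cap | base radius 0.072 m, extent 80°, fold frequency 10, amplitude 6 mm | superficial, moderately folded |
| cerebellum-like cap | base radius 0.055 m, extent 55° about the posterior-inferior (0,−1,−1) direction, fold frequency 24, amplitude 4 mm | deep, compact, highly folded |

Folding is a band-limited radial perturbation: r(u) = R + a·p(u) over the
unit-sphere parameterization, with p a sum of six seeded plane-wave
sinusoids of the given spatial frequency, bounded by 1. Dipole normals are
the **exact analytic normals** of that continuous surface (n ∝ u − a∇p/r)
rather than mesh-estimated normals: the unperturbed limit is then exactly
radial, and normal disorder is controlled by the single product a·f/R rather
than by mesh resolution.

The cortex fold parameters deserve a comment. In a spherical conductor only
the tangential part of a dipole is visible, and roughly half of real
cortical surface area lies in sulcal walls whose normals are tangential. A
nearly radial cortex cap would therefore be almost silent and would invert
the cortex-to-cerebellum sensitivity ratio that holds for real anatomy. The
defaults (frequency 10, amplitude 6 mm) give the cortex cap a mean
tangential normal fraction of ~0.17 against ~0.33 for the cerebellum cap,
and cortex-to-cerebellum sensitivity ratios of 1.35–1.6 across seeds —
chosen once for realism and reported here, not fitted to any target.

What the fixture does **not** emulate: skull conductivity (see
"Limitations"), anatomical folding statistics, hemispheric structure,
non-spherical head shape, and the very shallow posterior cerebellar surfaces
of real anatomy (the fixture's cerebellar crown is ~3.1 cm below the scalp
everywhere). Passing tests therefore demonstrate the correctness of the
machinery and the direction of the physics, not anatomical magnitudes.

## Sensor arrays

- Helmet-like layouts are Fibonacci spirals over a 115° spherical cap
  (reaching below the posterior head), projected to the scalp at the
  requested standoff — synthetic stand-ins for proprietary vendor
  geometries; real layouts can be read from TSV/JSON files.
- Scalp projection places each sensor at the closest scalp point plus
  standoff along the outward normal. The normal is taken as the direction
  from the closest surface point to the query point, which is the exact
  normal cone direction of the faceted surface; this makes projection
  idempotent to machine precision and exactly radial on spherical scalps.
- Tangential axes: tan1 = ẑ × radial (x̂ replacing ẑ within 1e-6 of the
  poles), tan2 = radial × tan1; deterministic and smooth away from poles.
- Standoffs: 5 mm for OPMs (sensitive element), 22 mm for SQUIDs (cryostat).
  Physical element lengths 17 mm (OPM) and 28 mm (SQUID) feed the overlap
  flag: when the mean nearest-neighbor sensor distance drops below the
  element length the layout could not be built physically and sweep results
  are flagged.

Uniform layouts of arbitrary count: candidate mesh (stereographic Delaunay
triangulation of the helmet sites, midpoint-subdivided to ≥ a target vertex
count — 5821 by default — re-projected to the standoff surface each round),
then a Dirichlet Laplace eigen-basis on the candidate mesh, then greedy
farthest-point sampling in the eigen-embedding.

Numerical choices for the embedding:

- Stiffness is the cotangent Laplacian. The **embedding eigenproblem uses
  identity mass**, so the basis functions are plainly orthogonal over
  interior vertices and every vertex carries equal weight in the sampling
  metric; the FEM lumped-mass path is retained for continuum-eigenvalue
  work (the first Dirichlet eigenvalue of a triangulated unit square
  converges to 2π², which the suite asserts).
- Each basis function is scaled to unit variance over interior vertices
  (uniform variance per function), and its sign fixed by making the
  largest-magnitude entry positive. Default basis size 100; recorded in
  outputs.
- FPS starts at the interior vertex with maximal graph distance to the
  boundary (deterministic); boundary vertices (pinned to zero by the
  Dirichlet condition) are excluded as candidates, since they are mutually
  indistinguishable in the embedding. Ties break toward the lowest index.
  Greedy selection makes layouts nested: the first k sensors of a larger
  layout are exactly the k-sensor layout, which the information-capacity
  sweep exploits.

## Metrics

- Sensitivity: s_j = moment · ‖L[:, j]‖₂ with a 100 nAm reference moment.
  Region comparisons are ratios of means (averages over all sources in each
  region), not means of ratios. Density summaries report percentiles
  (linear interpolation) and the peak of a Gaussian KDE with Silverman
  bandwidth on a 512-point grid; the peak is a qualitative quantity since
  the bandwidth is a convention. Per-sensor normalization divides by the
  sensor count, not the channel count (a triaxial array divides by its
  number of sensors).
- Conservation factor C = ‖Σ_j L[:, j]‖₂ / Σ_j ‖L[:, j]‖₂ ∈ [0, 1]
  quantifies cancellation of simultaneously active sources; it is invariant
  to channel-wise orthogonal transforms.
- Topography errors: RE = 100·‖t − t_ref‖/‖t_ref‖ (second argument is the
  reference — the more complete model) and Pearson correlation.

## Subspace correlations

Principal angles between lead-field column spaces follow the SVD
(Björck–Golub) route: orthonormal bases truncated at numerical rank
(singular values > max(m, n)·eps·σ_max), cosines = singular values of
U_Aᵀ U_B clipped to [0, 1]. The scalar summary is the arithmetic mean over
all r = min(rank) cosines (whether a truncated top set would be preferable
is a convention; all-r is implemented). Patches are Dijkstra balls of 10 mm
geodesic radius on the edge-weighted mesh graph; seeds are chosen greedily
in ascending vertex-id order with 15 mm minimum spacing, which also
guarantees every vertex lies within the spacing of some seed.

A fixture-scale caveat: in the single-sphere conductor the full cerebellar
gain matrix is numerically full-rank relative to the channel count, so the
patch-to-whole-region correlation saturates near 1 for single-axis arrays —
the real skull's low conductivity low-passes the fields and makes the deep
region's subspace effectively rank-deficient, which the sphere model cannot
reproduce. Array discrimination at fixture scale is therefore carried by the
patch-to-patch maps, whose small ranks do not saturate (typical means
0.75 / 0.55 / 0.45 for 22 mm, 5 mm and triaxial 102-sensor arrays).

## Information capacity

Whitening divides each channel row by its noise standard deviation
(homoscedastic diagonal noise). Orthogonalized channel SNRs are the
eigenvalues of q²·W Wᵀ (equivalently squared singular values of W —
asserted against an SVD oracle); the spectrum keeps one entry per channel,
zero eigenvalues contributing zero bits. Itot = ½ Σ log₂(SNR′ + 1).

Noise spectral densities default to 3 fT/√Hz (SQUID magnetometers and
gradiometers) and 10 or 15 fT/√Hz (OPMs), interpreted at a common 1 Hz
bandwidth (a config scalar; only relative levels matter for comparisons at
fixed bandwidth). The source covariance is q² times identity; q² is
calibrated so the mean per-source SNR, defined as q²‖w_j‖² for whitened
topography w_j, equals one on a designated reference (the 102-sensor SQUID
array for the fixed-array grid, the largest uniform SQUID array for the
count sweep) and is then reused unchanged for every array, sensor type and
region, making Itot values mutually comparable. Whole-brain Itot is computed
on the concatenated source space, never as a sum of regional values.

At fixture scale, single-axis OPMs do not overtake SQUIDs on the cerebellum
at any swept count, unlike on realistic anatomy: with the cerebellar crown
~3.1 cm under the scalp, the OPM proximity advantage (~2–3× in amplitude)
does not offset their 3.3–5× higher noise. The structural orderings —
triaxial ≥ single-axis at equal count, Itot non-decreasing in sensor count
for nested layouts, Itot decreasing in noise — hold and are asserted.

## Problem sizes and determinism

Default analyses use icosphere level 4 geometry (≈1060 cortical and ≈540
cerebellar dipoles after boundary exclusion), 102/275-sensor comparison
arrays and a 500-sensor sweep over a 5821-vertex candidate mesh; the test
suite uses level-3 geometry and smaller arrays. Every generator is a pure
function of (config, seed); pipeline runs write a resolved config with seed
and hash, and contain no timestamps, so reruns are byte-identical.

## Known limitations

- No multi-compartment BEM/FEM solve: realistic conductor geometry enters
  only through imported lead fields. Consequently skull low-pass effects on
  subspace ranks and forward-error analyses between head models are out of
  reach on the fixture.
- No brain noise, correlated noise, or interference modeling; sensor noise
  is white and homoscedastic per type.
- Sensor overlap at high counts is flagged, not modeled; Itot at flagged
  counts overestimates what physical arrays could achieve.
- The fixture is a single synthetic geometry (n = 1); numbers computed on it
  characterize the method, not any population.
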