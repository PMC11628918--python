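# Methods

This note records the models, parameter choices and numerical conventions
behind walklineage, and what the synthetic-data tests do and do not show
about real cytometry data.

## Preprocessing

Intensities are variance-stabilized with `asinh(x / cofactor)`, cofactor 5
(the mass-cytometry convention; configurable per run).  The transform is
recorded in the event table exactly once, so a double transform is a hard
error.  Gate labels ride in from a sidecar CSV keyed by
`(sample_id, 0-based event index in file order)`; FCS files are never
modified by gating.  FCS support is an own implementation of the 3.0/3.1
binary format (list mode, float32/float64 and uniform 16/32-bit integer
data, single dataset per file; multi-dataset files are rejected with an
explicit message).  Written files are FCS 3.1, float32, little-endian.

## Pseudotime as expected hitting time

For the symmetrized, unweighted kNN graph and an origin set O, pseudotime
is the expected number of steps a uniform-neighbor random walk takes from
each cell to first reach O.  Writing D for the degree matrix and A for the
adjacency, the free block satisfies the grounded-Laplacian system
`(D − A) h = d`, which is symmetric positive definite.  It is solved with a
sparse direct factorization up to 12,000 free vertices and preconditioned
conjugate gradients (Jacobi, relative tolerance 1e-12) above; both paths
agree with a dense solve to better than 1e-8 relative error (tested on
graphs up to 200 vertices, and the 4-vertex path graph has the closed-form
solution t = [0, 5, 8, 9]).

Hitting time was chosen over diffusion-map or geodesic variants because it
is deterministic, has an exact linear-algebra oracle, and increases
monotonically away from the origin along every dead-end branch — which is
what makes sinks meaningful endpoints.  Transition probabilities are
uniform over neighbors; a distance-weighted kernel would drop in at the
adjacency-construction step but is deliberately not a default.

## Orientation and the origin plateau

Edges are oriented toward larger pseudotime under an injective total
order, so the result is always a DAG.  The order is lexicographic
`(t, −escape_depth, vertex index)`: pseudotime first; then, *within the
t = 0 origin plateau only*, hop distance to the plateau boundary in
decreasing order; index last.  Without the middle component the plateau's
index tie-break strands most walks at spurious interior sinks (in a
20,000-cell run, ~93% of walks died inside the origin); ordering plateau
vertices by escape depth guarantees every origin cell keeps an out-edge
toward the boundary while preserving acyclicity.

## Expert endpoints

With an expert endpoint set E, pseudotime becomes the commute fraction
`t = h_O / (h_O + h_E)` with hitting times to O and E.  This pins t = 0 on
O and t = 1 on E exactly, so endpoints are global maxima and hence sinks.
The useful consequence is directional: inside a dead-end arm both h_O and
h_E grow by the same escape time a, so t(a) = (a + h_O)/(2a + h_O + h_E)
drifts toward 1/2 — arms whose junction satisfies h_E < h_O are oriented
*back out* of the arm, and walks that would have been absorbed there
continue toward E.  This is precisely the rescue needed when a distal
population is unreachable under origin-anchored pseudotime.

## Walks and endpoint groups

Walks (default 5000) start uniformly on O and step uniformly over
out-edges until absorbed; a single counter-based generator drives start
choices and steps in a fixed order, so a (graph, seed) pair reproduces the
walk set byte for byte.  A walk started on a sink terminates immediately
as a length-1 walk (logged, not an error).  Sinks reached by ≥ `min_walks`
(default 10) walks are merged by single linkage over undirected hop
distance ≤ `hop_radius` (default 2) and named EG1, EG2, … by descending
walk count.  Hop distance was preferred over marker-space distance because
it is scale-free and deterministic.

## Topological walk classification

Landmarks (default 500; tests and the annulus analyses use 80–150) are
chosen by greedy farthest-point sampling from a seeded start; every event
is assigned to its nearest landmark (ties to the lower landmark index).
Vietoris–Rips persistence of the landmark cloud is computed to dimension 1
with mod-2 coefficients by standard boundary-matrix reduction, implemented
with Python-integer bitsets; pairs surviving `max_scale` are truncated
there.  Representative cycles are retained for every H1 class: the reduced
triangle column at death for classes that die (a boundary at any scale
containing the death), the birth cycle for classes still alive at
`max_scale`.  Because all representatives have distinct leading edges they
form a basis of the cycle space of the ε-complex, and expressing any cycle
is a greedy top-bit elimination whose accumulated significance tags are
exactly its H1 coordinates.

Significant classes default to persistence ≥ γ · (max persistence) with
γ = 0.5; the working scale ε is the midpoint of the intersection of their
life intervals (an error instructs per-class scales if the intervals are
disjoint).  A walk is mapped to its landmark itinerary (consecutive
repeats dropped, so duplicated vertices cannot change the outcome), gaps
and the closure back to a fixed origin landmark are filled with shortest
paths in the ε-complex, and the resulting loop is reduced to its signature
bits.  The closure path is shared by construction, so it cancels in
pairwise XOR comparisons.  Walk dendrograms use average linkage on
`Hamming(signatures) + [terminal landmarks differ]`; the terminal term
makes endpoint selection and topology selection compose.  In the two-step
workflow (select an endpoint group, then cluster its walks by topology)
the terminal component is constant and cutting at height 0.5 splits purely
by homology class.

## Parametric embedding

The 2D map is a numpy autoencoder: encoder `z = A·x̃ + f(x̃)` and decoder
`x̂ = B·z + g(z)` with two 64-unit tanh hidden layers in f and g, where A
and B are initialized at the 2-component principal subspace of the
training subsample (one shared scale, preserving the principal-plane
aspect ratio) and the corrections start near zero — training therefore
refines an already sensible linear map.  Inputs are centered by per-marker
medians and scaled by one *global* median MAD: arcsinh intensities are
already variance-stabilized, and per-marker scaling would inflate
noise-only channels (a switch-like marker's MAD equals the noise width
regardless of its amplitude) and distort the marker-space geometry the
graph stages work in.

The loss is `MSE(x̃, x̂) + 0.01 · mean(z²) + 0.5 · mean‖z_i − z_j‖²` over
mutual 10-NN pairs of the subsample, optimized by Adam (learning rate
1e-3, batch 256, 40 epochs default) on a density-balanced subsample
(default 5000).  Sampling weights are `(distance to the 15-th neighbor)^d`
with d = min(n_markers, 10) — an inverse-density estimate, so rare
populations are not swamped; the estimate carries Gamma(k)-type noise, so
individual weights in uniform data scatter within a factor of several even
though the bulk is flat.  Training cost depends on the subsample, not the
dataset (asserted via loss-evaluation counters).  Normalization statistics
are frozen into the model; save/load round trips reproduce coordinates bit
for bit, which is what makes a months-old reference projection reusable.

## Trajectory analysis

Bundle membership uses visit counts with threshold `m_min` (default 2) to
drop cells grazed by single stray walks.  Marker curves use
equal-occupancy pseudotime bins (counts differ by ≤ 1) with per-bin mean
and median absolute deviation; empty bins are flagged, never interpolated;
panels share one binning per bundle.  Branch points use equal-width bins
on the union range so two bundles share a grid; the branch bin is the last
with Jaccard overlap ≥ τ = 0.5, and a fully non-overlapping pair returns
an explicit "already disjoint" result.  For branch *localization* the
bundles are built with m_min = 1: the visit-count filter thins coverage of
the shared trunk and biases the Jaccard crossing measurably early (~0.02
latent-time units on the 50,000-cell preset).

The probability-binning statistic builds K bins (default 100) on the
reference by recursive splits: each node splits its events along the
marker of greatest variance at the quantile that divides its target bin
count m into ⌊m/2⌋ : m − ⌊m/2⌋ (the median when m is even), so any K gives
equal occupancies ± 1.  The test sample's occupancies feed
`χ² = Σ (O − E)² / E / (1 + n_t/n_r)` — the correction accounts for the
reference proportions being estimates, keeping E[χ²] ≈ K − 1 under the
null — and `T = (χ²/K − 1)/√(2/K)` has mean ≈ 0 and variance ≈ 1 for
matched samples.  An identical copy of the reference gives the boundary
value T = −√(K/2), reported as-is.  T is validated only against its own
permutation null (pool, relabel, rebuild bins, recompute).

## The synthetic generator

Datasets are drawn from weighted root-to-leaf paths of a staged topology;
latent time is uniform on [0, 1] per path; each marker is a sum of kinetic
primitives of latent time (logistic switches, Gaussian bumps, constants,
circular arcs), optionally scoped to a subset of paths; noise is additive
Gaussian on the transformed scale.  `generate` is a pure function of
(specs, n_cells, noise_sd, seed).

`preset_bcell_like` (30 markers, ≥10 required): a six-stage trunk
(stem → pro-B → pre-BI → pre-BII → immature → transitional), a κ/λ naive
split at latent time 0.68, effector/memory splits at 0.80 (path weight
0.244 each), and two plasma-cell paths (weight 0.012 each) that continue
past the switched-memory stage through a corridor in which CD38
(half-rise 0.90) and CD138 (0.94) switch on while the remaining profile
stays memory-like.  The corridor parameters are the preset's calibrated
operating point: at 20,000 cells automatic walks essentially never end at
the tips while expert endpoints route ~100% of walks there; at 50,000
cells the denser corridor lets ~1–2% of automatic walks arrive, enough for
the tips to appear as small endpoint groups.  Kinetics follow the
canonical ordering (TdT early, CD10 mid, sIgM late, light chains after the
split, CD27/CD73 in memory).  `preset_loop` places two parallel routes as
an annulus in the first two markers (one H1 class) with noise-only
remaining dimensions.

What the generator does *not* emulate: spillover, acquisition drift,
doublets, barcode chemistry, batch effects across samples, non-Gaussian
(count-type) noise, and cell-type-specific noise scales.  Passing tests
therefore demonstrate the algorithms' correctness and their behavior on an
idealized branching manifold, not robustness to instrument artifacts.

## Problem sizes and determinism

The test suite runs the full-size scenarios the analyses are designed for —
50,000 cells for endpoint/branch recovery and 20,000 for the
expert-endpoint scenario, both with 5000 walks — and small instances
everywhere else; the whole suite takes a few minutes on one CPU.  All
randomness flows from explicit integer seeds (no wall-clock seeding);
pipeline reruns under an identical config reproduce artifact checksums bit
for bit at float32.

## Known limitations

* Hitting-time pseudotime is measured in steps and grows superlinearly
  with distance from the origin; only its order matters downstream.
* The commute-fraction rescue requires the endpoint set to be nearer (in
  hitting-time terms) than the origin from the basins that should drain;
  an extremely isolated endpoint set can still leave intermediate arms
  absorbing.
* Rips persistence is exact but cubic-ish in landmark count through the
  triangle reduction; hundreds of landmarks are comfortable, thousands are
  not.
* The walk-signature construction fixes one working scale ε for all
  significant classes; classes with disjoint life intervals need separate
  per-class runs.
* The embedding's neighborhood preservation is evaluated — and only
  claimed — relative to the 2-component linear baseline.
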