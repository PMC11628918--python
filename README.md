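# walklineage

Trajectory inference for single-cell cytometry built on pseudotime-directed
random walks, with topological classification of the discovered routes.

Mass-cytometry panels measure ~30 proteins per cell across hundreds of
thousands of cells, and questions like *"which developmental routes lead
from stem cells to each mature B-cell subset, and where do they branch?"*
require more than clustering: they require orienting the single-cell point
cloud along development and enumerating the paths through it.  walklineage
is a library (plus a thin `walklineage` CLI) for analysts who work with FCS
files and gated populations and want a fully scriptable, deterministic
version of that workflow — and for methods developers who want every step
testable against synthetic ground truth.

## The method

Given an events × markers table (arcsinh-transformed intensities):

1. **kNN graph.** Build the exact k-nearest-neighbor graph over events
   (default k = 30, Euclidean), symmetrized by edge union.
2. **Pseudotime.** For an origin population O (e.g. gated
   CD19⁻CD79a⁻TdT⁻CD34⁺ stem cells), pseudotime is the expected hitting
   time of a uniform random walk to O: h = 0 on O and
   (D − A) h = d on the remaining vertices — a symmetric positive-definite
   grounded-Laplacian system solved exactly.
3. **Orientation.** Each undirected edge {u, v} becomes u → v iff
   (t(u), u) < (t(v), v) in an injective total order, yielding a DAG whose
   sinks (out-degree 0) are candidate developmental endpoints.
4. **Random walks.** 5000 walks start at O and step uniformly over
   out-edges until absorbed at a sink.  Sinks reached by ≥ 10 walks are
   grouped by graph-hop proximity into endpoint groups.
5. **Expert endpoints.** When a known terminal population E is missed (a
   pseudotime "shortcut"), pseudotime is recomputed as the commute fraction
   t = h_O / (h_O + h_E), pinning t = 0 on O and t = 1 on E; dead-end side
   branches then drain back and walks reach E.
6. **Topology of routes.** On a maxmin landmark subset, Vietoris–Rips
   persistence (mod-2, own implementation) finds the significant H1 classes
   (loops) of the data.  Each walk's closed landmark loop gets a binary
   signature — its homology coordinates over those classes — and
   average-linkage clustering of signatures + terminals yields a dendrogram
   of topologically coherent trajectory bundles.
7. **Trajectory analysis.** Bundles become cell sets with visit counts;
   marker-vs-pseudotime curves use equal-occupancy bins; the branch point
   of two bundles is the last pseudotime bin where their cell sets still
   overlap (Jaccard ≥ τ = 0.5).  Sample compositions are compared with a
   probability-binning statistic T = (χ²/K − 1)/√(2/K) over K
   equal-occupancy reference bins.
8. **Embedding.** A parametric 2D autoencoder (numpy, PCA-initialized
   linear skips + tanh corrections, reconstruction + weak latent prior +
   mutual-kNN neighborhood loss) trains on a density-balanced subsample and
   is frozen for bit-exact reuse on later samples.

A first-class synthetic-data module generates branching (and looping)
datasets with known topology, latent time and marker kinetics, so every
step above is scored against ground truth.

## Worked example

`examples/03_expert_endpoints.py` reproduces the expert-endpoint rescue on
synthetic data: 20,000 cells from the B-lymphopoiesis-like preset, whose
two plasma-cell tips (31 cells) hide behind low-density corridors:

```
plasma tip cells: 31 of 20000
walks reaching the tips, automatic pseudotime:        0.0%
walks reaching the tips, expert endpoints enforced: 100.0%
pseudotime at the endpoint set: exactly [1.]
```

With origin-anchored pseudotime the tips are never walk destinations; after
designating them as endpoints the commute-fraction field makes them the
global pseudotime maximum and every walk arrives.  The other examples cover
the remaining capabilities — e.g. `examples/02_pseudotime_random_walks.py`
finds four endpoint groups of ~1200–1300 walks each, one per mature arm
(natural effector / switched memory × κ/λ), and
`examples/06_marker_curves_branch_points.py` localizes the κ/λ branch point
at mean true latent time 0.633 against a generator split at 0.68:

```
iTdT curve peak: bin 7 (mean 3.46) near pseudotime 15305
kappa/lambda branch: bin 92, 439 shared cells, mean true latent time 0.633
```

The CLI mirrors the library:

```bash
walklineage synth --preset bcell --n 20000 --noise 0.1 --seed 7 -o data/
walklineage run config.json           # full pipeline into a run directory
walklineage map --run RUNDIR patient.fcs
```

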