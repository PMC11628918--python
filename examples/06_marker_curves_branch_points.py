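"""Marker-vs-pseudotime curves and branch-point localization.

Selected walk bundles become cell-level trajectories: equal-occupancy
pseudotime bins give per-marker expression curves, and the pseudotime bin
where two bundles' cell memberships stop overlapping (Jaccard below 0.5)
localizes their branching point.
"""

import numpy as np

import walklineage as wl
from walklineage import analysis

topo, kin = wl.preset_bcell_like(30)
ds = wl.generate(topo, kin, n_cells=20_000, noise_sd=0.1, seed=5)

graph = wl.build_knn_graph(ds.table, k=30)
origin = np.flatnonzero(ds.table.gate_label == "stem")
pt = wl.compute_pseudotime(graph, origin)
walks = wl.simulate_walks(wl.orient_edges(graph, pt), origin, n_walks=5000, seed=55)
groups = wl.detect_endpoint_groups(walks, graph)

stages = ds.truth.stage.values
by_stage = {}
for g in groups:
    sink_stages = [stages[s] for s in g.sinks]
    by_stage.setdefault(max(set(sink_stages), key=sink_stages.count), g)

bundle_k = analysis.bundle_cells(wl.select_walks(walks, by_stage["nat_eff_k"]), m_min=1)
curve = analysis.marker_curve(bundle_k, ds.table, pt, "iTdT", n_bins=30)
peak = int(np.nanargmax(curve.mean))
print(f"iTdT curve peak: bin {peak} (mean {np.nanmax(curve.mean):.2f}) "
      f"near pseudotime {curve.bin_centers[peak]:.0f}")

bundle_l = analysis.bundle_cells(wl.select_walks(walks, by_stage["nat_eff_l"]), m_min=1)
bp = analysis.find_branch_point(bundle_k, bundle_l, pt, n_bins=100, tau=0.5)
latent = ds.truth.latent_time.values[bp.branch_cells].mean()
print(f"kappa/lambda branch: bin {bp.bin_index}, {len(bp.branch_cells)} shared cells, "
      f"mean true latent time {latent:.3f} (generator splits at 0.68)")
# The marker curve recovers the early iTdT peak, and the branch point of the
# kappa- and lambda-bound trajectories lands at the light-chain split.
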