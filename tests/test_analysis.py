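"""Trajectory bundles, marker curves, branch points, compositions, and the
probability-binning statistic."""

import numpy as np
import pytest

import walklineage as wl
from walklineage.analysis import (
    bundle_cells,
    find_branch_point,
    marker_curve,
    permutation_null_T,
    probability_binning_T,
    subset_distribution,
)
from walklineage.graph import orient_edges
from walklineage.walks import Walk, WalkSet, simulate_walks


def walkset(*vertex_lists):
    return WalkSet(
        walks=[Walk(np.array(v, dtype=np.int64)) for v in vertex_lists],
        seed=0,
        n_requested=len(vertex_lists),
    )


def field(t, origin=(0,)):
    return wl.PseudotimeField(
        t=np.asarray(t, dtype=float), mode="hitting_time", origin=np.array(origin)
    )


class TestBundles:
    def test_single_walk_members_are_its_vertices(self):
        b = bundle_cells(walkset([0, 3, 5]), m_min=1)
        np.testing.assert_array_equal(b.cells, [0, 3, 5])
        np.testing.assert_array_equal(b.visit_counts, [1, 1, 1])

    def test_two_identical_walks_double_counts(self):
        b = bundle_cells(walkset([0, 1, 2], [0, 1, 2]), m_min=2)
        np.testing.assert_array_equal(b.cells, [0, 1, 2])
        np.testing.assert_array_equal(b.visit_counts, [2, 2, 2])

    def test_y_graph_stem_shared_arms_private(self, y_graph):
        pt = wl.compute_pseudotime(y_graph, [0])
        og = orient_edges(y_graph, pt)
        ws = simulate_walks(og, [0], n_walks=300, seed=1)
        groups = {min(g.sinks): g for g in wl.detect_endpoint_groups(ws, y_graph)}
        ba = bundle_cells(wl.select_walks(ws, groups[4]), m_min=2)
        bb = bundle_cells(wl.select_walks(ws, groups[6]), m_min=2)
        for stem_v in (0, 1, 2):
            assert stem_v in ba.cells and stem_v in bb.cells
        assert 3 in ba.cells and 3 not in bb.cells
        assert 5 in bb.cells and 5 not in ba.cells

    def test_empty_walkset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bundle_cells(WalkSet(walks=[], seed=0, n_requested=0))


def toy_table(values_col, name="x"):
    v = np.asarray(values_col, dtype=float)[:, None]
    return wl.EventTable(
        values=np.column_stack([v, np.zeros_like(v)]),
        marker_names=[name, "other"],
        sample_id=np.repeat(np.array(["s"], dtype=object), len(v)),
    )


class TestMarkerCurve:
    def test_constant_marker_flat_curve(self):
        n = 100
        table = toy_table(np.full(n, 2.5))
        b = bundle_cells(walkset(list(range(n))), m_min=1)
        pt = field(np.arange(n, dtype=float))
        c = marker_curve(b, table, pt, "x", n_bins=10)
        np.testing.assert_allclose(c.mean, 2.5)
        assert c.count.sum() == n
        assert np.max(np.abs(np.diff(c.count))) <= 1

    def test_bump_argmax_recovered(self, bcell_dataset, bcell_graph, bcell_pt):
        # iTdT peaks at latent 0.22; the curve argmax must sit at matching cells
        ds = bcell_dataset
        og = orient_edges(bcell_graph, bcell_pt)
        ws = simulate_walks(og, bcell_pt.origin, n_walks=400, seed=9)
        b = bundle_cells(ws, m_min=2)
        c = marker_curve(b, ds.table, bcell_pt, "iTdT", n_bins=30)
        peak_bin = int(np.nanargmax(c.mean))
        cells = np.repeat(b.cells, b.visit_counts)
        t = bcell_pt.t[cells]
        in_peak = (t >= c.bin_edges[peak_bin]) & (t <= c.bin_edges[peak_bin + 1])
        lat = ds.truth.latent_time.values[cells[in_peak]]
        assert abs(np.mean(lat) - 0.22) <= 0.05

    def test_event_order_irrelevant(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        t = rng.uniform(0, 1, n)
        perm = rng.permutation(n)
        table = toy_table(x)
        table_p = toy_table(x[perm])
        b = bundle_cells(walkset(list(range(n))), m_min=1)
        bp_ = bundle_cells(walkset(list(np.argsort(perm))), m_min=1)
        c1 = marker_curve(b, table, field(t), "x", n_bins=8)
        c2 = marker_curve(bp_, table_p, field(t[perm]), "x", n_bins=8)
        np.testing.assert_allclose(c1.mean, c2.mean)

    def test_too_many_bins_rejected(self):
        table = toy_table(np.arange(5.0))
        b = bundle_cells(walkset([0, 1, 2, 3, 4]), m_min=1)
        with pytest.raises(ValueError, match="n_bins"):
            marker_curve(b, table, field(np.arange(5.0)), "x", n_bins=10)


class TestBranchPoint:
    def test_identical_bundles_branch_at_final_bin(self):
        b = bundle_cells(walkset(list(range(50))), m_min=1)
        bp = find_branch_point(b, b, field(np.arange(50.0)), n_bins=10)
        assert bp.bin_index == 9
        np.testing.assert_allclose(bp.overlap_profile, 1.0)

    def test_disjoint_bundles_flagged(self):
        a = bundle_cells(walkset(list(range(0, 20))), m_min=1)
        b = bundle_cells(walkset(list(range(20, 40))), m_min=1)
        t = np.concatenate([np.linspace(0, 1, 20), np.linspace(0, 1, 20)])
        bp = find_branch_point(a, b, field(t), n_bins=5)
        assert bp.already_disjoint
        assert bp.bin_index == 0

    def test_symmetric_in_arguments(self, y_graph):
        pt = wl.compute_pseudotime(y_graph, [0])
        og = orient_edges(y_graph, pt)
        ws = simulate_walks(og, [0], n_walks=300, seed=2)
        groups = {min(g.sinks): g for g in wl.detect_endpoint_groups(ws, y_graph)}
        ba = bundle_cells(wl.select_walks(ws, groups[4]), m_min=2)
        bb = bundle_cells(wl.select_walks(ws, groups[6]), m_min=2)
        ab = find_branch_point(ba, bb, pt, n_bins=4)
        ba_ = find_branch_point(bb, ba, pt, n_bins=4)
        assert ab.bin_index == ba_.bin_index
        np.testing.assert_array_equal(ab.branch_cells, ba_.branch_cells)
        np.testing.assert_allclose(ab.overlap_profile, ba_.overlap_profile)

    def test_synthetic_split_located_near_truth(self, bcell_dataset, bcell_graph, bcell_pt):
        ds = bcell_dataset
        og = orient_edges(bcell_graph, bcell_pt)
        ws = simulate_walks(og, bcell_pt.origin, n_walks=2000, seed=3)
        st = ds.truth.stage.values
        groups = wl.detect_endpoint_groups(ws, bcell_graph)
        by_stage = {}
        for g in groups:
            stages = [st[s] for s in g.sinks]
            by_stage.setdefault(max(set(stages), key=stages.count), g)
        ba = bundle_cells(wl.select_walks(ws, by_stage["nat_eff_k"]), m_min=1)
        bb = bundle_cells(wl.select_walks(ws, by_stage["nat_eff_l"]), m_min=1)
        bp = find_branch_point(ba, bb, bcell_pt, n_bins=60, tau=0.5)
        lat = ds.truth.latent_time.values[bp.branch_cells].mean()
        assert abs(lat - 0.68) <= 0.1  # coarse at this small scale


class TestSubsetDistribution:
    def test_single_label_is_one(self):
        t = toy_table(np.arange(4.0))
        t.gate_label = np.array(["A"] * 4, dtype=object)
        dist = subset_distribution([t])
        assert dist.loc["s", "A"] == 1.0

    def test_30_70_split(self):
        t = toy_table(np.arange(10.0))
        t.gate_label = np.array(["A"] * 3 + ["B"] * 7, dtype=object)
        dist = subset_distribution([t])
        assert dist.loc["s", "A"] == pytest.approx(0.3)
        assert dist.loc["s", "B"] == pytest.approx(0.7)

    def test_generator_proportions_recovered(self, bcell_dataset):
        dist = subset_distribution([bcell_dataset.table])
        counts = bcell_dataset.truth.stage.value_counts(normalize=True)
        for stage, frac in counts.items():
            assert dist.loc["synthetic", stage] == pytest.approx(frac)
        assert dist.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_missing_labels_rejected(self):
        with pytest.raises(ValueError, match="gate labels"):
            subset_distribution([toy_table(np.arange(3.0))])


class TestProbabilityBinning:
    def test_equal_occupancy_construction(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=(1037, 4))
        stat = probability_binning_T(ref, ref, n_bins=100)
        assert stat.reference_counts.max() - stat.reference_counts.min() <= 1

    def test_identical_copy_gives_negative_boundary_T(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(4000, 4))
        stat = probability_binning_T(ref, ref, n_bins=100)
        assert stat.T == pytest.approx(-np.sqrt(100 / 2), rel=1e-6)

    def test_null_below_permutation_99th_percentile(self):
        rng = np.random.default_rng(7)
        ref = rng.normal(size=(10000, 5))
        tst = rng.normal(size=(10000, 5))
        obs = probability_binning_T(ref, tst, n_bins=100).T
        null = permutation_null_T(ref, tst, n_bins=100, n_perm=100, seed=1)
        assert abs(obs) < np.quantile(np.abs(null), 0.99)

    def test_null_variance_near_unity(self):
        ts = []
        for i in range(200):
            r = np.random.default_rng(3000 + i)
            ts.append(probability_binning_T(r.normal(size=(2000, 4)), r.normal(size=(1000, 4)), n_bins=50).T)
        v = np.var(ts)
        assert 0.5 <= v <= 2.0

    def test_median_T_increases_with_shift(self):
        medians = []
        for shift in (0.0, 0.15, 0.3, 0.6):
            vals = []
            for s in range(20):
                r = np.random.default_rng(s)
                ref = r.normal(size=(3000, 5))
                tst = r.normal(size=(3000, 5)) + shift
                vals.append(probability_binning_T(ref, tst, n_bins=50).T)
            medians.append(np.median(vals))
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_insufficient_reference_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            probability_binning_T(np.zeros((50, 2)), np.zeros((50, 2)), n_bins=100)
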