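"""Landmarks, Rips persistence, walk signatures and the walk dendrogram."""

import collections

import numpy as np
import pytest

import walklineage as wl
from walklineage.topology import (
    H1Basis,
    cluster_walks,
    compute_persistence,
    dominant_landmark,
    h1_basis,
    select_landmarks,
    significant_classes,
    walk_signature,
    walk_signatures,
)
from walklineage.walks import Walk

from .oracles import cycle_is_boundary, rips_betti


def circle_points(n=60, r=1.0, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if noise:
        pts = pts + rng.normal(0, noise, pts.shape)
    return pts


class TestLandmarks:
    def test_all_points_selected_when_count_equals_n(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        lm = select_landmarks(x, count=20, seed=1)
        assert sorted(lm.indices.tolist()) == list(range(20))

    def test_square_corners_win_maxmin(self):
        # center + 4 corners: starting anywhere, maxmin picks all corners
        pts = np.array([[0.0, 0.0], [1, 1], [1, -1], [-1, 1], [-1, -1]])
        lm = select_landmarks(pts, count=4, seed=3)
        assert set(lm.indices.tolist()) >= {1, 2, 3, 4} - {lm.indices[0]}
        assert len(set(lm.indices.tolist()) & {1, 2, 3, 4}) >= 3

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(2).normal(size=(100, 4))
        a = select_landmarks(x, count=10, seed=9)
        b = select_landmarks(x, count=10, seed=9)
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.assignment, b.assignment)

    def test_bad_count_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            select_landmarks(np.zeros((5, 2)), count=0, seed=0)


class TestPersistence:
    def test_too_few_landmarks_empty_h1(self):
        res = compute_persistence(np.zeros((1, 2)), max_scale=1.0)
        assert res.h1_classes == []

    def test_circle_has_one_dominant_h1_class(self):
        res = compute_persistence(circle_points(60), max_scale=2.0)
        pers = res.diagram.persistence(1)
        assert len(pers) >= 1
        if len(pers) > 1:
            assert pers[0] > 0.5 * 2 * pers[1] or pers[1] < 0.5 * pers[0]
        assert pers[0] > 1.0  # hole of radius 1 lives for a long scale range

    def test_gaussian_blob_has_no_large_h1(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(200, 2))
        diam = np.max(np.linalg.norm(pts[:, None] - pts[None], axis=2))
        res = compute_persistence(pts, max_scale=0.5 * diam)
        pers = res.diagram.persistence(1)
        assert pers.size == 0 or pers.max() <= 0.2 * diam

    @pytest.mark.parametrize("seed", [0, 1])
    def test_betti_curves_match_gf2_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, size=(18, 2))
        max_scale = 0.8
        res = compute_persistence(pts, max_scale=max_scale)
        for scale in (0.2, 0.35, 0.5):
            b0o, b1o = rips_betti(pts, scale)
            h0 = res.diagram.pairs[0]
            b0 = int(np.sum((h0[:, 0] <= scale) & (h0[:, 1] > scale)))
            h1 = res.diagram.pairs[1]
            alive = [
                1
                for b, d, _ in res.h1_classes
                if b <= scale < (d if d < max_scale else np.inf)
            ]
            # classes truncated at max_scale are alive at any scale below it
            b1 = sum(alive)
            assert b0 == b0o
            assert b1 == b1o

    def test_diagram_sorted_by_persistence(self):
        res = compute_persistence(circle_points(40, noise=0.05, seed=5), max_scale=1.5)
        pers = res.diagram.persistence(1)
        assert np.all(np.diff(pers) <= 1e-12)

    def test_noise_stability_of_dominant_class(self, loop_dataset):
        lm = select_landmarks(loop_dataset.table, count=70, seed=2)
        diam = np.max(np.linalg.norm(lm.coordinates[:, None] - lm.coordinates[None], axis=2))
        base = compute_persistence(lm, max_scale=1.4)
        top = base.diagram.persistence(1)[0]
        rng = np.random.default_rng(0)
        noisy = lm.coordinates + rng.normal(0, 0.01 * diam, lm.coordinates.shape)
        pert = compute_persistence(noisy, max_scale=1.4)
        assert abs(pert.diagram.persistence(1)[0] - top) <= 0.1 * top


class TestSignificantClasses:
    def test_single_dominant_class_midpoint_epsilon(self):
        res = compute_persistence(circle_points(60), max_scale=2.0)
        sig = significant_classes(res, rule="ratio", gamma=0.5)
        assert len(sig.classes) == 1
        b, d, _ = sig.classes[0]
        assert sig.epsilon == pytest.approx((b + d) / 2)

    def test_disjoint_intervals_rejected(self):
        res = compute_persistence(circle_points(60), max_scale=2.0)
        fake = [(0.1, 0.2, res.h1_classes[0][2]), (0.5, 0.9, res.h1_classes[0][2])]
        res.h1_classes = fake
        with pytest.raises(ValueError, match="per-class"):
            significant_classes(res, rule="ratio", gamma=0.0)

    def test_annulus_gamma_half_selects_exactly_one(self, loop_dataset):
        lm = select_landmarks(loop_dataset.table, count=80, seed=0)
        res = compute_persistence(lm, max_scale=1.4)
        sig = significant_classes(res, rule="ratio", gamma=0.5)
        assert len(sig.classes) == 1

    def test_no_h1_rejected(self):
        res = compute_persistence(np.random.default_rng(0).normal(size=(5, 2)), max_scale=0.01)
        with pytest.raises(ValueError, match="no H1"):
            significant_classes(res)


def annulus_fixture():
    """Loop dataset with landmarks, basis, oriented walks, and side truth."""
    topo, kin = wl.preset_loop(n_markers=6)
    ds = wl.generate(topo, kin, n_cells=3000, noise_sd=0.08, seed=21)
    g = wl.build_knn_graph(ds.table, k=10)
    origin = np.flatnonzero(
        (ds.table.gate_label == "start") & (ds.truth.latent_time.values < 0.05)
    )
    pt = wl.compute_pseudotime(g, origin)
    og = wl.orient_edges(g, pt)
    ws = wl.simulate_walks(og, origin, n_walks=400, seed=11)
    lm = select_landmarks(ds.table, count=80, seed=0)
    res = compute_persistence(lm, max_scale=1.4)
    sig = significant_classes(res, rule="ratio", gamma=0.5)
    basis = h1_basis(res, sig)
    return ds, g, ws, lm, basis


@pytest.fixture(scope="module")
def annulus():
    return annulus_fixture()


class TestWalkSignature:
    def test_opposite_sides_differ_in_the_hole_bit(self, annulus):
        ds, g, ws, lm, basis = annulus
        bits, terms = walk_signatures(ws, lm, basis)
        assert bits.shape[1] == 1
        side = np.array(
            [
                collections.Counter(ds.truth.side.values[w.vertices]).most_common(1)[0][0]
                for w in ws.walks
            ]
        )
        # walks that completed the loop: terminal near the end stage
        end_mask = np.array(
            [ds.truth.latent_time.values[w.terminal] > 0.8 for w in ws.walks]
        )
        upper = bits[end_mask & (side == "upper"), 0]
        lower = bits[end_mask & (side == "lower"), 0]
        # the two route families land in opposite signature classes
        assert np.mean(upper == upper[0]) >= 0.9
        assert np.mean(lower == (1 - upper[0])) >= 0.9

    def test_duplicate_vertex_does_not_change_signature(self, annulus):
        ds, g, ws, lm, basis = annulus
        origin_lm = dominant_landmark(lm, [int(w.vertices[0]) for w in ws.walks])
        w = ws.walks[0]
        dup = Walk(np.insert(w.vertices, 3, w.vertices[3]))
        a = walk_signature(w, lm, basis, origin_lm)
        b = walk_signature(dup, lm, basis, origin_lm)
        assert np.array_equal(a.bits, b.bits)

    def test_contractible_loop_gets_zero_signature(self, annulus):
        # the boundary of any filled triangle of the epsilon-complex is a
        # null-homologous cycle, so its signature must be all zeros
        ds, g, ws, lm, basis = annulus
        adj = {}
        for p, (a, b, d) in enumerate(basis.edges):
            adj.setdefault(int(a), set()).add(int(b))
            adj.setdefault(int(b), set()).add(int(a))
        found = None
        for (a, b), p in basis.edge_pos.items():
            common = adj.get(a, set()) & adj.get(b, set())
            if common:
                found = (a, b, min(common))
                break
        assert found is not None
        a, b, c = found
        z = 0
        for e in ((a, b), (a, c), (b, c)):
            z ^= 1 << basis.edge_pos[(min(e), max(e))]
        np.testing.assert_array_equal(basis.reduce_cycle(z), np.zeros(1, dtype=np.uint8))

    def test_xor_additivity_against_brute_force(self, annulus):
        ds, g, ws, lm, basis = annulus
        origin_lm = dominant_landmark(lm, [int(w.vertices[0]) for w in ws.walks])
        bits, _ = walk_signatures(ws, lm, basis, origin_lm)
        # pick one walk from each side that completed the loop
        lat = ds.truth.latent_time.values
        side = ds.truth.side.values
        picks = {}
        for i, w in enumerate(ws.walks):
            if lat[w.terminal] > 0.85:
                s = collections.Counter(side[w.vertices]).most_common(1)[0][0]
                picks.setdefault(s, i)
        if len(picks) < 2:
            pytest.skip("one-sided draw")
        i, j = picks["upper"], picks["lower"]
        from walklineage.topology import _itinerary, _loop_bitset

        combined = (
            _loop_bitset(basis, [origin_lm] + _itinerary(ws.walks[i].vertices, lm) + [origin_lm])
            ^ _loop_bitset(basis, [origin_lm] + _itinerary(ws.walks[j].vertices, lm) + [origin_lm])
        )
        xor_bits = basis.reduce_cycle(combined)
        np.testing.assert_array_equal(xor_bits, bits[i] ^ bits[j])
        # and the combined loop is null-homologous iff the bits cancel
        edge_set = set()
        z = combined
        while z:
            p = z.bit_length() - 1
            z &= ~(1 << p)
            a, b, _d = basis.edges[p]
            edge_set.add((int(a), int(b)))
        bounds = cycle_is_boundary(lm.coordinates, basis.epsilon, edge_set)
        assert bounds == bool(np.all((bits[i] ^ bits[j]) == 0))


class TestDendrogram:
    def test_identical_signatures_merge_at_zero(self):
        bits = np.zeros((5, 2), dtype=np.uint8)
        terms = np.zeros(5, dtype=np.int64)
        dend = cluster_walks(bits, terms)
        assert np.all(dend.linkage_matrix[:, 2] == 0)
        assert len(np.unique(dend.cut(0.0))) == 1

    def test_single_walk_trivial_dendrogram(self):
        dend = cluster_walks(np.zeros((1, 3), dtype=np.uint8), np.array([2]))
        assert dend.linkage_matrix is None
        assert dend.to_newick(["w0"]) == "w0;"
        assert list(dend.cut(1.0)) == [0]

    def test_annulus_cut_separates_sides_with_purity(self, annulus):
        ds, g, ws, lm, basis = annulus
        bits, terms = walk_signatures(ws, lm, basis)
        # two-step workflow: select walks of the dominant endpoint group first,
        # then cluster those by topology (constant terminal within the group)
        groups = wl.detect_endpoint_groups(ws, g, min_walks=10, hop_radius=2)
        sel = groups[0].member_walks
        dend = cluster_walks(bits[sel], np.zeros(len(sel), dtype=np.int64))
        labels = dend.cut(0.5)
        assert len(np.unique(labels)) == 2
        side = np.array(
            [
                collections.Counter(ds.truth.side.values[ws.walks[i].vertices]).most_common(1)[0][0]
                for i in sel
            ]
        )
        purity = []
        for c in np.unique(labels):
            m = labels == c
            purity.append(max(np.mean(side[m] == "upper"), np.mean(side[m] == "lower")))
        assert min(purity) >= 0.9

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(0)
        bits = rng.integers(0, 2, size=(6, 2)).astype(np.uint8)
        dend = cluster_walks(bits, np.arange(6))
        nwk = dend.to_newick()
        assert nwk.endswith(";")
        for i in range(6):
            assert f"walk{i}" in nwk
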