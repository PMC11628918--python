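"""FCS I/O, transforms and concatenation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import walklineage as wl
from walklineage.fcs import (
    DerivedChannels,
    FcsFormatError,
    apply_gate_labels,
    read_gate_csv,
    write_fcs,
)

from .oracles import minimal_read_fcs


def make_table(n=10, markers=("a", "b", "c"), seed=0, labels=None):
    rng = np.random.default_rng(seed)
    return wl.EventTable(
        values=rng.uniform(0, 100, size=(n, len(markers))),
        marker_names=list(markers),
        sample_id=np.repeat(np.array(["s1"], dtype=object), n),
        gate_label=None if labels is None else np.array(labels, dtype=object),
    )


class TestPanelMap:
    def test_duplicate_channels_rejected(self):
        with pytest.raises(ValueError, match="duplicate channel"):
            wl.PanelMap((("c1", "CD3", True), ("c1", "CD4", True)))

    def test_needs_at_least_one_analysis_marker(self):
        with pytest.raises(ValueError, match="no analysis markers"):
            wl.PanelMap((("c1", "CD3", False),))


class TestReadWrite:
    def test_read_with_panel_subsets_and_renames(self, tmp_path):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 1000, size=(100, 5)).astype(np.float32)
        path = tmp_path / "x.fcs"
        write_fcs(path, data, [f"ch{i}" for i in range(5)])
        panel = wl.PanelMap(
            (
                ("ch0", "CD34", True),
                ("ch2", "CD19", True),
                ("ch4", "TdT", True),
                ("ch1", "junk", False),
            )
        )
        t = wl.read_fcs(path, panel)
        assert t.values.shape == (100, 3)
        assert t.marker_names == ["CD34", "CD19", "TdT"]
        assert t.transform_state == "raw"
        np.testing.assert_allclose(t.values, data[:, [0, 2, 4]], rtol=1e-6)

    def test_missing_channel_error_names_it(self, tmp_path):
        path = tmp_path / "x.fcs"
        write_fcs(path, np.ones((5, 2), dtype=np.float32), ["a", "b"])
        panel = wl.PanelMap((("Xx999", "CD3", True),))
        with pytest.raises(FcsFormatError, match="Xx999"):
            wl.read_fcs(path, panel)

    def test_corrupt_header_reports_offset(self, tmp_path):
        path = tmp_path / "bad.fcs"
        path.write_bytes(b"FCS3.1    " + b"garbage!" * 6)
        with pytest.raises(FcsFormatError, match="offset"):
            wl.read_fcs(path)

    def test_roundtrip_matches_independent_reader(self, tmp_path):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 50, size=(64, 4))
        path = tmp_path / "rt.fcs"
        write_fcs(path, data, ["w", "x", "y", "z"])
        names, back = minimal_read_fcs(path)
        assert names == ["w", "x", "y", "z"]
        np.testing.assert_allclose(back, data.astype(np.float32), rtol=0, atol=0)

    @settings(max_examples=20, deadline=None)
    @given(
        n=st.integers(1, 40),
        m=st.integers(1, 6),
        seed=st.integers(0, 2**16),
    )
    def test_roundtrip_lossless_at_float32(self, tmp_path_factory, n, m, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 100, size=(n, m))
        path = tmp_path_factory.mktemp("fcs") / "p.fcs"
        write_fcs(path, data, [f"c{i}" for i in range(m)])
        t = wl.read_fcs(path)
        np.testing.assert_array_equal(t.values.astype(np.float32), data.astype(np.float32))


class TestArcsinh:
    def test_analytic_values(self):
        t = make_table()
        t.values[0, 0] = 0.0
        t.values[0, 1] = 5.0
        out = wl.arcsinh_transform(t, cofactor=5)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(0.88137, abs=1e-5)
        assert out.transform_state == "arcsinh(5)"

    def test_inverse_recovers_raw(self):
        t = make_table(n=50, seed=3)
        out = wl.arcsinh_transform(t, cofactor=5)
        back = np.sinh(out.values) * 5
        np.testing.assert_allclose(back, t.values, rtol=1e-6)

    def test_double_transform_rejected(self):
        out = wl.arcsinh_transform(make_table())
        with pytest.raises(ValueError, match="already transformed"):
            wl.arcsinh_transform(out)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**16), cofactor=st.floats(0.5, 50))
    def test_monotone_per_marker(self, seed, cofactor):
        t = make_table(n=30, seed=seed)
        out = wl.arcsinh_transform(t, cofactor)
        for j in range(t.n_markers):
            assert np.array_equal(np.argsort(out.values[:, j]), np.argsort(t.values[:, j]))


class TestConcatenate:
    def test_accept_all_is_row_stack(self):
        a, b = make_table(10, seed=1), make_table(10, seed=2)
        out = wl.concatenate([a, b])
        assert out.n_events == 20
        np.testing.assert_array_equal(out.values[:10], a.values)

    def test_label_filter(self):
        labels = ["CD34+"] * 4 + ["CD19+"] * 3 + ["other"] * 3
        t = make_table(10, labels=labels)
        out = wl.concatenate([t], keep_predicate={"CD34+", "CD19+"})
        assert out.n_events == 7

    def test_marker_mismatch_reports_symmetric_difference(self):
        a = make_table(5, markers=("a", "b"))
        b = make_table(5, markers=("a", "c"))
        with pytest.raises(ValueError, match="'b'.*'c'|'c'.*'b'"):
            wl.concatenate([a, b])

    def test_groupby_sample_recovers_filtered_inputs(self):
        a = make_table(8, labels=["x"] * 5 + ["y"] * 3, seed=4)
        b = make_table(6, labels=["x"] * 2 + ["y"] * 4, seed=5)
        b.sample_id[:] = "s2"
        out = wl.concatenate([a, b], keep_predicate={"x"})
        for sid, expected in (("s1", a.values[:5]), ("s2", b.values[:2])):
            part = out.subset(out.sample_id == sid)
            np.testing.assert_array_equal(part.values, expected)

    def test_associative_up_to_row_order(self):
        a, b, c = (make_table(5, seed=s) for s in (1, 2, 3))
        left = wl.concatenate([wl.concatenate([a, b]), c])
        right = wl.concatenate([a, wl.concatenate([b, c])])
        np.testing.assert_array_equal(left.values, right.values)


class TestEnhancedFcs:
    def _derived(self, n):
        rng = np.random.default_rng(0)
        return DerivedChannels.assemble(
            n,
            embedding=rng.normal(size=(n, 2)),
            pseudotime=rng.uniform(0, 10, n),
            memberships={"EG1": (rng.random(n) > 0.5).astype(float)},
        )

    def test_channel_count_and_roundtrip(self, tmp_path):
        t = make_table(100)
        d = self._derived(100)
        path = tmp_path / "enh.fcs"
        wl.export_enhanced_fcs(t, d, path)
        back = wl.read_fcs(path)
        assert back.n_markers == 3 + 4
        pt_col = back.marker("TVB_pseudotime")
        assert np.max(np.abs(pt_col - d.columns["TVB_pseudotime"])) <= 1e-5

    def test_wrong_length_rejected(self, tmp_path):
        t = make_table(100)
        with pytest.raises(ValueError, match="rows"):
            wl.export_enhanced_fcs(t, self._derived(99), tmp_path / "x.fcs")

    def test_name_collision_rejected(self, tmp_path):
        t = make_table(10, markers=("TVB_vae1", "b", "c"))
        with pytest.raises(ValueError, match="collide"):
            wl.export_enhanced_fcs(t, self._derived(10), tmp_path / "x.fcs")

    def test_membership_must_be_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            DerivedChannels({"TVB_traj_a": np.array([0.0, 0.5])})


class TestGateLabels:
    def test_sidecar_csv_roundtrip(self, tmp_path):
        path = tmp_path / "gates.csv"
        path.write_text("sample_id,event_index,label\ns1,0,stem\ns1,2,blast\n")
        gates = read_gate_csv(path)
        t = apply_gate_labels(make_table(3), gates)
        assert list(t.gate_label) == ["stem", None, "blast"]

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="columns"):
            read_gate_csv(path)
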