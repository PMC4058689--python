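import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffrct.geometry import (CoronaryTree, EmulatorConfig, GeometryError,
                            Junction, StenosisSpec, VesselSegment,
                            build_porcine_lad_emulator, export_centerline,
                            insert_stenosis, read_tree, spec_at_location,
                            tree_from_dict, write_tree)


class TestEmulator:
    def test_default_tree_satisfies_anatomical_constraints(self, emulator_tree):
        assert len(emulator_tree.segments) == 8  # trunk + 7 branches
        assert len(emulator_tree.outlets) == 8
        trunk = emulator_tree.trunk
        assert min(trunk.samples_d) >= 2.0
        assert np.all(np.diff(trunk.samples_d) <= 0)  # monotone taper
        for seg in emulator_tree.segments:
            if seg.role == "branch":
                assert min(seg.samples_d) >= 1.0
        locs = emulator_tree.locations()
        assert list(sorted(locs)) == ["A", "B", "C", "D"]
        assert locs["A"] < locs["B"] < locs["C"] < locs["D"]

    def test_zero_branch_config_gives_single_tube(self):
        tree = build_porcine_lad_emulator(EmulatorConfig(
            branch_positions_mm=(), branch_diameters_mm=()))
        assert len(tree.segments) == 1
        assert tree.outlets == ("trunk",)

    def test_emulator_is_deterministic(self):
        a = build_porcine_lad_emulator(EmulatorConfig())
        b = build_porcine_lad_emulator(EmulatorConfig())
        assert a == b

    def test_constraint_violations_rejected(self):
        with pytest.raises(GeometryError, match="2 mm"):
            build_porcine_lad_emulator(EmulatorConfig(trunk_outlet_diameter_mm=1.5))
        with pytest.raises(GeometryError, match="1 mm"):
            build_porcine_lad_emulator(EmulatorConfig(
                branch_diameters_mm=(2.0, 1.8, 1.6, 1.5, 1.3, 1.2, 0.8)))
        with pytest.raises(GeometryError, match="monotone"):
            build_porcine_lad_emulator(EmulatorConfig(
                trunk_inlet_diameter_mm=2.5, trunk_outlet_diameter_mm=3.0))


class TestStenosis:
    def test_zero_ds_is_identity(self, emulator_tree):
        spec = spec_at_location(emulator_tree, 0.0, 4.0, "A")
        assert insert_stenosis(emulator_tree, spec) is emulator_tree

    @pytest.mark.parametrize("ds", [0.45, 0.55, 0.65, 0.75, 0.99])
    def test_throat_diameter_is_exactly_one_minus_ds(self, emulator_tree, ds):
        spec = spec_at_location(emulator_tree, ds, 4.0, "A")
        narrowed = insert_stenosis(emulator_tree, spec)
        d_normal = emulator_tree.trunk.diameter(spec.center_s)
        d_throat = narrowed.trunk.diameter(spec.center_s)
        assert d_throat / d_normal == pytest.approx(1.0 - ds, rel=1e-12)

    def test_profile_continuous_at_extent_edges(self, emulator_tree):
        spec = spec_at_location(emulator_tree, 0.55, 4.0, "A")
        narrowed = insert_stenosis(emulator_tree, spec)
        for s in (spec.s_start, spec.s_end):
            assert narrowed.trunk.diameter(s) == pytest.approx(
                emulator_tree.trunk.diameter(s), rel=1e-9)

    def test_original_tree_not_mutated_and_junctions_preserved(self, emulator_tree):
        before = [tuple(emulator_tree.trunk.samples_d)]
        spec = spec_at_location(emulator_tree, 0.75, 4.0, "B")
        narrowed = insert_stenosis(emulator_tree, spec)
        assert tuple(emulator_tree.trunk.samples_d) == before[0]
        assert narrowed.junctions == emulator_tree.junctions
        assert narrowed.trunk.length == emulator_tree.trunk.length

    def test_extent_overlapping_junction_is_rejected_naming_branch(self, emulator_tree):
        # branch "b" attaches at s=30; this lesion reaches it (but not "a")
        spec = StenosisSpec(ds=0.5, length=11.0, center_s=25.0)
        with pytest.raises(GeometryError, match="'b'"):
            insert_stenosis(emulator_tree, spec)

    def test_outside_trunk_rejected(self, emulator_tree):
        with pytest.raises(GeometryError, match="outside trunk"):
            insert_stenosis(emulator_tree, StenosisSpec(ds=0.5, length=10.0, center_s=99.0))

    @given(ds=st.floats(0.01, 0.99))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_window_bounded_and_peaks_at_throat(self, ds):
        spec = StenosisSpec(ds=ds, length=8.0, center_s=20.0)
        s = np.linspace(10, 30, 401)
        w = spec.window(s)
        assert np.all((w >= 0) & (w <= 1))
        assert spec.window(np.array([spec.center_s]))[0] == pytest.approx(1.0)
        assert w[s < spec.s_start].max(initial=0.0) == 0.0

    def test_trapezoid_shape_flat_throat(self):
        spec = StenosisSpec(ds=0.5, length=8.0, center_s=20.0, shape="trapezoid")
        w = spec.window(np.linspace(18, 22, 11))
        assert np.allclose(w, 1.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError):
            StenosisSpec(ds=1.0, length=4.0, center_s=20.0)
        with pytest.raises(GeometryError):
            StenosisSpec(ds=0.5, length=0.0, center_s=20.0)
        with pytest.raises(GeometryError):
            StenosisSpec(ds=0.5, length=4.0, center_s=20.0, shape="gaussian")


class TestSerialization:
    def test_round_trip_preserves_tree(self, emulator_tree, tmp_path):
        path = tmp_path / "tree.json"
        write_tree(emulator_tree, path)
        back = read_tree(path)
        assert back.inlet == emulator_tree.inlet
        assert back.outlets == emulator_tree.outlets
        for a, b in zip(back.segments, emulator_tree.segments):
            np.testing.assert_allclose(a.samples_s, b.samples_s, rtol=1e-12)
            np.testing.assert_allclose(a.samples_d, b.samples_d, rtol=1e-12)
        assert back.locations() == emulator_tree.locations()

    def test_missing_segments_key_reports_path(self):
        with pytest.raises(GeometryError, match=r"\$\.segments"):
            tree_from_dict({"junctions": [], "inlet": "t", "outlets": []})

    def test_cycle_rejected_on_read(self):
        seg = {"id": "a", "role": "trunk", "length": 10.0,
               "profile": [[0.0, 3.0], [10.0, 3.0]]}
        seg2 = dict(seg, id="b", role="branch")
        doc = {"segments": [seg, seg2],
               "junctions": [{"parent": "a", "s": 5.0, "child": "b"},
                             {"parent": "b", "s": 5.0, "child": "a"}],
               "inlet": "a", "outlets": ["b"]}
        with pytest.raises(GeometryError):
            tree_from_dict(doc)


class TestCenterlineExport:
    def test_csv_row_count_matches_samples(self, tmp_path):
        seg = VesselSegment.from_profile("t", np.linspace(0, 10, 11),
                                         np.full(11, 3.0), role="trunk")
        tree = CoronaryTree(segments=(seg,), junctions=(), inlet="t", outlets=("t",))
        path = tmp_path / "c.csv"
        export_centerline(tree, path, "csv")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 12  # header + 11 samples

    def test_vtk_polyline_per_segment(self, emulator_tree, tmp_path):
        path = tmp_path / "c.vtk"
        export_centerline(emulator_tree, path, "vtk-polyline")
        text = path.read_text()
        assert text.startswith("# vtk DataFile")
        nlines = int([ln for ln in text.splitlines() if ln.startswith("LINES")][0].split()[1])
        assert nlines == len(emulator_tree.segments)

    def test_unknown_format_rejected(self, emulator_tree, tmp_path):
        with pytest.raises(GeometryError, match="format"):
            export_centerline(emulator_tree, tmp_path / "x", "stl")


def test_tree_validation_rejects_orphans_and_duplicates():
    seg = VesselSegment.tapered("t", 10.0, 3.0, 3.0, role="trunk")
    other = VesselSegment.tapered("x", 5.0, 2.0, 2.0)
    with pytest.raises(GeometryError, match="not connected"):
        CoronaryTree(segments=(seg, other), junctions=(), inlet="t", outlets=("t", "x"))
    with pytest.raises(GeometryError, match="duplicate"):
        CoronaryTree(segments=(seg, seg), junctions=(), inlet="t", outlets=("t",))
    b = VesselSegment.tapered("b", 5.0, 2.0, 2.0)
    with pytest.raises(GeometryError, match="outside parent"):
        CoronaryTree(segments=(seg, b),
                     junctions=(Junction(parent="t", s=15.0, child="b"),),
                     inlet="t", outlets=("b", "t"))
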