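"""Geometry, surface meshes, MCI, and virtual slicing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from sxtmorph import RunConfig
from sxtmorph.compartments import CompartmentSegmentation, watershed_interior_split
from sxtmorph.morphometry import (
    classify_complexity,
    compute_mci,
    measure_geometry,
    measure_object,
    mesh_surface_area,
    principal_axes,
    virtual_slicing,
)
from sxtmorph.phantom import PhantomSpec, make_phantom

VS = 0.02


def _ball_mask(r, pad=4):
    n = 2 * (r + pad) + 1
    ax = np.arange(n) - (r + pad)
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return zz**2 + yy**2 + xx**2 <= r**2


def _seg(cristae, matrix=None, object_id=1):
    if matrix is None:
        matrix = np.zeros_like(cristae)
    return CompartmentSegmentation(object_id=object_id, cristae_label=cristae, matrix_label=matrix)


class TestComputeMci:
    def test_table_anchor_row(self):
        # matrix SA 1.62 µm², matrix volume 0.06 µm³
        assert round(compute_mci(1.62, 0.06), 2) == 7.48

    def test_unit_sphere_closed_form(self):
        sa = 4 * np.pi
        v = 4 * np.pi / 3
        assert compute_mci(sa, v) == pytest.approx(9 / (4 * np.pi), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(sa=st.floats(0.1, 100), v=st.floats(0.01, 10), k=st.floats(0.1, 10))
    def test_scale_invariance(self, sa, v, k):
        assert compute_mci(k**2 * sa, k**3 * v) == pytest.approx(compute_mci(sa, v), rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_mci(0.0, 0.06)
        with pytest.raises(ValueError):
            compute_mci(1.62, -0.01)

    @pytest.mark.parametrize(
        "mci,expected",
        [(7.48, "resolvable"), (7.0, "resolvable"), (3.82, "below_threshold")],
    )
    def test_complexity_classification(self, mci, expected):
        assert classify_complexity(mci) == expected


class TestSurfaceAndGeometry:
    def test_cuboid_volume_exact(self):
        cuboid = np.zeros((14, 14, 14), dtype=bool)
        cuboid[2:12, 2:12, 2:12] = True
        rec = measure_geometry(_seg(cuboid), None, VS)
        assert rec.volume_total_um3 == pytest.approx(0.008, abs=1e-12)

    def test_ball_mesh_surface_and_volume(self):
        r = 20
        ball = _ball_mask(r)
        sa = mesh_surface_area(ball, VS)
        assert sa == pytest.approx(4 * np.pi * (r * VS) ** 2, rel=0.05)
        vol = ball.sum() * VS**3
        assert vol == pytest.approx(4 / 3 * np.pi * (r * VS) ** 3, rel=0.02)

    def test_mesh_area_error_decreases_with_resolution(self):
        errors = []
        for r in (10, 20, 40):
            sa = mesh_surface_area(_ball_mask(r), VS)
            errors.append(abs(sa / (4 * np.pi * (r * VS) ** 2) - 1))
        assert errors[0] > errors[1] > errors[2]

    def test_ellipsoid_principal_extents(self):
        spec = PhantomSpec(
            n_objects=1, shape=(80, 80, 80), length_sd=0.0, width_sd=0.0,
            random_orientation=False, seed=0,
        )
        truth = make_phantom(spec)
        rec = measure_geometry(
            _seg(truth.objects[0].cristae_mask, truth.objects[0].matrix_mask), None, VS
        )
        assert rec.length_um == pytest.approx(0.90, rel=0.05)
        assert rec.width_um == pytest.approx(0.63, rel=0.05)
        assert 0 < rec.aspect_ratio <= 1

    def test_rotated_object_same_extents(self):
        spec = PhantomSpec(
            n_objects=1, shape=(80, 80, 80), length_sd=0.0, width_sd=0.0,
            random_orientation=True, seed=12,
        )
        truth = make_phantom(spec)
        obj = truth.objects[0]
        rec = measure_geometry(_seg(obj.cristae_mask, obj.matrix_mask), None, VS)
        assert rec.length_um == pytest.approx(0.90, rel=0.05)
        assert rec.width_um == pytest.approx(0.63, rel=0.05)

    def test_tiny_compartment_flagged_unreliable(self):
        cristae = np.zeros((12, 12, 12), dtype=bool)
        cristae[4:8, 4:8, 4:8] = True
        matrix = np.zeros_like(cristae)
        matrix[5, 5, 5:8] = True  # 3 voxels
        rec = measure_geometry(_seg(cristae & ~matrix, matrix), None, VS)
        assert "unreliable_matrix" in rec.flags

    def test_volume_conservation_exact(self, fixture_suite):
        voxvol = fixture_suite.lac.voxel_volume
        for obj, seg in zip(fixture_suite.objects, fixture_suite.segmentations):
            rec = measure_object(seg, fixture_suite.lac, fixture_suite.lac.voxel_size)
            assert rec.volume_cristae_um3 + rec.volume_matrix_um3 == pytest.approx(
                rec.volume_total_um3, abs=1e-12
            )
            assert rec.volume_total_um3 == pytest.approx(obj.voxel_count * voxvol, abs=1e-12)
            assert rec.volfrac_cristae_pct + rec.volfrac_matrix_pct == pytest.approx(100.0)


class TestMciOnPhantoms:
    def test_mci_above_isoperimetric_floor(self, fixture_suite):
        floor = 9 / (4 * np.pi)
        for seg in fixture_suite.segmentations:
            rec = measure_object(seg, fixture_suite.lac, fixture_suite.lac.voxel_size)
            assert rec.mci > floor

    def test_mci_strictly_increases_with_cristae_count(self):
        mcis = []
        for nc in (0, 2, 4, 8):
            spec = PhantomSpec(
                n_objects=1, n_cristae=nc, shape=(80, 80, 80), length_sd=0.0,
                width_sd=0.0, random_orientation=False, seed=3,
            )
            truth = make_phantom(spec)
            t = truth.objects[0]
            seg = watershed_interior_split(t.cristae_mask, t.object_mask)
            rec = measure_object(seg, truth.lac_volume, VS)
            mcis.append(rec.mci)
        assert all(a < b for a, b in zip(mcis, mcis[1:]))


@pytest.fixture(scope="module")
def shell_seg():
    ax = np.arange(40) - 20
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = zz**2 + yy**2 + xx**2
    obj = r2 <= 14**2
    shell = obj & (r2 > 10**2)
    return _seg(shell, obj & ~shell)


class TestVirtualSlicing:

    def test_shell_matrix_fraction_peaks_centrally(self, shell_seg):
        prof = virtual_slicing(shell_seg, "length", VS)
        mf = prof.matrix_fraction
        assert mf[0] == 0.0 and mf[-1] == 0.0
        assert np.argmax(mf) == pytest.approx(len(mf) / 2, abs=2)
        assert "degenerate_axes_global_z" in prof.flags

    def test_fractions_sum_to_one_where_present(self, shell_seg):
        prof = virtual_slicing(shell_seg, "width", VS)
        np.testing.assert_allclose(prof.cristae_fraction + prof.matrix_fraction, 1.0, atol=1e-12)

    def test_no_matrix_gives_zero_fraction_everywhere(self):
        ball = _ball_mask(8)
        prof = virtual_slicing(_seg(ball), "length", VS)
        assert (prof.matrix_fraction == 0).all()

    def test_length_axis_spans_object_length(self):
        spec = PhantomSpec(
            n_objects=1, shape=(80, 80, 80), length_sd=0.0, width_sd=0.0,
            random_orientation=True, seed=5,
        )
        truth = make_phantom(spec)
        t = truth.objects[0]
        seg = _seg(t.cristae_mask, t.matrix_mask)
        prof_l = virtual_slicing(seg, "length", VS)
        prof_w = virtual_slicing(seg, "width", VS)
        span_l = prof_l.positions_um[-1] - prof_l.positions_um[0]
        span_w = prof_w.positions_um[-1] - prof_w.positions_um[0]
        assert span_l == pytest.approx(0.90, rel=0.08)
        assert span_w == pytest.approx(0.63, rel=0.08)

    def test_unknown_axis_rejected(self, shell_seg):
        with pytest.raises(ValueError):
            virtual_slicing(shell_seg, "depth", VS)
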