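import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bladnet.preprocess import (
    BrainVolume,
    PreprocessConfig,
    SliceStack,
    ValidationError,
    group_slices,
    load_groups_hdf5,
    load_volume,
    normalize_intensity,
    preprocess_volume,
    resample_volume,
    save_groups_hdf5,
    save_volume,
    trim_zero_slices,
)


def _vol(arr, spacing=(1.0, 1.0, 1.0), **kw):
    return BrainVolume(voxels=np.asarray(arr, dtype=float), spacing=spacing, **kw)


class TestBrainVolume:
    def test_rejects_negative_intensities(self):
        with pytest.raises(ValidationError, match="non-negative"):
            _vol(-np.ones((2, 2, 2)))

    def test_rejects_bad_spacing(self):
        with pytest.raises(ValidationError, match="spacing"):
            _vol(np.ones((2, 2, 2)), spacing=(1.0, 0.0, 1.0))


class TestIO:
    def test_raw_array_identity_readback(self, tmp_path):
        v = _vol(np.ones((4, 4, 4)), spacing=(2.0, 2.0, 2.0), study_id="fixture")
        p = save_volume(v, tmp_path / "fix.raw", format="raw_array")
        back = load_volume(p)
        assert back.voxels.size == 64
        np.testing.assert_array_equal(back.voxels, 1.0)
        assert back.spacing == (2.0, 2.0, 2.0)
        assert back.study_id == "fixture"

    def test_nifti_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        v = _vol(rng.random((5, 6, 7)).astype(np.float32), spacing=(1.5, 1.5, 2.0))
        p = save_volume(v, tmp_path / "v.nii.gz")
        back = load_volume(p)
        np.testing.assert_array_equal(back.voxels, v.voxels)
        assert back.spacing == pytest.approx(v.spacing)

    def test_truncated_file_is_io_error(self, tmp_path):
        v = _vol(np.ones((4, 4, 4)))
        p = save_volume(v, tmp_path / "t.raw", format="raw_array")
        p.write_bytes(p.read_bytes()[:100])
        with pytest.raises(IOError, match="t.raw"):
            load_volume(p)

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(IOError, match="nope.nii"):
            load_volume(tmp_path / "nope.nii")

    def test_missing_sidecar_is_io_error(self, tmp_path):
        p = tmp_path / "bare.raw"
        np.ones(8, dtype=np.float32).tofile(p)
        with pytest.raises(IOError, match="sidecar"):
            load_volume(p)


class TestResample:
    def test_constant_stays_constant(self):
        v = _vol(np.full((8, 8, 8), 3.5))
        out = resample_volume(v, (5, 11, 3))
        assert out.shape == (5, 11, 3)
        np.testing.assert_allclose(out.voxels, 3.5, rtol=1e-6)

    def test_identity_when_shape_matches(self):
        rng = np.random.default_rng(1)
        v = _vol(rng.random((6, 5, 4)))
        out = resample_volume(v, (6, 5, 4))
        np.testing.assert_array_equal(out.voxels, v.voxels)

    def test_linear_ramp_matches_analytic_interpolant(self):
        # values linear in z: trilinear interpolation is exact, so downsampled
        # values equal the ramp evaluated at the sample coordinates
        nz, tz = 9, 5
        ramp = np.broadcast_to(np.arange(nz, dtype=float), (4, 4, nz)).copy()
        out = resample_volume(_vol(ramp), (4, 4, tz))
        expected = np.linspace(0.0, nz - 1.0, tz)
        np.testing.assert_allclose(out.voxels[2, 2], expected, atol=1e-12)

    def test_spacing_preserves_physical_extent(self):
        v = _vol(np.ones((8, 8, 8)), spacing=(2.0, 2.0, 2.0))
        out = resample_volume(v, (4, 4, 16))
        assert out.spacing == pytest.approx((4.0, 4.0, 1.0))

    def test_no_overshoot_on_monotone_ramp(self):
        ramp = np.broadcast_to(np.arange(10, dtype=float), (3, 3, 10)).copy()
        out = resample_volume(_vol(ramp), (3, 3, 7))
        assert out.voxels.min() >= 0.0
        assert out.voxels.max() <= 9.0

    def test_rejects_nonpositive_target(self):
        with pytest.raises(ValidationError):
            resample_volume(_vol(np.ones((3, 3, 3))), (3, 0, 3))


class TestNormalize:
    def test_minmax_affine_map(self):
        v = _vol(np.array([[[0.0, 5.0, 10.0]]]))
        out = normalize_intensity(v, "minmax")
        np.testing.assert_allclose(out.voxels, [[[0.0, 0.5, 1.0]]])

    def test_none_is_identity(self):
        v = _vol(np.random.default_rng(2).random((3, 3, 3)))
        assert normalize_intensity(v, "none") is v

    def test_constant_maps_to_zeros(self):
        out = normalize_intensity(_vol(np.full((2, 2, 2), 7.0)), "minmax")
        np.testing.assert_array_equal(out.voxels, 0.0)


class TestTrim:
    def _vol_with_zero_ends(self, n=96, lo=2, hi=2):
        arr = np.ones((4, 4, n))
        arr[:, :, :lo] = 0.0
        arr[:, :, n - hi :] = 0.0
        return _vol(arr)

    def test_trims_both_ends(self):
        stack = trim_zero_slices(self._vol_with_zero_ends())
        assert stack.n_slices == 92
        assert stack.source_range == (2, 94)

    def test_no_zero_slices_keeps_all(self):
        stack = trim_zero_slices(_vol(np.ones((4, 4, 10))))
        assert stack.source_range == (0, 10)

    def test_interior_zero_slice_is_kept(self):
        arr = np.ones((4, 4, 10))
        arr[:, :, 5] = 0.0
        stack = trim_zero_slices(_vol(arr))
        assert stack.n_slices == 10

    def test_all_zero_volume_errors(self):
        with pytest.raises(ValidationError, match="entirely zero"):
            trim_zero_slices(_vol(np.zeros((4, 4, 10))))

    def test_trim_idempotent(self):
        stack = trim_zero_slices(self._vol_with_zero_ends(20, 3, 1))
        again = trim_zero_slices(_vol(np.moveaxis(stack.slices, 0, 2)))
        assert again.source_range == (0, stack.n_slices)
        np.testing.assert_array_equal(again.slices, stack.slices)


class TestGrouping:
    def _stack(self, n):
        sl = np.arange(n, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        return SliceStack(slices=sl, source_range=(0, n))

    def test_92_slices_give_four_groups_of_23(self):
        gs = group_slices(self._stack(92), 4)
        assert gs.n_groups == 4
        assert all(g.n_slices == 23 for g in gs.groups)

    def test_interleaved_stride_assignment(self):
        gs = group_slices(self._stack(8), 4)
        got = [list(g.slices[:, 0, 0].astype(int)) for g in gs.groups]
        assert got == [[0, 4], [1, 5], [2, 6], [3, 7]]

    def test_truncation_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            gs = group_slices(self._stack(10), 4)
        assert all(g.n_slices == 2 for g in gs.groups)
        assert 8 not in gs.assignment and 9 not in gs.assignment
        assert any("dropping" in r.message for r in caplog.records)

    def test_contiguous_blocks(self):
        gs = group_slices(self._stack(8), 4, grouping="contiguous")
        got = [list(g.slices[:, 0, 0].astype(int)) for g in gs.groups]
        assert got == [[0, 1], [2, 3], [4, 5], [6, 7]]

    def test_too_few_slices_errors(self):
        with pytest.raises(ValidationError):
            group_slices(self._stack(3), 4)

    @settings(derandomize=True, max_examples=40)
    @given(n=st.integers(4, 60), k=st.integers(1, 6), interleaved=st.booleans())
    def test_groups_partition_retained_slices(self, n, k, interleaved):
        if n < k:
            return
        gs = group_slices(self._stack(n), k, "interleaved" if interleaved else "contiguous")
        kept = (n // k) * k
        assert sorted(gs.assignment) == list(range(kept))
        sizes = [g.n_slices for g in gs.groups]
        assert len(set(sizes)) == 1 and sum(sizes) == kept
        # each retained slice appears in exactly one group
        seen = np.concatenate([g.slices[:, 0, 0] for g in gs.groups])
        assert sorted(seen.astype(int)) == list(range(kept))


class TestPipeline:
    def _phantom_like(self):
        rng = np.random.default_rng(3)
        arr = rng.random((20, 20, 16)) + 0.1
        arr[:, :, :2] = 0.0
        arr[:, :, 14:] = 0.0
        return _vol(arr)

    def test_composition_matches_stepwise(self):
        v = self._phantom_like()
        cfg = PreprocessConfig(shape=(12, 12, 16))
        direct = preprocess_volume(v, cfg)
        stepwise = group_slices(
            trim_zero_slices(normalize_intensity(resample_volume(v, cfg.shape), cfg.normalize)),
            cfg.n_groups,
            cfg.grouping,
        )
        for a, b in zip(direct.groups, stepwise.groups):
            np.testing.assert_array_equal(a.slices, b.slices)

    def test_deterministic(self):
        v = self._phantom_like()
        cfg = PreprocessConfig(shape=(12, 12, 16))
        a = preprocess_volume(v, cfg).as_array()
        b = preprocess_volume(v, cfg).as_array()
        np.testing.assert_array_equal(a, b)

    def test_all_zero_volume_propagates_error(self):
        with pytest.raises(ValidationError):
            preprocess_volume(_vol(np.zeros((8, 8, 8))), PreprocessConfig(shape=(8, 8, 8)))

    def test_hdf5_round_trip(self, tmp_path):
        gs = preprocess_volume(self._phantom_like(), PreprocessConfig(shape=(12, 12, 16)))
        p = save_groups_hdf5(gs, tmp_path / "g.h5", study_id="s1")
        back = load_groups_hdf5(p)
        assert back.n_groups == gs.n_groups
        assert back.assignment == gs.assignment
        for a, b in zip(back.groups, gs.groups):
            np.testing.assert_array_equal(a.slices, b.slices)
            assert a.source_range == b.source_range and a.stride == b.stride
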