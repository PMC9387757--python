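"""Volume model, NIfTI round-trips, affine algebra and resampling."""

import nibabel as nib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ielec import (
    AffineTransform,
    Volume3D,
    compose,
    invert,
    read_volume,
    resample,
    voxel_to_world,
    world_to_voxel,
    write_volume,
)
from ielec.errors import DimensionError, FrameError, KindError


def random_affine(rng):
    """Random well-conditioned voxel->world affine."""
    A = np.eye(4)
    A[:3, :3] = rng.normal(scale=0.3, size=(3, 3)) + np.diag(rng.uniform(0.8, 2.0, 3))
    A[:3, 3] = rng.uniform(-20, 20, 3)
    if abs(np.linalg.det(A[:3, :3])) < 0.1:
        A[:3, :3] += np.eye(3)
    return A


class TestVolume3D:
    def test_rejects_non_3d_data(self):
        with pytest.raises(DimensionError):
            Volume3D(np.zeros((4, 4)), np.eye(4), frame="ct")
        with pytest.raises(DimensionError):
            Volume3D(np.zeros((4, 4, 4, 2)), np.eye(4), frame="ct")

    def test_rejects_singular_affine(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        with pytest.raises(ValueError):
            Volume3D(np.zeros((4, 4, 4)), aff, frame="ct")

    def test_label_kind_requires_nonnegative_integers(self):
        with pytest.raises(KindError):
            Volume3D(np.full((4, 4, 4), 0.5), np.eye(4), frame="mr_subject", kind="label")
        with pytest.raises(KindError):
            Volume3D(np.full((4, 4, 4), -1), np.eye(4), frame="mr_subject", kind="label")
        vol = Volume3D(np.ones((4, 4, 4)), np.eye(4), frame="mr_subject", kind="label")
        assert np.issubdtype(vol.data.dtype, np.integer)


class TestAffineTransform:
    def test_bottom_row_enforced(self):
        bad = np.eye(4)
        bad[3, 0] = 0.1
        with pytest.raises(ValueError):
            AffineTransform(bad, "ct", "mr_subject")

    def test_invert_swaps_frames_and_composes_to_identity(self, rng):
        tf = AffineTransform(random_affine(rng), "ct", "mr_subject")
        inv = invert(tf)
        assert (inv.source, inv.target) == ("mr_subject", "ct")
        ident = compose(tf, inv)
        assert np.allclose(ident.matrix, np.eye(4), atol=1e-12)

    def test_compose_is_associative(self, rng):
        a = AffineTransform(random_affine(rng), "b", "c")
        b = AffineTransform(random_affine(rng), "a", "b")
        c = AffineTransform(random_affine(rng), "z", "a")
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        assert np.allclose(left.matrix, right.matrix, atol=1e-9)
        assert np.allclose(left.matrix, a.matrix @ b.matrix @ c.matrix)

    def test_compose_frame_mismatch(self, rng):
        a = AffineTransform(random_affine(rng), "ct", "mr_subject")
        with pytest.raises(FrameError):
            compose(a, a)


class TestCoordinateMaps:
    def test_identity_affine_is_identity_map(self):
        vol = Volume3D(np.zeros((8, 8, 8)), np.eye(4), frame="ct")
        assert np.allclose(voxel_to_world(vol, [3, 4, 5]), [3, 4, 5])
        assert np.allclose(world_to_voxel(vol, [3, 4, 5]), [3, 4, 5])

    def test_scaling_with_translation_hand_computed(self):
        aff = np.diag([2.0, 2.0, 2.0, 1.0])
        aff[:3, 3] = -10
        vol = Volume3D(np.zeros((8, 8, 8)), aff, frame="ct")
        assert np.allclose(voxel_to_world(vol, [5, 5, 5]), [0, 0, 0])

    def test_voxel_world_round_trip_random_affines(self, rng):
        for _ in range(20):
            vol = Volume3D(np.zeros((4, 4, 4)), random_affine(rng), frame="ct")
            pts = rng.uniform(-50, 50, (10, 3))
            assert np.allclose(world_to_voxel(vol, voxel_to_world(vol, pts)), pts, atol=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        pt=st.lists(st.floats(-100, 100, allow_nan=False), min_size=3, max_size=3),
    )
    def test_round_trip_property(self, seed, pt):
        vol = Volume3D(np.zeros((4, 4, 4)),
                       random_affine(np.random.default_rng(seed)), frame="ct")
        back = world_to_voxel(vol, voxel_to_world(vol, np.array(pt)))
        assert np.allclose(back, pt, atol=1e-8)


class TestNiftiIO:
    def test_scalar_round_trip(self, small_volume, tmp_path):
        path = tmp_path / "vol.nii.gz"
        write_volume(small_volume, path)
        back = read_volume(path, frame="mr_subject")
        assert np.allclose(back.affine, small_volume.affine, atol=1e-5)
        assert np.max(np.abs(back.data - small_volume.data)) < 1e-5

    def test_label_round_trip_exact(self, tmp_path, rng):
        vol = Volume3D(rng.integers(0, 50, (9, 7, 5)), np.eye(4),
                       frame="mr_subject", kind="label")
        path = tmp_path / "seg.nii"
        write_volume(vol, path)
        back = read_volume(path, frame="mr_subject", kind="label")
        assert np.array_equal(back.data, vol.data)

    def test_qform_used_when_sform_code_zero(self, tmp_path, rng):
        # construct the two-header fixture with nibabel directly
        data = rng.normal(size=(5, 5, 5)).astype(np.float32)
        qform = np.diag([2.0, 2.0, 2.0, 1.0])
        qform[:3, 3] = [1, 2, 3]
        hdr = nib.Nifti1Header()
        hdr.set_data_shape(data.shape)
        hdr.set_data_dtype(np.float32)
        hdr.set_qform(qform, code=1)
        hdr.set_sform(None, code=0)
        img = nib.Nifti1Image(data, None, header=hdr)
        path = tmp_path / "qform.nii"
        nib.save(img, path)
        back = read_volume(path, frame="ct")
        assert np.allclose(back.affine, qform, atol=1e-5)

    def test_4d_file_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32), np.eye(4))
        path = tmp_path / "bold.nii"
        nib.save(img, path)
        with pytest.raises(DimensionError, match="4"):
            read_volume(path, frame="ct")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz", frame="ct")

    def test_write_to_missing_directory(self, small_volume, tmp_path):
        with pytest.raises(Exception):
            write_volume(small_volume, tmp_path / "nodir" / "x.nii")


class TestResample:
    def test_identity_map_identity_grids(self, small_volume):
        tf = AffineTransform.identity("mr_subject")
        out = resample(small_volume, small_volume, tf)
        assert np.allclose(out.data, small_volume.data, atol=1e-12)

    def test_integer_translation_matches_roll_oracle(self, rng):
        data = rng.normal(size=(12, 12, 12))
        vol = Volume3D(data, np.eye(4), frame="ct")
        tgt = Volume3D(np.zeros_like(data), np.eye(4), frame="mr_subject")
        shift = np.array([2.0, -1.0, 3.0])
        M = np.eye(4)
        M[:3, 3] = shift
        out = resample(vol, tgt, AffineTransform(M, "ct", "mr_subject"), interp="nearest")
        rolled = np.roll(data, (2, -1, 3), axis=(0, 1, 2))
        # compare away from wrapped borders
        sl = (slice(3, 10), slice(3, 10), slice(4, 10))
        assert np.array_equal(out.data[sl], rolled[sl])

    def test_label_resample_never_invents_labels(self, rng):
        data = rng.integers(0, 5, (10, 10, 10))
        vol = Volume3D(data, np.eye(4), frame="mr_subject", kind="label")
        tgt_aff = np.diag([0.7, 0.7, 0.7, 1.0])
        tgt = Volume3D(np.zeros((14, 14, 14)), tgt_aff, frame="mr_subject", kind="label")
        out = resample(vol, tgt, AffineTransform.identity("mr_subject"), interp="linear")
        assert set(np.unique(out.data)) <= set(np.unique(data)) | {0}
        assert out.kind == "label"

    def test_frame_mismatch_raises(self, small_volume):
        tf = AffineTransform.identity("ct")
        with pytest.raises(FrameError, match="ct"):
            resample(small_volume, small_volume, tf)
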