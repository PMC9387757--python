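"""Mutual information, affine registration, SDR fields and point warping.

The heavy ground-truth recovery runs (multi-seed rigid recovery, SDR field
recovery) live in the acceptance suite; here each path is exercised once
plus its cheap contracts and degenerate cases.
"""

import numpy as np
import pytest

from ielec import (
    AffineTransform,
    Volume3D,
    apply_point_registration,
    compare_linear_vs_sdr,
    compute_affine_registration,
    compute_sdr_registration,
    mutual_information,
)
from ielec.errors import DimensionError, KindError, OverlapError
from ielec.registration import DeformationField


@pytest.fixture(scope="module")
def textured_volume():
    rng = np.random.default_rng(5)
    data = np.zeros((32, 32, 32))
    idx = np.stack(np.meshgrid(*[np.arange(32)] * 3, indexing="ij"), axis=-1)
    for _ in range(15):
        c = rng.uniform(6, 26, 3)
        s = rng.uniform(2, 4)
        data += rng.uniform(0.3, 1.0) * np.exp(-0.5 * np.sum((idx - c) ** 2, -1) / s**2)
    return Volume3D(data, np.eye(4), frame="mr_subject")


class TestMutualInformation:
    def test_self_mi_equals_marginal_entropy(self, textured_volume):
        # independent oracle: entropy of the clipped histogram
        data = textured_volume.data
        lo, hi = np.percentile(data, [1, 99])
        edges = np.linspace(lo, hi, 33)
        ih = np.clip(np.searchsorted(edges, data.ravel(), side="right") - 1, 0, 31)
        p = np.bincount(ih, minlength=32).astype(float)
        p /= p.sum()
        entropy = -np.sum(p[p > 0] * np.log(p[p > 0]))
        assert mutual_information(textured_volume, textured_volume, 32) == pytest.approx(
            entropy, abs=1e-12
        )

    def test_constant_volume_zero_mi(self, textured_volume):
        const = Volume3D(np.ones_like(textured_volume.data), np.eye(4), frame="mr_subject")
        assert abs(mutual_information(textured_volume, const, 32)) <= 1e-12

    def test_symmetry(self, textured_volume, rng):
        other = Volume3D(rng.normal(size=textured_volume.shape), np.eye(4), frame="ct")
        a = mutual_information(textured_volume, other, 32)
        b = mutual_information(other, textured_volume, 32)
        assert abs(a - b) <= 1e-9

    def test_permutation_decreases_mi(self, textured_volume, rng):
        perm = textured_volume.data.ravel().copy()
        rng.shuffle(perm)
        shuffled = Volume3D(perm.reshape(textured_volume.shape), np.eye(4), frame="ct")
        self_mi = mutual_information(textured_volume, textured_volume, 32)
        assert mutual_information(textured_volume, shuffled, 32) < self_mi

    def test_shape_mismatch(self, textured_volume):
        small = Volume3D(np.zeros((4, 4, 4)), np.eye(4), frame="ct")
        with pytest.raises(DimensionError):
            mutual_information(textured_volume, small)


class TestAffineRegistration:
    def test_self_registration_is_identity(self, textured_volume):
        res = compute_affine_registration(
            textured_volume, textured_volume, stages=("translation", "rigid"),
            pyramid_factors=(2, 1), max_evals=100,
        )
        M = res.affine.matrix
        ang = np.degrees(np.arccos(np.clip((np.trace(M[:3, :3]) - 1) / 2, -1, 1)))
        assert ang <= 0.1
        assert np.linalg.norm(M[:3, 3] + (M[:3, :3] - np.eye(3)) @ np.full(3, 15.5)) <= 0.1

    def test_mi_trace_monotone_within_levels(self, textured_volume):
        res = compute_affine_registration(
            textured_volume, textured_volume, stages=("translation",),
            pyramid_factors=(2, 1), max_evals=50,
        )
        for level in {t[0] for t in res.mi_trace}:
            vals = [mi for lv, _, mi in res.mi_trace if lv == level]
            assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_label_volume_rejected(self, textured_volume):
        seg = Volume3D(np.zeros((32, 32, 32), dtype=np.int32), np.eye(4),
                       frame="mr_subject", kind="label")
        with pytest.raises(KindError):
            compute_affine_registration(seg, textured_volume)

    def test_disjoint_volumes_raise_overlap_error(self, textured_volume):
        far = AffineTransform(np.eye(4), "mr_subject", "mr_subject")
        shifted = np.eye(4)
        shifted[:3, 3] = 500.0
        moved = Volume3D(textured_volume.data, shifted, frame="mr_subject")
        with pytest.raises(OverlapError, match="pre-alignment"):
            compute_affine_registration(moved, textured_volume, initial=far)

    def test_rigid_recovery_and_covariance(self, bundle):
        """Recover the phantom misalignment; re-registering a pre-rotated copy
        recovers the composed transform (covariance under pre-composition)."""
        res = compute_affine_registration(bundle.ct, bundle.mr,
                                          stages=("translation", "rigid"))
        pts = np.array([c.position for c in bundle.montage_truth_ct.contacts])
        mapped, _ = apply_point_registration(pts, res)
        true = np.array([c.position for c in bundle.montage_truth.contacts])
        assert np.linalg.norm(mapped - true, axis=1).max() <= 1.0

        M = res.affine.matrix
        T = bundle.true_ct_to_mr.matrix
        R_err = M[:3, :3] @ np.linalg.inv(T[:3, :3])
        ang = np.degrees(np.arccos(np.clip((np.trace(R_err) - 1) / 2, -1, 1)))
        assert ang <= 1.0


class TestSDR:
    def test_self_registration_zero_field(self, textured_volume):
        fld = compute_sdr_registration(textured_volume, textured_volume,
                                       level_iters=(5, 5, 3))
        assert np.max(np.linalg.norm(fld.forward, axis=-1)) <= 0.1

    def test_label_volume_rejected(self, textured_volume):
        seg = Volume3D(np.zeros((32, 32, 32), dtype=np.int32), np.eye(4),
                       frame="mr_subject", kind="label")
        with pytest.raises(KindError):
            compute_sdr_registration(seg, textured_volume)


class TestApplyPoints:
    def test_identity_affine(self):
        tf = AffineTransform.identity("mr_subject", "mr_template")
        pts = np.array([[1.0, 2.0, 3.0]])
        out, outside = apply_point_registration(pts, tf)
        assert np.allclose(out, pts)
        assert not outside.any()

    def test_pure_translation(self):
        M = np.eye(4)
        M[0, 3] = 5.0
        tf = AffineTransform(M, "ct", "mr_subject")
        out, _ = apply_point_registration(np.zeros((1, 3)), tf)
        assert np.allclose(out, [[5, 0, 0]])

    def test_field_forward_backward_inverse(self, bundle, rng):
        fld = bundle.true_subject_to_template
        pts = rng.uniform(22, 42, (50, 3))
        fwd, _ = apply_point_registration(pts, fld, direction="forward")
        back, _ = apply_point_registration(fwd, fld, direction="backward")
        assert np.linalg.norm(back - pts, axis=1).mean() <= 0.2

    def test_point_outside_grid_flagged(self, bundle):
        fld = bundle.true_subject_to_template
        out, outside = apply_point_registration(np.array([[500.0, 0.0, 0.0]]), fld)
        assert outside.all()

    def test_nonfinite_points_rejected(self, bundle):
        with pytest.raises(ValueError):
            apply_point_registration(np.array([[np.nan, 0, 0]]),
                                     bundle.true_subject_to_template)


class TestCompareLinearVsSdr:
    def test_exact_linear_gives_zero_error(self, bundle):
        pts = np.array([c.position for c in bundle.montage_truth.contacts])
        identity_field = DeformationField(
            grid_affine=bundle.mr.affine,
            forward=np.zeros(bundle.mr.shape + (3,)),
            backward=np.zeros(bundle.mr.shape + (3,)),
            pre_affine=AffineTransform.identity("mr_subject", "mr_template"),
        )
        out = compare_linear_vs_sdr(
            pts,
            AffineTransform.identity("mr_subject", "mr_template"),
            identity_field,
            reference=pts,
        )
        assert out["linear_mean"] == pytest.approx(0.0, abs=1e-12)
        assert out["sdr_mean"] == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_lengths(self, bundle):
        with pytest.raises(DimensionError):
            compare_linear_vs_sdr(
                np.zeros((3, 3)),
                AffineTransform.identity("mr_subject", "mr_template"),
                bundle.true_subject_to_template,
                reference=np.zeros((4, 3)),
            )
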