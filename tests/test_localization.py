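"""Peak finding, snap-to-center region growth, montage and TSV round-trips."""

import numpy as np
import pytest

from ielec import (
    Contact,
    Montage,
    Volume3D,
    find_local_peak,
    mark_contact,
    read_electrodes_tsv,
    snap_to_center,
    write_electrodes_tsv,
)
from ielec.errors import BoundsError, FormatError, NameError_
from ielec.localization import _grow_region_bfs, _grow_region_fixed_point
from ielec.imagespace import voxel_to_world
from .conftest import jitter_ball


def gaussian_blob_volume(center, sigma=1.5, shape=(24, 24, 24), amplitude=10.0,
                         background=0.0, extra_centers=()):
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    data = np.full(shape, background, dtype=float)
    for c in (center, *extra_centers):
        d2 = np.sum((idx - np.asarray(c, float)) ** 2, axis=-1)
        data += amplitude * np.exp(-0.5 * d2 / sigma**2)
    return Volume3D(data, np.eye(4), frame="ct")


class TestFindLocalPeak:
    def test_single_bright_voxel(self):
        vol = Volume3D(np.zeros((16, 16, 16)), np.eye(4), frame="ct")
        vol.data[8, 9, 8] = 5.0
        assert np.array_equal(find_local_peak(vol, [8, 7, 8], radius=5.0), [8, 9, 8])

    def test_tie_broken_by_distance_to_seed(self):
        vol = Volume3D(np.zeros((16, 16, 16)), np.eye(4), frame="ct")
        vol.data[9, 8, 8] = 5.0   # 1 mm from seed
        vol.data[11, 8, 8] = 5.0  # 3 mm from seed
        assert np.array_equal(find_local_peak(vol, [8, 8, 8], radius=5.0), [9, 8, 8])

    def test_matches_exhaustive_ball_scan(self, rng):
        vol = Volume3D(rng.normal(size=(20, 20, 20)), np.eye(4), frame="ct")
        for _ in range(10):
            seed = rng.uniform(6, 13, 3)
            peak = find_local_peak(vol, seed, radius=4.0)
            # independent oracle: scan every voxel in the ball
            best = None
            for i in range(20):
                for j in range(20):
                    for k in range(20):
                        d = np.linalg.norm(np.array([i, j, k]) - seed)
                        if d <= 4.0:
                            key = (-vol.data[i, j, k], d, (i, j, k))
                            if best is None or key < best:
                                best = key
            assert tuple(peak) == best[2]

    def test_seed_outside_volume(self):
        vol = Volume3D(np.zeros((8, 8, 8)), np.eye(4), frame="ct")
        with pytest.raises(BoundsError):
            find_local_peak(vol, [40, 0, 0], radius=3.0)


class TestSnapToCenter:
    def test_recovers_gaussian_blob_center(self, rng):
        center = np.array([11.3, 12.6, 10.2])
        vol = gaussian_blob_volume(center)
        for seed in center + jitter_ball(rng, 8, 4.0):
            res = snap_to_center(vol, seed, radius=5.0)
            assert np.linalg.norm(res.center - center) < 0.2

    def test_idempotent(self, rng):
        center = np.array([11.3, 12.6, 10.2])
        vol = gaussian_blob_volume(center)
        res = snap_to_center(vol, center + [1.5, -1.0, 0.5], radius=5.0)
        res2 = snap_to_center(vol, res.center, radius=5.0)
        assert res2.moved_mm <= 0.05

    def test_region_excludes_second_blob(self):
        a = np.array([8.0, 12.0, 12.0])
        b = a + [8.0, 0.0, 0.0]
        vol = gaussian_blob_volume(a, extra_centers=[b])
        res = snap_to_center(vol, a + [1.0, 1.0, 0.0], radius=3.0, max_region_radius=5.0)
        assert np.linalg.norm(res.center - a) < 0.3
        region_world = voxel_to_world(vol, res.peak_voxel.astype(float))
        assert np.linalg.norm(region_world - b) > 5.0

    def test_seed_invariance_within_basin(self, rng):
        center = np.array([12.1, 11.7, 12.4])
        vol = gaussian_blob_volume(center)
        centers = [
            snap_to_center(vol, center + off, radius=5.0).center
            for off in jitter_ball(rng, 6, 4.0)
        ]
        spread = max(np.linalg.norm(c1 - c2) for c1 in centers for c2 in centers)
        assert spread <= 0.1

    def test_degenerate_flat_ball_centers_on_ball(self):
        vol = Volume3D(np.ones((16, 16, 16)), np.eye(4), frame="ct")
        res = snap_to_center(vol, [8, 8, 8], radius=3.0, max_region_radius=3.0)
        assert res.region_voxels > 1
        assert np.linalg.norm(res.center - [8, 8, 8]) < 0.5

    def test_shaft_recovery_on_phantom(self, bundle, rng):
        errs = []
        for name in bundle.seeg_names:
            truth = bundle.montage_truth_ct[name].position
            seed = truth + jitter_ball(rng, 1, 2.0)[0]
            res = snap_to_center(bundle.ct, seed, radius=2.5)
            errs.append(np.linalg.norm(res.center - truth))
        assert np.mean(errs) <= 0.3


class TestRegionOrderIndependence:
    def test_bfs_equals_fixed_point_on_random_volumes(self, rng):
        for _ in range(20):
            vol = Volume3D(rng.normal(size=(16, 16, 16)) ** 2, np.eye(4), frame="ct")
            seed = rng.uniform(5, 10, 3)
            peak = find_local_peak(vol, seed, radius=3.0)
            a = _grow_region_bfs(vol, peak, 0.25, 4.0)
            b = _grow_region_fixed_point(vol, peak, 0.25, 4.0)
            assert np.array_equal(a, b)


class TestMontage:
    def make(self):
        return Montage.from_names(["LPM1", "LPM2", "LPM9"], frame="ct")

    def test_mark_contact_locates(self):
        m = self.make()
        mark_contact(m, "LPM1", np.array([1.0, 2.0, 3.0]))
        assert m["LPM1"].status == "located"
        assert m.n_located == 1

    def test_unknown_name_suggests_near_matches(self):
        m = self.make()
        with pytest.raises(NameError_, match="LPM9"):
            mark_contact(m, "LPM99", np.array([0.0, 0.0, 0.0]))

    def test_remark_keeps_count(self):
        m = self.make()
        mark_contact(m, "LPM2", np.array([1.0, 1.0, 1.0]))
        mark_contact(m, "LPM2", np.array([2.0, 2.0, 2.0]))
        assert m.n_located == 1
        assert np.allclose(m["LPM2"].position, [2, 2, 2])

    def test_located_count_monotone(self, rng):
        m = self.make()
        counts = [m.n_located]
        for name in ("LPM1", "LPM2", "LPM1", "LPM9"):
            mark_contact(m, name, rng.normal(size=3))
            counts.append(m.n_located)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_duplicate_names_rejected(self):
        with pytest.raises(NameError_):
            Montage([Contact("A1"), Contact("A1")])


class TestElectrodesTsv:
    def test_round_trip_mixed(self, tmp_path):
        m = Montage(
            [
                Contact("LPM1", [1.2345, -2.5, 7.0], status="located"),
                Contact("LPM2"),
                Contact("G1", [0.001, 0.0, -0.001], status="located"),
            ]
        )
        path = tmp_path / "electrodes.tsv"
        write_electrodes_tsv(m, path)
        back = read_electrodes_tsv(path)
        assert back.names == m.names
        assert back["LPM2"].status == "unlocated"
        for name in ("LPM1", "G1"):
            assert np.allclose(back[name].position, m[name].position, atol=1e-3)

    def test_na_rows_unlocated(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("name\tx\ty\tz\nA1\tn/a\tn/a\tn/a\nA2\t1.0\t2.0\t3.0\n")
        m = read_electrodes_tsv(path)
        assert m["A1"].status == "unlocated"
        assert m["A2"].status == "located"

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("name\tx\ty\nA1\t1\t2\n")
        with pytest.raises(FormatError, match="z"):
            read_electrodes_tsv(path)
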