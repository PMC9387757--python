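"""Contact montages and the snap-to-center refinement on the CT volume.

A montage carries an ordered set of named contacts whose names come from a
predetermined channel-name list (as extracted from a recording file), which
eliminates naming mismatches between the recording and the localization.
Snapping refines a rough seed position to the intensity-weighted center of
mass of the voxels that decrease monotonically from the brightest voxel
near the seed — metal contacts are compact bright blobs in CT, so this
centers the position on the physical contact independent of where exactly
the seed landed.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import BoundsError, FormatError, NameError_, StateError
from .imagespace import Volume3D, voxel_to_world, world_to_voxel

__all__ = [
    "Contact",
    "Montage",
    "SnapResult",
    "find_local_peak",
    "snap_to_center",
    "mark_contact",
    "read_electrodes_tsv",
    "write_electrodes_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class Contact:
    name: str
    position: np.ndarray | None = None
    status: str = "unlocated"  # located | unlocated

    def __post_init__(self):
        if self.position is not None:
            self.position = np.asarray(self.position, dtype=float)
            if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
                raise ValueError(f"contact {self.name!r}: position must be a finite 3-vector")


@dataclass
class Montage:
    """Ordered, named electrode contacts in a tagged world frame (mm)."""

    contacts: list[Contact]
    frame: str = "mr_subject"
    allowed_names: tuple[str, ...] | None = None

    def __post_init__(self):
        names = [c.name for c in self.contacts]
        if len(set(names)) != len(names):
            raise NameError_("contact names must be unique")
        if self.allowed_names is None:
            self.allowed_names = tuple(names)
        for c in self.contacts:
            if c.status == "located" and c.name not in self.allowed_names:
                raise NameError_(f"located contact {c.name!r} not in allowed names")

    @classmethod
    def from_names(cls, names, frame: str = "mr_subject") -> "Montage":
        return cls([Contact(n) for n in names], frame=frame)

    def __len__(self) -> int:
        return len(self.contacts)

    def __getitem__(self, name: str) -> Contact:
        for c in self.contacts:
            if c.name == name:
                return c
        raise NameError_(f"no contact named {name!r}")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contacts]

    @property
    def n_located(self) -> int:
        return sum(c.status == "located" for c in self.contacts)

    def positions(self, names=None) -> np.ndarray:
        """(N, 3) positions of the selected (default: all located) contacts."""
        sel = self.contacts if names is None else [self[n] for n in names]
        out = []
        for c in sel:
            if c.status != "located":
                raise StateError(f"contact {c.name!r} is not located")
            out.append(c.position)
        return np.array(out, dtype=float).reshape(-1, 3)

    def copy(self) -> "Montage":
        return Montage(
            [replace(c, position=None if c.position is None else c.position.copy())
             for c in self.contacts],
            frame=self.frame,
            allowed_names=self.allowed_names,
        )


@dataclass
class SnapResult:
    """Outcome of snap_to_center: the refined contact position and its region."""

    center: np.ndarray
    peak_voxel: np.ndarray
    region_voxels: int
    region_mass: float
    moved_mm: float


def _ball_voxels(ct: Volume3D, center_mm: np.ndarray, radius: float):
    """Integer voxel indices whose centers lie within radius mm of center_mm."""
    vox_sizes = ct.voxel_sizes
    c_vox = world_to_voxel(ct, center_mm)
    half = np.ceil(radius / vox_sizes).astype(int) + 1
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.ceil(c_vox).astype(int) + half, np.array(ct.shape) - 1)
    if np.any(lo > hi):
        return np.empty((0, 3), dtype=int), np.empty((0,))
    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack(grids, axis=-1).reshape(-1, 3)
    centers = voxel_to_world(ct, idx.astype(float))
    dist = np.linalg.norm(centers - center_mm, axis=1)
    keep = dist <= radius
    return idx[keep], dist[keep]


def find_local_peak(ct: Volume3D, seed, radius: float = 5.0) -> np.ndarray:
    """Brightest voxel within ``radius`` mm of ``seed`` (world mm).

    Ties go to the voxel closest to the seed, then to the lexicographically
    smallest index, so the result is deterministic.
    """
    seed = np.asarray(seed, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    svox = world_to_voxel(ct, seed)
    if np.any(svox < -0.5) or np.any(svox > np.array(ct.shape) - 0.5):
        raise BoundsError(f"seed {seed} maps outside the volume grid")
    idx, dist = _ball_voxels(ct, seed, radius)
    if len(idx) == 0:
        raise BoundsError(f"no voxel centers within {radius} mm of seed {seed}")
    vals = ct.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], dist, -vals))
    return idx[order[0]].copy()


_NEIGHBORS26 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)],
    dtype=int,
)


def _region_candidates(ct: Volume3D, peak: np.ndarray, intensity_floor: float,
                       max_region_radius: float):
    """Candidate ball around the peak: bounding box arrays for region growth."""
    peak_mm = voxel_to_world(ct, peak.astype(float))
    idx, _ = _ball_voxels(ct, peak_mm, max_region_radius)
    peak_val = float(ct.data[tuple(peak)])
    vals = ct.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    ok = vals >= intensity_floor * peak_val
    return idx[ok], vals[ok]


def _grow_region_bfs(ct: Volume3D, peak: np.ndarray, intensity_floor: float,
                     max_region_radius: float) -> np.ndarray:
    """Monotone-descent region by breadth-first search from the peak.

    A voxel joins the region when reached from *any* already-admitted
    26-neighbor of intensity >= its own (and it passes the floor and radius
    gates), so the admitted set is the closure over descending paths and
    does not depend on traversal order.
    """
    cand_idx, _ = _region_candidates(ct, peak, intensity_floor, max_region_radius)
    cand = {tuple(v) for v in cand_idx}
    region = {tuple(peak)}
    queue = deque([tuple(peak)])
    data = ct.data
    while queue:
        v = queue.popleft()
        iv = float(data[v])
        for off in _NEIGHBORS26:
            n = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if n in region or n not in cand:
                continue
            if float(data[n]) <= iv:
                region.add(n)
                queue.append(n)
    return np.array(sorted(region), dtype=int)


def _grow_region_fixed_point(ct: Volume3D, peak: np.ndarray, intensity_floor: float,
                             max_region_radius: float) -> np.ndarray:
    """Same region as :func:`_grow_region_bfs`, by iteration to a fixed point.

    Each sweep admits every candidate voxel that has an admitted 26-neighbor
    of intensity >= its own, until no voxel changes. Kept as an independent
    formulation to check order-independence of the BFS.
    """
    cand_idx, _ = _region_candidates(ct, peak, intensity_floor, max_region_radius)
    lo = cand_idx.min(axis=0)
    hi = cand_idx.max(axis=0)
    shape = tuple(hi - lo + 1)
    cand = np.zeros(shape, dtype=bool)
    cand[tuple((cand_idx - lo).T)] = True
    sub = np.full(shape, -np.inf)
    sub[tuple((cand_idx - lo).T)] = ct.data[tuple(cand_idx.T)].astype(float)
    region = np.zeros(shape, dtype=bool)
    region[tuple(peak - lo)] = True
    footprint = np.ones((3, 3, 3), dtype=bool)
    while True:
        best_nb = ndimage.maximum_filter(
            np.where(region, sub, -np.inf), footprint=footprint, mode="constant", cval=-np.inf
        )
        # exclude self: a voxel not yet in the region contributes -inf anyway,
        # and one already in the region stays in.
        new = region | (cand & (best_nb >= sub) & np.isfinite(best_nb))
        if np.array_equal(new, region):
            break
        region = new
    out = np.argwhere(region) + lo
    return out[np.lexsort((out[:, 2], out[:, 1], out[:, 0]))]


def snap_to_center(
    ct: Volume3D,
    seed,
    radius: float = 5.0,
    intensity_floor: float = 0.25,
    max_region_radius: float = 5.0,
    _region_method: str = "bfs",
) -> SnapResult:
    """Refine a seed to the intensity-weighted center of a contact blob.

    Finds the brightest voxel within ``radius`` mm of the seed, grows the
    monotonically non-increasing 26-connected region around it (bounded
    below by ``intensity_floor`` x peak intensity and laterally by
    ``max_region_radius`` mm from the peak), and returns the
    intensity-weighted centroid of the region's voxel centers in world mm.
    Deterministic and idempotent for compact blobs.
    """
    seed = np.asarray(seed, dtype=float)
    peak = find_local_peak(ct, seed, radius)
    grow = _grow_region_bfs if _region_method == "bfs" else _grow_region_fixed_point
    region = grow(ct, peak, intensity_floor, max_region_radius)
    vals = ct.data[region[:, 0], region[:, 1], region[:, 2]].astype(float)
    centers = voxel_to_world(ct, region.astype(float))
    w = np.clip(vals, 0, None)
    if w.sum() <= 0:
        w = np.ones_like(vals)
    center = (centers * w[:, None]).sum(axis=0) / w.sum()
    return SnapResult(
        center=center,
        peak_voxel=peak,
        region_voxels=int(len(region)),
        region_mass=float(vals.sum()),
        moved_mm=float(np.linalg.norm(center - seed)),
    )


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def mark_contact(m: Montage, name: str, snap) -> Montage:
    """Set a contact's position (from a SnapResult or raw mm 3-vector).

    The name must be in the montage's predetermined list; unknown names
    raise with the nearest matches (edit distance <= 2) suggested.
    Remarking an already-located contact overwrites with a logged notice.
    """
    if name not in m.allowed_names:
        near = sorted(
            (n for n in m.allowed_names if _edit_distance(name, n) <= 2),
            key=lambda n: (_edit_distance(name, n), n),
        )
        hint = f"; did you mean {', '.join(near[:3])}?" if near else ""
        raise NameError_(f"unknown channel name {name!r}{hint}")
    pos = snap.center if isinstance(snap, SnapResult) else np.asarray(snap, dtype=float)
    contact = m[name]
    if contact.status == "located":
        logger.info("remarking contact %s: %s -> %s", name, contact.position, pos)
    contact.position = np.asarray(pos, dtype=float)
    contact.status = "located"
    return m


def read_electrodes_tsv(path, frame: str = "mr_subject") -> Montage:
    """Read a BIDS-iEEG style electrodes.tsv (columns name, x, y, z in mm)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("name", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"electrodes file {path} missing column(s): {', '.join(missing)}")
    contacts = []
    for _, row in df.iterrows():
        coords = [row["x"], row["y"], row["z"]]
        if any(v.strip().lower() in ("n/a", "nan", "") for v in coords):
            contacts.append(Contact(row["name"]))
        else:
            contacts.append(Contact(row["name"], position=[float(v) for v in coords],
                                    status="located"))
    return Montage(contacts, frame=frame)


def write_electrodes_tsv(m: Montage, path) -> None:
    """Write a montage as tab-separated name/x/y/z; unlocated rows get n/a."""
    rows = []
    for c in m.contacts:
        if c.status == "located":
            rows.append([c.name] + [f"{v:.3f}" for v in c.position])
        else:
            rows.append([c.name, "n/a", "n/a", "n/a"])
    pd.DataFrame(rows, columns=["name", "x", "y", "z"]).to_csv(path, sep="\t", index=False)
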