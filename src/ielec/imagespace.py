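"""Volumes, coordinate frames, affine algebra, NIfTI I/O and resampling.

Conventions
-----------
Voxel indices are 0-based and continuous (a voxel's center is at integer
index). World coordinates are scanner RAS in millimetres, as given by the
NIfTI affine; no reorientation is ever applied. Frames are tagged with one
of ``"ct"``, ``"mr_subject"``, ``"mr_template"`` (arbitrary tags are
accepted — the tags exist so that mixing frames is an error, not a silent
bug). An optional per-volume ``c_ras`` offset supports FreeSurfer-style
surface coordinates; it defaults to zero and all synthetic data uses zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DimensionError, FrameError, KindError

__all__ = [
    "Volume3D",
    "AffineTransform",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "resample",
    "compose",
    "invert",
]

FRAME_CT = "ct"
FRAME_MR = "mr_subject"
FRAME_TEMPLATE = "mr_template"


@dataclass
class Volume3D:
    """A 3D scalar or integer-label image grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (I, J, K)
        Intensities (arbitrary units) or non-negative integer labels.
    affine : ndarray, shape (4, 4)
        Maps homogeneous 0-based voxel indices to world mm (scanner RAS).
    frame : str
        Coordinate-frame tag, e.g. ``"ct"`` or ``"mr_subject"``.
    kind : {"scalar", "label"}
    c_ras : ndarray, shape (3,), optional
        Offset added when converting FreeSurfer surface coordinates to
        scanner RAS. Zero for all data generated by this package.
    """

    data: np.ndarray
    affine: np.ndarray
    frame: str
    kind: str = "scalar"
    c_ras: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.c_ras = np.asarray(self.c_ras, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionError(
                f"volume data must be 3D with non-empty axes, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise DimensionError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) <= 0.0:
            raise ValueError("volume affine is singular")
        if self.kind not in ("scalar", "label"):
            raise KindError(f"kind must be 'scalar' or 'label', got {self.kind!r}")
        if self.kind == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.array_equal(self.data, np.round(self.data)):
                    raise KindError("label volume contains non-integer values")
                self.data = self.data.astype(np.int32)
            if self.data.min() < 0:
                raise KindError("label volume contains negative ids")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Edge lengths of a voxel in mm along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class AffineTransform:
    """Invertible 4x4 homogeneous world-to-world map between tagged frames."""

    matrix: np.ndarray
    source: str
    target: str

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise DimensionError(f"transform matrix must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("bottom row of an affine transform must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) <= 0.0:
            raise ValueError("affine transform is singular")

    @classmethod
    def identity(cls, source: str, target: str | None = None) -> "AffineTransform":
        return cls(np.eye(4), source, target if target is not None else source)

    def invert(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.target, self.source)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) or (3,) array of world-mm points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_dict(self) -> dict:
        return {
            "matrix": [float(v) for v in self.matrix.ravel()],
            "source": self.source,
            "target": self.target,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.array(d["matrix"], dtype=float).reshape(4, 4), d["source"], d["target"])


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Return ``a ∘ b``: first apply ``b``, then ``a``. Requires a.source == b.target."""
    if a.source != b.target:
        raise FrameError(
            f"cannot compose: left transform source {a.source!r} != right target {b.target!r}"
        )
    return AffineTransform(a.matrix @ b.matrix, b.source, a.target)


def invert(a: AffineTransform) -> AffineTransform:
    return a.invert()


def read_volume(path, frame: str, kind: str = "scalar") -> Volume3D:
    """Read a NIfTI-1 file (optionally gzipped) as a :class:`Volume3D`.

    The affine is taken from the header's best available transform: sform
    when its code is valid, else qform, else the fallback base affine.
    Data axis order matches the on-disk voxel order; no reorientation.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionError(
            f"expected a 3D volume, got shape {data.shape} from {path}"
        )
    affine = img.header.get_best_affine()
    if kind == "label":
        data = np.asarray(np.round(data), dtype=np.int32)
    return Volume3D(data=data, affine=affine, frame=frame, kind=kind)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as NIfTI-1; integer data round-trips exactly, scalars as float32."""
    if vol.kind == "label":
        data = np.asarray(vol.data, dtype=np.int32)
    else:
        data = np.asarray(vol.data, dtype=np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_sform(vol.affine, code=1)
    img.header.set_qform(vol.affine, code=1)
    nib.save(img, str(path))


def voxel_to_world(vol: Volume3D, idx) -> np.ndarray:
    """Map continuous voxel indices to world mm via the volume affine."""
    arr = np.asarray(idx, dtype=float)
    out = np.atleast_2d(arr) @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if arr.ndim == 1 else out


def world_to_voxel(vol: Volume3D, xyz) -> np.ndarray:
    """Map world mm to continuous voxel indices (exact inverse of voxel_to_world)."""
    inv = np.linalg.inv(vol.affine)
    arr = np.asarray(xyz, dtype=float)
    out = np.atleast_2d(arr) @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if arr.ndim == 1 else out


def resample(
    moving: Volume3D,
    target: Volume3D,
    world_map: AffineTransform,
    interp: str = "linear",
) -> Volume3D:
    """Resample ``moving`` onto ``target``'s grid through a world-to-world map.

    Each target voxel v samples the moving image at
    ``world_to_voxel(moving, world_map^-1 · voxel_to_world(target, v))``.
    Out-of-bounds samples fill with 0 (air). Label volumes always use
    nearest-neighbour interpolation, so no new label ids can appear.
    """
    if world_map.source != moving.frame or world_map.target != target.frame:
        raise FrameError(
            f"world_map maps {world_map.source!r}->{world_map.target!r} but volumes are "
            f"moving={moving.frame!r}, target={target.frame!r}"
        )
    if moving.kind == "label":
        interp = "nearest"
    # target index -> moving index, as a single affine
    full = np.linalg.inv(moving.affine) @ np.linalg.inv(world_map.matrix) @ target.affine
    if (moving.shape == target.shape
            and np.allclose(full, np.eye(4), atol=1e-12)):
        # exact identity on the same grid: skip interpolation entirely
        return Volume3D(data=moving.data.copy(), affine=target.affine.copy(),
                        frame=target.frame, kind=moving.kind)
    order = 0 if interp == "nearest" else 1
    out = ndimage.affine_transform(
        np.asarray(moving.data, dtype=float if order else moving.data.dtype),
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=target.shape,
        order=order,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    if moving.kind == "label":
        out = np.asarray(out, dtype=moving.data.dtype)
    return Volume3D(data=out, affine=target.affine.copy(), frame=target.frame, kind=moving.kind)
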