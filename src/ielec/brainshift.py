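"""Brain-shift compensation: project ECoG contacts onto the leptomeningeal surface.

During a craniotomy the pressure change lets the brain sag, so grid and
strip contacts localized in the post-operative CT sit *inside* the
pre-operative pial surface. The standard correction moves each surface
contact to the nearest point on the leptomeningeal surface — the smoothed
envelope of the pial surface that bridges over sulci — restoring the
positions the grid occupied on the intact cortex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, FormatError, StateError, TopologyError
from .localization import Montage

__all__ = [
    "SurfaceMesh",
    "read_off",
    "write_off",
    "smooth_to_leptomeningeal",
    "nearest_point_on_mesh",
    "project_sensors_onto_brain",
]

logger = logging.getLogger(__name__)


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (V, 3) in mm, triangles (T, 3) indices."""

    vertices: np.ndarray
    triangles: np.ndarray
    frame: str = "mr_subject"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise DimensionError(f"vertices must be (V, 3), got {self.vertices.shape}")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise DimensionError(f"triangles must be (T, 3), got {self.triangles.shape}")
        if self.triangles.min(initial=0) < 0 or self.triangles.max(initial=-1) >= len(self.vertices):
            raise DimensionError("triangle indices out of vertex range")

    @property
    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def signed_volume(self) -> float:
        """Enclosed volume (positive for outward-oriented closed meshes)."""
        p = self.vertices[self.triangles]
        return float(np.sum(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])))) / 6.0

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two triangles."""
        edges = np.sort(
            np.concatenate([self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
                            self.triangles[:, [2, 0]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def read_off(path, frame: str = "mr_subject") -> SurfaceMesh:
    """Read an ASCII OFF mesh."""
    with open(path) as fh:
        tokens = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise FormatError(f"{path}: not an OFF file (missing OFF header)")
    nv, nt = int(tokens[1]), int(tokens[2])
    pos = 4  # skip edge count
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nt):
        k = int(tokens[pos])
        if k != 3:
            raise FormatError(f"{path}: only triangle faces supported, got {k}-gon")
        tris.append([int(t) for t in tokens[pos + 1:pos + 4]])
        pos += 1 + k
    return SurfaceMesh(verts, np.array(tris, dtype=int), frame=frame)


def write_off(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(mesh.vertices)} {len(mesh.triangles)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _vertex_adjacency(mesh: SurfaceMesh):
    V = len(mesh.vertices)
    nbrs = [set() for _ in range(V)]
    for a, b, c in mesh.triangles:
        nbrs[a].update((b, c))
        nbrs[b].update((a, c))
        nbrs[c].update((a, b))
    return nbrs


def smooth_to_leptomeningeal(
    pial: SurfaceMesh, iterations: int = 20, relaxation: float = 0.5
) -> SurfaceMesh:
    """Smooth a closed pial mesh into a leptomeningeal envelope.

    Iterative Laplacian smoothing with a non-shrinking constraint: after
    each relaxation step every vertex's radial distance from the surface
    centroid is clamped to at least its original value, so sulcal dents
    fill outward while gyral crowns stay put. On a star-shaped surface
    (any head-like mesh) this yields an envelope that encloses the input
    and changes the enclosed volume only by the (small) sulcal volume.
    """
    if not pial.is_closed():
        raise TopologyError("leptomeningeal smoothing requires a closed mesh")
    centroid = pial.vertices.mean(axis=0)
    rel = pial.vertices - centroid
    orig_r = np.linalg.norm(rel, axis=1)
    rhat = rel / np.maximum(orig_r, 1e-12)[:, None]
    nbrs = _vertex_adjacency(pial)
    nbr_idx = [np.array(sorted(s), dtype=int) for s in nbrs]
    # Smooth the radius as a scalar field on the mesh graph instead of
    # moving vertices through space: a full Laplacian step would shrink any
    # curved surface (the mean-curvature pull exceeds the sulcal signal),
    # whereas radius smoothing is exactly neutral on a sphere. The clamp to
    # the original radius makes the flow fill sulci without ever sinking
    # below the input surface.
    r = orig_r.copy()
    for _ in range(iterations):
        mean_r = np.array([r[idx].mean() for idx in nbr_idx])
        r = np.maximum(r + relaxation * (mean_r - r), orig_r)
    verts = centroid + rhat * r[:, None]
    return SurfaceMesh(verts, pial.triangles.copy(), frame=pial.frame)


def _closest_points_on_triangles(p: np.ndarray, tri_pts: np.ndarray) -> np.ndarray:
    """Closest point to ``p`` (3,) on each triangle in ``tri_pts`` (T, 3, 3).

    Vectorized barycentric region classification (Ericson's algorithm):
    the closest point is the projection onto the triangle plane clamped to
    the triangle, with vertex/edge/face cases handled exactly.
    """
    a, b, c = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d1 / (d1 - d3)
    out[m] = a[m] + v[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    with np.errstate(invalid="ignore", divide="ignore"):
        w = d2 / (d2 - d6)
    out[m] = a[m] + w[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)  # edge bc
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # face interior
    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def nearest_point_on_mesh(p, surface: SurfaceMesh):
    """Exact closest point on the mesh to a point (mm).

    Scans all triangles (vectorized); ties report the lowest triangle id.

    Returns
    -------
    (point, triangle_id, distance)
    """
    p = np.asarray(p, dtype=float)
    tri_pts = surface.vertices[surface.triangles]
    cand = _closest_points_on_triangles(p, tri_pts)
    d = np.linalg.norm(cand - p, axis=1)
    tid = int(np.argmin(d))  # argmin returns the first (lowest) index on ties
    return cand[tid].copy(), tid, float(d[tid])


def project_sensors_onto_brain(
    m: Montage, surface: SurfaceMesh, channels=None
) -> Montage:
    """Move the selected contacts to the nearest point on the surface mesh.

    ``channels`` defaults to every located contact. Unselected contacts are
    untouched. Per-contact shift distances are logged; pairs of projected
    contacts ending up closer than 1 mm trigger a warning (no collision
    resolution is attempted).
    """
    if not surface.is_closed():
        raise TopologyError("projection requires a closed surface mesh")
    if surface.signed_volume() <= 0:
        raise TopologyError("projection requires an outward-oriented surface mesh")
    out = m.copy()
    if channels is None:
        channels = [c.name for c in m.contacts if c.status == "located"]
    projected = []
    for name in channels:
        c = out[name]
        if c.status != "located":
            raise StateError(f"cannot project unlocated contact {name!r}")
        point, tid, dist = nearest_point_on_mesh(c.position, surface)
        logger.info("projected %s by %.3f mm (triangle %d)", name, dist, tid)
        c.position = point
        projected.append((name, point))
    for i in range(len(projected)):
        for j in range(i + 1, len(projected)):
            d = np.linalg.norm(projected[i][1] - projected[j][1])
            if d < 1.0:
                logger.warning(
                    "projected contacts %s and %s are %.2f mm apart",
                    projected[i][0], projected[j][0], d,
                )
    return out
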