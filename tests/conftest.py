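import numpy as np
import pytest

from ielec import Volume3D
from ielec.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def bundle():
    """Default phantom, shared by read-only tests across the whole session."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_volume():
    """16³ scalar volume with a non-trivial affine, for I/O and algebra tests."""
    r = np.random.default_rng(0)
    affine = np.array([
        [0.9, 0.1, 0.0, -12.0],
        [-0.1, 1.1, 0.0, 4.0],
        [0.0, 0.0, 1.3, 7.5],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return Volume3D(r.normal(size=(16, 16, 16)), affine, frame="mr_subject")


def jitter_ball(rng, n, radius):
    """n uniform random offsets with |offset| <= radius (direction uniform)."""
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return u * rng.uniform(0, radius, n)[:, None]


def oracle_point_mesh_distance(p, vertices, triangles):
    """Independent closest-point-on-mesh distance oracle.

    Enumerates candidate closest points per triangle from first principles —
    the orthogonal foot on the triangle plane (kept only when its
    barycentric coordinates are all non-negative) and the clamped
    projections onto the three edge segments (which cover the vertex
    cases) — and minimizes over all triangles. A deliberately different
    derivation from the region-classification algorithm in the package.
    """
    p = np.asarray(p, dtype=float)
    tri = vertices[triangles]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    best = np.full(len(tri), np.inf)
    # plane foot via barycentric solve
    ab, ac, ap = b - a, c - a, p - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    dist_plane = np.einsum("ij,ij->i", ap, n) / np.sqrt(np.maximum(nn, 1e-300))
    q = p - dist_plane[:, None] * n / np.sqrt(np.maximum(nn, 1e-300))[:, None]
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    qa = q - a
    d20 = np.einsum("ij,ij->i", qa, ab)
    d21 = np.einsum("ij,ij->i", qa, ac)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / np.maximum(denom, 1e-300)
    w = (d00 * d21 - d01 * d20) / np.maximum(denom, 1e-300)
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    best[inside] = np.linalg.norm(p - q[inside], axis=1)
    # clamped edge projections
    for u0, u1 in ((a, b), (b, c), (c, a)):
        e = u1 - u0
        t = np.clip(np.einsum("ij,ij->i", p - u0, e)
                    / np.maximum(np.einsum("ij,ij->i", e, e), 1e-300), 0.0, 1.0)
        foot = u0 + t[:, None] * e
        best = np.minimum(best, np.linalg.norm(p - foot, axis=1))
    return float(best.min())
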