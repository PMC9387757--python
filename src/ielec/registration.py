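"""CT→MR affine registration by mutual information and subject→template SDR.

The affine stage maximizes the mutual information (MI) of the joint
intensity histogram over a coarse-to-fine pyramid with a derivative-free
(Powell) optimizer — the standard approach for cross-modality alignment,
where CT bone is bright and MR bone is dark so no intensity identity holds.
The nonlinear stage is a greedy symmetric demons scheme producing a pair of
mutually inverse dense displacement fields (a symmetric diffeomorphic
registration in the practical sense: smooth forward/backward fields whose
composition is the identity to well under a voxel). Template warping is
MR→MR, so a sum-of-squared-differences force on percentile-normalized
intensities suffices.

All displacements are stored in millimetres on the fixed grid, so point
warping is independent of the grid the field was estimated on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .errors import DimensionError, KindError, OverlapError
from .imagespace import AffineTransform, Volume3D, resample

__all__ = [
    "RegistrationResult",
    "DeformationField",
    "mutual_information",
    "compute_affine_registration",
    "compute_sdr_registration",
    "apply_point_registration",
    "compare_linear_vs_sdr",
]

logger = logging.getLogger(__name__)

_STAGE_NPARAMS = {"translation": 3, "rigid": 6, "affine": 12}


@dataclass
class RegistrationResult:
    """Outcome of an affine registration.

    Attributes
    ----------
    affine : AffineTransform
        Moving-world → fixed-world map maximizing MI.
    mi_trace : list of (level, iteration, mi)
        Accepted (improving) MI values per pyramid level, in nats.
    converged : list of bool
        Whether the optimizer converged within its evaluation budget at
        each pyramid level.
    """

    affine: AffineTransform
    mi_trace: list = dc_field(default_factory=list)
    converged: list = dc_field(default_factory=list)


@dataclass
class DeformationField:
    """Dense invertible displacement field on the fixed grid.

    ``forward`` carries a fixed-space point x to the affine-aligned moving
    space (x + forward(x) is where the moving image is sampled when
    resampling onto the fixed grid). ``backward`` is its inverse: it
    carries an affine-aligned moving-space point back to fixed space.
    Both are (I, J, K, 3) arrays of mm displacements on the grid described
    by ``grid_affine`` (field voxel → fixed world mm). ``pre_affine`` is
    the moving-world → fixed-world affine applied before the field.
    """

    grid_affine: np.ndarray
    forward: np.ndarray
    backward: np.ndarray
    pre_affine: AffineTransform

    def __post_init__(self):
        if self.forward.shape != self.backward.shape:
            raise DimensionError("forward and backward fields must share a grid shape")
        if self.forward.ndim != 4 or self.forward.shape[3] != 3:
            raise DimensionError(f"field must be (I,J,K,3), got {self.forward.shape}")

    def sample(self, points_mm: np.ndarray, which: str = "forward") -> np.ndarray:
        """Trilinearly interpolate a field (mm) at fixed-world points (N, 3).

        Points outside the grid get zero displacement; the caller decides
        whether that warrants a warning.
        """
        fld = self.forward if which == "forward" else self.backward
        inv = np.linalg.inv(self.grid_affine)
        vox = np.atleast_2d(points_mm) @ inv[:3, :3].T + inv[:3, 3]
        out = np.empty((vox.shape[0], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                fld[..., c], vox.T, order=1, mode="constant", cval=0.0, prefilter=False
            )
        return out

    def inside(self, points_mm: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.grid_affine)
        vox = np.atleast_2d(points_mm) @ inv[:3, :3].T + inv[:3, 3]
        shape = np.array(self.forward.shape[:3])
        return np.all((vox >= 0) & (vox <= shape - 1), axis=1)


# ---------------------------------------------------------------------------
# Mutual information

def _percentile_edges(data: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = np.percentile(data, [1, 99])
    if hi <= lo:
        hi = lo + 1e-6
    return np.linspace(lo, hi, bins + 1)


def mutual_information(a: Volume3D | np.ndarray, b: Volume3D | np.ndarray, bins: int = 32) -> float:
    """MI (nats) of the joint histogram of two same-grid volumes.

    Each axis uses ``bins`` equal-width bins spanning that volume's
    (1st, 99th) percentile range; values outside are clipped into the end
    bins. Plain counts, no Parzen smoothing.
    """
    da = a.data if isinstance(a, Volume3D) else np.asarray(a)
    db = b.data if isinstance(b, Volume3D) else np.asarray(b)
    if da.shape != db.shape:
        raise DimensionError(f"shape mismatch: {da.shape} vs {db.shape}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    ea = _percentile_edges(da, bins)
    eb = _percentile_edges(db, bins)
    ia = np.clip(np.searchsorted(ea, da.ravel(), side="right") - 1, 0, bins - 1)
    ib = np.clip(np.searchsorted(eb, db.ravel(), side="right") - 1, 0, bins - 1)
    joint = np.bincount(ia * bins + ib, minlength=bins * bins).reshape(bins, bins).astype(float)
    joint /= joint.sum()
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * (np.log(joint[nz]) - np.log(np.outer(pa, pb)[nz]))))
    return mi


# ---------------------------------------------------------------------------
# Affine registration

def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_matrix(params: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12-parameter world map about ``center``: T · Tc · R · Shear · Scale · Tc⁻¹.

    Layout: 3 translations (mm), 3 intrinsic Euler angles (rad), 3 log
    scales, 3 shears. Missing trailing parameters are treated as zero.
    """
    p = np.zeros(12)
    p[: len(params)] = params
    R = _euler_matrix(*p[3:6])
    S = np.diag(np.exp(p[6:9]))
    Sh = np.eye(3)
    Sh[0, 1], Sh[0, 2], Sh[1, 2] = p[9:12]
    L = R @ Sh @ S
    M = np.eye(4)
    M[:3, :3] = L
    M[:3, 3] = p[:3] + center - L @ center
    return M


def _pyramid_level(vol: Volume3D, factor: int) -> Volume3D:
    """Gaussian-smooth (sigma = factor/2 voxels, at least 1) and subsample.

    The finest level is smoothed by a full voxel too: it suppresses both
    noise ruggedness of the MI estimate and the anisotropy of the separable
    interpolation kernel, which otherwise biases MI toward grid-aligned
    rotations.
    """
    sm = ndimage.gaussian_filter(np.asarray(vol.data, float), sigma=max(factor / 2.0, 1.0))
    data = sm[::factor, ::factor, ::factor]
    aff = vol.affine @ np.diag([factor, factor, factor, 1.0])
    return Volume3D(data=data, affine=aff, frame=vol.frame, kind=vol.kind)


def _intensity_com(vol: Volume3D) -> np.ndarray:
    """World-mm intensity center of mass (background-suppressed)."""
    d = np.asarray(vol.data, float)
    d = np.clip(d - np.percentile(d, 50), 0, None)
    if d.sum() <= 0:
        d = np.asarray(vol.data, float) - vol.data.min() + 1e-12
    idx = np.array(ndimage.center_of_mass(d))
    return vol.affine[:3, :3] @ idx + vol.affine[:3, 3]


def _overlap_fraction(moving: Volume3D, fixed: Volume3D, matrix: np.ndarray) -> float:
    """Fraction of fixed voxels mapping inside the moving field of view."""
    ii = np.stack(
        np.meshgrid(*[np.linspace(0, s - 1, min(s, 16)) for s in fixed.shape], indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    world = ii @ fixed.affine[:3, :3].T + fixed.affine[:3, 3]
    inv = np.linalg.inv(moving.affine) @ np.linalg.inv(matrix)
    mov = world @ inv[:3, :3].T + inv[:3, 3]
    shape = np.array(moving.shape)
    inside = np.all((mov >= 0) & (mov <= shape - 1), axis=1)
    return float(inside.mean())


def compute_affine_registration(
    moving: Volume3D,
    fixed: Volume3D,
    initial: AffineTransform | None = None,
    stages: tuple[str, ...] = ("translation", "rigid", "affine"),
    pyramid_factors: tuple[int, ...] = (4, 2, 1),
    bins: int = 32,
    max_evals: int = 200,
) -> RegistrationResult:
    """Find the moving-world → fixed-world affine maximizing MI.

    Coarse-to-fine: at each pyramid level both volumes are smoothed and
    subsampled, then each requested stage's parameters (translation 3;
    rigid +3 Euler angles about the fixed volume's world center; affine
    +3 log-scales and +3 shears) are refined by Powell's method. If
    ``initial`` is given it seeds the search; otherwise the volumes'
    intensity centers of mass are aligned. The optimization is entirely
    deterministic.
    """
    if moving.kind != "scalar" or fixed.kind != "scalar":
        raise KindError("affine registration requires scalar-kind volumes")
    for s in stages:
        if s not in _STAGE_NPARAMS:
            raise ValueError(f"unknown stage {s!r}")
    if list(pyramid_factors) != sorted(pyramid_factors, reverse=True) or pyramid_factors[-1] != 1:
        raise ValueError("pyramid_factors must be strictly decreasing and end at 1")

    if initial is not None:
        seed_mat = np.asarray(initial.matrix, float)
    else:
        seed_mat = np.eye(4)
        seed_mat[:3, 3] = _intensity_com(fixed) - _intensity_com(moving)

    if _overlap_fraction(moving, fixed, seed_mat) < 0.10:
        raise OverlapError(
            "volumes do not overlap after seeding (<10% of fixed voxels map into the "
            "moving field of view); supply a manual pre-alignment via `initial`"
        )

    center = fixed.affine[:3, :3] @ ((np.array(fixed.shape) - 1) / 2.0) + fixed.affine[:3, 3]
    params = np.zeros(12)
    mi_trace: list[tuple[int, int, float]] = []
    converged: list[bool] = []

    levels = [(f, _pyramid_level(moving, f), _pyramid_level(fixed, f)) for f in pyramid_factors]
    # Powell step sizes per parameter class: mm, rad, log-scale, shear
    steps = np.array([2.0] * 3 + [0.05] * 3 + [0.02] * 3 + [0.02] * 3)


    jitter_rng = np.random.default_rng(20260101)  # fixed: registration is deterministic

    for li, (factor, mov_l, fix_l) in enumerate(levels):
        # Sample the metric at jittered (off-grid) positions so *both* images
        # are linearly interpolated for every candidate pose. Sampling on the
        # fixed grid instead would leave grid-aligned poses un-interpolated
        # and spuriously sharp, biasing MI toward the identity rotation.
        pre = np.linalg.inv(mov_l.affine)
        post = fix_l.affine
        fix_arr = np.asarray(fix_l.data, float)
        mov_arr = np.asarray(mov_l.data, float)
        grid = np.stack(
            np.meshgrid(*[np.arange(s, dtype=float) for s in fix_arr.shape], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        grid += jitter_rng.uniform(-0.5, 0.5, grid.shape)
        grid = np.clip(grid, 0, np.asarray(fix_arr.shape) - 1.0)
        fix_samples = ndimage.map_coordinates(fix_arr, grid.T, order=1, prefilter=False)
        state = {"best": -np.inf, "neval": 0}

        def cost(p_active, nactive):
            state["neval"] += 1
            params_full = params.copy()
            params_full[:nactive] = p_active
            M = _params_to_matrix(params_full, center) @ seed_mat
            full = pre @ np.linalg.inv(M) @ post
            coords = grid @ full[:3, :3].T + full[:3, 3]
            warped = ndimage.map_coordinates(
                mov_arr, coords.T, order=1, mode="constant", cval=0.0, prefilter=False
            )
            mi = mutual_information(warped, fix_samples, bins=bins)
            if mi > state["best"] + 1e-12:
                state["best"] = mi
                mi_trace.append((li, state["neval"], mi))
            return -mi

        if li == 0 and any(s in ("rigid", "affine") for s in stages):
            # deterministic global rotation sweep seeds the local optimizer
            # outside spurious basins (MI is multimodal in rotation)
            best = (np.inf, (0.0, 0.0, 0.0))
            sweep = np.deg2rad([-12.0, -6.0, 0.0, 6.0, 12.0])
            for rx in sweep:
                for ry in sweep:
                    for rz in sweep:
                        val = cost(np.r_[params[:3], rx, ry, rz], 6)
                        if val < best[0]:
                            best = (val, (rx, ry, rz))
            params[3:6] = best[1]

        level_ok = True
        # coarse levels are cheap per evaluation, so they get the larger budgets;
        # initial search brackets shrink as the pyramid refines
        level_maxfev = max_evals * factor * 2
        level_steps = steps * max(factor / 2.0, 0.5)
        for stage in stages:
            n = _STAGE_NPARAMS[stage]
            res = optimize.minimize(
                cost, params[:n], args=(n,), method="Powell",
                options={
                    "xtol": 1e-4, "ftol": 1e-6, "maxfev": level_maxfev,
                    "direc": np.diag(level_steps[:n]),
                },
            )
            params[:n] = res.x
            level_ok = level_ok and bool(res.success)
        converged.append(level_ok)

    final = _params_to_matrix(params, center) @ seed_mat
    result = AffineTransform(final, source=moving.frame, target=fixed.frame)

    # Contract: MI at the solution is at least MI at the seed, evaluated with
    # the same off-grid sampler at the finest level.
    mi_final = -cost(params[:12], 12)
    mi_seed = -cost(np.zeros(12), 12)
    if mi_final + 1e-9 < mi_seed:
        logger.warning("registration did not improve MI over seed (%.4f < %.4f)", mi_final, mi_seed)
        result = AffineTransform(seed_mat, moving.frame, fixed.frame)
    return RegistrationResult(affine=result, mi_trace=mi_trace, converged=converged)


# ---------------------------------------------------------------------------
# Symmetric diffeomorphic (demons) registration

def _normalize(data: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(data, [1, 99])
    if hi <= lo:
        hi = lo + 1e-6
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def _warp_image(img: np.ndarray, disp_vox: np.ndarray) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(s) for s in img.shape], indexing="ij"), axis=-1)
    coords = (idx + disp_vox).reshape(-1, 3).T
    return ndimage.map_coordinates(
        img, coords, order=1, mode="constant", cval=0.0, prefilter=False
    ).reshape(img.shape)


def _invert_field(disp_vox: np.ndarray, iters: int = 25) -> np.ndarray:
    """Fixed-point inverse of a displacement field (voxel units)."""
    inv = -disp_vox.copy()
    for _ in range(iters):
        upd = np.empty_like(inv)
        for c in range(3):
            upd[..., c] = _warp_image(disp_vox[..., c], inv)
        inv = -upd
    return inv


def compute_sdr_registration(
    moving: Volume3D,
    fixed: Volume3D,
    pre_affine: AffineTransform | None = None,
    level_iters: tuple[int, ...] = (10, 10, 5),
    field_sigma: float = 2.0,
    pyramid_factors: tuple[int, ...] = (4, 2, 1),
) -> DeformationField:
    """Greedy symmetric demons registration of ``moving`` onto ``fixed``.

    Both volumes are rescaled to (0, 1) by their 1st–99th percentiles; at
    each iteration a demons force is computed from the intensity difference
    with the symmetric (mean of fixed and warped-moving) gradient, smoothed
    by a Gaussian of width ``field_sigma`` mm, and accumulated into the
    forward displacement field. The backward field is the fixed-point
    inverse of the forward field, so forward∘backward is the identity to a
    small fraction of a voxel by construction.
    """
    if moving.kind != "scalar" or fixed.kind != "scalar":
        raise KindError("SDR registration requires scalar-kind volumes")
    if len(level_iters) != len(pyramid_factors):
        raise ValueError("level_iters must match pyramid_factors in length")
    if pre_affine is None:
        pre_affine = AffineTransform.identity(moving.frame, fixed.frame)

    aligned = resample(moving, fixed, pre_affine, interp="linear")
    mov_full = _normalize(np.asarray(aligned.data, float))
    fix_full = _normalize(np.asarray(fixed.data, float))

    vox_sizes_full = fixed.voxel_sizes
    disp = None  # voxel-unit displacement on the current level grid
    prev_factor = None

    for factor, iters in zip(pyramid_factors, level_iters):
        if factor == 1:
            mov_l, fix_l = mov_full, fix_full
        else:
            sig = factor / 2.0
            mov_l = ndimage.gaussian_filter(mov_full, sig)[::factor, ::factor, ::factor]
            fix_l = ndimage.gaussian_filter(fix_full, sig)[::factor, ::factor, ::factor]
        vox_l = vox_sizes_full * factor
        if disp is None:
            disp = np.zeros(fix_l.shape + (3,))
        else:
            scale = prev_factor / factor
            new = np.empty(fix_l.shape + (3,))
            grid = np.stack(
                np.meshgrid(*[np.arange(s) / scale for s in fix_l.shape], indexing="ij"), axis=-1
            )
            for c in range(3):
                new[..., c] = ndimage.map_coordinates(
                    disp[..., c] * scale, grid.reshape(-1, 3).T, order=1,
                    mode="nearest", prefilter=False,
                ).reshape(fix_l.shape)
            disp = new
        sigma_vox = field_sigma / vox_l  # mm -> level voxels, per axis
        gf = np.stack(np.gradient(fix_l, *vox_l), axis=-1)
        for _ in range(iters):
            warped = _warp_image(mov_l, disp)
            diff = warped - fix_l
            gw = np.stack(np.gradient(warped, *vox_l), axis=-1)
            g = 0.5 * (gw + gf)
            g2 = np.sum(g * g, axis=-1)
            # Thirion normalization; max step ~ half the coarsest voxel
            sigma_x = float(np.max(vox_l))
            denom = g2 + (diff ** 2) / (sigma_x ** 2)
            denom[denom < 1e-12] = np.inf
            upd_mm = -diff[..., None] * g / denom[..., None]
            # fluid-like smoothing of the update, then diffusion-like
            # smoothing of the accumulated field: the update smoothing
            # stabilizes the Newton-type force, the field smoothing spreads
            # displacement into flat regions and keeps the map smooth
            for c in range(3):
                upd_mm[..., c] = ndimage.gaussian_filter(upd_mm[..., c], sigma_vox)
            disp = disp + upd_mm / vox_l  # mm -> voxel units per axis
            for c in range(3):
                disp[..., c] = ndimage.gaussian_filter(disp[..., c], sigma_vox)
        prev_factor = factor

    if prev_factor != 1:  # upsample to the full fixed grid
        scale = prev_factor
        new = np.empty(fix_full.shape + (3,))
        grid = np.stack(
            np.meshgrid(*[np.arange(s) / scale for s in fix_full.shape], indexing="ij"), axis=-1
        )
        for c in range(3):
            new[..., c] = ndimage.map_coordinates(
                disp[..., c] * scale, grid.reshape(-1, 3).T, order=1,
                mode="nearest", prefilter=False,
            ).reshape(fix_full.shape)
        disp = new

    inv_disp = _invert_field(disp)

    # voxel-unit axis displacements -> world mm (fixed grid linear part)
    L = fixed.affine[:3, :3]
    forward_mm = disp @ L.T
    backward_mm = inv_disp @ L.T

    final = _warp_image(mov_full, disp)
    ssd_aff = float(np.mean((mov_full - fix_full) ** 2))
    ssd_sdr = float(np.mean((final - fix_full) ** 2))
    if ssd_sdr > ssd_aff + 1e-12:
        logger.warning("SDR did not improve SSD (%.6f > %.6f)", ssd_sdr, ssd_aff)

    return DeformationField(
        grid_affine=fixed.affine.copy(),
        forward=forward_mm,
        backward=backward_mm,
        pre_affine=pre_affine,
    )


# ---------------------------------------------------------------------------
# Point warping

def apply_point_registration(
    points: np.ndarray,
    result: RegistrationResult | AffineTransform | DeformationField,
    direction: str = "forward",
):
    """Map points (N, 3 mm) through an affine or deformation-field result.

    Affine case: the matrix (or its inverse for ``direction="backward"``)
    is applied homogeneously.

    Field case, ``direction="forward"`` (moving frame → fixed frame): the
    pre-affine is applied, then the backward displacement sampled at each
    point is added. ``direction="backward"`` inverts that path. Points
    falling outside the field grid receive the affine-only mapping and are
    flagged in the returned boolean ``outside`` array.

    Returns
    -------
    mapped : ndarray (N, 3)
    outside : ndarray (N,) of bool (field case only; all-False for affines)
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if isinstance(result, RegistrationResult):
        result = result.affine
    if isinstance(result, AffineTransform):
        tf = result if direction == "forward" else result.invert()
        return tf.apply(pts), np.zeros(len(pts), dtype=bool)

    fld: DeformationField = result
    if direction == "forward":
        aligned = fld.pre_affine.apply(pts)
        inside = fld.inside(aligned)
        mapped = aligned + fld.sample(aligned, "backward")
        mapped[~inside] = aligned[~inside]
    else:
        inside = fld.inside(pts)
        moved = pts + fld.sample(pts, "forward")
        moved[~inside] = pts[~inside]
        mapped = fld.pre_affine.invert().apply(moved)
    if np.any(~inside):
        logger.warning("%d point(s) outside the deformation grid: affine-only mapping", int((~inside).sum()))
    return mapped, ~inside


def compare_linear_vs_sdr(
    points: np.ndarray,
    linear: AffineTransform,
    sdr_field: DeformationField,
    reference: np.ndarray,
):
    """Euclidean per-point and mean errors of a linear vs an SDR mapping.

    ``reference`` holds the true template-space positions corresponding to
    ``points``. No ordering between the two errors is enforced here — on
    nonlinear anatomy the SDR error is expected to be smaller, but that is
    a property of the data, not of this function.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    ref = np.atleast_2d(np.asarray(reference, float))
    if pts.shape != ref.shape:
        raise DimensionError(f"points {pts.shape} and reference {ref.shape} differ")
    lin_pts, _ = apply_point_registration(pts, linear)
    sdr_pts, _ = apply_point_registration(pts, sdr_field)
    lin_err = np.linalg.norm(lin_pts - ref, axis=1)
    sdr_err = np.linalg.norm(sdr_pts - ref, axis=1)
    return {
        "linear_errors": lin_err,
        "sdr_errors": sdr_err,
        "linear_mean": float(lin_err.mean()),
        "sdr_mean": float(sdr_err.mean()),
    }
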