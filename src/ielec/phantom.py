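"""Deterministic synthetic head phantom with ground truth for every pipeline stage.

The phantom is an ellipsoidal "head" built from analytic scene functions
evaluated on voxel grids, so every quantity the pipeline estimates has an
exact known answer:

* an MR image (bright brain with smooth internal texture, dark CSF
  ventricles, dark skull shell with angular thickness variation, bright
  subcutaneous fat rim, an air-dark frontal sinus — the usual T1 contrast),
* a CT image on its own, rigidly misaligned grid (bright skull, faint
  brain, and bright Gaussian blobs at the electrode contact positions —
  metal artifact-free idealized contacts),
* an integer segmentation of concentric anatomical bands with a
  FreeSurfer-style lookup table,
* pial (sinusoidally dented sphere) and leptomeningeal (smooth sphere)
  surface meshes,
* a template MR related to the subject MR by a known smooth sinusoidal
  deformation, stored with its exact inverse,
* ground-truth montages: sEEG shaft contacts, ECoG grid contacts both
  pre-shift (on the leptomeningeal surface) and post-shift (depressed
  inward, as brain shift leaves them in the post-operative CT).

Everything is a pure function of the spec and its integer seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .anatomy import LabelTable
from .brainshift import SurfaceMesh, write_off
from .errors import SpecError
from .imagespace import FRAME_CT, FRAME_MR, FRAME_TEMPLATE, AffineTransform, Volume3D, write_volume
from .localization import Contact, Montage, write_electrodes_tsv
from .registration import DeformationField

__all__ = ["PhantomSpec", "PhantomBundle", "make_phantom", "write_phantom"]


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise parameters of the synthetic head.

    Defaults describe a 64 mm cube at 1 mm isotropic resolution holding a
    mildly ellipsoidal head (brain semi-axes 25 x 23.75 x 22 mm inside a
    2 mm skull shell), a 10-contact sEEG shaft at 5.25 mm center-to-center
    spacing (wide-pitch depth leads; the largest spacing whose 10-contact
    span threads this brain along its long axis), and a 4x4 ECoG grid at
    6 mm pitch depressed 3 mm by brain shift. Contact blobs have sigma
    1.1 mm and amplitude 5 intensity units against CT noise of sigma 0.05
    (on this scale the skull is 1.0 ~ 1000 HU, so 0.05 ~ 50 HU — an order
    noisier than clinical CT, while keeping metal contacts at the huge
    contrast they really have).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 1.0
    head_radius: float = 28.5
    brain_radius: float = 25.0
    skull_inner: float = 25.5
    skull_outer: float = 27.5
    head_axes: tuple[float, float, float] = (1.0, 0.92, 0.84)
    # sEEG shaft: line through (center + offset) along a unit direction,
    # threaded along the head's long axis so the 10-contact span fits
    seeg_n_contacts: int = 10
    seeg_pitch: float = 5.25
    seeg_offset: tuple[float, float, float] = (0.0, -2.0, 1.0)
    seeg_direction: tuple[float, float, float] = (0.97, 0.17, 0.17)
    seeg_start: float = -23.625  # mm along direction of contact 1 (deepest)
    # ECoG grid
    grid_rows: int = 4
    grid_cols: int = 4
    grid_pitch: float = 6.0
    grid_depression: float = 3.0
    grid_normal: tuple[float, float, float] = (-0.25, 0.72, -0.65)
    # contrast / noise
    blob_sigma: float = 1.1
    blob_amplitude: float = 5.0
    ct_noise_sigma: float = 0.05
    mr_noise_sigma: float = 0.02
    # pial sulcal dents and template deformation
    dent_amplitude: float = 0.6
    warp_amplitude: float = 3.0
    warp_wavelength: float = 48.0
    # CT misalignment bounds
    min_rotation_deg: float = 5.0
    max_rotation_deg: float = 15.0
    max_center_shift: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("voxel_size", "head_radius", "brain_radius", "skull_inner",
                     "skull_outer", "seeg_pitch", "grid_pitch", "blob_sigma",
                     "blob_amplitude"):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be positive")
        if not (self.brain_radius < self.skull_inner < self.skull_outer <= self.head_radius):
            raise SpecError("need brain_radius < skull_inner < skull_outer <= head_radius")

    @property
    def center(self) -> np.ndarray:
        return (np.array(self.shape) - 1) / 2.0 * self.voxel_size


@dataclass
class PhantomBundle:
    """Everything :func:`make_phantom` produces, with ground truth."""

    spec: PhantomSpec
    mr: Volume3D
    ct: Volume3D
    seg: Volume3D
    lut: LabelTable
    pial: SurfaceMesh
    lepto: SurfaceMesh
    montage_truth: Montage            # all contacts at their CT-visible positions (MR frame)
    montage_truth_ct: Montage         # same contacts expressed in the CT frame
    grid_truth_preshift: Montage      # ECoG grid before brain shift (on the lepto surface)
    true_ct_to_mr: AffineTransform
    template_mr: Volume3D
    true_subject_to_template: DeformationField
    montage_truth_template: Montage   # contacts mapped to template space by the exact warp
    true_labels: dict = field(default_factory=dict)
    brain_mask: np.ndarray | None = None

    @property
    def seeg_names(self) -> list[str]:
        return [c.name for c in self.montage_truth.contacts if c.name.startswith("LPM")]

    @property
    def grid_names(self) -> list[str]:
        return [c.name for c in self.montage_truth.contacts if c.name.startswith("G")]


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _smoothstep(x, width: float = 0.7):
    """Sigmoid edge of the given width (mm); keeps scenes differentiable."""
    return 1.0 / (1.0 + np.exp(-np.clip(np.asarray(x, dtype=float) / width, -60, 60)))


class _Scene:
    """Analytic intensity/label functions of the phantom head in MR world mm.

    The head is a mild triaxial ellipsoid (no real head is a sphere, and a
    sphere would leave image rotation unconstrained); all tissue boundaries
    are thresholds on the elliptical radius rho, so rho plays the role mm
    radius plays in a spherical model. The CT soft-tissue intensity is a
    nonlinear function of the same texture field that modulates the MR —
    the cross-modality statistical dependence that mutual information
    registration exploits in real image pairs.
    """

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.center = spec.center
        self.axes = np.asarray(spec.head_axes, dtype=float)
        n = 40
        self.tex_centers = self.center + rng.uniform(-0.7, 0.7, (n, 3)) * (
            spec.brain_radius * self.axes
        )
        self.tex_sigma = rng.uniform(2.5, 5.0, n)
        self.tex_amp = rng.uniform(-0.35, 0.35, n)
        # fixed asymmetric anatomy: paired lateral ventricles and a frontal
        # sinus. These shared structures are what anchors cross-modality
        # registration in real heads; without them rotation is near-degenerate.
        self.vent_centers = self.center + np.array([[4.5, 5.0, 1.0], [-4.5, 5.0, 1.0]])
        self.vent_axes = np.array([3.5, 8.0, 3.5])
        self.sinus_center = self.center + 25.5 * _unit(np.array([0.85, 0.5, 0.2]) * self.axes)
        self.sinus_radius = 5.0

    def ventricles(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[:-1])
        for c in self.vent_centers:
            d = np.linalg.norm((pts - c) / self.vent_axes, axis=-1)
            out = np.maximum(out, _smoothstep((1.0 - d) * 3.0, width=0.7))
        return out

    def sinus(self, pts: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts - self.sinus_center, axis=-1)
        return _smoothstep(self.sinus_radius - d)

    def rho(self, pts: np.ndarray) -> np.ndarray:
        """Elliptical radius: mm along each semi-axis scaled to the x axis."""
        return np.linalg.norm((pts - self.center) / self.axes, axis=-1)

    def brain(self, pts: np.ndarray) -> np.ndarray:
        return _smoothstep(self.spec.brain_radius - self.rho(pts))

    def skull_bump(self, pts: np.ndarray) -> np.ndarray:
        """Angular skull-thickness variation (mm), as real calvaria have.

        A fixed low-order angular pattern; it gives the skull boundaries —
        visible in both modalities — the orientation signature a smooth
        ellipsoid shell lacks.
        """
        d = pts - self.center
        az = np.arctan2(d[..., 1], d[..., 0])
        pol = np.arccos(np.clip(d[..., 2] / np.maximum(np.linalg.norm(d, axis=-1), 1e-9), -1, 1))
        return 0.9 * np.sin(3 * az) * np.sin(2 * pol) + 0.8 * np.cos(2 * az) * np.sin(pol) ** 2

    def skull(self, pts: np.ndarray) -> np.ndarray:
        r = self.rho(pts)
        b = self.skull_bump(pts)
        inner = self.spec.skull_inner + 0.2 * b
        outer = self.spec.skull_outer + 0.8 * b
        return _smoothstep(r - inner) * _smoothstep(outer - r)

    def fat(self, pts: np.ndarray) -> np.ndarray:
        r = self.rho(pts)
        outer = self.spec.skull_outer + 0.8 * self.skull_bump(pts)
        return _smoothstep(r - outer) * _smoothstep(self.spec.head_radius - r)

    def texture(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(pts.shape[:-1])
        for c, s, a in zip(self.tex_centers, self.tex_sigma, self.tex_amp):
            d2 = np.sum((pts - c) ** 2, axis=-1)
            out += a * np.exp(-0.5 * d2 / s**2)
        return out

    def mr(self, pts: np.ndarray) -> np.ndarray:
        # T1-like: bright brain with texture, dark CSF ventricles, dark
        # skull, bright fat rim, air-dark frontal sinus
        vent = self.ventricles(pts)
        sinus = self.sinus(pts)
        brain_tissue = self.brain(pts) * (0.75 + self.texture(pts)) * (1.0 - 0.75 * vent)
        return (brain_tissue + 0.10 * self.skull(pts) + 0.85 * self.fat(pts)) * (1.0 - 0.95 * sinus)

    def ct(self, pts: np.ndarray, contacts: np.ndarray) -> np.ndarray:
        # soft tissue tracks the MR texture through a nonlinear map; the
        # sinus punches an air hole through the bright skull ring
        soft = 0.08 + 0.30 * (0.5 + 0.5 * np.tanh(2.0 * self.texture(pts)))
        soft = soft * (1.0 - 0.6 * self.ventricles(pts))
        out = (1.0 * self.skull(pts) + self.brain(pts) * soft) * (1.0 - 0.95 * self.sinus(pts))
        s2 = 2.0 * self.spec.blob_sigma**2
        for c in contacts:
            d2 = np.sum((pts - c) ** 2, axis=-1)
            out += self.spec.blob_amplitude * np.exp(-d2 / s2)
        return out

    def labels(self, pts: np.ndarray) -> np.ndarray:
        r = self.rho(pts)
        out = np.zeros(r.shape, dtype=np.int32)
        out[r < self.spec.skull_inner + 0.5] = 3     # cortical band, with a thin pial rim
        out[r < 16.0] = 2                            # white-matter band
        out[r < 9.0] = 10                            # deep gray band
        return out

    def surface_point(self, direction, rho: float) -> np.ndarray:
        """Point on the iso-rho surface along a unit direction from the center."""
        u = _unit(direction)
        return self.center + (rho / np.linalg.norm(u / self.axes)) * u

    def surface_normal(self, p: np.ndarray) -> np.ndarray:
        """Outward unit normal of the iso-rho ellipsoid through p."""
        return _unit((p - self.center) / self.axes**2)


def _grid_points(spec: PhantomSpec):
    """World-index grid of voxel centers, shape (*shape, 3), in grid world mm."""
    axes = [np.arange(s) * spec.voxel_size for s in spec.shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _seeg_positions(spec: PhantomSpec) -> np.ndarray:
    d = _unit(spec.seeg_direction)
    base = spec.center + np.asarray(spec.seeg_offset, float)
    s = spec.seeg_start + spec.seeg_pitch * np.arange(spec.seeg_n_contacts)
    return base + s[:, None] * d


def _grid_positions(spec: PhantomSpec, scene: "_Scene") -> tuple[np.ndarray, np.ndarray]:
    """Rows x cols ECoG grid on the brain surface, and its brain-shifted copy.

    Contacts are laid out geodesically around the grid normal on the
    leptomeningeal (iso-rho = brain radius) surface; the post-shift copy
    is each contact pushed ``grid_depression`` mm inward along the local
    surface normal, which is how the sagging brain carries the grid.
    """
    n = _unit(spec.grid_normal)
    u = _unit(np.cross(n, [0.0, 0.0, 1.0]))
    v = np.cross(n, u)
    radius = spec.brain_radius
    pre, post = [], []
    for i in range(spec.grid_rows):
        for j in range(spec.grid_cols):
            a = (i - (spec.grid_rows - 1) / 2) * spec.grid_pitch
            b = (j - (spec.grid_cols - 1) / 2) * spec.grid_pitch
            arc = np.hypot(a, b)
            if arc < 1e-12:
                direction = n
            else:
                t = _unit(a * u + b * v)
                theta = arc / radius
                direction = np.cos(theta) * n + np.sin(theta) * t
            p = scene.surface_point(direction, radius)
            pre.append(p)
            post.append(p - spec.grid_depression * scene.surface_normal(p))
    return np.array(pre), np.array(post)


def _pial_mesh(spec: PhantomSpec, scene: "_Scene") -> SurfaceMesh:
    """Brain surface with shallow sinusoidal sulcal dents (inward only)."""
    base = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    d = np.asarray(base.vertices, dtype=float)
    az = np.arctan2(d[:, 1], d[:, 0])
    pol = np.arccos(np.clip(d[:, 2], -1, 1))
    dent = spec.dent_amplitude * (np.sin(3 * az) ** 2) * (np.sin(2 * pol) ** 2)
    verts = np.array([
        scene.surface_point(di, spec.brain_radius - de) for di, de in zip(d, dent)
    ])
    return SurfaceMesh(verts, np.asarray(base.faces, dtype=int), frame=FRAME_MR)


def _lepto_mesh(spec: PhantomSpec, scene: "_Scene") -> SurfaceMesh:
    """Smooth leptomeningeal envelope: the iso-rho brain-radius ellipsoid."""
    base = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    d = np.asarray(base.vertices, dtype=float)
    verts = np.array([scene.surface_point(di, spec.brain_radius) for di in d])
    return SurfaceMesh(verts, np.asarray(base.faces, dtype=int), frame=FRAME_MR)


def _warp_displacement(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Smooth sinusoidal displacement u(p), |u| <= warp_amplitude, invertible."""
    a = spec.warp_amplitude
    k = 2 * np.pi / spec.warp_wavelength
    q = pts - spec.center
    u = np.empty_like(pts)
    u[..., 0] = a * np.sin(k * q[..., 1]) * np.cos(k * q[..., 2])
    u[..., 1] = a * np.sin(k * q[..., 2]) * np.cos(k * q[..., 0])
    u[..., 2] = a * np.sin(k * q[..., 0]) * np.cos(k * q[..., 1])
    return u


def _invert_warp_points(spec: PhantomSpec, pts: np.ndarray, iters: int = 60) -> np.ndarray:
    """Solve phi(q) = q + u(q) = p for q, by fixed-point iteration on the analytic u."""
    q = np.array(pts, dtype=float)
    for _ in range(iters):
        q = pts - _warp_displacement(spec, q)
    return q


def _rigid_ct_transform(spec: PhantomSpec, rng: np.random.Generator) -> AffineTransform:
    axis = _unit(rng.normal(size=3))
    angle = np.deg2rad(rng.uniform(spec.min_rotation_deg, spec.max_rotation_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    shift = rng.uniform(-spec.max_center_shift, spec.max_center_shift, 3)
    c = spec.center
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = c - R @ c + shift
    return AffineTransform(M, source=FRAME_CT, target=FRAME_MR)


def make_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Build the full phantom bundle; bit-identical for identical spec (incl. seed)."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    scene = _Scene(spec, rng)
    affine = np.diag([spec.voxel_size] * 3 + [1.0])
    pts = _grid_points(spec)

    # --- contact ground truth (MR world) -----------------------------------
    seeg = _seeg_positions(spec)
    grid_pre, grid_post = _grid_positions(spec, scene)
    all_contacts = np.vstack([seeg, grid_post])
    if np.any(scene.rho(all_contacts) >= spec.brain_radius + 0.5):
        raise SpecError("contact positions fall outside the brain")
    seeg_names = [f"LPM{i + 1}" for i in range(spec.seeg_n_contacts)]
    grid_names = [f"G{i + 1}" for i in range(spec.grid_rows * spec.grid_cols)]
    names = seeg_names + grid_names

    # --- volumes ------------------------------------------------------------
    mr_data = scene.mr(pts) + rng.normal(0, spec.mr_noise_sigma, spec.shape)
    mr = Volume3D(mr_data, affine, frame=FRAME_MR, kind="scalar")

    true_ct_to_mr = _rigid_ct_transform(spec, rng)
    pts_ct_in_mr = pts @ true_ct_to_mr.matrix[:3, :3].T + true_ct_to_mr.matrix[:3, 3]
    ct_data = scene.ct(pts_ct_in_mr, all_contacts) + rng.normal(0, spec.ct_noise_sigma, spec.shape)
    ct = Volume3D(ct_data, affine, frame=FRAME_CT, kind="scalar")

    seg = Volume3D(scene.labels(pts), affine, frame=FRAME_MR, kind="label")
    lut = LabelTable({
        0: ("Unknown", (0, 0, 0, 0)),
        2: ("Cerebral-White-Matter", (245, 245, 245, 255)),
        3: ("Cerebral-Cortex", (205, 62, 78, 255)),
        10: ("Deep-Gray", (0, 118, 14, 255)),
    })

    # --- template: subject MR seen through a known smooth warp --------------
    warped_pts = pts + _warp_displacement(spec, pts)
    template_data = scene.mr(warped_pts) + rng.normal(0, spec.mr_noise_sigma, spec.shape)
    template = Volume3D(template_data, affine, frame=FRAME_TEMPLATE, kind="scalar")

    forward = _warp_displacement(spec, pts)              # template voxel -> subject point
    inv_pts = _invert_warp_points(spec, pts)
    backward = inv_pts - pts                             # subject point -> template point
    true_field = DeformationField(
        grid_affine=affine.copy(),
        forward=forward,
        backward=backward,
        pre_affine=AffineTransform.identity(FRAME_MR, FRAME_TEMPLATE),
    )

    # --- montages ------------------------------------------------------------
    montage_truth = Montage(
        [Contact(n, p, status="located") for n, p in zip(names, all_contacts)],
        frame=FRAME_MR,
    )
    inv_ct = np.linalg.inv(true_ct_to_mr.matrix)
    ct_positions = all_contacts @ inv_ct[:3, :3].T + inv_ct[:3, 3]
    montage_truth_ct = Montage(
        [Contact(n, p, status="located") for n, p in zip(names, ct_positions)],
        frame=FRAME_CT,
    )
    grid_truth_preshift = Montage(
        [Contact(n, p, status="located") for n, p in zip(grid_names, grid_pre)],
        frame=FRAME_MR,
    )
    # label truth at the positions the pipeline ultimately reports:
    # sEEG at the shaft, ECoG at the projected (pre-shift) surface positions
    label_pts = np.vstack([seeg, grid_pre])
    true_ids = scene.labels(label_pts)
    true_labels = {n: lut.name(i) for n, i in zip(names, true_ids)}

    template_pts = _invert_warp_points(spec, all_contacts)
    montage_truth_template = Montage(
        [Contact(n, p, status="located") for n, p in zip(names, template_pts)],
        frame=FRAME_TEMPLATE,
    )

    brain_mask = scene.rho(pts) < 0.85 * spec.brain_radius

    return PhantomBundle(
        spec=spec,
        mr=mr,
        ct=ct,
        seg=seg,
        lut=lut,
        pial=_pial_mesh(spec, scene),
        lepto=_lepto_mesh(spec, scene),
        montage_truth=montage_truth,
        montage_truth_ct=montage_truth_ct,
        grid_truth_preshift=grid_truth_preshift,
        true_ct_to_mr=true_ct_to_mr,
        template_mr=template,
        true_subject_to_template=true_field,
        montage_truth_template=montage_truth_template,
        true_labels=true_labels,
        brain_mask=brain_mask,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_phantom(bundle: PhantomBundle, directory) -> None:
    """Write every phantom artifact plus a checksum manifest to a directory."""
    import os

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    import nibabel as nib

    files = {}

    def vol(name, v):
        path = os.path.join(directory, name)
        write_volume(v, path)
        files[name] = path

    vol("mr.nii.gz", bundle.mr)
    vol("ct.nii.gz", bundle.ct)
    vol("seg.nii.gz", bundle.seg)
    vol("template.nii.gz", bundle.template_mr)

    fld = bundle.true_subject_to_template
    img = nib.Nifti1Image(
        np.stack([fld.forward, fld.backward], axis=3).astype(np.float32),
        fld.grid_affine,
    )
    path = os.path.join(directory, "true_field.nii.gz")
    nib.save(img, path)
    files["true_field.nii.gz"] = path
    path = os.path.join(directory, "true_field.json")
    with open(path, "w") as fh:
        json.dump({"pre_affine": fld.pre_affine.to_dict()}, fh, indent=1)
    files["true_field.json"] = path

    path = os.path.join(directory, "lut.txt")
    with open(path, "w") as fh:
        fh.write("# id name R G B A\n")
        for lid, (name, rgba) in sorted(bundle.lut.entries.items()):
            fh.write(f"{lid} {name} {rgba[0]} {rgba[1]} {rgba[2]} {rgba[3]}\n")
    files["lut.txt"] = path

    for name, mesh in (("pial.off", bundle.pial), ("lepto.off", bundle.lepto)):
        path = os.path.join(directory, name)
        write_off(mesh, path)
        files[name] = path

    for name, m in (
        ("electrodes_truth.tsv", bundle.montage_truth),
        ("electrodes_truth_ct.tsv", bundle.montage_truth_ct),
        ("grid_preshift.tsv", bundle.grid_truth_preshift),
        ("electrodes_truth_template.tsv", bundle.montage_truth_template),
    ):
        path = os.path.join(directory, name)
        write_electrodes_tsv(m, path)
        files[name] = path

    path = os.path.join(directory, "true_ct_to_mr.json")
    with open(path, "w") as fh:
        json.dump(bundle.true_ct_to_mr.to_dict(), fh, indent=1)
    files["true_ct_to_mr.json"] = path

    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(bundle.spec).items()},
        "files": {name: _sha256(p) for name, p in sorted(files.items())},
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
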