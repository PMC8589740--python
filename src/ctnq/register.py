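"""Subject-to-template spatial normalization.

Alignment follows the two-stage scheme used for CT morphometry: a 9-parameter
affine (3 translations, 3 rotations, 3 scales) estimated on the *binary skull
masks* by minimizing sum-of-squared differences of Gaussian-smoothed masks
with a derivative-free multi-resolution search, then an optional nonrigid
refinement that maximizes the normalized mutual information (NMI) of the
grayscale images with a coarse free-form deformation.

Conventions
-----------
All transforms map **template world coordinates to subject world coordinates**
(the resampling direction for bringing the subject into template space).  The
composite map is ``phi(x) = A(x) + d(x)`` with ``A`` the affine and ``d`` the
displacement field defined on the template grid (mm).  ``transport`` resamples
either way; the template->native direction inverts ``phi`` exactly for the
affine part and by fixed-point iteration for the deformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .volume import Volume
from .skullstrip import BrainMask

__all__ = [
    "AffineTransform",
    "DeformationField",
    "AffineRegConfig",
    "NonrigidConfig",
    "affine_register_masks",
    "nonrigid_refine",
    "transport",
    "zscore_brain",
    "nmi",
]


class RegistrationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
@dataclass
class AffineTransform:
    """9-parameter affine: y = R S (x - c) + c + t (world mm).

    Rotations are in degrees (applied Rz Ry Rx), scales are unitless and the
    rotation/scaling center ``c`` is fixed at registration time (template mask
    centroid) so the parameters are interpretable and reproducible.
    """

    translations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotations: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scales: np.ndarray = field(default_factory=lambda: np.ones(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be positive")

    @staticmethod
    def _rot(rx: float, ry: float, rz: float) -> np.ndarray:
        ax, ay, az = np.deg2rad([rx, ry, rz])
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world->world matrix."""
        R = self._rot(*self.rotations)
        M = R @ np.diag(self.scales)
        out = np.eye(4)
        out[:3, :3] = M
        out[:3, 3] = self.center + self.translations - M @ self.center
        return out

    def apply(self, pts: np.ndarray) -> np.ndarray:
        M = self.matrix()
        return np.asarray(pts, float) @ M[:3, :3].T + M[:3, 3]

    def apply_inverse(self, pts: np.ndarray) -> np.ndarray:
        Minv = np.linalg.inv(self.matrix())
        return np.asarray(pts, float) @ Minv[:3, :3].T + Minv[:3, 3]

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "translations_mm": self.translations.tolist(),
            "rotations_deg": self.rotations.tolist(),
            "scales": self.scales.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(
            np.asarray(d["translations_mm"]),
            np.asarray(d["rotations_deg"]),
            np.asarray(d["scales"]),
            np.asarray(d["center_mm"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class DeformationField:
    """Dense displacement (mm) on the template grid, template->subject."""

    displacement: np.ndarray          # (3, nx, ny, nz)
    grid_affine: np.ndarray           # template voxel->world
    regularization_weight: float = 0.0

    def sample(self, world_pts: np.ndarray) -> np.ndarray:
        """Interpolate the displacement at template-space world points."""
        inv = np.linalg.inv(self.grid_affine)
        vox = np.asarray(world_pts, float) @ inv[:3, :3].T + inv[:3, 3]
        out = np.empty_like(np.asarray(world_pts, float))
        for k in range(3):
            out[..., k] = ndimage.map_coordinates(
                self.displacement[k], vox.reshape(-1, 3).T, order=1, mode="nearest"
            ).reshape(vox.shape[:-1])
        return out

    def jacobian_positive_fraction(self) -> float:
        """Fraction of voxels where det(J(phi_d)) > 0 for phi_d = id + d."""
        sp = np.sqrt((self.grid_affine[:3, :3] ** 2).sum(axis=0))
        J = np.zeros(self.displacement.shape[1:] + (3, 3))
        for k in range(3):
            for ax in range(3):
                J[..., k, ax] = np.gradient(self.displacement[k], sp[ax], axis=ax)
        J += np.eye(3)
        return float((np.linalg.det(J) > 0).mean())


# --------------------------------------------------------------------------
@dataclass(frozen=True)
class AffineRegConfig:
    smooth_sigma_vox: float = 1.0
    pyramid: tuple[int, ...] = (4, 2)
    final_full_res: bool = True
    maxiter: int = 30
    maxiter_full: int = 4
    xtol: float = 1e-3
    support_dilation_vox: int = 6


def _smoothed(mask: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(mask.astype(np.float64), sigma)


def _centroid_world(vol: Volume) -> np.ndarray:
    idx = np.argwhere(vol.data > 0)
    if idx.size == 0:
        raise RegistrationError("empty mask")
    return vol.voxel_to_world(idx.mean(axis=0))


def _pack(t, r, u):
    return np.concatenate([t, r, u])


def _unpack(p, center):
    # scales parametrized as 1 + u/50 so a unit Powell step is ~2%
    return AffineTransform(p[:3], p[3:6], 1.0 + p[6:9] / 50.0, center)


def affine_register_masks(
    subject_skull_mask: Volume,
    template_skull_mask: Volume,
    config: AffineRegConfig | None = None,
) -> AffineTransform:
    """Estimate the 9-parameter template->subject affine from skull masks.

    Both binary masks are Gaussian-smoothed so the SSD objective is smooth in
    the parameters; optimization is a deterministic multi-resolution Powell
    search initialized at the centroid shift.
    """
    cfg = config or AffineRegConfig()
    sub = subject_skull_mask
    tmp = template_skull_mask
    if not sub.data.any() or not tmp.data.any():
        raise RegistrationError("empty skull mask")
    center = _centroid_world(tmp)
    t0 = _centroid_world(sub) - center
    sub_inv = np.linalg.inv(sub.affine)

    support = ndimage.binary_dilation(tmp.data > 0, iterations=cfg.support_dilation_vox)
    p = _pack(t0, np.zeros(3), np.zeros(3))
    levels = list(cfg.pyramid) + ([1] if cfg.final_full_res else [])
    last_fun = np.inf
    for level in levels:
        sigma = cfg.smooth_sigma_vox * level
        tmp_s = _smoothed(tmp.data > 0, sigma)
        sub_s = _smoothed(sub.data > 0, sigma)
        idx = np.argwhere(support)[:: max(level, 2) ** 3]
        # deterministic stride subsample of the support for this level
        pts_world = tmp.voxel_to_world(idx)
        tmp_vals = tmp_s[tuple(idx.T)]

        def ssd(params: np.ndarray) -> float:
            A = _unpack(params, center)
            y = A.apply(pts_world)
            vox = y @ sub_inv[:3, :3].T + sub_inv[:3, 3]
            vals = ndimage.map_coordinates(sub_s, vox.T, order=1, mode="constant", cval=0.0)
            return float(np.mean((tmp_vals - vals) ** 2))

        res = optimize.minimize(
            ssd,
            p,
            method="Powell",
            options={
                "maxiter": cfg.maxiter_full if level == 1 else cfg.maxiter,
                "xtol": cfg.xtol,
                "ftol": 1e-8,
            },
        )
        p, last_fun = res.x, float(res.fun)
    out = _unpack(p, center)
    # sanity: the optimum must overlap the masks at all
    if last_fun >= float(np.mean(tmp_s[tuple(np.argwhere(support).T)] ** 2)):
        raise RegistrationError("affine registration failed to find mask overlap")
    return out


# --------------------------------------------------------------------------
def nmi(x: np.ndarray, y: np.ndarray, bins: int = 32, smooth: float = 1.0) -> float:
    """Normalized mutual information (Hx + Hy) / Hxy of two samples.

    The joint histogram is lightly Gaussian-smoothed (Parzen-style) so the
    measure is continuous under small deformations.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.std() == 0 or y.std() == 0:
        raise RegistrationError("NMI undefined for a constant image")
    h, _, _ = np.histogram2d(x, y, bins=bins)
    if smooth > 0:
        h = ndimage.gaussian_filter(h, smooth)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    return float((ent(px) + ent(py)) / ent(p.ravel()))


@dataclass(frozen=True)
class NonrigidConfig:
    control_knots: int = 3            # control grid per axis
    nmi_bins: int = 32
    regularization_weight: float = 1e-4   # NMI changes are O(1e-3); keep the
                                          # bending penalty subdominant
    max_outer: int = 2
    powell_maxiter: int = 1
    sample_stride: int = 3
    max_displacement_mm: float = 8.0
    fov_threshold: float | None = None  # restrict NMI samples to template > thr


def _upsample_control(ctrl: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear (order-1 B-spline) upsampling of the control grid."""
    g = ctrl.shape[1]
    coords = np.stack(
        np.meshgrid(*[np.linspace(0, g - 1, s) for s in shape], indexing="ij"), axis=0
    )
    return np.stack(
        [ndimage.map_coordinates(ctrl[k], coords, order=1, mode="nearest") for k in range(3)]
    )


def nonrigid_refine(
    subject_ct: Volume,
    template_ct: Volume,
    init: AffineTransform,
    config: NonrigidConfig | None = None,
) -> DeformationField:
    """Refine an affine pre-alignment with a coarse free-form deformation.

    Control-point displacements (order-1 B-spline grid) are optimized to
    maximize the NMI between the template and the deformed subject, with a
    second-difference (bending) penalty.  NMI over the outer iterations is
    nondecreasing: an outer step that does not improve the objective is
    rejected and the search stops.
    """
    cfg = config or NonrigidConfig()
    g = cfg.control_knots
    stride = cfg.sample_stride
    fov = (
        np.ones(template_ct.shape, dtype=bool)
        if cfg.fov_threshold is None
        else template_ct.data > cfg.fov_threshold
    )
    idx = np.argwhere(fov)[:: stride**3]
    pts_world = template_ct.voxel_to_world(idx)
    tmp_vals = template_ct.data[tuple(idx.T)]
    if tmp_vals.std() == 0:
        raise RegistrationError("NMI undefined for a constant template")
    sub_inv = np.linalg.inv(subject_ct.affine)
    shape = template_ct.shape
    # control-point world positions span the template grid
    ctrl_vox = np.stack(
        np.meshgrid(*[np.linspace(0, s - 1, g) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    ctrl_world = template_ct.voxel_to_world(ctrl_vox)

    def disp_at(pts: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
        # trilinear weights from template voxel coords scaled to control grid
        inv = np.linalg.inv(template_ct.affine)
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        cc = vox / (np.asarray(shape) - 1) * (g - 1)
        out = np.empty_like(pts)
        for k in range(3):
            out[:, k] = ndimage.map_coordinates(ctrl[k], cc.T, order=1, mode="nearest")
        return out

    def objective(flat: np.ndarray) -> float:
        ctrl = np.clip(flat.reshape(3, g, g, g), -cfg.max_displacement_mm, cfg.max_displacement_mm)
        y = init.apply(pts_world) + disp_at(pts_world, ctrl)
        vox = y @ sub_inv[:3, :3].T + sub_inv[:3, 3]
        vals = ndimage.map_coordinates(subject_ct.data, vox.T, order=1, mode="nearest")
        bend = sum(
            np.mean(np.diff(ctrl[k], n=2, axis=ax) ** 2) for k in range(3) for ax in range(3)
        )
        return -nmi(tmp_vals, vals, cfg.nmi_bins) + cfg.regularization_weight * bend

    ctrl = np.zeros(3 * g**3)
    best = objective(ctrl)
    for _ in range(cfg.max_outer):
        res = optimize.minimize(
            objective, ctrl, method="Powell",
            options={"maxiter": cfg.powell_maxiter, "xtol": 1e-3, "ftol": 1e-6},
        )
        if res.fun < best - 1e-12:
            ctrl, best = res.x, float(res.fun)
        else:
            break
    dense = _upsample_control(
        np.clip(ctrl.reshape(3, g, g, g), -cfg.max_displacement_mm, cfg.max_displacement_mm),
        shape,
    )
    return DeformationField(dense, template_ct.affine.copy(), cfg.regularization_weight)


# --------------------------------------------------------------------------
def transport(
    volume: Volume,
    affine: AffineTransform,
    deformation: DeformationField | None = None,
    direction: str = "inverse",
    interpolation: str = "linear",
    reference: Volume | None = None,
) -> Volume:
    """Resample a volume across the template/subject spaces.

    direction="forward": input lives in subject space; output on the template
    grid (``reference`` = a template-space volume), sampling the input at
    ``phi(x) = A(x) + d(x)``.

    direction="inverse": input lives in template space; output on the subject
    grid (``reference`` = a subject-space volume), sampling at ``phi^{-1}(y)``
    (exact for the affine; fixed-point iteration when a deformation is set).

    ``interpolation`` is "nearest" for labels/masks and "linear" for
    intensities and probabilities.
    """
    if reference is None:
        raise ValueError("transport needs a reference volume defining the output grid")
    order = {"nearest": 0, "linear": 1}[interpolation]
    shape = reference.shape
    ijk = np.argwhere(np.ones(shape, dtype=bool))
    world = reference.voxel_to_world(ijk)
    if direction == "forward":
        y = affine.apply(world)
        if deformation is not None:
            y = y + deformation.sample(world)
    elif direction == "inverse":
        x = affine.apply_inverse(world)
        if deformation is not None:
            for _ in range(5):
                x = affine.apply_inverse(world - deformation.sample(x))
        y = x
    else:
        raise ValueError(f"unknown direction {direction!r}")
    inv = np.linalg.inv(volume.affine)
    vox = y @ inv[:3, :3].T + inv[:3, 3]
    dtype = volume.data.dtype
    src = volume.data if order == 0 else volume.data.astype(np.float64)
    out = ndimage.map_coordinates(src, vox.T, order=order, mode="constant", cval=0.0)
    out = out.reshape(shape)
    if order == 0:
        out = out.astype(dtype)
    return Volume(out, reference.affine.copy())


def zscore_brain(ct: Volume, brain_mask: BrainMask | Volume, fill: float = 0.0) -> Volume:
    """Z-score the CT intensities over the brain voxels; fill elsewhere."""
    m = (brain_mask.mask if isinstance(brain_mask, BrainMask) else brain_mask).data.astype(bool)
    if m.sum() < 2:
        raise ValueError("brain mask too small for z-scoring")
    vals = ct.data[m]
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero intensity variance inside the brain mask")
    out = np.full(ct.shape, float(fill))
    out[m] = (vals - vals.mean()) / sd
    return ct.like(out)
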