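"""Synthetic head-CT phantom generator.

The phantom emulates the statistical structure the grading pipeline relies on:
a bright skull shell around a brain compartment, ventricular and sulcal CSF, a
sulcal CSF rim that widens with global cortical atrophy, bilateral
medial-temporal CSF pockets that grow with medial-temporal-lobe atrophy, and
deep-white-matter lesion blobs whose total volume grows with the
white-matter-lesion (Fazekas) load.  CT-like pseudo-Hounsfield intensities
(bone >> parenchyma > lesion > CSF >> air) plus additive Gaussian noise give
the intensity contrast the skull stripper and segmenter see on real scans.

Severity parameters map *linearly* to structure volumes by construction, so
calibration recovery downstream is well-posed.  Geometry is analytic
(ellipsoids evaluated on a rigidly posed coordinate grid), which keeps
generation exact, fast and dependency-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import Volume

__all__ = [
    "LABELS",
    "PhantomSpec",
    "PhantomPair",
    "CohortSampler",
    "make_phantom",
    "make_cohort",
    "brain_mask_from_labels",
]

# Integer label codes of the ground-truth volume.
LABELS = {"air": 0, "skull": 1, "gm": 2, "wm": 3, "csf": 4, "wml": 5}

# Default pseudo-Hounsfield class intensities.
DEFAULT_INTENSITIES = {
    "air": -1000.0,
    "skull": 900.0,
    "gm": 38.0,
    "wm": 30.0,
    "csf": 8.0,
    "wml": 20.0,
}

# --- fixed geometry of the head model (mm, head-centred coordinates) -------
SKULL_OUTER = (25.0, 29.0, 24.0)
SKULL_INNER = (22.0, 26.0, 21.0)          # intracranial cavity
# solid protrusions (occipital and nasofrontal) that make the skull shape
# chiral, like a real head -- without them an ellipsoidal shell is nearly
# invariant under 90-degree axis swaps and mask registration is ambiguous
SKULL_BUMPS = (
    ((0.0, -26.0, -6.0), (8.0, 6.0, 6.0)),
    ((0.0, 26.0, -11.0), (6.0, 6.0, 5.0)),
)
PARENCHYMA_FRAC0 = 0.94                    # cavity volume fraction at gca=0
PARENCHYMA_FRAC_SLOPE = 0.015              # uniform fraction lost per gca grade
# sulcal grooves: fixed radial slabs carved into the outer parenchyma shell,
# deepening with cortical atrophy.  Real sulci widen locally by millimetres,
# so the atrophy signal must be supra-voxel somewhere, not a uniform
# sub-voxel shift of the whole brain surface.
SULCUS_PLANES = (                          # (unit normal, offset mm)
    ((1.0, 0.0, 0.0), 0.0),               # interhemispheric analog
    ((0.924, 0.383, 0.0), 8.0),
    ((0.383, 0.924, 0.0), -6.0),
    ((-0.383, 0.924, 0.0), 6.0),
    ((0.707, 0.0, 0.707), -9.0),
    ((0.0, 0.707, 0.707), 9.0),
    ((0.924, -0.383, 0.0), -10.0),
    ((0.0, 0.924, -0.383), -4.0),
)
SULCUS_WIDTH_MM = 1.6
SULCUS_DEPTH0_MM = 1.0                     # groove depth at gca = 0
SULCUS_DEPTH_SLOPE_MM = 1.5                # added depth per gca grade
WM_FRAC = 0.70                             # of parenchyma volume
VENTRICLE_CENTERS = ((-6.0, 0.0, 2.0), (6.0, 0.0, 2.0))
VENTRICLE_AXES = (3.2, 9.0, 3.2)
MTL_CENTERS = {"left": (-13.0, -4.0, -11.0), "right": (13.0, -4.0, -11.0)}
MTL_ASPECT = (1.0, 1.4, 1.0)
MTL_BASE_MM3 = 30.0                        # pocket volume at severity 0
MTL_SLOPE_MM3 = 90.0                       # added volume per severity grade
WML_CENTERS = (
    (-9.5, 8.0, 3.0),
    (9.5, 8.0, 3.0),
    (-9.5, -8.0, 3.0),
    (9.5, -8.0, 3.0),
    (0.0, 0.0, 10.0),
)
WML_SHARES = (0.30, 0.25, 0.20, 0.15, 0.10)
WML_SLOPE_MM3 = 180.0                      # total lesion volume per grade
MTL_MASK_RADIUS_MM = 7.0
DEEP_WM_RADIUS_MM = 6.5
# lobe split planes (mm): anterior = frontal, posterior = occipital,
# inferior middle = temporal, superior middle = parietal
LOBE_Y_FRONTAL = 7.0
LOBE_Y_OCCIPITAL = -13.0
LOBE_Z_TEMPORAL = -6.0
LOBE_CODES = {"frontal": 1, "temporal": 2, "parietal": 3, "occipital": 4}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head.

    Severities are continuous: ``mta_left``/``mta_right`` in [0, 4],
    ``gca`` and ``fazekas`` in [0, 3].  ``pose`` is a small rigid perturbation
    (tx, ty, tz in voxels; rx, ry, rz in degrees); ``head_scale`` is an
    isotropic size factor, giving the cohort the scale variability a
    9-parameter affine registration must recover.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float | tuple[float, float, float] = 1.0
    mta_left: float = 0.0
    mta_right: float = 0.0
    gca: float = 0.0
    fazekas: float = 0.0
    noise_sd: float = 10.0
    rng_seed: int = 0
    pose: tuple[float, float, float, float, float, float] = (0, 0, 0, 0, 0, 0)
    head_scale: float = 1.0
    intensities: tuple[tuple[str, float], ...] = tuple(DEFAULT_INTENSITIES.items())

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("mta_left", 0, 4), ("mta_right", 0, 4), ("gca", 0, 3), ("fazekas", 0, 3),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(s < 32 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 32 per axis")
        if not (0.8 <= self.head_scale <= 1.25):
            raise ValueError("head_scale outside supported range [0.8, 1.25]")

    @property
    def spacing(self) -> np.ndarray:
        v = self.voxel_size_mm
        return np.asarray(v if np.ndim(v) else (v, v, v), dtype=float)

    @property
    def affine(self) -> np.ndarray:
        sp = self.spacing
        a = np.diag([*sp, 1.0])
        a[:3, 3] = -sp * (np.asarray(self.grid_shape) - 1) / 2.0
        return a


@dataclass
class PhantomPair:
    """A CT-like volume, its ground-truth labels and the true measures."""

    ct: Volume
    labels: Volume
    truth: dict[str, float]
    spec: PhantomSpec

    def brain_mask(self) -> np.ndarray:
        return brain_mask_from_labels(self.labels.data)


def brain_mask_from_labels(labels: np.ndarray) -> np.ndarray:
    """Brain = parenchyma plus intracranial CSF and lesions."""
    return np.isin(labels, [LABELS["gm"], LABELS["wm"], LABELS["csf"], LABELS["wml"]])


# --------------------------------------------------------------------------
def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rz @ Ry @ Rx with angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _head_coords(spec: PhantomSpec) -> np.ndarray:
    """World coordinates of every voxel, pulled back into head-model space.

    The rigid pose and isotropic head scale act on the head, so the model is
    evaluated at q = (R (p - t)) / s for grid point p.
    """
    shape = spec.grid_shape
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    world = ijk * spec.spacing + spec.affine[:3, 3]
    t = np.asarray(spec.pose[:3], dtype=float) * spec.spacing
    R = _rotation_matrix(*spec.pose[3:])
    return (world - t) @ R / spec.head_scale  # (p-t) @ R == R^T . (p-t) rows


def _inside(q: np.ndarray, center, axes) -> np.ndarray:
    d = (q - np.asarray(center, float)) / np.asarray(axes, float)
    return (d ** 2).sum(axis=-1) <= 1.0


def _ellipsoid_axes_for_volume(volume_mm3: float, aspect) -> np.ndarray:
    """Semi-axes r*aspect such that the ellipsoid volume equals volume_mm3."""
    aspect = np.asarray(aspect, float)
    r3 = volume_mm3 / (4.0 / 3.0 * np.pi * aspect.prod())
    return max(r3, 0.0) ** (1.0 / 3.0) * aspect


def structure_regions(spec: PhantomSpec, q: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Geometric region masks (maximum-extent) used for ground truth and for
    the synthetic template masks: per-hemisphere MTL spheres, deep-WM spheres
    around the lesion sites, and the four lobe sectors."""
    if q is None:
        q = _head_coords(spec)
    out: dict[str, np.ndarray] = {}
    for hemi, c in MTL_CENTERS.items():
        out[f"mtl_{hemi}"] = _inside(q, c, (MTL_MASK_RADIUS_MM,) * 3)
    deep = np.zeros(q.shape[:-1], dtype=bool)
    for c in WML_CENTERS:
        deep |= _inside(q, c, (DEEP_WM_RADIUS_MM,) * 3)
    out["deep_wm"] = deep
    lobes = np.zeros(q.shape[:-1], dtype=np.int16)
    y, z = q[..., 1], q[..., 2]
    lobes[y >= LOBE_Y_FRONTAL] = LOBE_CODES["frontal"]
    lobes[y <= LOBE_Y_OCCIPITAL] = LOBE_CODES["occipital"]
    mid = (y < LOBE_Y_FRONTAL) & (y > LOBE_Y_OCCIPITAL)
    lobes[mid & (z <= LOBE_Z_TEMPORAL)] = LOBE_CODES["temporal"]
    lobes[mid & (z > LOBE_Z_TEMPORAL)] = LOBE_CODES["parietal"]
    out["lobes"] = lobes
    return out


def make_phantom(spec: PhantomSpec) -> PhantomPair:
    """Generate one phantom head: labels, CT-like intensities and truth.

    Deterministic given ``spec.rng_seed``.
    """
    q = _head_coords(spec)
    L = LABELS
    labels = np.zeros(spec.grid_shape, dtype=np.int16)

    skull = _inside(q, (0, 0, 0), SKULL_OUTER) & ~_inside(q, (0, 0, 0), SKULL_INNER)
    cavity = _inside(q, (0, 0, 0), SKULL_INNER)
    for c, axes in SKULL_BUMPS:
        skull |= _inside(q, c, axes) & ~cavity
    par_frac = PARENCHYMA_FRAC0 - PARENCHYMA_FRAC_SLOPE * spec.gca
    s_par = par_frac ** (1.0 / 3.0)
    parenchyma = _inside(q, (0, 0, 0), np.asarray(SKULL_INNER) * s_par)
    s_wm = s_par * WM_FRAC ** (1.0 / 3.0)
    wm = _inside(q, (0, 0, 0), np.asarray(SKULL_INNER) * s_wm)

    labels[skull] = L["skull"]
    labels[cavity & ~parenchyma] = L["csf"]          # sulcal rim
    labels[parenchyma] = L["gm"]
    labels[wm] = L["wm"]

    # sulcal grooves deepening with cortical atrophy (kept out of the
    # medial-temporal region, whose CSF is governed by the MTA severities)
    par_axes = np.asarray(SKULL_INNER) * s_par
    rho = np.sqrt(((q / par_axes) ** 2).sum(axis=-1))
    depth = SULCUS_DEPTH0_MM + SULCUS_DEPTH_SLOPE_MM * spec.gca
    rho_min = 1.0 - depth / float(np.mean(par_axes))
    shell = parenchyma & (rho > rho_min)
    mtl_protect = np.zeros(spec.grid_shape, dtype=bool)
    for c in MTL_CENTERS.values():
        mtl_protect |= _inside(q, c, (MTL_MASK_RADIUS_MM + 2.0,) * 3)
    for normal, offset in SULCUS_PLANES:
        slab = np.abs(q @ np.asarray(normal) - offset) < SULCUS_WIDTH_MM / 2.0
        labels[slab & shell & ~mtl_protect] = L["csf"]

    for c in VENTRICLE_CENTERS:
        labels[_inside(q, c, VENTRICLE_AXES)] = L["csf"]

    for hemi, sev in (("left", spec.mta_left), ("right", spec.mta_right)):
        vol = MTL_BASE_MM3 + MTL_SLOPE_MM3 * sev
        axes = _ellipsoid_axes_for_volume(vol, MTL_ASPECT)
        pocket = _inside(q, MTL_CENTERS[hemi], axes) & parenchyma
        labels[pocket] = L["csf"]

    total_wml = WML_SLOPE_MM3 * spec.fazekas
    if total_wml > 0:
        for c, share in zip(WML_CENTERS, WML_SHARES):
            axes = _ellipsoid_axes_for_volume(total_wml * share, (1, 1, 1))
            blob = _inside(q, c, axes) & (labels == L["wm"])
            labels[blob] = L["wml"]

    inten = dict(spec.intensities)
    ct = np.full(spec.grid_shape, inten["air"], dtype=np.float64)
    for name, code in L.items():
        if name != "air":
            ct[labels == code] = inten[name]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        ct = ct + rng.normal(0.0, spec.noise_sd, size=ct.shape)

    truth = _truth_measures(spec, labels, q)
    aff = spec.affine
    return PhantomPair(ct=Volume(ct, aff), labels=Volume(labels, aff), truth=truth, spec=spec)


def _truth_measures(spec: PhantomSpec, labels: np.ndarray, q: np.ndarray) -> dict[str, float]:
    L = LABELS
    regions = structure_regions(spec, q)
    vox = float(np.prod(spec.spacing))
    brain = brain_mask_from_labels(labels)
    brain_ml = brain.sum() * vox / 1000.0
    if brain_ml <= 0:
        raise RuntimeError("phantom generated an empty brain")
    csf = labels == L["csf"]
    wml = labels == L["wml"]
    n_brain = brain.sum()
    truth = {
        "mta_left": spec.mta_left,
        "mta_right": spec.mta_right,
        "gca": spec.gca,
        "fazekas": spec.fazekas,
        "mta_left_raw": (csf & regions["mtl_left"]).sum() / n_brain,
        "mta_right_raw": (csf & regions["mtl_right"]).sum() / n_brain,
        "gca_raw": csf.sum() / n_brain,
        "fazekas_raw": (wml & regions["deep_wm"]).sum() / n_brain,
        "brain_volume_ml": brain_ml,
    }
    for lobe, code in LOBE_CODES.items():
        truth[f"gca_{lobe}_raw"] = (csf & (regions["lobes"] == code)).sum() / n_brain
    return {k: float(v) for k, v in truth.items()}


# --------------------------------------------------------------------------
@dataclass(frozen=True)
class CohortSampler:
    """Uniform severity/pose sampler for synthetic cohorts.

    Ranges default to the full grade scales; pose and head-scale ranges are
    small, as expected after scanner positioning.
    """

    mta_range: tuple[float, float] = (0.0, 4.0)
    gca_range: tuple[float, float] = (0.0, 3.0)
    fazekas_range: tuple[float, float] = (0.0, 3.0)
    translation_vox: float = 3.0
    rotation_deg: float = 8.0
    head_scale_range: tuple[float, float] = (0.97, 1.03)
    randomize_pose: bool = True

    def draw(self, rng: np.random.Generator) -> dict:
        pose = (0.0,) * 6
        scale = 1.0
        if self.randomize_pose:
            t = rng.uniform(-self.translation_vox, self.translation_vox, 3)
            r = rng.uniform(-self.rotation_deg, self.rotation_deg, 3)
            pose = tuple(np.concatenate([t, r]))
            scale = float(rng.uniform(*self.head_scale_range))
        return {
            "mta_left": float(rng.uniform(*self.mta_range)),
            "mta_right": float(rng.uniform(*self.mta_range)),
            "gca": float(rng.uniform(*self.gca_range)),
            "fazekas": float(rng.uniform(*self.fazekas_range)),
            "pose": pose,
            "head_scale": scale,
        }


def make_cohort(
    n: int,
    sampler: CohortSampler | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[PhantomPair], pd.DataFrame]:
    """Generate ``n`` phantoms with sampled severities and a cohort table.

    The table (one row per subject: severities, ground-truth measures) is the
    training input for grade calibration.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = sampler or CohortSampler()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    pairs: list[PhantomPair] = []
    rows: list[dict] = []
    for i in range(n):
        draw = sampler.draw(rng)
        spec = replace(base, rng_seed=int(rng.integers(0, 2**31 - 1)), **draw)
        pair = make_phantom(spec)
        pairs.append(pair)
        rows.append({"subject_id": f"sub-{i:03d}", **pair.truth})
    return pairs, pd.DataFrame(rows)


def write_cohort(pairs: list[PhantomPair], table: pd.DataFrame, out_dir: str | Path) -> None:
    """Write NIfTI pairs and the cohort CSV to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, pair in zip(table["subject_id"], pairs):
        pair.ct.save(out / f"{sid}_ct.nii.gz")
        pair.labels.save(out / f"{sid}_labels.nii.gz")
    table.to_csv(out / "cohort.csv", index=False)
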