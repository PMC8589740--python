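"""Brain extraction from head CT by two-class expectation-maximization.

The extractor runs five steps: (1) nonlocal-means denoising, (2) outlier
intensity clipping, (3) two-class EM intensity classification with fixed
mixing priors (soft tissue vs. bone), (4) derivation of a skull intensity
threshold from the fitted mixture, and (5) morphological fine-tuning of the
brain mask (opening, largest connected component, closing, hole filling).

Air is excluded up front with a fixed Hounsfield cutoff, so the mixture only
has to separate intracranial soft tissue from bone — on CT those classes are
hundreds of HU apart, which is what makes the simple two-class model work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.restoration import denoise_nl_means, estimate_sigma

from .volume import Volume

__all__ = [
    "SkullStripConfig",
    "EMModel",
    "BrainMask",
    "SkullStripResult",
    "denoise_nlm",
    "remove_outliers",
    "em_two_class",
    "skull_threshold_from_em",
    "refine_mask_morphology",
    "skull_strip",
]


class ExtractionError(RuntimeError):
    """Brain extraction failed (empty field of view, degenerate EM, ...)."""


@dataclass(frozen=True)
class SkullStripConfig:
    air_threshold_hu: float = -200.0
    denoise: str = "nlm"                 # "nlm" | "none"
    nlm_patch_radius: int = 1
    nlm_search_radius: int = 3
    nlm_h: float | None = None           # None -> 0.8 * estimated noise sigma
    outlier_percentiles: tuple[float, float] = (0.1, 99.9)
    em_priors: tuple[float, float] = (0.5, 0.5)
    em_max_iter: int = 50
    em_tol: float = 1e-6
    threshold_margin_hu: float = 0.0     # shift of the skull threshold toward bone
    fallback_threshold_hu: float = 200.0
    morph_radius: int = 2


@dataclass
class EMModel:
    """Fitted two-class Gaussian mixture with frozen mixing proportions."""

    class_means: np.ndarray
    class_sds: np.ndarray
    class_priors: np.ndarray
    loglik_history: list[float] = field(default_factory=list)
    n_iter: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(np.sum(self.class_priors), 1.0):
            raise ValueError("priors must sum to 1")
        if np.any(np.asarray(self.class_sds) <= 0):
            raise ValueError("class SDs must be positive")


@dataclass
class BrainMask:
    mask: Volume
    brain_volume_ml: float


@dataclass
class SkullStripResult:
    brain: BrainMask
    skull_mask: Volume
    em: EMModel
    skull_threshold_hu: float
    log: dict


# -- step 1 -----------------------------------------------------------------
def denoise_nlm(
    ct: Volume, patch_radius: int = 1, search_radius: int = 3, h: float | None = None
) -> Volume:
    """Edge-preserving nonlocal-means smoothing of the CT intensities."""
    if ct.data.ndim != 3:
        raise ValueError("expected a 3D volume")
    if h is not None and h <= 0:
        return ct.copy()
    data = ct.data.astype(np.float32)
    sigma = float(estimate_sigma(data))
    hval = 0.8 * sigma if h is None else float(h)
    if hval <= 0 or sigma == 0:
        return ct.copy()
    out = denoise_nl_means(
        data,
        patch_size=2 * patch_radius + 1,
        patch_distance=search_radius,
        h=hval,
        sigma=sigma,
        fast_mode=True,
        preserve_range=True,
    )
    return ct.like(out.astype(np.float64))


# -- step 2 -----------------------------------------------------------------
def remove_outliers(
    ct: Volume, low_pct: float = 0.1, high_pct: float = 99.9, fov_mask: np.ndarray | None = None
) -> Volume:
    """Clip in-field intensities to a percentile range.

    Percentiles are computed over the field of view (non-air voxels); voxels
    outside the field of view are left untouched.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low < high <= 100")
    if fov_mask is None:
        fov_mask = np.ones(ct.shape, dtype=bool)
    if not fov_mask.any():
        raise ExtractionError("empty field of view")
    vals = ct.data[fov_mask]
    lo, hi = np.percentile(vals, [low_pct, high_pct])
    out = ct.data.copy()
    out[fov_mask] = np.clip(vals, lo, hi)
    return ct.like(out)


# -- step 3 -----------------------------------------------------------------
def em_two_class(
    ct: Volume,
    priors: tuple[float, float] = (0.5, 0.5),
    init: tuple[np.ndarray, np.ndarray] | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    fov_mask: np.ndarray | None = None,
) -> tuple[EMModel, tuple[Volume, Volume]]:
    """Two-class Gaussian EM with fixed priors over the field of view.

    Only class means and SDs are updated; the mixing proportions stay frozen.
    Returns the fitted model (with its log-likelihood trace) and per-voxel
    posterior volumes that sum to one inside the field of view.
    """
    if fov_mask is None:
        fov_mask = np.ones(ct.shape, dtype=bool)
    x = ct.data[fov_mask].astype(np.float64)
    if x.size < 2 or np.var(x) == 0:
        raise ExtractionError("degenerate intensity distribution: EM cannot separate classes")
    pri = np.asarray(priors, dtype=float)
    if init is None:
        means = np.percentile(x, [25.0, 75.0]).astype(float)
        if means[0] == means[1]:
            means = np.array([x.min(), x.max()], dtype=float)
        sds = np.full(2, max(x.std() / 2.0, 1e-3))
    else:
        means = np.asarray(init[0], dtype=float).copy()
        sds = np.asarray(init[1], dtype=float).copy()
    loglik_history: list[float] = []
    prev = -np.inf
    resp = None
    for it in range(max_iter):
        logp = np.empty((2, x.size))
        for k in range(2):
            logp[k] = (
                np.log(pri[k])
                - 0.5 * np.log(2 * np.pi * sds[k] ** 2)
                - 0.5 * ((x - means[k]) / sds[k]) ** 2
            )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        loglik_history.append(ll)
        resp = np.exp(logp - lse)
        if ll - prev < tol * abs(prev) and it > 0:
            break
        prev = ll
        for k in range(2):
            w = resp[k]
            wsum = w.sum()
            if wsum <= 0:
                raise ExtractionError("EM class collapsed to zero responsibility")
            means[k] = (w * x).sum() / wsum
            var = (w * (x - means[k]) ** 2).sum() / wsum
            sds[k] = np.sqrt(max(var, 1e-6))
    order = np.argsort(means)
    means, sds = means[order], sds[order]
    pri_sorted = pri[order]
    resp = resp[order]
    post = []
    for k in range(2):
        vol = np.zeros(ct.shape)
        vol[fov_mask] = resp[k]
        post.append(ct.like(vol))
    model = EMModel(means, sds, pri_sorted, loglik_history, n_iter=len(loglik_history))
    return model, (post[0], post[1])


# -- step 4 -----------------------------------------------------------------
def skull_threshold_from_em(
    model: EMModel, margin: float = 0.0, fallback: float = 200.0
) -> float:
    """Intensity above which a voxel is called bone.

    The default rule is the equal-posterior crossing of the two fitted
    Gaussians (root of the posterior-equality quadratic between the class
    means), shifted toward bone by ``margin``.  If the classes are not
    separable the fixed HU ``fallback`` is returned with a warning.
    """
    (m1, m2), (s1, s2) = model.class_means, model.class_sds
    p1, p2 = model.class_priors
    if not (m2 > m1) or (m2 - m1) < 1e-6 * max(s1, s2, 1.0):
        warnings.warn("EM classes not separable; using fallback skull threshold")
        return float(fallback)
    a = 0.5 / s2**2 - 0.5 / s1**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        0.5 * m2**2 / s2**2
        - 0.5 * m1**2 / s1**2
        + np.log((p1 * s2) / (p2 * s1))
    )
    if abs(a) < 1e-12:
        roots = np.array([-c / b]) if b != 0 else np.array([])
    else:
        disc = b**2 - 4 * a * c
        if disc < 0:
            roots = np.array([])
        else:
            roots = (-b + np.array([-1.0, 1.0]) * np.sqrt(disc)) / (2 * a)
    between = [r for r in np.atleast_1d(roots) if m1 <= r <= m2]
    if not between:
        warnings.warn("no posterior crossing between class means; using fallback")
        return float(fallback)
    return float(between[0] + margin)


# -- step 5 -----------------------------------------------------------------
def refine_mask_morphology(raw_mask: Volume, radius: int = 2) -> BrainMask:
    """Open -> largest connected component -> close -> hole fill."""
    m = raw_mask.data.astype(bool)
    if not m.any():
        raise ExtractionError("empty raw mask")
    se = ball(radius)
    m = ndimage.binary_opening(m, structure=se)
    if not m.any():
        raise ExtractionError("mask vanished during morphological opening")
    lab, n = ndimage.label(m)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        m = lab == (1 + int(np.argmax(sizes)))
    m = ndimage.binary_closing(m, structure=se)
    m = ndimage.binary_fill_holes(m)
    vol = Volume(m, raw_mask.affine)
    return BrainMask(mask=vol, brain_volume_ml=float(m.sum() * vol.voxel_volume_mm3 / 1000.0))


# -- composition ------------------------------------------------------------
def skull_strip(ct: Volume, config: SkullStripConfig | None = None) -> SkullStripResult:
    """Run the five-step EM brain extraction on a head CT volume."""
    cfg = config or SkullStripConfig()
    fov = ct.data > cfg.air_threshold_hu
    if not fov.any():
        raise ExtractionError("no voxels above the air threshold: not a head CT?")
    log: dict = {"n_fov": int(fov.sum())}
    if cfg.denoise == "nlm":
        sm = denoise_nlm(ct, cfg.nlm_patch_radius, cfg.nlm_search_radius, cfg.nlm_h)
    elif cfg.denoise == "none":
        sm = ct
    else:
        raise ValueError(f"unknown denoise mode {cfg.denoise!r}")
    clipped = remove_outliers(sm, *cfg.outlier_percentiles, fov_mask=fov)
    model, _post = em_two_class(
        clipped, cfg.em_priors, max_iter=cfg.em_max_iter, tol=cfg.em_tol, fov_mask=fov
    )
    thr = skull_threshold_from_em(model, cfg.threshold_margin_hu, cfg.fallback_threshold_hu)
    raw_brain = fov & (clipped.data < thr)
    if not raw_brain.any():
        raise ExtractionError("no sub-threshold voxels inside the field of view")
    brain = refine_mask_morphology(ct.like(raw_brain), cfg.morph_radius)
    # the brain mask must not retain bone voxels picked up by closing
    final = brain.mask.data & (clipped.data < thr)
    brain = BrainMask(
        mask=Volume(final, ct.affine),
        brain_volume_ml=float(final.sum() * ct.voxel_volume_mm3 / 1000.0),
    )
    skull = Volume(fov & (clipped.data >= thr), ct.affine)
    log.update(
        em_means=model.class_means.tolist(),
        em_sds=model.class_sds.tolist(),
        skull_threshold_hu=thr,
        brain_volume_ml=brain.brain_volume_ml,
        n_skull=int(skull.data.sum()),
    )
    return SkullStripResult(brain=brain, skull_mask=skull, em=model, skull_threshold_hu=thr, log=log)
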