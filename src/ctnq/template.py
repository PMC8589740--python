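"""Template bundle: mean CT, masks, lobe labels and the CSF percentile map.

The bundle is the set of template-space reference data the pipeline
transports to each subject: a mean-intensity CT template with its skull mask,
binary medial-temporal-lobe (left/right) and deep-white-matter masks, a
frontal/temporal/parietal/occipital lobe label map extended into peripheral
CSF, and the voxelwise 99th percentile of CSF concentration over a reference
cohort.  Voxels where a subject's CSF probability exceeds that percentile map
are read as abnormal CSF, i.e. atrophy.

At desk scale the bundle is built from aligned synthetic phantoms; the
downstream contract (one grid, one manifest, the same roles) is what the
pipeline depends on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import phantom as ph
from .volume import Volume

__all__ = [
    "TemplateBundle",
    "build_mean_template",
    "build_csf_percentile_map",
    "build_lobe_labels",
    "draw_synthetic_masks",
    "build_synthetic_bundle",
]

LOBE_NAMES = {v: k for k, v in ph.LOBE_CODES.items()}


@dataclass
class TemplateBundle:
    mean_ct: Volume
    skull_mask: Volume
    brain_mask: Volume
    mtl_left_mask: Volume
    mtl_right_mask: Volume
    deep_wm_mask: Volume
    lobe_labels: Volume
    csf_p99: Volume
    provenance: dict

    _VOLUMES = (
        ("mean_ct", "linear"),
        ("skull_mask", "nearest"),
        ("brain_mask", "nearest"),
        ("mtl_left_mask", "nearest"),
        ("mtl_right_mask", "nearest"),
        ("deep_wm_mask", "nearest"),
        ("lobe_labels", "nearest"),
        ("csf_p99", "linear"),
    )

    def validate(self) -> None:
        ref = self.mean_ct
        for name, _ in self._VOLUMES:
            v: Volume = getattr(self, name)
            if not v.same_grid(ref):
                raise ValueError(f"bundle volume {name!r} is not on the template grid")
        p99 = self.csf_p99.data
        if p99.min() < -1e-9 or p99.max() > 1 + 1e-9:
            raise ValueError("csf_p99 must lie in [0, 1]")
        labs = np.unique(self.lobe_labels.data)
        if not set(labs.tolist()) <= {0, 1, 2, 3, 4}:
            raise ValueError("lobe_labels must use codes 0..4")
        skull = self.skull_mask.data.astype(bool)
        for name in ("mtl_left_mask", "mtl_right_mask", "deep_wm_mask"):
            if (getattr(self, name).data.astype(bool) & skull).any():
                raise ValueError(f"{name} overlaps the skull")

    # -- I/O ----------------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {"volumes": {}, "provenance": self.provenance}
        for name, interp in self._VOLUMES:
            fn = f"{name}.nii.gz"
            getattr(self, name).save(out / fn)
            digest = hashlib.sha256((out / fn).read_bytes()).hexdigest()[:16]
            manifest["volumes"][name] = {"file": fn, "interpolation": interp, "sha256": digest}
        (out / "bundle.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TemplateBundle":
        src = Path(in_dir)
        manifest = json.loads((src / "bundle.json").read_text())
        kwargs = {
            name: Volume.load(src / meta["file"])
            for name, meta in manifest["volumes"].items()
        }
        bundle = cls(provenance=manifest.get("provenance", {}), **kwargs)
        bundle.validate()
        return bundle


def build_mean_template(aligned_cts: list[Volume]) -> Volume:
    """Voxelwise mean of pre-aligned CT volumes (NaN-aware)."""
    if len(aligned_cts) < 2:
        raise ValueError("need at least 2 aligned volumes")
    ref = aligned_cts[0]
    for v in aligned_cts[1:]:
        if not v.same_grid(ref):
            raise ValueError("aligned volumes must share one grid")
    stack = np.stack([v.data.astype(np.float64) for v in aligned_cts])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return ref.like(np.nan_to_num(mean, nan=0.0))


def build_csf_percentile_map(reference_csf_probs: list[Volume], pct: float = 99.0) -> Volume:
    """Voxelwise empirical percentile of CSF concentration across subjects.

    Linear interpolation between order statistics; the subject order does not
    matter.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    if len(reference_csf_probs) < 2:
        raise ValueError("need at least 2 reference maps")
    ref = reference_csf_probs[0]
    for v in reference_csf_probs[1:]:
        if not v.same_grid(ref):
            raise ValueError("reference maps must share one grid")
    stack = np.stack([v.data.astype(np.float64) for v in reference_csf_probs])
    return ref.like(np.percentile(stack, pct, axis=0))


def build_lobe_labels(
    cortical_parcellation: Volume,
    brain_mask: Volume,
    csf_mask: Volume,
) -> Volume:
    """Extend a 4-lobe cortical parcellation into CSF.

    Every CSF voxel that carries no lobe label is assigned the label of the
    nearest labelled voxel (Euclidean distance in world mm, which stays
    correct under anisotropic spacing).  Ties are resolved by the distance
    transform's fixed scan order, so the result is deterministic.
    """
    parc = cortical_parcellation.data.astype(np.int16)
    if not (parc > 0).any():
        raise ValueError("empty parcellation")
    target = parc.copy()
    fill = csf_mask.data.astype(bool) & (parc == 0)
    if fill.any():
        sp = cortical_parcellation.spacing
        _, nearest = ndimage.distance_transform_edt(parc == 0, sampling=sp, return_indices=True)
        target[fill] = parc[tuple(nearest[:, fill])]
    keep = (parc > 0) | fill
    target[~keep] = 0
    return cortical_parcellation.like(target)


def draw_synthetic_masks(spec: ph.PhantomSpec) -> tuple[Volume, Volume, Volume]:
    """MTL (left, right) and deep-WM masks from the phantom geometry.

    Stands in for masks drawn on an anatomical template: spheres covering the
    medial-temporal CSF pockets at their maximal extent and the
    periventricular lesion sites, with margin.
    """
    regions = ph.structure_regions(spec)
    aff = spec.affine
    cavity = ph._inside(ph._head_coords(spec), (0, 0, 0), ph.SKULL_INNER)
    return (
        Volume((regions["mtl_left"] & cavity).astype(np.uint8), aff),
        Volume((regions["mtl_right"] & cavity).astype(np.uint8), aff),
        Volume((regions["deep_wm"] & cavity).astype(np.uint8), aff),
    )


def _csf_concentration(labels: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    return ndimage.gaussian_filter((labels == ph.LABELS["csf"]).astype(np.float64), sigma)


def build_synthetic_bundle(
    n_reference: int = 20,
    seed: int = 100,
    base_spec: ph.PhantomSpec | None = None,
    reference_severity_max: float = 0.5,
    pct: float = 99.0,
) -> TemplateBundle:
    """Build the full bundle from an aligned low-severity reference cohort.

    The reference cohort plays the cognitively-normal population: severities
    are drawn uniformly in [0, reference_severity_max], so the CSF percentile
    map encodes normal-range CSF and atrophic subjects exceed it.
    """
    base = base_spec or ph.PhantomSpec()
    sampler = ph.CohortSampler(
        mta_range=(0.0, reference_severity_max * 4 / 3),
        gca_range=(0.0, reference_severity_max),
        fazekas_range=(0.0, reference_severity_max),
        randomize_pose=False,
    )
    pairs, _ = ph.make_cohort(n_reference, sampler, seed=seed, base_spec=base)
    mean_ct = build_mean_template([p.ct for p in pairs])
    csf_p99 = build_csf_percentile_map(
        [p.ct.like(_csf_concentration(p.labels.data)) for p in pairs], pct=pct
    )

    geom = ph.make_phantom(
        ph.PhantomSpec(
            grid_shape=base.grid_shape, voxel_size_mm=base.voxel_size_mm, noise_sd=0.0
        )
    )
    lab = geom.labels.data
    skull = geom.labels.like((lab == ph.LABELS["skull"]).astype(np.uint8))
    brain = geom.labels.like(ph.brain_mask_from_labels(lab).astype(np.uint8))
    mtl_l, mtl_r, deep = draw_synthetic_masks(geom.spec)
    regions = ph.structure_regions(geom.spec)
    gm_parcels = np.where(lab == ph.LABELS["gm"], regions["lobes"], 0).astype(np.int16)
    lobes = build_lobe_labels(
        geom.labels.like(gm_parcels),
        brain,
        geom.labels.like(lab == ph.LABELS["csf"]),
    )
    bundle = TemplateBundle(
        mean_ct=mean_ct,
        skull_mask=skull,
        brain_mask=brain,
        mtl_left_mask=mtl_l,
        mtl_right_mask=mtl_r,
        deep_wm_mask=deep,
        lobe_labels=lobes,
        csf_p99=csf_p99,
        provenance={
            "n_reference": n_reference,
            "seed": seed,
            "reference_severity_max": reference_severity_max,
            "percentile": pct,
        },
    )
    bundle.validate()
    return bundle
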