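"""End-to-end orchestration: CT volume in, calibrated grades out.

Per subject the stages run in order: skull strip -> 9-parameter affine to the
template (on skull masks) -> z-scoring of brain intensities -> ensemble
segmentation in template space -> correlation-weighted fusion -> transport of
the fused maps and template data to native space -> normalized volumetric
measures -> calibrated MTA / GCA (global + per lobe) / Fazekas grades.  All
volumetric measures are computed in the native CT space.

The trained state (template bundle, K segmenter members, per-scale
calibration models) lives in a :class:`PipelineModel`, which can be fitted on
a synthetic training cohort with :func:`train_pipeline` and persisted to a
directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .grade import (
    GRADE_RANGES,
    CalibrationModel,
    GradeSet,
    MeasureRecord,
    apply_calibration,
    fit_calibration,
    measure_fazekas,
    measure_gca,
    measure_mta,
)
from .register import (
    AffineRegConfig,
    AffineTransform,
    NonrigidConfig,
    nonrigid_refine,
    transport,
    zscore_brain,
)
from .segment import (
    SegmenterConfig,
    TrainedSegmenter,
    fuse_ensemble,
    predict_ensemble,
    train_ensemble,
)
from .skullstrip import SkullStripConfig, skull_strip
from .template import TemplateBundle, build_synthetic_bundle
from .volume import Volume

__all__ = [
    "RunConfig",
    "PipelineModel",
    "run_subject",
    "run_cohort",
    "train_pipeline",
    "SCALES",
]

log = logging.getLogger("ctnq")

# scale name -> maximum grade
SCALES = {
    "mta_left": 4,
    "mta_right": 4,
    "mta": 4,
    "gca": 3,
    "gca_frontal": 3,
    "gca_temporal": 3,
    "gca_parietal": 3,
    "gca_occipital": 3,
    "fazekas": 3,
}


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for one pipeline run."""

    skullstrip: SkullStripConfig = field(default_factory=SkullStripConfig)
    affine: AffineRegConfig = field(default_factory=AffineRegConfig)
    nonrigid: NonrigidConfig = field(default_factory=lambda: NonrigidConfig(fov_threshold=-500.0))
    use_nonrigid: bool = False
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    ensemble_size: int = 10
    seed: int = 0
    save_intermediates: bool = False


@dataclass
class PipelineModel:
    """Trained pipeline state: template bundle, ensemble, calibrations."""

    bundle: TemplateBundle
    models: list[TrainedSegmenter]
    calibrations: dict[str, CalibrationModel]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.bundle.save(out / "bundle")
        (out / "calibrations.json").write_text(
            json.dumps({k: m.to_dict() for k, m in self.calibrations.items()}, indent=2)
        )
        mdir = out / "models"
        mdir.mkdir(exist_ok=True)
        for i, m in enumerate(self.models):
            arrays = dict(m.net.params)
            arrays["feature_mean"] = m.feature_mean
            arrays["feature_sd"] = m.feature_sd
            arrays["class_weights"] = m.class_weights
            np.savez(mdir / f"member_{i:02d}.npz", **arrays)
            meta = {"config": m.config.__dict__, "loss_history": m.loss_history}
            (mdir / f"member_{i:02d}.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, in_dir: str | Path) -> "PipelineModel":
        from .segment import _ResidualNet

        src = Path(in_dir)
        bundle = TemplateBundle.load(src / "bundle")
        calib = {
            k: CalibrationModel.from_dict(v)
            for k, v in json.loads((src / "calibrations.json").read_text()).items()
        }
        models = []
        for f in sorted((src / "models").glob("member_*.npz")):
            meta = json.loads(f.with_suffix(".json").read_text())
            cfgd = meta["config"]
            cfgd["feature_sigmas"] = tuple(cfgd["feature_sigmas"])
            cfg = SegmenterConfig(**cfgd)
            data = np.load(f)
            net = _ResidualNet(
                cfg.n_features, cfg.base_channels, cfg.n_residual_blocks, 3,
                np.random.default_rng(0),
            )
            for k in net.params:
                net.params[k] = data[k]
            models.append(
                TrainedSegmenter(
                    net, cfg, data["class_weights"], data["feature_mean"],
                    data["feature_sd"], meta["loss_history"],
                )
            )
        return cls(bundle, models, calib)


# --------------------------------------------------------------------------
def _spatial_stage(ct: Volume, bundle: TemplateBundle, cfg: RunConfig) -> dict:
    """Skull strip, affine to template, z-score: shared by train and apply."""
    t0 = time.time()
    strip = skull_strip(ct, cfg.skullstrip)
    A = affine = _affine_to_template(strip.skull_mask, bundle, cfg)
    ct_t = transport(ct, A, direction="forward", interpolation="linear", reference=bundle.mean_ct)
    brain_t = transport(
        strip.brain.mask, A, direction="forward", interpolation="nearest",
        reference=bundle.mean_ct,
    )
    bmask_t = brain_t.data.astype(bool)
    z_t = zscore_brain(ct_t, brain_t)
    log.info(
        json.dumps(
            {
                "stage": "spatial",
                "elapsed_s": round(time.time() - t0, 2),
                "brain_volume_ml": strip.brain.brain_volume_ml,
                "skull_threshold_hu": strip.skull_threshold_hu,
                "affine": affine.to_dict(),
            }
        )
    )
    return {"strip": strip, "affine": A, "ct_template": ct_t, "brain_template": bmask_t, "z_template": z_t}


def _affine_to_template(subject_skull: Volume, bundle: TemplateBundle, cfg: RunConfig) -> AffineTransform:
    from .register import affine_register_masks

    return affine_register_masks(subject_skull, bundle.skull_mask, cfg.affine)


def _measure_stage(
    ct: Volume,
    spatial: dict,
    model: PipelineModel,
    cfg: RunConfig,
    subject_id: str,
) -> tuple[MeasureRecord, dict]:
    t0 = time.time()
    bundle = model.bundle
    members = predict_ensemble(model.models, spatial["z_template"], mask=spatial["brain_template"])
    dom = spatial["brain_template"]
    csf_set = fuse_ensemble(members["csf"], domain_mask=dom)
    wml_set = fuse_ensemble(members["wml"], domain_mask=dom)

    deformation = None
    if cfg.use_nonrigid:
        deformation = nonrigid_refine(ct, bundle.mean_ct, spatial["affine"], cfg.nonrigid)

    A = spatial["affine"]

    def to_native(vol: Volume, interp: str) -> Volume:
        return transport(
            vol, A, deformation=deformation, direction="inverse",
            interpolation=interp, reference=ct,
        )

    csf_prob_n = to_native(csf_set.fused_prob, "linear")
    csf_mask_n = to_native(csf_set.fused, "nearest")
    wml_mask_n = to_native(wml_set.fused, "nearest")
    mtl_l_n = to_native(bundle.mtl_left_mask, "nearest")
    mtl_r_n = to_native(bundle.mtl_right_mask, "nearest")
    deep_n = to_native(bundle.deep_wm_mask, "nearest")
    lobes_n = to_native(bundle.lobe_labels, "nearest")
    p99_n = to_native(bundle.csf_p99, "linear")

    brain = spatial["strip"].brain
    mta_l, mta_r = measure_mta(csf_mask_n, mtl_l_n, mtl_r_n, brain)
    gca, lobes = measure_gca(csf_prob_n, p99_n, brain, lobes_n)
    faz = measure_fazekas(wml_mask_n, deep_n, brain)
    rec = MeasureRecord(
        subject_id=subject_id,
        mta_left_raw=mta_l,
        mta_right_raw=mta_r,
        gca_raw=gca,
        gca_lobe_raw=lobes,
        fazekas_raw=faz,
        brain_volume_ml=brain.brain_volume_ml,
    )
    artifacts = {
        "csf_prob_native": csf_prob_n,
        "csf_mask_native": csf_mask_n,
        "wml_mask_native": wml_mask_n,
        "fusion_weights_csf": csf_set.weights,
        "fusion_weights_wml": wml_set.weights,
        "deformation": deformation,
    }
    log.info(json.dumps({"stage": "measure", "elapsed_s": round(time.time() - t0, 2), **{
        k: v for k, v in rec.as_dict().items() if k != "subject_id"}}))
    return rec, artifacts


def _grades_from_measures(rec: MeasureRecord, calibrations: dict[str, CalibrationModel]) -> GradeSet:
    cont: dict[str, float] = {}
    cont["mta_left"] = float(apply_calibration(calibrations["mta_left"], rec.mta_left_raw))
    cont["mta_right"] = float(apply_calibration(calibrations["mta_right"], rec.mta_right_raw))
    cont["mta"] = 0.5 * (cont["mta_left"] + cont["mta_right"])
    cont["gca"] = float(apply_calibration(calibrations["gca"], rec.gca_raw))
    for lobe, frac in rec.gca_lobe_raw.items():
        cont[f"gca_{lobe}"] = float(apply_calibration(calibrations[f"gca_{lobe}"], frac))
    cont["fazekas"] = float(apply_calibration(calibrations["fazekas"], rec.fazekas_raw))
    return GradeSet(subject_id=rec.subject_id, continuous=cont)


def run_subject(
    ct: Volume | str | Path,
    model: PipelineModel,
    config: RunConfig | None = None,
    subject_id: str = "subject",
    out_dir: str | Path | None = None,
) -> tuple[GradeSet, MeasureRecord, dict]:
    """Run the full pipeline on one CT volume."""
    cfg = config or RunConfig()
    if not model.calibrations:
        raise ValueError("pipeline model has no calibration models")
    vol = ct if isinstance(ct, Volume) else Volume.load(ct)
    spatial = _spatial_stage(vol, model.bundle, cfg)
    rec, artifacts = _measure_stage(vol, spatial, model, cfg, subject_id)
    grades = _grades_from_measures(rec, model.calibrations)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([{**grades.as_dict(), **rec.as_dict()}]).to_csv(
            out / f"{subject_id}_grades.csv", index=False
        )
        if cfg.save_intermediates:
            spatial["strip"].brain.mask.save(out / f"{subject_id}_brainmask.nii.gz")
            artifacts["csf_prob_native"].save(out / f"{subject_id}_csfprob.nii.gz")
            artifacts["wml_mask_native"].save(out / f"{subject_id}_wml.nii.gz")
    return grades, rec, artifacts


def run_cohort(
    subjects: list[tuple[str, Volume | str | Path]],
    model: PipelineModel,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-subject runs plus an aggregated grade table.

    Individual failures are logged and skipped; the list of failed subject
    ids is returned alongside the table.
    """
    if not subjects:
        raise ValueError("empty cohort manifest")
    cfg = config or RunConfig()
    rows, failed = [], []
    for sid, ct in subjects:
        try:
            grades, rec, _ = run_subject(ct, model, cfg, subject_id=sid)
            rows.append({**grades.as_dict(), **{k: v for k, v in rec.as_dict().items() if k != "subject_id"}})
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            log.error(json.dumps({"subject": sid, "error": str(exc)}))
            failed.append(sid)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_grades.csv", index=False)
    return table, failed


# --------------------------------------------------------------------------
def _recalibrate_percentile_map(
    bundle: TemplateBundle, models: list[TrainedSegmenter], cfg: RunConfig
) -> TemplateBundle:
    """Rebuild csf_p99 from the trained segmenter's own reference probabilities.

    The abnormal-CSF comparison is only meaningful when the percentile map and
    the subject map come from the same probability source and the same spatial
    processing: a map built from reference label concentrations is exactly
    zero deep in parenchyma, where a softmax still emits small positive
    probabilities, and every brain voxel would read as abnormal.  The
    normal-range reference cohort is therefore given realistic poses, pushed
    through the regular spatial stage (skull strip, affine, z-score), and
    segmented by the fused ensemble; the resulting percentile map carries both
    the pipeline's probability noise floor and its registration-residual
    spread, so by construction ~1% of normal-range values exceed it.
    """
    from .template import build_csf_percentile_map

    prov = bundle.provenance
    sampler = ph.CohortSampler(
        mta_range=(0.0, prov.get("reference_severity_max", 0.5) * 4 / 3),
        gca_range=(0.0, prov.get("reference_severity_max", 0.5)),
        fazekas_range=(0.0, prov.get("reference_severity_max", 0.5)),
        randomize_pose=True,
    )
    refs, _ = ph.make_cohort(prov.get("n_reference", 20), sampler, seed=prov.get("seed", 100))
    maps = []
    for pair in refs:
        spatial = _spatial_stage(pair.ct, bundle, cfg)
        members = predict_ensemble(models, spatial["z_template"], mask=spatial["brain_template"])
        fused = fuse_ensemble(members["csf"], domain_mask=spatial["brain_template"])
        maps.append(fused.fused_prob)
    new_p99 = build_csf_percentile_map(maps, pct=prov.get("percentile", 99.0))
    out = TemplateBundle(
        mean_ct=bundle.mean_ct,
        skull_mask=bundle.skull_mask,
        brain_mask=bundle.brain_mask,
        mtl_left_mask=bundle.mtl_left_mask,
        mtl_right_mask=bundle.mtl_right_mask,
        deep_wm_mask=bundle.deep_wm_mask,
        lobe_labels=bundle.lobe_labels,
        csf_p99=new_p99,
        provenance={**prov, "csf_p99_source": "fused ensemble probabilities"},
    )
    out.validate()
    return out


def _seg_class_labels(labels: Volume) -> Volume:
    """Phantom labels -> segmenter classes (0 bg, 1 CSF, 2 WML)."""
    lab = labels.data
    out = np.zeros(lab.shape, dtype=np.int16)
    out[lab == ph.LABELS["csf"]] = 1
    out[lab == ph.LABELS["wml"]] = 2
    return labels.like(out)


def train_pipeline(
    train_pairs: list[ph.PhantomPair],
    truth: pd.DataFrame,
    bundle: TemplateBundle | None = None,
    config: RunConfig | None = None,
) -> PipelineModel:
    """Fit the full pipeline state on a labelled training cohort.

    Training CTs are skull-stripped and affinely normalized; their label
    volumes are transported to template space to train the K ensemble
    members.  Measures for the same subjects (computed by the regular
    pipeline path) then calibrate each grade scale against the ground-truth
    grades in ``truth``.
    """
    cfg = config or RunConfig()
    if bundle is None:
        bundle = build_synthetic_bundle(seed=cfg.seed + 9000)
    seg_cfg = replace(cfg.segmenter, seed=cfg.seed)
    spatials, seg_pairs, masks = [], [], []
    for pair in train_pairs:
        spatial = _spatial_stage(pair.ct, bundle, cfg)
        lab_t = transport(
            _seg_class_labels(pair.labels), spatial["affine"], direction="forward",
            interpolation="nearest", reference=bundle.mean_ct,
        )
        spatials.append(spatial)
        seg_pairs.append((spatial["z_template"], lab_t))
        masks.append(spatial["brain_template"])
    models = train_ensemble(seg_pairs, seg_cfg, K=cfg.ensemble_size, masks=masks)
    bundle = _recalibrate_percentile_map(bundle, models, cfg)
    interim = PipelineModel(bundle, models, calibrations={})

    recs = []
    for pair, spatial in zip(train_pairs, spatials):
        sid = f"train-{len(recs):03d}"
        rec, _ = _measure_stage(pair.ct, spatial, interim, cfg, sid)
        recs.append(rec)
    mdf = pd.DataFrame([r.as_dict() for r in recs])

    calibrations: dict[str, CalibrationModel] = {}
    pairs_spec = {
        "mta_left": ("mta_left_raw", "mta_left", GRADE_RANGES["mta"]),
        "mta_right": ("mta_right_raw", "mta_right", GRADE_RANGES["mta"]),
        "gca": ("gca_raw", "gca", GRADE_RANGES["gca"]),
        "fazekas": ("fazekas_raw", "fazekas", GRADE_RANGES["fazekas"]),
    }
    for lobe in ("frontal", "temporal", "parietal", "occipital"):
        pairs_spec[f"gca_{lobe}"] = (f"gca_{lobe}_raw", "gca", GRADE_RANGES["gca_lobe"])
    for scale, (mcol, gcol, rng_) in pairs_spec.items():
        calibrations[scale] = fit_calibration(
            mdf[mcol].to_numpy(), truth[gcol].to_numpy(), scale, rng_
        )
    return PipelineModel(bundle, models, calibrations)
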