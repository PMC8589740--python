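"""Volumetric measures and their calibration to atrophy / lesion grades.

Measures are unitless fractions of total brain volume, computed in the native
CT space: CSF volume inside the medial-temporal-lobe mask per hemisphere
(MTA), volume where the CSF probability exceeds the normative 99th-percentile
map (GCA, whole brain and per lobe), and lesion volume inside the deep
white-matter mask (Fazekas).

Calibration is a two-step regression learned on a training set with known
grades: (1) ordinary least squares grade ~ measure; (2) a piecewise-linear
correction that maps, for every observed integer grade, the median step-1
estimate within that grade onto the group's median ground-truth grade.  The
correction removes the systematic compression a single line produces on an
ordinal scale while staying monotone.  Continuous calibrated grades are
clamped to the scale range and rounded only at categorization time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .skullstrip import BrainMask
from .volume import Volume

__all__ = [
    "GRADE_RANGES",
    "MeasureRecord",
    "CalibrationModel",
    "GradeSet",
    "measure_mta",
    "measure_gca",
    "measure_fazekas",
    "fit_calibration",
    "apply_calibration",
    "categorize",
]

GRADE_RANGES = {
    "mta": (0.0, 4.0),
    "gca": (0.0, 3.0),
    "fazekas": (0.0, 3.0),
    "gca_lobe": (0.0, 3.0),
}

LOBE_ORDER = ("frontal", "temporal", "parietal", "occipital")


@dataclass
class MeasureRecord:
    """Normalized volumetric measures for one subject."""

    subject_id: str
    mta_left_raw: float
    mta_right_raw: float
    gca_raw: float
    gca_lobe_raw: dict[str, float]
    fazekas_raw: float
    brain_volume_ml: float

    def __post_init__(self) -> None:
        for name in ("mta_left_raw", "mta_right_raw", "gca_raw", "fazekas_raw"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} is not a fraction in [0, 1]")

    def as_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {
            "subject_id": self.subject_id,
            "mta_left_raw": self.mta_left_raw,
            "mta_right_raw": self.mta_right_raw,
            "gca_raw": self.gca_raw,
            "fazekas_raw": self.fazekas_raw,
            "brain_volume_ml": self.brain_volume_ml,
        }
        for lobe in LOBE_ORDER:
            out[f"gca_{lobe}_raw"] = self.gca_lobe_raw.get(lobe, np.nan)
        return out


def _brain_volume(brain: BrainMask) -> tuple[np.ndarray, float, float]:
    m = brain.mask.data.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty brain mask")
    return m, float(n), brain.mask.voxel_volume_mm3


def measure_mta(
    csf_mask: Volume, mtl_left: Volume, mtl_right: Volume, brain: BrainMask
) -> tuple[float, float]:
    """CSF volume inside each hemisphere's MTL mask / total brain volume."""
    m, n_brain, _ = _brain_volume(brain)
    csf = csf_mask.data.astype(bool)
    left = float((csf & mtl_left.data.astype(bool)).sum() / n_brain)
    right = float((csf & mtl_right.data.astype(bool)).sum() / n_brain)
    return left, right


def measure_gca(
    csf_prob: Volume,
    csf_p99: Volume,
    brain: BrainMask,
    lobe_labels: Volume | None = None,
) -> tuple[float, dict[str, float]]:
    """Brain fraction where CSF probability strictly exceeds the p99 map.

    ``csf_prob`` is the *un-thresholded* fused CSF probability.  With a lobe
    label map the same comparison is restricted to each lobe.
    """
    for v in (csf_p99,) + ((lobe_labels,) if lobe_labels is not None else ()):
        if v.shape != csf_prob.shape:
            raise ValueError("grid mismatch between probability, percentile map or lobes")
    m, n_brain, _ = _brain_volume(brain)
    abnormal = (csf_prob.data > csf_p99.data) & m
    gca = float(abnormal.sum() / n_brain)
    lobes: dict[str, float] = {}
    if lobe_labels is not None:
        from .phantom import LOBE_CODES

        for lobe, code in LOBE_CODES.items():
            lobes[lobe] = float((abnormal & (lobe_labels.data == code)).sum() / n_brain)
    return gca, lobes


def measure_fazekas(wml_mask: Volume, deep_wm_mask: Volume, brain: BrainMask) -> float:
    """Lesion volume inside the deep white-matter mask / total brain volume."""
    m, n_brain, _ = _brain_volume(brain)
    return float((wml_mask.data.astype(bool) & deep_wm_mask.data.astype(bool)).sum() / n_brain)


# --------------------------------------------------------------------------
@dataclass
class CalibrationModel:
    """Two-step measure -> continuous grade map for one scale."""

    scale: str
    slope: float
    intercept: float
    knots_est: np.ndarray = field(default_factory=lambda: np.array([]))
    knots_target: np.ndarray = field(default_factory=lambda: np.array([]))
    grade_range: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        self.knots_est = np.asarray(self.knots_est, dtype=float)
        self.knots_target = np.asarray(self.knots_target, dtype=float)
        if np.any(np.diff(self.knots_target) < -1e-12):
            raise ValueError("piecewise correction must be monotone nondecreasing")

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "slope": self.slope,
            "intercept": self.intercept,
            "knots_est": self.knots_est.tolist(),
            "knots_target": self.knots_target.tolist(),
            "grade_range": list(self.grade_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            d["scale"], d["slope"], d["intercept"],
            np.asarray(d["knots_est"]), np.asarray(d["knots_target"]),
            tuple(d["grade_range"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_calibration(
    measures: np.ndarray,
    grades: np.ndarray,
    scale: str,
    grade_range: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Fit the two-step calibration on training pairs (measure, true grade).

    Ground-truth grades may be continuous or integer.  One correction knot is
    placed per observed rounded grade at the per-grade median of the step-1
    estimates; non-monotone group medians are repaired isotonic with a
    warning.
    """
    x = np.asarray(measures, dtype=float)
    y = np.asarray(grades, dtype=float)
    if x.size != y.size or x.size < 10:
        raise ValueError("need >= 10 matched training pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate measure: zero variance")
    rng_ = grade_range or GRADE_RANGES.get(scale, GRADE_RANGES["gca"])
    grade_groups = categorize(y, rng_)[0]
    if np.unique(grade_groups).size < 3:
        raise ValueError("need >= 3 distinct rounded grades in the training set")
    slope, intercept = np.polyfit(x, y, 1)
    est = slope * x + intercept
    knots_e, knots_t = [], []
    for g in np.unique(grade_groups):
        sel = grade_groups == g
        knots_e.append(float(np.median(est[sel])))
        knots_t.append(float(np.median(y[sel])))
    order = np.argsort(knots_e)
    knots_e = np.asarray(knots_e)[order]
    knots_t = np.asarray(knots_t)[order]
    if np.any(np.diff(knots_t) < 0):
        warnings.warn(f"non-monotone per-grade medians for {scale}; applying isotonic repair")
        knots_t = IsotonicRegression().fit_transform(np.arange(knots_t.size), knots_t)
    return CalibrationModel(scale, float(slope), float(intercept), knots_e, knots_t, rng_)


def _piecewise(v: np.ndarray, ke: np.ndarray, kt: np.ndarray) -> np.ndarray:
    """Monotone piecewise-linear interpolation with linear end extrapolation."""
    if ke.size == 0:
        return v
    if ke.size == 1:
        return v + (kt[0] - ke[0])
    out = np.interp(v, ke, kt)
    lo_slope = (kt[1] - kt[0]) / (ke[1] - ke[0]) if ke[1] > ke[0] else 1.0
    hi_slope = (kt[-1] - kt[-2]) / (ke[-1] - ke[-2]) if ke[-1] > ke[-2] else 1.0
    below = v < ke[0]
    above = v > ke[-1]
    out = np.where(below, kt[0] + lo_slope * (v - ke[0]), out)
    out = np.where(above, kt[-1] + hi_slope * (v - ke[-1]), out)
    return out


def apply_calibration(model: CalibrationModel, measure: float | np.ndarray) -> float | np.ndarray:
    """Continuous grade for a measure; not clamped (see :func:`categorize`)."""
    v = np.asarray(measure, dtype=float)
    est = model.slope * v + model.intercept
    out = _piecewise(est, model.knots_est, model.knots_target)
    return float(out) if np.isscalar(measure) or out.ndim == 0 else out


def categorize(
    continuous: float | np.ndarray, grade_range: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Clamp to the allowed range, round to the nearest integer grade, and
    dichotomize into normal (grades 0-1) vs abnormal (grades > 1).

    Half-integer ties round away from zero (2.5 -> 3).
    """
    v = np.asarray(continuous, dtype=float)
    if np.isnan(v).any():
        raise ValueError("NaN grade cannot be categorized")
    lo, hi = grade_range
    clamped = np.clip(v, lo, hi)
    cat = np.floor(clamped + 0.5).astype(int)
    abnormal = cat > 1
    return cat, abnormal


@dataclass
class GradeSet:
    """Continuous, categorical and dichotomized grades for one subject."""

    subject_id: str
    continuous: dict[str, float]
    categorical: dict[str, int] = field(default_factory=dict)
    abnormal: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.categorical:
            for k, v in self.continuous.items():
                rng_ = GRADE_RANGES["mta"] if k.startswith("mta") else GRADE_RANGES["gca"]
                cat, ab = categorize(v, rng_)
                self.categorical[k] = int(cat)
                self.abnormal[k] = bool(ab)

    def as_dict(self) -> dict:
        out: dict = {"subject_id": self.subject_id}
        for k in sorted(self.continuous):
            out[f"{k}_cont"] = self.continuous[k]
            out[f"{k}_cat"] = self.categorical[k]
            out[f"{k}_abnormal"] = int(self.abnormal[k])
        return out
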