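"""Volumetric measures, two-step calibration and grade categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctnq.grade import (
    CalibrationModel,
    MeasureRecord,
    apply_calibration,
    categorize,
    fit_calibration,
    measure_fazekas,
    measure_gca,
    measure_mta,
)
from ctnq.phantom import LOBE_CODES
from ctnq.skullstrip import BrainMask
from ctnq.volume import Volume


def _brain(n=22, n_brain=10_000):
    m = np.zeros((n, n, n), bool)
    m.ravel()[:n_brain] = True
    vol = Volume(m)
    return BrainMask(vol, float(m.sum() * 1e-3))


class TestMeasures:
    def test_mta_forced_arithmetic(self):
        brain = _brain()
        csf = np.zeros(brain.mask.shape, bool)
        csf.ravel()[:100] = True
        left = np.zeros_like(csf)
        left.ravel()[:150] = True
        right = np.zeros_like(csf)
        l, r = measure_mta(Volume(csf), Volume(left), Volume(right), brain)
        assert l == pytest.approx(0.01)
        assert r == 0.0

    def test_gca_forced_arithmetic(self):
        n = 40
        m = np.zeros((n, n, n), bool)
        m.ravel()[:50_000] = True
        brain = BrainMask(Volume(m), 50.0)
        prob = np.zeros((n, n, n))
        prob.ravel()[:500] = 1.0
        p99 = np.full((n, n, n), 0.9)
        gca, _ = measure_gca(Volume(prob), Volume(p99), brain)
        assert gca == pytest.approx(0.01)

    def test_gca_zero_when_never_exceeding(self):
        brain = _brain()
        prob = Volume(np.full(brain.mask.shape, 0.3))
        p99 = Volume(np.full(brain.mask.shape, 0.3))  # strict > never fires
        gca, _ = measure_gca(prob, p99, brain)
        assert gca == 0.0

    def test_gca_lobe_additivity(self):
        n = 20
        m = np.ones((n, n, n), bool)
        brain = BrainMask(Volume(m), 8.0)
        rng = np.random.default_rng(0)
        prob = Volume(rng.random((n, n, n)))
        p99 = Volume(np.full((n, n, n), 0.5))
        lobes = Volume(rng.choice(list(LOBE_CODES.values()), size=(n, n, n)).astype(np.int16))
        total, per_lobe = measure_gca(prob, p99, brain, lobes)
        assert sum(per_lobe.values()) == pytest.approx(total)

    def test_fazekas_forced_arithmetic(self):
        n = 30
        m = np.zeros((n, n, n), bool)
        m.ravel()[:25_000] = True
        brain = BrainMask(Volume(m), 25.0)
        wml = np.zeros((n, n, n), bool)
        wml.ravel()[:250] = True
        deep = np.ones((n, n, n), bool)
        assert measure_fazekas(Volume(wml), Volume(deep), brain) == pytest.approx(0.01)

    def test_fazekas_outside_mask_is_zero(self):
        brain = _brain()
        wml = np.zeros(brain.mask.shape, bool)
        wml.ravel()[:40] = True
        deep = np.zeros_like(wml)
        deep.ravel()[5000:6000] = True
        assert measure_fazekas(Volume(wml), Volume(deep), brain) == 0.0

    def test_empty_brain_errors(self):
        empty = BrainMask(Volume(np.zeros((5, 5, 5), bool)), 0.0)
        z = Volume(np.zeros((5, 5, 5), bool))
        with pytest.raises(ValueError):
            measure_fazekas(z, z, empty)

    def test_measure_record_rejects_non_fraction(self):
        with pytest.raises(ValueError):
            MeasureRecord("s", 1.2, 0.0, 0.0, {}, 0.0, 1.0)


class TestCalibration:
    def _linear_data(self, n=40, slope=30.0, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0, 3, n)
        x = y / slope
        return x, y

    def test_exact_linear_fit_recovers_truth(self):
        x, y = self._linear_data()
        model = fit_calibration(x, y, "gca")
        pred = apply_calibration(model, x)
        np.testing.assert_allclose(pred, y, atol=1e-9)

    def test_per_grade_medians_match_on_training_data(self):
        # monotone nonlinear relation, odd-sized grade groups
        rng = np.random.default_rng(1)
        y = np.concatenate([g + rng.uniform(-0.3, 0.3, 9) for g in (0.5, 1.5, 2.5)])
        y = np.clip(y, 0, 3)
        x = np.sqrt(y / 3.0) + rng.normal(0, 0.01, y.size)
        model = fit_calibration(x, y, "gca")
        pred = np.asarray(apply_calibration(model, x))
        groups = categorize(y, (0, 3))[0]
        for g in np.unique(groups):
            sel = groups == g
            assert np.median(pred[sel]) == pytest.approx(np.median(y[sel]), abs=1e-6)

    def test_monotone_inputs_monotone_outputs(self):
        x, y = self._linear_data(seed=3)
        model = fit_calibration(x, y, "fazekas")
        grid = np.linspace(x.min() - 0.01, x.max() + 0.01, 200)
        out = np.asarray(apply_calibration(model, grid))
        assert (np.diff(out) >= -1e-12).all()

    def test_extrapolation_is_linear_beyond_last_knot(self):
        model = CalibrationModel(
            "gca", slope=1.0, intercept=0.0,
            knots_est=np.array([0.0, 1.0, 2.0]),
            knots_target=np.array([0.0, 1.0, 3.0]),
            grade_range=(0, 3),
        )
        # last segment slope = 2: value at 3.0 extrapolates to 3 + 2*1
        assert apply_calibration(model, 3.0) == pytest.approx(5.0)
        assert apply_calibration(model, -1.0) == pytest.approx(-1.0)

    def test_affine_rescaling_of_measure_absorbed(self):
        x, y = self._linear_data(seed=4)
        m1 = fit_calibration(x, y, "gca")
        m2 = fit_calibration(5.0 * x + 0.2, y, "gca")
        grid = np.linspace(x.min(), x.max(), 50)
        np.testing.assert_allclose(
            np.asarray(apply_calibration(m1, grid)),
            np.asarray(apply_calibration(m2, 5.0 * grid + 0.2)),
            atol=1e-8,
        )

    def test_synthetic_cohort_recovery(self):
        rng = np.random.default_rng(5)
        n = 200
        y = rng.uniform(0, 3, n)
        x = np.tanh(y / 2.0) * 0.1 + rng.normal(0, 0.004, n)  # monotone nonlinear + noise
        model = fit_calibration(x, y, "gca")
        pred = np.asarray(apply_calibration(model, x))
        r = np.corrcoef(pred, y)[0, 1]
        assert r >= 0.9
        cat_p = categorize(pred, (0, 3))[0]
        cat_t = categorize(y, (0, 3))[0]
        assert np.mean(np.abs(cat_p - cat_t) <= 1) >= 0.95

    def test_too_few_pairs_or_grades_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(np.arange(5) / 10, np.arange(5.0), "gca")
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            fit_calibration(x, np.zeros(20), "gca")
        with pytest.raises(ValueError):
            fit_calibration(np.full(20, 0.5), np.linspace(0, 3, 20), "gca")

    def test_non_monotone_medians_repaired_with_warning(self):
        rng = np.random.default_rng(6)
        # grades anti-correlated with the measure inside one group
        y = np.concatenate([np.full(7, 0.0), np.full(7, 1.0), np.full(7, 2.0)])
        x = np.concatenate([rng.uniform(0.5, 0.6, 7), rng.uniform(0.0, 0.1, 7), rng.uniform(0.52, 0.62, 7)])
        with pytest.warns(UserWarning, match="isotonic"):
            model = fit_calibration(x, y, "gca")
        assert (np.diff(model.knots_target) >= 0).all()

    def test_model_json_roundtrip(self, tmp_path):
        x, y = self._linear_data(seed=7)
        model = fit_calibration(x, y, "mta", grade_range=(0, 4))
        model.save(tmp_path / "m.json")
        back = CalibrationModel.load(tmp_path / "m.json")
        grid = np.linspace(0, 0.2, 20)
        np.testing.assert_allclose(
            np.asarray(apply_calibration(model, grid)),
            np.asarray(apply_calibration(back, grid)),
        )


class TestCategorize:
    @pytest.mark.parametrize(
        "value, grade_range, expected, abnormal",
        [
            (4.7, (0, 4), 4, True),
            (-0.3, (0, 3), 0, False),
            (2.4, (0, 3), 2, True),
            (2.6, (0, 3), 3, True),
            (2.5, (0, 3), 3, True),   # ties round away from zero
            (1.0, (0, 4), 1, False),
            (1.49, (0, 3), 1, False),
            (1.51, (0, 3), 2, True),
        ],
    )
    def test_examples(self, value, grade_range, expected, abnormal):
        cat, ab = categorize(value, grade_range)
        assert cat == expected
        assert bool(ab) is abnormal

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            categorize(np.nan, (0, 3))

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-10, 10), st.sampled_from([(0, 3), (0, 4)]))
    def test_always_in_range_and_consistent(self, value, grade_range):
        cat, ab = categorize(value, grade_range)
        assert grade_range[0] <= cat <= grade_range[1]
        assert bool(ab) == (cat > 1)
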