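"""Agreement battery vs direct-formula oracles and an independent package."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from ctnq.evaluate import (
    bland_altman,
    full_report,
    grade_agreement,
    normality_agreement,
    pearson_r,
    weighted_kappa,
)


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_printed_vector_against_formula(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([0.0, 1.0, 1.0, 3.0])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestGradeAgreement:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 3])
        pid, pw1, conf = grade_agreement(a, a, 3)
        assert pid == 100.0 and pw1 == 100.0
        assert np.all(conf == np.eye(4, dtype=int))

    def test_shift_by_one(self):
        pid, pw1, _ = grade_agreement(np.array([0, 1, 2]), np.array([1, 2, 3]), 3)
        assert pid == 0.0 and pw1 == 100.0

    def test_random_pairs_match_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(3, 40)
            G = int(rng.integers(2, 5))
            a = rng.integers(0, G + 1, n)
            b = rng.integers(0, G + 1, n)
            pid, pw1, conf = grade_agreement(a, b, G)
            n_id = sum(1 for x, y in zip(a, b) if x == y)
            n_w1 = sum(1 for x, y in zip(a, b) if abs(x - y) <= 1)
            assert pid == pytest.approx(100 * n_id / n)
            assert pw1 == pytest.approx(100 * n_w1 / n)
            for i in range(G + 1):
                for j in range(G + 1):
                    assert conf[i, j] == sum(1 for x, y in zip(a, b) if (x, y) == (i, j))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grade_agreement(np.array([0, 5]), np.array([0, 1]), 3)

    def test_symmetry_in_percentages(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 4, 30)
        b = rng.integers(0, 4, 30)
        assert grade_agreement(a, b, 3)[:2] == grade_agreement(b, a, 3)[:2]


class TestNormality:
    def test_dichotomy_matches_despite_grade_differences(self):
        assert normality_agreement(np.array([0, 1, 2, 3]), np.array([1, 0, 3, 2])) == 100.0

    def test_total_disagreement(self):
        assert normality_agreement(np.array([1, 1]), np.array([2, 2])) == 0.0

    def test_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 5, 50)
        b = rng.integers(0, 5, 50)
        expect = 100 * np.mean([(x > 1) == (y > 1) for x, y in zip(a, b)])
        assert normality_agreement(a, b) == pytest.approx(expect)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        assert weighted_kappa(np.diag([3, 4, 5, 2])) == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        row = np.array([10, 20, 30])
        col = np.array([15, 25, 20])
        conf = np.outer(row, col) / 60.0
        assert weighted_kappa(conf) == pytest.approx(0.0, abs=1e-12)

    def test_known_matrix_against_direct_formula(self):
        conf = np.array([[2, 1, 0], [1, 2, 1], [0, 1, 2]], dtype=float)
        n = conf.sum()
        G = 2
        w = np.array([[((i - j) / G) ** 2 for j in range(3)] for i in range(3)])
        e = np.outer(conf.sum(1), conf.sum(0)) / n
        expect = 1 - (w * conf).sum() / (w * e).sum()
        assert weighted_kappa(conf) == pytest.approx(expect, abs=1e-12)

    def test_matches_sklearn_on_random_gradings(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.integers(0, 4, 60)
            b = np.clip(a + rng.integers(-1, 2, 60), 0, 3)
            _, _, conf = grade_agreement(a, b, 3)
            ours = weighted_kappa(conf)
            ref = cohen_kappa_score(a, b, labels=[0, 1, 2, 3], weights="quadratic")
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_identity_weighting_reduces_to_unweighted(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        _, _, conf = grade_agreement(a, b, 2)
        ours = weighted_kappa(conf, weighting="identity")
        ref = cohen_kappa_score(a, b, labels=[0, 1, 2])
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_degenerate_marginal_rejected(self):
        conf = np.zeros((3, 3))
        conf[1, :] = [5, 5, 5]  # reference rater constant
        with pytest.raises(ValueError):
            weighted_kappa(conf)


class TestBlandAltman:
    def test_identical_sources(self):
        x = np.array([1.0, 2.0, 3.0])
        out = bland_altman(x, x)
        assert out["mean_diff"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0])
        out = bland_altman(x, x + 1.0)
        assert out["mean_diff"] == pytest.approx(-1.0)
        assert out["loa_high"] - out["loa_low"] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_on_random_data(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=50), rng.normal(size=50)
        out = bland_altman(x, y)
        d = x - y
        assert out["mean_diff"] == pytest.approx(d.mean())
        assert out["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_limits_cover_gaussian_differences(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 200)
        y = x + rng.normal(0, 0.5, 200)
        out = bland_altman(x, y)
        d = x - y
        frac = np.mean((d >= out["loa_low"]) & (d <= out["loa_high"]))
        assert frac >= 0.90


class TestFullReport:
    def _table(self, rng, n=30, prefix_noise=0.0):
        cont = rng.uniform(0, 3, n)
        from ctnq.grade import categorize

        cat, _ = categorize(cont + rng.normal(0, prefix_noise, n), (0, 3))
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "gca_cont": cont,
                "gca_cat": cat,
            }
        )

    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(7)
        t = self._table(rng)
        reports, table = full_report(t, t, {"gca": 3})
        r = reports[0]
        assert r.pearson_r == pytest.approx(1.0)
        assert r.pct_identical == 100.0
        assert r.kappa_quadratic == pytest.approx(1.0)
        assert len(table) == 1

    def test_report_row_per_scale(self, tmp_path):
        rng = np.random.default_rng(8)
        t = self._table(rng)
        t["mta_cont"] = rng.uniform(0, 4, len(t))
        from ctnq.grade import categorize

        t["mta_cat"] = categorize(t["mta_cont"].to_numpy(), (0, 4))[0]
        reports, table = full_report(t, t, {"gca": 3, "mta": 4}, out_dir=tmp_path)
        assert len(reports) == 2
        assert (tmp_path / "agreement_report.csv").exists()
        assert (tmp_path / "confusion_gca.csv").exists()

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        a = self._table(rng)
        b = self._table(rng).iloc[:-1]
        with pytest.raises(ValueError, match="mismatch"):
            full_report(a, b, {"gca": 3})
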