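"""Agreement statistics between two grade sources.

Implements the comparison battery used to judge how well one grading pipeline
reproduces another: Pearson correlation on continuous grades, percentage of
identical categorical grades, percentage within one grade, agreement of the
normal (grades 0-1) vs abnormal (> 1) dichotomy, quadratically weighted
Cohen's kappa, Bland-Altman bias and 95% limits of agreement, and confusion
matrices (rows = reference source, columns = test source).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "pearson_r",
    "grade_agreement",
    "normality_agreement",
    "weighted_kappa",
    "bland_altman",
    "full_report",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two continuous grade vectors."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(stats.pearsonr(x, y)[0])


def grade_agreement(
    a: np.ndarray, b: np.ndarray, max_grade: int
) -> tuple[float, float, np.ndarray]:
    """Percent identical, percent within one grade, and the confusion matrix.

    ``a`` is the reference source (rows), ``b`` the test source (columns).
    """
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("grade vectors must be matched and nonempty")
    if a.min() < 0 or b.min() < 0 or a.max() > max_grade or b.max() > max_grade:
        raise ValueError(f"grades outside [0, {max_grade}]")
    n = a.size
    pct_identical = 100.0 * np.mean(a == b)
    pct_within_one = 100.0 * np.mean(np.abs(a - b) <= 1)
    confusion = np.zeros((max_grade + 1, max_grade + 1), dtype=int)
    np.add.at(confusion, (a, b), 1)
    assert confusion.sum() == n
    return float(pct_identical), float(pct_within_one), confusion


def normality_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Percent of cases where the normal (0-1) vs abnormal (>1) split matches."""
    a = np.asarray(a, int)
    b = np.asarray(b, int)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("grade vectors must be matched and nonempty")
    return float(100.0 * np.mean((a > 1) == (b > 1)))


def weighted_kappa(confusion: np.ndarray, weighting: str = "quadratic") -> float:
    """Cohen's kappa with quadratic disagreement weights.

    kappa = 1 - sum(w o) / sum(w e) with w_ij = ((i - j)/G)^2 (any positive
    scaling of w cancels) and e the outer product of the marginals.
    """
    o = np.asarray(confusion, dtype=float)
    if o.ndim != 2 or o.shape[0] != o.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = o.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    G = o.shape[0] - 1
    i, j = np.indices(o.shape)
    if weighting == "quadratic":
        w = ((i - j) / max(G, 1)) ** 2
    elif weighting == "identity":
        w = (i != j).astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    rows, cols = o.sum(axis=1), o.sum(axis=0)
    if (rows > 0).sum() < 2 or (cols > 0).sum() < 2:
        raise ValueError("degenerate marginals: kappa undefined (a rater is constant)")
    e = np.outer(rows, cols) / n
    denom = (w * e).sum()
    if denom == 0:
        raise ValueError("degenerate marginals: kappa undefined")
    return float(1.0 - (w * o).sum() / denom)


def bland_altman(x: np.ndarray, y: np.ndarray) -> dict:
    """Mean difference, 95% limits of agreement, and plot-ready pairs.

    Differences are d = x - y; limits are mean(d) +/- 1.96 SD(d).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    d = x - y
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return {
        "mean_diff": mean_diff,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
        "pairs": np.column_stack([(x + y) / 2.0, d]),
    }


@dataclass
class AgreementReport:
    scale: str
    n: int
    pearson_r: float
    pct_identical: float
    pct_within_one: float
    pct_normality_identical: float
    kappa_quadratic: float
    mean_diff: float
    loa_low: float
    loa_high: float
    confusion: np.ndarray

    def __post_init__(self) -> None:
        assert self.confusion.sum() == self.n
        assert self.pct_within_one >= self.pct_identical

    def as_row(self) -> dict:
        return {
            "scale": self.scale,
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pct_identical": self.pct_identical,
            "pct_within_one": self.pct_within_one,
            "pct_normality_identical": self.pct_normality_identical,
            "kappa_quadratic": self.kappa_quadratic,
            "mean_diff": self.mean_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def _report_for_scale(
    scale: str,
    ref_cont: np.ndarray,
    ref_cat: np.ndarray,
    test_cont: np.ndarray,
    test_cat: np.ndarray,
    max_grade: int,
) -> AgreementReport:
    pct_id, pct_w1, conf = grade_agreement(ref_cat, test_cat, max_grade)
    try:
        kappa = weighted_kappa(conf, "quadratic")
    except ValueError:
        kappa = np.nan
    ba = bland_altman(test_cont, ref_cont)
    return AgreementReport(
        scale=scale,
        n=len(ref_cat),
        pearson_r=pearson_r(ref_cont, test_cont),
        pct_identical=pct_id,
        pct_within_one=pct_w1,
        pct_normality_identical=normality_agreement(ref_cat, test_cat),
        kappa_quadratic=kappa,
        mean_diff=ba["mean_diff"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        confusion=conf,
    )


def full_report(
    ref: pd.DataFrame,
    test: pd.DataFrame,
    scales: dict[str, int],
    out_dir: str | Path | None = None,
    make_figures: bool = False,
) -> tuple[list[AgreementReport], pd.DataFrame]:
    """One agreement report per scale, plus optional CSV/figure outputs.

    ``ref`` and ``test`` are grade tables with a shared ``subject_id`` column
    and per-scale ``<scale>_cont`` and ``<scale>_cat`` columns; ``scales``
    maps scale name to its maximum grade (4 for MTA, 3 otherwise).
    """
    merged = ref.merge(test, on="subject_id", suffixes=("_ref", "_test"), how="inner")
    missing = set(ref.subject_id).symmetric_difference(test.subject_id)
    if missing:
        raise ValueError(f"subject mismatch between grade tables: {sorted(missing)[:10]}")
    reports = []
    for scale, max_grade in scales.items():
        reports.append(
            _report_for_scale(
                scale,
                merged[f"{scale}_cont_ref"].to_numpy(),
                merged[f"{scale}_cat_ref"].to_numpy(),
                merged[f"{scale}_cont_test"].to_numpy(),
                merged[f"{scale}_cat_test"].to_numpy(),
                max_grade,
            )
        )
    table = pd.DataFrame([r.as_row() for r in reports])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "agreement_report.csv", index=False)
        for r in reports:
            pd.DataFrame(r.confusion).to_csv(out / f"confusion_{r.scale}.csv")
        if make_figures:
            _figures(merged, reports, out)
    return reports, table


def _figures(merged: pd.DataFrame, reports: list[AgreementReport], out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for r in reports:
        xc = merged[f"{r.scale}_cont_ref"].to_numpy()
        yc = merged[f"{r.scale}_cont_test"].to_numpy()
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(xc, yc, s=12, alpha=0.7)
        lim = [min(xc.min(), yc.min()), max(xc.max(), yc.max())]
        axes[0].plot(lim, lim, "k--", lw=0.8)
        axes[0].set_xlabel("reference grade")
        axes[0].set_ylabel("test grade")
        axes[0].set_title(f"{r.scale}: r = {r.pearson_r:.2f}")
        ba = bland_altman(yc, xc)
        axes[1].scatter(ba["pairs"][:, 0], ba["pairs"][:, 1], s=12, alpha=0.7)
        for yv, style in ((ba["mean_diff"], "-"), (ba["loa_low"], "--"), (ba["loa_high"], "--")):
            axes[1].axhline(yv, color="k", ls=style, lw=0.8)
        axes[1].set_xlabel("mean of sources")
        axes[1].set_ylabel("difference (test - ref)")
        axes[1].set_title("Bland-Altman")
        fig.tight_layout()
        fig.savefig(out / f"agreement_{r.scale}.png", dpi=110)
        plt.close(fig)
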