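"""Cohort-level agreement statistics for paired volume estimates.

Implements the standard agreement stack used to compare an automated
volume estimate against a reference standard: intraclass correlation
(two-way random effects, absolute agreement, single measurement — ICC(2,1))
with the conventional interpretation bands, Bland-Altman bias and limits of
agreement, and paired significance testing with a normality-driven choice
between the paired t-test and the Wilcoxon signed-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

ICC_BANDS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"))


def icc_category(icc: float) -> str:
    """Interpretation bands: <0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
    >0.90 excellent."""
    for upper, label in ICC_BANDS:
        if icc < upper or (label != "poor" and np.isclose(icc, upper)):
            return label
    return "excellent"


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    category: str


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of pairs, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs must be finite")
    return arr


def icc_agreement(pairs) -> ICCResult:
    """ICC(2,1) absolute agreement for paired measurements.

    Requires >= 5 pairs and nonzero between-case variance.  The estimate is
    the two-way random-effects, absolute-agreement, single-measurement ICC
    with its 95% confidence interval.
    """
    arr = _as_pairs(pairs)
    n = arr.shape[0]
    if n < 5:
        raise ValueError(f"icc_agreement needs >= 5 pairs, got {n}")
    if np.allclose(arr.mean(axis=1), arr.mean()):
        raise ValueError("degenerate input: no variance across cases")
    if np.array_equal(arr[:, 0], arr[:, 1]):
        # perfect agreement: the ANOVA error mean square is exactly zero
        return ICCResult(1.0, (1.0, 1.0), "excellent")
    df = pd.DataFrame({
        "case": np.repeat(np.arange(n), 2),
        "rater": np.tile(["a", "b"], n),
        "value": arr.reshape(-1),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(data=df, targets="case", raters="rater",
                                 ratings="value")
    # two-way random, absolute agreement, single measure: labelled ICC2 or
    # ICC(A,1) depending on the pingouin version
    row = res.loc[res["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    est = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci = tuple(float(x) for x in row[ci_col])
    return ICCResult(est, ci, icc_category(est))


@dataclass
class BlandAltman:
    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low


def bland_altman(pairs) -> BlandAltman:
    """Bland-Altman bias and 95% limits of agreement (mean +/- 1.96 SD).

    Differences are first-minus-second; the sample SD uses n-1 degrees of
    freedom.
    """
    arr = _as_pairs(pairs)
    if arr.shape[0] < 2:
        raise ValueError(f"bland_altman needs >= 2 pairs, got {arr.shape[0]}")
    d = arr[:, 0] - arr[:, 1]
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(mean, mean - 1.96 * sd, mean + 1.96 * sd, sd)


def bland_altman_plot(pairs, path, label_a: str = "method A",
                      label_b: str = "method B") -> None:
    """Write a Bland-Altman plot (PNG/PDF inferred from the path suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = _as_pairs(pairs)
    ba = bland_altman(arr)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.8)
    ax.axhline(ba.mean_diff, color="k")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b} (ml)")
    ax.set_ylabel(f"{label_a} - {label_b} (ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def paired_compare(x, y, alpha: float = 0.05) -> tuple[float, str]:
    """Two-sided paired comparison with distribution-driven test choice.

    Differences are tested for normality (Shapiro-Wilk at alpha); normal
    differences use the paired Student t-test, otherwise the Wilcoxon
    signed-rank test.  All-zero differences return p = 1 with a degenerate
    label (the signed-rank statistic is undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D paired samples")
    if x.size < 5:
        raise ValueError(f"paired_compare needs n >= 5, got {x.size}")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; test degenerate")
        return 1.0, "degenerate (all differences zero)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = stats.shapiro(d).pvalue > alpha
    if normal:
        p = float(stats.ttest_rel(x, y).pvalue)
        return p, "paired t-test"
    res = stats.wilcoxon(x, y, zero_method="wilcox", mode="auto")
    return float(res.pvalue), "wilcoxon signed-rank"


@dataclass
class VolumetryResult:
    """Per-exam segmentation quality and volumetry row."""

    exam_id: str
    pv_pred_ml: float
    pv_ref_ml: float
    rvd_percent: float
    dsc: float
    asd_mm: float

    def __post_init__(self) -> None:
        if self.pv_pred_ml < 0 or self.pv_ref_ml < 0:
            raise ValueError("volumes must be non-negative")
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError(f"dsc must be in [0,1], got {self.dsc}")
        if np.sign(self.rvd_percent) * np.sign(self.pv_pred_ml - self.pv_ref_ml) < 0:
            raise ValueError("rvd sign must match pv_pred - pv_ref")


@dataclass
class AgreementReport:
    """Cohort-level volumetry comparison for one model/scenario."""

    scenario: str
    model: str
    results: list[VolumetryResult]
    icc: ICCResult
    ba: BlandAltman
    paired_p: float
    test_used: str

    def per_case_frame(self) -> pd.DataFrame:
        rows = [{"exam_id": r.exam_id, "scenario": self.scenario,
                 "model": self.model, "dsc": r.dsc, "asd_mm": r.asd_mm,
                 "rvd_percent": r.rvd_percent, "abs_rvd_percent": abs(r.rvd_percent),
                 "pv_pred_ml": r.pv_pred_ml, "pv_ref_ml": r.pv_ref_ml}
                for r in self.results]
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        df = self.per_case_frame()
        return {
            "scenario": self.scenario,
            "model": self.model,
            "n": len(df),
            "dsc_mean": df["dsc"].mean(), "dsc_sd": df["dsc"].std(ddof=1),
            "asd_median_mm": df["asd_mm"].median(),
            "asd_q1_mm": df["asd_mm"].quantile(0.25),
            "asd_q3_mm": df["asd_mm"].quantile(0.75),
            "rvd_mean_percent": df["rvd_percent"].mean(),
            "rvd_sd_percent": df["rvd_percent"].std(ddof=1),
            "abs_rvd_mean_percent": df["abs_rvd_percent"].mean(),
            "pv_pred_mean_ml": df["pv_pred_ml"].mean(),
            "pv_ref_mean_ml": df["pv_ref_ml"].mean(),
            "icc": self.icc.estimate,
            "icc_ci_low": self.icc.ci95[0], "icc_ci_high": self.icc.ci95[1],
            "icc_category": self.icc.category,
            "ba_mean_diff_ml": self.ba.mean_diff,
            "ba_loa_low_ml": self.ba.loa_low, "ba_loa_high_ml": self.ba.loa_high,
            "paired_p": self.paired_p, "test_used": self.test_used,
        }


def build_agreement_report(scenario: str, model: str,
                           results: list[VolumetryResult]) -> AgreementReport:
    if not results:
        raise ValueError("empty cohort: no volumetry results")
    pairs = [(r.pv_pred_ml, r.pv_ref_ml) for r in results]
    icc = icc_agreement(pairs)
    ba = bland_altman(pairs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, test = paired_compare([r.pv_pred_ml for r in results],
                                 [r.pv_ref_ml for r in results])
    return AgreementReport(scenario, model, results, icc, ba, p, test)
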