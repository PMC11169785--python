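"""Group-level inference on pooled decoding results.

Covers the finite-sample chance level (binomial correction for a
finite test set), one-sample t-tests of accuracies against chance and
of fitted mean differences against zero, Benjamini-Hochberg FDR
control over the family of (ROI, band) features, the joint
significance rule (a feature counts only when both its accuracy and
its mean difference survive FDR), and the two-way fixed-effects ANOVA
of ROI x band effects on fold-level accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ChanceSpec",
    "FeatureResult",
    "AnovaResult",
    "finite_chance_level",
    "ttest_accuracy",
    "ttest_meandiff",
    "bh_fdr",
    "joint_significance",
    "anova_roi_band",
]


@dataclass(frozen=True)
class ChanceSpec:
    """Finite-sample chance specification."""

    n_test: int
    n_classes: int = 2
    conf_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class FeatureResult:
    """Pooled statistics for one (ROI, band) feature."""

    roi: str
    band: str
    accuracies: np.ndarray
    mean_diffs: np.ndarray
    p_acc: float = np.nan
    p_diff: float = np.nan
    sig_acc: bool = False
    sig_diff: bool = False

    @property
    def sig_joint(self) -> bool:
        return self.sig_acc and self.sig_diff

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def mean_diff(self) -> float:
        return float(np.mean(self.mean_diffs))


@dataclass(frozen=True)
class AnovaResult:
    """Two-way fixed-effects ANOVA summary."""

    f_roi: float
    f_band: float
    f_interaction: float
    p_roi: float
    p_band: float
    p_interaction: float
    df: tuple[float, float, float, float]  # (df_roi, df_band, df_inter, df_resid)


def finite_chance_level(spec: ChanceSpec) -> float:
    """Accuracy threshold accounting for the finite test-set size.

    The threshold is k*/n where k* is the smallest correct count whose
    probability of being reached by guessing (Binomial(n, 1/c)) is at
    most ``conf_alpha``.  It decreases toward 1/c as n grows.
    """
    n, p = spec.n_test, 1.0 / spec.n_classes
    # smallest k with P(X >= k) = sf(k - 1) <= alpha
    k = int(sps.binom.isf(spec.conf_alpha, n, p)) + 1
    while k <= n and sps.binom.sf(k - 1, n, p) > spec.conf_alpha:
        k += 1
    while k > 1 and sps.binom.sf(k - 2, n, p) <= spec.conf_alpha:
        k -= 1
    return k / n


def ttest_accuracy(accuracies, chance: float) -> float:
    """Two-sided one-sample t-test of accuracies against the chance
    threshold.  Zero-variance input returns NaN (degenerate)."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 accuracy values")
    if acc.std(ddof=1) == 0:
        return float("nan") if acc[0] != chance else 1.0
    return float(sps.ttest_1samp(acc, chance).pvalue)


def ttest_meandiff(diffs) -> float:
    """Two-sided one-sample t-test of mean differences against zero."""
    return ttest_accuracy(diffs, 0.0)


def bh_fdr(pvals, alpha: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags.

    Sort the p-values ascending as P(1) <= ... <= P(N), find the
    largest k with P(k) <= (k/N) * alpha, and reject every hypothesis
    with p <= P(k).  NaN p-values are never rejected and do not count
    toward N.
    """
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject = np.zeros(p.shape, dtype=bool)
    n = int(ok.sum())
    if n == 0:
        return reject
    ps = np.sort(p[ok])
    ranks = np.arange(1, n + 1)
    passing = ps <= ranks / n * alpha
    if not passing.any():
        return reject
    p_k = ps[np.flatnonzero(passing)[-1]]
    reject[ok] = p[ok] <= p_k
    return reject


def joint_significance(results: list[FeatureResult], alpha: float = 0.01,
                       require_above_chance: bool = True,
                       chance: float | None = None) -> list[FeatureResult]:
    """Apply FDR separately to the accuracy and mean-difference p-value
    families and set the significance flags in place.

    A feature's accuracy flag additionally requires its mean accuracy
    to exceed the chance threshold (when given): the two-sided t-test
    also fires for accuracies significantly *below* threshold, which is
    not evidence of decodability.
    """
    p_acc = np.array([r.p_acc for r in results], dtype=float)
    p_diff = np.array([r.p_diff for r in results], dtype=float)
    rej_acc = bh_fdr(p_acc, alpha)
    rej_diff = bh_fdr(p_diff, alpha)
    for r, ra, rd in zip(results, rej_acc, rej_diff):
        above = True
        if require_above_chance and chance is not None:
            above = r.mean_accuracy > chance
        r.sig_acc = bool(ra and above)
        r.sig_diff = bool(rd)
    return results


def anova_roi_band(records) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on fold accuracies.

    ``records`` is an iterable of ``(roi, band, accuracy)`` tuples (or
    a DataFrame with those columns); every (roi, band) cell must have
    at least 2 replicates.
    """
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if isinstance(records, pd.DataFrame):
        df = records[["roi", "band", "accuracy"]].copy()
    else:
        df = pd.DataFrame(list(records), columns=["roi", "band", "accuracy"])
    if df["roi"].nunique() < 2 or df["band"].nunique() < 2:
        raise ValueError("need at least 2 levels per factor")
    counts = df.groupby(["roi", "band"]).size()
    thin = counts[counts < 2]
    if len(thin) > 0:
        raise ValueError(f"cells with < 2 replicates: {list(thin.index)}")
    model = ols("accuracy ~ C(roi) * C(band)", data=df).fit()
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        tab = sm.stats.anova_lm(model, typ=2)
    # zero effect sum-of-squares means no effect: F = 0, p = 1
    # (anova_lm yields NaN or noise ratios when the response is constant)
    scale = float(((df["accuracy"] - df["accuracy"].mean()) ** 2).sum())
    scale = max(scale, 1e-18 * max(1.0, float((df["accuracy"] ** 2).sum())))
    zero_ss = tab["sum_sq"] <= 1e-12 * scale
    tab.loc[zero_ss, "F"] = 0.0
    tab.loc[zero_ss, "PR(>F)"] = 1.0
    f = tab["F"]
    p = tab["PR(>F)"]
    d = tab["df"]
    return AnovaResult(
        f_roi=float(f["C(roi)"]), f_band=float(f["C(band)"]),
        f_interaction=float(f["C(roi):C(band)"]),
        p_roi=float(p["C(roi)"]), p_band=float(p["C(band)"]),
        p_interaction=float(p["C(roi):C(band)"]),
        df=(float(d["C(roi)"]), float(d["C(band)"]),
            float(d["C(roi):C(band)"]), float(d["Residual"])),
    )
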