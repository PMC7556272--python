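"""Group-level statistics.

Demographics: a Lilliefors normality gate routes continuous variables to
a t-test (both groups normal) or a Wilcoxon rank-sum test; gender uses
Fisher's exact test.  Network metrics: per-metric, per-sparsity logistic
regression of group on the metric controlling gender (Wald p for the
metric coefficient), with an additional Bonferroni 0.05/116 flag for
nodal tests.  Metric-score associations: partial Pearson correlation
controlling gender.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

N_ROIS_DEFAULT = 116


@dataclass
class MetricTestResult:
    metric: str
    sparsity: float | None
    coefficient: float | None
    p_value: float | None
    significant_unadjusted: bool
    significant_bonferroni: bool


@dataclass
class PartialCorrelationResult:
    metric: str
    score: str
    sparsity: float | None
    r_partial: float
    p_value: float


def normality_gate(x: np.ndarray, alpha: float = 0.05) -> str:
    """'normal' or 'non-normal' by the Lilliefors test at alpha."""
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("normality gate needs n >= 5")
    if np.ptp(x) == 0.0:
        warnings.warn("constant sample treated as non-normal", stacklevel=2)
        return "non-normal"
    _, p = lilliefors(x, dist="norm")
    return "normal" if p > alpha else "non-normal"


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p (sum of tables as or less probable)."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])


def compare_continuous(x: np.ndarray, y: np.ndarray) -> tuple[str, float, float]:
    """(test name, statistic, p): t-test if both samples pass the
    normality gate, Wilcoxon rank-sum otherwise."""
    if normality_gate(x) == "normal" and normality_gate(y) == "normal":
        stat, p = scipy.stats.ttest_ind(x, y)
        return "t", float(stat), float(p)
    stat, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return "wilcoxon", float(stat), float(p)


def demographics_table(meta: pd.DataFrame, score_names: tuple[str, ...]) -> pd.DataFrame:
    """Per-variable group comparison on a cohort metadata table.

    ``meta`` needs columns group (two levels), gender (M/F) and the named
    score columns.
    """
    groups = sorted(meta["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    g0 = meta[meta["group"] == groups[0]]
    g1 = meta[meta["group"] == groups[1]]
    rows = []
    counts = np.array(
        [
            [(g["gender"] == "M").sum(), (g["gender"] == "F").sum()]
            for g in (g0, g1)
        ]
    )
    rows.append(
        {
            "variable": "gender",
            "test": "fisher",
            "statistic": np.nan,
            "p_value": fisher_exact_2x2(counts),
            groups[0]: f"{counts[0, 0]}/{counts[0, 1]}",
            groups[1]: f"{counts[1, 0]}/{counts[1, 1]}",
        }
    )
    for name in score_names:
        x, y = g0[name].to_numpy(float), g1[name].to_numpy(float)
        test, stat, p = compare_continuous(x, y)
        rows.append(
            {
                "variable": name,
                "test": test,
                "statistic": stat,
                "p_value": p,
                groups[0]: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                groups[1]: f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
            }
        )
    return pd.DataFrame(rows)


def logistic_group_test(
    metric: np.ndarray,
    group: np.ndarray,
    gender: np.ndarray,
    metric_name: str = "metric",
    sparsity: float | None = None,
    n_comparisons: int = N_ROIS_DEFAULT,
) -> MetricTestResult:
    """Wald test of the metric coefficient in group ~ metric + gender.

    ``group`` and ``gender`` may be labels or 0/1.  Perfect separation is
    flagged by returning p = None.
    """
    y = _binary(group)
    g = _binary(gender)
    x = np.asarray(metric, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both groups must be present")
    if not np.all(np.isfinite(x)):
        raise ValueError("metric contains missing values")
    if np.ptp(x) == 0.0:
        # a constant metric is collinear with the intercept: no signal
        return MetricTestResult(metric_name, sparsity, 0.0, 1.0, False, False)
    design = sm.add_constant(np.column_stack([x, g]), has_constant="add")
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        coef = float(fit.params[1])
        p = float(fit.pvalues[1])
        if not np.isfinite(p):
            raise PerfectSeparationError
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return MetricTestResult(metric_name, sparsity, None, None, False, False)
    return MetricTestResult(
        metric=metric_name,
        sparsity=sparsity,
        coefficient=coef,
        p_value=p,
        significant_unadjusted=p < 0.05,
        significant_bonferroni=p < 0.05 / n_comparisons,
    )


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    metric_name: str = "metric",
    score_name: str = "score",
    sparsity: float | None = None,
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing the covariate z.

    z may be labels or numeric (gender coded 0/1); a constant covariate
    reduces to the plain Pearson correlation.  p from a t distribution
    with n - 2 - k degrees of freedom, k = number of non-constant
    covariate columns.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4")
    zcol = _binary(z) if np.asarray(z).dtype.kind in "UOS" else np.asarray(z, dtype=float)
    k = 0 if np.ptp(zcol) == 0 else 1
    design = sm.add_constant(zcol, has_constant="add") if k else np.ones((n, 1))
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df))
    return PartialCorrelationResult(
        metric=metric_name, score=score_name, sparsity=sparsity, r_partial=r, p_value=p
    )


def _binary(labels: np.ndarray) -> np.ndarray:
    """Map a two-level label vector (or 0/1 numbers) to 0/1 floats."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        levels = sorted(np.unique(arr).tolist())
        if len(levels) > 2:
            raise ValueError(f"more than two levels: {levels}")
        positive = "MCI" if set(levels) == {"NC", "MCI"} else levels[-1]
        return (arr == positive).astype(float)
    return arr.astype(float)
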