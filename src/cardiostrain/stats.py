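"""Group comparisons on per-video metrics.

Two groups are compared with an unpaired two-sample t-test (pooled
variance by default, Welch behind a flag); three or more with one-way
ANOVA followed by Tukey's honestly-significant-difference pairwise
comparisons.  Rate-vs-strain confounding is screened with a Pearson
correlation.  Significance threshold is alpha = 0.05 throughout.

The unit of analysis is the video: one maximum-contractile-strain value
and one rate per video, no nesting by biological replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

METRICS_COLUMNS = [
    "video_id",
    "cell_line",
    "stiffness_kpa",
    "timepoint_day",
    "max_contractile_strain",
    "rate_bpm",
]


@dataclass
class TestResult:
    test_name: str
    groups: List[str]
    statistic: float
    p_value: float
    effect_percent: Optional[float] = None
    pairwise: List[dict] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _check_group(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError(f"group {name!r} needs n >= 2, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError(f"group {name!r} contains non-finite values")
    return x


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
    names: tuple = ("a", "b"),
) -> TestResult:
    """Unpaired two-sample t-test with percent-difference effect size.

    Effect is 100 * (mean_a - mean_b) / mean_b.  Pooled variance by
    default; ``welch=True`` drops the equal-variance assumption.
    """
    a = _check_group(a, names[0])
    b = _check_group(b, names[1])
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        # zero pooled variance and equal means: define t = 0, p = 1
        return TestResult(
            test_name="t-test (degenerate: zero variance, equal means)",
            groups=list(names),
            statistic=0.0,
            p_value=1.0,
            effect_percent=0.0,
        )
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    effect = 100.0 * (a.mean() - b.mean()) / b.mean() if b.mean() != 0 else np.nan
    return TestResult(
        test_name="Welch t-test" if welch else "t-test (pooled)",
        groups=list(names),
        statistic=float(t),
        p_value=float(p),
        effect_percent=float(effect),
        details={"mean_a": float(a.mean()), "mean_b": float(b.mean()),
                 "n_a": int(a.size), "n_b": int(b.size)},
    )


def anova_tukey(groups: Dict[str, Sequence[float]]) -> TestResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps label -> metric values.  Adjusted p-values come from
    the studentized-range distribution; a pair is flagged significant at
    adjusted p < 0.05.
    """
    if len(groups) < 2:
        raise ValueError("anova_tukey needs >= 2 groups")
    labels = list(groups)
    arrays = [_check_group(groups[k], k) for k in labels]
    f, p = sps.f_oneway(*arrays)
    tk = sps.tukey_hsd(*arrays)
    pairwise = []
    for i, j in combinations(range(len(labels)), 2):
        padj = float(tk.pvalue[i, j])
        pairwise.append(
            {
                "pair": (labels[i], labels[j]),
                "p_adjusted": padj,
                "significant": padj < ALPHA,
                "mean_difference": float(arrays[i].mean() - arrays[j].mean()),
            }
        )
    return TestResult(
        test_name="one-way ANOVA + Tukey HSD",
        groups=labels,
        statistic=float(f),
        p_value=float(p),
        pairwise=pairwise,
        details={k: {"n": int(v.size), "mean": float(v.mean())} for k, v in zip(labels, arrays)},
    )


def correlation_check(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation between paired metrics (e.g. rate vs strain).

    Used to verify that spontaneous rate is not a confounder of
    contractile strain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("correlation needs paired values, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult(
        test_name="Pearson correlation",
        groups=["x", "y"],
        statistic=float(r),
        p_value=float(p),
        details={"n": int(x.size)},
    )


def metrics_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble per-video metric rows into the standard table."""
    df = pd.DataFrame(list(rows))
    for col in METRICS_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return df[METRICS_COLUMNS]


def compare_metric(
    df: pd.DataFrame,
    metric: str,
    by: str,
    welch: bool = False,
) -> TestResult:
    """Compare one metric column across the levels of a grouping column."""
    sub = df[[by, metric]].dropna()
    levels = sorted(sub[by].unique(), key=str)
    groups = {str(lv): sub.loc[sub[by] == lv, metric].to_numpy() for lv in levels}
    if len(groups) < 2:
        raise ValueError(f"grouping column {by!r} has < 2 levels with data")
    if len(groups) == 2:
        (na, a), (nb, b) = groups.items()
        return two_sample_ttest(a, b, welch=welch, names=(na, nb))
    return anova_tukey(groups)
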