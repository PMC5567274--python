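"""Group-comparison and survival statistics used by the cohort analysis.

Thin, contract-specified wrappers: outlier screening by iterated Grubbs'
test, pooled-variance Student's t, two-tailed Fisher's exact test,
one-way ANOVA with Tukey's HSD (single pooled variance), Kaplan-Meier /
log-rank (Mantel-Cox), and a Cox proportional-hazards adjustment.  The
exact tests and survival machinery delegate to scipy and lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

__all__ = [
    "SurvivalRecord",
    "grubbs_screen",
    "compare_means_ttest",
    "fisher_exact_2x2",
    "anova_tukey",
    "km_logrank",
    "cox_adjust",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months from diagnosis to last follow-up or death
    event: bool  # death observed (False = censored alive)
    group: str
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be >= 0")
        if not self.group:
            raise ValueError("group label must be non-empty")


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value at sample size n."""
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))


def grubbs_screen(
    values: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove extreme studentized deviates (Grubbs' test).

    While G = max|x - mean| / sd exceeds the two-sided critical value at
    ``alpha``, the single most extreme point is removed.  Returns the kept
    values and the removed indices (into the original sequence).  With
    fewer than three points, or zero spread, nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        warnings.warn("Grubbs' test needs n >= 3; returning values unchanged")
        return x, []
    idx = np.arange(x.size)
    removed: list[int] = []
    while x.size >= 3:
        mean, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g > grubbs_critical(x.size, alpha):
            removed.append(int(idx[j]))
            x = np.delete(x, j)
            idx = np.delete(idx, j)
        else:
            break
    return x, removed


def compare_means_ttest(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed pooled-variance Student's t-test (df = n_a + n_b - 2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact p for a 2x2 count table.

    Sums hypergeometric probabilities no larger than the observed
    table's.  An empty margin carries no information: p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


def anova_tukey(
    groups: Sequence[Sequence[float]],
) -> tuple[float, float, dict[tuple[int, int], float]]:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Returns (F, omnibus p, pairwise adjusted p keyed by group index pair);
    Tukey uses the single pooled within-group variance.
    """
    if len(groups) < 3:
        raise ValueError("need at least three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if all(a.std(ddof=1) == 0 for a in arrays) and len(
        {a.mean() for a in arrays}
    ) == 1:
        return 0.0, 1.0, {
            (i, j): 1.0
            for i in range(len(arrays))
            for j in range(i + 1, len(arrays))
        }
    f, p = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairwise = {
        (i, j): float(hsd.pvalue[i, j])
        for i in range(len(arrays))
        for j in range(i + 1, len(arrays))
    }
    return float(f), float(p), pairwise


def _records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "group": [r.group for r in records],
        }
    )


def km_logrank(
    records: Sequence[SurvivalRecord], with_curves: bool = True
) -> tuple[float, float, dict[str, pd.DataFrame]]:
    """Log-rank (Mantel-Cox) comparison with Kaplan-Meier step tables.

    Returns (chi2, p, curves) where ``curves`` maps each group label to
    its KM survival table (empty when ``with_curves`` is off, e.g. in
    large calibration loops).
    """
    df = _records_frame(records)
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups with subjects")
    for g in labels:
        sub = df[df["group"] == g]
        if sub.empty:
            raise ValueError(f"group {g!r} has no subjects")
        if sub["event"].sum() == 0:
            warnings.warn(f"group {g!r} has no events; log-rank is degenerate")
    if len(labels) == 2:
        a = df[df["group"] == labels[0]]
        b = df[df["group"] == labels[1]]
        res = logrank_test(
            a["time"], b["time"], event_observed_A=a["event"],
            event_observed_B=b["event"],
        )
    else:
        res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    curves: dict[str, pd.DataFrame] = {}
    if with_curves:
        for g in labels:
            sub = df[df["group"] == g]
            kmf = KaplanMeierFitter()
            kmf.fit(sub["time"], sub["event"], label=str(g))
            curves[str(g)] = kmf.survival_function_.reset_index().rename(
                columns={"timeline": "time", str(g): "survival"}
            )
    return float(res.test_statistic), float(res.p_value), curves


def cox_adjust(
    records: Sequence[SurvivalRecord],
    covariates: Sequence[str],
) -> pd.DataFrame:
    """Cox proportional-hazards model of survival on the listed covariates.

    Covariates are taken from each record's ``covariates`` mapping;
    categorical values are dummy-coded.  Returns a table with hazard
    ratios and Wald 95% CIs per coefficient.  A constant covariate or a
    non-converging fit raises rather than silently dropping terms.
    """
    df = _records_frame(records)
    for cov in covariates:
        df[cov] = [r.covariates.get(cov) for r in records]
        if df[cov].isna().any():
            raise ValueError(f"covariate {cov!r} missing for some records")
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    model_df = pd.get_dummies(
        df[["time", "event", *covariates]], drop_first=True, dtype=float
    )
    if int(df["event"].sum()) < model_df.shape[1] - 2:
        raise ValueError("fewer events than model coefficients")
    cph = CoxPHFitter()
    try:
        cph.fit(model_df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError and others
        raise RuntimeError(f"Cox model did not converge: {exc}") from exc
    out = cph.summary[
        ["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]
    ].rename(
        columns={
            "exp(coef)": "hr",
            "exp(coef) lower 95%": "hr_lower95",
            "exp(coef) upper 95%": "hr_upper95",
        }
    )
    return out.reset_index(names="covariate")
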