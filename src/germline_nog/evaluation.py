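"""Risk-group evaluation: accuracy/recall, Kaplan-Meier, Cox, group contrasts.

Metric definitions follow the clinical-footnote convention used for
recurrence prediction tables:

* low-risk accuracy  — % of predicted-low samples that did not recur
* low-risk recall    — % of non-recurred samples that were predicted low
* high-risk accuracy — % of predicted-high samples that recurred
* high-risk recall   — % of recurred samples that were predicted high

Unpredicted samples are excluded before any metric; empty denominators are
reported as NA, never as 0.  Survival curves and tests use lifelines
(product-limit estimate, log-rank chi-square with 1 df, Cox partial
likelihood); feature contrasts between predicted groups use Welch's
two-sided t-test.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from ._typing import HIGH, LOW, as_binary_labels

logger = logging.getLogger(__name__)

STAGE_ORDINAL = {"I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class MetricReport:
    n: int
    low_accuracy: float
    low_recall: float
    high_accuracy: float
    high_recall: float
    counts: pd.DataFrame | None = None  # 2x2: call x label


def _calls_series(calls) -> pd.Series:
    """Accept a list of RiskCall, a Series, or a calls DataFrame."""
    if isinstance(calls, pd.Series):
        return calls
    if isinstance(calls, pd.DataFrame):
        return calls["call"]
    return pd.Series({c.sample_id: c.call for c in calls})


def accuracy_recall(calls, labels) -> MetricReport:
    """Compute the four table metrics from calls and recurrence labels."""
    call = _calls_series(calls)
    call = call[call.isin([LOW, HIGH])]
    if call.empty:
        raise ValueError("no samples received a low/high call")
    y = as_binary_labels(labels).reindex(call.index)
    if y.isna().any():
        missing = call.index[y.isna()].tolist()
        raise ValueError(f"labels missing for called samples: {missing}")

    low_nonrec = int(((call == LOW) & (y == 0)).sum())
    low_rec = int(((call == LOW) & (y == 1)).sum())
    high_nonrec = int(((call == HIGH) & (y == 0)).sum())
    high_rec = int(((call == HIGH) & (y == 1)).sum())
    n_low, n_high = low_nonrec + low_rec, high_nonrec + high_rec
    n_nonrec, n_rec = low_nonrec + high_nonrec, low_rec + high_rec

    def pct(num, den):
        return 100.0 * num / den if den else np.nan

    counts = pd.DataFrame(
        [[low_nonrec, low_rec], [high_nonrec, high_rec]],
        index=pd.Index([LOW, HIGH], name="call"),
        columns=pd.Index(["non-recurred", "recurred"], name="label"),
    )
    return MetricReport(
        n=int(len(call)),
        low_accuracy=pct(low_nonrec, n_low),
        low_recall=pct(low_nonrec, n_nonrec),
        high_accuracy=pct(high_rec, n_high),
        high_recall=pct(high_rec, n_rec),
        counts=counts,
    )


def km_logrank(records: pd.DataFrame):
    """Kaplan-Meier curves per risk group plus the log-rank test.

    ``records`` needs columns ``dfs_months``, ``event`` and ``group``
    (low/high).  Returns ``(curves, chi2, p)`` where ``curves`` maps group
    name to the step-function survival estimate.  The reported p is the
    two-sided tail of the chi-square(1) distribution of the log-rank
    statistic.
    """
    rec = records[records["group"].isin([LOW, HIGH])]
    groups = rec["group"].unique()
    if len(groups) < 2:
        raise ValueError("both risk groups are required for a log-rank test")
    if (rec["dfs_months"] < 0).any():
        raise ValueError("negative survival times")
    if rec["event"].astype(bool).sum() == 0:
        raise ValueError("no events observed")

    curves = {}
    for g in (LOW, HIGH):
        sub = rec[rec["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["dfs_months"], sub["event"].astype(bool), label=g)
        curves[g] = kmf.survival_function_

    lo = rec[rec["group"] == LOW]
    hi = rec[rec["group"] == HIGH]
    res = logrank_test(
        lo["dfs_months"], hi["dfs_months"],
        event_observed_A=lo["event"].astype(bool),
        event_observed_B=hi["event"].astype(bool),
    )
    return curves, float(res.test_statistic), float(res.p_value)


def logrank_statistic(time, event, group) -> float:
    """Textbook log-rank chi-square (1 df) computed from first principles.

    Kept independent of lifelines so it can serve as a cross-check and as
    the statistic inside permutation tests.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    g1 = group == group[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0
    return float(o_minus_e**2 / var)


def cox_covariates(records: pd.DataFrame, covariates=("age", "stage", "nodal"),
                   group_p: float | None = None) -> pd.DataFrame:
    """Cox proportional-hazards models over clinical covariates.

    Fits each covariate singly and all jointly; reports the likelihood-
    ratio p per model next to the risk-group log-rank p (computed from the
    ``group`` column when present, or passed in).  Stage is encoded
    ordinally I-IV and nodal status 0-3; X/NA values are dropped.
    Non-convergence is reported per model, not fatal.
    """
    df = records.copy()
    if "stage" in df.columns and df["stage"].dtype == object:
        df["stage"] = df["stage"].map(STAGE_ORDINAL)
    for c in ("nodal", "age"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")

    usable = []
    for c in covariates:
        if c not in df.columns:
            continue
        col = df[c].dropna()
        if col.nunique() < 2:
            logger.warning("covariate %s has no variation, dropped", c)
            continue
        usable.append(c)
    if not usable:
        raise ValueError("no covariates with variation")

    rows = []
    models = [(c, [c]) for c in usable] + [("joint", usable)]
    for name, covs in models:
        sub = df[["dfs_months", "event", *covs]].dropna()
        cph = CoxPHFitter()
        try:
            cph.fit(sub, duration_col="dfs_months", event_col="event")
            lr = cph.log_likelihood_ratio_test()
            rows.append({
                "model": name, "covariates": "+".join(covs),
                "p": float(lr.p_value), "converged": True,
                "coefficients": dict(cph.params_),
            })
        except Exception as exc:  # convergence failures are reported, not raised
            logger.warning("Cox model %s failed: %s", name, exc)
            rows.append({"model": name, "covariates": "+".join(covs),
                         "p": np.nan, "converged": False, "coefficients": {}})
    report = pd.DataFrame(rows)

    if group_p is None and "group" in df.columns and \
            df["group"].isin([LOW, HIGH]).sum() > 0:
        try:
            _, _, group_p = km_logrank(df)
        except ValueError:
            group_p = np.nan
    report.attrs["nog_css_group_p"] = group_p
    return report


@dataclass
class GroupComparison:
    feature: str
    mean_low: float
    mean_high: float
    t_statistic: float
    p_value: float
    df: float
    quartiles_low: tuple[float, float, float] | None = None
    quartiles_high: tuple[float, float, float] | None = None
    q_value: float | None = None


def compare_groups(feature_matrix: pd.DataFrame, calls,
                   adjust: bool = False) -> list[GroupComparison]:
    """Welch two-sided t-test per feature row between predicted risk groups.

    ``feature_matrix`` is features x samples (metagene expression, TIL
    fractions, burden counts...).  Unpredicted samples are excluded;
    groups with fewer than two samples yield NA.  Raw p-values by default;
    ``adjust=True`` adds Benjamini-Hochberg q-values.
    """
    call = _calls_series(calls)
    lo = [s for s in feature_matrix.columns if call.get(s) == LOW]
    hi = [s for s in feature_matrix.columns if call.get(s) == HIGH]
    out = []
    for feat, row in feature_matrix.iterrows():
        a, b = row[lo].dropna(), row[hi].dropna()
        if len(a) < 2 or len(b) < 2:
            out.append(GroupComparison(feat, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        out.append(GroupComparison(
            feature=feat,
            mean_low=float(a.mean()), mean_high=float(b.mean()),
            t_statistic=float(res.statistic), p_value=float(res.pvalue),
            df=float(res.df),
            quartiles_low=tuple(np.percentile(a, [25, 50, 75])),
            quartiles_high=tuple(np.percentile(b, [25, 50, 75])),
        ))
    if adjust:
        pvals = np.array([c.p_value for c in out])
        ok = ~np.isnan(pvals)
        q = np.full_like(pvals, np.nan)
        q[ok] = stats.false_discovery_control(pvals[ok])
        for c, qv in zip(out, q):
            c.q_value = None if np.isnan(qv) else float(qv)
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": c.feature, "mean_low": c.mean_low,
            "mean_high": c.mean_high, "t": c.t_statistic, "p": c.p_value,
            "welch_df": c.df, "q": c.q_value,
        }
        for c in comparisons
    ).set_index("feature")
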