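"""Downstream cancer statistics: co-expression, score distributions, survival.

Three analyses: (1) per-cancer-type Pearson correlation of PPARG and DNMT1
expression in tumor and control cohorts, with t-based significance and a
weak-correlation flag for r in (-0.5, 0.5); (2) a two-sample
Kolmogorov-Smirnov comparison of observed variant evolutionary-action
scores against the all-missense-changes null; (3) median-split
Kaplan-Meier survival with a two-group log-rank test, overall and within
chromosome-3 subgroups.

The KM product-limit estimator, the log-rank statistic and the KS D
statistic are computed directly from their defining formulas; scipy supplies
only the reference distributions (t, chi-square, Kolmogorov).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger(__name__)

WEAK_BAND = (-0.5, 0.5)


# ---------------------------------------------------------------------------
# Pearson correlation with t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    cancer_type: str
    cohort: str
    n: int
    r: float
    t: float
    p: float
    weak_flag: bool
    ci_low: float
    ci_high: float


def pearson_with_test(
    x, y, cancer_type: str = "", cohort: str = "", ci_level: float = 0.95
) -> CorrelationResult:
    """Sample Pearson r with two-sided t significance and a Fisher-z CI.

    t = r sqrt(n-2) / sqrt(1-r^2) against the t distribution with n-2 df.
    The weak flag marks -0.5 < r < 0.5.  Requires n >= 3, finite values and
    non-zero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf
        p = np.nextafter(0, 1)
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    # Fisher z interval
    z = np.arctanh(r) if abs(r) < 1 else np.sign(r) * np.inf
    se = 1.0 / np.sqrt(n - 3) if n > 3 else np.inf
    zc = stats.norm.ppf(0.5 + ci_level / 2)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(
        cancer_type, cohort, n, r, float(t), p,
        WEAK_BAND[0] < r < WEAK_BAND[1], float(lo), float(hi),
    )


def correlate_by_cancer(expression: pd.DataFrame, genes: tuple[str, str] = ("PPARG", "DNMT1")) -> pd.DataFrame:
    """One correlation row per (cancer_type, cohort) in a long table.

    Input columns: sample, cancer_type, cohort, plus the two gene columns.
    Cohorts with fewer than 3 samples are skipped with a warning.  Output is
    sorted by cancer_type then cohort.
    """
    required = {"cancer_type", "cohort", *genes}
    missing = required - set(expression.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    rows = []
    for (ctype, cohort), grp in expression.groupby(["cancer_type", "cohort"], sort=True):
        if len(grp) < 3:
            logger.warning("skipping %s/%s: only %d samples", ctype, cohort, len(grp))
            continue
        res = pearson_with_test(grp[genes[0]], grp[genes[1]], ctype, cohort)
        rows.append(
            {
                "cancer_type": ctype, "cohort": cohort, "n": res.n, "r": res.r,
                "t": res.t, "p": res.p, "neg_log10_p": -np.log10(res.p),
                "weak_flag": res.weak_flag, "ci_low": res.ci_low, "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "cohort", "n", "r", "t", "p", "neg_log10_p",
            "weak_flag", "ci_low", "ci_high",
        ],
    )


# ---------------------------------------------------------------------------
# Two-sample Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KsResult:
    D: float
    p: float
    n_obs: int
    n_null: int


def ks_two_sample(observed_scores, null_scores, method: str = "asymptotic") -> KsResult:
    """Two-sided two-sample KS test.

    D is the supremum ECDF difference, computed over the pooled sample
    points.  The p-value uses the asymptotic Kolmogorov distribution with
    effective n = n1*n2/(n1+n2); ``method='exact'`` delegates to the exact
    small-sample distribution (intended for n <= 25 per sample).
    """
    obs = np.sort(np.asarray(observed_scores, dtype=float))
    nul = np.sort(np.asarray(null_scores, dtype=float))
    n1, n2 = len(obs), len(nul)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([obs, nul])
    cdf1 = np.searchsorted(obs, pooled, side="right") / n1
    cdf2 = np.searchsorted(nul, pooled, side="right") / n2
    D = float(np.max(np.abs(cdf1 - cdf2)))
    ne = n1 * n2 / (n1 + n2)
    if method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(ne) * D))
    elif method == "exact":
        p = float(stats.ks_2samp(obs, nul, method="exact").pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return KsResult(D, p, n1, n2)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmCurve:
    """Product-limit curve: distinct event times with S(t) and at-risk counts."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p: float
    n_a: int
    n_b: int


def median_split(values) -> np.ndarray:
    """Boolean mask of the high group: value > median; ties go low.

    Requires n >= 4 and both resulting groups non-empty (a constant vector
    has no usable split).
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 values for a median split")
    high = v > np.median(v)
    if high.all() or not high.any():
        raise ValueError("degenerate split: all values on one side of the median")
    return high


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod over event times t_i <= t of (1 - d_i / n_i); censored cases
    leave the risk set without dropping the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValueError("empty group")
    if (t <= 0).any():
        raise ValueError("non-positive survival time")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    distinct = np.unique(t[e == 1])
    surv = []
    risk = []
    s = 1.0
    for ti in distinct:
        n_i = int(np.sum(t >= ti))
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        risk.append(n_i)
    return KmCurve(distinct, np.array(surv), np.array(risk, dtype=int), len(t))


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test with the hypergeometric variance.

    At each distinct pooled event time the observed events in group A are
    compared with their expectation under the null; chi-square =
    (sum(O-E))^2 / sum(V) on 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for ti in event_times:
        n1 = int(np.sum(ta >= ti))
        n2 = int(np.sum(tb >= ti))
        n = n1 + n2
        if n < 2:
            continue
        d1 = int(np.sum((ta == ti) & (ea == 1)))
        d2 = int(np.sum((tb == ti) & (eb == 1)))
        d = d1 + d2
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        chi2 = 0.0
    else:
        chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogRankResult(float(chi2), min(max(p, np.nextafter(0, 1)), 1.0), len(ta), len(tb))


def subgroup_survival(
    cohort: pd.DataFrame,
    class_filter: str = "all",
    expression_col: str = "expression",
) -> dict:
    """Median-split KM + log-rank within a chromosome-3 subgroup.

    ``class_filter`` selects all cases, or the disomy3 / monosomy3 stratum;
    the selected cases are split at the median of the expression column and
    the two arms compared.  Returns curves, the log-rank result and per-arm
    sizes.
    """
    if class_filter not in ("all", "disomy3", "monosomy3"):
        raise ValueError(f"unknown class filter {class_filter!r}")
    sub = cohort if class_filter == "all" else cohort[cohort["chr3_class"] == class_filter]
    if len(sub) == 0:
        raise ValueError(f"no cases in subgroup {class_filter!r}")
    high = median_split(sub[expression_col].to_numpy())
    hi, lo = sub[high], sub[~high]
    result = logrank_test(hi["time"], hi["event"], lo["time"], lo["event"])
    return {
        "class_filter": class_filter,
        "n_high": len(hi),
        "n_low": len(lo),
        "km_high": km_estimate(hi["time"], hi["event"]),
        "km_low": km_estimate(lo["time"], lo["event"]),
        "logrank": result,
    }


def km_curve_frame(curve: KmCurve, label: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group": label,
            "time": curve.event_times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
        }
    )
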