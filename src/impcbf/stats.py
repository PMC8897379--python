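"""Cerebrovascular reactivity and correlation-comparison statistics.

CVR (%) = 100 · (mCBF_stress − mCBF_rest) / mCBF_rest, with the stress
session acquired under acetazolamide.  Method agreement is summarized as
Pearson correlation plus the y-on-x regression line of each candidate
method against the arterial-sampling reference, with p-values from the
exact t-test on r.  Two correlations sharing the reference variable are
compared with the Meng–Rosenthal–Rubin z-test for dependent (overlapping)
correlations; the Fisher z-test for independent samples is available as a
fallback when the cross-correlation between the two candidate methods is
unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CvrResult",
    "CorrStats",
    "CorrComparison",
    "cvr",
    "pearson_regression",
    "r_to_p",
    "compare_correlations",
    "build_cohort_index",
    "validation_report",
]


@dataclass
class CvrResult:
    mcbf_rest: float
    mcbf_stress: float
    cvr_percent: float


@dataclass
class CorrStats:
    n: int
    r: float
    slope: float
    intercept: float
    p: float


@dataclass
class CorrComparison:
    r1: float
    r2: float
    n: int
    method: str
    z: float
    p: float
    r12: float | None = None


def cvr(mcbf_rest: float, mcbf_stress: float) -> CvrResult:
    """Percent flow change from rest to acetazolamide stress."""
    if mcbf_rest <= 0:
        raise ValueError(f"rest mCBF must be positive, got {mcbf_rest}")
    pct = (mcbf_stress - mcbf_rest) / mcbf_rest * 100.0
    return CvrResult(mcbf_rest, mcbf_stress, pct)


def r_to_p(r: float, n: int) -> float:
    """Two-sided p-value of Pearson r under the bivariate-normal null.

    Uses the exact t-transform t = r√(n−2)/√(1−r²) with n−2 degrees of
    freedom.  |r| = 1 returns p = 0 (a degenerate, perfectly collinear
    sample).
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_regression(xs, ys) -> CorrStats:
    """Pearson r and the OLS line of y on x, with the exact-t p-value."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("xs and ys must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    sxy = float(xm @ ym)
    r = sxy / np.sqrt(sxx * syy)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    return CorrStats(n=n, r=float(r), slope=float(slope),
                     intercept=intercept, p=r_to_p(r, n))


def compare_correlations(
    r1: float,
    r2: float,
    n: int,
    method: str = "fisher_independent",
    r12: float | None = None,
) -> CorrComparison:
    """Test whether two correlation coefficients differ.

    ``fisher_independent`` assumes r1 and r2 come from independent samples
    of equal size n: z = (atanh r1 − atanh r2) / √(2/(n−3)).

    ``meng_dependent`` (Meng, Rosenthal & Rubin, 1992) handles the
    overlapping case — both correlations measured on the same n subjects
    against a shared reference variable — and requires ``r12``, the
    correlation between the two non-shared variables:

        z = (atanh r1 − atanh r2) · √( (n−3) / (2(1−r12)·h) )

    with r̄² = (r1²+r2²)/2, f = min(1, (1−r12)/(2(1−r̄²))) and
    h = (1 − f·r̄²)/(1 − r̄²).  Two-sided normal p in both cases.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    dz = np.arctanh(r1) - np.arctanh(r2)
    if method == "fisher_independent":
        z = dz / np.sqrt(2.0 / (n - 3))
    elif method == "meng_dependent":
        if r12 is None:
            raise ValueError("meng_dependent requires r12, the correlation "
                             "between the two compared methods")
        rbar2 = (r1 * r1 + r2 * r2) / 2.0
        f = min(1.0, (1.0 - r12) / (2.0 * (1.0 - rbar2)))
        h = (1.0 - f * rbar2) / (1.0 - rbar2)
        z = dz * np.sqrt((n - 3) / (2.0 * (1.0 - r12) * h))
    else:
        raise ValueError(f"unknown method '{method}'")
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CorrComparison(r1=r1, r2=r2, n=n, method=method, z=float(z), p=p, r12=r12)


# ----------------------------------------------------------------------
# cohort bookkeeping and the validation report

def build_cohort_index(n_dual: int, n_rest_only: int, n_stress_only: int) -> pd.DataFrame:
    """Patient/session skeleton of a validation cohort.

    Dual patients contribute a rest and a stress acquisition (and hence a
    CVR row); single-session patients contribute one acquisition and no
    CVR.  Returns a DataFrame with columns ``patient_id`` and ``session``.
    """
    rows = []
    pid = 0
    for _ in range(n_dual):
        rows.append((f"P{pid:03d}", "rest"))
        rows.append((f"P{pid:03d}", "stress"))
        pid += 1
    for _ in range(n_rest_only):
        rows.append((f"P{pid:03d}", "rest"))
        pid += 1
    for _ in range(n_stress_only):
        rows.append((f"P{pid:03d}", "stress"))
        pid += 1
    return pd.DataFrame(rows, columns=["patient_id", "session"])


def _pivot_method(df: pd.DataFrame, method: str) -> pd.Series:
    sub = df[df["method"] == method]
    return sub.set_index(["patient_id", "session"])["mcbf"]


def validation_report(results: pd.DataFrame, reference: str = "ARG") -> dict:
    """Method-agreement report over an acquisition-level mCBF table.

    ``results`` has columns patient_id, session ∈ {rest, stress}, method,
    mcbf.  For each non-reference method the report gives n, Pearson r, the
    regression line of the method (y) on the reference (x) and the p-value,
    over all acquisitions where both were measured; then the dependent-test
    comparison of the first two candidate methods' correlations (r12 taken
    from their own cross-correlation); then the same statistics at the CVR
    level for patients with both sessions.  Patients lacking a stress
    session contribute mCBF rows but no CVR row.
    """
    required = {"patient_id", "session", "method", "mcbf"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table must have columns {sorted(required)}")
    methods = [m for m in results["method"].unique() if m != reference]
    ref = _pivot_method(results, reference)
    if ref.empty:
        raise ValueError(f"no rows for reference method '{reference}'")

    acq = results[["patient_id", "session"]].drop_duplicates()
    counts = {
        "n_patients": int(results["patient_id"].nunique()),
        "n_acquisitions": int(len(acq)),
        "n_rest": int((acq["session"] == "rest").sum()),
        "n_stress": int((acq["session"] == "stress").sum()),
    }

    mcbf_stats: dict[str, CorrStats] = {}
    aligned: dict[str, pd.Series] = {}
    for m in methods:
        s = _pivot_method(results, m)
        common = ref.index.intersection(s.index)
        if len(common) < 3:
            raise ValueError(f"fewer than 3 acquisitions pair '{m}' with '{reference}'")
        mcbf_stats[m] = pearson_regression(ref.loc[common].values, s.loc[common].values)
        aligned[m] = s

    comparison = None
    if len(methods) >= 2:
        m1, m2 = methods[0], methods[1]
        common = ref.index.intersection(aligned[m1].index).intersection(aligned[m2].index)
        r1 = pearson_regression(ref.loc[common].values, aligned[m1].loc[common].values).r
        r2 = pearson_regression(ref.loc[common].values, aligned[m2].loc[common].values).r
        r12 = pearson_regression(aligned[m1].loc[common].values,
                                 aligned[m2].loc[common].values).r
        comparison = compare_correlations(r1, r2, len(common),
                                          method="meng_dependent", r12=r12)

    # CVR level: patients with both sessions for the method and the reference
    def cvr_series(method: str) -> pd.Series:
        s = _pivot_method(results, method).unstack("session")
        if "rest" not in s.columns or "stress" not in s.columns:
            return pd.Series(dtype=float)
        s = s.dropna(subset=["rest", "stress"])
        return 100.0 * (s["stress"] - s["rest"]) / s["rest"]

    ref_cvr = cvr_series(reference)
    cvr_stats: dict[str, CorrStats] = {}
    for m in methods:
        mc = cvr_series(m)
        common = ref_cvr.index.intersection(mc.index)
        if len(common) >= 3:
            cvr_stats[m] = pearson_regression(ref_cvr.loc[common].values,
                                              mc.loc[common].values)
    counts["n_cvr"] = int(len(ref_cvr))

    return {
        "reference": reference,
        "counts": counts,
        "mcbf": mcbf_stats,
        "mcbf_comparison": comparison,
        "cvr": cvr_stats,
    }
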