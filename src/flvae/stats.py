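"""Paired longitudinal comparison of thrombus scores.

Per patient, the change between postoperative and follow-up scores is
``delta = followup - postop``; patients are classed as increased, unchanged
or decreased against a small tolerance (default 5e-4 on normalized scores,
below the display precision of 3 decimals).  At the cohort level the paired
differences are first checked for normality with the D'Agostino-Pearson
omnibus test, then compared to zero with a two-sided paired t-test.

Both tests are implemented from their published formulas so they are testable
in isolation; see the test suite for the cross-checks against SciPy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_UNCHANGED_TOL = 5e-4

CLASS_INCREASED = "increased"
CLASS_UNCHANGED = "unchanged"
CLASS_DECREASED = "decreased"
CHANGE_ORDER = (CLASS_INCREASED, CLASS_UNCHANGED, CLASS_DECREASED)


def classify_change(
    post: float, followup: float, tol: float = DEFAULT_UNCHANGED_TOL
) -> tuple[float, str]:
    """Delta and change class for one patient."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    if not (np.isfinite(post) and np.isfinite(followup)):
        raise ValueError("scores must be finite")
    delta = followup - post
    if abs(delta) <= tol:
        return delta, CLASS_UNCHANGED
    return delta, CLASS_INCREASED if delta > tol else CLASS_DECREASED


def summarize_changes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-class count and mean/min/max delta (3-decimal display rounding).

    ``records`` needs columns ``change_class`` and ``delta``.  Classes with
    no patients are reported with count 0 and NaN statistics.
    """
    if records.empty:
        raise ValueError("no paired records to summarize")
    rows = []
    for cls in CHANGE_ORDER:
        d = records.loc[records["change_class"] == cls, "delta"]
        rows.append(
            {
                "change": cls,
                "n_patients": int(len(d)),
                "mean_difference": round(float(d.mean()), 3) if len(d) else np.nan,
                "min_difference": round(float(d.min()), 3) if len(d) else np.nan,
                "max_difference": round(float(d.max()), 3) if len(d) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def dagostino_pearson(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    Combines D'Agostino's transformed sample skewness (Z1) with the
    Anscombe-Glaisher transformed sample kurtosis (Z2) into
    K2 = Z1^2 + Z2^2, referred to a chi-square distribution with 2 degrees
    of freedom.  Requires n >= 8; warns for n < 20 where the chi-square
    approximation is rough.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"omnibus normality test requires n >= 8, got n = {n}")
    if n < 20:
        warnings.warn(
            f"n = {n} < 20: the chi-square approximation of the omnibus "
            "statistic is inaccurate for small samples"
        )
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for constant input")
    m2 = np.mean((x - x.mean()) ** 2)
    m3 = np.mean((x - x.mean()) ** 3)
    m4 = np.mean((x - x.mean()) ** 4)

    # -- skewness: D'Agostino's Z1
    b1 = m3 / m2**1.5
    y = b1 * np.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = (
        3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3)
        / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1e-30, y)
    z1 = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # -- kurtosis: Anscombe-Glaisher Z2
    b2 = m4 / m2**2
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9))
        * np.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (
        2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1**2)
    )
    term = (1.0 - 2.0 / a) / (1.0 + xk * np.sqrt(2.0 / (a - 4.0)))
    z2 = (
        (1.0 - 2.0 / (9.0 * a)) - np.sign(term) * np.abs(term) ** (1.0 / 3.0)
    ) / np.sqrt(2.0 / (9.0 * a))

    k2 = float(z1**2 + z2**2)
    p = float(sps.chi2.sf(k2, df=2))
    return k2, p


def paired_t(
    post: Sequence[float], followup: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sided paired t-test on d = followup - post.

    t = mean(d) / (sd(d)/sqrt(n)) with the n-1 denominator in sd;
    df = n - 1.  Raises for length mismatch, n < 2, or zero-variance
    differences (e.g. identical arrays).
    """
    a = np.asarray(post, dtype=float)
    b = np.asarray(followup, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test requires n >= 2")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "paired differences have zero variance; t statistic undefined"
        )
    t = float(d.mean() / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * sps.t.sf(abs(t), df))
    return t, df, p


@dataclass
class CohortResult:
    """Paired per-patient records plus cohort-level test results."""

    records: pd.DataFrame  # patient_id, score_postop, score_followup, delta, change_class
    summary: pd.DataFrame  # summarize_changes output
    normality_stat: float
    normality_p: float
    t_stat: float | None
    t_df: int | None
    t_p: float | None
    unchanged_tol: float

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            row["change"]: int(row["n_patients"])
            for _, row in self.summary.iterrows()
        }

    def to_json_dict(self) -> dict:
        return {
            "n_patients": int(len(self.records)),
            "class_counts": self.class_counts,
            "normality": {"statistic": self.normality_stat, "p_value": self.normality_p},
            "paired_t": {"statistic": self.t_stat, "df": self.t_df, "p_value": self.t_p},
            "unchanged_tol": self.unchanged_tol,
        }


def pair_scores(patients: pd.DataFrame) -> pd.DataFrame:
    """Pivot a patient score table into one row per patient.

    Expects columns patient_id, timepoint, and a score column
    (``normalized_score`` preferred, falling back to ``raw_score``).
    Raises with the offending patient ids if any patient does not have
    exactly one postop and one followup row.
    """
    col = "normalized_score" if "normalized_score" in patients else "raw_score"
    bad = []
    for pid, grp in patients.groupby("patient_id"):
        tps = sorted(grp["timepoint"].tolist())
        if tps != ["followup", "postop"]:
            bad.append(str(pid))
    if bad:
        raise ValueError(
            "patients without exactly one postop and one followup series: "
            + ", ".join(sorted(bad))
        )
    wide = patients.pivot(index="patient_id", columns="timepoint", values=col)
    wide = wide.rename(columns={"postop": "score_postop", "followup": "score_followup"})
    return wide.reset_index()[["patient_id", "score_postop", "score_followup"]]


def run_comparison(
    patients: pd.DataFrame | str, tol: float = DEFAULT_UNCHANGED_TOL
) -> CohortResult:
    """Full paired analysis from a patient score table (or its CSV path).

    The normality of the paired differences is evaluated first; the paired
    t-test follows.  A zero-variance cohort (every patient unchanged) reports
    the t-test as undefined rather than failing the whole comparison.
    """
    if isinstance(patients, str):
        patients = pd.read_csv(patients)
    paired = pair_scores(patients)
    deltas, classes = zip(
        *(
            classify_change(r.score_postop, r.score_followup, tol)
            for r in paired.itertuples()
        )
    )
    records = paired.assign(delta=deltas, change_class=classes)
    summary = summarize_changes(records)

    d = records["delta"].to_numpy()
    try:
        k2, norm_p = dagostino_pearson(d)
    except ValueError:
        k2, norm_p = float("nan"), float("nan")
    try:
        t, df, p = paired_t(records["score_postop"], records["score_followup"])
    except ValueError:
        t = df = p = None
    return CohortResult(
        records=records,
        summary=summary,
        normality_stat=k2,
        normality_p=norm_p,
        t_stat=t,
        t_df=df,
        t_p=p,
        unchanged_tol=tol,
    )
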