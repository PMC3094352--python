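"""Baseline-characteristics group comparisons.

Continuous characteristics are compared with Welch's unequal-variance t-test
(computable either from raw values or from published n/mean/SD summaries —
the two agree exactly when the summaries come from the data); categorical
characteristics with Fisher's exact test on the 2×2 counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "SummaryStat", "TTestResult", "welch_t_from_summary", "welch_t_from_data",
    "fisher_exact_2x2", "baseline_table_report",
]


@dataclass(frozen=True)
class SummaryStat:
    """n / mean / SD summary of one group's continuous characteristic."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("summary needs n >= 2")
        if self.sd < 0:
            raise InsufficientDataError("sd must be >= 0")

    @classmethod
    def from_data(cls, x, label: str = "") -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        return cls(n=len(x), mean=float(x.mean()),
                   sd=float(x.std(ddof=1)), label=label)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p_value: float


def welch_t_from_summary(a: SummaryStat, b: SummaryStat) -> TTestResult:
    """Welch's t-test from group summaries, with Welch–Satterthwaite df.

    If both SDs are zero the statistic is undefined; by convention p = 1 for
    equal means (no evidence of a difference without variance information).
    """
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    se2 = va + vb
    if se2 == 0:
        return TTestResult(t=0.0 if a.mean == b.mean else np.inf,
                           df=float(a.n + b.n - 2),
                           p_value=1.0 if a.mean == b.mean else 0.0)
    t = (b.mean - a.mean) / np.sqrt(se2)
    df = se2 ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p_value=float(p))


def welch_t_from_data(x, y) -> TTestResult:
    """Welch's t-test from raw per-patient values."""
    return welch_t_from_summary(SummaryStat.from_data(x),
                                SummaryStat.from_data(y))


def fisher_exact_2x2(table) -> dict:
    """Fisher's exact test on a 2×2 count table.

    Two-sided p by the minimum-likelihood convention (sum over tables at most
    as probable as the observed one); the one-sided (greater) p is also
    returned. A zero margin carries no information: p = 1 with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InsufficientDataError("need a 2×2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("2×2 table has a zero margin; p = 1", stacklevel=2)
        return dict(p_two_sided=1.0, p_one_sided=1.0, odds_ratio=np.nan)
    odds, p2 = stats.fisher_exact(t, alternative="two-sided")
    _, p1 = stats.fisher_exact(t, alternative="greater")
    return dict(p_two_sided=float(p2), p_one_sided=float(p1),
                odds_ratio=float(odds))


def baseline_table_report(cov: pd.DataFrame,
                          continuous=("age", "t2_volume"),
                          categorical=("sex", "gad_present")) -> pd.DataFrame:
    """Group-comparison table of baseline characteristics.

    ``cov`` needs ``label`` (GR/PR) plus the characteristic columns; excluded
    patients (``exclusion_flag == 1``) are dropped. Continuous rows report
    mean (SD) per group with a Welch p; categorical rows report percentage
    positive (F for sex) with a Fisher exact p. Display rounding of p-values
    to two decimals is left to the caller.
    """
    if "exclusion_flag" in cov:
        cov = cov[cov["exclusion_flag"] == 0]
    groups = sorted(cov["label"].unique())
    if len(groups) < 2:
        raise InsufficientDataError(f"need two responder groups, found {groups}")
    gr = cov[cov["label"] == "GR"]
    pr = cov[cov["label"] == "PR"]
    rows = []
    for col in continuous:
        res = welch_t_from_data(gr[col], pr[col])
        rows.append(dict(
            characteristic=col, kind="continuous",
            gr_n=len(gr), pr_n=len(pr),
            gr_value=f"{gr[col].mean():.2f} ({gr[col].std(ddof=1):.2f})",
            pr_value=f"{pr[col].mean():.2f} ({pr[col].std(ddof=1):.2f})",
            p_value=res.p_value))
    for col in categorical:
        pos = (cov[col].astype(str).str.upper() == "F") if col == "sex" \
            else cov[col].astype(int) == 1
        k_gr = int(pos[gr.index].sum())
        k_pr = int(pos[pr.index].sum())
        table = [[k_gr, len(gr) - k_gr], [k_pr, len(pr) - k_pr]]
        res = fisher_exact_2x2(table)
        rows.append(dict(
            characteristic=col, kind="categorical",
            gr_n=len(gr), pr_n=len(pr),
            gr_value=f"{100 * k_gr / len(gr):.1f}%",
            pr_value=f"{100 * k_pr / len(pr):.1f}%",
            p_value=res["p_two_sided"]))
    return pd.DataFrame(rows)
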