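"""Induction ratios and longitudinal stability of the molecular response.

The induction ratio (IR) of a gene is the ratio of its (optionally
background-corrected, optionally total-signal-normalized) membrane signal 12 h
after an injection to the pre-injection signal. IR > 1 means induction,
IR < 1 repression; IR >= 2.0 defines an *induced* gene. The stability of a
patient's response fingerprint between two injections is the Pearson
correlation of log2 IRs across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientDataError

__all__ = [
    "IRMatrix",
    "compute_ir",
    "count_induced",
    "induced_counts",
    "stability_correlation",
    "per_patient_stability",
    "cohort_stability_summary",
    "StabilitySummary",
    "DEFAULT_INDUCTION_THRESHOLD",
]

DEFAULT_INDUCTION_THRESHOLD = 2.0


class IRMatrix:
    """Induction ratios per (patient, gene, timepoint) with a log2 view.

    Thin wrapper over a tidy table with columns ``patient_id``, ``timepoint``,
    ``gene_id``, ``ir``; wide patient × gene matrices per time point are
    produced on demand and cached.
    """

    def __init__(self, table: pd.DataFrame,
                 induction_threshold: float = DEFAULT_INDUCTION_THRESHOLD):
        required = {"patient_id", "timepoint", "gene_id", "ir"}
        missing = required - set(table.columns)
        if missing:
            raise DataError(f"IR table missing columns: {sorted(missing)}")
        if induction_threshold <= 1.0:
            raise DataError("induction_threshold must be > 1")
        if not np.all(np.isfinite(table["ir"])) or (table["ir"] <= 0).any():
            bad = table.loc[~np.isfinite(table["ir"]) | (table["ir"] <= 0),
                            ["patient_id", "gene_id"]]
            raise DataError(
                "nonpositive or nonfinite IRs for records: "
                + "; ".join(f"({p}, {g})" for p, g in bad.itertuples(index=False)))
        dup = table.duplicated(["patient_id", "timepoint", "gene_id"])
        if dup.any():
            raise DataError("duplicate (patient, timepoint, gene) records")
        self._table = table.reset_index(drop=True)
        self.induction_threshold = float(induction_threshold)
        self._wide_cache: dict = {}

    @property
    def long(self) -> pd.DataFrame:
        """Tidy table with an added ``log2_ir`` column."""
        out = self._table.copy()
        out["log2_ir"] = np.log2(out["ir"])
        return out

    def timepoints(self) -> list:
        return sorted(self._table["timepoint"].unique().tolist())

    def patients(self, timepoint=None) -> list:
        t = self._table
        if timepoint is not None:
            t = t[t["timepoint"] == timepoint]
        return sorted(t["patient_id"].unique().tolist())

    def genes(self) -> list:
        return sorted(self._table["gene_id"].unique().tolist())

    def wide(self, timepoint) -> pd.DataFrame:
        """Patients × genes matrix of raw IRs at one time point."""
        if timepoint not in self._wide_cache:
            sub = self._table[self._table["timepoint"] == timepoint]
            if sub.empty:
                raise KeyError(f"timepoint {timepoint!r} not present")
            self._wide_cache[timepoint] = sub.pivot(
                index="patient_id", columns="gene_id", values="ir")
        return self._wide_cache[timepoint]

    def log2_wide(self, timepoint) -> pd.DataFrame:
        return np.log2(self.wide(timepoint))


def compute_ir(intensities: pd.DataFrame, background=None,
               normalize: str | None = None,
               induction_threshold: float = DEFAULT_INDUCTION_THRESHOLD) -> IRMatrix:
    """Compute induction ratios from pre/post-injection signal records.

    Parameters
    ----------
    intensities
        Columns ``patient_id, timepoint, gene_id, pre_signal, post_signal``.
    background
        ``None``, a scalar offset subtracted from every signal, or an
        array/Series aligned with the rows of ``intensities``.
    normalize
        ``None`` (default) or ``"total"``: divide each signal by the total
        signal of its (patient, timepoint, channel) before taking the ratio,
        compensating for per-membrane labelling/exposure differences.

    Raises
    ------
    DataError
        If pre or post signals are missing, or any background-corrected
        signal is nonpositive (offending (patient, gene) pairs are listed).
    """
    required = {"patient_id", "timepoint", "gene_id", "pre_signal", "post_signal"}
    missing = required - set(intensities.columns)
    if missing:
        raise DataError(f"intensity table missing columns: {sorted(missing)}")
    df = intensities.copy()
    if df[["pre_signal", "post_signal"]].isna().any().any():
        bad = df.loc[df[["pre_signal", "post_signal"]].isna().any(axis=1),
                     ["patient_id", "gene_id"]]
        raise DataError("missing pre or post signal for records: "
                        + "; ".join(f"({p}, {g})"
                                    for p, g in bad.itertuples(index=False)))
    pre = df["pre_signal"].to_numpy(dtype=float)
    post = df["post_signal"].to_numpy(dtype=float)
    if background is not None:
        bg = np.asarray(background, dtype=float)
        if bg.ndim == 0:
            bg = np.full(len(df), float(bg))
        if (bg < 0).any():
            raise DataError("background offsets must be nonnegative")
        pre = pre - bg
        post = post - bg
    nonpos = (pre <= 0) | (post <= 0)
    if nonpos.any():
        bad = df.loc[nonpos, ["patient_id", "gene_id"]]
        raise DataError(
            "nonpositive background-corrected signal for records: "
            + "; ".join(f"({p}, {g})" for p, g in bad.itertuples(index=False)))
    if normalize == "total":
        key = df[["patient_id", "timepoint"]].apply(tuple, axis=1)
        pre = pre / pd.Series(pre).groupby(key).transform("sum").to_numpy()
        post = post / pd.Series(post).groupby(key).transform("sum").to_numpy()
    elif normalize is not None:
        raise DataError(f"unknown normalization {normalize!r}")
    out = df[["patient_id", "timepoint", "gene_id"]].copy()
    out["ir"] = post / pre
    return IRMatrix(out, induction_threshold=induction_threshold)


def count_induced(ir: IRMatrix, patient_id, timepoint,
                  threshold: float | None = None) -> int:
    """Number of genes with IR >= threshold (inclusive) for one patient."""
    thr = ir.induction_threshold if threshold is None else threshold
    wide = ir.wide(timepoint)
    if patient_id not in wide.index:
        raise KeyError(f"patient {patient_id!r} not present at timepoint {timepoint!r}")
    row = wide.loc[patient_id].dropna()
    return int((row >= thr).sum())


def induced_counts(ir: IRMatrix, timepoint,
                   threshold: float | None = None) -> pd.Series:
    """Per-patient induced-gene counts at one time point."""
    thr = ir.induction_threshold if threshold is None else threshold
    return (ir.wide(timepoint) >= thr).sum(axis=1)


def stability_correlation(ir: IRMatrix, patient_id, timepoint_a, timepoint_b) -> float:
    """Pearson r of a patient's log2 IRs across genes at two time points.

    Genes missing at either time point are dropped pairwise; at least three
    complete pairs are required.
    """
    a = ir.log2_wide(timepoint_a)
    b = ir.log2_wide(timepoint_b)
    for tp, w in ((timepoint_a, a), (timepoint_b, b)):
        if patient_id not in w.index:
            raise KeyError(f"patient {patient_id!r} not present at timepoint {tp!r}")
    pair = pd.concat([a.loc[patient_id], b.loc[patient_id]], axis=1).dropna()
    if len(pair) < 3:
        raise InsufficientDataError(
            f"patient {patient_id!r}: only {len(pair)} complete gene pairs "
            f"between timepoints {timepoint_a!r} and {timepoint_b!r} (need >= 3)")
    return float(stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])[0])


def per_patient_stability(ir: IRMatrix, timepoint_a=0, timepoint_b=6,
                          exclude=()) -> pd.Series:
    """Stability correlations for every non-excluded patient present at both
    time points."""
    excl = set(exclude)
    patients = [p for p in ir.patients(timepoint_a)
                if p in set(ir.patients(timepoint_b)) and p not in excl]
    return pd.Series(
        {p: stability_correlation(ir, p, timepoint_a, timepoint_b)
         for p in patients}, name="stability_r")


@dataclass
class StabilitySummary:
    """Per-group mean ± SD of per-patient stability correlations, the pooled
    pairwise correlations for the long-term subset, and the exclusions."""

    per_group: pd.DataFrame   # index: group + 'overall'; columns n, mean_r, sd_r
    pooled: pd.DataFrame      # group, timepoint_a, timepoint_b, r, n_points
    excluded: pd.DataFrame    # patient_id, reason


def cohort_stability_summary(ir: IRMatrix, labels: pd.DataFrame,
                             exclusions: pd.DataFrame | None = None,
                             timepoint_a=0, timepoint_b=6) -> StabilitySummary:
    """Summarize response stability for the cohort.

    ``labels`` must cover every non-excluded patient (columns ``patient_id``,
    ``label``). Patients with data at three or more time points additionally
    contribute to pooled all-genes correlations for every time-point pair.
    """
    if exclusions is not None and len(exclusions):
        excl = exclusions[["patient_id"]].assign(
            reason=exclusions.get("reason", exclusions.get("exclusion_reason", "")))
    else:
        excl = pd.DataFrame(columns=["patient_id", "reason"])
    r = per_patient_stability(ir, timepoint_a, timepoint_b,
                              exclude=excl["patient_id"])
    lab = labels.set_index("patient_id")["label"]
    missing = [p for p in r.index if p not in lab.index]
    if missing:
        raise DataError(f"labels missing for patients: {missing}")

    rows = []
    for grp, vals in r.groupby(lab.reindex(r.index)):
        if len(vals) == 0:
            raise InsufficientDataError(f"group {grp!r} empty after exclusions")
        rows.append(dict(group=grp, n=len(vals), mean_r=vals.mean(),
                         sd_r=vals.std(ddof=1) if len(vals) > 1 else 0.0))
    if not rows:
        raise InsufficientDataError("no patients left after exclusions")
    rows.append(dict(group="overall", n=len(r), mean_r=r.mean(),
                     sd_r=r.std(ddof=1) if len(r) > 1 else 0.0))
    per_group = pd.DataFrame(rows).set_index("group")

    # pooled pairwise correlations over the subset assayed at >= 3 time points
    tps = ir.timepoints()
    pooled_rows = []
    if len(tps) >= 3:
        subset = [p for p in r.index
                  if all(p in ir.wide(tp).index for tp in tps)]
        for grp in sorted(set(lab.reindex(subset))):
            members = [p for p in subset if lab[p] == grp]
            if not members:
                continue
            for i, ta in enumerate(tps):
                for tb in tps[i + 1:]:
                    xs, ys = [], []
                    for p in members:
                        pair = pd.concat([ir.log2_wide(ta).loc[p],
                                          ir.log2_wide(tb).loc[p]], axis=1).dropna()
                        xs.append(pair.iloc[:, 0].to_numpy())
                        ys.append(pair.iloc[:, 1].to_numpy())
                    x = np.concatenate(xs)
                    y = np.concatenate(ys)
                    pooled_rows.append(dict(
                        group=grp, timepoint_a=ta, timepoint_b=tb,
                        r=float(stats.pearsonr(x, y)[0]), n_points=len(x)))
    pooled = pd.DataFrame(pooled_rows,
                          columns=["group", "timepoint_a", "timepoint_b",
                                   "r", "n_points"])
    return StabilitySummary(per_group=per_group, pooled=pooled, excluded=excl)
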