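"""Good- vs poor-responder comparison of the molecular response.

For each regulated gene, covariate-adjusted least-squares means of the
log2-transformed IRs are compared between responder groups by ANCOVA
(covariates: baseline age, sex, presence of gadolinium-enhancing lesions, and
T2 lesion volume). A gene shows an *exaggerated* response when the
poor-responder adjusted mean lies further from no-change in the gene's
regulated direction (PR > GR for upregulated genes, PR < GR for
downregulated). Whether exaggerated genes exceed half of all regulated genes
is tested with an exact one-sided binomial test against p <= 0.5.

A per-patient *magnitude of exaggeration* score sums, over regulated genes,
how far the patient's raw IR exceeds the cohort median in the regulated
direction; group differences in the score are tested with the same ANCOVA
machinery on the untransformed score.

The least-squares fit is vectorized across genes (one shared design matrix,
many responses), which keeps replicate-cohort simulations cheap; it is
cross-checked against statsmodels OLS in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientDataError, ModelError
from .genes import DOWNREGULATED, UPREGULATED
from .induction import IRMatrix

__all__ = [
    "AncovaResult", "ExaggerationResult", "MagnitudeScore",
    "ancova_lsmeans", "ancova_lsmeans_all", "flag_exaggeration",
    "binomial_proportion_test", "magnitude_score",
    "magnitude_group_comparison", "poisson_induced_count_test",
]

COVARIATE_COLUMNS = ("age", "sex", "gad_present", "t2_volume")


@dataclass
class AncovaResult:
    """Covariate-adjusted group comparison for a single response."""

    adjusted_mean_gr: float
    adjusted_mean_pr: float
    p_value: float
    df_resid: int
    n: int
    response: str = ""


@dataclass
class ExaggerationResult:
    """Per-gene exaggeration flags plus the cohort-level binomial test."""

    per_gene: pd.DataFrame    # gene_id-indexed: direction, adj means, p, exaggerated
    n_regulated: int
    n_exaggerated: int
    binomial_p: float

    @property
    def proportion(self) -> float:
        return self.n_exaggerated / self.n_regulated if self.n_regulated else float("nan")


@dataclass
class MagnitudeScore:
    """Per-patient exaggeration-magnitude scores and their per-gene parts."""

    scores: pd.Series          # patient_id -> score (IR units)
    contributions: pd.DataFrame  # patients × regulated genes
    medians: pd.Series         # gene_id -> cohort median IR


# ---------------------------------------------------------------------------
# ANCOVA machinery


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design with intercept, PR indicator and the four baseline covariates.

    Returns (X, column names, row giving each group's LS-mean evaluation
    point stacked as a 2×p array [GR; PR]): covariates at their grand means,
    including the mean of the sex indicator.
    """
    required = {"patient_id", "label", *COVARIATE_COLUMNS}
    missing = required - set(cov.columns)
    if missing:
        raise DataError(f"covariate table missing columns: {sorted(missing)}")
    if cov[list(COVARIATE_COLUMNS)].isna().any().any():
        raise DataError("missing covariate values for included patients")
    group = (cov["label"] == "PR").to_numpy(dtype=float)
    for lab in ("GR", "PR"):
        if (cov["label"] == lab).sum() < 2:
            raise ModelError(f"group {lab!r} has fewer than 2 patients")
    sex = (cov["sex"].astype(str).str.upper() == "F").to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(cov)), group,
        cov["age"].to_numpy(dtype=float), sex,
        cov["gad_present"].to_numpy(dtype=float),
        cov["t2_volume"].to_numpy(dtype=float)])
    names = ["intercept", "group_pr", "age", "sex_female", "gad_present",
             "t2_volume"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        const = [n for n, col in zip(names[1:], X.T[1:]) if np.ptp(col) == 0]
        detail = (f"constant columns {const}" if const
                  else "a covariate is confounded with another term")
        raise ModelError(f"rank-deficient ANCOVA design: {detail}")
    xbar = X.mean(axis=0)
    eval_pts = np.vstack([xbar, xbar])
    eval_pts[0, 1] = 0.0  # GR
    eval_pts[1, 1] = 1.0  # PR
    return X, names, eval_pts


def _ols_group_test(X: np.ndarray, Y: np.ndarray,
                    eval_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Least-squares fit of many responses on one design.

    Returns (lsmeans (2, k), p-values (k,), group coefficients (k,), df)."""
    n, p = X.shape
    if n <= p:
        raise InsufficientDataError(f"need more than {p} patients, have {n}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)              # (p, k)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df  # (k,)
    # an exactly-interpolated response leaves only rounding noise
    tiny = np.finfo(float).eps * np.maximum((Y ** 2).sum(axis=0), 1.0)
    sigma2 = np.where(sigma2 <= tiny, 0.0, sigma2)
    se_group = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se_group > 0, beta[1] / se_group, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    pval = np.where(se_group > 0, pval, 1.0)
    lsmeans = eval_pts @ beta               # (2, k)
    return lsmeans, pval, beta[1], df


def _aligned_cov(cov: pd.DataFrame, patients: pd.Index) -> pd.DataFrame:
    cov = cov[cov.get("exclusion_flag", 0) == 0] if "exclusion_flag" in cov else cov
    sub = cov.set_index("patient_id").reindex(patients)
    if sub["label"].isna().any():
        missing = sub.index[sub["label"].isna()].tolist()
        raise DataError(f"covariates/labels missing for patients: {missing}")
    return sub.reset_index()


def ancova_lsmeans_all(ir: IRMatrix, cls: pd.DataFrame, cov: pd.DataFrame,
                       timepoint, exclude=()) -> pd.DataFrame:
    """ANCOVA comparison for every retained gene at one time point.

    ``cls`` is the classification frame from :func:`~ifnresponse.genes.classify_genes`;
    ``cov`` must carry ``label`` (GR/PR) plus the baseline covariates. Adjusted
    means are back-transformed to the IR scale (2**LS-mean of log2 IR).
    Returns a gene-indexed frame with ``direction``, ``adj_mean_gr``,
    ``adj_mean_pr`` and ``p_value``.
    """
    retained = cls.index[~cls["filtered_out"]]
    wide = ir.wide(timepoint)
    wide = wide.drop(index=[p for p in exclude if p in wide.index])
    sub = _aligned_cov(cov, wide.index)
    X, _, eval_pts = _design_matrix(sub)
    Y = np.log2(wide[retained].to_numpy(dtype=float))
    if np.isnan(Y).any():
        # pairwise-complete fits would need per-gene designs; fall back to
        # mean imputation only if a spot failed for very few patients
        raise DataError("missing IRs among retained genes; "
                        "drop incomplete patients or genes first")
    lsmeans, pval, _, df = _ols_group_test(X, Y, eval_pts)
    out = pd.DataFrame({
        "direction": cls.loc[retained, "status"],
        "adj_mean_gr": 2.0 ** lsmeans[0],
        "adj_mean_pr": 2.0 ** lsmeans[1],
        "p_value": pval,
    }, index=retained)
    out["p_bh"] = _benjamini_hochberg(out["p_value"].to_numpy())
    out.index.name = "gene_id"
    return out


def ancova_lsmeans(ir: IRMatrix, cls: pd.DataFrame, cov: pd.DataFrame,
                   timepoint, gene, exclude=()) -> AncovaResult:
    """ANCOVA result for a single retained gene (see :func:`ancova_lsmeans_all`)."""
    if gene not in cls.index:
        raise KeyError(f"gene {gene!r} not classified")
    if cls.loc[gene, "filtered_out"]:
        raise DataError(f"gene {gene!r} was filtered out; no group comparison")
    table = ancova_lsmeans_all(ir, cls, cov, timepoint, exclude=exclude)
    row = table.loc[gene]
    n = len(ir.wide(timepoint).index.difference(pd.Index(exclude)))
    return AncovaResult(adjusted_mean_gr=float(row["adj_mean_gr"]),
                        adjusted_mean_pr=float(row["adj_mean_pr"]),
                        p_value=float(row["p_value"]),
                        df_resid=n - 6, n=n, response=str(gene))


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# exaggeration


def flag_exaggeration(per_gene: pd.DataFrame,
                      cls: pd.DataFrame | None = None) -> ExaggerationResult:
    """Flag exaggerated genes and test their proportion.

    A gene is exaggerated iff (strictly) PR adjusted mean > GR for
    upregulated genes, or PR < GR for downregulated genes; ties and
    undetermined-direction genes are never flagged. The binomial denominator
    is every gene outside the filter band (undetermined genes included — they
    count against the exaggeration proportion but can never be flagged).
    """
    required = {"direction", "adj_mean_gr", "adj_mean_pr"}
    missing = required - set(per_gene.columns)
    if missing:
        raise DataError(f"per-gene table missing columns: {sorted(missing)}")
    if per_gene["direction"].isna().any():
        raise DataError("direction missing for some genes")
    up = per_gene["direction"] == UPREGULATED
    down = per_gene["direction"] == DOWNREGULATED
    flags = ((up & (per_gene["adj_mean_pr"] > per_gene["adj_mean_gr"]))
             | (down & (per_gene["adj_mean_pr"] < per_gene["adj_mean_gr"])))
    out = per_gene.copy()
    out["exaggerated"] = flags
    n_reg = int(len(per_gene))
    k = int(flags.sum())
    return ExaggerationResult(per_gene=out, n_regulated=n_reg,
                              n_exaggerated=k,
                              binomial_p=binomial_proportion_test(k, n_reg))


def binomial_proportion_test(k: int, n: int) -> float:
    """Exact one-sided binomial test of proportion <= 0.5.

    Upper-tail probability P(X >= k) for X ~ Binomial(n, 1/2).
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if not 0 <= k <= n:
        raise DataError(f"k={k} outside [0, n={n}]")
    return float(stats.binom.sf(k - 1, n, 0.5))


# ---------------------------------------------------------------------------
# magnitude of exaggeration


def magnitude_score(ir: IRMatrix, cls: pd.DataFrame, timepoint,
                    patient=None, exclude=(),
                    per_group_medians: pd.DataFrame | None = None) -> MagnitudeScore:
    """Per-patient sum of exaggerated amounts on the raw IR scale.

    For each regulated gene with cohort median m: a patient contributes
    max(0, IR − m) if the gene is upregulated, max(0, m − IR) if
    downregulated, and nothing for undetermined genes. Medians are taken over
    all included patients pooled across responder groups; pass
    ``per_group_medians`` (a labels frame) to use within-group medians
    instead.
    """
    wide = ir.wide(timepoint)
    wide = wide.drop(index=[p for p in exclude if p in wide.index])
    if patient is not None and patient not in wide.index:
        if patient in set(exclude):
            raise DataError(f"patient {patient!r} is excluded from the analysis")
        raise KeyError(f"patient {patient!r} not present at timepoint {timepoint!r}")
    up_genes = cls.index[cls["status"] == UPREGULATED]
    down_genes = cls.index[cls["status"] == DOWNREGULATED]
    genes = up_genes.append(down_genes)
    sub = wide[genes]
    if per_group_medians is not None:
        lab = per_group_medians.set_index("patient_id")["label"].reindex(sub.index)
        group_med = sub.groupby(lab).median()
        med = group_med.loc[lab].set_axis(sub.index)
        excess_up = sub[up_genes] - med[up_genes]
        excess_down = med[down_genes] - sub[down_genes]
    else:
        medians = sub.median(axis=0)
        excess_up = sub[up_genes] - medians[up_genes]
        excess_down = medians[down_genes] - sub[down_genes]
    contrib = pd.concat([excess_up, excess_down], axis=1)[genes].clip(lower=0.0)
    scores = contrib.sum(axis=1)
    scores.name = "magnitude_score"
    result = MagnitudeScore(scores=scores, contributions=contrib,
                            medians=sub.median(axis=0))
    if patient is not None:
        result.scores = scores.loc[[patient]]
        result.contributions = contrib.loc[[patient]]
    return result


def magnitude_group_comparison(scores: pd.Series,
                               cov: pd.DataFrame) -> AncovaResult:
    """ANCOVA on the untransformed magnitude scores (same covariates as the
    per-gene analysis)."""
    sub = _aligned_cov(cov, scores.index)
    X, _, eval_pts = _design_matrix(sub)
    Y = scores.to_numpy(dtype=float)[:, None]
    lsmeans, pval, _, df = _ols_group_test(X, Y, eval_pts)
    return AncovaResult(adjusted_mean_gr=float(lsmeans[0, 0]),
                        adjusted_mean_pr=float(lsmeans[1, 0]),
                        p_value=float(pval[0]), df_resid=df,
                        n=len(scores), response="magnitude_score")


# ---------------------------------------------------------------------------
# induced-count comparison


def poisson_induced_count_test(counts: pd.Series, labels: pd.DataFrame) -> dict:
    """Poisson regression of induced-gene counts on responder group.

    Two-sided Wald test of the group (PR vs GR) coefficient in a log-linear
    model. Returns rate ratio (PR/GR) and p-value.
    """
    import statsmodels.api as sm

    lab = labels.set_index("patient_id")["label"].reindex(counts.index)
    if lab.isna().any():
        raise DataError(f"labels missing for patients: "
                        f"{counts.index[lab.isna()].tolist()}")
    y = counts.to_numpy(dtype=float)
    if (y < 0).any():
        raise DataError("counts must be nonnegative")
    if y.sum() == 0:
        raise ModelError("all induced-gene counts are zero; Poisson fit degenerate")
    g = (lab == "PR").to_numpy(dtype=float)
    for grp, mask in (("GR", g == 0), ("PR", g == 1)):
        if mask.sum() < 2:
            raise InsufficientDataError(f"group {grp!r} has fewer than 2 patients")
    X = np.column_stack([np.ones_like(g), g])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return dict(rate_ratio=float(np.exp(fit.params[1])),
                p_value=float(fit.pvalues[1]),
                rate_gr=float(np.exp(fit.params[0])),
                rate_pr=float(np.exp(fit.params[0] + fit.params[1])))
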