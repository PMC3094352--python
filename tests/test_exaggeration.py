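"""ANCOVA LS means, exaggeration flags, binomial test, magnitude score,
Poisson induced-count comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from conftest import make_ir
from ifnresponse.errors import (DataError, InsufficientDataError, ModelError)
from ifnresponse.exaggeration import (ancova_lsmeans, ancova_lsmeans_all,
                                      binomial_proportion_test,
                                      flag_exaggeration,
                                      magnitude_group_comparison,
                                      magnitude_score,
                                      poisson_induced_count_test)
from ifnresponse.genes import classify_genes


def _cov_table(n_gr=6, n_pr=6, seed=0):
    rng = np.random.default_rng(seed)
    n = n_gr + n_pr
    return pd.DataFrame({
        "patient_id": [f"P{i + 1}" for i in range(n)],
        "label": ["GR"] * n_gr + ["PR"] * n_pr,
        "age": rng.uniform(20, 55, n).round(1),
        "sex": rng.choice(["F", "M"], n),
        "gad_present": rng.integers(0, 2, n),
        "t2_volume": rng.uniform(0.5, 12, n).round(2),
    })


def _small_ir(cov, log2_ir):
    return make_ir({pid: [2.0 ** v] for pid, v in
                    zip(cov["patient_id"], log2_ir)})


class TestAncova:
    def test_lsmeans_equal_normal_equations_oracle(self):
        """Hand-rolled normal-equations solution on a small table."""
        cov = _cov_table(seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(1.0, 0.8, len(cov))
        y[cov["label"] == "PR"] += 0.9
        ir = _small_ir(cov, y)
        cls = classify_genes(ir, 0)
        res = ancova_lsmeans(ir, cls, cov, 0, "G001")

        X = np.column_stack([
            np.ones(len(cov)), (cov["label"] == "PR").astype(float),
            cov["age"], (cov["sex"] == "F").astype(float),
            cov["gad_present"], cov["t2_volume"]])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log2(2.0 ** y))
        xbar = X.mean(axis=0)
        ls_gr = xbar @ beta - xbar[1] * beta[1]
        ls_pr = ls_gr + beta[1]
        assert res.adjusted_mean_gr == pytest.approx(2.0 ** ls_gr, rel=1e-10)
        assert res.adjusted_mean_pr == pytest.approx(2.0 ** ls_pr, rel=1e-10)

    def test_group_p_value_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        cov = _cov_table(n_gr=10, n_pr=8, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(0.5, 0.6, len(cov)) + 0.02 * cov["age"].to_numpy()
        ir = _small_ir(cov, y)
        cls = classify_genes(ir, 0)
        res = ancova_lsmeans(ir, cls, cov, 0, "G001")

        X = sm.add_constant(np.column_stack([
            (cov["label"] == "PR").astype(float), cov["age"],
            (cov["sex"] == "F").astype(float), cov["gad_present"],
            cov["t2_volume"]]))
        fit = sm.OLS(y, X).fit()
        assert res.p_value == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_null_case_adjusted_means_close_and_p_uniform(self):
        """With no group effect, the group-coefficient p-value is uniform."""
        rejections = 0
        n_sims = 200
        for s in range(n_sims):
            cov = _cov_table(n_gr=20, n_pr=10, seed=s)
            y = np.random.default_rng(1000 + s).normal(1.0, 0.5, len(cov))
            ir = _small_ir(cov, y)
            cls = classify_genes(ir, 0)
            res = ancova_lsmeans_all(ir, cls, cov, 0)
            rejections += int(res["p_value"].iloc[0] < 0.05)
        assert 0.01 <= rejections / n_sims <= 0.10

    def test_rank_deficient_design_raises_model_error(self):
        cov = _cov_table(seed=5)
        cov["gad_present"] = 1  # constant, confounded with the intercept
        ir = _small_ir(cov, np.linspace(0.2, 1.4, len(cov)))
        cls = classify_genes(ir, 0)
        with pytest.raises(ModelError, match="gad_present"):
            ancova_lsmeans(ir, cls, cov, 0, "G001")

    def test_single_patient_group_raises(self):
        cov = _cov_table(n_gr=10, n_pr=1, seed=6)
        ir = _small_ir(cov, np.linspace(0.2, 1.4, len(cov)))
        cls = classify_genes(ir, 0)
        with pytest.raises(ModelError, match="PR"):
            ancova_lsmeans(ir, cls, cov, 0, "G001")

    def test_true_upregulated_genes_show_pr_excess(self, default_cohort,
                                                   default_ir, default_cov):
        cls = classify_genes(default_ir, 0)
        res = ancova_lsmeans_all(default_ir, cls, default_cov, 0)
        truth = default_cohort.truth.genes.set_index("gene_id")
        up = [g for g in res.index
              if truth.loc[g, "direction"] == "up"
              and truth.loc[g, "mu_log2"] > 0.5]
        frac = (res.loc[up, "adj_mean_pr"] > res.loc[up, "adj_mean_gr"]).mean()
        assert frac > 0.8


class TestFlagging:
    @staticmethod
    def _per_gene(rows):
        return pd.DataFrame(rows, columns=["direction", "adj_mean_gr",
                                           "adj_mean_pr"],
                            index=[f"G{i}" for i in range(len(rows))])

    def test_directional_rule(self):
        per_gene = self._per_gene([
            ("upregulated", 2.0, 2.5),    # exaggerated
            ("downregulated", 0.7, 0.9),  # PR less repressed: not exaggerated
            ("downregulated", 0.9, 0.7),  # exaggerated
            ("upregulated", 2.0, 2.0),    # tie: strict inequality, no flag
            ("undetermined", 1.0, 3.0),   # never flagged
        ])
        res = flag_exaggeration(per_gene)
        assert res.per_gene["exaggerated"].tolist() == [True, False, True,
                                                        False, False]
        assert res.n_regulated == 5 and res.n_exaggerated == 2

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        per_gene = self._per_gene([
            (rng.choice(["upregulated", "downregulated"]),
             float(rng.uniform(0.4, 4.0)), float(rng.uniform(0.4, 4.0)))
            for _ in range(40)])
        swapped = per_gene.rename(columns={"adj_mean_gr": "adj_mean_pr",
                                           "adj_mean_pr": "adj_mean_gr"})
        a = flag_exaggeration(per_gene).per_gene["exaggerated"]
        b = flag_exaggeration(swapped).per_gene["exaggerated"]
        strict = per_gene["adj_mean_gr"] != per_gene["adj_mean_pr"]
        assert (a[strict] == ~b[strict]).all()

    def test_missing_direction_is_structural_error(self):
        per_gene = self._per_gene([("upregulated", 2.0, 2.5)])
        per_gene.loc["G0", "direction"] = None
        with pytest.raises(DataError):
            flag_exaggeration(per_gene)


class TestBinomial:
    @pytest.mark.parametrize("k, n, expected", [
        (0, 7, 1.0),
        (3, 3, 0.125),
    ])
    def test_closed_form_tails(self, k, n, expected):
        assert binomial_proportion_test(k, n) == pytest.approx(expected)

    def test_headline_counts_are_overwhelming(self):
        assert binomial_proportion_test(97, 118) < 1e-10

    @given(st.integers(min_value=1, max_value=12), st.data())
    def test_agrees_with_full_enumeration(self, n, data):
        k = data.draw(st.integers(min_value=0, max_value=n))
        # enumerate all 2^n equally likely outcomes
        exact = sum(math.comb(n, j) for j in range(k, n + 1)) / 2.0 ** n
        assert binomial_proportion_test(k, n) == pytest.approx(exact, rel=1e-12)

    def test_invalid_k_raises(self):
        with pytest.raises(DataError):
            binomial_proportion_test(5, 4)


class TestMagnitudeScore:
    @staticmethod
    def _toy(values_by_patient, statuses):
        ir = make_ir(values_by_patient)
        genes = sorted({g for v in values_by_patient.values() for g in
                        [f"G{i + 1:03d}" for i in range(len(v))]})
        cls = pd.DataFrame({"status": statuses,
                            "filtered_out": [s == "filtered_out"
                                             for s in statuses]},
                           index=genes)
        return ir, cls

    def test_up_gene_excess_over_median(self):
        # three patients; medians: G1 -> 2.0
        ir, cls = self._toy({"P1": [2.5], "P2": [2.0], "P3": [1.0]},
                            ["upregulated"])
        res = magnitude_score(ir, cls, 0)
        assert res.scores["P1"] == pytest.approx(0.5)
        assert res.scores["P3"] == pytest.approx(0.0)  # below median: nothing

    def test_up_and_down_contributions_add(self):
        ir, cls = self._toy(
            {"P1": [2.4, 0.6], "P2": [2.0, 0.8], "P3": [1.0, 1.2]},
            ["upregulated", "downregulated"])
        res = magnitude_score(ir, cls, 0)
        assert res.scores["P1"] == pytest.approx(0.4 + 0.2)
        assert res.scores["P1"] == pytest.approx(
            res.contributions.loc["P1"].sum())

    def test_patient_at_all_medians_scores_zero(self):
        ir, cls = self._toy(
            {"P1": [2.0, 0.8], "P2": [2.5, 0.5], "P3": [1.5, 1.1]},
            ["upregulated", "downregulated"])
        res = magnitude_score(ir, cls, 0)
        assert res.scores["P1"] == pytest.approx(0.0)

    def test_undetermined_genes_contribute_nothing(self):
        ir, cls = self._toy({"P1": [5.0], "P2": [4.0], "P3": [3.0]},
                            ["undetermined"])
        res = magnitude_score(ir, cls, 0)
        assert (res.scores == 0).all()

    def test_excluded_patient_requests_are_rejected(self):
        ir, cls = self._toy({"P1": [2.5], "P2": [2.0], "P3": [1.0]},
                            ["upregulated"])
        with pytest.raises(DataError, match="excluded"):
            magnitude_score(ir, cls, 0, patient="P1", exclude=("P1",))


class TestMagnitudeComparison:
    def test_constant_scores_give_zero_difference_p_one(self):
        cov = _cov_table(n_gr=8, n_pr=6, seed=7)
        scores = pd.Series(3.0, index=cov["patient_id"])
        res = magnitude_group_comparison(scores, cov)
        assert res.adjusted_mean_pr - res.adjusted_mean_gr == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_null_rejection_rate_near_alpha(self):
        rej = 0
        n_sims = 200
        for s in range(n_sims):
            cov = _cov_table(n_gr=20, n_pr=10, seed=s)
            scores = pd.Series(
                np.random.default_rng(5000 + s).gamma(2.0, 3.0, len(cov)),
                index=cov["patient_id"])
            rej += int(magnitude_group_comparison(scores, cov).p_value < 0.05)
        assert 0.01 <= rej / n_sims <= 0.10

    def test_default_cohort_pr_scores_higher(self, default_ir, default_cov):
        cls = classify_genes(default_ir, 0)
        mag = magnitude_score(default_ir, cls, 0)
        res = magnitude_group_comparison(mag.scores, default_cov)
        assert res.adjusted_mean_pr > res.adjusted_mean_gr
        assert res.p_value < 0.05


class TestPoisson:
    def test_strong_rate_difference_detected_and_matches_lr_oracle(self):
        rng = np.random.default_rng(0)
        counts = pd.Series(np.r_[rng.poisson(10, 20), rng.poisson(100, 20)],
                           index=[f"P{i}" for i in range(40)])
        labels = pd.DataFrame({"patient_id": counts.index,
                               "label": ["GR"] * 20 + ["PR"] * 20})
        res = poisson_induced_count_test(counts, labels)
        assert res["p_value"] < 1e-3
        assert res["rate_ratio"] == pytest.approx(
            counts[20:].mean() / counts[:20].mean(), rel=1e-6)
        # likelihood-ratio oracle: saturated group model vs pooled
        y1, y2 = counts[:20].to_numpy(), counts[20:].to_numpy()
        lam1, lam2, lam0 = y1.mean(), y2.mean(), counts.mean()
        llr = 2 * (y1.sum() * np.log(lam1 / lam0)
                   + y2.sum() * np.log(lam2 / lam0))
        p_lr = stats.chi2.sf(llr, df=1)
        assert res["p_value"] < 1e-3 and p_lr < 1e-3

    def test_null_rates_give_uniform_p(self):
        rej = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            counts = pd.Series(rng.poisson(40, 30).astype(float),
                               index=[f"P{i}" for i in range(30)])
            labels = pd.DataFrame({"patient_id": counts.index,
                                   "label": ["GR"] * 20 + ["PR"] * 10})
            rej += int(poisson_induced_count_test(counts, labels)["p_value"]
                       < 0.05)
        assert rej / 100 <= 0.12

    def test_single_patient_group_raises(self):
        counts = pd.Series([5.0, 7.0], index=["P1", "P2"])
        labels = pd.DataFrame({"patient_id": ["P1", "P2"],
                               "label": ["GR", "PR"]})
        with pytest.raises(InsufficientDataError):
            poisson_induced_count_test(counts, labels)

    def test_all_zero_counts_degenerate(self):
        counts = pd.Series(0.0, index=[f"P{i}" for i in range(10)])
        labels = pd.DataFrame({"patient_id": counts.index,
                               "label": ["GR"] * 5 + ["PR"] * 5})
        with pytest.raises(ModelError):
            poisson_induced_count_test(counts, labels)
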