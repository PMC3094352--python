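"""End-to-end analysis convenience: cohort tables in, study results out."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import exaggeration as ex
from .baseline import baseline_table_report
from .genes import DEFAULT_BAND, classify_genes
from .induction import (IRMatrix, StabilitySummary, cohort_stability_summary,
                        compute_ir, induced_counts)
from .mri import classify_responders
from .simulate import SyntheticCohort


@dataclass
class TimepointAnalysis:
    """Results of the responder comparison at one injection time point."""

    timepoint: int
    classification: pd.DataFrame
    per_gene: pd.DataFrame
    exaggeration: ex.ExaggerationResult
    magnitude: ex.MagnitudeScore
    magnitude_comparison: ex.AncovaResult
    n_filtered: int = field(init=False)

    def __post_init__(self):
        self.n_filtered = int(self.classification["filtered_out"].sum())


@dataclass
class CohortAnalysis:
    """Full pipeline output for a cohort."""

    labels: pd.DataFrame
    baseline_table: pd.DataFrame
    stability: StabilitySummary
    induced_count_test: dict
    timepoints: dict  # timepoint -> TimepointAnalysis


def analyze_timepoint(ir: IRMatrix, cov: pd.DataFrame, timepoint,
                      band=DEFAULT_BAND, exclude=()) -> TimepointAnalysis:
    """Classify genes and run the exaggeration analysis at one time point.

    ``cov`` must include a ``label`` column (merge the MRI labels in) and the
    four baseline covariates.
    """
    cls = classify_genes(ir, timepoint, band=band, exclude=exclude)
    per_gene = ex.ancova_lsmeans_all(ir, cls, cov, timepoint, exclude=exclude)
    flagged = ex.flag_exaggeration(per_gene)
    mag = ex.magnitude_score(ir, cls, timepoint, exclude=exclude)
    mag_cmp = ex.magnitude_group_comparison(mag.scores, cov)
    return TimepointAnalysis(timepoint=timepoint, classification=cls,
                             per_gene=per_gene, exaggeration=flagged,
                             magnitude=mag, magnitude_comparison=mag_cmp)


def analyze_cohort(cohort: SyntheticCohort, timepoints=(0, 6),
                   band=DEFAULT_BAND) -> CohortAnalysis:
    """Run the whole study pipeline on a (synthetic or real) cohort bundle.

    Responder labels come from the MRI lesion rule; patients with an
    exclusion flag in the covariate table are omitted from every statistic.
    """
    labels = classify_responders(cohort.lesions)
    cov = cohort.covariates.merge(labels[["patient_id", "label"]],
                                  on="patient_id", how="left")
    excluded = cov.loc[cov["exclusion_flag"] == 1, "patient_id"].tolist()
    ir = compute_ir(cohort.intensities)
    results = {tp: analyze_timepoint(ir, cov, tp, band=band, exclude=excluded)
               for tp in timepoints}
    stability = cohort_stability_summary(
        ir, labels, exclusions=cov[cov["exclusion_flag"] == 1].rename(
            columns={"exclusion_reason": "reason"}),
        timepoint_a=timepoints[0], timepoint_b=timepoints[1])
    counts = induced_counts(ir, timepoints[0]).drop(index=excluded,
                                                    errors="ignore")
    poisson = ex.poisson_induced_count_test(counts, labels)
    return CohortAnalysis(labels=labels,
                          baseline_table=baseline_table_report(cov),
                          stability=stability,
                          induced_count_test=poisson,
                          timepoints=results)
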