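"""Tab-separated input/output with fixed, documented column names.

Tables:

* intensities: ``patient_id, timepoint, gene_id, pre_signal, post_signal``
* covariates:  ``patient_id, age, sex, gad_present, t2_volume,
  exclusion_flag, exclusion_reason``
* lesions:     ``patient_id, lesion_id, baseline_vol_mm3, followup_vol_mm3,
  n_new_lesions``
* IRs:         ``patient_id, timepoint, gene_id, ir, log2_ir``
* labels:      ``patient_id, n_new, n_enlarging, label``
* classification: ``gene_id, timepoint, mean_ir, status, fraction_above_one``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import DataError
from .induction import IRMatrix
from .simulate import SyntheticCohort

INTENSITY_COLUMNS = ["patient_id", "timepoint", "gene_id",
                     "pre_signal", "post_signal"]
COVARIATE_COLUMNS = ["patient_id", "age", "sex", "gad_present", "t2_volume",
                     "exclusion_flag", "exclusion_reason"]
LESION_COLUMNS = ["patient_id", "lesion_id", "baseline_vol_mm3",
                  "followup_vol_mm3", "n_new_lesions"]


def _read(path, required) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_intensities(path) -> pd.DataFrame:
    return _read(path, INTENSITY_COLUMNS)


def read_covariates(path) -> pd.DataFrame:
    df = _read(path, COVARIATE_COLUMNS[:-1])
    if "exclusion_reason" not in df:
        df["exclusion_reason"] = ""
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    return df


def read_lesions(path) -> pd.DataFrame:
    return _read(path, LESION_COLUMNS)


def read_ir(path, induction_threshold: float = 2.0) -> IRMatrix:
    df = _read(path, ["patient_id", "timepoint", "gene_id", "ir"])
    return IRMatrix(df[["patient_id", "timepoint", "gene_id", "ir"]],
                    induction_threshold=induction_threshold)


def read_labels(path) -> pd.DataFrame:
    return _read(path, ["patient_id", "label"])


def read_classification(path) -> pd.DataFrame:
    df = _read(path, ["gene_id", "mean_ir", "status"])
    df = df.set_index("gene_id")
    df["filtered_out"] = df["status"] == "filtered_out"
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def write_ir(ir: IRMatrix, path) -> Path:
    return write_tsv(ir.long, path)


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the three cohort tables plus the ground-truth tables; returns
    the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": write_tsv(cohort.intensities, outdir / "intensities.tsv"),
        "covariates": write_tsv(cohort.covariates, outdir / "covariates.tsv"),
        "lesions": write_tsv(cohort.lesions, outdir / "lesions.tsv"),
        "truth_patients": write_tsv(cohort.truth.patients,
                                    outdir / "truth_patients.tsv"),
        "truth_genes": write_tsv(cohort.truth.genes, outdir / "truth_genes.tsv"),
        "truth_fingerprints": write_tsv(
            cohort.truth.fingerprints.rename_axis("patient_id"),
            outdir / "truth_fingerprints.tsv", index=True),
    }
    return paths
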