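import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import ifnresponse as ifr
from ifnresponse.induction import IRMatrix, compute_ir
from ifnresponse.mri import classify_responders

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort shared across tests."""
    return ifr.generate_cohort(ifr.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def default_ir(default_cohort):
    return compute_ir(default_cohort.intensities)


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    return classify_responders(default_cohort.lesions)


@pytest.fixture(scope="session")
def default_cov(default_cohort, default_labels):
    return default_cohort.covariates.merge(
        default_labels[["patient_id", "label"]], on="patient_id")


def make_ir(values_by_patient, timepoints=(0,), genes=None,
            threshold=2.0) -> IRMatrix:
    """Build an IRMatrix from {patient: {timepoint: [IRs]}} or
    {patient: [IRs]} (single time point)."""
    rows = []
    for pid, per_tp in values_by_patient.items():
        if not isinstance(per_tp, dict):
            per_tp = {timepoints[0]: per_tp}
        for tp, vals in per_tp.items():
            g = genes or [f"G{i + 1:03d}" for i in range(len(vals))]
            for gid, v in zip(g, vals):
                rows.append(dict(patient_id=pid, timepoint=tp,
                                 gene_id=gid, ir=float(v)))
    return IRMatrix(pd.DataFrame(rows), induction_threshold=threshold)


def vectors_with_correlation(r, n_genes=12, rng_seed=0):
    """Two log2-IR vectors across genes with exact Pearson correlation r."""
    rng = np.random.default_rng(rng_seed)
    x = rng.normal(0, 1, n_genes)
    z = rng.normal(0, 1, n_genes)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    zc = z - z.mean() - (z - z.mean()) @ xc * xc
    zc /= np.linalg.norm(zc)
    y = r * xc + np.sqrt(1 - r * r) * zc
    return x, y
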