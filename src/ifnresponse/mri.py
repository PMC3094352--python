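"""MRI treatment-response classification from matched T2 lesion tables.

Operates downstream of image registration/subtraction: the input is a table
of matched lesions (baseline and 6-month volumes in mm³) plus a per-patient
count of new lesions. A lesion counts as *enlarging* if it grew by >= 20%
(baseline volume >= 150 mm³) or by >= 50% (baseline < 150 mm³) — the size
breakpoint reflects scan-rescan reproducibility of small-lesion volumes. A
patient is a poor responder (PR) when new + enlarging lesions >= 3, otherwise
a good responder (GR).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "SIZE_BREAK_MM3", "GROWTH_LARGE", "GROWTH_SMALL",
    "DEFAULT_LESION_THRESHOLD",
    "is_enlarging", "classify_responder", "classify_responders",
]

SIZE_BREAK_MM3 = 150.0
GROWTH_LARGE = 1.20   # lesions >= 150 mm³ must grow 20%
GROWTH_SMALL = 1.50   # lesions < 150 mm³ must grow 50%
DEFAULT_LESION_THRESHOLD = 3


def is_enlarging(baseline_vol, followup_vol) -> bool | np.ndarray:
    """Whether a matched lesion counts as enlarging (thresholds inclusive).

    A zero baseline volume is a new-lesion candidate, never enlarging.
    Accepts scalars or aligned arrays.
    """
    b = np.asarray(baseline_vol, dtype=float)
    f = np.asarray(followup_vol, dtype=float)
    if (b < 0).any() or (f < 0).any():
        raise DataError("lesion volumes must be nonnegative")
    required = np.where(b >= SIZE_BREAK_MM3, GROWTH_LARGE * b, GROWTH_SMALL * b)
    out = (b > 0) & (f >= required)
    return bool(out) if out.ndim == 0 else out


def _counts_for_patient(sub: pd.DataFrame) -> tuple[int, int]:
    if sub["lesion_id"].duplicated().any():
        raise DataError("duplicate lesion_id within a patient")
    n_new_col = sub["n_new_lesions"].unique()
    if len(n_new_col) != 1:
        raise DataError("inconsistent n_new_lesions within a patient")
    n_new = int(n_new_col[0])
    base = sub["baseline_vol_mm3"].to_numpy(dtype=float)
    fup = sub["followup_vol_mm3"].to_numpy(dtype=float)
    # zero-baseline records are unmatched new lesions that slipped into the
    # matched table; count them as new, not enlarging
    n_new += int(((base == 0) & (fup > 0)).sum())
    n_enlarging = int(np.asarray(is_enlarging(base, fup)).sum())
    return n_new, n_enlarging


def classify_responder(lesions: pd.DataFrame, patient_id,
                       threshold: int = DEFAULT_LESION_THRESHOLD) -> dict:
    """Responder label for one patient: PR iff new + enlarging >= threshold."""
    sub = lesions[lesions["patient_id"] == patient_id]
    if sub.empty:
        raise KeyError(f"patient {patient_id!r} not in lesion table")
    n_new, n_enl = _counts_for_patient(sub)
    return dict(patient_id=patient_id, n_new=n_new, n_enlarging=n_enl,
                label="PR" if n_new + n_enl >= threshold else "GR")


def classify_responders(lesions: pd.DataFrame,
                        threshold: int = DEFAULT_LESION_THRESHOLD) -> pd.DataFrame:
    """Labels for every patient in the lesion table."""
    rows = [classify_responder(lesions, pid, threshold)
            for pid in lesions["patient_id"].unique()]
    return pd.DataFrame(rows, columns=["patient_id", "n_new", "n_enlarging",
                                       "label"])
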