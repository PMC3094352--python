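"""Noise filter and direction classification of interferon-regulated genes.

At each time point, genes whose cohort-mean raw IR lies inside a no-change
band (default 0.9–1.1, closed) are filtered out as unregulated. Remaining
genes are called upregulated if a strict majority of subjects has IR > 1,
downregulated if a strict majority has IR < 1, and undetermined otherwise
(IRs of exactly 1.0 count toward neither side).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .induction import IRMatrix

__all__ = [
    "DEFAULT_BAND",
    "FILTERED_OUT", "UPREGULATED", "DOWNREGULATED", "UNDETERMINED",
    "filter_genes", "classify_direction", "classify_genes",
]

DEFAULT_BAND = (0.9, 1.1)

FILTERED_OUT = "filtered_out"
UPREGULATED = "upregulated"
DOWNREGULATED = "downregulated"
UNDETERMINED = "undetermined"


def _included_wide(ir: IRMatrix, timepoint, exclude) -> pd.DataFrame:
    wide = ir.wide(timepoint)
    wide = wide.drop(index=[p for p in exclude if p in wide.index])
    if wide.empty:
        raise InsufficientDataError("no patients left after exclusions")
    return wide


def filter_genes(ir: IRMatrix, timepoint, band=DEFAULT_BAND,
                 exclude=()) -> pd.DataFrame:
    """Mark genes whose cohort-mean raw IR falls inside the closed band.

    The mean is taken over all included patients on the raw ratio scale.
    Returns a gene-indexed frame with ``mean_ir`` and ``filtered_out``.
    """
    lo, hi = band
    if not lo < hi:
        raise InsufficientDataError(f"invalid band {band!r}")
    wide = _included_wide(ir, timepoint, exclude)
    mean_ir = wide.mean(axis=0, skipna=True)
    out = pd.DataFrame({"mean_ir": mean_ir})
    out["filtered_out"] = (mean_ir >= lo) & (mean_ir <= hi)
    out.index.name = "gene_id"
    return out


def classify_direction(ir: IRMatrix, timepoint,
                       filtered: pd.DataFrame, exclude=()) -> pd.DataFrame:
    """Apply the strict-majority direction rule to retained genes.

    ``filtered`` is the output of :func:`filter_genes`. Adds
    ``fraction_above_one``, ``fraction_below_one`` and ``status``.
    """
    wide = _included_wide(ir, timepoint, exclude)
    n_obs = wide.notna().sum(axis=0)
    frac_up = (wide > 1.0).sum(axis=0) / n_obs
    frac_down = (wide < 1.0).sum(axis=0) / n_obs
    out = filtered.copy()
    out["fraction_above_one"] = frac_up
    out["fraction_below_one"] = frac_down
    status = np.where(out["filtered_out"], FILTERED_OUT,
                      np.where(frac_up > 0.5, UPREGULATED,
                               np.where(frac_down > 0.5, DOWNREGULATED,
                                        UNDETERMINED)))
    out["status"] = status
    return out


def classify_genes(ir: IRMatrix, timepoint, band=DEFAULT_BAND,
                   exclude=()) -> pd.DataFrame:
    """Filter then classify: one status per gene at the given time point."""
    return classify_direction(ir, timepoint,
                              filter_genes(ir, timepoint, band, exclude),
                              exclude)
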