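"""Cell- and strain-level quality control on feature tables.

Filter order is fixed: cells -> NaN imputation -> strains.  Cells are
dropped on area (outside [300, 2000] px) and on the stored shape metric
(> 0.2; see :func:`plast.features.solidity_metric` for the convention);
NaNs are replaced by within-strain per-feature medians; strains with fewer
than two surviving cells, or on user-supplied exclusion lists, are removed.
All filters are idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["QCPolicy", "filter_cells", "impute_nans", "filter_strains", "run_qc"]

META_COLS = ("strain_id", "cell_id", "qc_area", "qc_solidity")


@dataclass
class QCPolicy:
    min_area: int = 300
    max_area: int = 2000
    max_solidity_metric: float = 0.2
    min_cells_per_strain: int = 2

    def __post_init__(self):
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def filter_cells(table: pd.DataFrame, policy: QCPolicy | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells failing the area or shape rules.

    Returns (filtered table, removal log with per-rule counts)."""
    policy = policy or QCPolicy()
    for col in ("qc_area", "qc_solidity"):
        if col not in table.columns:
            raise SchemaError(f"missing qc column {col!r}")
    small = table["qc_area"] < policy.min_area
    large = table["qc_area"] > policy.max_area
    badshape = table["qc_solidity"] > policy.max_solidity_metric
    keep = ~(small | large | badshape)
    log = pd.DataFrame(
        {
            "rule": ["area_too_small", "area_too_large", "solidity"],
            "n_removed": [int(small.sum()), int((large & ~small).sum()), int((badshape & ~small & ~large).sum())],
        }
    )
    return table.loc[keep].reset_index(drop=True), log


def impute_nans(table: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN feature values by within-strain per-feature medians.

    A feature that is all-NaN within a strain becomes 0 with a warning."""
    out = table.copy()
    cols = _feature_cols(out)
    cell_id_free = [c for c in cols if c != "cell_id"]
    num = out[cell_id_free].select_dtypes(include=[np.number]).columns.tolist()
    if out[num].isna().any().any():
        med = out.groupby("strain_id")[num].transform("median")
        out[num] = out[num].fillna(med)
        if out[num].isna().any().any():
            warnings.warn("all-NaN feature within a strain; imputing 0", stacklevel=2)
            out[num] = out[num].fillna(0.0)
    return out


def filter_strains(
    table: pd.DataFrame,
    policy: QCPolicy | None = None,
    exclusion_lists: tuple = (),
) -> pd.DataFrame:
    """Remove whole strains: too few cells, or on an exclusion list."""
    policy = policy or QCPolicy()
    excluded = set()
    for lst in exclusion_lists:
        excluded.update(lst)
    counts = table.groupby("strain_id")["cell_id"].count()
    ok = set(counts[counts >= policy.min_cells_per_strain].index) - excluded
    return table[table["strain_id"].isin(ok)].reset_index(drop=True)


def run_qc(
    table: pd.DataFrame,
    policy: QCPolicy | None = None,
    exclusion_lists: tuple = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC pass in the fixed order; returns (table, removal log)."""
    policy = policy or QCPolicy()
    out, log = filter_cells(table, policy)
    out = impute_nans(out)
    n_before = out["strain_id"].nunique()
    out = filter_strains(out, policy, exclusion_lists)
    log = pd.concat(
        [log, pd.DataFrame({"rule": ["strain"], "n_removed": [n_before - out["strain_id"].nunique()]})],
        ignore_index=True,
    )
    return out, log
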