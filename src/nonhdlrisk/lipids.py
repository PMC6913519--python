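"""Lipid derivation, unit conversion, treatment inflation and categorisation.

Non-HDL cholesterol is total cholesterol minus HDL cholesterol, the standard
proxy for all apoB-containing atherogenic lipoproteins. Baseline values of
subjects on lipid-lowering medication are inflated by 30% to approximate the
untreated concentration. Subjects are then placed into five guideline-derived
threshold categories with bounds (in mmol/L) at 2.6, 3.7, 4.8 and 5.7 —
corresponding to <100, 100-<145, 145-<185, 185-<220 and >=220 mg/dL, using
38.67 mg/dL per mmol/L. Intervals are half-open [lower, upper): a value
exactly on a threshold falls in the higher category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MGDL_PER_MMOL",
    "TREATMENT_INFLATION",
    "DEFAULT_CATEGORY_EDGES",
    "LipidCategory",
    "convert_units",
    "derive_non_hdl",
    "adjust_for_treatment",
    "assign_category",
    "category_table",
    "prepare_cohort",
]

#: mg/dL of (non-HDL or LDL) cholesterol per mmol/L
MGDL_PER_MMOL = 38.67
#: multiplicative inflation applied to recorded values of treated subjects
TREATMENT_INFLATION = 1.30
#: guideline category bounds in mmol/L; the 3.7 cutoff is the adapted
#: 145 mg/dL low-risk treatment goal (rather than the 130 mg/dL / 3.4 mmol/L
#: guideline cutpoint)
DEFAULT_CATEGORY_EDGES = (2.6, 3.7, 4.8, 5.7)


@dataclass(frozen=True)
class LipidCategory:
    index: int  # 1..5
    lower_mmol: float
    upper_mmol: float  # may be +inf
    label: str


def category_table(edges: Sequence[float] = DEFAULT_CATEGORY_EDGES) -> list[LipidCategory]:
    """The five half-open categories partitioning [0, inf)."""
    bounds = [0.0, *edges, math.inf]
    cats = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if i == 0:
            label = f"<{hi:g}"
        elif math.isinf(hi):
            label = f">={lo:g}"
        else:
            label = f"{lo:g} to <{hi:g}"
        cats.append(LipidCategory(i + 1, lo, hi, label))
    return cats


def convert_units(value, direction: Literal["mg_to_mmol", "mmol_to_mg"]):
    """Convert lipid concentrations between mg/dL and mmol/L (no rounding)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("lipid concentration must be non-negative")
    if direction == "mg_to_mmol":
        out = arr / MGDL_PER_MMOL
    elif direction == "mmol_to_mg":
        out = arr * MGDL_PER_MMOL
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out if out.ndim else float(out)


def derive_non_hdl(total_chol, hdl_chol):
    """Non-HDL cholesterol = total - HDL (mmol/L), exact.

    Raises ValueError if any HDL >= total (physiologically impossible record).
    """
    tc = np.asarray(total_chol, dtype=float)
    hdl = np.asarray(hdl_chol, dtype=float)
    bad = ~(tc > hdl) | (hdl < 0)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))
        raise ValueError(
            f"HDL must satisfy 0 <= HDL < total cholesterol; "
            f"{idx.size} offending record(s), first at position {idx[0]}"
        )
    out = tc - hdl
    return out if out.ndim else float(out)


def adjust_for_treatment(non_hdl, on_lipid_lowering, factor: float = TREATMENT_INFLATION):
    """Inflate recorded non-HDL by 30% for subjects on lipid-lowering therapy."""
    x = np.asarray(non_hdl, dtype=float)
    if np.any(x < 0):
        raise ValueError("non_hdl must be non-negative")
    treated = np.asarray(on_lipid_lowering, dtype=bool)
    out = np.where(treated, x * factor, x)
    return out if out.ndim else float(out)


def assign_category(non_hdl, edges: Sequence[float] = DEFAULT_CATEGORY_EDGES):
    """Category index 1..5 for a non-HDL value (half-open [lower, upper))."""
    x = np.asarray(non_hdl, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("non_hdl contains NaN")
    if np.any(x < 0):
        raise ValueError("non_hdl must be non-negative")
    # np.digitize with right=False: x == edge goes to the higher bin
    out = np.digitize(x, np.asarray(edges, dtype=float)) + 1
    return out if out.ndim else int(out)


def prepare_cohort(
    df: pd.DataFrame, edges: Sequence[float] = DEFAULT_CATEGORY_EDGES
) -> pd.DataFrame:
    """Add derived lipid columns to a cohort table.

    Adds ``non_hdl`` (total - HDL, recorded), ``non_hdl_adj`` (treatment-
    inflated) and ``non_hdl_cat`` (guideline category 1..5 of the adjusted
    value). Returns a copy; the input is untouched.
    """
    out = df.copy()
    non_hdl = derive_non_hdl(out["total_chol"].to_numpy(), out["hdl_chol"].to_numpy())
    adj = adjust_for_treatment(non_hdl, out["lipid_lowering_med"].to_numpy().astype(bool))
    out["non_hdl"] = non_hdl
    out["non_hdl_adj"] = adj
    out["non_hdl_cat"] = assign_category(adj, edges)
    return out
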