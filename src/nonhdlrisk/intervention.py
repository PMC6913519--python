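"""Hypothetical benefit of lowering non-HDL cholesterol by 30% or 50%.

The expected proportional risk reduction per mmol/L of cholesterol lowered,
for a treatment lasting t years, is

    r(t) = 1 - exp(-0.249 + (t - 5) * (-0.0152)),

an empirical meta-analysis-derived dose-duration relation (about 22% per
mmol/L at 5 years, about 51% at 35 years). Effects per mmol/L compound
multiplicatively on the probability scale: lowering non-HDL by
Delta = fraction x baseline non-HDL gives relative risk

    RR = (1 - r(t)) ** Delta,       p1 = p0 * RR,

with treatment assumed to run from baseline age to the age-75 horizon
(t = 75 - baseline age). From cell-averaged probabilities (in percent) the
absolute risk difference, number needed to treat (NNT = 100 / RD) and
relative risk reduction (RRR = RD / p0) follow. Treated cumulative-incidence
curves are forced monotone by a running maximum, since the increasing r(t)
can otherwise make the raw product decrease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cuminc import CIFCurve

__all__ = [
    "TreatmentParams",
    "proportional_reduction",
    "treated_probability",
    "nnt_rrr",
    "treated_cif_curve",
    "benefit_table",
]


@dataclass(frozen=True)
class TreatmentParams:
    intercept: float = -0.249
    slope_per_year: float = -0.0152
    reference_duration: float = 5.0
    reduction_fraction: float = 0.5
    horizon: float = 75.0

    def __post_init__(self):
        if not 0.0 < self.reduction_fraction < 1.0:
            raise ValueError(
                f"reduction_fraction must be in (0, 1), got {self.reduction_fraction}"
            )


def proportional_reduction(treatment_years, params: TreatmentParams = TreatmentParams()):
    """Proportional risk reduction per mmol/L for a given treatment duration."""
    t = np.asarray(treatment_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("treatment_years must be >= 0")
    out = 1.0 - np.exp(
        params.intercept + (t - params.reference_duration) * params.slope_per_year
    )
    return out if out.ndim else float(out)


def treated_probability(
    p0, non_hdl_adj, age_baseline, params: TreatmentParams = TreatmentParams()
):
    """Post-treatment probability p1 = p0 * (1 - r(75 - age)) ** Delta.

    ``p0`` is a proportion in [0, 1]; ``Delta`` = reduction_fraction x
    non_hdl_adj is the absolute lowering in mmol/L.
    """
    p0 = np.asarray(p0, dtype=float)
    age = np.asarray(age_baseline, dtype=float)
    if np.any((p0 < 0) | (p0 > 1)):
        raise ValueError("p0 must be a proportion in [0, 1]")
    if np.any((age < 35.0) | (age > 70.0)):
        raise ValueError("age_baseline must be within [35, 70]")
    delta = params.reduction_fraction * np.asarray(non_hdl_adj, dtype=float)
    r = proportional_reduction(params.horizon - age, params)
    out = p0 * (1.0 - r) ** delta
    return out if out.ndim else float(out)


def nnt_rrr(p0_cell, p1_cell):
    """Risk difference (%), NNT and RRR from cell probabilities in percent.

    NNT is reported to one decimal, RRR to two (matching the usual tabular
    presentation); a zero risk difference yields an infinite NNT.
    """
    p0 = np.asarray(p0_cell, dtype=float)
    p1 = np.asarray(p1_cell, dtype=float)
    if np.any((p1 > p0) | (p0 > 100) | (p1 < 0)):
        raise ValueError("need 0 <= p1 <= p0 <= 100 (percent scale)")
    rd = p0 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        nnt = np.where(rd > 0, np.round(100.0 / np.where(rd > 0, rd, 1.0), 1), np.inf)
        rrr = np.where(p0 > 0, np.round(rd / np.where(p0 > 0, p0, 1.0), 2), 0.0)
    if p0.ndim == 0:
        return float(rd), float(nnt), float(rrr)
    return rd, nnt, rrr


def treated_cif_curve(
    cif0: CIFCurve,
    age_baseline: float,
    non_hdl_adj: float,
    params: TreatmentParams = TreatmentParams(),
) -> CIFCurve:
    """Treated cumulative incidence on an age grid, forced monotone.

    ``cif0.times`` are attained ages >= ``age_baseline``. The raw pointwise
    product cif0(u) * (1 - r(u - age_baseline)) ** Delta may decrease where
    r grows faster than the incidence; the returned curve is its running
    maximum, hence a valid CIF.
    """
    u = np.asarray(cif0.times, dtype=float)
    if np.any(np.diff(u) < 0):
        raise ValueError("cif0 time grid must be sorted ascending")
    if np.any(u < age_baseline):
        raise ValueError("cif0 must be defined on ages >= age_baseline")
    delta = params.reduction_fraction * float(non_hdl_adj)
    r = proportional_reduction(u - age_baseline, params)
    raw = cif0.cif * (1.0 - r) ** delta
    mono = np.maximum.accumulate(raw)
    return CIFCurve(
        cause=cif0.cause,
        times=u,
        cif=mono,
        variance=np.full_like(mono, np.nan),
        at_risk=cif0.at_risk,
        survival=cif0.survival,
        group=cif0.group,
    )


def benefit_table(
    cells: pd.DataFrame,
    records: pd.DataFrame,
    predictions: np.ndarray,
    params: TreatmentParams = TreatmentParams(),
) -> pd.DataFrame:
    """Per-cell treated probabilities and benefit metrics.

    Subject-level treated probabilities (each subject's own non-HDL and age)
    are averaged within the same 60 cells as ``cells`` (the untreated
    averages), then RD/NNT/RRR are computed on the percent scale.
    """
    from .lifetime import _cell_codes  # cell definition shared with averaging

    p1_subject = treated_probability(
        np.asarray(predictions, dtype=float),
        records["non_hdl_adj"].to_numpy(dtype=float),
        records["age_baseline"].to_numpy(dtype=float),
        params,
    )
    codes = _cell_codes(records)
    sums = np.bincount(codes, weights=p1_subject, minlength=60)
    cnts = np.bincount(codes, minlength=60)
    with np.errstate(invalid="ignore"):
        p1 = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan) * 100.0

    out = cells.copy()
    out["p1"] = p1
    ok = out["p0"].notna() & out["p1"].notna()
    rd = np.full(len(out), np.nan)
    nnt = np.full(len(out), np.nan)
    rrr = np.full(len(out), np.nan)
    if ok.any():
        rd[ok], nnt[ok], rrr[ok] = nnt_rrr(
            out.loc[ok, "p0"].to_numpy(), out.loc[ok, "p1"].to_numpy()
        )
    out["risk_difference"] = rd
    out["nnt"] = nnt
    out["rrr"] = rrr
    return out
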