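"""Derivation/validation split, agreement, discrimination and calibration.

The cohort is halved at random *within* each cohort so that every cohort is
represented in both the derivation and the validation data. Agreement between
the two independently fitted lifetime-risk models is measured by the root
mean square error (RMSE, percentage points) across the 60 averaged risk
cells. Discrimination uses a Harrell-type concordance index of predicted CVD
risk at a timeframe, with ten-fold cross-validation (competing events are
treated as non-events censored at their time; pairs are truncated at the
timeframe). Calibration regresses jackknife pseudo-values of the
Aalen-Johansen cause-1 cumulative incidence,

    PV_i = n * F(t) - (n - 1) * F_{(-i)}(t),

on the predicted risks with a lowess smoother; pseudo-values may fall
outside [0, 1] by construction, their mean equals F(t) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines.utils import concordance_index

from .cuminc import _aj_components
from .lifetime import (
    CELL_KEYS,
    average_cells,
    fit_cause_specific_models,
    predict_cif_at_age,
    predict_cvd_by_75,
)

__all__ = [
    "SplitResult",
    "CalibrationCurve",
    "split_cohort",
    "rmse_cells",
    "lifetime_cell_pipeline",
    "split_rmse",
    "leave_one_group_out_rmse",
    "cindex_cv",
    "pseudo_values",
    "pseudo_value_calibration",
]


@dataclass
class SplitResult:
    derivation_ids: np.ndarray
    validation_ids: np.ndarray
    seed: int


def split_cohort(records: pd.DataFrame, seed: int = 0) -> SplitResult:
    """Within-cohort random halving; deterministic given the seed.

    A cohort with a single subject goes to the derivation half (warning).
    """
    rng = np.random.default_rng(seed)
    ids = records["subject_id"].to_numpy()
    cohorts = records["cohort_id"].to_numpy()
    der, val = [], []
    for c in np.unique(cohorts):
        member_ids = ids[cohorts == c]
        if len(member_ids) == 1:
            warnings.warn(f"cohort {c!r} has a single subject; assigned to derivation")
            der.append(member_ids)
            continue
        perm = rng.permutation(member_ids)
        half = (len(perm) + 1) // 2
        der.append(perm[:half])
        val.append(perm[half:])
    return SplitResult(
        np.sort(np.concatenate(der)),
        np.sort(np.concatenate(val)) if val else np.array([], dtype=ids.dtype),
        seed,
    )


def rmse_cells(cells_der: pd.DataFrame, cells_val: pd.DataFrame) -> float:
    """RMSE (percentage points) between two cell tables over shared cells."""
    merged = cells_der.merge(cells_val, on=CELL_KEYS, suffixes=("_der", "_val"))
    merged = merged.dropna(subset=["p0_der", "p0_val"])
    if len(merged) == 0:
        raise ValueError("no shared non-empty cells")
    diff = merged["p0_der"].to_numpy() - merged["p0_val"].to_numpy()
    return float(np.sqrt(np.mean(diff**2)))


def lifetime_cell_pipeline(
    prepared: pd.DataFrame, n_bootstrap: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Fit the cause-specific model and return the 60-cell averaged table."""
    model = fit_cause_specific_models(prepared)
    lo, hi = model.eligible_baseline_ages
    eligible = prepared[
        (prepared["age_baseline"] >= lo) & (prepared["age_baseline"] <= hi)
    ]
    pred = predict_cvd_by_75(eligible, model)
    return average_cells(pred, eligible, n_bootstrap=n_bootstrap, seed=seed)


def split_rmse(prepared: pd.DataFrame, seed: int = 0) -> dict:
    """Full derivation/validation agreement check on a prepared cohort."""
    split = split_cohort(prepared, seed)
    by_id = prepared.set_index("subject_id", drop=False)
    cells_der = lifetime_cell_pipeline(by_id.loc[split.derivation_ids])
    cells_val = lifetime_cell_pipeline(by_id.loc[split.validation_ids])
    return {
        "rmse": rmse_cells(cells_der, cells_val),
        "n_derivation": len(split.derivation_ids),
        "n_validation": len(split.validation_ids),
        "cells_derivation": cells_der,
        "cells_validation": cells_val,
    }


def leave_one_group_out_rmse(
    prepared: pd.DataFrame, group_col: str = "cohort_id", seed: int = 0
) -> pd.DataFrame:
    """Group-specific RMSE: model on all-but-one group vs on that group.

    Generalises the split agreement check; with a single group it reduces to
    the plain within-group split RMSE.
    """
    groups = np.unique(prepared[group_col].to_numpy())
    if len(groups) == 1:
        return pd.DataFrame(
            [{group_col: groups[0], "rmse": split_rmse(prepared, seed)["rmse"]}]
        )
    rows = []
    for g in groups:
        inside = prepared[prepared[group_col] == g]
        outside = prepared[prepared[group_col] != g]
        rows.append(
            {group_col: g,
             "rmse": rmse_cells(lifetime_cell_pipeline(outside),
                                lifetime_cell_pipeline(inside))}
        )
    return pd.DataFrame(rows)


def cindex_cv(
    records: pd.DataFrame,
    timeframe: float,
    folds: int = 10,
    seed: int = 0,
    model_fitter=fit_cause_specific_models,
    predictor=None,
) -> float:
    """Cross-validated Harrell concordance of predicted risk at a timeframe.

    The model is refitted on each training split; on the held-out fold the
    predicted cause-1 CIF at baseline age + timeframe scores the subjects.
    ``predictor(model, test, target_age) -> risk`` may replace the default
    scoring (used e.g. to check the null behaviour of the concordance).
    """
    if not timeframe > 0:
        raise ValueError("timeframe must be > 0")
    rng = np.random.default_rng(seed)
    n = len(records)
    fold_of = rng.permuted(np.arange(n) % folds)
    cs = []
    for f in range(folds):
        test = records.iloc[fold_of == f]
        train = records.iloc[fold_of != f]
        t = test["followup_years"].to_numpy(dtype=float)
        cause = test["event_cause"].to_numpy()
        event = (cause == 1) & (t <= timeframe)
        if event.sum() == 0:
            warnings.warn(f"fold {f} has no events within the timeframe; skipped")
            continue
        model = model_fitter(train)
        target = test["age_baseline"].to_numpy(dtype=float) + timeframe
        if predictor is None:
            risk = predict_cif_at_age(test, model, target)
        else:
            risk = predictor(model, test, target)
        dur = np.minimum(t, timeframe)
        cs.append(concordance_index(dur, -risk, event.astype(int)))
    if not cs:
        raise ValueError("no fold had events within the timeframe")
    return float(np.mean(cs))


def pseudo_values(durations, causes, timeframe: float, cause: int = 1) -> np.ndarray:
    """Jackknife pseudo-values of the Aalen-Johansen CIF at ``timeframe``.

    Exact leave-one-out computation, grouped by distinct (time, cause) pairs
    (subjects sharing both have identical pseudo-values).
    """
    t = np.asarray(durations, dtype=float)
    c = np.asarray(causes)
    n = len(t)
    if n < 50:
        raise ValueError("pseudo-values are unstable below n = 50")

    def cif_at(tt, cc, when):
        times, at_risk, d1, d2, surv, surv_prev = _aj_components(tt, cc)
        d = d1 if cause == 1 else d2
        with np.errstate(divide="ignore", invalid="ignore"):
            cif = np.cumsum(np.where(at_risk > 0, surv_prev * d / at_risk, 0.0))
        idx = np.searchsorted(times, when, side="right") - 1
        return float(cif[idx]) if idx >= 0 else 0.0

    full = cif_at(t, c, timeframe)
    pv = np.empty(n)
    pairs = {}
    for key in set(zip(t.tolist(), c.tolist())):
        mask = (t == key[0]) & (c == key[1])
        i = np.flatnonzero(mask)[0]
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        loo = cif_at(t[keep], c[keep], timeframe)
        pairs[key] = n * full - (n - 1) * loo
    for i in range(n):
        pv[i] = pairs[(t[i], c[i])]
    return pv


@dataclass
class CalibrationCurve:
    grid: np.ndarray
    observed: np.ndarray
    timeframe: float
    sex: object = None
    pseudo: np.ndarray = field(default=None, repr=False)
    predicted: np.ndarray = field(default=None, repr=False)


def pseudo_value_calibration(
    records: pd.DataFrame,
    predictions,
    timeframe: float,
    sex: str | None = None,
    span: float = 0.75,
    n_grid: int = 100,
) -> CalibrationCurve:
    """Smooth calibration curve from pseudo-values at ``timeframe``.

    Pseudo-values of the observed cause-1 cumulative incidence are regressed
    on the predicted risks with a lowess smoother (span 0.75) and evaluated
    on a 100-point grid across the range of predictions.
    """
    pred = np.asarray(predictions, dtype=float)
    if len(pred) != len(records):
        raise ValueError("one prediction per record required")
    if sex is not None:
        mask = records["sex"].to_numpy() == sex
        records = records[mask]
        pred = pred[mask]
    pv = pseudo_values(
        records["followup_years"].to_numpy(dtype=float),
        records["event_cause"].to_numpy(),
        timeframe,
    )
    grid = np.linspace(pred.min(), pred.max(), n_grid)
    # robustness iterations must stay off: pseudo-values are two-point-like
    # (near 0 and near 1) and would be downweighted as "outliers"
    smoothed = sm.nonparametric.lowess(pv, pred, frac=span, it=0, xvals=grid)
    return CalibrationCurve(grid, smoothed, timeframe, sex, pv, pred)
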