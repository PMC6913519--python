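"""Multivariable Cox models for the non-HDL cholesterol / CVD association.

All models use age as the timescale with delayed entry at the baseline age
(left truncation: a subject contributes to risk sets only between their entry
age and their exit age), are stratified by sex and cohort, handle ties by
Efron's method, and adjust for smoking, diabetes, BMI, systolic blood
pressure and antihypertensive medication. The non-HDL exposure is coded
either as guideline categories (dummy variables, lowest category reference)
or as a natural cubic spline (3 interior knots at the exposure quartiles,
boundary knots at the winsorisation bounds 1.6 and 8.5 mmol/L). Sex- and
age-group-specific hazard ratios come from interaction terms with the
exposure; because sex and cohort are strata their main effects are absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .lipids import DEFAULT_CATEGORY_EDGES
from .splines import NaturalSpline

__all__ = [
    "AGE_GROUP_EDGES",
    "WINSOR_BOUNDS",
    "age_group",
    "DesignSpec",
    "CoxFit",
    "fit_stratified_cox",
    "categorical_hr_table",
    "spline_hr_curve",
    "wald_test",
]

#: baseline-age group boundaries: <45, 45-59, >=60
AGE_GROUP_EDGES = (45.0, 60.0)
#: display/winsorisation bounds for the continuous non-HDL association, mmol/L
WINSOR_BOUNDS = (1.6, 8.5)

ADJUSTMENT_COVARIATES = ("smoking", "diabetes", "bmi", "sbp", "antihypertensive_med")
SEX_LEVELS = ("female", "male")
AGE_GROUP_LEVELS = ("<45", "45-59", ">=60")


def age_group(age_baseline) -> np.ndarray:
    """Baseline age category labels: '<45', '45-59', '>=60'."""
    a = np.asarray(age_baseline, dtype=float)
    idx = np.digitize(a, AGE_GROUP_EDGES)
    return np.asarray(AGE_GROUP_LEVELS, dtype=object)[idx]


@dataclass
class DesignSpec:
    """Recipe for the Cox design matrix; reusable at prediction time."""

    exposure: str = "categorical"  # "categorical" | "spline" | "none"
    interactions: tuple = ("sex",)  # subset of {"sex", "age_group"}
    adjustment: tuple = ADJUSTMENT_COVARIATES
    category_edges: tuple = DEFAULT_CATEGORY_EDGES
    spline: Optional[NaturalSpline] = None
    exposure_col: str = "non_hdl_adj"
    extra_splines: dict = field(default_factory=dict)  # e.g. {"bmi": NaturalSpline}

    def _exposure_blocks(self, df: pd.DataFrame) -> dict:
        """Exposure columns before interaction coding: name -> values."""
        if self.exposure == "none":
            return {}
        if self.exposure == "categorical":
            cat = np.digitize(
                df[self.exposure_col].to_numpy(dtype=float),
                np.asarray(self.category_edges, dtype=float),
            ) + 1
            return {f"cat{j}": (cat == j).astype(float) for j in range(2, 6)}
        if self.exposure == "spline":
            B = self.spline.basis(df[self.exposure_col].to_numpy(dtype=float))
            return {f"ns{j + 1}": B[:, j] for j in range(B.shape[1])}
        raise ValueError(f"unknown exposure spec {self.exposure!r}")

    def build(self, df: pd.DataFrame) -> pd.DataFrame:
        """Design matrix (covariate columns only)."""
        out = {}
        blocks = self._exposure_blocks(df)
        if blocks:
            levels = [("", np.ones(len(df)))]
            if "sex" in self.interactions:
                sex = df["sex"].to_numpy()
                levels = [(f"[{s}]", (sex == s).astype(float)) for s in SEX_LEVELS]
            if "age_group" in self.interactions:
                ag = age_group(df["age_baseline"].to_numpy())
                levels = [
                    (f"{suf}[{a}]", ind * (ag == a).astype(float))
                    for suf, ind in levels
                    for a in AGE_GROUP_LEVELS
                ]
            for name, x in blocks.items():
                for suf, ind in levels:
                    out[f"{name}{suf}"] = x * ind
        for cov in self.adjustment:
            if cov in self.extra_splines:
                B = self.extra_splines[cov].basis(df[cov].to_numpy(dtype=float))
                for j in range(B.shape[1]):
                    out[f"{cov}_ns{j + 1}"] = B[:, j]
            else:
                out[cov] = df[cov].to_numpy(dtype=float)
        return pd.DataFrame(out, index=df.index)


@dataclass
class CoxFit:
    """A fitted stratified Cox model (age timescale, Efron ties)."""

    params: pd.Series
    cov: pd.DataFrame
    design: DesignSpec
    strata: tuple = ("sex", "cohort_id")
    timescale: str = "age"
    ties: str = "efron"
    n_events: int = 0
    log_likelihood: float = float("nan")

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        X = self.design.build(df)
        return X[self.params.index].to_numpy() @ self.params.to_numpy()

    def hazard_ratio(self, contrast: np.ndarray) -> tuple:
        """HR, (lo, hi) for a linear combination c'beta (Wald 95% CI)."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.params.to_numpy())
        se = float(np.sqrt(c @ self.cov.to_numpy() @ c))
        z = stats.norm.ppf(0.975)
        return np.exp(est), (np.exp(est - z * se), np.exp(est + z * se))


def wald_test(fit: CoxFit, constraints: np.ndarray) -> tuple:
    """Chi-square Wald test of C beta = 0; returns (stat, df, p)."""
    C = np.atleast_2d(np.asarray(constraints, dtype=float))
    b = fit.params.to_numpy()
    V = C @ fit.cov.to_numpy() @ C.T
    stat = float(C @ b @ np.linalg.solve(V, C @ b))
    df = C.shape[0]
    return stat, df, float(stats.chi2.sf(stat, df))


def _prune_empty_strata(df: pd.DataFrame, strata: Sequence[str], event_col: str):
    counts = df.groupby(list(strata), observed=True)[event_col].sum()
    empty = counts[counts == 0].index
    if len(empty):
        warnings.warn(
            f"dropping {len(empty)} stratum/strata with zero events: "
            f"{list(empty)[:5]}"
        )
        keep = ~df.set_index(list(strata)).index.isin(empty)
        df = df.loc[np.asarray(keep)]
    return df


def fit_stratified_cox(
    records: pd.DataFrame,
    exposure: str | DesignSpec = "categorical",
    interactions: Sequence[str] = ("sex",),
    event_cause: int = 1,
    strata: Sequence[str] = ("sex", "cohort_id"),
    robust: bool = False,
) -> CoxFit:
    """Stratified Cox partial-likelihood fit on the age timescale.

    ``exposure`` may be ``"categorical"``, ``"spline"`` or a ready
    :class:`DesignSpec`. The event is ``event_cause`` (1 = CVD); other causes
    are censored at their event time (cause-specific hazard modelling).
    """
    if isinstance(exposure, DesignSpec):
        spec = exposure
    else:
        spec = DesignSpec(exposure=exposure, interactions=tuple(interactions))
        if exposure == "spline" and spec.spline is None:
            x = np.clip(
                records[spec.exposure_col].to_numpy(dtype=float), *WINSOR_BOUNDS
            )
            interior = np.percentile(x, [25, 50, 75])
            spec.spline = NaturalSpline(
                tuple(np.unique(np.r_[WINSOR_BOUNDS[0], interior, WINSOR_BOUNDS[1]]))
            )

    X = spec.build(records)
    df = X.copy()
    df["age_entry"] = records["age_baseline"].to_numpy(dtype=float)
    df["age_exit"] = df["age_entry"] + records["followup_years"].to_numpy(dtype=float)
    df["event"] = (records["event_cause"].to_numpy() == event_cause).astype(int)
    for s in strata:
        df[s] = records[s].to_numpy()
    df = _prune_empty_strata(df, strata, "event")
    if df["event"].sum() == 0:
        raise ValueError("no events of the requested cause")

    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="age_exit",
        event_col="event",
        entry_col="age_entry",
        strata=list(strata),
        robust=robust,
        show_progress=False,
    )
    return CoxFit(
        params=cph.params_.copy(),
        cov=cph.variance_matrix_.copy(),
        design=spec,
        strata=tuple(strata),
        n_events=int(df["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )


def categorical_hr_table(fit: CoxFit, by_age_group: bool = False) -> pd.DataFrame:
    """Sex-specific (optionally age-group-specific) category hazard ratios.

    Rows: (sex, age_group, category, hr, ci_low, ci_high); the reference
    category 1 appears with HR exactly 1 and CI (1, 1). When ``by_age_group``
    the result carries a Wald test of equal category effects across age
    groups in ``.attrs['interaction_test']`` as (stat, df, p).
    """
    if fit.design.exposure != "categorical":
        raise ValueError("fit does not use a categorical exposure")
    want_age = by_age_group
    has_age = "age_group" in fit.design.interactions
    has_sex = "sex" in fit.design.interactions
    if want_age and not has_age:
        raise ValueError("fit lacks the age_group interaction terms")
    names = list(fit.params.index)
    sexes = SEX_LEVELS if has_sex else ("all",)
    ages = AGE_GROUP_LEVELS if want_age else ("all",)
    rows = []
    for sex in sexes:
        for ag in ages:
            rows.append(
                {"sex": sex, "age_group": ag, "category": 1,
                 "hr": 1.0, "ci_low": 1.0, "ci_high": 1.0}
            )
            for j in range(2, 6):
                term = f"cat{j}"
                if has_sex:
                    term += f"[{sex}]"
                if has_age:
                    term += f"[{ag}]"
                if want_age or not has_age:
                    if term not in names:
                        raise ValueError(f"missing model term {term!r}")
                    c = np.zeros(len(names))
                    c[names.index(term)] = 1.0
                else:
                    # fit has age interactions but an overall HR is requested
                    raise ValueError(
                        "fit includes age_group interactions; request "
                        "by_age_group=True or refit without them"
                    )
                hr, (lo, hi) = fit.hazard_ratio(c)
                rows.append(
                    {"sex": sex, "age_group": ag, "category": j,
                     "hr": hr, "ci_low": lo, "ci_high": hi}
                )
    out = pd.DataFrame(rows)
    if want_age:
        # H0: category effects identical across age groups
        C = []
        for sex in sexes:
            for j in range(2, 6):
                base = f"cat{j}[{sex}]" if has_sex else f"cat{j}"
                ref_idx = names.index(f"{base}[{AGE_GROUP_LEVELS[0]}]")
                for ag in AGE_GROUP_LEVELS[1:]:
                    row = np.zeros(len(names))
                    row[names.index(f"{base}[{ag}]")] = 1.0
                    row[ref_idx] = -1.0
                    C.append(row)
        out.attrs["interaction_test"] = wald_test(fit, np.array(C))
    return out


def spline_hr_curve(
    fit: CoxFit,
    reference: float = 2.6,
    winsor_bounds: tuple = WINSOR_BOUNDS,
    sex: str | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Continuous HR curve HR(x) = exp(s(x) - s(ref)) with delta-method CI.

    Inputs are clamped to ``winsor_bounds``; the curve equals exactly 1 at the
    reference (2.6 mmol/L by convention).
    """
    if fit.design.exposure != "spline":
        raise ValueError("fit does not use a spline exposure")
    lo, hi = winsor_bounds
    if not lo <= reference <= hi:
        raise ValueError(f"reference {reference} outside winsor bounds {winsor_bounds}")
    if grid is None:
        grid = np.linspace(lo, hi, 139)
    grid = np.clip(np.asarray(grid, dtype=float), lo, hi)
    spline = fit.design.spline
    B = spline.basis(grid)
    Bref = spline.basis(np.array([reference]))
    D = B - Bref  # (m, nb)
    names = list(fit.params.index)
    has_sex = "sex" in fit.design.interactions
    suffix = f"[{sex}]" if has_sex else ""
    if has_sex and sex is None:
        raise ValueError("fit has sex-specific splines; pass sex=")
    cols = []
    for j in range(spline.n_basis):
        term = f"ns{j + 1}{suffix}"
        if term not in names:
            raise ValueError(f"missing model term {term!r}")
        cols.append(names.index(term))
    C = np.zeros((len(grid), len(names)))
    C[:, cols] = D
    est = C @ fit.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, fit.cov.to_numpy(), C))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "non_hdl": grid,
            "hr": np.exp(est),
            "ci_low": np.exp(est - z * se),
            "ci_high": np.exp(est + z * se),
        }
    )
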