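"""Nonparametric cumulative incidence under competing risks.

The Aalen-Johansen estimator generalises Kaplan-Meier to several causes: the
cause-specific cumulative incidence function (CIF) accumulates increments
S(t-) * d_c(t) / Y(t), where S is the all-cause Kaplan-Meier survival, d_c the
number of cause-c events at t and Y the number at risk. With a tie between an
event and a censoring at the same time the event is counted first (censored
subjects remain in the risk set at that time).

Group comparison uses Gray's K-sample test for equality of subdistribution
hazards (rho = 0 weighting). The subdistribution risk set is
``R_k(t) = Y_k(t) * (1 - F_1k(t-)) / S_k(t-)``, which keeps subjects who
failed earlier from the competing cause "at risk" with the appropriate
censoring-consistent weight; the score and its log-rank-type variance are
referred to a chi-square distribution with (groups - 1) degrees of freedom.

Variance of the CIF uses the standard counting-process (delta-method)
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CIFCurve", "aalen_johansen", "grays_test", "GraysTestResult"]


@dataclass
class CIFCurve:
    """One cause's cumulative incidence on the distinct observed-time grid."""

    cause: int
    times: np.ndarray  # distinct observed times, ascending
    cif: np.ndarray
    variance: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray  # all-cause Kaplan-Meier at the same grid
    group: object = None

    def at(self, t) -> np.ndarray:
        """CIF evaluated at arbitrary times (right-continuous step function)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.cif[np.clip(idx, 0, None)], 0.0)
        return out if out.ndim else float(out)

    def at_risk_at(self, t) -> np.ndarray:
        """Number still at risk at each requested time (time >= t)."""
        t = np.asarray(t, dtype=float)
        # at_risk[i] counts subjects with observed time >= times[i]
        idx = np.searchsorted(self.times, t, side="left")
        ext = np.append(self.at_risk, 0.0)
        n0 = self.at_risk[0] if len(self.at_risk) else 0.0
        out = np.where(idx < len(self.times), ext[idx], 0.0)
        out = np.where(t <= (self.times[0] if len(self.times) else np.inf), n0, out)
        return out


def _aj_components(durations: np.ndarray, causes: np.ndarray):
    """Distinct times with at-risk counts, per-cause event counts, KM survival."""
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    c = causes[order]
    n = len(t)
    times, start = np.unique(t, return_index=True)
    # counts per distinct time
    d1 = np.zeros(len(times))
    d2 = np.zeros(len(times))
    grp = np.searchsorted(times, t)
    np.add.at(d1, grp, (c == 1).astype(float))
    np.add.at(d2, grp, (c == 2).astype(float))
    at_risk = n - start  # events precede censorings: all with time >= t at risk
    d = d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        km_factor = np.where(at_risk > 0, 1.0 - d / at_risk, 1.0)
    surv = np.cumprod(km_factor)
    surv_prev = np.concatenate([[1.0], surv[:-1]])
    return times, at_risk.astype(float), d1, d2, surv, surv_prev


def _cif_variance(times, at_risk, d_cause, d_all, surv_prev, cif):
    """Delta-method variance of the Aalen-Johansen CIF (per grid point)."""
    Y = at_risk
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(Y * (Y - d_all) > 0, d_all / (Y * (Y - d_all)), 0.0)
        b = surv_prev**2 * np.where(Y > 0, (Y - d_cause) / Y * d_cause / Y**2, 0.0)
        c = surv_prev * np.where(Y > 0, d_cause / Y**2, 0.0)
    var = np.empty_like(cif)
    # Var F(t) = sum_{s<=t} (F(t)-F(s))^2 a_s + b_s - 2 (F(t)-F(s)) c_s
    # expand the square so one forward pass suffices
    ca = np.cumsum(a)
    caF = np.cumsum(a * cif)
    caF2 = np.cumsum(a * cif**2)
    cb = np.cumsum(b)
    cc = np.cumsum(c)
    ccF = np.cumsum(c * cif)
    var = (
        cif**2 * ca - 2 * cif * caF + caF2 + cb - 2 * (cif * cc - ccF)
    )
    return np.maximum(var, 0.0)


def _aj_curves(durations, causes, group=None) -> dict:
    times, at_risk, d1, d2, surv, surv_prev = _aj_components(durations, causes)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc1 = np.where(at_risk > 0, surv_prev * d1 / at_risk, 0.0)
        inc2 = np.where(at_risk > 0, surv_prev * d2 / at_risk, 0.0)
    cif1 = np.cumsum(inc1)
    cif2 = np.cumsum(inc2)
    d = d1 + d2
    return {
        1: CIFCurve(1, times, cif1, _cif_variance(times, at_risk, d1, d, surv_prev, cif1),
                    at_risk, surv, group),
        2: CIFCurve(2, times, cif2, _cif_variance(times, at_risk, d2, d, surv_prev, cif2),
                    at_risk, surv, group),
    }


def aalen_johansen(records: pd.DataFrame, group: str | None = None,
                   duration_col: str = "followup_years",
                   cause_col: str = "event_cause") -> dict:
    """Aalen-Johansen CIF curves per cause, optionally per group.

    Returns ``{cause: CIFCurve}`` without grouping, else
    ``{group_label: {cause: CIFCurve}}``. Raises on an empty table or group.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    t = records[duration_col].to_numpy(dtype=float)
    c = records[cause_col].to_numpy()
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    if not np.isin(c, [0, 1, 2]).all():
        raise ValueError("event_cause must be in {0, 1, 2}")
    if group is None:
        return _aj_curves(t, c)
    out = {}
    for g, sub in records.groupby(group, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        out[g] = _aj_curves(
            sub[duration_col].to_numpy(dtype=float), sub[cause_col].to_numpy(), group=g
        )
    if not out:
        raise ValueError(f"no groups found in column {group!r}")
    return out


@dataclass
class GraysTestResult:
    statistic: float
    df: int
    p_value: float
    scores: np.ndarray = field(default=None, repr=False)


def _left_step(xs, ys, t, fill):
    """Left-continuous evaluation of a right-continuous step function."""
    idx = np.searchsorted(xs, t, side="left") - 1
    return np.where(idx >= 0, ys[np.clip(idx, 0, None)], fill)


def grays_test(records: pd.DataFrame, group: str, cause: int = 1,
               duration_col: str = "followup_years",
               cause_col: str = "event_cause") -> GraysTestResult:
    """Gray's K-sample test for equality of cause-specific cumulative incidence.

    Compares the subdistribution hazards of ``cause`` across the groups in
    column ``group``; chi-square reference with (K - 1) degrees of freedom.
    """
    t = records[duration_col].to_numpy(dtype=float)
    c = records[cause_col].to_numpy()
    labels, g = np.unique(records[group].to_numpy(), return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError(f"Gray's test needs >= 2 groups, found {K}")
    if cause == 2:
        c = np.where(c == 1, 2, np.where(c == 2, 1, 0))

    # pooled distinct cause-1 event times
    ev_times = np.unique(t[c == 1])
    if len(ev_times) == 0:
        raise ValueError("no events of the tested cause")
    m = len(ev_times)

    d1k = np.zeros((K, m))
    Rk = np.zeros((K, m))
    for k in range(K):
        mask = g == k
        tk, ck = t[mask], c[mask]
        if (ck == 1).sum() == 0:
            raise ValueError(f"group {labels[k]!r} has no events of the tested cause")
        times, at_risk, d1, d2, surv, surv_prev = _aj_components(tk, ck)
        with np.errstate(divide="ignore", invalid="ignore"):
            cif1 = np.cumsum(np.where(at_risk > 0, surv_prev * d1 / at_risk, 0.0))
        # left limits at the pooled event times
        Y = len(tk) - np.searchsorted(np.sort(tk), ev_times, side="left")
        F1_prev = _left_step(times, cif1, ev_times, 0.0)
        S_prev = _left_step(times, surv, ev_times, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(S_prev > 0, (1.0 - F1_prev) / S_prev, 0.0)
        Rk[k] = Y * w
        # cause-1 event counts of this group at the pooled times
        et = tk[ck == 1]
        idx = np.searchsorted(ev_times, et)
        np.add.at(d1k[k], idx, 1.0)

    R = Rk.sum(axis=0)
    d1 = d1k.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(R > 0, Rk / R, 0.0)
    scores = (d1k - p * d1).sum(axis=1)

    # log-rank-type covariance with multiplicity correction for tied events
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(R > 1, (R - d1) / (R - 1), 1.0)
    wts = d1 * np.clip(corr, 0.0, None)
    V = np.zeros((K, K))
    for k in range(K):
        for l in range(k, K):
            if k == l:
                V[k, k] = np.sum(wts * p[k] * (1 - p[k]))
            else:
                V[k, l] = V[l, k] = -np.sum(wts * p[k] * p[l])

    z = scores[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    df = K - 1
    return GraysTestResult(stat, df, float(stats.chi2.sf(stat, df)), scores)
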