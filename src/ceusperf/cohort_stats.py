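"""Longitudinal week-effect analysis on irregular perfusion panels.

Subjects in the cohort drop out at different weeks, so the panel is
irregular. Each perfusion index is analysed with a random-intercept
(compound-symmetry) model

    y_iw = mu + sum_w beta_w * [week == w] + b_i + eps_iw,

estimated by feasible generalized least squares: ordinary least squares
for the fixed effects, method-of-moments variance components from the
OLS residuals, then a GLS re-estimate under the implied within-subject
covariance. Each week's effect versus the baseline week gets a Wald z
test; the earliest week with p below the significance level is the
index's detection week.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .models import DegenerateDesignError

__all__ = [
    "WeekEffects",
    "fit_week_effects",
    "earliest_significant_week",
    "bonferroni_pairwise",
]


@dataclass(frozen=True)
class WeekEffects:
    """Per-week fixed effects of one index versus the baseline week.

    ``table`` has one row per non-baseline week: estimate, se, z, p,
    ci_low, ci_high. Variance components are the between-subject
    (random-intercept) and residual variances.
    """

    index: str
    baseline_week: int
    table: pd.DataFrame
    sigma2_between: float
    sigma2_residual: float
    n_subjects: int
    n_obs: int
    dropped_weeks: Tuple[int, ...] = ()


def _design(df: pd.DataFrame, weeks: Sequence[int], baseline: int) -> np.ndarray:
    X = np.ones((len(df), 1 + len(weeks) - 1))
    for j, w in enumerate(w for w in weeks if w != baseline):
        X[:, 1 + j] = (df["week"].to_numpy() == w).astype(float)
    return X


def fit_week_effects(
    panel: pd.DataFrame,
    index: str,
    value_col: Optional[str] = None,
    baseline_week: Optional[int] = None,
) -> WeekEffects:
    """Fit the random-intercept week-effect model for one index.

    Parameters
    ----------
    panel : DataFrame
        Long format with columns subject, week, index, value — or wide
        format with a column named ``index`` (pass value_col to override).
    index : str
        Which perfusion index to analyse (e.g. "TTP").
    baseline_week : int, optional
        Reference week; defaults to the smallest observed week.

    Weeks observed in fewer than 2 subjects are dropped with a warning;
    a single-subject panel raises DegenerateDesignError.
    """
    if value_col is None and {"index", "value"} <= set(panel.columns):
        df = panel.loc[panel["index"] == index, ["subject", "week", "value"]].copy()
    else:
        col = value_col or index
        if col not in panel.columns:
            raise KeyError(f"panel has no column or index entry {index!r}")
        df = panel[["subject", "week", col]].rename(columns={col: "value"}).copy()
    df = df.dropna(subset=["value"])
    if df.duplicated(["subject", "week"]).any():
        raise ValueError("duplicate (subject, week) rows in panel")

    if df["subject"].nunique() < 2:
        raise DegenerateDesignError("need >= 2 subjects to separate variance components")

    counts = df.groupby("week")["subject"].nunique()
    thin = tuple(int(w) for w in counts.index[counts < 2])
    if thin:
        warnings.warn(
            f"dropping weeks observed in < 2 subjects: {thin}", stacklevel=2
        )
        df = df[~df["week"].isin(thin)]

    weeks = sorted(int(w) for w in df["week"].unique())
    if len(weeks) < 2:
        raise DegenerateDesignError("need >= 2 retained weeks including baseline")
    baseline = int(weeks[0]) if baseline_week is None else int(baseline_week)
    if baseline not in weeks:
        raise ValueError(f"baseline week {baseline} not present in panel")

    df = df.sort_values(["subject", "week"]).reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    X = _design(df, weeks, baseline)
    n, p = X.shape

    # Stage 1: OLS for the fixed effects
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols

    # Stage 2: method-of-moments variance components from OLS residuals.
    # Total residual variance estimates sigma_b^2 + sigma^2; the mean
    # cross-product of distinct within-subject residual pairs estimates
    # sigma_b^2 under compound symmetry.
    dof = max(n - p, 1)
    s2_total = float(resid @ resid) / dof
    cross_sum = 0.0
    n_pairs = 0
    for _, g in df.assign(resid=resid).groupby("subject"):
        r = g["resid"].to_numpy()
        m = r.size
        if m >= 2:
            cross_sum += (r.sum() ** 2 - (r**2).sum())
            n_pairs += m * (m - 1)
    sigma2_b = max(cross_sum / n_pairs, 0.0) if n_pairs else 0.0
    sigma2_b = min(sigma2_b, s2_total)
    sigma2_e = max(s2_total - sigma2_b, 0.0)

    # Stage 3: GLS under V_i = sigma_e^2 I + sigma_b^2 J via Woodbury.
    se_floor = max(sigma2_e, 1e-30)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for _, g in df.groupby("subject", sort=False):
        idx = g.index.to_numpy()
        Xi, yi = X[idx], y[idx]
        m = len(idx)
        shrink = sigma2_b / (se_floor + m * sigma2_b) if sigma2_b > 0 else 0.0
        Vinv_X = (Xi - shrink * Xi.sum(axis=0)) / se_floor
        XtVX += Xi.T @ Vinv_X
        XtVy += Vinv_X.T @ yi
    cov = np.linalg.pinv(XtVX)
    beta = cov @ XtVy

    rows = []
    nonbase = [w for w in weeks if w != baseline]
    z_crit = stats.norm.ppf(0.975)
    # scale-aware zero: on a zero-variance panel both estimates and SEs
    # are floating-point residue; treat them as exact zeros
    zero_tol = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    for j, w in enumerate(nonbase):
        est = float(beta[1 + j])
        se = float(np.sqrt(max(cov[1 + j, 1 + j], 0.0)))
        if se > zero_tol:
            z = est / se
            pval = 2.0 * stats.norm.sf(abs(z))
        else:
            z = 0.0 if abs(est) <= zero_tol else np.inf * np.sign(est)
            pval = 1.0 if abs(est) <= zero_tol else 0.0
        rows.append(
            {
                "week": w,
                "estimate": est,
                "se": se,
                "z": z,
                "p": pval,
                "ci_low": est - z_crit * se,
                "ci_high": est + z_crit * se,
            }
        )
    table = pd.DataFrame(rows)
    return WeekEffects(
        index=index,
        baseline_week=baseline,
        table=table,
        sigma2_between=sigma2_b,
        sigma2_residual=sigma2_e,
        n_subjects=int(df["subject"].nunique()),
        n_obs=n,
        dropped_weeks=thin,
    )


def earliest_significant_week(
    effects: WeekEffects, alpha: float = 0.05
) -> Optional[int]:
    """Smallest week whose effect-vs-baseline p-value is below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    hits = effects.table.loc[effects.table["p"] < alpha, "week"]
    return int(hits.min()) if len(hits) else None


def bonferroni_pairwise(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise two-sample t tests with Bonferroni-adjusted p-values.

    ``groups`` maps stage label -> scalar values. Stages with fewer than
    2 values are dropped with a warning. Adjusted p = raw p times the
    number of comparisons, capped at 1.
    """
    usable = {}
    for label, vals in groups.items():
        arr = np.asarray(list(vals), dtype=float)
        if arr.size < 2:
            warnings.warn(f"dropping stage {label!r} with < 2 values", stacklevel=2)
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise DegenerateDesignError("need >= 2 stages with >= 2 values each")
    pairs = list(itertools.combinations(sorted(usable), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(usable[a], usable[b])
        p_adj = min(float(p) * m, 1.0)
        rows.append(
            {
                "stage_a": a,
                "stage_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
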