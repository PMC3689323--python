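"""Regression of model performance profiles against human profiles.

For each model the per-condition thresholds t_M (and estimate SDs s_M) are
regressed against the human values with ordinary least squares,

    t_H = alpha + beta * t_M,        s_H = alpha + beta * s_M,

with the human data as the response.  R^2 measures whether model and human
profiles share a shape; the gain beta is near 1 when the model's threshold
magnitudes match the human ones.  Fits are reported over three dot-level
subsets: the low range ("5-50"), the primary range ("5-200"), and their
union ("all").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

SUBSETS = ("5-50", "5-200", "all")
_PRIMARY_DOTS = {5, 50, 100, 200}
_FOLLOWUP_DOTS = {5, 15, 25, 35, 50}


@dataclass
class RegressionResult:
    alpha: float
    beta: float
    r_squared: float
    p_value: float
    n: int


def _subset_mask(dots: pd.Series, subset: str) -> pd.Series:
    if subset == "5-50":
        return dots <= 50
    if subset == "5-200":
        return dots.isin(_PRIMARY_DOTS)
    if subset == "all":
        return pd.Series(True, index=dots.index)
    raise ValueError(f"subset must be one of {SUBSETS}")


def regress_profiles(model_table: pd.DataFrame, human_table: pd.DataFrame,
                     subset: str = "all",
                     value: str = "threshold_deg") -> RegressionResult:
    """OLS of human values on model values over matched (dots, noise) cells."""
    merged = pd.merge(model_table, human_table, on=["dots", "noise_sd"],
                      suffixes=("_model", "_human"))
    merged = merged[_subset_mask(merged["dots"], subset)]
    xm = merged[f"{value}_model"].to_numpy(dtype=float)
    yh = merged[f"{value}_human"].to_numpy(dtype=float)
    keep = np.isfinite(xm) & np.isfinite(yh)
    xm, yh = xm[keep], yh[keep]
    if len(xm) < 3:
        raise ValueError("insufficient data: need >= 3 matched cells")
    fit = sm.OLS(yh, sm.add_constant(xm)).fit()
    return RegressionResult(alpha=float(fit.params[0]),
                            beta=float(fit.params[1]),
                            r_squared=float(fit.rsquared),
                            p_value=float(fit.pvalues[1]),
                            n=len(xm))


def regression_tables(model_tables: dict[str, pd.DataFrame],
                      human_table: pd.DataFrame,
                      value: str = "threshold_deg") -> pd.DataFrame:
    """R^2/beta/p for every model x subset; one tidy row per fit."""
    rows = []
    for name, mt in model_tables.items():
        for subset in SUBSETS:
            try:
                r = regress_profiles(mt, human_table, subset, value)
            except ValueError:
                continue
            rows.append({"model": name, "subset": subset, "measure": value,
                         "alpha": r.alpha, "beta": r.beta,
                         "r_squared": r.r_squared, "p_value": r.p_value,
                         "n": r.n})
    return pd.DataFrame(rows)


def compare_resolutions(results_1deg: pd.DataFrame,
                        results_halfdeg: pd.DataFrame,
                        r2_tol: float = 0.05,
                        beta_rel_tol: float = 0.2) -> pd.DataFrame:
    """Side-by-side R^2 and beta at the two grid resolutions, flagging fits
    that moved by more than ``r2_tol`` (R^2) or ``beta_rel_tol`` (relative,
    beta).  lhp80 has no resolution parameter, so its rows must be
    identical by construction."""
    keys = ["model", "subset", "measure"]
    m = pd.merge(results_1deg, results_halfdeg, on=keys,
                 suffixes=("_1deg", "_halfdeg"))
    m["r2_change"] = m["r_squared_halfdeg"] - m["r_squared_1deg"]
    with np.errstate(divide="ignore", invalid="ignore"):
        m["beta_rel_change"] = (m["beta_halfdeg"] - m["beta_1deg"]) / np.abs(
            m["beta_1deg"])
    m["flagged"] = (np.abs(m["r2_change"]) > r2_tol) | (
        np.abs(m["beta_rel_change"]) > beta_rel_tol)
    return m[keys + ["r_squared_1deg", "r_squared_halfdeg", "beta_1deg",
                     "beta_halfdeg", "r2_change", "beta_rel_change", "flagged"]]
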