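"""Psychometric fitting, threshold extraction, and weighted aggregation.

Percent-correct scores from the left/right heading task are fitted with a
cumulative Gaussian as a function of unsigned FoE offset, by least squares
(not binomial likelihood, because downstream weighting uses the RMS error of
the fit).  The 75%-correct offset is the threshold.  Two parameterizations
are supported:

``plain``    P(x) = Phi((x - mu) / sigma)           (default)
``floored``  P(x) = 0.5 + 0.5 * Phi((x - mu) / sigma)

Observer thresholds are normalized by each observer's grand mean before
weighted averaging (weights proportional to 1/RMSE, summing to 1), and
group contrasts use a weighted paired t-test that reduces to the classical
paired t-test under uniform weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: RMSE floor used when forming 1/RMSE weights (a perfect fit gets the
#: largest finite weight instead of an infinite one)
RMSE_EPS = 1e-6
CONVENTIONS = ("plain", "floored")


@dataclass
class PsychometricFit:
    mu: float
    sigma: float
    rmse: float
    threshold75: float
    convention: str = "plain"

    @property
    def ok(self) -> bool:
        return np.isfinite(self.rmse)


def _curve(x, mu, sigma, convention):
    z = stats.norm.cdf((x - mu) / sigma)
    return 0.5 + 0.5 * z if convention == "floored" else z


def threshold_from_params(mu: float, sigma: float,
                          convention: str = "plain") -> float:
    """Offset at which the fitted curve reaches 0.75."""
    if convention == "floored":
        return mu  # 0.5 + 0.5*Phi = 0.75  <=>  Phi = 0.5  <=>  x = mu
    return mu + sigma * stats.norm.ppf(0.75)


def fit_cumulative_gaussian(offsets, pcorrect,
                            convention: str = "plain") -> PsychometricFit:
    """Least-squares cumulative-Gaussian fit of %correct vs unsigned offset.

    Non-convergent fits (or parameter-bound hits) are returned flagged with
    ``rmse = inf`` so they receive zero weight downstream.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    x = np.asarray(offsets, dtype=float)
    p = np.asarray(pcorrect, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct offsets")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("pcorrect values must lie in [0, 1]")

    span = x.max() - x.min()
    sigma_hi = 100.0 * max(span, 1.0)
    p0 = (float(np.median(x)), max(span / 2, 1e-2))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            # mu >= 0: offsets are unsigned and a zero-offset judgment is
            # chance, so saturated cells (correct everywhere) pin the
            # threshold near 0 instead of drifting to arbitrary negatives
            popt, _ = optimize.curve_fit(
                lambda xx, mu, sg: _curve(xx, mu, sg, convention),
                x, p, p0=p0,
                bounds=([0.0, 1e-6], [10 * max(span, 1.0), sigma_hi]),
                maxfev=5000)
        mu, sigma = float(popt[0]), float(popt[1])
        resid = p - _curve(x, mu, sigma, convention)
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        if sigma >= 0.999 * sigma_hi:
            raise RuntimeError("sigma bound hit")
    except (RuntimeError, ValueError):
        return PsychometricFit(np.nan, np.nan, np.inf, np.nan, convention)
    return PsychometricFit(mu, sigma, rmse,
                           threshold_from_params(mu, sigma, convention),
                           convention)


def weighted_mean_thresholds(values, rmses) -> tuple[float, np.ndarray]:
    """Inverse-RMSE weighted mean; weights normalized to sum to 1.

    Infinite-RMSE entries get exactly zero weight; zero RMSEs are floored at
    ``RMSE_EPS``.  Returns (mean, weights).
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(rmses, dtype=float)
    if np.any(r < 0):
        raise ValueError("rmse values must be nonnegative")
    inv = np.where(np.isfinite(r), 1.0 / np.maximum(r, RMSE_EPS), 0.0)
    if inv.sum() == 0:
        raise ValueError("no finite-rmse values to aggregate")
    w = inv / inv.sum()
    return float(w @ v), w


def normalize_thresholds(table: pd.DataFrame,
                         value: str = "threshold_deg",
                         rmse: str = "rmse") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grand-mean normalization and weighted group averaging.

    ``table`` holds one row per (observer, dots, noise_sd) with a threshold
    and a fit RMSE.  Each observer's thresholds are divided by that
    observer's grand mean (over their non-missing cells); per condition the
    normalized thresholds are averaged with 1/RMSE weights and multiplied
    back by the grand mean over all observers.

    Returns (per-observer normalized table, group-level table).
    """
    df = table.copy()
    df = df[np.isfinite(df[value])]
    grand = df.groupby("observer")[value].mean()
    empty = set(table["observer"]) - set(grand.index)
    if empty:
        warnings.warn(f"dropping observers with no usable cells: {sorted(empty)}")
    df["grand_mean"] = df["observer"].map(grand)
    df["normalized"] = df[value] / df["grand_mean"]
    group_grand_mean = float(grand.mean())

    rows = []
    for (dots, noise), cell in df.groupby(["dots", "noise_sd"]):
        m, _ = weighted_mean_thresholds(cell["normalized"], cell[rmse])
        rows.append({"dots": dots, "noise_sd": noise,
                     "normalized_mean": m,
                     "threshold_deg": m * group_grand_mean,
                     "n_observers": len(cell)})
    group = pd.DataFrame(rows).sort_values(["noise_sd", "dots"],
                                           ignore_index=True)
    group.attrs["grand_mean"] = group_grand_mean
    return df, group


@dataclass
class WeightedTTest:
    t: float
    df: float
    p: float


def weighted_t_test(a, b, weights, paired: bool = True) -> WeightedTTest:
    """Weighted comparison of paired means.

    The statistic is the weighted mean difference over its standard error:
    with weights normalized to sum 1, Var(dbar) = sigma^2 * sum(w^2) and
    sigma^2 is estimated unbiasedly by sum(w*(d - dbar)^2) / (1 - sum(w^2)).
    Degrees of freedom use the effective sample size n_eff = 1/sum(w^2), so
    uniform weights reduce exactly to the classical paired t-test while
    weights concentrated on a single pair drive df -> 0 and p -> 1 (no
    inferential power from one effective observation).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not paired:
        raise NotImplementedError("only the paired form is used here")
    if len(a) != len(b) or len(a) != len(w):
        raise ValueError("a, b, weights must have equal length")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    d = a - b
    dbar = float(w @ d)
    sw2 = float(w @ w)
    df = 1.0 / sw2 - 1.0
    denom = 1.0 - sw2
    if denom <= 0 or df <= 0:
        return WeightedTTest(t=np.nan, df=0.0, p=1.0)
    sigma2 = float(w @ (d - dbar) ** 2) / denom
    se = np.sqrt(sigma2 * sw2)
    if se == 0:
        t = 0.0 if dbar == 0 else np.sign(dbar) * np.inf
    else:
        t = dbar / se
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return WeightedTTest(t=float(t), df=df, p=p)
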