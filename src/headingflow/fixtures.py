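"""Synthetic stand-ins for the human psychophysics data.

The study's human thresholds exist only as figures, so every downstream
stage (normalization, weighted averaging, regression against models) is
exercised against generated tables that reproduce the *qualitative*
structure of human heading performance: thresholds around 0.5-1.0 deg at
high dot counts, rising sharply below a knee of ~25 dots per frame, and
rising with directional noise above that range (with noise mattering little
in very sparse fields).  No numerical fidelity to the real observers is
claimed; see the generated tables' validation for exactly what is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class HumanProfileParams:
    """Shape parameters of the synthetic human threshold surface.

    plateau_thresholds : asymptotic threshold (deg) per noise level
        {0: 0.5, 7.5: 0.75, 15: 1.0} -- high-dot-count thresholds roughly
        double from no noise to the strongest noise.
    knee : dot count above which thresholds have flattened out.
    low_dot_inflation : multiplicative threshold factor at 5 dots.
    observer_sd : log-scale SD of the per-observer multiplicative factor.
    cell_jitter_sd : log-scale SD of independent per-cell jitter (kept small
        so the qualitative orderings hold for every observer).
    sd_ratio : estimate SDs are this fraction of the threshold.
    n_observers : number of synthetic participants.
    """

    plateau_thresholds: tuple = ((0.0, 0.5), (7.5, 0.75), (15.0, 1.0))
    knee: float = 25.0
    low_dot_inflation: float = 3.0
    observer_sd: float = 0.2
    cell_jitter_sd: float = 0.05
    sd_ratio: float = 0.6
    n_observers: int = 19

    def __post_init__(self):
        plat = dict(self.plateau_thresholds)
        noises = sorted(plat)
        if any(plat[a] >= plat[b] for a, b in zip(noises, noises[1:])):
            raise ValueError("plateau thresholds must increase with noise")
        if not 5 < self.knee < 50:
            raise ValueError("knee must lie between 5 and 50 dots")
        if self.low_dot_inflation <= 1:
            raise ValueError("low_dot_inflation must exceed 1")


def _sparseness(dots, knee: float) -> np.ndarray:
    """Smooth 1 -> 0 saturation: 1 at 5 dots, ~0 above the knee."""
    tau = (knee - 5.0) / 3.0
    return np.exp(-(np.asarray(dots, float) - 5.0) / tau)


def profile_threshold(dots, noise_sd, params: HumanProfileParams) -> np.ndarray:
    """Noise-free threshold surface (deg): plateau(noise) inflated at low
    dot counts, with noise sensitivity fading in sparse fields (matching
    the observation that noise barely matters at 5 dots per frame)."""
    plat = dict(params.plateau_thresholds)
    base = plat[min(plat)]
    s = _sparseness(dots, params.knee)
    plateau = np.vectorize(plat.__getitem__)(noise_sd)
    # in sparse fields the threshold is dominated by dot scarcity and the
    # noise effect is suppressed
    effective = base + (plateau - base) * (1.0 - 0.9 * s)
    return effective * (1.0 + (params.low_dot_inflation - 1.0) * s)


def check_human_profile(table: pd.DataFrame) -> None:
    """Validate the qualitative structure every fixture table must carry:
    per observer, thresholds rise with noise at >= 50 dots and fall from
    5 to 50 dots within every noise level."""
    for obs, df in table.groupby("observer"):
        wide = df.pivot(index="dots", columns="noise_sd",
                        values="threshold_deg")
        noises = sorted(wide.columns)
        dense = wide.loc[wide.index >= 50]
        for lo, hi in zip(noises, noises[1:]):
            if not (dense[hi] > dense[lo]).all():
                raise ValueError(f"observer {obs}: noise ordering violated")
        for nv in noises:
            if not (wide.loc[5, nv] > wide.loc[50, nv]):
                raise ValueError(f"observer {obs}: dots ordering violated")


def generate_human_thresholds(params: HumanProfileParams = HumanProfileParams(),
                              dots_levels=(5, 50, 100, 200),
                              rng=None) -> pd.DataFrame:
    """Per-observer synthetic threshold table.

    One row per (observer, dots, noise_sd) with ``threshold_deg``,
    ``sd_deg`` (proportional to the threshold) and a positive fit ``rmse``
    for downstream weighting.  The table is validated against the
    qualitative human profile before being returned.
    """
    rng = np.random.default_rng(rng)
    noise_levels = [n for n, _ in params.plateau_thresholds]
    rows = []
    for obs in range(params.n_observers):
        factor = float(np.exp(rng.normal(0.0, params.observer_sd)))
        for noise in noise_levels:
            for dots in dots_levels:
                base = float(profile_threshold(dots, noise, params))
                jitter = float(np.exp(rng.normal(0.0, params.cell_jitter_sd)))
                thr = base * factor * jitter
                rows.append({"observer": obs, "dots": dots, "noise_sd": noise,
                             "threshold_deg": thr,
                             "sd_deg": thr * params.sd_ratio
                             * float(np.exp(rng.normal(0.0, params.cell_jitter_sd))),
                             "rmse": float(rng.uniform(0.02, 0.10))})
    table = pd.DataFrame(rows)
    check_human_profile(table)
    return table


def generate_response_set(true_sigma: float, offsets, reps: int, rng=None,
                          convention: str = "plain", mu: float = 0.0
                          ) -> pd.DataFrame:
    """Binary 2AFC responses from a known psychometric observer.

    P(correct at offset x) follows the chosen cumulative-Gaussian
    convention; returns one row per offset with ``n_trials``/``n_correct``
    (the shape of one human design cell is 5 offsets x 16 reps).
    """
    if reps < 1:
        raise ValueError("need at least one repetition")
    rng = np.random.default_rng(rng)
    x = np.asarray(offsets, dtype=float)
    z = stats.norm.cdf((x - mu) / true_sigma) if true_sigma > 0 else (
        (x > mu).astype(float))
    p = 0.5 + 0.5 * z if convention == "floored" else z
    n_correct = rng.binomial(reps, p)
    return pd.DataFrame({"offset_deg": x, "n_trials": reps,
                         "n_correct": n_correct})


def matched_human_table(model_table: pd.DataFrame, gain: float = 2.0,
                        noise_frac: float = 0.02, rng=None) -> pd.DataFrame:
    """Human-like table constructed to be (nearly) collinear with a model
    table: human = gain * model plus small multiplicative noise.  Used by
    the end-to-end regression recovery check."""
    rng = np.random.default_rng(rng)
    out = model_table[["dots", "noise_sd"]].copy()
    for col in ("threshold_deg", "sd_deg"):
        if col in model_table:
            vals = gain * model_table[col].to_numpy(dtype=float)
            out[col] = vals * np.exp(rng.normal(0.0, noise_frac, len(vals)))
    return out
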