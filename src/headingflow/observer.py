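"""Simulated two-alternative forced-choice heading experiment.

A model observer sees, per trial, seven independent flow fields (a 2 s trial
divided by the ~270 ms of flow one heading estimate needs), each with a
freshly sampled dot cloud and fresh directional noise and with the dot count
augmented by 40% for visual persistence.  The seven horizontal estimates are
averaged and the observer answers "right" iff the mean falls right of the
target (fixed at the image center for model runs); a model that fails on
every field answers with a seeded coin flip, as a forced-choice observer
must.

Condition runs convert responses to %correct over FoE offsets; a full
psychometric run over all offsets yields one threshold replicate, and
replicates accumulate until their standard error drops below 0.2 deg.
Estimate variability is summarized as the SD of per-trial mean estimates
over 1000 trials at a fixed representative offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .core import DegenerateGeometryError, InsufficientDataError
from .psychometrics import fit_cumulative_gaussian
from .stimulus import SceneConfig, StimulusCondition, make_flow_field

logger = logging.getLogger(__name__)

PAPER_OFFSETS = (0.2, 0.5, 1.0, 2.0, 4.0)
PAPER_DOTS = (5, 50, 100, 200)
FOLLOWUP_DOTS = (5, 15, 25, 35, 50)
NOISE_LEVELS = (0.0, 7.5, 15.0)


@dataclass(frozen=True)
class TrialResult:
    mean_estimate: float    # deg, average horizontal estimate
    response: str           # "left" | "right"
    correct: bool
    n_valid_estimates: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of the human experiment (signed offsets/targets)."""

    dots_levels: tuple = PAPER_DOTS
    noise_levels: tuple = NOISE_LEVELS
    offsets: tuple = tuple(s * o for o in PAPER_OFFSETS for s in (+1, -1))
    target_locations: tuple = (-4.0, -2.0, 2.0, 4.0)
    sessions: int = 2

    def __post_init__(self):
        if not (self.dots_levels and self.noise_levels and self.offsets
                and self.target_locations):
            raise ValueError("design levels must be nonempty")


def enumerate_design(design: ExperimentDesign) -> tuple[int, int, int]:
    """(full factorial count, count after collapsing signed offsets and
    target locations, repetitions per collapsed cell over all sessions)."""
    full = (len(design.dots_levels) * len(design.noise_levels)
            * len(design.offsets) * len(design.target_locations))
    n_abs_offsets = len({abs(o) for o in design.offsets})
    collapsed = (len(design.dots_levels) * len(design.noise_levels)
                 * n_abs_offsets)
    reps = design.sessions * full // collapsed
    return full, collapsed, reps


def run_trial(model, condition: StimulusCondition, rng,
              config: SceneConfig = SceneConfig()) -> TrialResult:
    """One 2AFC trial: average the model's horizontal estimate over the
    trial's independent flow fields and answer left/right of the target."""
    rng = np.random.default_rng(rng)
    n_estimates = config.estimates_per_trial()
    estimates = []
    for _ in range(n_estimates):
        fld = make_flow_field(condition, config, rng)
        try:
            est = model(fld, rng=rng)
        except (DegenerateGeometryError, InsufficientDataError):
            continue
        estimates.append(est.x_deg)

    if estimates:
        mean_est = float(np.mean(estimates))
        if mean_est > condition.target_position:
            response = "right"
        elif mean_est < condition.target_position:
            response = "left"
        else:
            response = "right" if rng.random() < 0.5 else "left"
    else:  # model degenerate on every field: forced-choice coin flip
        mean_est = np.nan
        response = "right" if rng.random() < 0.5 else "left"
    correct = (response == "right") == (condition.foe_offset > condition.target_position)
    return TrialResult(mean_estimate=mean_est, response=response,
                       correct=correct, n_valid_estimates=len(estimates))


def run_condition(model, condition: StimulusCondition, n_trials: int, rng,
                  config: SceneConfig = SceneConfig()
                  ) -> tuple[float, np.ndarray]:
    """%correct over independent trials, plus the per-trial mean estimates
    (for SD summaries)."""
    if n_trials < 1:
        raise ValueError("need at least one trial")
    rng = np.random.default_rng(rng)
    results = [run_trial(model, condition, rng, config) for _ in range(n_trials)]
    pc = 100.0 * np.mean([r.correct for r in results])
    return float(pc), np.array([r.mean_estimate for r in results])


def run_psychometric(model, dots: int, noise_sd: float, rng,
                     offsets=PAPER_OFFSETS, trials_per_offset: int = 16,
                     config: SceneConfig = SceneConfig(),
                     convention: str = "plain"):
    """One full psychometric run: signed offsets balanced within each
    unsigned level, %correct per level, cumulative-Gaussian fit."""
    rng = np.random.default_rng(rng)
    pcs = []
    for off in offsets:
        half = trials_per_offset // 2
        signs = [+1] * (trials_per_offset - half) + [-1] * half
        correct = 0
        for s in signs:
            cond = StimulusCondition(dots_per_frame=dots, noise_sd=noise_sd,
                                     foe_offset=s * off)
            correct += run_trial(model, cond, rng, config).correct
        pcs.append(correct / trials_per_offset)
    return fit_cumulative_gaussian(np.asarray(offsets, float),
                                   np.asarray(pcs), convention)


def run_threshold_replicates(model, dots: int, noise_sd: float, rng,
                             offsets=PAPER_OFFSETS,
                             trials_per_offset: int = 16,
                             sem_stop: float = 0.2,
                             max_reps: int = 200,
                             min_reps: int = 3,
                             config: SceneConfig = SceneConfig(),
                             convention: str = "plain") -> np.ndarray:
    """Collect 75% threshold replicates until their SEM drops below
    ``sem_stop`` (or ``max_reps``); unfittable runs are recorded as NaN."""
    if sem_stop <= 0:
        raise ValueError("sem_stop must be positive")
    rng = np.random.default_rng(rng)
    thresholds: list[float] = []
    while True:
        fit = run_psychometric(model, dots, noise_sd, rng, offsets,
                               trials_per_offset, config, convention)
        if fit.ok and np.isfinite(fit.threshold75):
            thresholds.append(fit.threshold75)
        else:
            thresholds.append(np.nan)
            logger.warning("unfittable psychometric run at dots=%s noise=%s",
                           dots, noise_sd)
        good = np.array([t for t in thresholds if np.isfinite(t)])
        if len(thresholds) >= max_reps:
            break
        if len(good) >= min_reps:
            sem = good.std(ddof=1) / np.sqrt(len(good))
            if sem < sem_stop:
                break
    return np.asarray(thresholds)


def estimate_sd(model, dots: int, noise_sd: float, rng,
                offset: float = 1.0, n_trials: int = 1000,
                config: SceneConfig = SceneConfig()) -> float:
    """SD of per-trial mean heading estimates at a fixed representative
    offset (default +1 deg, mid-range of the design)."""
    if n_trials < 2:
        raise ValueError("need at least 2 trials for an SD")
    cond = StimulusCondition(dots_per_frame=dots, noise_sd=noise_sd,
                             foe_offset=offset)
    _, estimates = run_condition(model, cond, n_trials, rng, config)
    good = estimates[np.isfinite(estimates)]
    if len(good) < 2:
        return np.nan
    return float(np.std(good, ddof=1))


def run_experiment(model, model_name: str, rng,
                   dots_levels=PAPER_DOTS, noise_levels=NOISE_LEVELS,
                   offsets=PAPER_OFFSETS,
                   trials_per_offset: int = 16,
                   sem_stop: float = 0.2, max_reps: int = 200,
                   sd_trials: int = 1000,
                   config: SceneConfig = SceneConfig(),
                   convention: str = "plain") -> pd.DataFrame:
    """Full threshold/SD table for one model over the factorial design.

    Returns one row per (dots, noise) cell:
    ``model, dots, noise_sd, threshold_deg, threshold_sem, sd_deg,
    n_replicates``.
    """
    rng = np.random.default_rng(rng)
    rows = []
    for noise in noise_levels:
        for dots in dots_levels:
            reps = run_threshold_replicates(
                model, dots, noise, rng, offsets, trials_per_offset,
                sem_stop, max_reps, config=config, convention=convention)
            good = reps[np.isfinite(reps)]
            thr = float(good.mean()) if len(good) else np.nan
            sem = (float(good.std(ddof=1) / np.sqrt(len(good)))
                   if len(good) > 1 else np.nan)
            sd = estimate_sd(model, dots, noise, rng, n_trials=sd_trials,
                             config=config)
            rows.append({"model": model_name, "dots": dots, "noise_sd": noise,
                         "threshold_deg": thr, "threshold_sem": sem,
                         "sd_deg": sd, "n_replicates": len(reps)})
    return pd.DataFrame(rows)
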