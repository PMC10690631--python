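"""Synthetic interception trials with the structure the regression assumes.

The generator is the hierarchical twin of the analysis model: each subject
gets a correlated random intercept and random slope on a chosen arrival-time
predictor; each subject-by-condition latent mean adds condition-level noise;
each trial adds trial-level noise. The driving predictor is a mixture
(1 - w_optical) * gravity(t_e) + w_optical * optical, so a nonzero
``w_optical`` injects a genuine optical contribution for sensitivity tests.

Defaults mirror the fitted population values of the reference experiment
(fixed intercept -8.8 ms, slope 0.99, subject intercept SD 68.08 ms, slope
SD 0.02, intercept-slope correlation -0.5, engagement time 450 ms,
32 subjects x 12 conditions x 20 trials). The two noise levels are chosen
so per-condition trial SDs (~60 ms) and the residual of the regression on
the 384 condition means (~sqrt(20² + 60²/20) ≈ 24 ms) are both plausible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .predictors import build_predictor_table, engagement_column
from .scene_kinematics import MotionCondition, SceneGeometry, build_condition_table

__all__ = [
    "GenerativeParams",
    "make_schedule",
    "simulate_trials",
    "latent_condition_means",
    "compute_te",
    "filter_outliers",
    "aggregate",
    "write_trials_csv",
    "read_trials_csv",
    "write_summary_csv",
    "read_summary_csv",
]

TRIAL_COLUMNS = ["subject_id", "label", "duration_s", "trial_index", "rt_ms", "te_ms", "excluded"]


@dataclass(frozen=True)
class GenerativeParams:
    """Population parameters of the generative response model.

    All time quantities in ms; slopes are dimensionless (ms per ms of
    predicted arrival).
    """

    beta0: float = -8.8
    beta_grav: float = 0.99
    sd_intercept: float = 68.08
    sd_slope: float = 0.02
    cor_int_slope: float = -0.5
    sigma_cond: float = 20.0
    sigma_trial: float = 60.0
    w_optical: float = 0.0
    engagement_ms: int = 450
    n_subjects: int = 32
    n_reps: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_intercept, self.sd_slope, self.sigma_cond, self.sigma_trial) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 <= self.cor_int_slope <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")
        if not 0.0 <= self.w_optical <= 1.0:
            raise ValueError("w_optical must lie in [0, 1]")
        if self.n_subjects < 1 or self.n_reps < 1:
            raise ValueError("need at least one subject and one repetition")

    @property
    def random_effect_cov(self) -> np.ndarray:
        cov = np.array(
            [
                [self.sd_intercept**2, self.cor_int_slope * self.sd_intercept * self.sd_slope],
                [self.cor_int_slope * self.sd_intercept * self.sd_slope, self.sd_slope**2],
            ]
        )
        if np.any(np.linalg.eigvalsh(cov) < -1e-12):
            raise ValueError("random-effect covariance is not positive semi-definite")
        return cov

    def replace(self, **kwargs) -> "GenerativeParams":
        return replace(self, **kwargs)


def make_schedule(
    n_reps: int,
    conditions: Sequence[MotionCondition],
    seed: int | np.random.Generator = 0,
) -> list[MotionCondition]:
    """Pseudorandom trial order: a seeded uniform permutation of
    ``n_reps`` copies of each condition."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = [c for c in conditions for _ in range(n_reps)]
    order = rng.permutation(len(pool))
    return [pool[i] for i in order]


def latent_condition_means(
    params: GenerativeParams,
    predictors: pd.DataFrame,
) -> pd.Series:
    """Predictor value P_j driving each condition's latent mean (ms)."""
    col = engagement_column(params.engagement_ms)
    if col not in predictors.columns:
        raise ValueError(f"engagement time {params.engagement_ms} ms not on the predictor grid")
    gravity = predictors[col]
    if params.w_optical > 0 and "optical" not in predictors.columns:
        raise ValueError("predictor table lacks an optical column")
    optical = predictors["optical"] if "optical" in predictors.columns else 0.0
    return (1.0 - params.w_optical) * gravity + params.w_optical * optical


def simulate_trials(
    params: GenerativeParams | None = None,
    predictors: pd.DataFrame | None = None,
    conditions: Sequence[MotionCondition] | None = None,
    geometry: SceneGeometry | None = None,
) -> pd.DataFrame:
    """Simulate button-press response times for all subjects.

    Per subject i: (b0_i, b1_i) ~ N(0, Sigma). Per condition j the latent
    mean is beta0 + b0_i + (beta_grav + b1_i) * P_j + eps_ij with
    eps_ij ~ N(0, sigma_cond). Each of the n_reps trials adds
    N(0, sigma_trial). Trials are laid out in each subject's pseudorandom
    schedule. Deterministic given ``params.seed``.
    """
    params = params or GenerativeParams()
    geometry = geometry or SceneGeometry()
    conditions = conditions if conditions is not None else build_condition_table(geometry)
    if predictors is None:
        predictors = build_predictor_table(geometry, conditions=conditions)
    p_j = latent_condition_means(params, predictors)
    rng = np.random.default_rng(params.seed)
    cov = params.random_effect_cov

    rows = []
    for subj in range(params.n_subjects):
        # eigh path tolerates the singular covariance of noise-free settings
        b0, b1 = rng.multivariate_normal([0.0, 0.0], cov, method="eigh")
        cond_mean = {
            c.key: params.beta0 + b0 + (params.beta_grav + b1) * p_j.loc[c.key]
            + rng.normal(0.0, params.sigma_cond)
            for c in conditions
        }
        schedule = make_schedule(params.n_reps, conditions, rng)
        counters: dict[tuple, int] = {}
        for cond in schedule:
            k = counters.get(cond.key, 0)
            counters[cond.key] = k + 1
            rt = cond_mean[cond.key] + rng.normal(0.0, params.sigma_trial)
            rows.append(
                {
                    "subject_id": subj,
                    "label": cond.label,
                    "duration_s": cond.duration,
                    "trial_index": k,
                    "rt_ms": rt,
                }
            )
    trials = pd.DataFrame(rows)
    trials["te_ms"] = np.nan
    trials["excluded"] = False
    return compute_te(trials, conditions)


def compute_te(trials: pd.DataFrame, conditions: Sequence[MotionCondition]) -> pd.DataFrame:
    """Timing error: response time minus true arrival time (ms).

    Negative values are anticipated responses, positive delayed.
    """
    arrival = {c.key: 1000.0 * c.duration for c in conditions}
    keys = list(zip(trials["label"], trials["duration_s"]))
    unknown = {k for k in keys if k not in arrival}
    if unknown:
        raise KeyError(f"unknown condition keys: {sorted(unknown)}")
    out = trials.copy()
    out["te_ms"] = out["rt_ms"].to_numpy() - np.array([arrival[k] for k in keys])
    return out


def filter_outliers(trials: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Flag trials whose TE deviates more than ``k`` SDs from its cell mean.

    A cell is one subject x condition; mean and SD (n-1 denominator) are
    computed from the unfiltered cell in a single pass. Cells with a zero
    SD keep all trials.
    """
    out = trials.copy()
    excluded = np.zeros(len(out), dtype=bool)
    for _, idx in out.groupby(["subject_id", "label", "duration_s"]).groups.items():
        te = out.loc[idx, "te_ms"].to_numpy()
        if len(te) < 2:
            raise ValueError("outlier filter needs at least 2 trials per cell")
        m, sd = te.mean(), te.std(ddof=1)
        if sd > 0:
            excluded[out.index.get_indexer(idx)] = np.abs(te - m) > k * sd
    out["excluded"] = excluded
    return out


def aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition summaries over non-excluded trials.

    Returns one row per cell with mean_rt, mean_te, std_te (ms) and the
    kept-trial count; raises if filtering emptied a cell.
    """
    kept = trials[~trials["excluded"]]
    n_cells = trials.groupby(["subject_id", "label", "duration_s"]).ngroups
    grouped = kept.groupby(["subject_id", "label", "duration_s"])
    if grouped.ngroups != n_cells:
        raise ValueError("a subject x condition cell is empty after filtering")
    summary = grouped.agg(
        mean_rt=("rt_ms", "mean"),
        mean_te=("te_ms", "mean"),
        std_te=("te_ms", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        n_kept=("rt_ms", "size"),
    ).reset_index()
    return summary


# ---------------------------------------------------------------------------
# CSV round-trip (also the dialect for externally supplied real data)

def write_trials_csv(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    df["excluded"] = df["excluded"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False, float_format="%.17g")


def read_summary_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
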