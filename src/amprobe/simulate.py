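"""Synthetic participants and per-trial binary responses.

The generator mirrors the structure the downstream analysis assumes: each
participant judges trials with probability linear in the manipulated AM
parameter (a linear, not logistic, psychometric rule — the model the
behavioural data favour), with participant-level slope heterogeneity, a
lapse mixture, a musical-sophistication covariate correlated with slope,
and non-compliant archetypes (constant responders, probe failures, extreme
response bias) that exist to exercise the exclusion filters.

Sophistication scores emulate the Goldsmiths Musical Sophistication Index
General subscale: range 18–126, population norm mean 81.58, SD 20.62.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import ConditionGrid, TrialSchedule, build_schedule

__all__ = [
    "ParticipantProfile",
    "PopulationSpec",
    "sample_population",
    "response_probability",
    "simulate_responses",
    "simulate_experiment",
    "batch_slope_experiments",
    "MSI_RANGE",
    "MSI_NORM_MEAN",
    "MSI_NORM_SD",
]

#: Bounds of the sophistication score.
MSI_RANGE = (18.0, 126.0)
#: Published norms of the General subscale.
MSI_NORM_MEAN = 81.58
MSI_NORM_SD = 20.62


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters of one simulated participant.

    ``beta`` is the true response slope per unit of the manipulated
    parameter (per Hz, or per sigma unit); ``alpha`` the response
    probability at the reference level; ``lapse`` the probability of a
    uniform random response.  Compliance flags mark archetypes that the
    exclusion filters must catch.
    """

    participant_id: str
    beta: float
    alpha: float = 0.5
    lapse: float = 0.02
    msi: float = MSI_NORM_MEAN
    all_same_responder: bool = False
    probe_failure_rate: float = 0.0
    bias_target: float | None = None  # fixed response-1 rate, ignoring stimuli
    headphone_pass: bool = True
    completed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse < 0.5):
            raise ValueError("lapse must be in [0, 0.5)")
        if not (MSI_RANGE[0] <= self.msi <= MSI_RANGE[1]):
            raise ValueError(f"msi must lie in {MSI_RANGE}")


@dataclass(frozen=True)
class PopulationSpec:
    """Distributional description of a simulated participant population."""

    n: int
    beta_mean: float = 0.05
    beta_sd: float = 0.07
    msi_mean: float = MSI_NORM_MEAN
    msi_sd: float = MSI_NORM_SD
    rho: float = 0.2  # correlation between beta and msi
    alpha_mean: float = 0.5
    # bias heterogeneity chosen so ~20% of responders sit outside the
    # 50 +/- 15% window, matching the prevalence the bias filter removes
    alpha_sd: float = 0.12
    lapse_low: float = 0.0
    lapse_high: float = 0.1
    frac_all_same: float = 0.0
    frac_probe_fail: float = 0.0
    frac_biased: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if min(self.beta_sd, self.msi_sd, self.alpha_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if self.frac_all_same + self.frac_probe_fail + self.frac_biased > 1:
            raise ValueError("archetype fractions must sum to <= 1")


def _child_rng(master_seed: int | None, participant_index: int) -> np.random.Generator:
    """One independent stream per participant, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=(participant_index,)))


def sample_population(spec: PopulationSpec, seed: int | None = None) -> list[ParticipantProfile]:
    """Draw a participant population.

    (beta, msi) come from a bivariate normal with correlation ``rho``; msi
    is truncated to [18, 126] by resampling (no boundary atoms).  Archetype
    flags are assigned to disjoint random subsets at the stated fractions.
    """
    rng = np.random.default_rng(seed)
    if spec.msi_sd > 0:
        cov = np.array(
            [
                [spec.beta_sd**2, spec.rho * spec.beta_sd * spec.msi_sd],
                [spec.rho * spec.beta_sd * spec.msi_sd, spec.msi_sd**2],
            ]
        )
        mean = np.array([spec.beta_mean, spec.msi_mean])
        draws = np.empty((0, 2))
        while len(draws) < spec.n:
            cand = rng.multivariate_normal(mean, cov, size=2 * spec.n, method="cholesky")
            ok = (cand[:, 1] >= MSI_RANGE[0]) & (cand[:, 1] <= MSI_RANGE[1])
            draws = np.vstack([draws, cand[ok]])
        beta, msi = draws[: spec.n, 0], draws[: spec.n, 1]
    else:
        beta = rng.normal(spec.beta_mean, spec.beta_sd, size=spec.n)
        msi = np.full(spec.n, spec.msi_mean)

    alpha = rng.normal(spec.alpha_mean, spec.alpha_sd, size=spec.n)
    alpha = np.clip(alpha, 0.05, 0.95)
    lapse = rng.uniform(spec.lapse_low, spec.lapse_high, size=spec.n)

    idx = rng.permutation(spec.n)
    n_same = int(round(spec.frac_all_same * spec.n))
    n_probe = int(round(spec.frac_probe_fail * spec.n))
    n_bias = int(round(spec.frac_biased * spec.n))
    same_ids = set(idx[:n_same])
    probe_ids = set(idx[n_same : n_same + n_probe])
    bias_ids = set(idx[n_same + n_probe : n_same + n_probe + n_bias])

    profiles = []
    for i in range(spec.n):
        profiles.append(
            ParticipantProfile(
                participant_id=f"p{i:04d}",
                beta=float(beta[i]),
                alpha=float(alpha[i]),
                lapse=float(lapse[i]),
                msi=float(msi[i]),
                all_same_responder=i in same_ids,
                probe_failure_rate=0.5 if i in probe_ids else 0.0,
                bias_target=(0.9 if i in bias_ids else None),
            )
        )
    return profiles


def response_probability(profile: ParticipantProfile, x: float | np.ndarray, x_ref: float) -> np.ndarray:
    """Probability of responding 1 at manipulated-parameter value ``x``.

    ``p = clip(alpha + beta (x - x_ref), 0, 1)`` mixed with a lapse:
    ``p <- lapse/2 + (1 - lapse) p``.
    """
    p = np.clip(profile.alpha + profile.beta * (np.asarray(x, dtype=float) - x_ref), 0.0, 1.0)
    return profile.lapse / 2.0 + (1.0 - profile.lapse) * p


def simulate_responses(
    profile: ParticipantProfile,
    schedule: TrialSchedule,
    seed: int | None = None,
    x_ref: float | None = None,
    manipulated: str = "m",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one participant's responses to a schedule.

    Testing trials are Bernoulli draws from :func:`response_probability`;
    probe trials are correct with probability ``1 - probe_failure_rate``;
    constant responders emit all-ones; biased responders emit 1 at their
    fixed target rate regardless of the stimulus.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trials = schedule.trials
    col = "m_hz" if manipulated == "m" else "sigma"
    x = trials[col].to_numpy(dtype=float)
    if x_ref is None:
        x_ref = float(np.nanmean(np.unique(x[trials["kind"] == "testing"])))

    rows = []
    for i, (_, tr) in enumerate(trials.iterrows()):
        if tr["kind"] == "probe":
            correct = bool(rng.random() >= profile.probe_failure_rate)
            rows.append(
                (tr["trial_index"], "probe", tr["task"], tr["block"], np.nan, np.nan, np.nan, np.nan, correct)
            )
            continue
        if profile.all_same_responder:
            resp = 1
        elif profile.bias_target is not None:
            resp = int(rng.random() < profile.bias_target)
        else:
            p = float(response_probability(profile, x[i], x_ref))
            resp = int(rng.random() < p)
        rows.append(
            (tr["trial_index"], tr["kind"], tr["task"], tr["block"], tr["m_hz"], tr["sigma"], x[i], resp, np.nan)
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "trial_index", "kind", "task", "block", "m_hz", "sigma", "x_value", "response", "probe_correct",
        ],
    )
    out.insert(0, "participant_id", profile.participant_id)
    return out


def simulate_experiment(
    grid: ConditionGrid,
    spec: PopulationSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole experiment: population, schedules, responses.

    Returns ``(responses, participants)``; ``participants`` carries the
    covariates and compliance flags the exclusion filters need.
    """
    profiles = sample_population(spec, seed=np.random.SeedSequence(entropy=seed, spawn_key=(0,)).generate_state(1)[0] % 2**31)
    x_ref = float(np.mean(grid.levels))
    tables = []
    for i, profile in enumerate(profiles):
        rng = _child_rng(seed, i + 1)
        schedule = build_schedule(
            grid, seed=int(rng.integers(2**31)), participant_id=profile.participant_id, include_practice=False
        )
        tables.append(
            simulate_responses(profile, schedule, x_ref=x_ref, manipulated=grid.manipulated, rng=rng)
        )
    responses = pd.concat(tables, ignore_index=True)
    participants = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "msi_general": [p.msi for p in profiles],
            "true_beta": [p.beta for p in profiles],
            "completed": [p.completed for p in profiles],
            "headphone_pass": [p.headphone_pass for p in profiles],
        }
    )
    return responses, participants


def batch_slope_experiments(
    n_experiments: int,
    n_participants: int,
    x_trials: np.ndarray,
    spec: PopulationSpec,
    seed: int | None = None,
    x_ref: float | None = None,
) -> np.ndarray:
    """Vectorized repeated experiments for calibration studies.

    Each simulated experiment draws ``n_participants`` (beta, alpha, lapse)
    from ``spec``, simulates Bernoulli responses over the fixed trial-level
    design ``x_trials`` with the same lapse-mixture rule as
    :func:`simulate_responses`, and fits the per-participant OLS slope in
    closed form.  Returns an ``(n_experiments, n_participants)`` slope
    array.  Used for null-calibration and power checks, where per-trial
    bookkeeping would dominate the run time.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x_trials, dtype=float)
    if x_ref is None:
        x_ref = float(np.mean(np.unique(x)))
    dx = x - x.mean()
    sxx = float(np.dot(dx, dx))
    total = n_experiments * n_participants
    beta = rng.normal(spec.beta_mean, spec.beta_sd, size=(total, 1))
    alpha = np.clip(rng.normal(spec.alpha_mean, spec.alpha_sd, size=(total, 1)), 0.05, 0.95)
    lapse = rng.uniform(spec.lapse_low, spec.lapse_high, size=(total, 1))
    p = np.clip(alpha + beta * (x[None, :] - x_ref), 0.0, 1.0)
    p = lapse / 2.0 + (1.0 - lapse) * p
    y = rng.random(size=(total, len(x))) < p
    slopes = (y @ dx) / sxx
    return slopes.reshape(n_experiments, n_participants)
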