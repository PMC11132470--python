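"""Condition grids, stimulus pools, and per-participant trial schedules.

Four experiments share one machinery:

* Experiment 1 — peak AM frequency varied over 10 log-spaced levels on
  [0.6, 6] Hz, regularity fixed at sigma = 0.35; 15 draws per condition
  from pools of 100; a music-vs-speech judgment task.
* Experiment 2 — regularity varied over 5 levels at each of 3 peak
  frequencies (1, 2.5, 4 Hz); 10 draws per condition from pools of 50.
* Experiment 3 — like Experiment 1 but 5 peak levels, pools of 50, and
  separate music- and speech-detection blocks.
* Experiment 4 — regularity varied at a fixed 2-Hz peak, detection blocks.

Experiments 1–2 present each of 150 unique stimuli once per half (300
testing trials); Experiments 3–4 present the same 75 stimuli in each of 4
blocks (music/speech within each half, 150 trials per task).  Twelve probe
trials (count 1–4 brief tones) are spread roughly evenly, and a self-paced
break falls every 10 trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionGrid",
    "TrialSchedule",
    "condition_grid",
    "build_schedule",
    "make_probe_trial",
    "practice_conditions",
    "N_PROBE_TRIALS",
    "BREAK_EVERY",
    "SIGMA_DEFAULT",
]

#: Probe trials per participant.
N_PROBE_TRIALS = 12
#: Self-paced break interval, in trials.
BREAK_EVERY = 10
#: Regularity used whenever sigma is not the manipulated parameter.
SIGMA_DEFAULT = 0.35
#: Extreme peak-frequency levels, Hz (grids are log-spaced between them).
PEAK_RANGE = (0.6, 6.0)
#: Extreme regularity levels for the sigma-manipulating experiments.
SIGMA_RANGE = (0.10, 1.00)

#: Probe tone length, s, and response window, s.
PROBE_TONE_DURATION = 0.1
PROBE_WINDOW = 2.0


@dataclass(frozen=True)
class ConditionGrid:
    """The condition set of one experiment.

    ``conditions`` lists (m, sigma) pairs; ``manipulated`` names which of
    the two is the independent variable ("m" or "sigma"); ``tasks`` is
    ("judgment",) for the two-alternative experiments and
    ("music", "speech") for the detection experiments.
    """

    experiment_id: int
    conditions: tuple[tuple[float, float], ...]
    pool_size: int
    draws: int
    manipulated: str
    tasks: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3, 4):
            raise ValueError("experiment_id must be 1-4")
        if self.manipulated not in ("m", "sigma"):
            raise ValueError("manipulated must be 'm' or 'sigma'")
        if self.draws > self.pool_size:
            raise ValueError("cannot draw more unique stimuli than the pool holds")

    @property
    def n_unique(self) -> int:
        """Unique stimuli drawn per participant."""
        return len(self.conditions) * self.draws

    @property
    def levels(self) -> np.ndarray:
        """Distinct values of the manipulated parameter, ascending."""
        idx = 0 if self.manipulated == "m" else 1
        return np.unique([c[idx] for c in self.conditions])


@dataclass(frozen=True)
class TrialSchedule:
    """Ordered trials for one participant, plus break positions."""

    participant_id: str
    experiment_id: int
    trials: pd.DataFrame = field(repr=False)
    break_positions: tuple[int, ...]
    seed: int | None = None

    @property
    def testing(self) -> pd.DataFrame:
        return self.trials[self.trials["kind"] == "testing"]

    @property
    def probes(self) -> pd.DataFrame:
        return self.trials[self.trials["kind"] == "probe"]


def condition_grid(experiment_id: int, **overrides) -> ConditionGrid:
    """Default condition grid for an experiment, with keyword overrides.

    Overridable: ``peak_levels``, ``sigma_levels``, ``pool_size``,
    ``draws``.  Only the printed extremes and Experiment 2's three peak
    frequencies are fixed by the study; interior levels are log-spaced.
    """
    if experiment_id == 1:
        peaks = overrides.pop("peak_levels", np.geomspace(*PEAK_RANGE, 10))
        sigmas = overrides.pop("sigma_levels", [SIGMA_DEFAULT])
        pool, draws, manipulated, tasks = 100, 15, "m", ("judgment",)
    elif experiment_id == 2:
        peaks = overrides.pop("peak_levels", [1.0, 2.5, 4.0])
        sigmas = overrides.pop("sigma_levels", np.geomspace(*SIGMA_RANGE, 5))
        pool, draws, manipulated, tasks = 50, 10, "sigma", ("judgment",)
    elif experiment_id == 3:
        peaks = overrides.pop("peak_levels", np.geomspace(*PEAK_RANGE, 5))
        sigmas = overrides.pop("sigma_levels", [SIGMA_DEFAULT])
        pool, draws, manipulated, tasks = 50, 15, "m", ("music", "speech")
    elif experiment_id == 4:
        peaks = overrides.pop("peak_levels", [2.0])
        sigmas = overrides.pop("sigma_levels", np.geomspace(*SIGMA_RANGE, 5))
        pool, draws, manipulated, tasks = 50, 15, "sigma", ("music", "speech")
    else:
        raise ValueError(f"experiment_id must be 1-4, got {experiment_id}")
    pool = overrides.pop("pool_size", pool)
    draws = overrides.pop("draws", draws)
    if overrides:
        raise TypeError(f"unknown overrides: {sorted(overrides)}")
    conditions = tuple((float(m), float(s)) for m in np.asarray(peaks) for s in np.asarray(sigmas))
    return ConditionGrid(experiment_id, conditions, pool, draws, manipulated, tasks)


def _condition_label(m: float, sigma: float) -> str:
    return f"m{m:g}_s{sigma:g}"


def _draw_stimuli(
    grid: ConditionGrid,
    rng: np.random.Generator,
    pool_manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw ``grid.draws`` pool members per condition, without replacement.

    With a manifest (columns stimulus_id, m_hz, sigma), draws real pool
    entries and checks each condition's pool is large enough; otherwise
    synthesizes deterministic virtual ids over ``grid.pool_size``.
    """
    rows = []
    for ci, (m, sigma) in enumerate(grid.conditions):
        if pool_manifest is not None:
            members = pool_manifest[
                np.isclose(pool_manifest["m_hz"], m) & np.isclose(pool_manifest["sigma"], sigma)
            ]
            if len(members) < grid.pool_size:
                raise ValueError(
                    f"pool for condition (m={m:g}, sigma={sigma:g}) has only "
                    f"{len(members)} stimuli; {grid.pool_size} required"
                )
            ids = members["stimulus_id"].to_numpy()
            picks = ids[rng.choice(len(ids), size=grid.draws, replace=False)]
        else:
            picks = [
                f"e{grid.experiment_id}_c{ci:02d}_p{k:03d}"
                for k in rng.choice(grid.pool_size, size=grid.draws, replace=False)
            ]
        for sid in picks:
            rows.append(
                {
                    "stimulus_id": sid,
                    "m_hz": m,
                    "sigma": sigma,
                    "condition_label": _condition_label(m, sigma),
                }
            )
    return pd.DataFrame(rows)


def make_probe_trial(seed: int | None = None, rng: np.random.Generator | None = None) -> dict:
    """Spec for one probe trial: 1–4 brief tones in a 2-s window.

    Onsets are uniform in the window subject to non-overlap (drawn via the
    uniform-spacing construction); the correct answer is the tone count.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_tones = int(rng.integers(1, 5))
    # place n non-overlapping tones: draw starts in the slack left after
    # removing the tone durations, then re-inflate
    slack = PROBE_WINDOW - n_tones * PROBE_TONE_DURATION
    gaps = np.sort(rng.uniform(0.0, slack, size=n_tones))
    onsets = gaps + PROBE_TONE_DURATION * np.arange(n_tones)
    return {
        "n_tones": n_tones,
        "onsets": onsets,
        "tone_duration": PROBE_TONE_DURATION,
        "window": PROBE_WINDOW,
        "correct_answer": n_tones,
    }


def practice_conditions(grid: ConditionGrid, n: int = 4) -> list[tuple[float, float]]:
    """Practice parameters at geometric midpoints between adjacent testing
    levels — within the tested range but never equal to a tested value."""
    levels = grid.levels
    if len(levels) < 2:
        # nothing to interpolate on the manipulated axis; nudge off-grid
        mids = [float(levels[0] * f) for f in (0.85, 0.95, 1.05, 1.18)]
    else:
        mids = list(np.sqrt(levels[:-1] * levels[1:]))
    mids = (mids * ((n + len(mids) - 1) // len(mids)))[:n]
    other_m = float(np.median([c[0] for c in grid.conditions]))
    other_s = float(np.median([c[1] for c in grid.conditions]))
    if grid.manipulated == "m":
        return [(v, other_s) for v in mids]
    return [(other_m, v) for v in mids]


def _interleave_probes(testing: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Mix 12 probe trials into the testing sequence, stratified so that one
    probe falls at a random position within each consecutive stratum."""
    n = len(testing)
    stratum = n // N_PROBE_TRIALS
    probe_rows = []
    for j in range(N_PROBE_TRIALS):
        spec = make_probe_trial(rng=rng)
        pos = int(rng.integers(j * stratum, (j + 1) * stratum))  # after this many testing trials
        probe_rows.append((pos, spec))
    out = []
    probe_iter = iter(sorted(probe_rows, key=lambda t: t[0]))
    next_probe = next(probe_iter, None)
    for i, (_, row) in enumerate(testing.iterrows()):
        while next_probe is not None and next_probe[0] == i:
            out.append(_probe_row(next_probe[1]))
            next_probe = next(probe_iter, None)
        out.append(row.to_dict())
    while next_probe is not None:
        out.append(_probe_row(next_probe[1]))
        next_probe = next(probe_iter, None)
    return pd.DataFrame(out)


def _probe_row(spec: dict) -> dict:
    return {
        "kind": "probe",
        "task": "probe",
        "block": 0,
        "half": 0,
        "stimulus_id": "",
        "m_hz": np.nan,
        "sigma": np.nan,
        "condition_label": "probe",
        "correct_probe_answer": spec["correct_answer"],
    }


def build_schedule(
    grid: ConditionGrid,
    seed: int | None = None,
    participant_id: str = "p000",
    include_practice: bool = True,
    pool_manifest: pd.DataFrame | None = None,
) -> TrialSchedule:
    """Build the full trial schedule for one participant.

    Deterministic given ``seed``.  Counts (trials per half/block/task,
    probes, breaks) are seed-invariant; draws and orderings are not.
    ``pool_manifest`` (columns stimulus_id, m_hz, sigma) draws from a real
    stimulus pool instead of virtual ids.
    """
    rng = np.random.default_rng(seed)
    drawn = _draw_stimuli(grid, rng, pool_manifest)

    halves = []
    if grid.tasks == ("judgment",):
        for half in (1, 2):
            order = drawn.iloc[rng.permutation(len(drawn))].copy()
            order["half"] = half
            order["block"] = half
            order["task"] = "judgment"
            halves.append(order)
    else:
        block_no = 0
        for half in (1, 2):
            tasks = list(grid.tasks)
            rng.shuffle(tasks)
            for task in tasks:
                block_no += 1
                order = drawn.iloc[rng.permutation(len(drawn))].copy()
                order["half"] = half
                order["block"] = block_no
                order["task"] = task
                halves.append(order)
    testing = pd.concat(halves, ignore_index=True)
    testing["kind"] = "testing"
    testing["correct_probe_answer"] = np.nan

    trials = _interleave_probes(testing, rng)

    if include_practice:
        practice = pd.DataFrame(
            {
                "kind": "practice",
                "task": grid.tasks[0],
                "block": 0,
                "half": 0,
                "stimulus_id": [f"practice_{i}" for i in range(len(practice_conditions(grid)))],
                "m_hz": [c[0] for c in practice_conditions(grid)],
                "sigma": [c[1] for c in practice_conditions(grid)],
                "condition_label": "practice",
                "correct_probe_answer": np.nan,
            }
        )
        trials = pd.concat([practice, trials], ignore_index=True)

    trials.insert(0, "trial_index", np.arange(len(trials)))
    trials.insert(0, "participant_id", participant_id)
    n_main = int((trials["kind"] != "practice").sum())
    breaks = tuple(range(BREAK_EVERY, n_main, BREAK_EVERY))
    return TrialSchedule(
        participant_id=participant_id,
        experiment_id=grid.experiment_id,
        trials=trials,
        break_positions=breaks,
        seed=seed,
    )
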