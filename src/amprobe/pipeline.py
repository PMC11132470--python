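"""File formats, run configuration, and the end-to-end pipeline.

A run is fully determined by a :class:`RunConfig` (experiment, master
seed, sizes): stimuli manifests, schedules, simulated responses and the
statistics report are byte-reproducible from it.  Audio is synthesized on
demand — each manifest row carries the per-stimulus seed, so waveforms can
be re-rendered exactly without storing them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import __version__
from .analysis import analyze_experiment
from .design import build_schedule, condition_grid
from .simulate import PopulationSpec, simulate_experiment
from .synthesis import AMParams, Stimulus, equalize_rms, synthesize_stimulus, DEFAULT_TARGET_RMS

__all__ = [
    "RunConfig",
    "run_pipeline",
    "write_wav",
    "stimulus_manifest",
    "render_stimulus",
    "read_s1_data",
    "logger",
]

logger = logging.getLogger("amprobe")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("amprobe %(levelname)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    experiment_id: int
    seed: int
    n_participants: int = 20
    audio_rate: int = 44_100
    outdir: str = "amprobe_out"
    write_audio: bool = False
    n_per_condition: int | None = None  # pool-size override
    design_overrides: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    quiet: bool = False

    def __post_init__(self) -> None:
        if self.experiment_id not in (1, 2, 3, 4):
            raise ValueError("experiment_id must be 1-4")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Audio + manifest output
# ---------------------------------------------------------------------------


def write_wav(path: str | Path, waveform: np.ndarray, rate: int, float32: bool = False) -> None:
    """Write mono or stereo RIFF WAV, 16-bit PCM by default (no dither)."""
    waveform = np.asarray(waveform)
    if float32:
        wavfile.write(path, rate, waveform.astype(np.float32))
    else:
        clipped = np.clip(waveform, -1.0, 1.0)
        wavfile.write(path, rate, np.round(clipped * 32767.0).astype(np.int16))


def _stimulus_seed(master_seed: int, condition_index: int, pool_index: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(condition_index, pool_index))
    return int(ss.generate_state(1)[0] % 2**31)


def stimulus_manifest(
    experiment_id: int,
    seed: int,
    n_per_condition: int | None = None,
    **design_overrides,
) -> pd.DataFrame:
    """Manifest of the full stimulus pool: ids, parameters, per-stimulus seeds.

    Pool sizes default to the per-experiment values (100 for Experiment 1,
    50 for Experiments 2–4).  The waveforms themselves are rendered lazily
    by :func:`render_stimulus`.
    """
    grid = condition_grid(experiment_id, **design_overrides)
    pool = n_per_condition or grid.pool_size
    rows = []
    for ci, (m, sigma) in enumerate(grid.conditions):
        for k in range(pool):
            rows.append(
                {
                    "stimulus_id": f"e{experiment_id}_c{ci:02d}_p{k:03d}",
                    "experiment": experiment_id,
                    "condition": f"m{m:g}_s{sigma:g}",
                    "m_hz": m,
                    "sigma": sigma,
                    "seed": _stimulus_seed(seed, ci, k),
                    "rms": DEFAULT_TARGET_RMS,
                    "file": "",
                }
            )
    return pd.DataFrame(rows)


def render_stimulus(row: pd.Series, rate: int = 44_100) -> Stimulus:
    """Re-render one manifest row to audio, equalized to the manifest RMS."""
    stim = synthesize_stimulus(AMParams(row["m_hz"], row["sigma"]), seed=int(row["seed"]), rate=rate)
    return equalize_rms([stim], target_rms=float(row["rms"]))[0]


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Synthesize -> schedule -> simulate -> analyze; write all artifacts.

    Writes ``stimuli.csv`` (pool manifest), ``schedule_<pid>.csv`` per
    participant, ``responses.csv``, ``participants.csv``,
    ``report.json`` and a ``run_manifest.json`` sidecar carrying the seed
    and package version.  Idempotent for a fixed config.
    """
    if config.quiet:
        logger.setLevel(logging.WARNING)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("synthesize (manifest)")
        manifest = stimulus_manifest(
            config.experiment_id, config.seed, config.n_per_condition, **config.design_overrides
        )
        if config.write_audio:
            wav_dir = outdir / "stimuli"
            wav_dir.mkdir(exist_ok=True)
            for i, row in manifest.iterrows():
                stim = render_stimulus(row, rate=config.audio_rate)
                fname = f"{row['stimulus_id']}.wav"
                write_wav(wav_dir / fname, stim.waveform, stim.rate)
                manifest.loc[i, "file"] = f"stimuli/{fname}"
        manifest.to_csv(outdir / "stimuli.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"[synthesize] {err}") from err

    try:
        _stage("schedule")
        grid = condition_grid(config.experiment_id, **config.design_overrides)
        for i in range(config.n_participants):
            sched = build_schedule(
                grid,
                seed=_stimulus_seed(config.seed, 10_000, i),
                participant_id=f"p{i:04d}",
            )
            sched.trials.to_csv(outdir / f"schedule_p{i:04d}.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"[schedule] {err}") from err

    try:
        _stage("simulate")
        spec = PopulationSpec(n=config.n_participants, **config.population)
        responses, participants = simulate_experiment(grid, spec, seed=config.seed)
        responses.to_csv(outdir / "responses.csv", index=False)
        participants.to_csv(outdir / "participants.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"[simulate] {err}") from err

    try:
        _stage("analyze")
        # the sigma-by-peak design estimates slopes separately per peak frequency
        report = analyze_experiment(
            responses,
            participants,
            config.experiment_id,
            group_by="m_hz" if config.experiment_id == 2 else None,
        )
        report_dict = report.to_dict()
        with open(outdir / "report.json", "w") as fh:
            json.dump(report_dict, fh, indent=2, sort_keys=True, allow_nan=True)
    except Exception as err:
        raise RuntimeError(f"[analyze] {err}") from err

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "package": "amprobe",
                "version": __version__,
                "seed": config.seed,
                "config": dataclasses.asdict(config),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    logger.info("run complete: %s", outdir)
    return report_dict


# ---------------------------------------------------------------------------
# Deposited-data ingestion
# ---------------------------------------------------------------------------

S1_REQUIRED_COLUMNS = ("experiment", "participant_id", "level", "mean_response")


def read_s1_data(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a locally available deposited-data export (XLSX or CSV).

    Expects a long-format table with columns ``experiment`` (1–4),
    ``participant_id``, ``level`` (the manipulated-parameter value),
    ``mean_response`` (per-level mean response), optionally ``task`` and
    per-participant covariate columns (``msi_general`` and subscales).
    XLSX files may split experiments across sheets; all sheets are
    concatenated.  Returns ``(level_means, covariates)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        frames = list(sheets.values())
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.read_csv(path)
    data.columns = [str(c).strip().lower().replace(" ", "_") for c in data.columns]
    missing = [c for c in S1_REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(
            f"deposited-data file {path.name} is missing required column(s): {missing}; "
            f"found {list(data.columns)}"
        )
    if "task" not in data.columns:
        data["task"] = "judgment"
    level_means = data[["experiment", "participant_id", "task", "level", "mean_response"]].copy()
    cov_cols = [
        c
        for c in data.columns
        if c not in ("experiment", "task", "level", "mean_response")
    ]
    covariates = data[cov_cols].drop_duplicates(subset="participant_id").reset_index(drop=True)
    return level_means, covariates
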