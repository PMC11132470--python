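"""Headphone screening: dichotic tone triplets, playback physics, scoring.

Online listeners must wear headphones for the antiphase manipulation to
work.  Each trial presents three 1-s, 200-Hz pure tones — a binaurally
in-phase loud tone, an antiphase loud tone, and an in-phase quiet tone at
exactly -6 dB — and asks for the quietest.  Over headphones the quiet tone
is the obvious pick; over loudspeakers the antiphase tone cancels in the
air and becomes the quietest, so an attentive loudspeaker listener picks
the wrong tone.  Passing requires at least 5 of 6 correct trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScreeningTriplet",
    "make_screening_trial",
    "make_screening_task",
    "render_playback",
    "ideal_pick",
    "score_screening",
    "TONE_FREQ",
    "TONE_DURATION",
    "RAMP_DURATION",
    "LOUD_AMPLITUDE",
    "QUIET_GAIN",
    "PASS_THRESHOLD",
    "N_TRIALS",
]

#: Pure-tone frequency, Hz.
TONE_FREQ = 200.0
#: Tone duration, s.
TONE_DURATION = 1.0
#: Raised-cosine on/off ramp duration, s.
RAMP_DURATION = 0.1
#: "Loud" reference amplitude re full scale.
LOUD_AMPLITUDE = 0.5
#: Quiet-tone gain: exactly -6 dB.
QUIET_GAIN = 10.0 ** (-6.0 / 20.0)
#: Minimum number of correct trials (out of :data:`N_TRIALS`) to pass.
PASS_THRESHOLD = 5
N_TRIALS = 6

LABELS = ("inphase_loud", "antiphase_loud", "inphase_quiet")


@dataclass(frozen=True)
class ScreeningTriplet:
    """Three stereo tones and their presentation order for one trial.

    ``tones`` maps each label to a ``(left, right)`` pair of sample arrays.
    ``order`` is the presentation order of the labels; ``correct_index`` is
    the position of the in-phase quiet tone (the right answer under
    headphone listening).
    """

    tones: dict[str, tuple[np.ndarray, np.ndarray]]
    order: tuple[str, str, str]
    rate: int

    @property
    def correct_index(self) -> int:
        return self.order.index("inphase_quiet")


def _pure_tone(rate: int) -> np.ndarray:
    t = np.arange(int(round(TONE_DURATION * rate))) / rate
    tone = LOUD_AMPLITUDE * np.sin(2.0 * np.pi * TONE_FREQ * t)
    n_ramp = int(round(RAMP_DURATION * rate))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))  # raised cosine
    tone[:n_ramp] *= ramp
    tone[-n_ramp:] *= ramp[::-1]
    return tone


def make_screening_trial(
    seed: int | None = None,
    rate: int = 44_100,
    order: tuple[str, str, str] | None = None,
) -> ScreeningTriplet:
    """Build one screening trial.

    The presentation order is drawn at random from the six permutations
    unless given explicitly (the task builder counterbalances all six).
    """
    if rate <= 2 * TONE_FREQ:
        raise ValueError(f"rate must exceed {2 * TONE_FREQ} Hz")
    base = _pure_tone(rate)
    tones = {
        "inphase_loud": (base, base.copy()),
        "antiphase_loud": (base, -base),
        "inphase_quiet": (QUIET_GAIN * base, QUIET_GAIN * base),
    }
    if order is None:
        rng = np.random.default_rng(seed)
        order = tuple(LABELS[i] for i in rng.permutation(3))
    elif sorted(order) != sorted(LABELS):
        raise ValueError(f"order must be a permutation of {LABELS}")
    return ScreeningTriplet(tones=tones, order=tuple(order), rate=rate)


def make_screening_task(seed: int | None = None, rate: int = 44_100) -> list[ScreeningTriplet]:
    """Six trials whose orders counterbalance all 6 permutations of 3 positions."""
    rng = np.random.default_rng(seed)
    perms = list(itertools.permutations(LABELS))
    rng.shuffle(perms)
    return [make_screening_trial(rate=rate, order=perm) for perm in perms]


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


def render_playback(triplet: ScreeningTriplet, mode: str) -> list[float]:
    """Perceived RMS level of each tone, in presentation order, under a mode.

    ``headphones`` delivers each ear unchanged (level = RMS over both ear
    signals); ``loudspeaker`` sums the channels in the air to a mono signal
    ``(left + right) / 2``, cancelling the antiphase tone.
    """
    levels = []
    for label in triplet.order:
        left, right = triplet.tones[label]
        if mode == "headphones":
            levels.append(_rms(np.concatenate([left, right])))
        elif mode == "loudspeaker":
            levels.append(_rms((left + right) / 2.0))
        else:
            raise ValueError(f"unknown playback mode: {mode!r}")
    return levels


def ideal_pick(triplet: ScreeningTriplet, mode: str) -> int:
    """Index an ideal intensity-judging listener picks as quietest."""
    return int(np.argmin(render_playback(triplet, mode)))


def score_screening(responses: list[int], answers: list[int]) -> tuple[bool, int]:
    """Score 6 picks against the correct indices: pass iff >= 5 correct."""
    if len(responses) != N_TRIALS or len(answers) != N_TRIALS:
        raise ValueError(f"screening requires exactly {N_TRIALS} trials")
    n_correct = sum(int(r == a) for r, a in zip(responses, answers))
    return n_correct >= PASS_THRESHOLD, n_correct
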