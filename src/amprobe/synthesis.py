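"""Synthesis of noise stimuli with parametrically designated amplitude modulation.

The generator runs an analysis pipeline in reverse: a shifted lognormal
curve defines the target AM spectrum (peak frequency ``m`` in Hz, regularity
``sigma``), the curve is tilted by 1/f, an inverse FFT with random phases
turns it into a 20-s amplitude envelope, and the envelope modulates a
low-noise-noise (LNN) carrier — broadband noise iteratively flattened so
that all envelope fluctuation in the final stimulus comes from the imposed
modulator.  The middle 4 s of the modulated carrier is the stimulus.

``estimate_am_spectrum`` closes the loop: it recovers the modulation
spectrum from audio so designed peaks can be verified on the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "AMParams",
    "SpectrumCurve",
    "Envelope",
    "Stimulus",
    "lognormal_am_spectrum",
    "apply_one_over_f",
    "spectrum_to_envelope",
    "make_low_noise_noise",
    "synthesize_stimulus",
    "equalize_rms",
    "estimate_am_spectrum",
    "compensated_peak",
    "estimate_designed_peak",
    "designed_am_spectrum",
    "AUDIO_RATE",
    "ENVELOPE_RATE",
    "FULL_DURATION",
    "STIMULUS_DURATION",
    "AM_BAND_TOP",
    "CARRIER_BAND",
    "LNN_ITERATIONS",
    "DEFAULT_TARGET_RMS",
]

# ---------------------------------------------------------------------------
# Synthesis constants
# ---------------------------------------------------------------------------

#: Audio sampling rate of delivered stimuli, Hz.
AUDIO_RATE = 44_100
#: Internal envelope synthesis rate, Hz.  AM content lives below
#: :data:`AM_BAND_TOP`, so a full-audio-rate FFT would be wasteful.
ENVELOPE_RATE = 1_000
#: Duration of the synthesized signal before excerpt extraction, s.
FULL_DURATION = 20.0
#: Duration of the delivered stimulus (middle excerpt), s.
STIMULUS_DURATION = 4.0
#: Upper edge of the modulation band the lognormal is evaluated on, Hz.
AM_BAND_TOP = 64.0
#: Carrier passband, Hz.
CARRIER_BAND = (20.0, 20_000.0)
#: Number of envelope-division/bandpass rounds used to flatten the carrier.
LNN_ITERATIONS = 10
#: Default RMS after equalization, re full scale; keeps 16-bit output
#: unclipped after modulation.
DEFAULT_TARGET_RMS = 0.05

#: Slope of the x-shift ``b`` as a function of the peak frequency ``m``.
B_PER_M = -1.2813


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AMParams:
    """Designated AM-spectrum parameters.

    Parameters
    ----------
    m : float
        Peak (mode) of the 1/f-compensated AM spectrum, Hz.  Must be > 0.
    sigma : float
        Regularity parameter: the log-SD of the lognormal.  Smaller values
        concentrate modulation power near the peak, producing a more
        isochronous envelope.  Must be > 0.

    The x-shift ``b = -1.2813 m`` and location ``mu = ln(m - b) + sigma**2``
    are derived, so the mode identity ``b + exp(mu - sigma**2) == m`` holds
    exactly by construction.
    """

    m: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError(f"peak frequency m must be > 0, got {self.m}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def b(self) -> float:
        """x-shift, Hz (negative for every valid ``m``)."""
        return B_PER_M * self.m

    @property
    def mu(self) -> float:
        """Lognormal location parameter."""
        return math.log(self.m - self.b) + self.sigma**2


@dataclass(frozen=True)
class SpectrumCurve:
    """A sampled modulation-power curve on a strictly positive frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if freqs.size and (freqs[0] <= 0 or np.any(np.diff(freqs) <= 0)):
            raise ValueError("freqs must be strictly increasing and start above 0")
        if not np.all(np.isfinite(power)) or np.any(power < 0):
            raise ValueError("power must be finite and nonnegative")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)


@dataclass(frozen=True)
class Envelope:
    """Amplitude envelope in [0, 1] with its sampling rate and phase seed."""

    samples: np.ndarray
    rate: float
    seed: int | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.min() < 0 or samples.max() > 1:
            raise ValueError("envelope samples must lie in [0, 1]")
        object.__setattr__(self, "samples", samples)


@dataclass(frozen=True)
class Stimulus:
    """An audio stimulus with its provenance."""

    waveform: np.ndarray
    rate: int
    params: AMParams
    seed: int | None = None
    rms: float = field(default=0.0)

    def __post_init__(self) -> None:
        waveform = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", waveform)
        object.__setattr__(self, "rms", float(np.sqrt(np.mean(waveform**2))))

    @property
    def duration(self) -> float:
        return len(self.waveform) / self.rate


# ---------------------------------------------------------------------------
# Spectrum design
# ---------------------------------------------------------------------------


def lognormal_am_spectrum(params: AMParams, freqs: np.ndarray) -> SpectrumCurve:
    """Evaluate the shifted lognormal AM-spectrum model on a frequency grid.

    The curve is ``1 / ((x - b) sigma sqrt(2 pi)) *
    exp(-(ln(x - b) - mu)^2 / (2 sigma^2))`` with ``b = -1.2813 m`` and
    ``mu = ln(m - b) + sigma^2``; its continuous mode sits exactly at ``m``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size and freqs.min() <= 0:
        raise ValueError("frequency grid must be strictly positive")
    x = freqs - params.b  # b < 0, so x > freqs > 0
    power = (
        1.0
        / (x * params.sigma * math.sqrt(2.0 * math.pi))
        * np.exp(-((np.log(x) - params.mu) ** 2) / (2.0 * params.sigma**2))
    )
    return SpectrumCurve(freqs, power)


def apply_one_over_f(curve: SpectrumCurve) -> SpectrumCurve:
    """Tilt a spectrum by 1/f, undoing the f-weighting used when analysing
    natural envelope spectra.

    The designated peak ``m`` is the peak of the 1/f-*compensated* spectrum
    (``power * f``), not of the tilted curve returned here.
    """
    if curve.freqs.size and curve.freqs.min() <= 0:
        raise ValueError("1/f weighting requires a DC-free grid")
    return SpectrumCurve(curve.freqs, curve.power / curve.freqs)


# ---------------------------------------------------------------------------
# Envelope synthesis
# ---------------------------------------------------------------------------


def spectrum_to_envelope(
    curve: SpectrumCurve,
    duration: float = FULL_DURATION,
    env_rate: float = ENVELOPE_RATE,
    seed: int | None = None,
) -> Envelope:
    """Inverse-FFT a designed spectrum into an amplitude envelope in [0, 1].

    Bin magnitudes are taken from ``curve`` on the FFT grid (spacing
    ``1/duration`` Hz, DC forced to zero), phases are i.i.d. uniform on
    [0, 2pi), and the conjugate-symmetric spectrum is inverse-transformed.
    The zero-mean result is min–max rescaled to [0, 1], which preserves the
    designed spectrum shape up to the affine terms.
    """
    n = duration * env_rate
    if abs(n - round(n)) > 1e-9:
        raise ValueError("duration * env_rate must be an integer number of samples")
    n = int(round(n))
    support_top = curve.freqs[curve.power > 0]
    if support_top.size and support_top.max() > env_rate / 2:
        raise ValueError(
            f"env_rate {env_rate} Hz cannot represent spectrum content up to "
            f"{support_top.max():g} Hz"
        )
    bin_freqs = np.fft.rfftfreq(n, d=1.0 / env_rate)
    mags = np.interp(bin_freqs, curve.freqs, curve.power, left=0.0, right=0.0)
    mags[0] = 0.0
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mags.size)
    spectrum = mags * np.exp(1j * phases)
    # force the purely real bins of an even-length rfft grid
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = np.fft.irfft(spectrum, n=n)
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise ValueError("degenerate (constant) envelope; spectrum has no support")
    samples = (x - lo) / (hi - lo)
    return Envelope(samples=samples, rate=env_rate, seed=seed)


# ---------------------------------------------------------------------------
# Carrier
# ---------------------------------------------------------------------------


def _bandpass_sos(band: tuple[float, float], rate: float) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < rate/2 ({rate/2})")
    return sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")


def make_low_noise_noise(
    duration: float,
    rate: float = AUDIO_RATE,
    band: tuple[float, float] = CARRIER_BAND,
    n_iter: int = LNN_ITERATIONS,
    seed: int | None = None,
) -> np.ndarray:
    """Generate a unit-RMS low-noise-noise carrier.

    Starts from bandpassed white noise and repeats ``n_iter`` rounds of
    dividing by the instantaneous (analytic-signal) envelope and
    re-bandpassing (zero-phase 4th-order Butterworth).  Each round flattens
    the envelope further, so the envelope's coefficient of variation
    decreases across iterations.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    sos = _bandpass_sos(band, rate)
    n = int(round(duration * rate))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    x = sps.sosfiltfilt(sos, x)
    for _ in range(n_iter):
        env = np.abs(sps.hilbert(x))
        env = np.maximum(env, 1e-12 * env.max())
        x = x / env
        x = sps.sosfiltfilt(sos, x)
    return x / np.sqrt(np.mean(x**2))


# ---------------------------------------------------------------------------
# Full stimulus
# ---------------------------------------------------------------------------


def _am_bin_grid(duration: float) -> np.ndarray:
    """FFT-bin frequencies from 1/duration up to the AM band top, Hz."""
    n_bins = int(math.floor(AM_BAND_TOP * duration))
    return np.arange(1, n_bins + 1) / duration


def designed_am_spectrum(params: AMParams, duration: float = FULL_DURATION) -> SpectrumCurve:
    """The 1/f-weighted lognormal evaluated on the synthesis FFT bins."""
    return apply_one_over_f(lognormal_am_spectrum(params, _am_bin_grid(duration)))


def synthesize_stimulus(
    params: AMParams,
    seed: int | None = None,
    rate: int = AUDIO_RATE,
    env_rate: float = ENVELOPE_RATE,
    full_duration: float = FULL_DURATION,
    out_duration: float = STIMULUS_DURATION,
) -> Stimulus:
    """Synthesize one amplitude-modulated LNN stimulus.

    Pipeline: lognormal AM spectrum -> 1/f tilt -> random-phase inverse FFT
    (20-s envelope) -> band-limited upsampling to the audio rate -> multiply
    with an LNN carrier -> extract the middle 4-s excerpt.  Deterministic
    given ``seed``: the phase and carrier streams are spawned from it.
    """
    ss = np.random.SeedSequence(seed)
    phase_seed, carrier_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]

    curve = designed_am_spectrum(params, full_duration)
    env = spectrum_to_envelope(curve, full_duration, env_rate, seed=phase_seed)

    up = int(rate)
    down = int(env_rate)
    g = math.gcd(up, down)
    env_hi = sps.resample_poly(env.samples, up // g, down // g)
    env_hi = np.clip(env_hi, 0.0, 1.0)  # remove band-limited-resampling overshoot
    n_full = int(round(full_duration * rate))
    env_hi = env_hi[:n_full]

    carrier = make_low_noise_noise(full_duration, rate, seed=carrier_seed)
    modulated = env_hi * carrier[: len(env_hi)]

    n_out = int(round(out_duration * rate))
    start = (len(modulated) - n_out) // 2
    waveform = modulated[start : start + n_out]
    return Stimulus(waveform=waveform, rate=rate, params=params, seed=seed)


def equalize_rms(stimuli: list[Stimulus], target_rms: float = DEFAULT_TARGET_RMS) -> list[Stimulus]:
    """Scale each stimulus to a common RMS (gain only, no re-synthesis)."""
    out = []
    for stim in stimuli:
        if stim.rms <= 0:
            raise ValueError("cannot equalize a silent stimulus")
        scaled = stim.waveform * (target_rms / stim.rms)
        out.append(Stimulus(waveform=scaled, rate=stim.rate, params=stim.params, seed=stim.seed))
    return out


# ---------------------------------------------------------------------------
# Verification: AM spectrum estimation from audio
# ---------------------------------------------------------------------------


#: Zero-padding factor for envelope FFTs (finer peak read-out grid).
NFFT_FACTOR = 16


def _extract_envelope(waveform: np.ndarray, rate: float, max_freq: float) -> tuple[np.ndarray, float]:
    """Analytic-signal envelope, low-passed below ``max_freq`` and decimated."""
    env = np.abs(sps.hilbert(waveform))
    sos = sps.butter(4, max_freq, btype="lowpass", fs=rate, output="sos")
    env = sps.sosfiltfilt(sos, env)
    # content is band-limited by the filter, so plain stride decimation is safe
    step = max(int(rate // (4 * max_freq)), 1)
    return env[::step], rate / step


def estimate_am_spectrum(
    waveform: np.ndarray,
    rate: float,
    max_freq: float = AM_BAND_TOP,
    nfft_factor: int = NFFT_FACTOR,
) -> SpectrumCurve:
    """Estimate the modulation (envelope) magnitude spectrum of a waveform.

    Extracts the amplitude envelope as the analytic-signal magnitude,
    low-passes it below ``max_freq``, downsamples, removes the mean, applies
    a Hann window, and returns the zero-padded FFT magnitude on
    (0, max_freq].  Multiplying by frequency (see :func:`compensated_peak`)
    undoes the natural 1/f tilt so designated peaks can be read off.
    """
    waveform = np.asarray(waveform, dtype=float)
    if len(waveform) < rate:
        raise ValueError("need at least 1 s of audio to estimate an AM spectrum")
    env, fs = _extract_envelope(waveform, rate, max_freq)
    env = env - env.mean()
    env = env * sps.get_window("hann", len(env))
    nfft = nfft_factor * len(env)
    mags = np.abs(np.fft.rfft(env, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = (freqs > 0) & (freqs <= max_freq)
    return SpectrumCurve(freqs[keep], mags[keep])


def compensated_peak(curve: SpectrumCurve) -> float:
    """Peak frequency of the 1/f-compensated spectrum (``power * f``), Hz."""
    return float(curve.freqs[np.argmax(curve.power * curve.freqs)])


# ---------------------------------------------------------------------------
# Designed-peak verification on short excerpts
# ---------------------------------------------------------------------------
#
# A 4-s excerpt holds only a few cycles of sub-Hz modulation, so the raw
# compensated argmax on one excerpt is both noisy and biased by window
# leakage.  The verification fit below removes the window bias by modelling
# the *expected* excerpt periodogram exactly: every design bin contributes a
# randomly phased sinusoid that is segment-mean-subtracted, Hann-windowed
# and zero-padded, and those per-bin response shapes are precomputed into a
# kernel.  Fitting the designated lognormal family (sigma fixed at the
# designed value) through this kernel to a seed-averaged periodogram then
# reads out the peak without the leakage bias.

_KERNEL_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _segment_kernel(
    nseg: int,
    fs: float,
    max_fit_freq: float,
    design_duration: float = FULL_DURATION,
    nfft_factor: int = NFFT_FACTOR,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expected-periodogram kernel for mean-subtracted, Hann-windowed segments.

    Returns ``(fk, fo, M)``: design-bin frequencies, output frequencies, and
    the matrix mapping per-design-bin power to expected periodogram values.
    """
    key = (nseg, round(fs, 6), round(max_fit_freq, 6), round(design_duration, 6), nfft_factor)
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    fk = _am_bin_grid(design_duration)
    t = np.arange(nseg) / fs
    w = sps.get_window("hann", nseg)
    nfft = nfft_factor * nseg
    v = np.exp(2j * np.pi * np.outer(fk, t))
    v -= v.mean(axis=1, keepdims=True)
    v *= w[None, :]
    g = np.fft.fft(v, n=nfft, axis=1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep_idx = np.where((freqs > 0) & (freqs <= max_fit_freq))[0]
    fo = freqs[keep_idx]
    m = 0.25 * (np.abs(g[:, keep_idx]) ** 2 + np.abs(g[:, (nfft - keep_idx) % nfft]) ** 2)
    _KERNEL_CACHE[key] = (fk, fo, m)
    return fk, fo, m


def estimate_designed_peak(
    stimuli: list[Stimulus],
    sigma: float | None = None,
    max_fit_freq: float = 16.0,
    max_freq: float = AM_BAND_TOP,
) -> float:
    """Estimate the designated AM peak frequency from a set of stimuli.

    Averages the envelope periodograms of the given stimuli (independent
    phase realizations of one condition), then fits the 1/f-weighted
    lognormal family — propagated through the exact segment/window response
    — to the averaged compensated spectrum.  ``sigma`` defaults to the
    designed regularity of the stimuli.  Returns the fitted peak, Hz.
    """
    from scipy import optimize

    if not stimuli:
        raise ValueError("need at least one stimulus")
    rate = stimuli[0].rate
    if sigma is None:
        sigma = stimuli[0].params.sigma
    acc = None
    for stim in stimuli:
        env, fs = _extract_envelope(stim.waveform, rate, max_freq)
        env = env - env.mean()
        env = env * sps.get_window("hann", len(env))
        nfft = NFFT_FACTOR * len(env)
        power = np.abs(np.fft.rfft(env, n=nfft)) ** 2
        acc = power if acc is None else acc + power
        nseg = len(env)
    fk, fo, kernel = _segment_kernel(nseg, fs, max_fit_freq)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    keep = (freqs > 0) & (freqs <= max_fit_freq)
    comp = acc[keep] * fo**2
    comp = comp / comp.max()

    def model(log_m: float) -> np.ndarray:
        params = AMParams(math.exp(log_m), sigma)
        amp = apply_one_over_f(lognormal_am_spectrum(params, fk)).power
        return (amp * amp) @ kernel * fo**2

    def residuals(theta: np.ndarray) -> np.ndarray:
        s = model(theta[0])
        gain = np.dot(s, comp) / np.dot(s, s)
        # relative weighting: periodogram noise scales with the signal
        return (gain * s - comp) / (gain * s + 0.05)

    best = None
    for m0 in (0.4, 0.8, 1.5, 3.0, 6.0, 10.0):
        fit = optimize.least_squares(
            residuals, x0=[math.log(m0)], bounds=([math.log(0.05)], [math.log(32.0)])
        )
        if best is None or fit.cost < best.cost:
            best = fit
    return float(math.exp(best.x[0]))
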