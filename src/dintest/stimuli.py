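"""Acoustic stimulus preparation on synthetic audio.

Covers the corpus-homogenization pipeline: estimate a talker's long-term
average speech spectrum (LTASS) and design a linear-phase FIR correction
filter matching it to a reference spectrum; summarize digit exemplars by
RMS level and duration and retain those within +/-1 SD of the per-digit
means on both measures; pick the final exemplars by fundamental-frequency
(f0) similarity to the per-digit median; and equalize the survivors to a
common RMS level. Everything operates on 44.1 kHz mono signals; WAV files
on disk are 16-bit PCM.

A synthetic token generator produces digit-like bursts (speech-shaped
noise with optional f0-like periodicity, controllable level and duration)
so the whole pipeline is testable without recordings. It is a synthetic
stand-in for a recorded corpus, not a speech synthesizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

SAMPLE_RATE = 44100


@dataclass(frozen=True)
class AudioClip:
    """Mono audio held as float64 in [-1, 1]; 16-bit PCM on disk."""

    samples: np.ndarray
    rate: int = SAMPLE_RATE

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate

    def rms_db(self) -> float:
        r = float(np.sqrt(np.mean(self.samples ** 2)))
        if r <= 0:
            raise ValueError("silent clip has no defined RMS level")
        return 20.0 * np.log10(r)

    def save(self, path: str | Path) -> None:
        x = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(str(path), self.rate,
                      np.round(x * 32767).astype(np.int16))

    @classmethod
    def load(cls, path: str | Path) -> "AudioClip":
        rate, data = wavfile.read(str(path))
        if data.ndim > 1:
            data = data.mean(axis=1)
        if data.dtype == np.int16:
            data = data / 32768.0
        return cls(samples=np.asarray(data, dtype=float), rate=int(rate))


@dataclass(frozen=True)
class LtassConfig:
    """Welch analysis parameters for LTASS estimation."""

    window_samples: int = 1024
    overlap: float = 0.5
    third_octave_smooth: bool = True


@dataclass(frozen=True)
class Spectrum:
    """Band levels in dB on a fixed frequency grid, normalized to 0 dB overall."""

    freqs_hz: np.ndarray
    levels_db: np.ndarray


def ltass(clip: AudioClip, cfg: LtassConfig = LtassConfig()) -> Spectrum:
    """Long-term average spectrum via Welch averaging, in dB per band.

    Levels are normalized so the power-weighted overall level is 0 dB,
    making spectra from differently scaled recordings comparable. Requires
    at least 1 s of signal.
    """
    if len(clip.samples) < clip.rate:
        raise ValueError("need at least 1 s of audio for a stable LTASS")
    nover = int(cfg.window_samples * cfg.overlap)
    f, pxx = signal.welch(clip.samples, fs=clip.rate, nperseg=cfg.window_samples,
                          noverlap=nover, window="hann")
    if cfg.third_octave_smooth:
        pxx = _third_octave_smooth(f, pxx)
    total = np.sum(pxx * np.gradient(f))
    levels = 10.0 * np.log10(np.maximum(pxx / total, 1e-30))
    return Spectrum(freqs_hz=f, levels_db=levels)


def _third_octave_smooth(f: np.ndarray, pxx: np.ndarray) -> np.ndarray:
    out = np.empty_like(pxx)
    lo = f / 2 ** (1 / 6)
    hi = f * 2 ** (1 / 6)
    for i in range(len(f)):
        m = (f >= lo[i]) & (f <= hi[i])
        out[i] = pxx[m].mean() if m.any() else pxx[i]
    return out


def design_correction_filter(talker: Spectrum, reference: Spectrum,
                             n_taps: int = 513, max_gain_db: float = 20.0,
                             ) -> np.ndarray:
    """Linear-phase FIR whose magnitude is reference - talker (dB).

    Gains are capped at +/-``max_gain_db`` per band so that bands where
    the talker has negligible energy are not amplified into noise.
    Applying the filter to the talker signal brings its LTASS toward the
    reference.
    """
    if talker.freqs_hz.shape != reference.freqs_hz.shape or \
            not np.allclose(talker.freqs_hz, reference.freqs_hz):
        raise ValueError("spectra must share one frequency grid")
    gain_db = np.clip(reference.levels_db - talker.levels_db,
                      -max_gain_db, max_gain_db)
    gain = 10.0 ** (gain_db / 20.0)
    f = talker.freqs_hz
    nyq = f[-1]
    # firwin2 needs endpoints at 0 and 1 of normalized frequency
    freqs = np.concatenate([[0.0], f / nyq]) if f[0] > 0 else f / nyq
    gains = np.concatenate([[gain[0]], gain]) if f[0] > 0 else gain
    return signal.firwin2(n_taps, freqs, gains)


def apply_filter(clip: AudioClip, taps: np.ndarray) -> AudioClip:
    """Zero-delay application of a linear-phase FIR (group delay removed)."""
    y = signal.fftconvolve(clip.samples, taps, mode="full")
    delay = (len(taps) - 1) // 2
    return AudioClip(samples=y[delay:delay + len(clip.samples)], rate=clip.rate)


# ---------------------------------------------------------------- exemplars

@dataclass(frozen=True)
class ExemplarStats:
    """Level (dB RMS) and duration (ms) for every exemplar of every digit."""

    level_db: Mapping[str, float]
    duration_ms: Mapping[str, float]
    digit_of: Mapping[str, int]

    @classmethod
    def from_clips(cls, clips: Mapping[str, AudioClip],
                   digit_of: Mapping[str, int]) -> "ExemplarStats":
        return cls(level_db={k: c.rms_db() for k, c in clips.items()},
                   duration_ms={k: c.duration_ms for k, c in clips.items()},
                   digit_of=dict(digit_of))


def select_exemplars(stats: ExemplarStats) -> dict[int, list[str]]:
    """Retain exemplars within +/-1 SD of their digit's mean level *and* duration.

    SDs are population SDs across the digit's exemplars; degenerate digits
    (all exemplars identical) retain everything.
    """
    by_digit: dict[int, list[str]] = {}
    for k, d in stats.digit_of.items():
        by_digit.setdefault(d, []).append(k)
    out: dict[int, list[str]] = {}
    for d, keys in by_digit.items():
        if len(keys) < 2:
            raise ValueError(f"digit {d}: need >= 2 exemplars")
        lev = np.array([stats.level_db[k] for k in keys])
        dur = np.array([stats.duration_ms[k] for k in keys])
        keep = (np.abs(lev - lev.mean()) <= lev.std()) & \
               (np.abs(dur - dur.mean()) <= dur.std())
        out[d] = [k for k, ok in zip(keys, keep) if ok]
    return out


def estimate_f0(clip: AudioClip, fmin: float = 60.0, fmax: float = 400.0) -> float:
    """Fundamental frequency by autocorrelation peak picking (Hz)."""
    x = clip.samples - clip.samples.mean()
    ac = signal.correlate(x, x, mode="full")[len(x) - 1:]
    lo = int(clip.rate / fmax)
    hi = min(int(clip.rate / fmin), len(ac) - 1)
    if hi <= lo:
        raise ValueError("clip too short for f0 estimation")
    lag = lo + int(np.argmax(ac[lo:hi]))
    return clip.rate / lag


def select_by_f0(clips: Mapping[str, AudioClip], retained: Sequence[str],
                 n_final: int = 6) -> list[str]:
    """Final automated selection: the retained exemplars whose f0 is
    closest to the median f0 of the retained set.

    Automated stand-in for the corpus's subjective same-voice-quality
    choice.
    """
    f0s = {k: estimate_f0(clips[k]) for k in retained}
    med = float(np.median(list(f0s.values())))
    ranked = sorted(retained, key=lambda k: abs(f0s[k] - med))
    return ranked[:n_final]


def equalize_level(clips: Sequence[AudioClip]) -> list[AudioClip]:
    """Scale clips to share one RMS level: the pre-equalization mean (dB)."""
    levels = np.array([c.rms_db() for c in clips])
    target = float(levels.mean())
    out = []
    for c, lev in zip(clips, levels):
        gain = 10.0 ** ((target - lev) / 20.0)
        out.append(AudioClip(samples=c.samples * gain, rate=c.rate))
    return out


# ---------------------------------------------------- synthetic test corpus

def speech_shaped_noise(duration_s: float, rng: np.random.Generator,
                        rate: int = SAMPLE_RATE, corner_hz: float = 500.0,
                        slope_db_per_octave: float = -6.0) -> AudioClip:
    """Noise with a speech-like spectrum: flat below ``corner_hz``, rolling
    off at ``slope_db_per_octave`` above it."""
    n = int(duration_s * rate)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.ones_like(f)
    above = f > corner_hz
    shape[above] = 2.0 ** (np.log2(f[above] / corner_hz)
                           * slope_db_per_octave / 6.0206)
    x = np.fft.irfft(spec * shape, n)
    x /= np.max(np.abs(x)) * 1.05
    return AudioClip(samples=x, rate=rate)


def synthetic_digit_token(rng: np.random.Generator, duration_ms: float = 500.0,
                          level_db: float = -23.0, f0_hz: float | None = 180.0,
                          rate: int = SAMPLE_RATE) -> AudioClip:
    """Digit-like synthetic token: speech-shaped noise, optionally with
    f0-periodic amplitude structure, at a target RMS level."""
    base = speech_shaped_noise(duration_ms / 1000.0, rng, rate=rate)
    x = base.samples
    if f0_hz:
        t = np.arange(len(x)) / rate
        x = x * (0.35 + 0.65 * 0.5 * (1 + np.cos(2 * np.pi * f0_hz * t)))
        x = x + 0.4 * np.sin(2 * np.pi * f0_hz * t) * np.std(x)
    # 10 ms raised-cosine onset/offset ramps
    ramp = int(0.010 * rate)
    env = np.ones(len(x))
    env[:ramp] = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    x = x * env
    cur = 20 * np.log10(np.sqrt(np.mean(x ** 2)))
    x = x * 10 ** ((level_db - cur) / 20.0)
    return AudioClip(samples=x, rate=rate)
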