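"""Class-conditional synthetic EEG emulating the music-listening corpus.

Each recording is a 1/f^a Gaussian background plus band-limited
oscillations whose amplitudes depend on the emotion label, mirroring the
spectral effects reported for music-evoked affect: elevated frontal-midline
theta (4-8 Hz) for positive/liked music and elevated frontal beta
(13-30 Hz) for negative/disliked music.  Neutral clips carry no added
oscillation.  The generator is a pure function of its spec: identical
seeds give bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .eeg_io import Montage, Recording, canonical_montage
from .errors import ConfigError, DataError

__all__ = ["BandEffect", "SynthSpec", "generate_corpus", "band_power"]


@dataclass(frozen=True)
class BandEffect:
    """One class-conditional oscillation: a band, a scalp region, a gain."""

    band: tuple[float, float]  # [f_lo, f_hi], Hz
    channels: tuple[str, ...]  # electrode labels carrying the effect
    gain: float = 1.0          # amplitude multiplier (>= 0)


def default_class_effects() -> dict[int, tuple[BandEffect, ...]]:
    """Literature-motivated effect topography per emotion label."""
    return {
        1: (BandEffect((4.0, 8.0), ("Fz", "Cz", "AF3", "AF4"), 1.0),),
        -1: (BandEffect((13.0, 30.0), ("Fp1", "Fp2", "F3", "F4", "F7", "F8"), 1.0),),
        0: (),
    }


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters; defaults mirror the acquisition protocol.

    32 subjects x 12 one-minute clips (4 per class), 32 channels at 128 Hz.
    ``snr`` is the RMS ratio of an added oscillation (at unit gain) to the
    1/f background on its target channels.
    """

    n_subjects: int = 32
    clips_per_class: int = 4
    clip_s: float = 60.0
    fs: float = 128.0
    montage: Montage = field(default_factory=canonical_montage)
    class_effects: dict[int, tuple[BandEffect, ...]] = field(
        default_factory=default_class_effects
    )
    noise_exponent: float = 1.0
    snr: float = 6.0
    background_rms_uv: float = 10.0
    n_components: int = 3  # sinusoids summed per band-limited oscillation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_s <= 0 or self.fs <= 0:
            raise ConfigError("clip_s and fs must be positive")
        if self.n_subjects < 1 or self.clips_per_class < 1:
            raise ConfigError("need at least one subject and one clip per class")
        nyq = self.fs / 2.0
        for label, effects in self.class_effects.items():
            for eff in effects:
                lo, hi = eff.band
                if not (0 < lo < hi < nyq):
                    raise ConfigError(
                        f"band {eff.band} for label {label} outside (0, {nyq})"
                    )
                if eff.gain < 0:
                    raise ConfigError("effect gain must be >= 0")

    @property
    def labels(self) -> tuple[int, ...]:
        return tuple(sorted(self.class_effects))


def _one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _band_oscillation(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float],
    n_components: int,
) -> np.ndarray:
    """Unit-RMS sum of sinusoids with random frequencies/phases in a band."""
    t = np.arange(n) / fs
    freqs = rng.uniform(band[0], band[1], n_components)
    phases = rng.uniform(0.0, 2.0 * np.pi, n_components)
    x = np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(0)
    return x / np.std(x)


def generate_corpus(spec: SynthSpec) -> list[Recording]:
    """One Recording per subject x clip, balanced across emotion labels."""
    n = int(round(spec.clip_s * spec.fs))
    n_ch = len(spec.montage)
    recordings: list[Recording] = []
    for si in range(spec.n_subjects):
        for li, label in enumerate(spec.labels):
            effects = spec.class_effects[label]
            targets = [
                (spec.montage.index_of(ch), eff)
                for eff in effects for ch in eff.channels
            ]
            for ci in range(spec.clips_per_class):
                # child seed per recording: reproducible regardless of order
                ss = np.random.SeedSequence(spec.seed, spawn_key=(si, li, ci))
                rng = np.random.default_rng(ss)
                data = np.empty((n, n_ch))
                for ch in range(n_ch):
                    data[:, ch] = spec.background_rms_uv * _one_over_f(
                        rng, n, spec.noise_exponent
                    )
                for ch_idx, eff in targets:
                    osc = _band_oscillation(
                        rng, n, spec.fs, eff.band, spec.n_components
                    )
                    amp = eff.gain * spec.snr * spec.background_rms_uv
                    data[:, ch_idx] += amp * osc
                recordings.append(
                    Recording(
                        samples=data,
                        fs=spec.fs,
                        montage=spec.montage,
                        label=label,
                        subject_id=f"s{si:02d}",
                        clip_id=f"clip{li}_{ci}",
                    )
                )
    return recordings


def band_power(
    rec: Recording,
    band: tuple[float, float],
    channels: Sequence[str] | None = None,
    nperseg: int = 256,
) -> float:
    """Band-integrated Welch power, averaged over the given channels (uV^2).

    Welch periodogram with Hann windows of ``nperseg`` samples and 50%
    overlap; the PSD is integrated over ``band`` and averaged across the
    channel subset (all channels if None).
    """
    lo, hi = band
    if not (0 <= lo < hi <= rec.fs / 2.0):
        raise ConfigError(f"band {band} outside [0, Nyquist={rec.fs / 2}]")
    if channels is None:
        idx = list(range(len(rec.montage)))
    else:
        if len(list(channels)) == 0:
            raise DataError("empty channel subset")
        idx = rec.montage.indices_of(channels)
    nperseg = min(nperseg, rec.n_samples)
    f, psd = sps.welch(
        rec.samples[:, idx], fs=rec.fs, nperseg=nperseg,
        noverlap=nperseg // 2, axis=0,
    )
    df = f[1] - f[0]
    sel = (f >= lo) & (f <= hi)
    return float(psd[sel].sum(axis=0).mean() * df)
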