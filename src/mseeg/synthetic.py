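"""Synthetic resting-state EEG with a planted two-class band-power contrast.

The real study population (resting eyes-closed recordings from people
with multiple sclerosis and healthy controls, 3 channels at 250 Hz) is
private, so this module emulates its statistical structure instead of
its physiology.  Each channel is a sum of three stochastic parts:

* a 1/f^beta background (spectrally shaped Gaussian noise), the broadband
  scale-free floor characteristic of resting EEG;
* one amplitude-modulated narrowband Gaussian oscillation per clinical
  band (white noise band-passed to the band, normalized to unit power,
  slowly modulated), rather than pure sinusoids, so entropy and fractal
  descriptors remain non-degenerate;
* additive white measurement noise.

The MS class differs from the healthy class in two ways, both scaled by
a single ``effect_size`` knob: alpha/beta/gamma oscillation amplitudes
are multiplied by ``(1 + effect_size)``, and the white-noise standard
deviation by ``1 + (complexity_factor - 1) * effect_size`` so that
irregularity descriptors also discriminate.  At ``effect_size = 0`` the
two class generators are *identical* — the null-control property the
evaluation module relies on.

Channels are correlated the way nearby scalp electrodes are: each
channel mixes a shared per-band oscillation source with its own
independent one (default weight 0.5).

Everything is a pure function of ``(spec, seed)``: per-recording
generators are spawned deterministically from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .preprocess import Recording, band_edges

__all__ = [
    "SpecError",
    "SyntheticSpec",
    "generate_recording",
    "generate_dataset",
    "CONTRAST_BANDS",
]

#: Bands whose oscillation amplitude carries the between-class contrast.
CONTRAST_BANDS = ("alpha", "beta", "gamma")

_DEFAULT_BAND_POWER = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 1.0,
    "beta": 0.7,
    "gamma": 0.5,
}


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass
class SyntheticSpec:
    """Parameters of the two-class EEG generator.

    Attributes
    ----------
    fs : float
        Sampling rate in Hz (study value: 250).
    duration : float
        Recording length in seconds (study analyses use 15 s segments).
    n_channels : int
        Channels per recording (study value: 3).
    band_power : dict
        Band name -> healthy-class oscillation amplitude (signal units).
        The per-band oscillation is normalized to unit variance before
        scaling, so the band's oscillatory power equals amplitude**2.
    background_exponent : float
        Spectral slope beta of the 1/f^beta background, >= 0.
    background_sd : float
        Standard deviation of the background component.
    noise_sd : float
        Standard deviation of the additive white noise (healthy class).
    effect_size : float
        Scales the between-class contrast; 0 means identical classes.
    channel_mixing : float
        Weight in [0, 1] of the shared oscillation source per band.
    complexity_factor : float
        White-noise SD multiplier for the MS class at effect_size = 1.
    seed : int
        Root seed; all randomness derives from it.
    """

    fs: float = 250.0
    duration: float = 15.0
    n_channels: int = 3
    band_power: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BAND_POWER))
    background_exponent: float = 1.0
    background_sd: float = 0.4
    noise_sd: float = 0.3
    effect_size: float = 1.0
    channel_mixing: float = 0.5
    complexity_factor: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SpecError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise SpecError(f"duration must be positive, got {self.duration}")
        if self.n_channels < 1:
            raise SpecError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.effect_size < 0:
            raise SpecError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.background_exponent < 0:
            raise SpecError("background_exponent must be >= 0")
        if not 0.0 <= self.channel_mixing <= 1.0:
            raise SpecError("channel_mixing must lie in [0, 1]")

    @property
    def n_times(self) -> int:
        return int(round(self.fs * self.duration))


def _powerlaw_noise(n: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^beta power spectrum."""
    white = rng.standard_normal(n)
    if beta == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    scale[0] = 0.0  # no DC drift
    shaped = np.fft.irfft(spec * scale, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _narrowband(n: int, fs: float, low: float, high: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise via zero-phase Butterworth."""
    nyq = fs / 2.0
    low = max(low, 0.4)  # keep the delta band off DC
    high = min(high, nyq * 0.99)
    sos = sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _envelope(n: int, fs: float, rng: np.random.Generator, depth: float = 0.5) -> np.ndarray:
    """Slow positive amplitude-modulation envelope (~0.2 Hz bursting)."""
    nyq = fs / 2.0
    sos = sps.butter(2, 0.3 / nyq, btype="lowpass", output="sos")
    slow = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    return np.clip(1.0 + depth * slow, 0.1, None)


def _class_parameters(spec: SyntheticSpec, class_label: str) -> tuple[dict[str, float], float]:
    """Resolve per-class oscillation amplitudes and white-noise SD."""
    if class_label not in ("healthy", "MS"):
        raise SpecError(f"class_label must be 'healthy' or 'MS', got {class_label!r}")
    amps = dict(spec.band_power)
    noise_sd = spec.noise_sd
    if class_label == "MS":
        for band in CONTRAST_BANDS:
            if band in amps:
                amps[band] = amps[band] * (1.0 + spec.effect_size)
        noise_sd = noise_sd * (1.0 + (spec.complexity_factor - 1.0) * spec.effect_size)
    return amps, noise_sd


def generate_recording(
    spec: SyntheticSpec,
    class_label: str,
    rng: np.random.Generator,
    recording_id: str = "",
) -> Recording:
    """Generate one labeled multichannel recording.

    The per-band oscillation is normalized to unit variance *after*
    amplitude modulation, so its power contribution is exactly the
    squared class amplitude; with the default MS scaling ``(1 +
    effect_size)`` in alpha/beta/gamma, the MS/healthy band-power ratio
    in those bands approaches ``(1 + effect_size)**2``.
    """
    amps, noise_sd = _class_parameters(spec, class_label)
    n = spec.n_times
    edges = band_edges(spec.fs) if spec.fs >= 100 else band_edges(250.0)
    if spec.fs < 100:
        # Sub-dyadic rates cannot host a gamma band; scale edges to fs.
        edges = {b: (lo * spec.fs / 250.0, hi * spec.fs / 250.0) for b, (lo, hi) in edges.items()}

    w = spec.channel_mixing
    norm = np.sqrt(w**2 + (1.0 - w) ** 2) if (0.0 < w < 1.0) else 1.0

    shared: dict[str, np.ndarray] = {}
    for band in amps:
        lo, hi = edges[band]
        osc = _narrowband(n, spec.fs, lo, hi, rng) * _envelope(n, spec.fs, rng)
        shared[band] = osc / osc.std()

    channels = np.zeros((spec.n_channels, n))
    for ch in range(spec.n_channels):
        x = spec.background_sd * _powerlaw_noise(n, spec.background_exponent, rng)
        for band, amp in amps.items():
            lo, hi = edges[band]
            own = _narrowband(n, spec.fs, lo, hi, rng) * _envelope(n, spec.fs, rng)
            own = own / own.std()
            mixed = (w * shared[band] + (1.0 - w) * own) / norm
            x = x + amp * mixed
        x = x + noise_sd * rng.standard_normal(n)
        channels[ch] = x

    return Recording(
        samples=channels,
        fs=spec.fs,
        label=class_label,
        recording_id=recording_id,
    )


def generate_dataset(spec: SyntheticSpec, n_per_class: int) -> list[Recording]:
    """Generate a balanced labeled dataset of ``2 * n_per_class`` recordings.

    Per-recording seeds are spawned deterministically from ``spec.seed``,
    so recordings within a class are distinct but the whole dataset is a
    pure function of the spec.
    """
    if n_per_class < 1:
        raise SpecError(f"n_per_class must be >= 1, got {n_per_class}")
    seq = np.random.SeedSequence(spec.seed)
    children = seq.spawn(2 * n_per_class)
    recordings: list[Recording] = []
    for i in range(n_per_class):
        rng = np.random.default_rng(children[2 * i])
        recordings.append(
            generate_recording(spec, "healthy", rng, recording_id=f"healthy_{i:03d}")
        )
        rng = np.random.default_rng(children[2 * i + 1])
        recordings.append(generate_recording(spec, "MS", rng, recording_id=f"ms_{i:03d}"))
    return recordings


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of ``spec`` with the class contrast removed (effect_size = 0)."""
    return replace(spec, effect_size=0.0)
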