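"""Electrode-shift split construction and channel-damage injection.

A 10 mm shift of the whole grid (one electrode pitch) is simulated by
splitting channels into two interleaved parity classes along the shift axis:
the model trains on one class and is tested on the other, so every test
electrode sits exactly one pitch away from a training electrode. Damage is
simulated by replacing the raw signal of a fixed set of channels — the same
channels in both the training and testing sides — with 50 Hz
powerline-style noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal as sps

from semgshift.grid import ElectrodeGrid, GridError, ShiftDirection
from semgshift.synth import RawRecording

__all__ = [
    "ShiftSplit",
    "DamageConfig",
    "split_shift",
    "make_damage_noise",
    "inject_damage",
    "sample_damage_channels",
]


@dataclass(frozen=True)
class ShiftSplit:
    """Complementary train/test channel subsets for one shift direction.

    Channel indices are in full-grid coordinates, ordered row-major within
    each subset so that reshaping to ``train_shape``/``test_shape`` preserves
    the physical layout.
    """

    direction: ShiftDirection
    train_channels: np.ndarray
    test_channels: np.ndarray
    train_shape: tuple[int, int]
    test_shape: tuple[int, int]


def split_shift(grid: ElectrodeGrid, direction: ShiftDirection | str) -> ShiftSplit:
    """Build the interleaved train/test split for one shift direction.

    Column-parity directions (inwards/onwards) yield ``(n_rows, n_cols/2)``
    half-grids; row-parity directions (upwards/downwards) yield
    ``(n_rows/2, n_cols)``. Inwards trains on even columns and tests on odd
    ones; onwards is the exact complement; likewise upwards/downwards for
    rows.
    """
    direction = ShiftDirection(direction)
    if direction.axis == "col":
        if grid.n_cols % 2 != 0:
            raise GridError(f"column split needs an even column count, got {grid.n_cols}")
        shape = (grid.n_rows, grid.n_cols // 2)
    else:
        if grid.n_rows % 2 != 0:
            raise GridError(f"row split needs an even row count, got {grid.n_rows}")
        shape = (grid.n_rows // 2, grid.n_cols)
    p = direction.train_parity
    return ShiftSplit(
        direction=direction,
        train_channels=grid.channels_with_parity(direction.axis, p),
        test_channels=grid.channels_with_parity(direction.axis, 1 - p),
        train_shape=shape,
        test_shape=shape,
    )


@dataclass(frozen=True)
class DamageConfig:
    """A fixed set of damaged channels and the noise that replaces them.

    The same channel list applies to the training and testing sides of a
    shift split (channels are full-grid indices). ``rms_mv=None`` matches the
    noise amplitude to the median per-channel RMS of the recording being
    damaged, so the damage is neither invisible nor saturating. ``mode``
    selects the noise model: ``"resonant"`` (default) drives a narrow
    resonance at the carrier frequency with white Gaussian noise — the
    standard powerline-interference model, a 50 Hz carrier with
    Rayleigh-distributed envelope and slowly wandering phase;
    ``"bandpass"`` is Gaussian noise band-passed around the carrier.
    """

    channels: tuple[int, ...] = ()
    noise_seed: int = 0
    carrier_hz: float = 50.0
    rms_mv: float | None = None
    mode: str = "resonant"

    @property
    def n_damaged(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels),
            "noise_seed": self.noise_seed,
            "carrier_hz": self.carrier_hz,
            "rms_mv": self.rms_mv,
            "mode": self.mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DamageConfig":
        return cls(
            channels=tuple(int(c) for c in d.get("channels", ())),
            noise_seed=int(d.get("noise_seed", 0)),
            carrier_hz=float(d.get("carrier_hz", 50.0)),
            rms_mv=d.get("rms_mv"),
            mode=d.get("mode", "am_sine"),
        )


def make_damage_noise(
    n_samples: int,
    fs_hz: float,
    cfg: DamageConfig,
    rms_mv: float | None = None,
    stream: int = 0,
) -> np.ndarray:
    """Generate the replacement noise for one damaged channel.

    Default model: white Gaussian noise through a narrow resonance at the
    carrier frequency (Q = 10, applied forward-backward so there is no phase
    distortion or startup transient). The result is narrowband Gaussian
    noise — a 50 Hz oscillation with Rayleigh-distributed envelope — whose
    power spectrum peaks exactly on the carrier. ``stream`` decorrelates
    channels that share one config. The output is scaled to the requested
    RMS (priority: argument, then ``cfg.rms_mv``, then 1 mV) and clamped to
    the +/-2.5 mV dynamic range.
    """
    if fs_hz <= 2 * cfg.carrier_hz:
        raise ValueError(
            f"sampling rate {fs_hz} Hz cannot represent a {cfg.carrier_hz} Hz carrier"
        )
    target_rms = rms_mv if rms_mv is not None else (cfg.rms_mv if cfg.rms_mv is not None else 1.0)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.noise_seed, stream)))

    white = rng.standard_normal(n_samples)
    if cfg.mode == "resonant":
        b, a = sps.iirpeak(cfg.carrier_hz, Q=10.0, fs=fs_hz)
        noise = sps.filtfilt(b, a, white)
    elif cfg.mode == "bandpass":
        bw = 0.2 * cfg.carrier_hz
        sos = sps.butter(
            4, [cfg.carrier_hz - bw, cfg.carrier_hz + bw], btype="bandpass", fs=fs_hz, output="sos"
        )
        noise = sps.sosfiltfilt(sos, white)
    else:
        raise ValueError(f"unknown damage noise mode {cfg.mode!r}")

    rms = np.sqrt(np.mean(noise**2))
    noise = noise * (target_rms / max(rms, 1e-30))
    return np.clip(noise, -2.5, 2.5)


def inject_damage(rec: RawRecording, cfg: DamageConfig) -> RawRecording:
    """Replace the raw signal of each damaged channel with generated noise.

    Replacement happens at the raw-signal level (before RMS/FSI) so the
    feature pipeline sees the noise statistics. All other channels are
    bit-identical to the input. Each damaged channel gets its own noise
    stream keyed by its index, so channels are decorrelated but the whole
    operation is deterministic given the config.
    """
    if cfg.n_damaged == 0:
        return rec
    n_ch = rec.grid.n_channels
    for ch in cfg.channels:
        if not 0 <= ch < n_ch:
            raise IndexError(f"damaged channel {ch} out of range for {n_ch}-channel grid")
    if len(set(cfg.channels)) != cfg.n_damaged:
        raise ValueError("damaged channels must be distinct")

    signal = np.array(rec.signal, copy=True)
    if cfg.rms_mv is None:
        channel_rms = np.sqrt(np.mean(np.asarray(rec.signal, dtype=np.float64) ** 2, axis=1))
        target = float(np.median(channel_rms))
        cfg_eff = dc_replace(cfg, rms_mv=target)
    else:
        cfg_eff = cfg
    for ch in cfg.channels:
        noise = make_damage_noise(rec.n_samples, rec.fs_hz, cfg_eff, stream=int(ch))
        signal[ch] = noise.astype(signal.dtype)
    return dc_replace(rec, signal=signal)


def sample_damage_channels(grid: ElectrodeGrid, n: int, seed: int, **kwargs) -> DamageConfig:
    """Draw ``n`` distinct damaged channels uniformly at random.

    The returned config is meant to be reused verbatim for every recording
    of a condition, so the damaged electrodes are the same across trials,
    subjects and the two sides of a shift split.
    """
    if n < 0 or n > grid.n_channels:
        raise ValueError(f"cannot damage {n} of {grid.n_channels} channels")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))
    channels = tuple(int(c) for c in sorted(rng.choice(grid.n_channels, size=n, replace=False)))
    return DamageConfig(channels=channels, noise_seed=seed, **kwargs)
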