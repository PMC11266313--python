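"""Seeded synthetic HD-sEMG generator.

Emulates the statistical structure the downstream pipeline consumes: a
rectangular electrode grid records gesture-specific, spatially smooth
amplitude topographies riding on band-limited stochastic carriers. The model
is a standard amplitude-modulation surrogate for interference-pattern EMG —
per-channel gain (a smooth activation field) times zero-mean band-limited
Gaussian noise — plus spatially correlated background noise. It makes no
attempt at motor-unit physiology; what it preserves is exactly what windowed
RMS imaging sees: a reproducible, gesture-dependent, spatially smooth RMS
topography with realistic trial-to-trial variability.

Every artifact is a pure function of ``(profile, seed)``; per-trial random
substreams are derived from ``(seed, gesture, repetition)`` so generation
order never matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal as sps

from semgshift.grid import ElectrodeGrid, make_grid

__all__ = ["SubjectProfile", "RawRecording", "gesture_activation_map", "simulate_trial", "make_subject"]

# Substream tags keep activation-map draws independent of trial draws.
_MAP_STREAM = 101
_TRIAL_STREAM = 202

#: Conventional surface-EMG band (Hz) for the carrier noise.
_EMG_BAND = (20.0, 500.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Generation parameters for one synthetic subject.

    Defaults mirror the acquisition protocol the pipeline targets: a 8 x 24
    grid at 10 mm pitch sampled at 2,048 Hz, nine gestures with 16
    repetitions each, and 4,500-sample task windows. Amplitude parameters are
    free choices (the acquisition dynamic range is +/-2.5 mV but no amplitude
    statistics are prescribed): active channels default to 0.3 mV RMS.

    ``snr`` is the power ratio of the gesture-specific component to the
    spatially correlated background noise; at ``snr=0`` recordings carry no
    gesture information at all and any classifier must fall to chance.
    """

    grid: ElectrodeGrid = field(default_factory=lambda: make_grid(8, 24))
    n_gestures: int = 9
    n_repetitions: int = 16
    fs_hz: float = 2048.0
    window_samples: int = 4500
    amplitude_mv: float = 2.5
    active_rms_mv: float = 0.3
    spatial_scale_mm: float = 25.0
    snr: float = 16.0
    gain_jitter_sigma: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_mv > 2.5:
            raise ValueError("amplitude_mv must not exceed 2.5 mV (the FSI dynamic range)")
        if self.spatial_scale_mm < self.grid.pitch_mm:
            raise ValueError(
                "spatial_scale_mm must be >= the electrode pitch; otherwise adjacent "
                "channels are uncorrelated and shift splits carry no information"
            )
        if self.snr < 0:
            raise ValueError("snr must be nonnegative")

    @property
    def margin_samples(self) -> int:
        """Slack on each side of the task window (10% of its length)."""
        return self.window_samples // 10

    @property
    def recording_samples(self) -> int:
        return self.window_samples + 2 * self.margin_samples

    def with_seed(self, seed: int) -> "SubjectProfile":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class RawRecording:
    """One trial: ``signal`` is channels x samples in mV.

    ``center_sample`` marks the tracked movement center; the 4,500-sample
    task window is taken symmetrically around it.
    """

    signal: np.ndarray
    grid: ElectrodeGrid
    gesture: int
    repetition: int
    center_sample: int
    fs_hz: float

    def __post_init__(self) -> None:
        if self.signal.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels but grid has {self.grid.n_channels}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


def _rng(profile: SubjectProfile, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((profile.seed, *key)))


def _bump_field(grid: ElectrodeGrid, centers_mm: np.ndarray, amps: np.ndarray, width_mm: float) -> np.ndarray:
    """Sum of Gaussian bumps evaluated at electrode positions, in grid layout."""
    rr, cc = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    y = rr * grid.pitch_mm
    x = cc * grid.pitch_mm
    out = np.zeros(grid.shape)
    for (cy, cx), a in zip(centers_mm, amps):
        out += a * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * width_mm**2))
    return out


def _draw_bumps(profile: SubjectProfile, gesture: int) -> tuple[np.ndarray, np.ndarray]:
    """Bump centers (mm) and amplitudes for one gesture's activation field."""
    rng = _rng(profile, _MAP_STREAM, gesture)
    n_bumps = int(rng.integers(2, 4))
    height = (profile.grid.n_rows - 1) * profile.grid.pitch_mm
    width = (profile.grid.n_cols - 1) * profile.grid.pitch_mm
    centers = np.column_stack(
        [rng.uniform(0, height, size=n_bumps), rng.uniform(0, width, size=n_bumps)]
    )
    amps = rng.uniform(0.5, 1.0, size=n_bumps)
    return centers, amps


def gesture_activation_map(profile: SubjectProfile, gesture: int) -> np.ndarray:
    """Spatially smooth nonnegative gain field for one gesture, peak gain 1.

    A mixture of 2-3 Gaussian bumps (width ``spatial_scale_mm``) placed at
    gesture-specific locations on the grid; deterministic given
    ``(profile.seed, gesture)``.
    """
    if not 0 <= gesture < profile.n_gestures:
        raise ValueError(f"gesture {gesture} out of range [0, {profile.n_gestures})")
    centers, amps = _draw_bumps(profile, gesture)
    field_ = _bump_field(profile.grid, centers, amps, profile.spatial_scale_mm)
    return field_ / field_.max()


def _bandpass_sos(fs_hz: float) -> np.ndarray:
    lo, hi = _EMG_BAND
    hi = min(hi, 0.45 * fs_hz)
    return sps.butter(4, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")


def _unit_rms(x: np.ndarray, axis: int = -1) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2, axis=axis, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def simulate_trial(profile: SubjectProfile, gesture: int, repetition: int) -> RawRecording:
    """Simulate one trial of one gesture.

    The per-channel signal is ``A * (sqrt(snr/(1+snr)) * g_c * e_c(t)
    + sqrt(1/(1+snr)) * b_c(t))`` where ``g_c`` is the (jittered) activation
    gain, ``e_c`` a unit-RMS band-limited Gaussian carrier independent per
    channel, ``b_c`` a unit-RMS spatially correlated background, and
    ``A = active_rms_mv``. Trial-to-trial variability comes from a lognormal
    global gain jitter and a sub-pitch random shift of the bump centers.
    Samples are hard-clipped to ``+/-amplitude_mv``.
    """
    if not 0 <= gesture < profile.n_gestures:
        raise ValueError(f"gesture {gesture} out of range [0, {profile.n_gestures})")
    if not 0 <= repetition < profile.n_repetitions:
        raise ValueError(f"repetition {repetition} out of range [0, {profile.n_repetitions})")

    grid = profile.grid
    n_ch = grid.n_channels
    n_samp = profile.recording_samples
    rng = _rng(profile, _TRIAL_STREAM, gesture, repetition)

    # Jittered activation field: sub-pitch shift of every bump center plus a
    # global lognormal gain factor.
    centers, amps = _draw_bumps(profile, gesture)
    shift = rng.uniform(-0.5, 0.5, size=2) * grid.pitch_mm
    gain_factor = rng.lognormal(mean=0.0, sigma=profile.gain_jitter_sigma)
    field_ = _bump_field(grid, centers + shift, amps, profile.spatial_scale_mm)
    gains = gain_factor * (field_ / field_.max()).ravel()

    sos = _bandpass_sos(profile.fs_hz)

    # Gesture-driven component: independent band-limited carriers per channel.
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samp)), axis=1)
    carrier = _unit_rms(carrier)

    # Background: band-limited noise smoothed across the grid so that nearby
    # electrodes see correlated interference.
    bg = sps.sosfiltfilt(sos, rng.standard_normal((n_ch, n_samp)), axis=1)
    sigma_px = profile.spatial_scale_mm / grid.pitch_mm
    bg = bg.reshape(grid.n_rows, grid.n_cols, n_samp)
    bg = ndimage.gaussian_filter(bg, sigma=(sigma_px, sigma_px, 0), mode="nearest")
    bg = _unit_rms(bg.reshape(n_ch, n_samp))

    w_sig = np.sqrt(profile.snr / (1.0 + profile.snr))
    w_bg = np.sqrt(1.0 / (1.0 + profile.snr))
    sig = profile.active_rms_mv * (w_sig * gains[:, None] * carrier + w_bg * bg)
    np.clip(sig, -profile.amplitude_mv, profile.amplitude_mv, out=sig)

    # Center placed mid-recording with a small jitter; the margin guarantees
    # the task window always fits.
    max_jitter = profile.margin_samples // 4
    center = n_samp // 2 + int(rng.integers(-max_jitter, max_jitter + 1))

    return RawRecording(
        signal=sig.astype(np.float32),
        grid=grid,
        gesture=gesture,
        repetition=repetition,
        center_sample=center,
        fs_hz=profile.fs_hz,
    )


def make_subject(profile: SubjectProfile) -> list[RawRecording]:
    """All trials for one subject: ``n_gestures * n_repetitions`` recordings.

    At defaults that is 9 x 16 = 144 labelled recordings.
    """
    return [
        simulate_trial(profile, g, r)
        for g in range(profile.n_gestures)
        for r in range(profile.n_repetitions)
    ]
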