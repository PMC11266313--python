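"""RMS windowing and featured-sEMG-image (FSI) construction.

The feature pipeline is: cut a 4,500-sample task window around the tracked
trial center, divide it evenly into 30 non-overlapping 150-sample frames,
compute per-channel RMS for each frame, arrange the per-channel values as a
2-D image by physical electrode placement, map mV to a 0-255 grayscale via a
fixed affine transform of the +/-2.5 mV dynamic range, and max-min normalize
each image to [0, 1].

All feature math runs in double precision; images stay floating point (the
grayscale step is a normalization device, not an 8-bit storage format).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from semgshift.synth import RawRecording

__all__ = [
    "SegmentationError",
    "RmsFrame",
    "FSI",
    "WINDOW_SAMPLES",
    "RMS_FRAME_LEN",
    "MV_RANGE",
    "segment_task_window",
    "compute_rms",
    "mv_to_gray",
    "build_fsi",
    "build_fsi_stack",
    "generate_fsi_dataset",
]

#: Task-window length in samples (2.2 s at 2,048 Hz).
WINDOW_SAMPLES = 4500
#: RMS frame length in samples; 4,500 / 150 = 30 frames per trial.
RMS_FRAME_LEN = 150
#: Full scale of the acquisition in mV, mapped linearly onto 0-255 gray.
MV_RANGE = 2.5


class SegmentationError(ValueError):
    """Task window does not fit inside the recording."""


@dataclass(frozen=True)
class RmsFrame:
    """Per-channel RMS values (mV) for one 150-sample frame of one trial."""

    values: np.ndarray
    frame_index: int
    gesture: int
    repetition: int


@dataclass(frozen=True)
class FSI:
    """One featured sEMG image: pixels in [0, 1] arranged by electrode placement."""

    pixels: np.ndarray
    label: int
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def segment_task_window(rec: RawRecording, window_samples: int = WINDOW_SAMPLES) -> np.ndarray:
    """Cut the task window ``[center - w/2, center + w/2)`` from a recording."""
    half = window_samples // 2
    lo = rec.center_sample - half
    hi = lo + window_samples
    if lo < 0 or hi > rec.n_samples:
        raise SegmentationError(
            f"task window [{lo}, {hi}) outside recording of {rec.n_samples} samples"
        )
    return np.asarray(rec.signal[:, lo:hi], dtype=np.float64)


def compute_rms(
    window: np.ndarray,
    frame_len: int = RMS_FRAME_LEN,
    gesture: int = -1,
    repetition: int = -1,
) -> list[RmsFrame]:
    """Per-channel RMS over contiguous non-overlapping frames.

    The window must divide evenly into frames (no partial frames); frame ``k``
    covers samples ``[k * frame_len, (k+1) * frame_len)`` and each value is
    ``sqrt(mean(x_i^2))`` over the frame.
    """
    window = np.asarray(window, dtype=np.float64)
    n_ch, n_samp = window.shape
    if frame_len <= 0 or n_samp % frame_len != 0:
        raise ValueError(
            f"window length {n_samp} is not an integer multiple of frame_len {frame_len}"
        )
    n_frames = n_samp // frame_len
    framed = window.reshape(n_ch, n_frames, frame_len)
    rms = np.sqrt(np.mean(framed**2, axis=2))  # (n_ch, n_frames)
    return [
        RmsFrame(values=rms[:, k].copy(), frame_index=k, gesture=gesture, repetition=repetition)
        for k in range(n_frames)
    ]


def rms_matrix(window: np.ndarray, frame_len: int = RMS_FRAME_LEN) -> np.ndarray:
    """Vectorized variant of :func:`compute_rms`: returns (n_frames, n_channels)."""
    window = np.asarray(window, dtype=np.float64)
    n_ch, n_samp = window.shape
    if frame_len <= 0 or n_samp % frame_len != 0:
        raise ValueError(
            f"window length {n_samp} is not an integer multiple of frame_len {frame_len}"
        )
    framed = window.reshape(n_ch, n_samp // frame_len, frame_len)
    return np.sqrt(np.mean(framed**2, axis=2)).T


def mv_to_gray(x):
    """Affine map from the (-2.5, 2.5) mV dynamic range onto (0, 255) gray.

    Out-of-range values clamp to the endpoints; the map is monotone
    nondecreasing everywhere.
    """
    x = np.asarray(x, dtype=np.float64)
    gray = (x + MV_RANGE) * (255.0 / (2.0 * MV_RANGE))
    return np.clip(gray, 0.0, 255.0)


def _normalize_max_min(img: np.ndarray) -> np.ndarray:
    """Per-image max-min normalization to [0, 1]; constant images map to zeros."""
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def build_fsi(
    frame: RmsFrame,
    grid_shape: tuple[int, int],
    channel_map: Sequence[int] | None = None,
    provenance: dict | None = None,
) -> FSI:
    """Turn one RMS frame into a featured sEMG image.

    Pipeline: arrange the per-channel values into the 2-D grid layout
    (``channel_map[row * cols + col]`` names the frame entry for each pixel;
    identity by default), convert mV to grayscale, then max-min normalize the
    image to [0, 1].
    """
    rows, cols = grid_shape
    values = np.asarray(frame.values, dtype=np.float64)
    if channel_map is not None:
        channel_map = np.asarray(channel_map, dtype=np.intp)
        if len(channel_map) != rows * cols or len(set(channel_map.tolist())) != rows * cols:
            raise ValueError("channel_map must cover every pixel exactly once")
        values = values[channel_map]
    if values.size != rows * cols:
        raise ValueError(f"frame has {values.size} channels, expected {rows}x{cols}")
    gray = mv_to_gray(values.reshape(rows, cols))
    return FSI(
        pixels=_normalize_max_min(gray),
        label=frame.gesture,
        provenance=dict(provenance or {}, frame_index=frame.frame_index, repetition=frame.repetition),
    )


def build_fsi_stack(rms: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Vectorized FSI construction for a stack of RMS frames.

    ``rms`` is (n_frames, n_channels) with channels already selected and in
    row-major grid order; returns (n_frames, rows, cols) images in [0, 1].
    """
    rows, cols = grid_shape
    n_frames, n_ch = rms.shape
    if n_ch != rows * cols:
        raise ValueError(f"frames have {n_ch} channels, expected {rows}x{cols}")
    gray = mv_to_gray(rms)
    lo = gray.min(axis=1, keepdims=True)
    hi = gray.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (gray - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out.reshape(n_frames, rows, cols)


def generate_fsi_dataset(
    recordings: Iterable[RawRecording],
    channels: Sequence[int] | None = None,
    grid_shape: tuple[int, int] | None = None,
) -> list[FSI]:
    """Featurize a set of recordings into labelled FSIs.

    Each recording contributes 30 FSIs (one per RMS frame). ``channels``
    optionally restricts to a rectangular channel subset (e.g. one side of a
    shift split) given in full-grid indices and row-major subset order;
    ``grid_shape`` is then the subset's layout. With 144 trials (9 gestures x
    16 repetitions) the full dataset holds 4,320 FSIs.
    """
    out: list[FSI] = []
    channels_arr = None if channels is None else np.asarray(channels, dtype=np.intp)
    for rec in recordings:
        shape = grid_shape if grid_shape is not None else rec.grid.shape
        window = segment_task_window(rec)
        for frame in compute_rms(window, gesture=rec.gesture, repetition=rec.repetition):
            if channels_arr is not None:
                frame = RmsFrame(
                    values=frame.values[channels_arr],
                    frame_index=frame.frame_index,
                    gesture=frame.gesture,
                    repetition=frame.repetition,
                )
            out.append(build_fsi(frame, shape))
    return out
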