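"""2D input representations for the convolutional quality classifiers.

Every transform maps a 5000-sample segment to a fixed (80, 100) matrix:

* ``sliding_window_matrix`` — overlapping raw-sample windows (length 10,
  step 5) flattened row-major and uniformly decimated to 8000 values;
* ``stft_image`` — one-sided STFT magnitude (Hanning window 100, 50%
  overlap), frequency rows x time-frame columns resampled to the grid;
* ``fft_image`` — magnitude of the Hanning-windowed FFT of consecutive
  100-sample frames, mapped to the same grid.

The window arithmetic (999 windows x 10 samples = 9990 values) does not land
on 80 x 100 = 8000 exactly; the mapping is fixed as uniform decimation and
isolated in :func:`_to_8000` so it can be swapped wholesale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .features import STFT_WINDOW, stft_magnitude
from .segment import ECGSegment

__all__ = ["InputKind", "InputMatrix", "sliding_window_matrix", "stft_image", "fft_image"]

IMAGE_SHAPE = (80, 100)
WINDOW_LEN = 10
WINDOW_STEP = 5


class InputKind(enum.Enum):
    RAW_WINDOW = "raw_window"
    STFT = "stft"
    FFT = "fft"


@dataclass
class InputMatrix:
    values: np.ndarray
    kind: InputKind

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != IMAGE_SHAPE:
            raise ValueError(f"input matrix must be {IMAGE_SHAPE}, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("input matrix entries must be finite")


def _require_standard(seg: ECGSegment) -> np.ndarray:
    seg.require_length(5000)
    return seg.values.astype(float)


def _to_8000(flat: np.ndarray) -> np.ndarray:
    """Uniform decimation of a flat value stream to exactly 8000 entries."""
    idx = np.linspace(0, len(flat) - 1, 8000).round().astype(int)
    return flat[idx]


def _resample_axis(a: np.ndarray, n: int, axis: int) -> np.ndarray:
    """Uniform index resampling (nearest sample) of one axis to length *n*."""
    src = a.shape[axis]
    idx = np.linspace(0, src - 1, n).round().astype(int)
    return np.take(a, idx, axis=axis)


def sliding_window_matrix(seg: ECGSegment) -> InputMatrix:
    """Raw-sample representation: length-10 windows at step 5, decimated to (80, 100)."""
    x = _require_standard(seg)
    n_windows = (len(x) - WINDOW_LEN) // WINDOW_STEP + 1  # 999 at standard length
    starts = np.arange(n_windows) * WINDOW_STEP
    windows = x[starts[:, None] + np.arange(WINDOW_LEN)]
    flat = windows.reshape(-1)
    return InputMatrix(_to_8000(flat).reshape(IMAGE_SHAPE), InputKind.RAW_WINDOW)


def stft_image(seg: ECGSegment) -> InputMatrix:
    """STFT magnitude image: frequency rows (to 80) x time-frame columns (to 100)."""
    x = _require_standard(seg)
    mag = stft_magnitude(x)  # (51, 99) at standard geometry
    mag = _resample_axis(mag, IMAGE_SHAPE[0], axis=0)
    mag = _resample_axis(mag, IMAGE_SHAPE[1], axis=1)
    return InputMatrix(mag, InputKind.STFT)


def fft_image(seg: ECGSegment) -> InputMatrix:
    """Windowed-FFT image: Hanning-windowed nonoverlapping 100-sample frames.

    Rows are one-sided frequency bins resampled to 80, columns the 50 frames
    resampled to 100.
    """
    x = _require_standard(seg)
    frame = STFT_WINDOW
    n_frames = len(x) // frame
    win = np.hanning(frame)
    frames = x[: n_frames * frame].reshape(n_frames, frame) * win
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # (51, 50)
    mag = _resample_axis(mag, IMAGE_SHAPE[0], axis=0)
    mag = _resample_axis(mag, IMAGE_SHAPE[1], axis=1)
    return InputMatrix(mag, InputKind.FFT)


_TRANSFORMS = {
    InputKind.RAW_WINDOW: sliding_window_matrix,
    InputKind.STFT: stft_image,
    InputKind.FFT: fft_image,
}


def transform_segments(segments, kind: InputKind) -> np.ndarray:
    """Stack the chosen transform over segments into an (n, 80, 100) array."""
    fn = _TRANSFORMS[kind]
    if not segments:
        return np.empty((0, *IMAGE_SHAPE))
    return np.stack([fn(s).values for s in segments])
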