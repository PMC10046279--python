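"""Core containers for 20-s single-lead ECG segments and their quality labels.

A segment is a fixed-length vector of amplitudes in millivolts sampled at a
known rate (250 Hz by default, 20 s, hence 5000 samples).  Quality is a
three-way judgement: *acceptable* (nearly flawless), *unacceptable* (QRS
complexes indistinguishable somewhere, or severe artefact), *uncertain*
(mildly flawed but QRS locations discernible throughout).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np


class QualityLabel(enum.Enum):
    """Three-class ECG segment quality judgement."""

    ACCEPTABLE = "acceptable"
    UNACCEPTABLE = "unacceptable"
    UNCERTAIN = "uncertain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def from_string(cls, s: str) -> "QualityLabel":
        try:
            return cls(s.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown quality label {s!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: canonical class order used for confusion matrices and probability columns
LABEL_ORDER = (
    QualityLabel.ACCEPTABLE,
    QualityLabel.UNACCEPTABLE,
    QualityLabel.UNCERTAIN,
)


class MalformedSegmentError(ValueError):
    """Raised when a segment's length disagrees with fs x duration."""


@dataclass
class ECGSegment:
    """A single-lead ECG segment in mV.

    Parameters
    ----------
    values : ndarray of float
        Amplitudes in millivolts.  Length must equal ``fs_hz * duration_s``.
    fs_hz : int
        Sampling rate in Hz.
    label : QualityLabel, optional
        Ground-truth quality class when known (synthetic data carries it by
        construction; real data carries the expert annotation).
    segment_id : str, optional
        Identifier used in manifests, feature tables and prediction files.
    """

    values: np.ndarray
    fs_hz: int = 250
    label: Optional[QualityLabel] = None
    segment_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise MalformedSegmentError(
                f"segment values must be 1-D, got shape {self.values.shape}"
            )
        if self.fs_hz <= 0:
            raise MalformedSegmentError(f"fs_hz must be positive, got {self.fs_hz}")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fs_hz

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def require_length(self, n: int) -> None:
        """Raise :class:`MalformedSegmentError` unless the segment has *n* samples."""
        if self.n_samples != n:
            raise MalformedSegmentError(
                f"segment {self.segment_id or '<unnamed>'} has {self.n_samples} "
                f"samples, expected {n}"
            )

    def with_values(self, values: np.ndarray) -> "ECGSegment":
        """Copy of this segment with replaced sample values (metadata kept)."""
        return ECGSegment(
            values=np.asarray(values, dtype=float),
            fs_hz=self.fs_hz,
            label=self.label,
            segment_id=self.segment_id,
        )


#: default segment geometry: 250 Hz x 20 s = 5000 samples
DEFAULT_FS_HZ = 250
DEFAULT_DURATION_S = 20.0
DEFAULT_N_SAMPLES = int(DEFAULT_FS_HZ * DEFAULT_DURATION_S)
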