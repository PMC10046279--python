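"""Data cleaning for 20-s ECG segments.

Fixed three-stage chain, applied in order:

1. **Exclusion** — segments fully blank, or containing any blank run strictly
   longer than 0.5 s, never enter training or testing.  "Blank" means an
   exactly-zero or missing (NaN) sample, the two ways patient-monitor gaps
   arrive.
2. **Extreme-value zeroing** — samples beyond +/-5 mV (abrupt spikes can reach
   beyond +/-100 mV) are set to 0.
3. **Single-zero interpolation** — an isolated zero with two nonzero
   neighbours is replaced by their midpoint; longer zero runs and boundary
   zeros are left alone.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .segment import ECGSegment

__all__ = [
    "ExclusionReason",
    "PreprocessResult",
    "BatchReport",
    "filter_segment",
    "clip_extremes",
    "interpolate_single_zeros",
    "preprocess_segment",
    "preprocess_batch",
    "BLANK_RUN_MAX_S",
    "CLIP_MV",
]

#: a blank run strictly longer than this (in seconds) excludes the segment
BLANK_RUN_MAX_S = 0.5
#: magnitude cutoff in mV; samples beyond it are zeroed
CLIP_MV = 5.0


class ExclusionReason(enum.Enum):
    FULLY_BLANK = "fully_blank"
    BLANK_RUN_GT_HALF_S = "blank_run_gt_half_s"


@dataclass
class PreprocessResult:
    kept: bool
    reason: Optional[ExclusionReason] = None
    cleaned: Optional[ECGSegment] = None
    n_clipped: int = 0
    n_interpolated: int = 0


@dataclass
class BatchReport:
    n_total: int
    n_kept: int
    n_excluded: int
    n_fully_blank: int
    n_blank_run: int
    results: List[PreprocessResult]

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def _blank_mask(values: np.ndarray) -> np.ndarray:
    return (values == 0.0) | np.isnan(values)


def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True in a boolean vector."""
    if not mask.any():
        return 0
    # boundaries of runs via diff on the padded mask
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return int((ends - starts).max())


def filter_segment(
    seg: ECGSegment,
    expected_duration_s: float = 20.0,
    max_blank_run_s: float = BLANK_RUN_MAX_S,
) -> PreprocessResult:
    """Exclusion decision only: keep unless fully blank or blank for > 0.5 s.

    The threshold is strict: a run of exactly ``0.5 * fs`` blank samples
    (125 at 250 Hz) is kept; 126 is excluded.
    """
    expected = int(round(seg.fs_hz * expected_duration_s))
    seg.require_length(expected)
    mask = _blank_mask(seg.values)
    if mask.all():
        return PreprocessResult(kept=False, reason=ExclusionReason.FULLY_BLANK)
    max_run = _longest_run(mask)
    if max_run > max_blank_run_s * seg.fs_hz:
        return PreprocessResult(kept=False, reason=ExclusionReason.BLANK_RUN_GT_HALF_S)
    return PreprocessResult(kept=True, cleaned=seg)


def clip_extremes(seg: ECGSegment, clip_mv: float = CLIP_MV) -> Tuple[ECGSegment, int]:
    """Zero every sample with magnitude strictly above *clip_mv*."""
    values = np.nan_to_num(seg.values, nan=0.0)  # NaNs in kept segments act as zeros
    extreme = np.abs(values) > clip_mv
    out = np.where(extreme, 0.0, values)
    return seg.with_values(out), int(extreme.sum())


def interpolate_single_zeros(seg: ECGSegment) -> Tuple[ECGSegment, int]:
    """Replace isolated zeros (both neighbours nonzero) by the neighbour midpoint.

    Runs of two or more zeros, and zeros at either boundary, are untouched:
    those are genuine gaps for the exclusion rule, not dropouts.
    """
    v = seg.values
    if len(v) < 3:
        return seg.with_values(v.copy()), 0
    inner = v[1:-1]
    isolated = (inner == 0.0) & (v[:-2] != 0.0) & (v[2:] != 0.0)
    out = v.copy()
    idx = np.flatnonzero(isolated) + 1
    out[idx] = 0.5 * (v[idx - 1] + v[idx + 1])
    return seg.with_values(out), len(idx)


def preprocess_segment(
    seg: ECGSegment,
    expected_duration_s: float = 20.0,
    clip_mv: float = CLIP_MV,
    max_blank_run_s: float = BLANK_RUN_MAX_S,
) -> PreprocessResult:
    """Full chain on one segment: filter, then clip, then interpolate."""
    res = filter_segment(seg, expected_duration_s, max_blank_run_s)
    if not res.kept:
        return res
    clipped, n_clipped = clip_extremes(seg, clip_mv)
    cleaned, n_interp = interpolate_single_zeros(clipped)
    return PreprocessResult(
        kept=True, cleaned=cleaned, n_clipped=n_clipped, n_interpolated=n_interp
    )


def preprocess_batch(
    segments: Iterable[ECGSegment],
    expected_duration_s: float = 20.0,
    clip_mv: float = CLIP_MV,
    max_blank_run_s: float = BLANK_RUN_MAX_S,
) -> Tuple[List[ECGSegment], BatchReport]:
    """Apply the chain to a batch; return kept segments and an exclusion report."""
    results: List[PreprocessResult] = []
    kept: List[ECGSegment] = []
    n_fully = n_run = 0
    for seg in segments:
        res = preprocess_segment(seg, expected_duration_s, clip_mv, max_blank_run_s)
        results.append(res)
        if res.kept:
            kept.append(res.cleaned)  # type: ignore[arg-type]
        elif res.reason is ExclusionReason.FULLY_BLANK:
            n_fully += 1
        else:
            n_run += 1
    report = BatchReport(
        n_total=len(results),
        n_kept=len(kept),
        n_excluded=n_fully + n_run,
        n_fully_blank=n_fully,
        n_blank_run=n_run,
        results=results,
    )
    return kept, report
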