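"""Labeled synthetic ECG segments for exercising the quality pipeline.

Real patient-monitor data behind the quality classes cannot be shipped, so
this module emulates the acquisition conditions: a quasi-periodic QRS train
(sum of Gaussian lobes per beat) contaminated with baseline wander, broadband
noise, powerline interference, extreme spikes (possibly far beyond 100 mV),
pacing-like narrow spikes, and blank (zero) runs.  Every generated segment
carries a quality label assigned *by construction* from the contamination
parameters, so the full classification pipeline is testable with ground truth
known exactly.

The class thresholds are stand-ins for expert judgement, chosen from
signal-to-noise reasoning (see docs/methods.md) and exposed as module
constants so they can be tuned for other acquisition setups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .segment import ECGSegment, QualityLabel, LABEL_ORDER

__all__ = [
    "SegmentSpec",
    "InvalidSpecError",
    "generate_segment",
    "generate_dataset",
    "well_separated_dataset",
    "label_for_spec",
    "NOISE_SIGMA_ACCEPTABLE_MV",
    "NOISE_SIGMA_UNACCEPTABLE_MV",
    "WANDER_ACCEPTABLE_MV",
    "WANDER_UNACCEPTABLE_MV",
]

# Label-by-construction thresholds (mV).  With a 1 mV R peak, broadband noise
# below 0.05 mV RMS is barely visible while 0.25 mV RMS swamps the QRS onset
# and offset; wander below 0.3 mV is a subtle sway while 1.5 mV dwarfs the
# beats themselves.
NOISE_SIGMA_ACCEPTABLE_MV = 0.05
NOISE_SIGMA_UNACCEPTABLE_MV = 0.25
WANDER_ACCEPTABLE_MV = 0.3
WANDER_UNACCEPTABLE_MV = 1.5


class InvalidSpecError(ValueError):
    """Raised when a :class:`SegmentSpec` violates its invariants."""


@dataclass
class SegmentSpec:
    """Recipe for one synthetic ECG segment.

    All amplitudes are in mV; the contamination fields default to zero, i.e.
    a clean quasi-periodic QRS train.
    """

    heart_rate_bpm: float = 60.0
    fs_hz: int = 250
    duration_s: float = 20.0
    qrs_amplitude_mv: float = 1.0
    wander_amplitude_mv: float = 0.0
    wander_freq_hz: float = 0.25
    noise_sigma_mv: float = 0.0
    powerline_amplitude_mv: float = 0.0
    powerline_freq_hz: float = 60.0
    spike_count: int = 0
    spike_amplitude_mv: float = 120.0
    pacing_spike_count: int = 0
    pacing_amplitude_mv: float = 2.0
    blank_runs: List[Tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.heart_rate_bpm <= 0:
            raise InvalidSpecError(f"heart_rate_bpm must be > 0, got {self.heart_rate_bpm}")
        if self.fs_hz <= 0 or int(self.fs_hz) != self.fs_hz:
            raise InvalidSpecError(f"fs_hz must be a positive integer, got {self.fs_hz}")
        if self.duration_s <= 0:
            raise InvalidSpecError(f"duration_s must be > 0, got {self.duration_s}")
        n = self.fs_hz * self.duration_s
        if abs(n - round(n)) > 1e-9:
            raise InvalidSpecError(
                f"fs_hz x duration_s must be an integer number of samples, got {n}"
            )
        for lo, hi, name in (
            (self.wander_amplitude_mv, None, "wander_amplitude_mv"),
            (self.wander_freq_hz, None, "wander_freq_hz"),
            (self.noise_sigma_mv, None, "noise_sigma_mv"),
            (self.powerline_amplitude_mv, None, "powerline_amplitude_mv"),
        ):
            if lo < 0:
                raise InvalidSpecError(f"{name} must be nonnegative, got {lo}")
        if self.spike_count < 0 or self.pacing_spike_count < 0:
            raise InvalidSpecError("spike counts must be nonnegative")
        for start, dur in self.blank_runs:
            if start < 0 or dur < 0 or start + dur > self.duration_s:
                raise InvalidSpecError(
                    f"blank run ({start}, {dur}) must lie inside [0, {self.duration_s}]"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.duration_s))


def label_for_spec(spec: SegmentSpec) -> QualityLabel:
    """Quality label implied by the contamination parameters.

    *Unacceptable*: broadband noise or wander beyond the severe thresholds, or
    any extreme/pacing spike — artefacts that render QRS complexes
    indistinguishable somewhere in the trace.  *Acceptable*: everything at or
    below the mild thresholds with no spikes and no blank runs.  Anything in
    between — mild noise, subtle sway, short blanks — is *uncertain*.
    """
    if (
        spec.noise_sigma_mv >= NOISE_SIGMA_UNACCEPTABLE_MV
        or spec.wander_amplitude_mv >= WANDER_UNACCEPTABLE_MV
        or spec.spike_count > 0
        or spec.pacing_spike_count > 0
    ):
        return QualityLabel.UNACCEPTABLE
    if (
        spec.noise_sigma_mv <= NOISE_SIGMA_ACCEPTABLE_MV
        and spec.wander_amplitude_mv <= WANDER_ACCEPTABLE_MV
        and not spec.blank_runs
    ):
        return QualityLabel.ACCEPTABLE
    return QualityLabel.UNCERTAIN


def _beat_template_lobes(qrs_amplitude_mv: float):
    """Gaussian lobes (offset_s, width_s, amplitude_mv) approximating Q-R-S-T."""
    a = qrs_amplitude_mv
    return (
        (-0.040, 0.010, -0.10 * a),  # Q
        (0.000, 0.012, 1.00 * a),    # R
        (0.035, 0.010, -0.15 * a),   # S
        (0.180, 0.055, 0.25 * a),    # T
    )


def _qrs_train(spec: SegmentSpec, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic beat train: Gaussian-lobe beats with 2% RR jitter."""
    n = spec.n_samples
    t = np.arange(n) / spec.fs_hz
    rr = 60.0 / spec.heart_rate_bpm
    # beat times: phase offset then jittered RR intervals; cover full duration
    n_beats = int(np.ceil(spec.duration_s / rr)) + 2
    jitter = rng.normal(0.0, 0.02 * rr, size=n_beats)
    beat_times = rng.uniform(0, rr) + np.cumsum(np.full(n_beats, rr) + jitter) - rr
    beat_times = beat_times[(beat_times > -0.3) & (beat_times < spec.duration_s + 0.3)]
    x = np.zeros(n)
    for bt in beat_times:
        for off, width, amp in _beat_template_lobes(spec.qrs_amplitude_mv):
            centre = bt + off
            # Gaussians decay fast; only touch +/- 5 widths around the centre
            lo = max(0, int((centre - 5 * width) * spec.fs_hz))
            hi = min(n, int((centre + 5 * width) * spec.fs_hz) + 1)
            if hi > lo:
                x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - centre) / width) ** 2)
    return x


def generate_segment(spec: SegmentSpec) -> ECGSegment:
    """Generate one labeled synthetic ECG segment from *spec*.

    Deterministic in ``spec.seed``: the same spec always yields the identical
    sample vector.  The returned segment's label follows
    :func:`label_for_spec`.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs_hz

    x = _qrs_train(spec, rng)

    if spec.wander_amplitude_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.wander_amplitude_mv * np.sin(
            2 * np.pi * spec.wander_freq_hz * t + phase
        )
    if spec.noise_sigma_mv > 0:
        x += rng.normal(0.0, spec.noise_sigma_mv, size=n)
    if spec.powerline_amplitude_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += spec.powerline_amplitude_mv * np.sin(
            2 * np.pi * spec.powerline_freq_hz * t + phase
        )
    for _ in range(spec.spike_count):
        pos = rng.integers(0, n)
        sign = rng.choice((-1.0, 1.0))
        x[pos] = sign * spec.spike_amplitude_mv
    for _ in range(spec.pacing_spike_count):
        pos = rng.integers(0, n - 2)
        sign = rng.choice((-1.0, 1.0))
        x[pos : pos + 2] += sign * spec.pacing_amplitude_mv
    for start, dur in spec.blank_runs:
        lo = int(round(start * spec.fs_hz))
        hi = int(round((start + dur) * spec.fs_hz))
        x[lo:hi] = 0.0

    return ECGSegment(values=x, fs_hz=int(spec.fs_hz), label=label_for_spec(spec))


# ---------------------------------------------------------------------------
# dataset generation


def _counts_from_proportions(proportions: Sequence[float], n: int) -> Tuple[int, int, int]:
    """Floor each class count; any leftover goes to the last (rarest) class."""
    p = np.asarray(proportions, dtype=float)
    if p.sum() <= 0:
        raise InvalidSpecError("proportions must sum to a positive value")
    p = p / p.sum()
    floors = np.floor(p * n).astype(int)
    floors[-1] += n - floors.sum()
    return tuple(int(c) for c in floors)  # type: ignore[return-value]


def _spec_for_class(
    label: QualityLabel, rng: np.random.Generator, fs_hz: int, duration_s: float
) -> SegmentSpec:
    """Draw class-consistent contamination parameters."""
    hr = rng.uniform(50, 110)
    qrs = rng.uniform(0.7, 1.4) * rng.choice((1.0, 1.0, 1.0, -1.0))  # rare inversion
    seed = int(rng.integers(0, 2**31 - 1))
    common = dict(
        heart_rate_bpm=hr, fs_hz=fs_hz, duration_s=duration_s,
        qrs_amplitude_mv=qrs, seed=seed,
        powerline_amplitude_mv=rng.uniform(0, 0.03),
        wander_freq_hz=rng.uniform(0.15, 0.4),
    )
    if label is QualityLabel.ACCEPTABLE:
        return SegmentSpec(
            noise_sigma_mv=rng.uniform(0, 0.6 * NOISE_SIGMA_ACCEPTABLE_MV),
            wander_amplitude_mv=rng.uniform(0, 0.6 * WANDER_ACCEPTABLE_MV),
            **common,
        )
    if label is QualityLabel.UNCERTAIN:
        # mild noise and/or subtle sway, strictly between the thresholds
        mode = rng.integers(0, 3)
        noise = (
            rng.uniform(1.4 * NOISE_SIGMA_ACCEPTABLE_MV, 0.8 * NOISE_SIGMA_UNACCEPTABLE_MV)
            if mode in (0, 2)
            else rng.uniform(0, 0.6 * NOISE_SIGMA_ACCEPTABLE_MV)
        )
        wander = (
            rng.uniform(1.4 * WANDER_ACCEPTABLE_MV, 0.8 * WANDER_UNACCEPTABLE_MV)
            if mode in (1, 2)
            else rng.uniform(0, 0.6 * WANDER_ACCEPTABLE_MV)
        )
        return SegmentSpec(noise_sigma_mv=noise, wander_amplitude_mv=wander, **common)
    # unacceptable: severe noise, extreme sway, or spike artefacts
    mode = rng.integers(0, 4)
    spec = SegmentSpec(
        noise_sigma_mv=(
            rng.uniform(NOISE_SIGMA_UNACCEPTABLE_MV, 3 * NOISE_SIGMA_UNACCEPTABLE_MV)
            if mode == 0
            else rng.uniform(0, 0.6 * NOISE_SIGMA_ACCEPTABLE_MV)
        ),
        wander_amplitude_mv=(
            rng.uniform(WANDER_UNACCEPTABLE_MV, 3 * WANDER_UNACCEPTABLE_MV)
            if mode == 1
            else rng.uniform(0, 0.6 * WANDER_ACCEPTABLE_MV)
        ),
        spike_count=int(rng.integers(1, 4)) if mode == 2 else 0,
        spike_amplitude_mv=float(rng.uniform(100, 200)),
        pacing_spike_count=int(rng.integers(1, 6)) if mode == 3 else 0,
        **common,
    )
    return spec


def well_separated_dataset(
    n_per_class: Sequence[int],
    seed: int = 0,
    fs_hz: int = 250,
    duration_s: float = 20.0,
) -> List[ECGSegment]:
    """Dataset with deliberately well-separated quality classes.

    Unlike :func:`generate_dataset`, whose contamination levels form a
    realistic continuum, this sampler keeps *acceptable* nearly pristine and
    places the two flawed classes far from it but adjacent to each other —
    the regime where class membership is unambiguous from the waveform.
    Used for parameter-recovery checks.
    """
    rng = np.random.default_rng(seed)
    segments: List[ECGSegment] = []
    idx = 0
    for label, count in zip(LABEL_ORDER, n_per_class):
        for _ in range(count):
            common = dict(
                heart_rate_bpm=rng.uniform(55, 100),
                fs_hz=fs_hz,
                duration_s=duration_s,
                qrs_amplitude_mv=rng.uniform(0.8, 1.3),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if label is QualityLabel.ACCEPTABLE:
                spec = SegmentSpec(
                    noise_sigma_mv=rng.uniform(0, 0.02),
                    wander_amplitude_mv=rng.uniform(0, 0.1),
                    **common,
                )
            elif label is QualityLabel.UNCERTAIN:
                # clearly flawed (near the severe thresholds) yet below them
                spec = SegmentSpec(
                    noise_sigma_mv=rng.uniform(0.18, 0.24),
                    wander_amplitude_mv=rng.uniform(1.1, 1.45),
                    **common,
                )
            else:
                spec = SegmentSpec(
                    noise_sigma_mv=rng.uniform(0.3, 0.5),
                    wander_amplitude_mv=rng.uniform(1.6, 2.2),
                    **common,
                )
            seg = generate_segment(spec)
            assert seg.label is label
            seg.segment_id = f"seg{idx:05d}"
            idx += 1
            segments.append(seg)
    return segments


def generate_dataset(
    n_per_class: Optional[Sequence[int]] = None,
    proportions: Optional[Sequence[float]] = None,
    n_total: Optional[int] = None,
    fs_hz: int = 250,
    duration_s: float = 20.0,
    seed: int = 0,
) -> List[ECGSegment]:
    """Generate a labeled synthetic dataset.

    Either pass ``n_per_class=(n_acceptable, n_unacceptable, n_uncertain)``,
    or ``proportions`` together with ``n_total`` (counts then follow the
    largest-remainder rounding rule, leftover to the rarer classes).  Class
    counts in the output match the request exactly; order is acceptable block,
    unacceptable block, uncertain block.  Deterministic in *seed*.
    """
    if n_per_class is None:
        if proportions is None or n_total is None:
            raise InvalidSpecError("pass n_per_class, or proportions with n_total")
        n_per_class = _counts_from_proportions(proportions, n_total)
    if len(n_per_class) != 3 or any(c < 0 for c in n_per_class):
        raise InvalidSpecError(f"need three nonnegative class counts, got {n_per_class}")

    rng = np.random.default_rng(seed)
    segments: List[ECGSegment] = []
    idx = 0
    for label, count in zip(LABEL_ORDER, n_per_class):
        for _ in range(count):
            spec = _spec_for_class(label, rng, fs_hz, duration_s)
            seg = generate_segment(spec)
            assert seg.label is label, "construction rule and sampler disagree"
            seg.segment_id = f"seg{idx:05d}"
            idx += 1
            segments.append(seg)
    return segments
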