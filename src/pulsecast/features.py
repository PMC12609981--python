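"""Cardiac-cycle segmentation and the point-aligned 7-channel feature matrix.

A cycle is delimited trough-to-trough and carries four morphological
features — amplitude (peak minus trough), pulse width (boundary-to-boundary
duration), rise time (trough to peak) and fall time (peak to next boundary)
— plus pointwise first and second derivatives.  Broadcasting each cycle's
scalar features to every sample it spans, alongside the raw signal and the
two derivative channels, yields a T x 7 matrix aligned point-by-point with
the input: [raw, amplitude, width, rise, fall, d1, d2].

The boundary of cycle *i* is its opening trough, which makes
``width = rise + fall`` hold exactly for every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import SegmentationError, ValidationError
from .signal_io import SignalTrace

__all__ = [
    "CHANNEL_NAMES",
    "CycleSegmentation",
    "CycleFeatureTable",
    "FeatureMatrix",
    "segment_cycles",
    "cycle_features",
    "derivatives",
    "build_feature_matrix",
]

CHANNEL_NAMES = ("raw", "amplitude", "width", "rise", "fall", "d1", "d2")

DEFAULT_HR_RANGE = (40.0, 180.0)

# fraction of the interquartile amplitude range a trough/peak must protrude
_PROMINENCE_FRAC = 0.25


@dataclass(frozen=True)
class CycleSegmentation:
    """Trough, peak and boundary sample indices of the detected cycles.

    ``boundaries`` equals ``troughs`` under the trough-to-trough convention;
    cycle *i* spans ``[boundaries[i], boundaries[i+1])`` and contains exactly
    one peak, ``peaks[i]``.
    """

    troughs: np.ndarray
    peaks: np.ndarray
    boundaries: np.ndarray

    def __post_init__(self) -> None:
        for name in ("troughs", "peaks", "boundaries"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValidationError(f"{name} must be strictly increasing")
        if self.boundaries.size != self.peaks.size + 1:
            raise ValidationError(
                f"need len(boundaries) == n_cycles + 1, got {self.boundaries.size} "
                f"boundaries for {self.peaks.size} peaks"
            )
        # interleaving t_v,i < t_p,i < t_v,i+1
        if self.peaks.size and not (
            np.all(self.boundaries[:-1] < self.peaks)
            and np.all(self.peaks < self.boundaries[1:])
        ):
            raise ValidationError("peaks must interleave strictly between boundaries")

    @property
    def n_cycles(self) -> int:
        return int(self.peaks.size)


@dataclass(frozen=True)
class CycleFeatureTable:
    """Per-cycle amplitude (signal units) and width/rise/fall (seconds)."""

    amp: np.ndarray
    width: np.ndarray
    rise: np.ndarray
    fall: np.ndarray

    def __post_init__(self) -> None:
        for name in ("amp", "width", "rise", "fall"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if np.any(self.amp < 0):
            raise ValidationError("negative cycle amplitude")
        if np.any(self.width <= 0) or np.any(self.rise <= 0) or np.any(self.fall <= 0):
            raise ValidationError("cycle durations must be positive")

    @property
    def n_cycles(self) -> int:
        return int(self.amp.size)


@dataclass(frozen=True)
class FeatureMatrix:
    """T x 7 composite feature array; channel 0 is the input verbatim."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(CHANNEL_NAMES):
            raise ValidationError(f"feature matrix must be T x 7, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("feature matrix contains NaN/Inf")
        if self.fs <= 0:
            raise ValidationError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return int(self.values.shape[0])


def segment_cycles(
    trace: SignalTrace,
    hr_range_bpm: tuple[float, float] = DEFAULT_HR_RANGE,
) -> CycleSegmentation:
    """Detect trough-to-trough cardiac cycles.

    Troughs are local minima with a minimum separation of ``60*fs/hr_high``
    samples and prominence at least 0.25x the interquartile amplitude range;
    each consecutive trough pair delimits one cycle whose peak is the maximum
    between them.  A cycle containing more than one comparably prominent
    local maximum in most cycles indicates a dominant rhythm outside
    ``hr_range_bpm`` (aliased detection) and raises a segmentation error.
    """
    hr_low, hr_high = hr_range_bpm
    if not 0 < hr_low < hr_high:
        raise ValidationError(f"bad heart-rate range {hr_range_bpm}")
    s = trace.samples
    if trace.duration_s < 2 * 60.0 / hr_low:
        raise SegmentationError(
            f"trace too short: {trace.duration_s:.2f} s < 2 expected cycles at {hr_low} bpm"
        )

    q75, q25 = np.percentile(s, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise SegmentationError("constant signal has no extrema to segment")
    min_dist = max(1, int(round(60.0 * trace.fs / hr_high)))
    prominence = _PROMINENCE_FRAC * iqr

    troughs, _ = find_peaks(-s, distance=min_dist, prominence=prominence)
    if troughs.size < 2:
        raise SegmentationError(f"only {troughs.size} troughs detected; need >= 2")

    peaks = np.array(
        [lo + int(np.argmax(s[lo + 1 : hi])) + 1 for lo, hi in zip(troughs[:-1], troughs[1:])],
        dtype=np.int64,
    )

    # aliasing guard: a cycle spanning several true periods shows multiple
    # comparably prominent maxima; if that is the norm, detection is invalid
    ambiguous = 0
    for lo, hi in zip(troughs[:-1], troughs[1:]):
        seg = s[lo : hi + 1]
        rng = seg.max() - seg.min()
        if rng == 0:
            continue
        local_max, _ = find_peaks(seg, prominence=_PROMINENCE_FRAC * rng)
        if local_max.size > 1:
            ambiguous += 1
    if ambiguous * 2 >= peaks.size:
        raise SegmentationError(
            "ambiguous cycles: dominant rhythm appears outside the expected "
            f"heart-rate range {hr_range_bpm}"
        )

    return CycleSegmentation(troughs=troughs, peaks=peaks, boundaries=troughs)


def cycle_features(trace: SignalTrace, seg: CycleSegmentation) -> CycleFeatureTable:
    """Per-cycle amplitude and durations (seconds), boundary = opening trough."""
    s = trace.samples
    b0 = seg.boundaries[:-1].astype(np.float64)
    b1 = seg.boundaries[1:].astype(np.float64)
    p = seg.peaks.astype(np.float64)
    amp = s[seg.peaks] - s[seg.boundaries[:-1]]
    rise = (p - b0) / trace.fs
    fall = (b1 - p) / trace.fs
    # width := rise + fall keeps the identity float-exact; it equals
    # (b1 - b0)/fs by the boundary convention
    return CycleFeatureTable(amp=amp, width=rise + fall, rise=rise, fall=fall)


def derivatives(trace: SignalTrace) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives (units/s, units/s^2), same length as input.

    Central differences at interior points (exact for quadratics), one-sided
    at the two edges.
    """
    s = trace.samples
    if s.size < 3:
        raise ValidationError(f"derivatives need >= 3 samples, got {s.size}")
    fs = trace.fs
    d1 = np.empty_like(s)
    d1[1:-1] = (s[2:] - s[:-2]) * (fs / 2.0)
    d1[0] = (s[1] - s[0]) * fs
    d1[-1] = (s[-1] - s[-2]) * fs
    d2 = np.empty_like(s)
    d2[1:-1] = (s[2:] - 2.0 * s[1:-1] + s[:-2]) * fs * fs
    # the 3-point second difference needs an interior stencil; reuse the
    # nearest interior value at the edges
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d1, d2


def build_feature_matrix(
    trace: SignalTrace,
    seg: CycleSegmentation | None = None,
    hr_range_bpm: tuple[float, float] = DEFAULT_HR_RANGE,
) -> FeatureMatrix:
    """Assemble the T x 7 point-aligned composite matrix.

    Channels 1–4 hold each cycle's amp/width/rise/fall broadcast to every
    sample in ``[boundaries[i], boundaries[i+1])``; samples before the first
    boundary copy the first cycle's values and samples at/after the last
    boundary copy the last cycle's.  Channels 5–6 hold the pointwise
    derivatives.
    """
    if seg is None:
        seg = segment_cycles(trace, hr_range_bpm)
    table = cycle_features(trace, seg)
    T = len(trace)
    # cycle index per sample: searchsorted against boundaries, clipped to ends
    cyc = np.searchsorted(seg.boundaries, np.arange(T), side="right") - 1
    cyc = np.clip(cyc, 0, table.n_cycles - 1)
    d1, d2 = derivatives(trace)
    values = np.column_stack(
        [
            trace.samples,
            table.amp[cyc],
            table.width[cyc],
            table.rise[cyc],
            table.fall[cyc],
            d1,
            d2,
        ]
    )
    return FeatureMatrix(values=values, fs=trace.fs)
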