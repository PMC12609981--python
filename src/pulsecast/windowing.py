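"""Fixed-length windowing, per-channel normalization and overlap fusion.

Long records are sliced into windows of ``T`` samples every ``S`` samples
(defaults 700/100).  Predictions made window-by-window are fused back into a
full-length sequence by a Hann-tapered weighted average whose weights are
renormalized to sum to one at every covered sample, so regions covered by a
single window pass through unchanged and fusing untouched windows is an
exact identity on the covered range.  Channel statistics for z-scoring are
fitted on the training partition only, to keep held-out data out of the
normalizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FusionError, ValidationError

__all__ = ["WindowSpec", "Normalizer", "make_windows", "fit_normalizer", "fuse_overlapping", "FusedPrediction"]


@dataclass(frozen=True)
class WindowSpec:
    """Window length ``T`` and stride ``S`` in samples."""

    T: int = 700
    S: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.S <= self.T):
            raise ValidationError(f"need 0 < S <= T, got T={self.T}, S={self.S}")

    def n_windows(self, length: int) -> int:
        if length < self.T:
            raise ValidationError(f"signal length {length} shorter than window T={self.T}")
        return (length - self.T) // self.S + 1

    def starts(self, length: int) -> np.ndarray:
        return np.arange(self.n_windows(length)) * self.S


def make_windows(x: np.ndarray, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Slice rows of ``x`` (shape (L,) or (L, C)) into overlapping windows.

    Returns ``(windows, starts)`` where windows has shape (N, T) or
    (N, T, C) with ``N = floor((L - T)/S) + 1``; no padding is applied.
    """
    x = np.asarray(x)
    starts = spec.starts(x.shape[0])
    windows = np.stack([x[s : s + spec.T] for s in starts])
    return windows, starts


@dataclass(frozen=True)
class Normalizer:
    """Per-channel affine (z-score) parameters for inputs and target.

    ``normalize_*`` maps to zero mean / unit variance using statistics
    fitted on the training partition; ``denormalize_y`` restores physical
    units before metrics are computed.
    """

    x_shift: np.ndarray
    x_scale: np.ndarray
    y_shift: float
    y_scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_shift", np.asarray(self.x_shift, dtype=np.float64))
        object.__setattr__(self, "x_scale", np.asarray(self.x_scale, dtype=np.float64))
        if np.any(self.x_scale <= 0) or self.y_scale <= 0:
            raise ValidationError("normalizer scales must be strictly positive")

    def normalize_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.x_shift) / self.x_scale

    def normalize_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=np.float64) - self.y_shift) / self.y_scale

    def denormalize_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=np.float64) * self.y_scale + self.y_shift

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "x_shift": self.x_shift.tolist(),
                "x_scale": self.x_scale.tolist(),
                "y_shift": self.y_shift,
                "y_scale": self.y_scale,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Normalizer":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            x_shift=np.asarray(d["x_shift"]),
            x_scale=np.asarray(d["x_scale"]),
            y_shift=float(d["y_shift"]),
            y_scale=float(d["y_scale"]),
        )


def _channel_stats(a: np.ndarray, axis) -> tuple[np.ndarray, np.ndarray]:
    mean = a.mean(axis=axis)
    sd = a.std(axis=axis, ddof=0)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            "zero-variance channel(s) in normalizer fit; scale set to 1",
            stacklevel=3,
        )
        sd = np.where(degenerate, 1.0, sd)
    return mean, sd


def fit_normalizer(training_x: np.ndarray, training_y: np.ndarray) -> Normalizer:
    """Fit per-channel z-score parameters on training samples only.

    ``training_x`` is (L, C); ``training_y`` is (L,).  A zero-variance
    channel gets scale 1 with a warning.
    """
    training_x = np.asarray(training_x, dtype=np.float64)
    training_y = np.asarray(training_y, dtype=np.float64)
    if training_x.size == 0 or training_y.size == 0:
        raise ValidationError("cannot fit a normalizer on empty training data")
    if training_x.ndim != 2:
        raise ValidationError(f"training_x must be 2-D (L, C), got shape {training_x.shape}")
    x_shift, x_scale = _channel_stats(training_x, axis=0)
    y_shift, y_scale = _channel_stats(training_y, axis=None)
    return Normalizer(
        x_shift=x_shift, x_scale=x_scale, y_shift=float(y_shift), y_scale=float(y_scale)
    )


@dataclass(frozen=True)
class FusedPrediction:
    """Full-length fused sequence plus the mask of covered samples."""

    values: np.ndarray
    covered: np.ndarray

    @property
    def covered_slice(self) -> slice:
        idx = np.flatnonzero(self.covered)
        return slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0)


def _taper(T: int) -> np.ndarray:
    # Hann evaluated on interior points only, so every weight is strictly
    # positive and single-window regions renormalize to exactly 1
    n = np.arange(1, T + 1)
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * n / (T + 1))


def fuse_overlapping(
    window_predictions: list[tuple[int, np.ndarray]],
    L: int,
    spec: WindowSpec,
) -> FusedPrediction:
    """Merge overlapping window predictions into one sequence of length ``L``.

    Each covered sample is the Hann-taper-weighted average of all windows
    covering it, with weights renormalized to sum to one.  Gaps in coverage
    raise a fusion error; trailing samples beyond the last window are
    reported uncovered.
    """
    if not window_predictions:
        raise ValidationError("no window predictions to fuse")
    acc = np.zeros(L, dtype=np.float64)
    wsum = np.zeros(L, dtype=np.float64)
    taper = _taper(spec.T)
    last_end = 0
    for start, values in sorted(window_predictions, key=lambda p: p[0]):
        values = np.asarray(values, dtype=np.float64).reshape(-1)
        if values.size != spec.T:
            raise ValidationError(
                f"window at {start} has length {values.size}, expected T={spec.T}"
            )
        if start < 0 or start + spec.T > L:
            raise ValidationError(f"window [{start}, {start + spec.T}) outside [0, {L})")
        acc[start : start + spec.T] += taper * values
        wsum[start : start + spec.T] += taper
        last_end = max(last_end, start + spec.T)

    covered = wsum > 0
    gaps = np.flatnonzero(~covered[:last_end])
    if gaps.size:
        runs = np.split(gaps, np.flatnonzero(np.diff(gaps) > 1) + 1)
        desc = ", ".join(f"[{r[0]}, {r[-1] + 1})" for r in runs)
        raise FusionError(f"coverage gap(s) in fused prediction: {desc}")

    out = np.zeros(L, dtype=np.float64)
    out[covered] = acc[covered] / wsum[covered]
    return FusedPrediction(values=out, covered=covered)
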