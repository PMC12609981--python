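"""Three-step noise reduction for pulsatile waveforms.

The chain is: (1) spike removal — samples whose first difference is an
outlier on a robust (MAD) scale are replaced by cubic-spline interpolation
through their unflagged neighbours; (2) baseline-drift removal — the
baseline is estimated as the mean of grayscale opening and closing with a
flat structuring element spanning a bit more than one cardiac cycle and
subtracted; (3) band-pass filtering — a zero-phase (forward–backward)
Butterworth filter, 0.5–10 Hz by default, suppresses residual drift below
the cardiac band and high-frequency electronic noise above it.

All three stages preserve signal length and, being offline, are applied
with zero phase so the pulse morphology is not shifted in time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import grey_closing, grey_opening
from scipy.signal import butter, sosfiltfilt

from .errors import QualityError, ValidationError
from .signal_io import SignalTrace

__all__ = ["DenoiseConfig", "despike", "remove_baseline", "bandpass", "denoise_pipeline"]


@dataclass(frozen=True)
class DenoiseConfig:
    """Parameters of the three-stage chain.

    spike_mad_k : threshold multiplier on the MAD of first differences.
    spike_pad : samples by which each flagged run is widened on both sides.
    morph_window_s : flat structuring-element length in seconds; should
        exceed one cardiac cycle (1.5 s covers resting heart rates).
    bp_low_hz, bp_high_hz, bp_order : Butterworth band edges and order.
    """

    spike_mad_k: float = 6.0
    spike_pad: int = 2
    morph_window_s: float = 1.5
    bp_low_hz: float = 0.5
    bp_high_hz: float = 10.0
    bp_order: int = 4

    def __post_init__(self) -> None:
        if self.spike_mad_k <= 0:
            raise ValidationError(f"spike_mad_k must be > 0, got {self.spike_mad_k}")
        if self.spike_pad < 0:
            raise ValidationError(f"spike_pad must be >= 0, got {self.spike_pad}")
        if self.morph_window_s <= 0:
            raise ValidationError(f"morph_window_s must be > 0, got {self.morph_window_s}")
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise ValidationError(
                f"need 0 < bp_low_hz < bp_high_hz, got ({self.bp_low_hz}, {self.bp_high_hz})"
            )
        if self.bp_order < 1:
            raise ValidationError(f"bp_order must be >= 1, got {self.bp_order}")


def despike(trace: SignalTrace, cfg: DenoiseConfig | None = None) -> SignalTrace:
    """Replace abrupt spikes by cubic-spline interpolation.

    A sample is flagged when either adjacent first difference exceeds
    ``spike_mad_k`` times the median absolute deviation of all first
    differences; flagged runs are widened by ``spike_pad`` samples.  An
    all-but-constant signal (MAD = 0) is returned unchanged.
    """
    cfg = cfg or DenoiseConfig()
    s = trace.samples
    if s.size < 8:
        raise ValidationError(f"despike needs >= 8 samples, got {s.size}")

    d = np.diff(s)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0.0:
        return trace

    big = np.abs(d - med) > cfg.spike_mad_k * mad
    flagged = np.zeros(s.size, dtype=bool)
    # a large diff d[i] implicates both of its endpoints i and i+1
    flagged[:-1] |= big
    flagged[1:] |= big
    if cfg.spike_pad > 0 and flagged.any():
        idx = np.flatnonzero(flagged)
        for i in idx:
            lo = max(0, i - cfg.spike_pad)
            hi = min(s.size, i + cfg.spike_pad + 1)
            flagged[lo:hi] = True

    if not flagged.any():
        return trace
    if flagged.mean() > 0.5:
        raise QualityError(
            f"{flagged.mean():.0%} of samples flagged as spikes; signal unusable"
        )

    good = np.flatnonzero(~flagged)
    out = s.copy()
    spline = CubicSpline(good, s[good])
    bad = np.flatnonzero(flagged)
    out[bad] = spline(bad)
    return trace.with_samples(out)


def remove_baseline(trace: SignalTrace, cfg: DenoiseConfig | None = None) -> SignalTrace:
    """Subtract the morphological baseline estimate.

    The baseline is the mean of grayscale opening and closing with a flat
    structuring element of ``round(morph_window_s * fs)`` samples; averaging
    the two treats peaks and troughs symmetrically so pulse amplitude is not
    biased.  For a monotone input opening = closing = the input, hence pure
    slow ramps are removed entirely.
    """
    cfg = cfg or DenoiseConfig()
    size = int(round(cfg.morph_window_s * trace.fs))
    if size < 3:
        raise ValidationError(
            f"structuring element of {size} samples too short (need >= 3); "
            f"increase morph_window_s"
        )
    if size > len(trace):
        raise ValidationError(
            f"structuring element ({size} samples) longer than signal ({len(trace)})"
        )
    s = trace.samples
    baseline = 0.5 * (grey_opening(s, size=size) + grey_closing(s, size=size))
    return trace.with_samples(s - baseline)


def bandpass(trace: SignalTrace, cfg: DenoiseConfig | None = None) -> SignalTrace:
    """Zero-phase Butterworth band-pass of the configured order and band."""
    cfg = cfg or DenoiseConfig()
    nyq = trace.fs / 2.0
    if not cfg.bp_high_hz < nyq:
        raise ValidationError(
            f"bp_high_hz={cfg.bp_high_hz} must be below Nyquist ({nyq} Hz at fs={trace.fs})"
        )
    sos = butter(
        cfg.bp_order,
        [cfg.bp_low_hz, cfg.bp_high_hz],
        btype="bandpass",
        fs=trace.fs,
        output="sos",
    )
    padlen = min(3 * (2 * sos.shape[0] + 1), len(trace) - 1)
    out = sosfiltfilt(sos, trace.samples, padlen=padlen)
    return trace.with_samples(out)


def denoise_pipeline(trace: SignalTrace, cfg: DenoiseConfig | None = None) -> SignalTrace:
    """despike -> remove_baseline -> bandpass, in that order."""
    cfg = cfg or DenoiseConfig()
    return bandpass(remove_baseline(despike(trace, cfg), cfg), cfg)
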