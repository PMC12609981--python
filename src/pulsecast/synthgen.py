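"""Seeded generator of paired physiological-like waveforms with ground truth.

The source emulates a pulsatile optical/pressure signal: a train of
asymmetric per-beat templates (raised-cosine rise, exponential-like fall,
optional dicrotic-notch bump) whose beat periods jitter around the mean
heart rate, amplitude-modulated by a slow respiratory sinusoid, plus
baseline drift, Poisson spike artifacts and white noise.  The target is a
known transfer of the source — pure delay, first-order smoothing, gain and
a mild quadratic term, plus independent noise — so a model trained on the
pair can be scored against an exactly known mapping.

Every draw is keyed to the config seed (per-record streams are derived from
one root seed), so identical configs regenerate byte-identical data.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .errors import ValidationError
from .features import CycleSegmentation
from .signal_io import PairedRecord, SignalTrace, write_trace

__all__ = [
    "SynthConfig",
    "TransferConfig",
    "gen_components",
    "gen_source",
    "derive_target",
    "make_dataset",
    "make_paired",
]


@dataclass(frozen=True)
class TransferConfig:
    """Source -> target mapping: delay, smoothing, gain, mild nonlinearity."""

    delay_s: float = 0.2
    smoothing_tau_s: float = 0.05
    gain: float = 1.0
    nonlin_coeff: float = 0.1
    target_noise_sd: float = 0.02


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the simulator.

    Defaults emulate a resting adult at 70 bpm sampled at 50 Hz: 4% per-beat
    period jitter, respiratory amplitude modulation at 0.25 Hz (15% depth),
    slow baseline drift, sparse spike artifacts and light white noise on a
    unit-amplitude pulse train.
    """

    fs: float = 50.0
    duration_s: float = 60.0
    hr_bpm: float = 70.0
    hr_jitter: float = 0.04
    rise_frac: float = 0.3
    notch_depth: float = 0.15
    resp_hz: float = 0.25
    resp_depth: float = 0.15
    drift_amp: float = 0.3
    spike_rate_hz: float = 0.05
    spike_amp: float = 5.0
    noise_sd: float = 0.02
    transfer: TransferConfig = field(default_factory=TransferConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 20.0:
            raise ValidationError(f"fs must exceed 20 Hz (band support), got {self.fs}")
        if not 40.0 <= self.hr_bpm <= 180.0:
            raise ValidationError(f"hr_bpm must be in [40, 180], got {self.hr_bpm}")
        if not 0.0 < self.rise_frac < 1.0:
            raise ValidationError(f"rise_frac must be in (0, 1), got {self.rise_frac}")
        for name in ("hr_jitter", "notch_depth", "resp_depth", "drift_amp", "spike_rate_hz", "spike_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")


def _beat_template(n: int, rise_frac: float, notch_depth: float) -> np.ndarray:
    """One beat of ``n`` samples: raised-cosine rise, decaying fall, notch."""
    u = np.arange(n) / n
    pulse = np.empty(n)
    rise = u < rise_frac
    pulse[rise] = 0.5 - 0.5 * np.cos(np.pi * u[rise] / rise_frac)
    v = (u[~rise] - rise_frac) / (1.0 - rise_frac)
    # smooth decay that lands near zero at the next beat onset
    pulse[~rise] = np.exp(-3.0 * v) * (1.0 - v)
    if notch_depth > 0:
        notch_pos = rise_frac + 0.25 * (1.0 - rise_frac)
        pulse += notch_depth * np.exp(-0.5 * ((u - notch_pos) / 0.04) ** 2)
    return pulse


def gen_components(cfg: SynthConfig) -> dict:
    """Simulate the source and return its constituents separately.

    Returns a dict with the clean physiological pulse train (``clean``), the
    sensor artifacts (``drift``, ``spikes``, ``noise``), the assembled noisy
    ``source`` trace and the true ``segmentation``.  The clean component is
    the shared physiology a paired sensor would also see; drift, spikes and
    white noise are local to this sensor.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = int(round(cfg.duration_s * cfg.fs))
    mean_period = 60.0 / cfg.hr_bpm * cfg.fs  # samples

    # first full beat starts after a short lead-in carrying the tail of a
    # virtual previous beat, so the opening trough is an interior minimum
    # that a detector can actually find
    lead = max(4, int(round(0.5 * mean_period)))
    onsets = [lead]
    while True:
        period = mean_period * (1.0 + cfg.hr_jitter * rng.standard_normal())
        period = max(period, 0.4 * mean_period)
        nxt = onsets[-1] + int(round(period))
        if nxt >= n_total:
            break
        onsets.append(nxt)

    t = np.arange(n_total) / cfg.fs
    resp_gain = 1.0 + cfg.resp_depth * np.sin(2.0 * np.pi * cfg.resp_hz * t)
    clean = np.zeros(n_total)
    peaks = []
    virtual = _beat_template(int(round(mean_period)), cfg.rise_frac, cfg.notch_depth)
    clean[:lead] = virtual[-lead:] * resp_gain[0]
    for k, onset in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < len(onsets) else n_total
        n_beat = end - onset
        if n_beat < 4:
            continue
        beat = _beat_template(n_beat, cfg.rise_frac, cfg.notch_depth)
        clean[onset:end] = beat * resp_gain[onset]
        peaks.append(onset + int(np.argmax(beat)))

    troughs = np.asarray(onsets, dtype=np.int64)
    peaks_arr = np.asarray(peaks, dtype=np.int64)
    # true cycles: trough-to-trough; drop the unterminated final beat's peak
    seg = CycleSegmentation(
        troughs=troughs,
        peaks=peaks_arr[: troughs.size - 1],
        boundaries=troughs,
    )

    drift = cfg.drift_amp * np.sin(2.0 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    drift += cfg.drift_amp * 0.5 * (t / t[-1])
    noise = cfg.noise_sd * rng.standard_normal(n_total)
    spikes = np.zeros(n_total)
    n_spikes = rng.poisson(cfg.spike_rate_hz * cfg.duration_s)
    if n_spikes > 0:
        pos = rng.integers(0, n_total, size=n_spikes)
        spikes[pos] = cfg.spike_amp * rng.choice([-1.0, 1.0], size=n_spikes)

    samples = clean + drift + spikes + noise
    trace = SignalTrace(samples=samples, fs=cfg.fs, label="synthetic-source", units="a.u.")
    return {
        "clean": SignalTrace(samples=clean, fs=cfg.fs, label="clean-source", units="a.u."),
        "drift": drift,
        "spikes": spikes,
        "noise": noise,
        "source": trace,
        "segmentation": seg,
    }


def gen_source(cfg: SynthConfig) -> tuple[SignalTrace, CycleSegmentation]:
    """Simulate the source waveform and return its true segmentation.

    Beat onsets are the troughs/boundaries; the per-beat template maximum is
    the peak.  With jitter, noise and drift all zero, beat spacing is
    exactly ``round(60/hr_bpm * fs)`` samples.
    """
    comps = gen_components(cfg)
    return comps["source"], comps["segmentation"]


def derive_target(source: SignalTrace, cfg: SynthConfig) -> SignalTrace:
    """Apply the known transfer: delay -> smoothing -> gain + quadratic + noise."""
    tr = cfg.transfer
    delay = int(round(tr.delay_s * source.fs))
    if delay >= len(source):
        raise ValidationError(
            f"delay of {delay} samples exceeds signal length {len(source)}"
        )
    s = source.samples
    delayed = np.concatenate([np.full(delay, s[0]), s[: len(s) - delay]])

    if tr.smoothing_tau_s > 0:
        a = float(np.exp(-1.0 / (tr.smoothing_tau_s * source.fs)))
        smoothed = lfilter([1.0 - a], [1.0, -a], delayed)
    else:
        smoothed = delayed

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7A46]))
    samples = (
        tr.gain * smoothed
        + tr.nonlin_coeff * smoothed**2
        + tr.target_noise_sd * rng.standard_normal(len(s))
    )
    return SignalTrace(samples=samples, fs=source.fs, label="synthetic-target", units="a.u.")


def make_paired(cfg: SynthConfig) -> tuple[PairedRecord, dict]:
    """One paired record: noisy source, target transferred from the clean pulse.

    The transfer acts on the shared physiological component (the clean pulse
    train), not on the source's sensor artifacts: drift, spikes and white
    noise are local to the measuring channel, while the target carries its
    own independent noise.  Ground-truth components and segmentation are
    returned alongside.
    """
    comps = gen_components(cfg)
    target = derive_target(comps["clean"], cfg)
    record = PairedRecord(
        source=comps["source"],
        target=target,
        meta={"seed": cfg.seed, "transfer": asdict(cfg.transfer)},
    )
    return record, comps


def make_dataset(
    cfg: SynthConfig,
    n_records: int,
    out_dir: str | Path | None = None,
) -> tuple[list[PairedRecord], dict]:
    """Generate ``n_records`` seeded paired records plus a provenance manifest.

    Per-record seeds are derived deterministically from the root seed, so
    regenerating from the manifest reproduces every record exactly.  When
    ``out_dir`` is given, each pair is written as CSV with JSON sidecars and
    the manifest as ``manifest.json``.
    """
    if n_records < 1:
        raise ValidationError(f"n_records must be >= 1, got {n_records}")
    records: list[PairedRecord] = []
    manifest: dict = {"config": _config_dict(cfg), "n_records": n_records, "records": []}
    for i in range(n_records):
        rec_seed = int(np.random.SeedSequence([cfg.seed, i]).generate_state(1)[0] % (2**31))
        rec_cfg = replace(cfg, seed=rec_seed)
        record, comps = make_paired(rec_cfg)
        seg = comps["segmentation"]
        meta = {
            "index": i,
            "seed": rec_seed,
            "true_troughs": seg.troughs.tolist(),
            "true_peaks": seg.peaks.tolist(),
            "transfer": asdict(rec_cfg.transfer),
        }
        records.append(PairedRecord(source=record.source, target=record.target, meta=meta))
        manifest["records"].append(meta)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import json

        for rec in records:
            i = rec.meta["index"]
            write_trace(rec.source, out_dir / f"record{i:03d}_source.csv")
            write_trace(rec.target, out_dir / f"record{i:03d}_target.csv")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return records, manifest


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    return d
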