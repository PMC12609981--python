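"""Exception hierarchy shared across the pipeline stages."""


class PulsecastError(Exception):
    """Base class for all package errors."""


class FormatError(PulsecastError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(PulsecastError):
    """A trace or matrix violates a domain invariant (NaN, non-positive fs, ...)."""


class PairingError(PulsecastError):
    """Source and target traces cannot form a paired record."""


class TraceIOError(PulsecastError):
    """Reading or writing a trace failed at the filesystem level."""


class QualityError(PulsecastError):
    """A signal is too corrupted to process (e.g. mostly spikes)."""


class SegmentationError(PulsecastError):
    """Cardiac-cycle segmentation failed or produced no usable cycles."""


class FusionError(PulsecastError):
    """Overlap fusion found a coverage gap."""


class TrainingError(PulsecastError):
    """Training diverged or was given unusable data."""


class ConfigError(PulsecastError):
    """A configuration block failed schema validation."""


class StageError(PulsecastError):
    """A pipeline stage is missing a prerequisite artifact."""
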