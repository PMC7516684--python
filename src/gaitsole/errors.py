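"""Exception hierarchy for the gaitsole pipeline."""


class GaitsoleError(Exception):
    """Base class for all gaitsole errors."""


class FormatError(GaitsoleError):
    """A file does not match the declared CSV/JSON dialect (e.g. missing column)."""


class DataValidationError(GaitsoleError):
    """Data violates a physical or structural invariant (e.g. negative pressure)."""


class EmptyInputError(GaitsoleError):
    """A file or series contains no samples."""


class AlignmentError(GaitsoleError):
    """Bilateral streams cannot be aligned (sampling-rate or window mismatch)."""


class MetadataError(GaitsoleError):
    """Trial or cohort metadata is missing or inconsistent."""


class ConfigError(GaitsoleError):
    """A simulation or segmentation configuration is invalid."""


class SegmentationError(GaitsoleError):
    """Phase/TUG segmentation failed (e.g. no gait detected in the trial)."""


class InputError(GaitsoleError):
    """A statistical routine received an unusable sample (too small, non-finite)."""
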