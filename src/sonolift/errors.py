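"""Exception hierarchy shared across the toolkit."""


class SonoliftError(Exception):
    """Base class for all sonolift errors."""


class FormatError(SonoliftError):
    """A file does not conform to the declared dialect (missing headers, bad columns)."""


class StructureError(SonoliftError):
    """A parsed file is structurally inconsistent (ragged frame counts, duplicate markers)."""


class ContractError(SonoliftError):
    """Inputs to an operation violate its length/shape contract."""


class GeometryError(SonoliftError):
    """Degenerate geometry (e.g. coincident barbell endpoints after projection)."""


class CalibrationError(SonoliftError):
    """A static calibration capture cannot yield a reference value."""


class SegmentationError(SonoliftError):
    """Repetition segmentation received unusable input."""


class SummaryError(SonoliftError):
    """A session cannot be summarized (e.g. no retained repetitions)."""


class SampleSizeError(SonoliftError):
    """A statistical test received fewer observations than it requires."""


class PairingError(SonoliftError):
    """Paired samples have mismatched lengths."""


class DegenerateTableError(SonoliftError):
    """A contingency table has a zero marginal."""


class SingularDesignError(SonoliftError):
    """A linear-model design matrix is rank deficient."""
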