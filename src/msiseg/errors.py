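"""Exception hierarchy for msiseg."""


class MSISegError(Exception):
    """Base class for all msiseg errors."""


class MaskFormatError(MSISegError):
    """The input file is not a readable NIfTI mask."""


class MetadataError(MSISegError):
    """The NIfTI header carries unusable metadata (e.g. non-positive spacing)."""


class IncompatibleVolumesError(MSISegError):
    """Reference and test volumes disagree in shape, spacing or slice axis."""


class EmptyStructureError(MSISegError):
    """An operation that requires a non-empty mask or contour received an empty one."""


class ConfigurationError(MSISegError):
    """Invalid hyperparameter or unknown weighting identifier."""


class ShapeSpecError(MSISegError):
    """A synthetic shape specification does not fit its grid or is malformed."""


class DegenerateOutputError(MSISegError):
    """A perturbation emptied the mask or otherwise produced an unusable result."""
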