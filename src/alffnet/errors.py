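"""Exception hierarchy for alffnet."""


class AlffnetError(Exception):
    """Base class for all alffnet errors."""


class ParameterError(AlffnetError, ValueError):
    """A parameter is outside its documented range."""


class GridMismatchError(AlffnetError, ValueError):
    """Two volumes do not share shape and affine."""


class ROIOutsideBrainError(AlffnetError, ValueError):
    """A seed ROI resolves to no voxels inside the brain mask."""


class DegenerateInputError(AlffnetError, ValueError):
    """Input is degenerate for the requested statistic (constant series,
    zero mask mean, empty mask, ...)."""


class CollinearDesignError(AlffnetError, ValueError):
    """The design/nuisance matrix is rank deficient."""


class ConfigurationError(AlffnetError, ValueError):
    """A study configuration value is invalid or inconsistent."""


class ValidationError(AlffnetError, ValueError):
    """Study inputs failed validation."""
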