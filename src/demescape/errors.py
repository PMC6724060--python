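"""Exception hierarchy.

Everything raised on purpose by demescape derives from :class:`DemescapeError`
so callers can catch package errors without swallowing programming mistakes.
"""


class DemescapeError(Exception):
    """Base class for all demescape errors."""


class FormatError(DemescapeError):
    """A file does not conform to the expected on-disk format."""


class ConfigurationError(DemescapeError):
    """A configuration value is inconsistent or produces an empty model."""


class ParameterError(DemescapeError):
    """A numeric parameter is outside its valid domain."""


class PlacementError(DemescapeError):
    """A sampling locality refers to a cell that is not a suitable deme."""


class SamplingError(DemescapeError):
    """A genealogy was requested from a deme with no individuals."""


class AlignmentError(DemescapeError):
    """Sequences that should be aligned have inconsistent lengths."""


class DegenerateGroupError(DemescapeError):
    """A statistic requires >=2 sequences per group and a group is smaller."""


class EmptyPosteriorError(DemescapeError):
    """An epsilon-rejection step retained zero simulations."""
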