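"""Exception hierarchy for methcap.

All toolkit-raised errors derive from :class:`MethcapError` so callers (and
the CLI) can distinguish data/usage problems from genuine bugs.
"""


class MethcapError(Exception):
    """Base class for all methcap errors."""


class FormatError(MethcapError, ValueError):
    """A file does not conform to its declared format."""


class CoordinateError(MethcapError, ValueError):
    """An interval or position falls outside the attached sequence."""


class DataError(MethcapError, ValueError):
    """Input records are internally inconsistent."""


class ConfigurationError(MethcapError, ValueError):
    """A run was configured with impossible or missing parameters."""


class PackingError(ConfigurationError):
    """Requested non-overlapping placements do not fit in the genome."""


class ContractViolationError(MethcapError, ValueError):
    """An operation was called with arguments violating its contract."""


class UndefinedStatisticError(DataError):
    """A statistic (e.g. a correlation) is undefined for the given data."""
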