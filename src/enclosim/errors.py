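"""Exception hierarchy shared across the package."""


class EnclosimError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(EnclosimError):
    """An input file is malformed (missing columns, bad extension)."""


class ValidationError(EnclosimError):
    """A parsed record violates an invariant (negative count, bad sum)."""


class DegenerateTestError(EnclosimError):
    """A statistic is undefined for the given counts (e.g. monomorphic HWE test)."""


class AlignmentError(EnclosimError):
    """Observed records do not cover a common time-point grid across rooms."""


class ScheduleError(EnclosimError):
    """A demography schedule is internally inconsistent or infeasible."""


class ExtinctionError(EnclosimError):
    """A simulated room lost all individuals of one sex before a breeding step."""


class DegenerateWeightsError(EnclosimError):
    """All candidate parents have zero sampling weight."""
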