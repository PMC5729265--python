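"""Exception hierarchy for methrda.

All package errors derive from :class:`MethRdaError` so callers (and the
command-line interface) can catch one base class and map it to a clean
non-zero exit.
"""


class MethRdaError(Exception):
    """Base class for all methrda errors."""


class FormatError(MethRdaError):
    """Malformed or non-numeric input data (files, tables, region strings)."""


class RegionError(MethRdaError):
    """A genomic region cannot be analyzed."""


class EmptyRegionError(RegionError):
    """The region contains no annotated CpGs (or names an absent chromosome)."""


class RegionTooSmallError(RegionError):
    """The region resolves to fewer CpGs than the analyzable minimum."""


class RankError(MethRdaError):
    """Design matrix is rank deficient after encoding and centering."""


class InsufficientSamplesError(MethRdaError):
    """Too few samples for the requested number of model degrees of freedom."""


class ParameterError(MethRdaError):
    """An invalid tuning parameter (permutation count, component count, ...)."""


class InfeasibleError(MethRdaError):
    """A sampling request cannot be satisfied (no eligible window/placement)."""
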