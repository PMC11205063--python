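"""Exception hierarchy for the pipeline.

Fatal conditions (empty datasets, infeasible graphs, undefined statistics)
raise subclasses of :class:`FluencyNetError`; recoverable anomalies are
logged, never raised.
"""


class FluencyNetError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(FluencyNetError):
    """An input file is missing a required column or has a bad dialect."""


class IntegrityError(FluencyNetError):
    """An input violates a structural invariant (e.g. duplicate keys)."""


class EmptyResultError(FluencyNetError):
    """A filtering step removed everything, leaving nothing to analyze."""


class UndefinedStatisticError(FluencyNetError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
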