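"""Error taxonomy shared across the pipeline.

Exit-code mapping used by the CLI:
  ConfigurationError -> 2, DataError -> 3, NumericalError -> 4.
"""


class ExcessRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ExcessRiskError):
    """Invalid configuration (bad parameter values, incomplete grids, ...)."""


class DataError(ExcessRiskError):
    """Malformed or inconsistent input data (duplicate ids, missing cells, ...)."""


class NumericalError(ExcessRiskError):
    """A numerical procedure failed (non-convergence, degenerate likelihood)."""
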