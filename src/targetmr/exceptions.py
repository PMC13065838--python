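"""Exception hierarchy.

All errors raised by the package derive from :class:`TargetMRError` so
callers (and the CLI) can distinguish configuration problems, malformed
input tables and statistical preconditions from genuine bugs.
"""


class TargetMRError(Exception):
    """Base class for all package errors."""


class ConfigError(TargetMRError, ValueError):
    """Invalid configuration value (threshold, prior, simulation setting)."""


class FormatError(TargetMRError, ValueError):
    """Malformed input table (missing column, invariant violation)."""


class InsufficientInstrumentsError(TargetMRError, ValueError):
    """An estimator was asked to fit fewer SNPs than it requires."""


class DegenerateInstrumentError(TargetMRError, ValueError):
    """Instrument set carries no exposure signal (e.g. all beta_exp == 0)."""
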