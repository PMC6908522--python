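"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`CoexmetaError` naming the offending
input, so the orchestrator can halt with the stage and offender attached.
"""


class CoexmetaError(Exception):
    """Base class for all errors raised by coexmeta."""


class ConfigurationError(CoexmetaError):
    """An invalid configuration value; the message names the field."""


class FormatError(CoexmetaError):
    """A malformed external file; the message carries the offender/line."""


class NormalizationError(CoexmetaError):
    """Degenerate calibration or transform; the message names the sample."""


class StatisticsError(CoexmetaError):
    """Invalid input to a statistical routine."""


class ConsensusError(CoexmetaError):
    """Probe/gene harmonization or cross-study table construction failed."""


class NetworkError(CoexmetaError):
    """Similarity/threshold/graph construction failed."""


class SurvivalError(CoexmetaError):
    """Survival-analysis input is degenerate or a fit did not converge."""
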