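"""Exception hierarchy for liwgs."""


class LiwgsError(Exception):
    """Base class for all liwgs-specific errors."""


class InvalidDesignError(LiwgsError, ValueError):
    """A sequencing library design with impossible parameters (e.g. zero genome size)."""


class ValidationError(LiwgsError, ValueError):
    """An argument outside its documented domain."""


class UnattainablePowerError(LiwgsError, ValueError):
    """The requested detection power cannot be reached for the given event frequency."""


class ParseError(LiwgsError, ValueError):
    """A malformed alignment or annotation record; the message names the offending line."""


class EmptyProfileError(LiwgsError, ValueError):
    """No eligible read pairs from which to build an insert-size profile."""


class InfeasibleError(LiwgsError, ValueError):
    """A downsampling target exceeding the available mapped reads."""


class ConfigError(LiwgsError, ValueError):
    """An invalid simulation or caller configuration (e.g. overlapping implanted events)."""


class EmptyTrackError(LiwgsError, ValueError):
    """A coverage track with no fragments to normalise by."""


class InsufficientDataError(LiwgsError, ValueError):
    """Too few points for a statistic to be defined (e.g. DLRS on < 3 points)."""
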