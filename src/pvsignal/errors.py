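"""Exception hierarchy for pvsignal."""


class PvSignalError(Exception):
    """Base class for all pvsignal errors."""


class ConfigurationError(PvSignalError):
    """A configuration object violates its invariants (bad probability,
    unknown vocabulary entry, inverted date range, ...)."""


class LineListingError(PvSignalError):
    """A line-listing file could not be parsed; the message carries the
    1-based line number of the offending row."""


class IntegrityError(PvSignalError):
    """Inputs are mutually inconsistent: conflicting merges of the same
    report id, or signals computed against a different report universe."""
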