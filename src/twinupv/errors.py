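"""Exception hierarchy for twinupv."""


class TwinUPVError(Exception):
    """Base class for all twinupv errors."""


class ConfigurationError(TwinUPVError):
    """A configuration value violates its contract; the message names the field."""


class InsufficientDataError(TwinUPVError):
    """Too few pairs/individuals/points for the requested computation."""


class ConvergenceError(TwinUPVError):
    """An iterative fit failed to converge after all restarts."""
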