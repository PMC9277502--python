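"""Exception hierarchy shared across the package."""


class PlatformSimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PlatformSimError, ValueError):
    """An elicited parameter or distribution argument is out of range."""


class InsufficientDataError(PlatformSimError, ValueError):
    """Too few observations to compute the requested statistic."""


class InvalidDesignError(PlatformSimError, ValueError):
    """A trial design violates its structural constraints."""


class UndefinedTestError(PlatformSimError, ValueError):
    """A test statistic is undefined (e.g. zero log-rank variance)."""


class InvalidConfigError(PlatformSimError, ValueError):
    """A scenario or run configuration is malformed."""


class PairingError(PlatformSimError, ValueError):
    """Matched-iteration inputs cannot be paired."""


class ConsistencyError(PlatformSimError, ValueError):
    """Cost components from different realizations were mixed."""
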