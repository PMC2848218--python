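"""Exception hierarchy shared across the package."""


class FrontostriatalError(Exception):
    """Base class for all package errors."""


class DomainError(FrontostriatalError, ValueError):
    """An input lies outside the mathematically valid domain
    (negative concentration, occupancy outside [0, 1), ...)."""


class InfeasibleError(FrontostriatalError, ValueError):
    """The requested computation has no solution satisfying the
    physiological positivity constraints, or an observation is
    inconsistent with the stated depletion fraction."""
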