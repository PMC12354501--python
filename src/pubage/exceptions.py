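"""Exception hierarchy.

All user-facing errors derive from :class:`PubageError` so callers (and the
CLI) can catch one type; domain errors additionally derive from the matching
builtin so they behave idiomatically in plain-library use.
"""


class PubageError(Exception):
    """Base class for all errors raised by this package."""


class DomainError(PubageError, ValueError):
    """An argument is outside its scientific domain (e.g. non-positive age)."""


class InvalidModelError(PubageError, ValueError):
    """A transition model violates its invariants (unordered thresholds, sigma <= 0)."""


class DegenerateDataError(PubageError, ValueError):
    """The data cannot identify the model (e.g. fewer than two observed phases)."""


class EmptyPosteriorError(PubageError, ValueError):
    """The phase likelihood is identically zero on the prior support."""


class ConfigError(PubageError, ValueError):
    """A run configuration is invalid."""


class ConvergenceWarning(UserWarning):
    """Raised as a warning when the optimizer fails to report convergence."""
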