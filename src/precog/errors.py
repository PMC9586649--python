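"""Exception hierarchy for the package.

All errors derive from :class:`PrecogError` so callers can catch one type;
the subclasses distinguish user-facing failure classes (bad formula, bad
data, bad configuration) from internal invariant violations.
"""


class PrecogError(Exception):
    """Base class for all package errors."""


class ParseError(PrecogError, ValueError):
    """A design formula could not be parsed; names the offending token."""


class DesignError(PrecogError, ValueError):
    """A structurally invalid design (duplicate facets, cyclic nesting, ...)."""


class DataError(PrecogError, ValueError):
    """A score table that violates the balanced-design contract."""


class ConfigError(PrecogError, ValueError):
    """An invalid run configuration, plan, cost schedule or distribution."""


class UndefinedCoefficientError(PrecogError, ZeroDivisionError):
    """Object and error variance both zero: the coefficient is 0/0."""


class DominanceError(PrecogError, ZeroDivisionError):
    """ICER requested for plans with equal effectiveness (compare costs directly)."""


class InternalError(PrecogError, RuntimeError):
    """An invariant that should be unreachable was violated (e.g. singular EMS)."""


class PipelineError(PrecogError, RuntimeError):
    """A pipeline step failed; the message names the step."""
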