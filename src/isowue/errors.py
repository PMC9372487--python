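"""Exception hierarchy shared across the package."""


class IsoWueError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IsoWueError, ValueError):
    """An input value violates a field invariant (non-finite, out of bounds...)."""


class DomainError(IsoWueError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateConstantsError(IsoWueError, ValueError):
    """Discrimination constants make a formula degenerate (e.g. a == b)."""


class ConfigurationError(IsoWueError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class InapplicableTestError(IsoWueError, ValueError):
    """A statistical test cannot be applied to the given sample."""
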