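"""Exception hierarchy.

All package-raised errors derive from :class:`LueYieldError` so callers (and
the CLI) can separate validation failures from genuine runtime faults.
"""


class LueYieldError(Exception):
    """Base class for all errors raised by lueyield."""


class InvalidConfigError(LueYieldError, ValueError):
    """A configuration object violates its invariants."""


class InvalidInputError(LueYieldError, ValueError):
    """Input data violates a precondition (lengths, signs, ranges...)."""


class DomainError(InvalidInputError):
    """A numerical domain violation (division by zero, undefined ratio)."""


class SeasonIntegrityError(InvalidInputError):
    """Composites of a season overlap, gap, or fail to tile the window."""


class DegenerateDataError(InvalidInputError):
    """Data too degenerate to fit (constant column, < 2 distinct x...)."""


class DivergenceError(LueYieldError, RuntimeError):
    """Training produced a non-finite loss."""
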