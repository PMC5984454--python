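"""Exception hierarchy used across the package.

Every error raised on a user-facing path derives from :class:`RankCBRError`
so the CLI can map failures to a named class and a nonzero exit code.
"""


class RankCBRError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(RankCBRError, ValueError):
    """A cohort or peak specification violates its invariants."""


class ParseError(RankCBRError, ValueError):
    """A CSV cohort/feature file is malformed; the message names row/column."""


class CoverageError(RankCBRError, ValueError):
    """A thermogram grid does not cover the feature-extraction windows."""


class RetrievalError(RankCBRError, ValueError):
    """Retrieval asked for more neighbours than the case-base holds."""


class EstimationError(RankCBRError, ValueError):
    """Weight estimation received a degenerate training set (e.g. one class)."""


class ConvergenceError(RankCBRError, RuntimeError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class StratificationError(RankCBRError, ValueError):
    """Requested fold count exceeds the smaller class count."""


class ConfigError(RankCBRError, ValueError):
    """An experiment configuration names an unknown model or option."""
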