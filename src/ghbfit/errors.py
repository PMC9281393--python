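"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`GhbfitError`
so callers can catch the package's failures in one clause while letting
programming errors (``TypeError`` etc.) propagate.
"""


class GhbfitError(Exception):
    """Base class for all errors raised by ghbfit."""


class ClassificationError(GhbfitError):
    """Unknown residue or atom name during donor/acceptor classification."""


class ConfigurationError(GhbfitError):
    """Invalid switching-function or regularization configuration."""


class DimensionError(GhbfitError):
    """Mismatched array shapes between frames, pairs, weights or observables."""


class InputError(GhbfitError):
    """Invalid input values (negative distance, non-binary indicator, ...)."""


class NumericalError(GhbfitError):
    """Non-finite intermediate produced by a numerical routine."""


class SupportError(GhbfitError):
    """Posterior weight positive where the prior weight is zero."""


class ContractError(GhbfitError):
    """A precondition stated by the API (e.g. normalized weights) was violated."""


class ConvergenceError(GhbfitError):
    """Iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class FitError(GhbfitError):
    """All optimizer restarts failed."""


class SplitError(GhbfitError):
    """Too few frames, observable groups or systems for the requested CV split."""


class ProjectError(GhbfitError):
    """Project validation failed; ``problems`` lists every issue found."""

    def __init__(self, problems: list[str]):
        super().__init__("project validation failed:\n" + "\n".join(f"  - {p}" for p in problems))
        self.problems = list(problems)
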